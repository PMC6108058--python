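"""Complexity-entropy spectrum analysis of segmented process images.

Projected segmentation stacks are decomposed into local scale-orientation
features; the normalised band power at each pixel is a probability vector P
over N features.  Two information measures follow:

* relative entropy  H[P] = S[P] / S_max,  S the Shannon entropy (bits) and
  S_max = log2 N the entropy of the equiprobable distribution P_e;
* statistical complexity  C[P] = H[P] * J[P, P_e] / J_max,  with
  J[P, P_e] = S[(P + P_e)/2] - (S[P] + S[P_e])/2  the Jensen-Shannon
  divergence from P_e and J_max its value at a singular distribution
  (all probability on one feature).

Ordered patterns sit at low H / low C, pure noise at high H / low C, and
structured-but-heterogeneous patterns carry high C at intermediate H.  The
spectrum of a class of structures is summarised against the pooled median
complexity per entropy bin ("median curve"); the signed deviation of each
pixel from the curve is its excess complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.stats import gaussian_kde
from skimage.measure import block_reduce

from ._shearlet import ShearletTransform

#: pixels with total feature power below this are considered structureless
POWER_FLOOR = 1e-12
#: number of entropy bins of the median curve
N_ENTROPY_BINS = 51


# ----------------------------------------------------------------------
@dataclass
class FeatureProbabilityField:
    """Per-pixel probability vector over N scale-orientation features."""
    P: np.ndarray          # (N, H, W), normalised where mask is True
    mask: np.ndarray       # (H, W) pixels with any structure
    bands: list            # (scale, orientation) per feature

    @property
    def n_features(self):
        return self.P.shape[0]


@dataclass
class CEMap:
    H: np.ndarray          # relative entropy in [0, 1]
    C: np.ndarray          # statistical complexity in [0, 1]
    mask: np.ndarray

    def values(self):
        """(H, C) pairs of the unmasked pixels."""
        return self.H[self.mask], self.C[self.mask]


@dataclass
class CESpectrum:
    entropy_bin_edges: np.ndarray
    median_curve: np.ndarray            # spline-smoothed median C per bin centre
    median_raw: np.ndarray              # raw medians (NaN for empty bins)
    hist2d: dict = field(default_factory=dict)   # class -> (H, C) histogram
    excess: dict = field(default_factory=dict)   # class -> per-pixel excess C
    kde: dict = field(default_factory=dict)      # class -> KDE of the excess
    spline: object = None

    @property
    def entropy_bin_centers(self):
        e = self.entropy_bin_edges
        return 0.5 * (e[:-1] + e[1:])


# ----------------------------------------------------------------------
def project_stack(stack, downsample=2, mode="sum"):
    """Z-projection of a binary segmentation stack plus in-plane downsampling.

    The stack is summed (or averaged, ``mode='mean'``) along its first axis
    and block-averaged ``downsample`` times in X and Y; the result maps the
    local abundance of the segmented structure.
    """
    stack = np.asarray(stack)
    vals = np.unique(stack)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("segmentation stack must be binary (0/1)")
    img = stack.sum(axis=0, dtype=float)
    if mode == "mean":
        img /= stack.shape[0]
    elif mode != "sum":
        raise ValueError("mode must be 'sum' or 'mean'")
    if downsample and downsample > 1:
        img = block_reduce(img, (downsample, downsample), np.mean)
    return img


def feature_probabilities(image, n_scales=4, include_lowpass=False,
                          transform=None) -> FeatureProbabilityField:
    """Normalised local band power as per-pixel feature probabilities.

    The lowpass band encodes mean intensity rather than oriented structure
    and is excluded by default; pixels whose remaining total power falls
    below ``POWER_FLOOR`` (relative to the image mean power) are masked.
    """
    image = np.asarray(image, float)
    st = transform or ShearletTransform(image.shape, n_scales=n_scales)
    coeffs = st.transform(image)
    power = np.abs(coeffs) ** 2
    if include_lowpass:
        low = np.abs(st.lowpass_coefficients(image)) ** 2
        power = np.concatenate([power, low[None]], axis=0)
    total = power.sum(axis=0)
    scale = max(float(total.mean()), POWER_FLOOR)
    mask = total > POWER_FLOOR * scale
    P = np.where(mask[None], power / np.where(total == 0, 1.0, total)[None],
                 0.0)
    bands = list(st.bands) + ([("lowpass", 0)] if include_lowpass else [])
    return FeatureProbabilityField(P=P, mask=mask, bands=bands)


def _shannon_bits(P, axis=0):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(P > 0, P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    return -t.sum(axis=axis)


def entropy_map(F: FeatureProbabilityField) -> np.ndarray:
    """Relative entropy H = S[P] / log2 N per pixel (0 outside the mask)."""
    H = _shannon_bits(F.P) / np.log2(F.n_features)
    return np.where(F.mask, np.clip(H, 0.0, 1.0), 0.0)


def jsd_max(n: int) -> float:
    """J[P, P_e] for a singular P (one feature certain), in bits."""
    m = np.full(n, 1.0 / (2.0 * n))
    m[0] += 0.5
    return float(_shannon_bits(m) - 0.5 * np.log2(n))


def complexity_map(F: FeatureProbabilityField) -> np.ndarray:
    """Statistical complexity C = H * J / J_max per pixel."""
    n = F.n_features
    S = _shannon_bits(F.P)
    H = S / np.log2(n)
    M = 0.5 * (F.P + 1.0 / n)
    J = _shannon_bits(M) - 0.5 * (S + np.log2(n))
    C = H * J / jsd_max(n)
    return np.where(F.mask, np.clip(C, 0.0, 1.0), 0.0)


def ce_map(image, n_scales=4, transform=None) -> CEMap:
    """Entropy and complexity fields of one abundance image."""
    F = feature_probabilities(image, n_scales=n_scales, transform=transform)
    return CEMap(H=entropy_map(F), C=complexity_map(F), mask=F.mask)


# ----------------------------------------------------------------------
def ce_spectrum(maps: dict, n_entropy_bins=N_ENTROPY_BINS,
                n_hist_bins=64) -> CESpectrum:
    """Pooled median curve and per-class excess-complexity distributions.

    ``maps`` maps class names (e.g. 'leaflet', 'branchlet') to CEMap objects.
    All classes are pooled to compute the median complexity in each of
    ``n_entropy_bins`` entropy bins, smoothed by a cubic spline; the excess
    complexity of each pixel is its C minus the curve at its H.
    """
    if len(maps) < 1:
        raise ValueError("need at least one class map")
    for cls, m in maps.items():
        if not m.mask.any():
            raise ValueError(f"class {cls!r} has no unmasked pixels")
    Hs = np.concatenate([m.values()[0] for m in maps.values()])
    Cs = np.concatenate([m.values()[1] for m in maps.values()])
    edges = np.linspace(0.0, 1.0, n_entropy_bins + 1)
    idx = np.clip(np.digitize(Hs, edges) - 1, 0, n_entropy_bins - 1)
    med = np.full(n_entropy_bins, np.nan)
    for b in np.unique(idx):
        med[b] = np.median(Cs[idx == b])
    centers = 0.5 * (edges[:-1] + edges[1:])
    pop = np.isfinite(med)
    if pop.sum() >= 4:
        spline = UnivariateSpline(centers[pop], med[pop], k=3)
        curve = spline(centers)
    else:  # too few populated bins for a cubic: nearest-filled constant curve
        spline = None
        curve = np.where(pop, med, np.nanmedian(med))

    def curve_at(h):
        if spline is not None:
            return spline(h)
        return np.full_like(np.asarray(h, float), np.nanmedian(med))

    spec = CESpectrum(entropy_bin_edges=edges, median_curve=curve,
                      median_raw=med, spline=spline)
    for cls, m in maps.items():
        h, c = m.values()
        spec.hist2d[cls] = np.histogram2d(
            h, c, bins=n_hist_bins, range=[[0, 1], [0, 1]])[0]
        ex = c - curve_at(h)
        spec.excess[cls] = ex
        if len(ex) > 3 and np.std(ex) > 0:
            spec.kde[cls] = gaussian_kde(ex)  # Silverman-style bandwidth
    return spec


# ----------------------------------------------------------------------
def make_stripe_image(size=128, period=8):
    x = np.arange(size)
    return np.tile(((x // period) % 2).astype(float), (size, 1))


def stripe_toy(swap_fractions=(0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0,
                               12.0),
               size=128, period=8, seed=0, n_scales=4):
    """Entropy/complexity trajectory of a gradually corrupted stripe pattern.

    Starting from a regular stripe image, pixel values are swapped with
    random 4-neighbours; a swap fraction f performs ``f * n_pixels``
    (cumulative) swaps, so f > 1 means repeated sweeps of local mixing.
    Returns an array of (fraction, mean H, mean C) rows: entropy rises with
    corruption while complexity passes through a transient interior maximum
    before relaxing toward the fully shuffled limit.
    """
    rng = np.random.default_rng(seed)
    img = make_stripe_image(size, period)
    st = ShearletTransform(img.shape, n_scales=n_scales)
    fractions = np.sort(np.asarray(swap_fractions, float))
    n_pix = img.size
    rows = []
    done = 0
    for f in fractions:
        target = int(round(f * n_pix))
        n_new = max(target - done, 0)
        if n_new:
            ii = rng.integers(1, size - 1, n_new)
            jj = rng.integers(1, size - 1, n_new)
            di, dj = np.array([[0, 0, 1, -1], [1, -1, 0, 0]])
            pick = rng.integers(0, 4, n_new)
            for i, j, p in zip(ii, jj, pick):
                i2, j2 = i + di[p], j + dj[p]
                img[i, j], img[i2, j2] = img[i2, j2], img[i, j]
            done = target
        m = ce_map(img, transform=st)
        rows.append((f, float(m.H[m.mask].mean()), float(m.C[m.mask].mean())))
    return np.array(rows)
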