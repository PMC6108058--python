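"""Fourier-domain scale-orientation band decomposition (shearlet-style).

Tiles the 2D frequency plane into dyadic radial scales and, per scale, a set
of raised-cosine angular sectors (orientations modulo pi, doubling every
other scale, as in cone-adapted shearlet systems).  The squared band filters
plus the residual lowpass sum to one everywhere (a Parseval tight frame), so
band powers partition the local signal energy - the contract required for
treating normalised band power as feature probabilities.
"""

from __future__ import annotations

import numpy as np


def _smoothstep(x):
    """Meyer-type C^3 step: 0 below 0, 1 above 1."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)


class ShearletTransform:
    """Band-limited scale x orientation analysis of a fixed image shape.

    Parameters
    ----------
    shape : (H, W) of the images to analyse.
    n_scales : number of dyadic scales (finest to coarsest above the lowpass).
    n_orient_base : orientations of the coarsest scale; doubled every other
        scale (4, 8, 8, 16 for the defaults).

    Attributes
    ----------
    bands : list of (scale, orientation) tuples indexing the output planes;
        the lowpass residual is kept separately.
    """

    def __init__(self, shape, n_scales=4, n_orient_base=4):
        if min(shape) < 64:
            raise ValueError("image must be at least 64x64 for the band "
                             "decomposition")
        if 2 ** (n_scales + 1) > min(shape):
            raise ValueError(f"too many scales ({n_scales}) for shape {shape}")
        self.shape = tuple(shape)
        self.n_scales = n_scales
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.fftfreq(shape[1])[None, :]
        r = np.hypot(fy, fx)
        phi = np.mod(np.arctan2(fy, fx), np.pi)  # orientation modulo pi

        # radial partition of unity in log2 radius: lowpass + n_scales rings
        r_max = 0.5
        with np.errstate(divide="ignore"):
            ell = np.log2(np.maximum(r, 1e-12) / r_max)  # <= ~0.5 at corners
        knots = [-(n_scales - j) for j in range(n_scales)]  # -J .. -1
        rises = [_smoothstep((ell - (k - 1.0)) / 1.0) for k in knots]
        rises.append(np.zeros_like(ell))  # finest ring extends to the corners
        p_rad = [rises[j] - rises[j + 1] for j in range(n_scales)]
        p_low = 1.0 - rises[0]

        self.filters = []
        self.bands = []
        for j in range(n_scales):
            n_or = n_orient_base * 2 ** ((j + 1) // 2)
            delta = np.pi / n_or
            for k in range(n_or):
                c = (k + 0.5) * np.pi / n_or
                d = np.abs(phi - c)
                d = np.minimum(d, np.pi - d)  # wrap modulo pi
                q = np.where(d <= delta, np.cos(np.pi * d / (2 * delta)) ** 2,
                             0.0)
                self.filters.append(np.sqrt(p_rad[j] * q))
                self.bands.append((j, k))
        self.lowpass = np.sqrt(p_low)
        # DC belongs to the lowpass exactly
        self.lowpass[0, 0] = 1.0
        for f in self.filters:
            f[0, 0] = 0.0

    @property
    def n_bands(self):
        return len(self.filters)

    def frame_residual(self):
        """Max deviation of the squared-filter sum from 1 (tightness check)."""
        total = self.lowpass ** 2 + sum(f ** 2 for f in self.filters)
        return float(np.abs(total - 1.0).max())

    def transform(self, image):
        """Band coefficients, shape (n_bands, H, W), complex.

        Coefficients are essentially real for real input except on the
        unpaired Nyquist rows of even-sized grids; keeping them complex
        preserves the exact energy partition (use ``abs(c)**2`` as power).
        """
        image = np.asarray(image, float)
        if image.shape != self.shape:
            raise ValueError(f"image shape {image.shape} != transform shape "
                             f"{self.shape}")
        F = np.fft.fft2(image)
        out = np.empty((self.n_bands,) + self.shape, dtype=complex)
        for i, filt in enumerate(self.filters):
            out[i] = np.fft.ifft2(F * filt)
        return out

    def lowpass_coefficients(self, image):
        F = np.fft.fft2(np.asarray(image, float))
        return np.fft.ifft2(F * self.lowpass).real
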