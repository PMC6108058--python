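"""Plotting helpers for VF profiles, the complexity-entropy plane and the
radius sweep.  Kept thin: every function takes an optional Axes and returns
it, so figures compose in the usual matplotlib way."""

from __future__ import annotations

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_vf_profile(profile, ax=None, label=None, **kw):
    """Astrocyte VF vs distance with the binomial standard-error band."""
    ax = ax or plt.gca()
    x = profile.bin_centers
    ax.plot(x, profile.vf, label=label or profile.object_id, **kw)
    ok = np.isfinite(profile.vf)
    ax.fill_between(x[ok], (profile.vf - profile.vf_se)[ok],
                    (profile.vf + profile.vf_se)[ok], alpha=0.2)
    ax.set_xlabel("distance (μm)")
    ax.set_ylabel("astrocyte volume fraction")
    ax.set_ylim(0, None)
    return ax

def plot_ce_plane(spectrum, ax=None, classes=None, cmaps=("Reds", "Greens")):
    """2D (H, C) histograms per class with the pooled median curve."""
    ax = ax or plt.gca()
    classes = classes or list(spectrum.hist2d)
    for cls, cmap in zip(classes, cmaps):
        h = spectrum.hist2d[cls].T
        ax.imshow(np.log1p(h), origin="lower", extent=(0, 1, 0, 1),
                  aspect="auto", cmap=cmap, alpha=0.6)
    ax.plot(spectrum.entropy_bin_centers, spectrum.median_curve, "k-",
            lw=1.5, label="median curve")
    ax.set_xlabel("entropy H")
    ax.set_ylabel("complexity C")
    ax.legend()
    return ax

def plot_radius_sweep(df, ax=None):
    """Normalised peak open probabilities vs synapse radius."""
    ax = ax or plt.gca()
    for col, style in (("peak_po_glua_psd_norm", "r-o"),
                       ("peak_po_glua_extra_norm", "g-o"),
                       ("peak_po_glun_psd_norm", "r--s"),
                       ("peak_po_glun_extra_norm", "g--s")):
        if col in df:
            ax.plot(df["r"], df[col], style, label=col.replace("peak_po_", "")
                    .replace("_norm", ""))
    ax.set_xlabel("synapse radius (μm)")
    ax.set_ylabel("peak Po (normalised to smallest r)")
    ax.legend()
    return ax
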