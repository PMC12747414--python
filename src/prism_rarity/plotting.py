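"""Reference plots: FSH maps and Pnd histograms.

Minimal matplotlib renderings of the package's data products; callers
wanting publication figures should start from the exported tables
instead.
"""

from __future__ import annotations

import numpy as np

from .seqspace import FunctionalDensity, fsh_map_data

__all__ = ["plot_fsh_map", "plot_pnd_histogram"]


def plot_fsh_map(density: FunctionalDensity, boundaries=(), ax=None,
                 cmap: str = "inferno_r"):
    """Radial functional-sequence-heat map.

    Radius is Hamming distance n from the wildtype (origin); shade is
    the functional density PDF(n).  Target boundaries draw as rings.
    """
    import matplotlib.pyplot as plt

    table, rings = fsh_map_data(density, boundaries)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.linspace(0, 2 * np.pi, 181)
    r = table["n"].to_numpy(dtype=float)
    z = np.tile(table["pdf"].to_numpy()[:, None], (1, theta.size))
    ax.pcolormesh(theta, r, z, cmap=cmap, shading="auto")
    for ring in rings:
        ax.plot(theta, np.full_like(theta, ring["radius"]),
                lw=1.0, ls="--", color="tab:blue")
        ax.annotate(ring["label"], (0.0, ring["radius"]), fontsize=7)
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.set_title("functional sequence heat map")
    return ax


def plot_pnd_histogram(pnd_frame, g_th: float, ax=None, bins=10):
    """Histogram of per-protein non-destabilizing fractions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(pnd_frame["pnd"], bins=bins, range=(0, 1),
            color="grey", edgecolor="black")
    ax.set_xlabel(f"Pnd (cutoff {g_th:g} kcal/mol)")
    ax.set_ylabel("proteins")
    return ax
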