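"""Figure helpers: phasor histograms, landscape densities, delta histograms.

All functions draw on a provided axes (or create one) and return the
figure, so they compose with any matplotlib backend; callers save to
SVG/PNG as needed.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .calibration import EndpointPair  # noqa: E402
from .phasor import PhasorImage  # noqa: E402
from .profiles import PHProfile  # noqa: E402

__all__ = ["plot_phasor_histogram", "plot_landscape", "plot_delta_histogram"]


def plot_phasor_histogram(
    image: PhasorImage,
    endpoints: EndpointPair | None = None,
    bins: int = 200,
    ax=None,
):
    """2D phasor histogram with the universal semicircle and, optionally,
    the protonation endpoint segment (rainbow-coded as 0–100%)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sel = image.valid
    h = ax.hist2d(
        image.g[sel],
        image.s[sel],
        bins=bins,
        range=[[0, 1], [0, 0.7]],
        cmap="viridis",
        cmin=1,
    )
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k--", lw=0.8)
    if endpoints is not None:
        t = np.linspace(0, 1, 100)
        seg = endpoints.p0.as_array()[None, :] + t[:, None] * (
            endpoints.p100.as_array() - endpoints.p0.as_array()
        )
        ax.scatter(seg[:, 0], seg[:, 1], c=t, cmap="rainbow", s=4)
        ax.annotate("0%", endpoints.p0.as_array())
        ax.annotate("100%", endpoints.p100.as_array())
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.figure.colorbar(h[3], ax=ax, label="pixels")
    return ax.figure


def plot_landscape(profiles: list[PHProfile], value_label: str = "pH", ax=None):
    """Smoothed per-distance-bin densities, colored by the bin mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    nonempty = [p for p in profiles if p.smoothed_density is not None]
    if nonempty:
        means = [p.mean_value for p in nonempty]
        norm = plt.Normalize(min(means), max(means))
        cmap = plt.get_cmap("rainbow")
        for i, p in enumerate(nonempty):
            ax.plot(
                p.grid,
                p.smoothed_density + 1.2 * i,
                color=cmap(norm(p.mean_value)),
                label=f"d ∈ [{p.distance_bin[0]:.2f}, {p.distance_bin[1]:.2f})",
            )
        ax.legend(fontsize=7)
    ax.set_xlabel(value_label)
    ax.set_ylabel("density (offset per bin)")
    return ax.figure


def plot_delta_histogram(edges: np.ndarray, delta: np.ndarray, ax=None):
    """Per-%Protonation-bin granule count change, rainbow-coded by bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    centers = 0.5 * (edges[:-1] + edges[1:])
    cmap = plt.get_cmap("rainbow")
    ax.bar(centers, delta, width=edges[1] - edges[0], color=cmap(centers))
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("%Protonation")
    ax.set_ylabel("Δ count")
    return ax.figure
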