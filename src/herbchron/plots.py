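"""Minimal plotting helpers (response-surface heatmap, chronology)."""

from __future__ import annotations

from .chronology import Chronology
from .climate import ResponseSurface


def plot_response_surface(surface: ResponseSurface, path: str) -> None:
    """Heatmap of Pearson r over (start offset, window width)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    extent = (surface.offsets[0], surface.offsets[-1], surface.widths[0], surface.widths[-1])
    im = ax.imshow(
        surface.r,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
    )
    ax.axvline(365.5, color="k", lw=0.5, ls="--")  # previous-year / ring-year boundary
    ax.set_xlabel("window start (day 1 = Jan 1 of previous year)")
    ax.set_ylabel("window width (days)")
    ax.set_title(f"{surface.variable} ({surface.aggregation}), n = {surface.n_years} yr")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_chronology(chron: Chronology, path: str) -> None:
    """Z-scored chronology with sample depth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(chron.years, chron.zscore, color="seagreen", lw=1.5, label="chronology (z)")
    ax.axhline(0, color="gray", lw=0.5)
    ax2 = ax.twinx()
    ax2.fill_between(chron.years, chron.depth, color="lightgray", alpha=0.5, step="mid")
    ax2.set_ylabel("sample depth")
    ax.set_xlabel("year")
    ax.set_ylabel("ring-width index (z-score)")
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
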