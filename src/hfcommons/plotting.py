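"""Minimal, backend-free figure helpers for the two standard summaries."""

from __future__ import annotations

from matplotlib.figure import Figure

__all__ = ["sharing_histogram", "pathway_scatter"]


def sharing_histogram(profile) -> Figure:
    """Bar chart of the DEG-sharing profile (n comparisons vs gene count)."""
    fig = Figure(figsize=(7, 4))
    ax = fig.subplots()
    ax.bar(profile.counts.index, profile.counts.to_numpy(), color="#4472a8")
    for x, y in profile.counts.items():
        ax.text(x, y, str(int(y)), ha="center", va="bottom", fontsize=7)
    ax.set_xlabel("number of comparisons")
    ax.set_ylabel("number of DEGs")
    return fig


def pathway_scatter(coords, frequent=None) -> Figure:
    """Scatter of pathway consensus coordinates, consensus set highlighted."""
    fig = Figure(figsize=(5, 5))
    ax = fig.subplots()
    ax.scatter(coords["x"], coords["y"], s=12, c="#999999", label="all pathways")
    if frequent is not None:
        sel = coords.loc[coords.index.intersection(frequent)]
        ax.scatter(sel["x"], sel["y"], s=18, c="#c23b22", label="frequent")
        ax.legend(frameon=False, fontsize=8)
    lim = max(1.0, float(coords["x"].max() if len(coords) else 1.0))
    ax.plot([0, lim], [0, lim / 2], ls="--", c="#bbbbbb", lw=0.8)
    ax.plot([0, lim], [0, -lim / 2], ls="--", c="#bbbbbb", lw=0.8)
    ax.set_xlabel("up fraction + down fraction")
    ax.set_ylabel("up fraction - down fraction")
    return fig
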