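"""Bar-graph rendering of the consensus index with feature glyphs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .context_assign import Annotation  # noqa: E402

_STATE_COLORS = {"H": "#d62728", "B": "#1f77b4", "C": "#7f7f7f"}
_TURN_COLORS = {
    "I": "#2ca02c",
    "II": "#9467bd",
    "I'": "#8c564b",
    "II'": "#e377c2",
    "VIII": "#bcbd22",
}


def render_plot(ann: Annotation, consensus: list[int], path) -> None:
    """Deterministic vector rendering of the annotation.

    Consensus bars are coloured by 3-state call; helices/strands are drawn
    as glyph bands with edge strands outlined, turns as colour-coded
    markers and hairpins as brackets.
    """
    n = ann.n_residues
    fig, ax = plt.subplots(figsize=(max(6.0, n / 8.0), 3.2))
    xs = range(1, n + 1)
    colors = [_STATE_COLORS[s] for s in ann.states]
    ax.bar(xs, consensus, width=0.8, color=colors, linewidth=0)
    ax.axhline(0.0, color="black", linewidth=0.6)

    for lo, hi in _runs(ann.states, "H"):
        ax.add_patch(
            plt.Rectangle((lo - 0.5, 1.25), hi - lo + 1, 0.25,
                          color=_STATE_COLORS["H"], lw=0)
        )
    for topo in ann.strands:
        lo, hi = topo.span
        edge = topo.call == "edge"
        ax.add_patch(
            plt.Rectangle((lo - 0.5, 1.25), hi - lo + 1, 0.25,
                          facecolor=_STATE_COLORS["B"],
                          edgecolor="black" if edge else "none",
                          lw=1.2 if edge else 0)
        )
    for t in ann.turns:
        a, b = t.central
        ax.plot([a, b], [1.1, 1.1], color=_TURN_COLORS[t.turn_type], lw=2.5)
    for h in ann.hairpins:
        ax.plot(
            [h.strand1[0], h.strand2[1]], [1.65, 1.65],
            color="black", lw=0.9,
        )

    ax.set_xlim(0.5, n + 0.5)
    ax.set_ylim(-1.6, 1.9)
    ax.set_yticks([-1, 0, 1])
    ax.set_xlabel("residue")
    ax.set_ylabel("consensus index")
    fig.tight_layout()
    fig.savefig(Path(path), format="svg", metadata={"Date": None})
    plt.close(fig)


def _runs(states: str, which: str):
    start = None
    for i, s in enumerate(states + "\x00", 1):
        if s == which and start is None:
            start = i
        elif s != which and start is not None:
            yield (start, i - 1)
            start = None
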