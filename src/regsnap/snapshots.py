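"""Regulatory snapshot figures: per-time-point double-semicircle graphics.

A snapshot exposes the architecture of a regulatory module at one time
point: transcription factors sit on an outer top semicircle, left to right
in decreasing order of their diffusion score, the module's target genes on
a smaller bottom semicircle, and regulations are drawn as arcs between the
two semi-circumferences.  Orange arcs mark "regulates" relations; green
arcs mark the incoming ("regulated by") regulations of an explicitly
highlighted node set.  Rendering a snapshot per time point of a module
exposes how the relevance of each TF moves over the course of the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .biclustering import CCCBicluster
from .network import RegulatoryNetwork
from .tfrank import TimeSeriesRanking

ORANGE = "#e6842a"   # regulates
GREEN = "#4a9c42"    # regulated by (highlighted nodes' incoming edges)
NEUTRAL = "#b0b0b0"


@dataclass
class Snapshot:
    """Display-ready content of one regulatory snapshot."""

    module_id: int | None
    time_label: object
    tfs: list[tuple[str, float]]          # (tf, score), non-increasing score
    targets: list[str]
    arcs: list[tuple[str, str, str]]      # (source, sink, relation)
    top_k: int = 30
    highlight: frozenset = frozenset()

    def __post_init__(self) -> None:
        scores = [s for _, s in self.tfs]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("TF scores must be non-increasing left to right")
        shown = {t for t, _ in self.tfs} | set(self.targets)
        for u, v, _ in self.arcs:
            if u not in shown or v not in shown:
                raise ValueError(f"arc endpoint not displayed: {u} -> {v}")


def build_snapshot(
    b: CCCBicluster,
    ranking,
    net: RegulatoryNetwork,
    top_k: int = 30,
    highlight=(),
    score_threshold: float | None = None,
) -> Snapshot:
    """Select the displayed TFs, targets and arcs for one time point.

    ``ranking`` is a RankingVector (or its (tf, score, rank) triples).
    Complexity is controlled either by keeping the ``top_k`` best-scoring
    regulators (default 30) or, if ``score_threshold`` is given, those
    with score >= threshold.  Arcs are all network edges among displayed
    nodes; an arc is "regulated_by" when its sink is highlighted, else
    "regulates".
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    triples = getattr(ranking, "ranking", ranking)
    if not triples:
        raise ValueError("empty ranking: nothing to display")
    if score_threshold is not None:
        kept = [(name, score) for name, score, _ in triples if score >= score_threshold]
    else:
        kept = [(name, score) for name, score, _ in triples[:top_k]]
    if not kept:
        raise ValueError("no regulator passes the display threshold")
    targets = [g for g in (b.gene_ids or ()) if g in net]
    highlight = frozenset(highlight)
    shown_tfs = {name for name, _ in kept}
    shown = shown_tfs | set(targets)
    arcs: list[tuple[str, str, str]] = []
    for u, v, _w in net.edges():
        if u in shown_tfs and v in shown:
            rel = "regulated_by" if v in highlight else "regulates"
            arcs.append((u, v, rel))
    arcs.sort()
    return Snapshot(
        module_id=b.id,
        time_label=getattr(ranking, "time_point", None),
        tfs=kept,
        targets=list(targets),
        arcs=arcs,
        top_k=top_k,
        highlight=highlight,
    )


# -- layout -------------------------------------------------------------

def _semicircle_positions(
    names, cx: float, cy: float, radius: float, upper: bool
) -> dict[str, tuple[float, float]]:
    """Evenly angle-spaced positions on a semicircle, left to right."""
    n = len(names)
    pos = {}
    for i, name in enumerate(names):
        theta = math.pi * (1 - (i + 1) / (n + 1))  # pi -> 0, left to right
        x = cx + radius * math.cos(theta)
        dy = radius * math.sin(theta)
        y = cy - dy if upper else cy + dy
        pos[name] = (round(x, 3), round(y, 3))
    return pos


def render_svg(s: Snapshot, path: str | Path, width: int = 900) -> Path:
    """Write the snapshot as a standalone SVG 1.1 file (deterministic bytes).

    Top semicircle radius is 1.25x the bottom one; TF x-positions follow
    the score order exactly.  Arcs are cubic Beziers pulled toward the
    center.
    """
    path = Path(path)
    cx = width / 2
    r_bottom = width * 0.30
    r_top = 1.25 * r_bottom
    cy = r_top + 60
    height = int(cy + r_bottom + 80)

    tf_names = [name for name, _ in s.tfs]
    pos = _semicircle_positions(tf_names, cx, cy, r_top, upper=True)
    pos.update(_semicircle_positions(s.targets, cx, cy, r_bottom, upper=False))

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">',
        f'<title>module {s.module_id} snapshot at {s.time_label}</title>',
        f'<text x="{cx}" y="24" text-anchor="middle" font-size="16" '
        f'font-family="sans-serif">module {s.module_id} — time {s.time_label}</text>',
    ]
    for u, v, rel in s.arcs:
        (x1, y1), (x2, y2) = pos[u], pos[v]
        color = GREEN if rel == "regulated_by" else ORANGE
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        c1x, c1y = round((x1 + mx) / 2, 3), round((y1 + cy) / 2, 3)
        c2x, c2y = round((x2 + mx) / 2, 3), round((y2 + cy) / 2, 3)
        lines.append(
            f'<path d="M {x1} {y1} C {c1x} {c1y}, {c2x} {c2y}, {x2} {y2}" '
            f'fill="none" stroke="{color}" stroke-width="1.2" opacity="0.7"/>'
        )
    for name, score in s.tfs:
        x, y = pos[name]
        fill = "#2a5fe6" if name in s.highlight else "#444444"
        lines.append(f'<circle cx="{x}" cy="{y}" r="6" fill="{fill}" class="tf"/>')
        lines.append(
            f'<text x="{x}" y="{y - 10}" text-anchor="middle" font-size="10" '
            f'font-family="sans-serif" '
            f'transform="rotate(-45 {x} {y - 10})">{name} ({score:.3g})</text>'
        )
    for name in s.targets:
        x, y = pos[name]
        fill = "#2a5fe6" if name in s.highlight else "#777777"
        lines.append(f'<circle cx="{x}" cy="{y}" r="4" fill="{fill}" class="target"/>')
        lines.append(
            f'<text x="{x}" y="{y + 16}" text-anchor="middle" font-size="9" '
            f'font-family="sans-serif" '
            f'transform="rotate(45 {x} {y + 16})">{name}</text>'
        )
    lines.append("</svg>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def render_series(
    rankings: TimeSeriesRanking,
    b: CCCBicluster,
    net: RegulatoryNetwork,
    out_dir: str | Path,
    top_k: int = 30,
    highlight=(),
) -> list[Path]:
    """One SVG per non-skipped time point, plus a rank-trajectory TSV.

    A TF keeps its label across frames; only its position and score change.
    Files are named ``module_<id>_t<label>.svg``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label in rankings.time_labels:
        if label not in rankings.rankings:
            continue
        snap = build_snapshot(b, rankings.rankings[label], net,
                              top_k=top_k, highlight=highlight)
        written.append(
            render_svg(snap, out_dir / f"module_{b.id}_t{label}.svg")
        )
    _write_trajectory(rankings, out_dir / f"module_{b.id}_rank_trajectory.tsv")
    return written


def _write_trajectory(rankings: TimeSeriesRanking, path: Path) -> None:
    """TF x time matrix of ranks for every TF seen in any frame."""
    labels = [t for t in rankings.time_labels if t in rankings.rankings]
    tfs = sorted({name for t in labels for name, _, _ in rankings.rankings[t].ranking})
    with path.open("w", encoding="utf-8") as fh:
        fh.write("tf\t" + "\t".join(str(t) for t in labels) + "\n")
        for tf in tfs:
            ranks = [str(rankings.rankings[t].rank_of(tf)) for t in labels]
            fh.write(tf + "\t" + "\t".join(ranks) + "\n")
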