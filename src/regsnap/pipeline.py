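"""End-to-end orchestration: expression + network in, regulatory modules out.

Stages: read -> filter missing -> normalize -> discretize -> stamp ->
enumerate maximal CCC-biclusters -> score/filter -> (optional) enrichment
-> per-time-point TF ranking -> snapshot SVGs.  Every stage logs its
input/output cardinalities and the run manifest echoes the configuration,
package version and stage counts, so two runs with identical inputs are
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .biclustering import (
    biclusters_to_records,
    build_generalized_suffix_tree,
    enumerate_maximal_ccc_biclusters,
)
from .expression import (
    discretize_transitions,
    filter_missing,
    normalize_by_gene,
    read_expression_tsv,
    transform_alphabet,
    write_discretized_tsv,
)
from .network import read_edge_list
from .significance import (
    enrichment_to_tsv,
    filter_biclusters,
    hypergeometric_enrichment,
    read_annotations_tsv,
    score_biclusters,
)
from .snapshots import render_series
from .tfrank import DiffusionParams, rank_module_over_time, rankings_to_tsv

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunables of a run; defaults follow the method's parameterization.

    tau = 0 discretization threshold; pattern p-value cutoff 0.01
    (Bonferroni-corrected); overlap Jaccard cutoff 0.25; diffusion t = 0.25
    over Z = 100 iterations; snapshots keep the top 30 regulators.
    """

    expression: str = ""
    network: str = ""
    annotations: str | None = None
    out_dir: str = "regsnap_out"
    tau: float = 0.0
    p_cut: float = 0.01
    jac_cut: float = 0.25
    min_genes: int = 2
    min_timepoints: int = 2
    t: float = 0.25
    Z: int = 100
    top_k: int = 30
    use_absolute: bool = True
    max_modules: int | None = None
    render: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for name in ("p_cut", "jac_cut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.min_timepoints < 2:
            raise ValueError("min_timepoints must be >= 2")
        DiffusionParams(self.t, self.Z)  # validates t, Z
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    biclusters: list
    kept: list
    rankings: dict = field(default_factory=dict)     # module id -> TimeSeriesRanking
    enrichment: dict = field(default_factory=dict)   # module id -> results
    manifest: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full method; writes all outputs under cfg.out_dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    expr = _stage("read_expression")(read_expression_tsv)(cfg.expression)
    counts["genes_read"] = expr.n_genes
    counts["timepoints"] = expr.n_timepoints
    expr = _stage("filter_missing")(filter_missing)(expr)
    counts["genes_complete"] = expr.n_genes
    expr = _stage("normalize")(normalize_by_gene)(expr)
    counts["genes_normalized"] = expr.n_genes
    d = _stage("discretize")(discretize_transitions)(expr, cfg.tau)
    write_discretized_tsv(d, out_dir / "discretized.tsv")

    net = _stage("read_network")(read_edge_list)(cfg.network)
    counts["network_vertices"] = net.n_vertices
    counts["network_edges"] = net.n_edges
    counts["network_regulators"] = len(net.regulators)

    rows = _stage("transform_alphabet")(transform_alphabet)(d)
    tree = _stage("suffix_tree")(build_generalized_suffix_tree)(rows)
    bs = _stage("enumerate")(enumerate_maximal_ccc_biclusters)(tree, d)
    counts["maximal_biclusters"] = len(bs)
    bs = _stage("score")(score_biclusters)(bs, d)
    kept = _stage("filter")(filter_biclusters)(
        bs, cfg.p_cut, cfg.jac_cut, cfg.min_genes, cfg.min_timepoints
    )
    counts["filtered_biclusters"] = len(kept)
    if cfg.max_modules is not None:
        kept = kept[: cfg.max_modules]
    counts["modules_analyzed"] = len(kept)

    (out_dir / "biclusters.json").write_text(
        json.dumps(biclusters_to_records(kept), indent=1) + "\n", encoding="utf-8"
    )
    with (out_dir / "biclusters.tsv").open("w", encoding="utf-8") as fh:
        fh.write("id\tn_genes\tc_start\tc_end\tpattern\tpvalue\tcorrected_pvalue\tgenes\n")
        for b in kept:
            fh.write(
                f"{b.id}\t{b.n_genes}\t{b.c_start}\t{b.c_end}\t"
                f"{''.join(b.pattern)}\t{b.pvalue!r}\t{b.corrected_pvalue!r}\t"
                f"{','.join(b.gene_ids)}\n"
            )

    result = PipelineResult(biclusters=bs, kept=kept, out_dir=out_dir)

    annotations = None
    if cfg.annotations:
        annotations = _stage("read_annotations")(read_annotations_tsv)(cfg.annotations)
    background = set(expr.gene_ids)

    params = DiffusionParams(cfg.t, cfg.Z)
    ranking_rows: list[tuple] = []
    for b in kept:
        ts = _stage("rank")(rank_module_over_time)(
            b, expr, net, params, cfg.use_absolute
        )
        result.rankings[b.id] = ts
        ranking_rows.extend(ts.tsv_rows())
        if annotations is not None:
            res = _stage("enrich")(hypergeometric_enrichment)(
                set(b.gene_ids) & background, annotations, background
            )
            result.enrichment[b.id] = res
        if cfg.render:
            _stage("snapshots")(render_series)(
                ts, b, net, out_dir / "snapshots", top_k=cfg.top_k
            )
    with (out_dir / "rankings.tsv").open("w", encoding="utf-8") as fh:
        fh.write("module\ttime\trank\tregulator\tscore\n")
        for mod, t, rank, name, score in ranking_rows:
            fh.write(f"{mod}\t{t}\t{rank}\t{name}\t{score!r}\n")
    if annotations is not None:
        for mid, res in result.enrichment.items():
            enrichment_to_tsv(res, out_dir / f"enrichment_module_{mid}.tsv")
    counts["rankings_written"] = len(ranking_rows)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "counts": counts,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    result.manifest = manifest
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return result
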