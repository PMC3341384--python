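"""Heat-kernel personalized ranking of transcription factors over time.

For a transcriptional module (bicluster) at one time point, the preference
vector ``p_0`` places mass on the module's genes proportional to their
expression magnitude at that time point.  That mass is diffused over the
*transposed* regulatory network — regulations traversed in reverse, so a
target's mass splits among its regulators — with the discrete heat-kernel
update

    p <- p (I - (t/Z)(I - W))      repeated Z times,

where ``W`` is the row-normalized random-walk matrix of the transposed
graph and ``L = I - W`` its walk Laplacian.  As ``Z`` grows this converges
to ``p_0 expm(-t L)``, the heat-kernel rank.  The diffusion coefficient
``t`` trades off preference for proximal versus distal regulators; the
defaults ``t = 0.25`` and ``Z = 100`` moderately favor proximal ones.
Scores restricted to the regulator set give one TF ranking per time point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .biclustering import CCCBicluster
from .expression import ExpressionMatrix
from .network import RegulatoryNetwork, transition_matrix, transpose

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionParams:
    """Heat diffusion coefficient t >= 0 and iteration count Z >= 1."""

    t: float = 0.25
    Z: int = 100

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"heat diffusion coefficient must be >= 0, got {self.t}")
        if self.Z < 1:
            raise ValueError(f"iteration count must be >= 1, got {self.Z}")
        if self.t / self.Z > 1:
            warnings.warn(
                f"t/Z = {self.t / self.Z:.3g} > 1: the diffusion update may leave "
                "the non-negative simplex",
                stacklevel=2,
            )


@dataclass
class PreferenceVector:
    """Initial mass p_0 over the network's vertex ordering."""

    p0: np.ndarray
    seeds: list[str]
    excluded: list[str]
    time_point: object = None

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if (self.p0 < 0).any():
            raise ValueError("preference vector entries must be non-negative")
        if not self.p0.any():
            raise ValueError("preference vector is all-zero (no usable seed genes)")


@dataclass
class RankingVector:
    """Diffused scores over all vertices plus the regulator-only ranking."""

    scores: np.ndarray
    ranking: list[tuple[str, float, int]]  # (regulator, score, rank), rank from 1
    time_point: object = None

    def rank_of(self, regulator: str) -> int | None:
        for name, _, rank in self.ranking:
            if name == regulator:
                return rank
        return None

    def score_of(self, regulator: str) -> float | None:
        for name, score, _ in self.ranking:
            if name == regulator:
                return score
        return None


@dataclass
class TimeSeriesRanking:
    """One regulator ranking per (non-skipped) time point of a module."""

    module_id: int | None
    time_labels: list
    rankings: dict = field(default_factory=dict)  # time label -> RankingVector
    skipped: list = field(default_factory=list)

    def tsv_rows(self) -> list[tuple]:
        rows = []
        for t in self.time_labels:
            if t not in self.rankings:
                continue
            for name, score, rank in self.rankings[t].ranking:
                rows.append((self.module_id, t, rank, name, score))
        return rows


def build_preference_vector(
    module_genes,
    expr: ExpressionMatrix,
    time_point,
    net: RegulatoryNetwork,
    use_absolute: bool = True,
) -> PreferenceVector:
    """Seed p_0 with the module genes' expression at one time point.

    With ``use_absolute`` (the default) the magnitude |e(u)| is used, since
    diffused scores are additive and sign would cancel mass; otherwise
    negative values are clipped to zero.  Module genes absent from the
    network cannot receive mass and are recorded as excluded.
    """
    if time_point not in expr.time_labels:
        raise ValueError(f"unknown time point: {time_point!r}")
    j = expr.time_labels.index(time_point)
    p0 = np.zeros(net.n_vertices)
    seeds: list[str] = []
    excluded: list[str] = []
    for g in module_genes:
        if g not in net:
            excluded.append(g)
            continue
        e = expr.values[expr.gene_ids.index(g), j]
        p0[net.index_of(g)] = abs(e) if use_absolute else max(e, 0.0)
        seeds.append(g)
    if excluded:
        logger.warning(
            "build_preference_vector: %d module gene(s) absent from the network "
            "and excluded: %s", len(excluded), ", ".join(sorted(excluded)[:10]),
        )
    return PreferenceVector(p0=p0, seeds=seeds, excluded=sorted(excluded),
                            time_point=time_point)


def heat_kernel_diffuse(
    p0: PreferenceVector | np.ndarray,
    W: sp.spmatrix | np.ndarray,
    params: DiffusionParams = DiffusionParams(),
) -> RankingVector | np.ndarray:
    """Apply Z discrete heat-kernel steps p <- (1 - t/Z) p + (t/Z) p W.

    ``p`` is a row vector multiplied on the right by the transition matrix
    of the (already transposed) graph.  With t/Z <= 1 all entries stay
    non-negative; with a fully stochastic W total mass is conserved.
    Returns a bare array when given a bare array.
    """
    vec = p0.p0 if isinstance(p0, PreferenceVector) else np.asarray(p0, dtype=float)
    n = W.shape[0]
    if vec.shape != (n,):
        raise ValueError(f"vector length {vec.shape} does not match W ({n}x{n})")
    alpha = params.t / params.Z
    p = vec.copy()
    for _ in range(params.Z):
        p = (1.0 - alpha) * p + alpha * (p @ W)
    p = np.asarray(p).ravel()
    if isinstance(p0, PreferenceVector):
        return RankingVector(scores=p, ranking=[], time_point=p0.time_point)
    return p


def rank_regulators(p: RankingVector, net: RegulatoryNetwork) -> RankingVector:
    """Restrict diffused scores to the regulator set of the ORIGINAL network.

    Sorted descending by score; ties broken lexicographically by gene id.
    Ranks start at 1.  Returns the same RankingVector with its ranking
    filled in.
    """
    regs = net.regulators
    if not regs:
        raise ValueError("network has no regulators (no vertex with outgoing edges)")
    scored = sorted(
        ((r, float(p.scores[net.index_of(r)])) for r in regs),
        key=lambda x: (-x[1], x[0]),
    )
    p.ranking = [(name, score, i + 1) for i, (name, score) in enumerate(scored)]
    return p


def rank_module_over_time(
    b: CCCBicluster,
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    params: DiffusionParams = DiffusionParams(),
    use_absolute: bool = True,
    skip_empty: bool = True,
) -> TimeSeriesRanking:
    """One TF ranking per original time point spanned by the bicluster.

    The transition interval [c_start, c_end] covers time points c_start
    through c_end + 1.  Diffusion runs on the transposed network; a time
    point whose preference vector has no usable seeds is skipped with a
    warning (or raises, with ``skip_empty=False``).
    """
    t_first, t_last = b.time_span
    if t_last > expr.n_timepoints:
        raise ValueError("bicluster time span exceeds the expression matrix")
    labels = [expr.time_labels[t - 1] for t in range(t_first, t_last + 1)]
    W_rev = transition_matrix(transpose(net))
    result = TimeSeriesRanking(module_id=b.id, time_labels=labels)
    genes = b.gene_ids if b.gene_ids else tuple(expr.gene_ids[g] for g in b.rows)
    for label in labels:
        try:
            p0 = build_preference_vector(genes, expr, label, net, use_absolute)
        except ValueError:
            if skip_empty:
                logger.warning(
                    "module %s: no usable seeds at time point %r; skipped",
                    b.id, label,
                )
                result.skipped.append(label)
                continue
            raise
        pt = heat_kernel_diffuse(p0, W_rev, params)
        result.rankings[label] = rank_regulators(pt, net)
    return result


def rankings_to_tsv(ts: TimeSeriesRanking, path) -> None:
    """Write `module<TAB>time<TAB>rank<TAB>regulator<TAB>score` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module\ttime\trank\tregulator\tscore\n")
        for mod, t, rank, name, score in ts.tsv_rows():
            fh.write(f"{mod}\t{t}\t{rank}\t{name}\t{score!r}\n")
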