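"""Seeded synthetic data with planted modules and dominant regulators.

The generator emulates the structure the method assumes so that every
stage is testable without external datasets: expression matrices in which
a chosen set of genes follows a common real-valued trajectory whose
transition discretization reproduces a requested U/D/N pattern over a
contiguous column interval, and regulatory networks in which one planted
TF covers an entire module against sparse background regulation.  All
randomness flows from one explicit seed; ground truth is recorded so
recovery can be re-verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expression import SIGMA, ExpressionMatrix
from .network import RegulatoryNetwork


@dataclass
class PlantedModule:
    genes: tuple[str, ...]
    gene_indices: tuple[int, ...]
    c_start: int
    c_end: int
    pattern: tuple[str, ...]


@dataclass
class PlantedTruth:
    """Ground-truth record sufficient to re-verify recovery."""

    modules: list[PlantedModule] = field(default_factory=list)
    regulator_wiring: dict[str, tuple[str, ...]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


# step size for planted trajectories: tau plus a noise margin so the
# requested pattern survives discretization under additive noise
def _step(sym: str, tau: float, margin: float) -> float:
    if sym == "U":
        return tau + margin
    if sym == "D":
        return -(tau + margin)
    return 0.0


def generate_planted_expression(
    n_genes: int,
    n_timepoints: int,
    modules,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau: float = 0.0,
    margin: float | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with planted CCC-bicluster patterns.

    ``modules`` is a list of ``(size, (c_start, c_end), pattern)`` with a
    U/D/N symbol per transition column of the contiguous 1-based interval.
    Background values are i.i.d. standard normal; planted rows follow a
    cumulative-sum trajectory with per-transition steps of magnitude
    ``tau + margin`` (margin defaults to ``max(3 * noise_sd, 0.5)``), plus
    Gaussian noise of sd ``noise_sd``, so discretization at ``tau``
    recovers the requested pattern with margin to spare.  Deterministic
    under ``seed``.  Genes are assigned to modules in order: module m
    occupies a fresh block of rows.
    """
    rng = np.random.default_rng(seed)
    if margin is None:
        margin = max(3.0 * noise_sd, 0.5)
    n_cols = n_timepoints - 1
    values = rng.standard_normal((n_genes, n_timepoints))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    truth = PlantedTruth(params={
        "n_genes": n_genes, "n_timepoints": n_timepoints,
        "noise_sd": noise_sd, "seed": seed, "tau": tau, "margin": margin,
    })
    next_row = 0
    for size, (c_start, c_end), pattern in modules:
        pattern = tuple(pattern)
        if size < 2:
            raise ValueError("planted module size must be >= 2")
        if not (1 <= c_start <= c_end <= n_cols):
            raise ValueError(
                f"interval [{c_start}, {c_end}] outside 1..{n_cols}"
            )
        if len(pattern) != c_end - c_start + 1:
            raise ValueError("pattern length does not match the column interval")
        if any(s not in SIGMA for s in pattern):
            raise ValueError(f"pattern symbols must be in {SIGMA}")
        if next_row + size > n_genes:
            raise ValueError("planted modules need more rows than n_genes provides")
        rows = range(next_row, next_row + size)
        # one shared trajectory over the planted interval, offset per gene;
        # outside the interval each gene continues as a unit-variance random
        # walk from the interval's endpoints, so the transitions adjacent to
        # the planted window are independent fair coin flips per gene rather
        # than a shared bias leaking the module into neighboring columns
        base = np.cumsum([0.0] + [_step(s, tau, margin) for s in pattern])
        for g in rows:
            offset = rng.standard_normal()
            traj = base + offset + rng.normal(0.0, noise_sd, size=base.shape)
            values[g, c_start - 1 : c_end + 1] = traj
            for j in range(c_start - 2, -1, -1):  # walk back before the window
                values[g, j] = values[g, j + 1] - rng.standard_normal()
            for j in range(c_end + 1, n_timepoints):  # and forward after it
                values[g, j] = values[g, j - 1] + rng.standard_normal()
        truth.modules.append(PlantedModule(
            genes=tuple(gene_ids[g] for g in rows),
            gene_indices=tuple(rows),
            c_start=c_start,
            c_end=c_end,
            pattern=pattern,
        ))
        next_row += size
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        time_labels=[f"t{j}" for j in range(1, n_timepoints + 1)],
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )
    return expr, truth


def generate_planted_network(
    n_tfs: int,
    n_targets: int,
    planted: tuple[str, tuple[str, ...]] | None = None,
    background_p: float = 0.05,
    seed: int = 0,
    target_ids=None,
    max_background_coverage: float | None = None,
) -> tuple[RegulatoryNetwork, PlantedTruth]:
    """Regulatory network with one planted dominant regulator.

    The planted TF gets a weight-1 edge to every gene of its target set;
    each background TF -> target edge appears independently with
    probability ``background_p``.  With ``max_background_coverage`` set,
    background TFs are additionally capped to that fraction of the planted
    target set, guaranteeing the planted TF's dominance by construction.
    Deterministic under ``seed``.
    """
    if not (0.0 <= background_p <= 1.0):
        raise ValueError(f"background_p must be in [0, 1], got {background_p}")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tfs)]
    if target_ids is None:
        target_ids = [f"G{i:04d}" for i in range(n_targets)]
    else:
        target_ids = list(target_ids)
        if len(target_ids) != n_targets:
            raise ValueError("target_ids length must equal n_targets")
    g = nx.DiGraph()
    order = tf_ids + target_ids
    g.add_nodes_from(order)
    truth = PlantedTruth(params={
        "n_tfs": n_tfs, "n_targets": n_targets,
        "background_p": background_p, "seed": seed,
    })
    planted_tf, planted_targets = (None, frozenset())
    if planted is not None:
        planted_tf, targets = planted
        planted_targets = frozenset(targets)
        if not planted_targets <= set(target_ids):
            raise ValueError("planted target set must be a subset of the targets")
        for v in sorted(planted_targets):
            g.add_edge(planted_tf, v, weight=1.0)
        if planted_tf not in order:
            order.insert(0, planted_tf)
        truth.regulator_wiring[planted_tf] = tuple(sorted(planted_targets))
    cap = (
        None if max_background_coverage is None or planted is None
        else int(max_background_coverage * len(planted_targets))
    )
    for tf in tf_ids:
        if tf == planted_tf:
            continue
        hits = [v for v in target_ids if rng.random() < background_p]
        if cap is not None:
            in_module = [v for v in hits if v in planted_targets]
            if len(in_module) > cap:
                drop = set(rng.choice(in_module, size=len(in_module) - cap,
                                      replace=False))
                hits = [v for v in hits if v not in drop]
        for v in hits:
            g.add_edge(tf, v, weight=1.0)
        if hits:
            truth.regulator_wiring[tf] = tuple(hits)
    return RegulatoryNetwork(graph=g, vertex_order=order), truth
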