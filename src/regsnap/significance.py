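"""Bicluster significance, overlap filtering and annotation enrichment.

The pattern p-value asks how surprising a bicluster is: under a null model
in which each transition column draws symbols independently from its
empirical frequencies, a random gene matches pattern ``P`` over columns
``J`` with probability ``p(P) = prod_c f_c(P_c)``, and the p-value is the
binomial upper tail ``P(X >= |I|)`` for ``X ~ Binomial(n_genes, p(P))`` —
the chance that at least as many genes would share the pattern in a matrix
of equal size.  Pattern p-values are Bonferroni-corrected over the family
of enumerated biclusters; heavily overlapping biclusters (cell-wise
Jaccard above a cutoff) are reduced to the most significant one.
Annotation enrichment uses the hypergeometric upper tail with Bonferroni
correction over tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .biclustering import CCCBicluster
from .expression import SIGMA, DiscretizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class PatternNullModel:
    """Per-column empirical symbol frequencies of a discretized matrix."""

    freqs: np.ndarray  # shape (n_columns, len(SIGMA)), rows sum to 1

    @classmethod
    def from_matrix(cls, d: DiscretizedMatrix) -> "PatternNullModel":
        n_cols = d.n_transition_columns
        freqs = np.zeros((n_cols, len(SIGMA)))
        for c in range(n_cols):
            col = d.symbols[:, c]
            for s, sym in enumerate(SIGMA):
                freqs[c, s] = np.mean(col == sym)
        return cls(freqs=freqs)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("per-column symbol frequencies must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]

    def pattern_probability(self, pattern, c_start: int) -> float:
        """Probability that one random gene shows ``pattern`` from column c_start."""
        p = 1.0
        for k, sym in enumerate(pattern):
            c = c_start + k
            if not (1 <= c <= self.n_columns):
                raise ValueError(f"column {c} outside the model's {self.n_columns}")
            p *= self.freqs[c - 1, SIGMA.index(sym)]
        return p


@dataclass
class EnrichmentResult:
    term: str
    k: int        # overlap between module and term
    K: int        # term size within the background
    n: int        # module size
    N_bg: int     # background size
    pvalue: float
    corrected_pvalue: float

    @property
    def highly_significant(self) -> bool:
        return self.corrected_pvalue < 0.01


def pattern_pvalue(b: CCCBicluster, model: PatternNullModel, n_genes: int) -> float:
    """Upper-tail probability that >= |I| of ``n_genes`` random rows match.

    Evaluated with the binomial survival function for numerical stability;
    a pattern containing a zero-frequency symbol has match probability 0
    and hence p-value 0 (it could never occur by chance under the model).
    """
    q = model.pattern_probability(b.pattern, b.c_start)
    if q == 0.0:
        logger.info("pattern with zero null probability: p-value 0")
        return 0.0
    return float(stats.binom.sf(b.n_genes - 1, n_genes, q))


def bonferroni(pvals, m: int) -> list[float]:
    """Multiply by the number of tests m and cap at 1; order preserved."""
    pvals = list(pvals)
    if m < len(pvals):
        raise ValueError(f"m = {m} is smaller than the number of p-values {len(pvals)}")
    out = []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def jaccard_similarity(a: CCCBicluster, b: CCCBicluster) -> float:
    """Cell-wise Jaccard: overlap of the (gene, column) cell sets."""
    ca, cb = a.cells(), b.cells()
    union = len(ca | cb)
    return len(ca & cb) / union if union else 0.0


def score_biclusters(
    bs: list[CCCBicluster], d: DiscretizedMatrix
) -> list[CCCBicluster]:
    """Attach raw and Bonferroni-corrected pattern p-values in place.

    The correction factor is the number of enumerated maximal biclusters —
    the family of tests actually performed.
    """
    model = PatternNullModel.from_matrix(d)
    raw = [pattern_pvalue(b, model, d.n_genes) for b in bs]
    corrected = bonferroni(raw, max(len(bs), 1))
    for b, p, cp in zip(bs, raw, corrected):
        b.pvalue = p
        b.corrected_pvalue = cp
    return bs


def filter_biclusters(
    bs: list[CCCBicluster],
    p_cut: float = 0.01,
    jac_cut: float = 0.25,
    min_genes: int = 2,
    min_timepoints: int = 2,
) -> list[CCCBicluster]:
    """Significance, size and overlap filtering.

    Drops biclusters with corrected p above ``p_cut``, fewer than
    ``min_genes`` genes or spanning fewer than ``min_timepoints`` time
    points; then scans survivors in ascending corrected-p order, discarding
    any bicluster whose cell Jaccard with an already-kept one exceeds
    ``jac_cut`` (the more significant member of an overlapping pair wins).
    """
    survivors = [
        b for b in bs
        if (b.corrected_pvalue is not None and b.corrected_pvalue <= p_cut)
        and b.n_genes >= min_genes
        and b.n_timepoints >= min_timepoints
    ]
    survivors.sort(key=lambda b: (b.corrected_pvalue, -b.area, b.c_start, b.rows))
    kept: list[CCCBicluster] = []
    for b in survivors:
        if all(jaccard_similarity(b, k) <= jac_cut for k in kept):
            kept.append(b)
    logger.info(
        "filter_biclusters: %d -> %d (p<=%g, Jaccard<=%g, >=%d genes, >=%d time points)",
        len(bs), len(kept), p_cut, jac_cut, min_genes, min_timepoints,
    )
    return kept


def hypergeometric_enrichment(
    module_genes, annotations: dict[str, set], background
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of annotation terms in a module.

    Population = background, successes = term members in the background,
    draws = module size, observed = overlap; Bonferroni over tested terms.
    Results sorted by corrected then raw p-value.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    module = set(module_genes)
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    n = len(module)
    N_bg = len(background)
    results: list[EnrichmentResult] = []
    raw: list[float] = []
    for term, members in sorted(annotations.items()):
        term_bg = set(members) & background
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & module)
        p = float(stats.hypergeom.sf(k - 1, N_bg, K, n))
        raw.append(p)
        results.append(EnrichmentResult(term=term, k=k, K=K, n=n, N_bg=N_bg,
                                        pvalue=p, corrected_pvalue=1.0))
    m = len(results)
    for r, cp in zip(results, bonferroni(raw, max(m, 1))):
        r.corrected_pvalue = cp
    results.sort(key=lambda r: (r.corrected_pvalue, r.pvalue, r.term))
    return results


def read_annotations_tsv(path: str | Path) -> dict[str, set]:
    """Read a 2-column gene<TAB>term TSV into a term -> gene-set map."""
    path = Path(path)
    terms: dict[str, set] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(cells)}")
            gene, term = cells
            terms.setdefault(term, set()).add(gene)
    return terms


def enrichment_to_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tk\tK\tn\tN_bg\tpvalue\tcorrected_pvalue\thighly_significant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N_bg}\t{r.pvalue!r}\t"
                f"{r.corrected_pvalue!r}\t{int(r.highly_significant)}\n"
            )
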