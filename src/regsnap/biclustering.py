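"""Maximal CCC-bicluster enumeration from the generalized suffix tree.

A CCC-bicluster ``B = (I, J)`` is a set of genes ``I`` sharing an identical
transition pattern over a contiguous interval ``J`` of transition columns.
``B`` is *maximal* when no further gene matches the pattern (row-maximal)
and extending ``J`` by one column on either side strictly shrinks the
matching gene set (left-/right-maximal).  Biclusters with a single row are
discarded as biologically uninteresting.

Because the alphabet transformation stamps each symbol with its column, a
pattern starting with ``(sigma, c)`` can only occur at column ``c``: every
internal node of the generalized suffix tree of the stamped rows is one
right- and row-maximal CCC-bicluster with at least two rows, and vice
versa.  Left-maximality is decided from suffix links: the node for pattern
``P`` fails it exactly when some node ``aP`` has an equal subtree leaf
count (then every occurrence of ``P`` is preceded by the same symbol
``a``), so a node is reported iff every incoming suffix link comes from a
node with a strictly smaller leaf count.  The whole enumeration is linear
in the size of the transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .expression import TERMINATOR, DiscretizedMatrix, TransformedRows
from .suffixtree import GeneralizedSuffixTree


@dataclass
class CCCBicluster:
    """Genes ``rows`` sharing ``pattern`` over transition columns [c_start, c_end].

    Columns are 1-based; transition column c sits between time points c and
    c+1, so the bicluster spans the original time points c_start .. c_end+1.
    """

    rows: tuple[int, ...]              # gene indices, sorted ascending
    c_start: int
    c_end: int
    pattern: tuple[str, ...]
    gene_ids: tuple[str, ...] = ()
    pvalue: float | None = None
    corrected_pvalue: float | None = None
    id: int | None = None

    def __post_init__(self) -> None:
        if len(self.pattern) != self.c_end - self.c_start + 1:
            raise ValueError("pattern length does not match column interval")
        if len(self.rows) < 2:
            raise ValueError("CCC-biclusters with fewer than 2 rows are discarded")

    @property
    def n_genes(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return self.c_end - self.c_start + 1

    @property
    def time_span(self) -> tuple[int, int]:
        """First and last original time point covered (1-based)."""
        return (self.c_start, self.c_end + 1)

    @property
    def n_timepoints(self) -> int:
        return self.n_columns + 1

    @property
    def area(self) -> int:
        return self.n_genes * self.n_columns

    def cells(self) -> frozenset[tuple[int, int]]:
        """The (gene index, transition column) cells covered."""
        return frozenset(
            (g, c) for g in self.rows for c in range(self.c_start, self.c_end + 1)
        )

    def key(self) -> tuple[tuple[int, ...], int, int]:
        return (self.rows, self.c_start, self.c_end)


def build_generalized_suffix_tree(rows: TransformedRows) -> GeneralizedSuffixTree:
    """Build the suffix tree of the stamped row strings (unique terminators)."""
    return GeneralizedSuffixTree(rows.rows)


def _sort_key(b: CCCBicluster):
    # deterministic output order: large modules first
    return (-b.area, b.c_start, b.pattern, b.rows)


def enumerate_maximal_ccc_biclusters(
    tree: GeneralizedSuffixTree, d: DiscretizedMatrix
) -> list[CCCBicluster]:
    """Report every maximal CCC-bicluster with >= 2 rows.

    Each internal node is a candidate; the suffix-link leaf-count rule
    filters those that are not left-maximal.  Rows are recovered from the
    leaf string-ids under the node; the column interval from the stamp of
    the node's first path token and its token depth.
    """
    incoming = tree.incoming_suffix_links()
    out: list[CCCBicluster] = []
    gene_ids = tuple(d.gene_ids)
    n_cols = d.n_transition_columns
    for node in tree.internal_nodes():
        sources = incoming.get(id(node), ())
        if any(src.leaf_count >= node.leaf_count for src in sources):
            continue  # some left extension keeps the full row set
        first = tree.first_path_token(node)
        sym, c_start = first  # type: ignore[misc]
        if sym == TERMINATOR:
            raise ValueError("internal node path starts with a terminator token")
        c_end = c_start + node.path_len - 1
        if not (1 <= c_start and c_end <= n_cols):
            raise ValueError(
                f"stamp {first!r} with depth {node.path_len} falls outside "
                f"the {n_cols} transition columns of the matrix"
            )
        rows = tuple(tree.leaf_rows_under(node).tolist())
        if len(rows) < 2:
            continue  # single-row repeats cannot arise with stamped tokens
        pattern = tuple(d.symbols[rows[0], c_start - 1 : c_end])
        out.append(
            CCCBicluster(
                rows=rows,
                c_start=c_start,
                c_end=c_end,
                pattern=pattern,
                gene_ids=tuple(gene_ids[g] for g in rows),
            )
        )
    out.sort(key=_sort_key)
    for i, b in enumerate(out):
        b.id = i + 1
    return out


def bruteforce_enumerate(d: DiscretizedMatrix) -> list[CCCBicluster]:
    """Exhaustive-search oracle for the suffix-tree enumeration (tests only).

    For every contiguous column interval, genes are grouped by their exact
    symbol sub-row; groups of >= 2 genes are candidates, and a candidate is
    kept iff no one-column extension of the interval preserves the whole
    group.  Quadratic in the number of columns — guarded to small inputs.
    """
    n_genes, n_cols = d.symbols.shape
    if n_genes * n_cols > 10_000:
        raise ValueError("bruteforce_enumerate is a test oracle; input too large")
    out: list[CCCBicluster] = []
    gene_ids = tuple(d.gene_ids)
    for c1 in range(1, n_cols + 1):
        for c2 in range(c1, n_cols + 1):
            groups: dict[tuple[str, ...], list[int]] = {}
            for g in range(n_genes):
                pat = tuple(d.symbols[g, c1 - 1 : c2])
                groups.setdefault(pat, []).append(g)
            for pat, rows in groups.items():
                if len(rows) < 2:
                    continue
                # left-maximality: all rows share the symbol one column left?
                if c1 > 1 and len({d.symbols[g, c1 - 2] for g in rows}) == 1:
                    continue
                # right-maximality
                if c2 < n_cols and len({d.symbols[g, c2] for g in rows}) == 1:
                    continue
                out.append(
                    CCCBicluster(
                        rows=tuple(rows),
                        c_start=c1,
                        c_end=c2,
                        pattern=pat,
                        gene_ids=tuple(gene_ids[g] for g in rows),
                    )
                )
    out.sort(key=_sort_key)
    for i, b in enumerate(out):
        b.id = i + 1
    return out


def verify_maximality(b: CCCBicluster, d: DiscretizedMatrix) -> bool:
    """Re-check all CCC-bicluster invariants directly against the matrix."""
    n_genes, n_cols = d.symbols.shape
    cols = slice(b.c_start - 1, b.c_end)
    pat = np.array(b.pattern, dtype="<U1")
    matches = {g for g in range(n_genes) if np.array_equal(d.symbols[g, cols], pat)}
    if set(b.rows) != matches:
        return False  # pattern mismatch or not row-maximal
    if b.c_start > 1 and len({d.symbols[g, b.c_start - 2] for g in b.rows}) == 1:
        return False
    if b.c_end < n_cols and len({d.symbols[g, b.c_end] for g in b.rows}) == 1:
        return False
    return True


def biclusters_to_records(bs: Iterable[CCCBicluster]) -> list[dict]:
    """JSON-ready records for a list of biclusters."""
    recs = []
    for b in bs:
        recs.append(
            {
                "id": b.id,
                "genes": list(b.gene_ids) if b.gene_ids else list(b.rows),
                "c_start": b.c_start,
                "c_end": b.c_end,
                "time_span": list(b.time_span),
                "pattern": "".join(b.pattern),
                "pvalue": b.pvalue,
                "corrected_pvalue": b.corrected_pvalue,
            }
        )
    return recs
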