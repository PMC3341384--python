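"""Expression time-series I/O, preprocessing and transition discretization.

The temporal biclustering stage does not operate on the raw expression
matrix M' but on a symbolic matrix M of *transitions*: each consecutive
pair of time points is encoded as up-trend (``U``), down-trend (``D``) or
no-trend (``N``) relative to a threshold ``tau``.  A final alphabet
transformation stamps every symbol with its (1-based) transition-column
index so that rows become strings over an alphabet in which a symbol can
only ever match at its own column — the property that makes the suffix-tree
enumeration of contiguous-column biclusters possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Symbols of the transition alphabet: down-trend, no-trend, up-trend.
SIGMA = ("D", "N", "U")

#: Cell contents treated as missing when reading expression TSVs.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

#: Marker used as the first element of terminator tokens; never in SIGMA.
TERMINATOR = "$"


@dataclass
class ExpressionMatrix:
    """Genes x ordered time points of real expression values.

    Time labels keep the chronological order of the input end-to-end;
    ``missing_mask`` is True where the input had no usable number.
    """

    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if self.values.shape != (len(self.gene_ids), len(self.time_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.time_labels)} time points"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        if len(self.time_labels) < 2:
            raise ValueError("an expression time series needs at least 2 time points")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_labels)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.time_labels)


@dataclass
class DiscretizedMatrix:
    """Symbolic transition matrix over {D, N, U}.

    Column c (1-based) encodes the trend between time points c and c+1 of
    the source matrix; there are exactly ``n_timepoints - 1`` columns.
    """

    gene_ids: list[str]
    symbols: np.ndarray  # dtype '<U1', shape (n_genes, n_timepoints - 1)
    tau: float

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype="<U1")
        bad = set(np.unique(self.symbols)) - set(SIGMA)
        if bad:
            raise ValueError(f"symbols outside alphabet {SIGMA}: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_transition_columns(self) -> int:
        return self.symbols.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [str(c) for c in range(1, self.n_transition_columns + 1)]
        return pd.DataFrame(self.symbols, index=self.gene_ids, columns=cols)


@dataclass
class TransformedRows:
    """Column-stamped string form of a discretized matrix.

    Each row is a sequence of ``(symbol, column)`` tokens followed by a
    per-row terminator token ``('$', row_index)``.  Tokens are compared as
    tuples, so column indices >= 10 are unambiguous.
    """

    gene_ids: list[str]
    rows: list[list[tuple[str, int]]]

    def __post_init__(self) -> None:
        terms = [r[-1] for r in self.rows]
        if len(set(terms)) != len(terms):
            raise ValueError("row terminators are not unique")
        for r in self.rows:
            if any(tok[0] == TERMINATOR for tok in r[:-1]):
                raise ValueError("terminator token occurs before end of row")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Header row = time labels; first column = gene id; cells numeric or a
    missing token (empty, NA, NaN, null — case-insensitive).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError(
                f"{path}: need at least 2 time columns, found {len(header) - 1}"
            )
        time_labels = header[1:]
        n_cols = len(time_labels)
        gene_ids: list[str] = []
        seen: set[str] = set()
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols + 1} cells, found {len(cells)}"
                )
            gid = cells[0]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id: {gid!r}")
            seen.add(gid)
            gene_ids.append(gid)
            row: list[float] = []
            for j, cell in enumerate(cells[1:], start=2):
                if cell.strip().lower() in MISSING_TOKENS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: column {j}: not a number: {cell!r}"
                        ) from exc
            data.append(row)
    values = np.array(data, dtype=float).reshape(len(gene_ids), n_cols)
    return ExpressionMatrix(gene_ids=gene_ids, time_labels=time_labels, values=values)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect that :func:`read_expression_tsv` consumes."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(str(t) for t in m.time_labels) + "\n")
        for i, gid in enumerate(m.gene_ids):
            cells = [
                "NA" if m.missing_mask[i, j] else repr(float(m.values[i, j]))
                for j in range(m.n_timepoints)
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def filter_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only genes whose rows have no missing values."""
    keep = ~m.missing_mask.any(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_missing: removed %d gene(s) with missing values", n_removed)
    if not keep.any():
        raise ValueError("all genes have missing values; nothing to analyze")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        time_labels=list(m.time_labels),
        values=m.values[keep],
        missing_mask=m.missing_mask[keep],
    )


def normalize_by_gene(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Normalize each gene's profile to zero mean and unit standard deviation.

    Uses the sample convention (divisor n-1) by default; pass ``ddof=0`` for
    the population convention.  Constant rows carry no trend signal and are
    dropped with a warning.
    """
    if m.missing_mask.any():
        raise ValueError("normalize_by_gene requires a matrix without missing values")
    sd = m.values.std(axis=1, ddof=ddof)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.warning("normalize_by_gene: dropped %d constant row(s)", n_const)
    if not keep.any():
        raise ValueError("all rows are constant; nothing to normalize")
    vals = m.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        time_labels=list(m.time_labels),
        values=vals,
        missing_mask=np.zeros_like(vals, dtype=bool),
    )


def discretize_transitions(m: ExpressionMatrix, tau: float = 0.0) -> DiscretizedMatrix:
    """Encode consecutive-time-point transitions as U / D / N symbols.

    Transition column c holds ``U`` if value[c+1] - value[c] >= tau, ``D``
    if <= -tau, else ``N``.  With the default ``tau = 0`` any strict
    increase is ``U``, any strict decrease ``D`` and an exact tie ``N``.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    if m.missing_mask.any():
        raise ValueError("discretize_transitions requires a matrix without missing values")
    diff = np.diff(m.values, axis=1)
    symbols = np.full(diff.shape, "N", dtype="<U1")
    if tau == 0:
        symbols[diff > 0] = "U"
        symbols[diff < 0] = "D"
    else:
        symbols[diff >= tau] = "U"
        symbols[diff <= -tau] = "D"
    return DiscretizedMatrix(gene_ids=list(m.gene_ids), symbols=symbols, tau=tau)


def transform_alphabet(d: DiscretizedMatrix) -> TransformedRows:
    """Stamp every symbol with its 1-based column and append terminators.

    Cell (sigma, c) becomes the token ``(sigma, c)``; row i gets the unique
    terminator ``('$', i)``.
    """
    rows: list[list[tuple[str, int]]] = []
    for i in range(d.n_genes):
        toks = [(str(d.symbols[i, c]), c + 1) for c in range(d.n_transition_columns)]
        toks.append((TERMINATOR, i))
        rows.append(toks)
    return TransformedRows(gene_ids=list(d.gene_ids), rows=rows)


def decode_token(tok: tuple[str, int]) -> tuple[str, int]:
    """Decode a stamped token back to (symbol, column); identity on tuples."""
    sym, c = tok
    if sym not in SIGMA:
        raise ValueError(f"not a stamped alphabet token: {tok!r}")
    return sym, c


def write_discretized_tsv(d: DiscretizedMatrix, path: str | Path) -> None:
    """Debug output: the symbolic transition matrix as TSV."""
    d.to_frame().to_csv(path, sep="\t", index_label="gene")
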