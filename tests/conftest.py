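import numpy as np
import pytest

from regsnap.expression import DiscretizedMatrix, ExpressionMatrix


def random_discretized(rng, n_genes, n_cols) -> DiscretizedMatrix:
    sym = rng.choice(list("DNU"), size=(n_genes, n_cols))
    return DiscretizedMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)], symbols=sym, tau=0.0
    )


def random_walk_matrix(rng, n, density=0.15):
    """Dense row-normalized random-walk matrix of a random digraph."""
    a = (rng.random((n, n)) < density) * rng.random((n, n))
    np.fill_diagonal(a, 0)
    out = a.sum(axis=1)
    inv = np.divide(1.0, out, out=np.zeros(n), where=out > 0)
    return np.diag(inv) @ a


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 time points, no missing values."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        time_labels=["t1", "t2", "t3", "t4"],
        values=np.array([
            [0.0, 1.0, 1.2, 0.2],
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 1.0, 0.5],
        ]),
    )


@pytest.fixture
def expr_tsv(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene\t0\t5\t15\n"
        "YAL001C\t0.5\t1.5\t-0.5\n"
        "YAL002W\t-1.0\tNA\t2.0\n"
        "YAL003W\t0.0\t0.0\t1.0\n",
        encoding="utf-8",
    )
    return p


@pytest.fixture
def edge_tsv(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text(
        "# regulator\ttarget\tweight\n"
        "tfA\tg1\t2\n"
        "tfA\tg2\t3\n"
        "tfB\tg1\n"
        "tfB\ttfA\t1\n",
        encoding="utf-8",
    )
    return p
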