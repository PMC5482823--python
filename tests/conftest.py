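import numpy as np
import pandas as pd
import pytest

from bodymap.core import ExpressionMatrix, GeneAnnotation, SampleMetadata
from bodymap.synthetic import SimulationConfig, generate_dataset


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    """Two tissues x two sexes, four samples."""
    return SampleMetadata(
        pd.DataFrame(
            {
                "tissue": ["brain", "brain", "liver", "liver"],
                "sex": ["female", "male", "female", "male"],
                "individual": ["m1", "m2", "m1", "m2"],
                "sexual_tissue": [False] * 4,
            },
            index=pd.Index(["b1", "b2", "l1", "l2"], name="sample_id"),
        )
    )


@pytest.fixture
def tiny_matrix(tiny_meta) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    vals = rng.lognormal(1.0, 1.0, (10, 4)).round(3)
    vals[0] = 0.0  # planted all-zero row
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
            columns=tiny_meta.sample_ids,
        )
    )


@pytest.fixture
def tiny_annotation(tiny_matrix) -> GeneAnnotation:
    n = tiny_matrix.n_genes
    return GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": [f"S{i}" for i in range(n)],
                "biotype": ["protein_coding"] * (n - 2) + ["ncRNA", "pseudogene"],
                "chromosome": ["chr1"] * n,
            },
            index=pd.Index(tiny_matrix.gene_ids, name="gene_id"),
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Medium synthetic dataset shared across tests (seed 11)."""
    cfg = SimulationConfig(n_genes=1000, seed=11, frac_silent=0.1)
    return cfg, generate_dataset(cfg)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive; no shared code paths
# with the package internals they check)


def oracle_welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value from the textbook formulas."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 1.0 if mx == my else 0.0
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2 * tdist.sf(abs(t), df))


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """BH step-up by literal sort / p*m/i / running minimum from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.array(q)


def oracle_pearson_distance(values: pd.DataFrame) -> np.ndarray:
    """1 - r for every sample pair, one pair at a time."""
    cols = list(values.columns)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            x = values[cols[i]].to_numpy()
            y = values[cols[j]].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            d[i, j] = 0.0 if i == j else 1.0 - r
    return d


def oracle_r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation via explicit sums."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return float((num / den) ** 2)
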