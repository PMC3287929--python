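import numpy as np
import pandas as pd
import pytest

from raretag.genotype_core import GenotypeMatrix


def make_matrix(columns, prefix="v", individual_prefix="ind"):
    """GenotypeMatrix from a list of dosage columns (each length N)."""
    arr = np.column_stack([np.asarray(c, dtype=np.int8) for c in columns])
    n, m = arr.shape
    return GenotypeMatrix(
        arr,
        tuple(f"{individual_prefix}{i}" for i in range(n)),
        tuple(f"{prefix}{j}" for j in range(m)),
    )


def make_variants(positions, var_classes, chromosome="1", functional=None, prefix="v"):
    """Minimal variant table aligned with make_matrix column naming."""
    m = len(positions)
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{j}" for j in range(m)],
            "chromosome": chromosome,
            "position": list(positions),
            "maf": 0.1,
            "var_class": list(var_classes),
            "functional": functional if functional is not None else ["none"] * m,
        }
    )


# ---------------------------------------------------------------------------
# Independent oracles (used to derive and check expected values; these stay
# deliberately naive and separate from the package implementations)
# ---------------------------------------------------------------------------

def pearson_r2_oracle(x, y):
    """Direct evaluation of Pearson's product-moment formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (num / den) ** 2


def r2_normal_equations_oracle(y, X):
    """R^2 from an explicit normal-equations solve (full-rank designs only)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    D = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - rss / tss


def anova_F_oracle(y, X_A, X_B):
    """Nested-model F from residual sums of squares of two explicit fits."""
    y = np.asarray(y, float)
    X_A = np.asarray(X_A, float)
    X_B = np.asarray(X_B, float)
    n = len(y)

    def rss(X):
        D = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        r = y - D @ beta
        return r @ r

    rss_a, rss_b = rss(X_A), rss(X_B)
    df1 = X_B.shape[1] - X_A.shape[1]
    df2 = n - X_B.shape[1] - 1
    return ((rss_a - rss_b) / df1) / (rss_b / df2)


def ks_statistic_oracle(a, b):
    """Brute-force two-sample KS statistic: max ECDF gap over all points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    points = np.concatenate([a, b])
    gaps = [
        abs(np.mean(a <= t) - np.mean(b <= t)) for t in points
    ]
    return max(gaps)


def random_dosage_matrix(rng, n, m, min_variance=True):
    """Random non-constant dosage columns for property tests."""
    while True:
        x = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        if not min_variance or all(np.ptp(x[:, j]) > 0 for j in range(m)):
            return x


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
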