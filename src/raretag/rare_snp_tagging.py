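"""Stage 2: per-rare-SNP nested comparison of tag sets A ⊆ B.

For each rare SNP, the common SNPs within a window are pruned into nested
sets A and B under two pairwise r^2 ceilings. The gain of the B regression
over the A regression is tested with the nested-model F statistic

    F = [(R2_B - R2_A) / (n_B - n_A)] / [(1 - R2_B) / (N - n_B - 1)]

against both the analytic F(df1, df2) tail and a block-permutation null in
which the rows of the B\\A predictors are permuted jointly — breaking their
LD with everything outside the block while preserving it within.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from raretag.bin_correlation import adjusted_R2, multiple_R2
from raretag.errors import ConfigurationError
from raretag.genotype_core import GenotypeMatrix
from raretag.ld_structure import build_tag_sets, window_select
from raretag.permutation_null import NullComparison
from raretag.rng import child_rng

logger = logging.getLogger(__name__)


@dataclass
class Stage2Config:
    threshold_A: float = 0.80
    threshold_B: float = 0.95
    window_bp: int = 1_000_000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (self.threshold_A < self.threshold_B < 1.0):
            raise ConfigurationError("require threshold_A < threshold_B < 1")
        if self.window_bp <= 0 or self.n_perm < 1:
            raise ConfigurationError("window_bp and n_perm must be positive")


def nested_F(R2_A: float, R2_B: float, n_A: int, n_B: int, N: int):
    """Nested-regression F statistic with df1 = n_B - n_A, df2 = N - n_B - 1.

    Returns (F, df1, df2); F is +inf when R2_B == 1 (flagged upstream).
    """
    if n_B <= n_A:
        raise ConfigurationError("n_B must exceed n_A")
    df1 = n_B - n_A
    df2 = N - n_B - 1
    if df2 < 1:
        raise ConfigurationError(f"df2 = {df2} < 1")
    if R2_B < R2_A - 1e-12:
        raise ConfigurationError("nested models require R2_B >= R2_A")
    num = max(R2_B - R2_A, 0.0) / df1
    if R2_B >= 1.0:
        return float("inf"), df1, df2
    den = (1.0 - R2_B) / df2
    return num / den, df1, df2


def analytic_F_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution at F."""
    if df1 < 1 or df2 < 1:
        raise ConfigurationError("degrees of freedom must be >= 1")
    if F < 0:
        raise ConfigurationError("F must be non-negative")
    if np.isinf(F):
        return 0.0
    return float(stats.f.sf(F, df1, df2))


def block_permutation_pvalue(
    y,
    X_A: np.ndarray,
    X_BminusA: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
):
    """Permutation p-value for the nested F under joint row permutation of
    the B\\A block.

    One shared row permutation per replicate is applied to every column of
    X_BminusA (within-block LD preserved); X_A stays fixed, F is recomputed,
    and p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Returns (p, array of permuted F values).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    yv = np.asarray(y, dtype=np.float64)
    X_A = np.asarray(X_A, dtype=np.float64)
    if X_A.ndim == 1:
        X_A = X_A[:, None]
    X_BminusA = np.asarray(X_BminusA, dtype=np.float64)
    if X_BminusA.ndim == 1:
        X_BminusA = X_BminusA[:, None]
    if X_BminusA.shape[1] < 1:
        raise ConfigurationError("X_BminusA must have at least one column")
    n = yv.shape[0]
    n_A = X_A.shape[1]
    n_B = n_A + X_BminusA.shape[1]
    R2_A = multiple_R2(yv, X_A)
    f_obs = _nested_F_from_fit(yv, X_A, X_BminusA, R2_A, n_A, n_B, n)
    f_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        f_perm[i] = _nested_F_from_fit(yv, X_A, X_BminusA[perm, :], R2_A, n_A, n_B, n)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(p), f_perm


def _nested_F_from_fit(yv, X_A, X_block, R2_A, n_A, n_B, n) -> float:
    R2_B = multiple_R2(yv, np.column_stack([X_A, X_block]))
    R2_B = max(R2_B, R2_A)  # guard fp noise; column space of B contains A's
    f, _, _ = nested_F(R2_A, R2_B, n_A, n_B, n)
    return f


STAGE2_COLUMNS = [
    "rare_id",
    "threshold_A",
    "threshold_B",
    "n_A",
    "n_B",
    "R2_A",
    "R2_B",
    "adjR2_A",
    "adjR2_B",
    "F",
    "df1",
    "df2",
    "p_analytic",
    "p_permutation",
    "n_permutations",
    "degenerate_flag",
]


def run_stage2(
    g: GenotypeMatrix,
    variants: pd.DataFrame,
    config: Stage2Config,
) -> pd.DataFrame:
    """Per-rare-SNP tag-set comparison over the whole cohort.

    Rare SNPs with an empty window (or no admissible tag set) are skipped with
    a log entry; those whose B set adds nothing over A (n_B == n_A) are
    recorded with F and p-values absent; degenerate models (df2 < 1) are
    flagged and excluded from testing.
    """
    rows = []
    n_ind = g.n_individuals
    rare = variants[variants["var_class"] == "rare"].sort_values(["chromosome", "position"])
    for rare_id in rare["variant_id"]:
        candidates = window_select(variants, rare_id, config.window_bp)
        candidates = [c for c in candidates if np.ptp(g.column(c)) > 0]
        if not candidates:
            logger.info("rare SNP %s: empty window, skipped", rare_id)
            continue
        pair = build_tag_sets(
            g, candidates, config.threshold_A, config.threshold_B, focal_rare_id=rare_id
        )
        if pair.n_A == 0:
            logger.info("rare SNP %s: no tag SNPs admitted, skipped", rare_id)
            continue
        y = g.column(rare_id).astype(np.float64)
        if np.ptp(y) == 0:
            logger.warning("rare SNP %s: constant dosage, skipped", rare_id)
            continue
        X_A = g.columns(pair.set_A).astype(np.float64)
        R2_A = multiple_R2(y, X_A)
        row = {
            "rare_id": rare_id,
            "threshold_A": config.threshold_A,
            "threshold_B": config.threshold_B,
            "n_A": pair.n_A,
            "n_B": pair.n_B,
            "R2_A": R2_A,
            "R2_B": np.nan,
            "adjR2_A": np.nan,
            "adjR2_B": np.nan,
            "F": np.nan,
            "df1": pair.n_B - pair.n_A,
            "df2": n_ind - pair.n_B - 1,
            "p_analytic": np.nan,
            "p_permutation": np.nan,
            "n_permutations": 0,
            "degenerate_flag": False,
        }
        if n_ind - pair.n_A - 1 > 0:
            row["adjR2_A"] = adjusted_R2(R2_A, n_ind, pair.n_A)
        if pair.n_B == pair.n_A:
            row["R2_B"] = R2_A
            row["adjR2_B"] = row["adjR2_A"]
            rows.append(row)
            continue
        X_block = g.columns(pair.set_B_minus_A).astype(np.float64)
        R2_B = max(multiple_R2(y, np.column_stack([X_A, X_block])), R2_A)
        row["R2_B"] = R2_B
        df2 = n_ind - pair.n_B - 1
        if df2 < 1:
            row["degenerate_flag"] = True
            rows.append(row)
            continue
        row["adjR2_B"] = adjusted_R2(R2_B, n_ind, pair.n_B)
        f, df1, df2 = nested_F(R2_A, R2_B, pair.n_A, pair.n_B, n_ind)
        row["F"] = f
        row["p_analytic"] = analytic_F_pvalue(f, df1, df2)
        rng = child_rng(config.seed, "stage2", rare_id, config.threshold_A, config.threshold_B)
        p_perm, _ = block_permutation_pvalue(y, X_A, X_block, config.n_perm, rng)
        row["p_permutation"] = p_perm
        row["n_permutations"] = config.n_perm
        rows.append(row)
    return pd.DataFrame(rows, columns=STAGE2_COLUMNS)


def compare_stage2_distributions(results: pd.DataFrame) -> NullComparison:
    """KS test plus paired t test between the adjusted R^2 of sets A and B
    across rare SNPs."""
    ok = results.dropna(subset=["adjR2_A", "adjR2_B"])
    if len(ok) < 2:
        raise ConfigurationError("need at least 2 records with both adjusted R^2 values")
    a = ok["adjR2_A"].values.astype(float)
    b = ok["adjR2_B"].values.astype(float)
    ks = stats.ks_2samp(b, a, method="auto")
    if np.allclose(a, b):
        t_p = 1.0
    else:
        t_p = float(stats.ttest_rel(b, a).pvalue)
    return NullComparison(
        stratum="all",
        statistic_name="adjusted_R2_B_vs_A",
        observed=b,
        null=a,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        t_p=t_p,
        mean_observed=float(b.mean()),
        mean_null=float(a.mean()),
    )


def write_stage2_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_stage2_scatter(results: pd.DataFrame, path, gain_threshold: float = 0.30) -> None:
    """Companion table of (adjR2_A, adjR2_B) points with significance flags."""
    ok = results.dropna(subset=["adjR2_A", "adjR2_B"]).copy()
    ok["gain"] = ok["adjR2_B"] - ok["adjR2_A"]
    ok["large_gain"] = ok["gain"] > gain_threshold
    cols = ["rare_id", "adjR2_A", "adjR2_B", "gain", "large_gain", "p_analytic", "p_permutation"]
    ok[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
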