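"""Stage-1 permutation null and distribution-level comparisons.

Each common SNP is permuted independently across individuals within its bin,
which destroys both the SNP-load association and the SNP-SNP LD while
preserving every per-SNP dosage multiset (and hence MAF). Observed and null
correlation distributions are then compared with a two-sample
Kolmogorov-Smirnov test and a Welch t test on the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from raretag.bin_correlation import Stage1Config, run_stage1
from raretag.errors import ConfigurationError
from raretag.genotype_core import GenotypeMatrix


@dataclass(frozen=True)
class NullComparison:
    stratum: str
    statistic_name: str
    observed: np.ndarray
    null: np.ndarray
    ks_statistic: float
    ks_p: float
    t_p: float  # NaN when undefined (degenerate equal samples)
    mean_observed: float
    mean_null: float


def permute_common_within_bin(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column of X across rows; X is not modified."""
    X = np.asarray(X)
    if X.size == 0:
        raise ConfigurationError("X must be non-empty")
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(n), j]
    return out


def null_stage1(
    g: GenotypeMatrix,
    variants: pd.DataFrame,
    labels: pd.Series,
    config: Stage1Config,
) -> pd.DataFrame:
    """Stage-1 pipeline with per-bin column permutation of the common SNPs.

    The rare-SNP samples are drawn from the same derived random streams as
    the observed run with the same config seed, so each null row is paired
    with its observed counterpart.
    """
    return run_stage1(g, variants, labels, config, permute=True)


def compare_distributions(
    observed, null, stratum: str = "all", statistic_name: str = "adjusted_R2"
) -> NullComparison:
    """Two-sample KS statistic/p and Welch t-test p for observed vs null."""
    observed = np.asarray(observed, dtype=np.float64)
    null = np.asarray(null, dtype=np.float64)
    observed = observed[~np.isnan(observed)]
    null = null[~np.isnan(null)]
    if observed.size < 2 or null.size < 2:
        raise ConfigurationError("need at least 2 values per sample")
    ks = stats.ks_2samp(observed, null, method="auto")
    if np.ptp(observed) == 0 and np.ptp(null) == 0:
        # zero-variance samples: t undefined unless the constants agree
        t_p = 1.0 if observed[0] == null[0] else np.nan
    else:
        t_p = float(stats.ttest_ind(observed, null, equal_var=False).pvalue)
    return NullComparison(
        stratum=stratum,
        statistic_name=statistic_name,
        observed=observed,
        null=null,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        t_p=t_p,
        mean_observed=float(observed.mean()),
        mean_null=float(null.mean()),
    )


STAGE1_STATS = ("max_single_r2", "multiple_R2", "adjusted_R2")


def compare_stage1_runs(observed: pd.DataFrame, null: pd.DataFrame) -> pd.DataFrame:
    """Per (stratum, functional, statistic) KS/t comparison table between the
    observed and null stage-1 result frames."""
    rows = []
    keys = observed[["stratum", "functional"]].drop_duplicates()
    for _, (stratum, functional) in keys.iterrows():
        obs = observed[(observed["stratum"] == stratum) & (observed["functional"] == functional)]
        nul = null[(null["stratum"] == stratum) & (null["functional"] == functional)]
        for stat in STAGE1_STATS:
            o = obs[stat].dropna().values
            u = nul[stat].dropna().values
            if len(o) < 2 or len(u) < 2:
                continue
            cmp_ = compare_distributions(o, u, stratum=stratum, statistic_name=stat)
            rows.append(
                {
                    "stratum": stratum,
                    "functional": functional,
                    "statistic_name": stat,
                    "n_observed": len(o),
                    "n_null": len(u),
                    "mean_observed": cmp_.mean_observed,
                    "mean_null": cmp_.mean_null,
                    "ks_statistic": cmp_.ks_statistic,
                    "ks_p": cmp_.ks_p,
                    "t_p": cmp_.t_p,
                }
            )
    return pd.DataFrame(rows)
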