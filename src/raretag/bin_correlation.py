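"""Stage 1: per-bin correlation between common SNPs and the rare-allele load.

The genome is tiled with fixed, non-overlapping bins. Within each bin, random
subsets of n_s rare SNPs are drawn; the per-individual total of rare alleles
(or its presence/absence collapse) is correlated with the bin's common SNPs
via (a) the maximum single-SNP squared Pearson correlation and (b) the
multiple R^2 of a linear regression with intercept, reported alongside the
predictor-count-adjusted R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from raretag.errors import ConfigurationError, DegenerateModelError
from raretag.genotype_core import GenotypeMatrix, classify_variants, compute_maf
from raretag.rng import child_rng

logger = logging.getLogger(__name__)

FUNCTIONAL_STRATA = ("all", "synonymous", "nonsynonymous")


@dataclass(frozen=True)
class Bin:
    """Half-open genomic interval [start, end) holding classified variants."""

    chromosome: str
    start: int
    end: int
    rare_ids: tuple
    common_ids: tuple

    @property
    def n_r(self) -> int:
        return len(self.rare_ids)


@dataclass(frozen=True)
class RareAlleleLoad:
    """Per-individual rare-allele burden for one sampled rare-SNP subset."""

    values: np.ndarray
    mode: str  # "count" or "collapse"
    sampled_rare_ids: tuple


@dataclass
class Stage1Config:
    bin_size: int = 1_000_000
    n_s: int = 5
    rare_threshold: float = 0.01
    common_threshold: float = 0.05
    min_stratum_size: int = 20
    recompute_class_within_stratum: bool = True
    mode: str = "count"  # or "collapse"
    seed: int = 0

    def __post_init__(self):
        if self.bin_size <= 0 or self.n_s < 1:
            raise ConfigurationError("bin_size and n_s must be positive")
        if self.mode not in ("count", "collapse"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


def make_bins(variants: pd.DataFrame, bin_size: int) -> list[Bin]:
    """Assign every rare/common variant to the fixed bin containing its
    1-based position: bin index floor((pos - 1) / bin_size). Empty bins are
    omitted; bins are returned sorted by (chromosome, start)."""
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    used = variants[variants["var_class"].isin(("rare", "common"))]
    groups: dict[tuple, dict[str, list]] = {}
    for vid, chrom, pos, cls in zip(
        used["variant_id"], used["chromosome"], used["position"], used["var_class"]
    ):
        b = (int(pos) - 1) // bin_size
        key = (str(chrom), b)
        slot = groups.setdefault(key, {"rare": [], "common": []})
        slot[cls].append((int(pos), vid))
    bins = []
    for (chrom, b), slot in sorted(groups.items()):
        bins.append(
            Bin(
                chromosome=chrom,
                start=b * bin_size + 1,
                end=(b + 1) * bin_size + 1,
                rare_ids=tuple(v for _, v in sorted(slot["rare"])),
                common_ids=tuple(v for _, v in sorted(slot["common"])),
            )
        )
    return bins


def sample_rare_replicates(rare_ids: Sequence, n_s: int, rng: np.random.Generator) -> list[tuple]:
    """Random rare-SNP subsets for one bin.

    With n_r > n_s, draws round(n_r / n_s) independent without-replacement
    samples of size n_s (ties in the rounding go half-up). With
    0 < n_r <= n_s a single replicate containing every rare SNP is returned.
    """
    if n_s < 1:
        raise ConfigurationError("n_s must be >= 1")
    rare_ids = list(rare_ids)
    n_r = len(rare_ids)
    if n_r == 0:
        return []
    if n_r <= n_s:
        return [tuple(rare_ids)]
    n_rep = int(np.floor(n_r / n_s + 0.5))  # round half-up
    return [
        tuple(rng.choice(rare_ids, size=n_s, replace=False)) for _ in range(n_rep)
    ]


def rare_allele_load(g: GenotypeMatrix, rare_ids: Sequence) -> RareAlleleLoad:
    """Count mode: per-individual sum of minor-allele dosages over rare_ids."""
    rare_ids = tuple(rare_ids)
    if not rare_ids:
        raise ConfigurationError("rare_ids must be non-empty")
    values = g.columns(rare_ids).sum(axis=1, dtype=np.int64)
    return RareAlleleLoad(values=values, mode="count", sampled_rare_ids=rare_ids)


def collapsing_indicator(g: GenotypeMatrix, rare_ids: Sequence) -> RareAlleleLoad:
    """Collapse mode: 1 if any rare allele is present, else 0."""
    load = rare_allele_load(g, rare_ids)
    return RareAlleleLoad(
        values=(load.values > 0).astype(np.int64),
        mode="collapse",
        sampled_rare_ids=load.sampled_rare_ids,
    )


def max_single_r2(y, g: GenotypeMatrix, common_ids: Sequence):
    """Maximum squared Pearson correlation between y and each common SNP.

    Constant common columns are skipped; a constant y yields (0.0, None) with
    a warning rather than an error.
    """
    values = y.values if isinstance(y, RareAlleleLoad) else np.asarray(y)
    common_ids = list(common_ids)
    if not common_ids:
        raise ConfigurationError("common_ids must be non-empty")
    yv = values.astype(np.float64)
    dy = yv - yv.mean()
    vy = dy @ dy
    if vy == 0:
        logger.warning("max_single_r2: constant response, returning 0")
        return 0.0, None
    x = g.columns(common_ids).astype(np.float64)
    dx = x - x.mean(axis=0)
    vx = (dx**2).sum(axis=0)
    ok = vx > 0
    if not ok.any():
        return 0.0, None
    r2 = np.zeros(len(common_ids))
    r2[ok] = (dy @ dx[:, ok]) ** 2 / (vx[ok] * vy)
    j = int(np.argmax(r2))
    return min(float(r2[j]), 1.0), common_ids[j]


def multiple_R2(y, X) -> float:
    """Coefficient of determination of the least-squares fit of y on X plus an
    intercept. Rank-deficient X uses the minimum-norm solution; R^2 stays
    well defined as 1 - RSS/TSS. Zero predictors give 0.0."""
    yv = (y.values if isinstance(y, RareAlleleLoad) else np.asarray(y)).astype(np.float64)
    n = yv.shape[0]
    if n <= 1:
        raise DegenerateModelError("need at least 2 observations")
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateModelError("constant response: R^2 undefined")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return 0.0
    if X.shape[0] != n:
        raise ConfigurationError("X rows must match len(y)")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    rss = float(resid @ resid)
    return float(np.clip(1.0 - rss / tss, 0.0, 1.0))


def adjusted_R2(R2: float, N: int, n: int) -> float:
    """Predictor-count adjustment: 1 - (1 - R^2) (N - 1) / (N - n - 1).

    Can be negative; requires positive residual degrees of freedom.
    """
    if N - n - 1 <= 0:
        raise DegenerateModelError(f"N - n - 1 = {N - n - 1} <= 0")
    return 1.0 - (1.0 - R2) * (N - 1) / (N - n - 1)


# ---------------------------------------------------------------------------
# Stage-1 driver
# ---------------------------------------------------------------------------

STAGE1_COLUMNS = [
    "stratum",
    "functional",
    "chrom",
    "bin_start",
    "bin_end",
    "replicate",
    "n_r",
    "n_s_used",
    "n_common",
    "max_single_r2",
    "multiple_R2",
    "adjusted_R2",
    "degenerate_flag",
]


def _strata(labels: pd.Series, individual_ids, min_size: int):
    """Yield (name, row-index array) for 'all' plus each subpopulation large
    enough; small strata are skipped with a warning."""
    ids = list(individual_ids)
    yield "all", np.arange(len(ids))
    pops = labels.reindex(ids)
    for pop in sorted(pops.dropna().unique()):
        idx = np.flatnonzero((pops == pop).values)
        if idx.size < min_size:
            logger.warning("stratum %s skipped: %d < %d individuals", pop, idx.size, min_size)
            continue
        yield str(pop), idx


def run_stage1(
    g: GenotypeMatrix,
    variants: pd.DataFrame,
    labels: pd.Series,
    config: Stage1Config,
    *,
    permute: bool = False,
) -> pd.DataFrame:
    """Run the binned correlation analysis over every (subpopulation,
    functional) stratum.

    MAF and rare/common classes are recomputed within each subpopulation
    stratum unless the config disables it. With ``permute=True`` the common
    dosages of each bin are column-permuted before correlating (the stage-1
    null); the rare-SNP samples use the same derived random streams either
    way, so observed and null runs are paired replicate-by-replicate.
    """
    rows = []
    seed = config.seed
    for stratum, idx in _strata(labels, g.individual_ids, config.min_stratum_size):
        g_s = g.subset_individuals(idx) if stratum != "all" else g
        n_ind = g_s.n_individuals
        if config.recompute_class_within_stratum and stratum != "all":
            maf = compute_maf(g_s)
            cls = classify_variants(maf, config.rare_threshold, config.common_threshold)
            vt = variants.copy()
            # preserve global perfect-LD exclusions
            keep_excl = vt["var_class"] == "excluded_perfect_ld"
            vt["var_class"] = cls
            vt.loc[keep_excl, "var_class"] = "excluded_perfect_ld"
        else:
            vt = variants
        bins = make_bins(vt, config.bin_size)
        functional_of = dict(zip(vt["variant_id"], vt["functional"]))
        for functional in FUNCTIONAL_STRATA:
            for bin_idx, bn in enumerate(bins):
                if functional == "all":
                    rare_ids = bn.rare_ids
                else:
                    rare_ids = tuple(v for v in bn.rare_ids if functional_of[v] == functional)
                if not rare_ids or not bn.common_ids:
                    continue
                rng = child_rng(
                    seed, "stage1", "sample", stratum, functional, bn.chromosome, bn.start
                )
                replicates = sample_rare_replicates(rare_ids, config.n_s, rng)
                X_obs = g_s.columns(bn.common_ids)
                for rep_i, subset in enumerate(replicates):
                    if config.mode == "collapse":
                        load = collapsing_indicator(g_s, subset)
                    else:
                        load = rare_allele_load(g_s, subset)
                    X = X_obs
                    if permute:
                        from raretag.permutation_null import permute_common_within_bin

                        perm_rng = child_rng(
                            seed,
                            "stage1",
                            "perm",
                            stratum,
                            functional,
                            bn.chromosome,
                            bn.start,
                            rep_i,
                        )
                        X = permute_common_within_bin(X_obs, perm_rng)
                    n_common = X.shape[1]
                    degenerate = n_common >= n_ind - 2
                    if np.ptp(load.values) == 0:
                        max_r2, r2 = 0.0, 0.0
                        logger.warning(
                            "constant load in %s/%s %s:%d rep %d",
                            stratum,
                            functional,
                            bn.chromosome,
                            bn.start,
                            rep_i,
                        )
                    else:
                        max_r2, _ = max_single_r2(load, g_s, bn.common_ids) if not permute else _max_r2_matrix(load.values, X)
                        r2 = multiple_R2(load.values, X)
                    adj = np.nan if degenerate else adjusted_R2(r2, n_ind, n_common)
                    rows.append(
                        {
                            "stratum": stratum,
                            "functional": functional,
                            "chrom": bn.chromosome,
                            "bin_start": bn.start,
                            "bin_end": bn.end - 1,
                            "replicate": rep_i,
                            "n_r": len(rare_ids),
                            "n_s_used": len(subset),
                            "n_common": n_common,
                            "max_single_r2": max_r2,
                            "multiple_R2": r2,
                            "adjusted_R2": adj,
                            "degenerate_flag": bool(degenerate),
                            "mode": config.mode,
                            "sampled_rare_ids": ";".join(map(str, subset)),
                        }
                    )
    return pd.DataFrame(rows, columns=STAGE1_COLUMNS + ["mode", "sampled_rare_ids"])


def _max_r2_matrix(y: np.ndarray, X: np.ndarray):
    """max single-predictor r^2 against the columns of a raw matrix (used for
    permuted bins where the matrix no longer lives in the GenotypeMatrix)."""
    yv = np.asarray(y, dtype=np.float64)
    dy = yv - yv.mean()
    vy = dy @ dy
    if vy == 0:
        return 0.0, None
    dx = X - X.mean(axis=0)
    vx = (dx**2).sum(axis=0)
    ok = vx > 0
    if not ok.any():
        return 0.0, None
    r2 = np.zeros(X.shape[1])
    r2[ok] = (dy @ dx[:, ok]) ** 2 / (vx[ok] * vy)
    return min(float(r2.max()), 1.0), int(np.argmax(r2))


def write_stage1_tsv(results: pd.DataFrame, path) -> None:
    results[STAGE1_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
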