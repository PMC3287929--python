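"""Genotype data model: dosage matrices, MAF, variant classification, and
removal of perfect-LD duplicates.

The dosage convention throughout the package is the count of *minor* alleles
per individual, an integer in {0, 1, 2}. VCF input is re-oriented at load
time when the ALT allele turns out to be the major one, and missing calls are
imputed to the rounded per-variant mean dosage so that every downstream
statistic can assume complete data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from raretag.errors import ConfigurationError, DataValidationError

logger = logging.getLogger(__name__)

VAR_CLASSES = ("rare", "common", "neither", "excluded_perfect_ld", "monomorphic")
FUNCTIONAL_LABELS = ("synonymous", "nonsynonymous", "none")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix.

    Parameters
    ----------
    dosages
        Integer array of shape (N, M) with entries in {0, 1, 2}.
    individual_ids, variant_ids
        Unique ordered identifiers matching the matrix dimensions.
    """

    dosages: np.ndarray
    individual_ids: tuple
    variant_ids: tuple
    _col_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        dosages = np.asarray(self.dosages)
        if dosages.ndim != 2:
            raise DataValidationError("dosages must be a 2-D array")
        if dosages.size and not np.isin(dosages, (0, 1, 2)).all():
            raise DataValidationError("dosage entries must all be in {0, 1, 2}")
        ind = tuple(self.individual_ids)
        var = tuple(self.variant_ids)
        if len(set(ind)) != len(ind):
            raise DataValidationError("individual_ids are not unique")
        if len(set(var)) != len(var):
            raise DataValidationError("variant_ids are not unique")
        if dosages.shape != (len(ind), len(var)):
            raise DataValidationError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(ind)} individuals x {len(var)} variants"
            )
        object.__setattr__(self, "dosages", dosages.astype(np.int8, copy=False))
        object.__setattr__(self, "individual_ids", ind)
        object.__setattr__(self, "variant_ids", var)
        object.__setattr__(self, "_col_index", {v: j for j, v in enumerate(var)})

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id) -> np.ndarray:
        return self.dosages[:, self._col_index[variant_id]]

    def columns(self, variant_ids: Sequence) -> np.ndarray:
        """Dosage submatrix (N x len(variant_ids)) in the requested order."""
        idx = [self._col_index[v] for v in variant_ids]
        return self.dosages[:, idx]

    def subset_individuals(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            self.dosages[indices, :],
            tuple(self.individual_ids[i] for i in indices),
            self.variant_ids,
        )

    def subset_variants(self, variant_ids: Sequence) -> "GenotypeMatrix":
        return GenotypeMatrix(self.columns(variant_ids), self.individual_ids, tuple(variant_ids))


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency.

    p = sum(dosages) / (2N) is the frequency of the counted allele; the MAF
    is min(p, 1 - p), always in [0, 0.5].
    """
    n = g.n_individuals
    if n == 0:
        raise DataValidationError("cannot compute MAF with zero individuals")
    p = g.dosages.sum(axis=0, dtype=np.float64) / (2.0 * n)
    return np.minimum(p, 1.0 - p)


def classify_variants(
    maf: np.ndarray, rare_threshold: float = 0.01, common_threshold: float = 0.05
) -> np.ndarray:
    """Classify each variant as monomorphic / rare / common / neither.

    ``rare`` means 0 < maf < rare_threshold, ``common`` means
    maf > common_threshold; intermediate frequencies get ``neither`` and take
    part in no analysis.
    """
    if not (0 < rare_threshold <= common_threshold < 0.5):
        raise ConfigurationError(
            f"require 0 < rare_threshold <= common_threshold < 0.5, "
            f"got ({rare_threshold}, {common_threshold})"
        )
    maf = np.asarray(maf, dtype=float)
    out = np.full(maf.shape, "neither", dtype=object)
    out[maf == 0] = "monomorphic"
    out[(maf > 0) & (maf < rare_threshold)] = "rare"
    out[maf > common_threshold] = "common"
    return out


def _standardize_columns(x: np.ndarray):
    """Column-standardize; returns (Z, non_constant_mask). Constant columns are
    left as zeros in Z."""
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=0)
    centered = x - mean
    std = centered.std(axis=0)
    ok = std > 0
    z = np.zeros_like(centered)
    z[:, ok] = centered[:, ok] / std[ok]
    return z, ok


def remove_perfect_ld(
    g: GenotypeMatrix,
    order: Sequence | None = None,
    tol: float = 1e-12,
):
    """Drop variants in perfect LD (r^2 = 1) with an earlier-kept variant.

    ``order`` gives the scan priority (e.g. indices sorted by chromosome,
    position, variant_id); by default the existing column order is used, which
    is assumed position-sorted. Within each group of mutually perfectly
    correlated variants only the first in scan order is kept. Monomorphic
    variants have no defined r^2 and are always retained.

    Returns
    -------
    (reduced GenotypeMatrix, list of excluded variant_ids)
    """
    m = g.n_variants
    if order is None:
        order = range(m)
    order = list(order)
    z, ok = _standardize_columns(g.dosages)
    n = g.n_individuals
    # r matrix over non-constant columns; constant columns never match.
    corr = (z.T @ z) / n
    keep_flags = np.ones(m, dtype=bool)
    kept_so_far: list[int] = []
    for j in order:
        if not ok[j]:
            kept_so_far.append(j)
            continue
        perfect = False
        for k in kept_so_far:
            if ok[k] and corr[j, k] ** 2 >= 1.0 - tol:
                perfect = True
                break
        if perfect:
            keep_flags[j] = False
        else:
            kept_so_far.append(j)
    kept_ids = [g.variant_ids[j] for j in sorted(i for i in range(m) if keep_flags[i])]
    excluded = [g.variant_ids[j] for j in range(m) if not keep_flags[j]]
    if excluded:
        logger.info("remove_perfect_ld: excluded %d of %d variants", len(excluded), m)
    return g.subset_variants(kept_ids), excluded


def build_variant_table(
    g: GenotypeMatrix,
    annotation: pd.DataFrame,
    rare_threshold: float = 0.01,
    common_threshold: float = 0.05,
    excluded_perfect_ld: Sequence = (),
) -> pd.DataFrame:
    """Assemble the per-variant table driving binning and stratification.

    ``annotation`` must carry variant_id, chromosome, position and may carry a
    functional label; missing functional labels become "none". Variants listed
    in ``excluded_perfect_ld`` keep that class regardless of MAF.
    """
    ann = annotation.set_index("variant_id")
    missing = [v for v in g.variant_ids if v not in ann.index]
    if missing:
        raise DataValidationError(f"{len(missing)} variants lack annotation rows, e.g. {missing[:3]}")
    maf = compute_maf(g)
    var_class = classify_variants(maf, rare_threshold, common_threshold)
    table = pd.DataFrame(
        {
            "variant_id": list(g.variant_ids),
            "chromosome": ann.loc[list(g.variant_ids), "chromosome"].astype(str).values,
            "position": ann.loc[list(g.variant_ids), "position"].astype(np.int64).values,
            "maf": maf,
            "var_class": var_class,
        }
    )
    if "functional" in ann.columns:
        table["functional"] = ann.loc[list(g.variant_ids), "functional"].fillna("none").values
    else:
        table["functional"] = "none"
    bad_fun = ~table["functional"].isin(FUNCTIONAL_LABELS)
    if bad_fun.any():
        raise DataValidationError(
            f"unknown functional labels: {sorted(table.loc[bad_fun, 'functional'].unique())}"
        )
    if (table["position"] <= 0).any():
        raise DataValidationError("positions must be positive (1-based)")
    excluded_set = set(excluded_perfect_ld)
    if excluded_set:
        table.loc[table["variant_id"].isin(excluded_set), "var_class"] = "excluded_perfect_ld"
    dup = table.duplicated(subset=["chromosome", "position", "variant_id"])
    if dup.any():
        raise DataValidationError("duplicate (chromosome, position, variant_id) rows")
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, variants: pd.DataFrame, path) -> None:
    """Write dosages as a minimal uncompressed VCF v4.2 (GT only).

    ALT is taken to be the counted (minor) allele, so dosage d maps to
    0/0, 0/1, 1/1 for d = 0, 1, 2. REF/ALT bases are placeholders.
    """
    ann = variants.set_index("variant_id")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(ann.loc[list(g.variant_ids), "chromosome"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in g.individual_ids)
            + "\n"
        )
        rows = ann.loc[list(g.variant_ids)]
        order = np.lexsort((rows["position"].values, rows["chromosome"].astype(str).values))
        for j in order:
            vid = g.variant_ids[j]
            chrom = str(rows["chromosome"].iloc[j])
            pos = int(rows["position"].iloc[j])
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def load_vcf(path):
    """Load a biallelic-SNP VCF into a GenotypeMatrix plus position frame.

    ALT dosages are computed from GT; columns whose ALT frequency exceeds 0.5
    are flipped so that dosages count the minor allele. Missing calls are
    imputed to the rounded per-variant mean and counted in the log.

    Returns
    -------
    (GenotypeMatrix, DataFrame with variant_id / chromosome / position)
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    meta = []
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataValidationError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        gts = np.array([a[0] + a[1] if a[0] >= 0 and a[1] >= 0 else -1 for a in var.genotypes])
        missing = gts < 0
        if missing.any():
            known = gts[~missing]
            fill = int(round(known.mean())) if known.size else 0
            gts = gts.copy()
            gts[missing] = fill
            n_imputed += int(missing.sum())
        p_alt = gts.sum() / (2.0 * len(gts)) if len(gts) else 0.0
        if p_alt > 0.5:
            gts = 2 - gts
        cols.append(gts.astype(np.int8))
        meta.append((var.ID, str(var.CHROM), int(var.POS)))
    vcf.close()
    if n_imputed:
        logger.info("load_vcf: imputed %d missing genotype calls", n_imputed)
    dosages = (
        np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    variant_ids = tuple(m[0] for m in meta)
    frame = pd.DataFrame(meta, columns=["variant_id", "chromosome", "position"])
    return GenotypeMatrix(dosages, tuple(samples), variant_ids), frame


def load_dosage_tsv(path) -> GenotypeMatrix:
    """Read the plain dosage-matrix alternative: header row of variant IDs,
    first column of individual IDs, one row per individual."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        df.values.astype(np.int8), tuple(str(i) for i in df.index), tuple(df.columns)
    )


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=list(g.individual_ids), columns=list(g.variant_ids))
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def load_annotation(path) -> pd.DataFrame:
    """Variant annotation TSV: variant_id, chromosome, position[, functional]."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chromosome": str})
    required = {"variant_id", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"annotation needs columns {sorted(required)}")
    return df


def load_populations(path) -> pd.Series:
    """Population TSV (individual_id, subpopulation) -> Series keyed by id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"individual_id", "subpopulation"}.issubset(df.columns):
        raise DataValidationError("population file needs individual_id and subpopulation columns")
    if df["individual_id"].duplicated().any():
        raise DataValidationError("duplicate individual_id in population file")
    return df.set_index("individual_id")["subpopulation"]


def validate_population_labels(labels: pd.Series, g: GenotypeMatrix) -> None:
    missing = [i for i in g.individual_ids if i not in labels.index]
    if missing:
        raise DataValidationError(f"{len(missing)} individuals lack a subpopulation label")
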