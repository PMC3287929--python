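"""Pairwise LD on genotype dosages, window selection around a focal variant,
and greedy construction of nested tag-SNP sets under pairwise r^2 ceilings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from raretag.errors import ConfigurationError, ConstantVectorError
from raretag.genotype_core import GenotypeMatrix


@dataclass(frozen=True)
class TagSetPair:
    """Nested tag sets A ⊆ B for one focal rare variant.

    All pairs within set_A have r^2 <= threshold_A and all pairs within set_B
    have r^2 <= threshold_B, with threshold_A < threshold_B < 1.
    """

    focal_rare_id: object
    set_A: tuple
    set_B: tuple
    threshold_A: float
    threshold_B: float

    def __post_init__(self):
        if not set(self.set_A).issubset(self.set_B):
            raise ConfigurationError("set_A must be a subset of set_B")
        if not (self.threshold_A < self.threshold_B < 1.0):
            raise ConfigurationError("require threshold_A < threshold_B < 1")

    @property
    def n_A(self) -> int:
        return len(self.set_A)

    @property
    def n_B(self) -> int:
        return len(self.set_B)

    @property
    def set_B_minus_A(self) -> tuple:
        a = set(self.set_A)
        return tuple(v for v in self.set_B if v not in a)


def pairwise_r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors (composite genotypic
    LD). Raises ConstantVectorError if either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = dx @ dx
    vy = dy @ dy
    if vx == 0 or vy == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = (dx @ dy) / np.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def window_select(
    variants: pd.DataFrame, focal_id, width: int
) -> list:
    """Common-class variant IDs within ``width``/2 bp of the focal variant on
    the same chromosome, excluding the focal variant, ordered by position."""
    if width <= 0:
        raise ConfigurationError("window width must be positive")
    row = variants.loc[variants["variant_id"] == focal_id]
    if row.empty:
        raise ConfigurationError(f"focal variant {focal_id!r} not found")
    chrom = row["chromosome"].iloc[0]
    pos = int(row["position"].iloc[0])
    half = width / 2.0
    mask = (
        (variants["chromosome"] == chrom)
        & (variants["var_class"] == "common")
        & (variants["variant_id"] != focal_id)
        & ((variants["position"] - pos).abs() <= half)
    )
    hits = variants.loc[mask].sort_values(["position", "variant_id"])
    return list(hits["variant_id"])


def build_tag_sets(
    g: GenotypeMatrix,
    candidate_ids: Sequence,
    threshold_A: float,
    threshold_B: float,
    focal_rare_id=None,
) -> TagSetPair:
    """Greedy nested tag-set construction.

    First pass scans candidates in the given (position) order and admits a
    candidate into A when its maximum r^2 with current members of A is at most
    ``threshold_A``. Second pass re-scans the rejected candidates in order and
    admits one into B\\A when its maximum r^2 with current members of B is at
    most ``threshold_B``. B = A ∪ (B\\A).
    """
    if not (threshold_A < threshold_B < 1.0):
        raise ConfigurationError("require threshold_A < threshold_B < 1")
    candidate_ids = list(candidate_ids)
    if not candidate_ids:
        return TagSetPair(focal_rare_id, (), (), threshold_A, threshold_B)
    x = g.columns(candidate_ids).astype(np.float64)
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    if (norms == 0).any():
        raise ConstantVectorError("candidate tag SNPs must be non-constant")
    z = centered / norms
    r2 = np.clip((z.T @ z) ** 2, 0.0, 1.0)

    set_a_idx: list[int] = []
    rejected: list[int] = []
    for j in range(len(candidate_ids)):
        if all(r2[j, k] <= threshold_A for k in set_a_idx):
            set_a_idx.append(j)
        else:
            rejected.append(j)
    set_b_idx = list(set_a_idx)
    for j in rejected:
        if all(r2[j, k] <= threshold_B for k in set_b_idx):
            set_b_idx.append(j)
    set_b_idx.sort()
    return TagSetPair(
        focal_rare_id,
        tuple(candidate_ids[j] for j in set_a_idx),
        tuple(candidate_ids[j] for j in set_b_idx),
        threshold_A,
        threshold_B,
    )
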