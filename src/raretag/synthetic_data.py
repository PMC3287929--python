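"""Synthetic genotype generator with controllable LD and population structure.

Cohorts are built from a pool of founder haplotypes whose alleles follow a
first-order Markov chain along the chromosome (adjacent-site correlation
decaying with physical distance), copied into individuals as template mosaics
with a per-base switch rate. Subpopulations differ through Balding-Nichols
perturbed founder weights. Rare variants are then planted either *linked*
(carriers drawn from individuals carrying a designated founder segment, so
the rare allele rides a common-haplotype background) or *unlinked* (carriers
drawn uniformly, independent of every genotype).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from raretag.errors import ConfigurationError, DataValidationError
from raretag.genotype_core import GenotypeMatrix, build_variant_table, compute_maf, write_vcf
from raretag.rng import child_rng

logger = logging.getLogger(__name__)

_MAX_SITE_RETRIES = 200


@dataclass
class SimulationConfig:
    n_individuals: int = 100  # per subpopulation
    n_subpopulations: int = 2
    fst: float = 0.05
    chromosome_length: int = 2_000_000
    n_common: int = 40
    n_rare: int = 20
    ld_decay: float = 2e-5  # per-base decay of founder-haplotype correlation
    n_founders: int = 8
    mosaic_switch_rate: float = 1e-6  # per-base template switch probability
    rare_mode: str = "linked"  # or "unlinked"
    rare_carrier_count: int = 2
    p_nonsynonymous: float = 0.5
    rare_threshold: float = 0.01
    common_threshold: float = 0.05
    chromosome: str = "1"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_individuals, self.n_subpopulations, self.n_common, self.n_rare,
               self.n_founders, self.chromosome_length) <= 0:
            raise ConfigurationError("all counts and lengths must be positive")
        if not (0 <= self.fst < 1):
            raise ConfigurationError("fst must be in [0, 1)")
        if not (0 <= self.p_nonsynonymous <= 1):
            raise ConfigurationError("p_nonsynonymous must be a probability")
        if self.rare_mode not in ("linked", "unlinked"):
            raise ConfigurationError(f"unknown rare_mode {self.rare_mode!r}")
        n_total = self.n_individuals * self.n_subpopulations
        if self.rare_carrier_count < 1:
            raise ConfigurationError("rare_carrier_count must be >= 1")
        if self.rare_carrier_count / (2.0 * n_total) >= self.rare_threshold:
            raise ConfigurationError(
                f"carrier count {self.rare_carrier_count} gives MAF >= "
                f"rare_threshold {self.rare_threshold} at N = {n_total}"
            )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    labels: pd.Series
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def simulate_founders(
    n_founders: int,
    n_common: int,
    ld_decay: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotype pool: (n_founders, n_common) 0/1 array.

    Site j copies site j-1 with probability (1 + rho)/2 where
    rho = exp(-ld_decay * gap); otherwise it flips. This keeps every marginal
    at 1/2 and gives adjacent-site correlation rho within founders, so cohort
    r^2 decays with physical distance. ld_decay -> 0 freezes whole haplotypes;
    ld_decay -> inf makes sites independent.
    """
    positions = np.asarray(positions)
    if positions.shape != (n_common,):
        raise ConfigurationError("positions must have length n_common")
    hap = np.empty((n_founders, n_common), dtype=np.int8)
    hap[:, 0] = rng.integers(0, 2, size=n_founders)
    gaps = np.diff(positions).astype(float)
    rho = np.exp(-ld_decay * gaps)
    for j in range(1, n_common):
        copy = rng.random(n_founders) < (1.0 + rho[j - 1]) / 2.0
        hap[:, j] = np.where(copy, hap[:, j - 1], 1 - hap[:, j - 1])
    return hap


def simulate_subpopulation_frequencies(
    base_freq: float, fst: float, rng: np.random.Generator, size=None
):
    """Balding-Nichols subpopulation frequency draw.

    Beta(p (1-F)/F, (1-p)(1-F)/F) with mean p and variance F p (1-p); F = 0
    returns the base frequency exactly.
    """
    if not (0 < base_freq < 1):
        raise ConfigurationError("base_freq must be in (0, 1)")
    if not (0 <= fst < 1):
        raise ConfigurationError("fst must be in [0, 1)")
    if fst == 0:
        return base_freq if size is None else np.full(size, base_freq)
    scale = (1.0 - fst) / fst
    draw = rng.beta(base_freq * scale, (1.0 - base_freq) * scale, size=size)
    return float(draw) if size is None else draw


def _founder_weights(n_founders: int, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Per-subpopulation founder weights: independent Balding-Nichols draws
    around the uniform weight, normalized. fst = 0 gives exactly uniform."""
    if fst == 0:
        return np.full(n_founders, 1.0 / n_founders)
    raw = simulate_subpopulation_frequencies(1.0 / n_founders, fst, rng, size=n_founders)
    raw = np.clip(raw, 1e-9, None)
    return raw / raw.sum()


def simulate_individuals(
    founders: np.ndarray,
    founder_weights: np.ndarray,
    mosaic_switch_rate: float,
    n: int,
    positions: np.ndarray,
    rng: np.random.Generator,
):
    """Diploid dosages for one subpopulation.

    Each of the 2n haplotypes is a mosaic of founder templates: the template
    index switches between consecutive sites with probability
    1 - exp(-rate * gap), the new template drawn from ``founder_weights``.

    Returns (dosages (n, M) int8, templates (n, 2, M) int16).
    """
    n_founders, m = founders.shape
    positions = np.asarray(positions)
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-mosaic_switch_rate * gaps)
    templates = np.empty((n, 2, m), dtype=np.int16)
    for i in range(n):
        for h in range(2):
            t = rng.choice(n_founders, p=founder_weights)
            templates[i, h, 0] = t
            switch = rng.random(m - 1) < p_switch
            for j in range(1, m):
                if switch[j - 1]:
                    t = rng.choice(n_founders, p=founder_weights)
                templates[i, h, j] = t
    hap_alleles = founders[templates, np.arange(m)]  # (n, 2, M)
    dosages = hap_alleles.sum(axis=1).astype(np.int8)
    return dosages, templates


def place_rare_variants(
    templates: np.ndarray,
    common_positions: np.ndarray,
    rare_positions: np.ndarray,
    rare_mode: str,
    carrier_count: int,
    rng: np.random.Generator,
):
    """Plant heterozygous rare variants and record the generative truth.

    linked: carriers are sampled from individuals carrying a designated
    founder template at the common site nearest the rare position, so carrier
    status coincides with a common-haplotype background. unlinked: carriers
    are sampled uniformly, independent of all genotypes.

    Returns (rare dosage matrix (N, n_rare) int8, truth DataFrame).
    """
    n = templates.shape[0]
    n_founders = int(templates.max()) + 1
    if carrier_count > n:
        raise ConfigurationError("carrier_count exceeds cohort size")
    cols = np.zeros((n, len(rare_positions)), dtype=np.int8)
    truth_rows = []
    for j, pos in enumerate(rare_positions):
        anchor = int(np.argmin(np.abs(common_positions - pos)))
        if rare_mode == "unlinked":
            carriers = rng.choice(n, size=carrier_count, replace=False)
            founder = -1
        else:
            order = rng.permutation(n_founders)
            carriers = None
            for founder in order:
                eligible = np.flatnonzero((templates[:, :, anchor] == founder).any(axis=1))
                if eligible.size >= carrier_count:
                    carriers = rng.choice(eligible, size=carrier_count, replace=False)
                    break
            if carriers is None:
                raise DataValidationError(
                    f"no founder segment at anchor site {anchor} has >= "
                    f"{carrier_count} carriers"
                )
        cols[carriers, j] = 1
        truth_rows.append(
            {
                "position": int(pos),
                "mode": rare_mode,
                "founder": int(founder),
                "anchor_position": int(common_positions[anchor]),
                "n_carriers": int(carrier_count),
            }
        )
    return cols, pd.DataFrame(truth_rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic cohort per the config; fully deterministic
    given config.seed."""
    seed = config.seed
    n_total = config.n_individuals * config.n_subpopulations

    pos_rng = child_rng(seed, "positions")
    all_pos = pos_rng.choice(
        np.arange(1, config.chromosome_length + 1),
        size=config.n_common + config.n_rare,
        replace=False,
    )
    all_pos.sort()
    pick_common = np.sort(pos_rng.choice(all_pos.size, size=config.n_common, replace=False))
    mask = np.zeros(all_pos.size, dtype=bool)
    mask[pick_common] = True
    common_pos = all_pos[mask]
    rare_pos = all_pos[~mask]

    founders = simulate_founders(
        config.n_founders, config.n_common, config.ld_decay, common_pos,
        child_rng(seed, "founders"),
    )

    dosage_blocks, template_blocks, labels = [], [], []
    for s in range(config.n_subpopulations):
        w = _founder_weights(config.n_founders, config.fst, child_rng(seed, "weights", s))
        d, t = simulate_individuals(
            founders, w, config.mosaic_switch_rate, config.n_individuals, common_pos,
            child_rng(seed, "individuals", s),
        )
        dosage_blocks.append(d)
        template_blocks.append(t)
        labels.extend([f"pop{s + 1}"] * config.n_individuals)
    common_dosages = np.vstack(dosage_blocks)
    templates = np.vstack(template_blocks)

    # Enforce realized common MAF above the common threshold: redraw the
    # founder alleles of violating sites and rebuild the column from the
    # fixed mosaic paths, which leaves every other column untouched.
    fix_rng = child_rng(seed, "maf_fix")
    for j in range(config.n_common):
        for attempt in range(_MAX_SITE_RETRIES):
            p = common_dosages[:, j].sum() / (2.0 * n_total)
            if min(p, 1 - p) > config.common_threshold:
                break
            founders[:, j] = fix_rng.integers(0, 2, size=config.n_founders)
            common_dosages[:, j] = founders[templates[:, :, j], j].sum(axis=1)
        else:
            raise DataValidationError(f"could not realize common MAF at site {j}")
    # orient to minor allele
    p = common_dosages.sum(axis=0) / (2.0 * n_total)
    flip = p > 0.5
    common_dosages[:, flip] = 2 - common_dosages[:, flip]

    rare_dosages, truth = place_rare_variants(
        templates, common_pos, rare_pos, config.rare_mode, config.rare_carrier_count,
        child_rng(seed, "rares"),
    )

    fun_rng = child_rng(seed, "functional")
    rare_functional = np.where(
        fun_rng.random(config.n_rare) < config.p_nonsynonymous, "nonsynonymous", "synonymous"
    )

    common_ids = [f"c{p:09d}" for p in common_pos]
    rare_ids = [f"r{p:09d}" for p in rare_pos]
    truth.insert(0, "variant_id", rare_ids)
    ann = pd.DataFrame(
        {
            "variant_id": common_ids + rare_ids,
            "chromosome": config.chromosome,
            "position": np.concatenate([common_pos, rare_pos]),
            "functional": ["none"] * config.n_common + list(rare_functional),
        }
    ).sort_values("position", kind="stable", ignore_index=True)

    dosages = np.hstack([common_dosages, rare_dosages])
    order = np.argsort(np.concatenate([common_pos, rare_pos]), kind="stable")
    dosages = dosages[:, order]
    variant_ids = [(common_ids + rare_ids)[k] for k in order]
    individual_ids = tuple(f"ind{i:05d}" for i in range(n_total))
    g = GenotypeMatrix(dosages, individual_ids, tuple(variant_ids))

    variants = build_variant_table(g, ann, config.rare_threshold, config.common_threshold)
    realized = variants.set_index("variant_id")
    bad_common = [v for v in common_ids if realized.loc[v, "var_class"] != "common"]
    bad_rare = [v for v in rare_ids if realized.loc[v, "var_class"] != "rare"]
    if bad_common or bad_rare:
        raise DataValidationError(
            f"realized classes off target: {len(bad_common)} commons, {len(bad_rare)} rares"
        )
    label_series = pd.Series(labels, index=list(individual_ids), name="subpopulation")
    return SimulatedDataset(g, variants, label_series, truth, config)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir) -> dict:
    """Write VCF + annotation/population/truth TSVs; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "annotation": out / "annotation.tsv",
        "populations": out / "populations.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(dataset.genotypes, dataset.variants, paths["vcf"])
    dataset.variants[["variant_id", "chromosome", "position", "functional"]].to_csv(
        paths["annotation"], sep="\t", index=False
    )
    dataset.labels.rename_axis("individual_id").reset_index().to_csv(
        paths["populations"], sep="\t", index=False
    )
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    if dataset.config is not None:
        dataset.config.to_json(out / "sim_config.json")
        paths["config"] = out / "sim_config.json"
    return paths
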