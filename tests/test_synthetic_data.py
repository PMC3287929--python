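import logging

import numpy as np
import pytest

from raretag.cli import load_inputs
from raretag.errors import ConfigurationError
from raretag.genotype_core import compute_maf
from raretag.ld_structure import pairwise_r2
from raretag.synthetic_data import (
    SimulationConfig,
    place_rare_variants,
    simulate_dataset,
    simulate_founders,
    simulate_individuals,
    simulate_subpopulation_frequencies,
    write_dataset,
)

SMALL = dict(
    n_individuals=60,
    n_subpopulations=2,
    fst=0.05,
    chromosome_length=1_000_000,
    n_common=15,
    n_rare=8,
    ld_decay=1e-5,
    n_founders=6,
    rare_carrier_count=2,
    seed=0,
)


class TestSimulationConfig:
    def test_carrier_count_vs_rare_threshold(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_individuals=50, n_subpopulations=1, rare_carrier_count=5)

    def test_fst_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(fst=1.0)

    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(**SMALL)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimulationConfig.from_json(path) == cfg


class TestSimulateFounders:
    def test_tiny_decay_freezes_haplotypes(self, rng):
        positions = np.arange(1, 21) * 1000
        hap = simulate_founders(50, 20, 1e-12, positions, rng)
        # flip probability ~ 0: every founder is constant along the chromosome
        assert all(np.ptp(hap[f]) == 0 for f in range(50))

    def test_huge_decay_independent_sites(self, rng):
        positions = np.arange(1, 401) * 10_000
        hap = simulate_founders(200, 400, 1e3, positions, rng)
        adj = np.array([
            np.corrcoef(hap[:, j], hap[:, j + 1])[0, 1] for j in range(0, 399, 20)
        ])
        assert np.abs(np.nanmean(adj)) < 0.05

    def test_adjacent_correlation_matches_decay(self):
        # Monte-Carlo oracle: adjacent-site correlation should approximate
        # rho = exp(-decay * gap) for +-1-coded alleles
        decay, gap = 2e-5, 30_000
        rho = np.exp(-decay * gap)
        positions = np.arange(1, 101) * gap
        rng = np.random.default_rng(42)
        hap = simulate_founders(4000, 100, decay, positions, rng)
        signed = 2.0 * hap - 1.0
        est = np.mean([
            np.corrcoef(signed[:, j], signed[:, j + 1])[0, 1] for j in range(99)
        ])
        assert est == pytest.approx(rho, abs=0.03)

    def test_marginal_half(self, rng):
        positions = np.arange(1, 51) * 1000
        hap = simulate_founders(2000, 50, 1e-5, positions, rng)
        assert hap.mean() == pytest.approx(0.5, abs=0.03)


class TestSubpopulationFrequencies:
    def test_fst_zero_identity(self, rng):
        assert simulate_subpopulation_frequencies(0.3, 0.0, rng) == 0.3

    def test_mean_matches_base(self, rng):
        draws = simulate_subpopulation_frequencies(0.3, 0.1, rng, size=20_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.3) < 4 * se

    def test_variance_matches_balding_nichols(self, rng):
        p, fst = 0.3, 0.1
        draws = simulate_subpopulation_frequencies(p, fst, rng, size=20_000)
        target = fst * p * (1 - p)
        assert draws.var() == pytest.approx(target, rel=0.1)

    def test_bad_base_freq(self, rng):
        with pytest.raises(ConfigurationError):
            simulate_subpopulation_frequencies(0.0, 0.1, rng)


class TestSimulateIndividuals:
    def test_single_founder_no_switch(self, rng):
        positions = np.arange(1, 11) * 1000
        founders = simulate_founders(1, 10, 1e-5, positions, rng)
        dosages, templates = simulate_individuals(
            founders, np.array([1.0]), 0.0, 5, positions, rng
        )
        expected = 2 * founders[0]
        assert (dosages == expected).all()
        assert (templates == 0).all()

    def test_dosage_bounds(self, rng):
        positions = np.arange(1, 21) * 1000
        founders = simulate_founders(5, 20, 1e-5, positions, rng)
        dosages, _ = simulate_individuals(
            founders, np.full(5, 0.2), 1e-5, 30, positions, rng
        )
        assert np.isin(dosages, (0, 1, 2)).all()

    def test_ld_decays_with_distance(self):
        from scipy.stats import spearmanr

        cfg = SimulationConfig(**{**SMALL, "n_individuals": 200, "n_common": 30, "seed": 9})
        ds = simulate_dataset(cfg)
        commons = ds.variants[ds.variants.var_class == "common"]
        ids = list(commons.variant_id)
        pos = commons.set_index("variant_id")["position"]
        dists, r2s = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ds.genotypes.column(ids[i]), ds.genotypes.column(ids[j])
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    continue
                dists.append(abs(pos[ids[i]] - pos[ids[j]]))
                r2s.append(pairwise_r2(a, b))
        rho, _ = spearmanr(dists, r2s)
        assert rho < 0


class TestPlaceRareVariants:
    def _templates(self, rng, n=200, m=10, n_founders=5):
        return rng.integers(0, n_founders, size=(n, 2, m)).astype(np.int16)

    def test_unlinked_independent_of_genotype(self, rng):
        templates = self._templates(rng)
        common_pos = np.arange(1, 11) * 1000
        cols, truth = place_rare_variants(
            templates, common_pos, np.array([5500]), "unlinked", 4, rng
        )
        assert cols.sum() == 4
        assert (truth["founder"] == -1).all()

    def test_linked_carriers_on_background(self, rng):
        templates = self._templates(rng)
        common_pos = np.arange(1, 11) * 1000
        cols, truth = place_rare_variants(
            templates, common_pos, np.array([5500]), "linked", 4, rng
        )
        founder = truth["founder"].iloc[0]
        anchor = np.argmin(np.abs(common_pos - 5500))
        carriers = np.flatnonzero(cols[:, 0])
        assert all((templates[c, :, anchor] == founder).any() for c in carriers)

    def test_linked_nested_indicator_r2_closed_form(self, rng):
        # one founder per individual (both haplotypes), common SNP = exact
        # founder indicator: r^2 between rare dosage and that SNP follows the
        # closed form p_y (1 - p_z) / ((1 - p_y) p_z) for nested binaries
        n, n_founders, carriers = 500, 5, 4
        assign = rng.integers(0, n_founders, size=n)
        templates = np.repeat(assign[:, None], 2, axis=1)[:, :, None].astype(np.int16)
        common_pos = np.array([1000])
        cols, truth = place_rare_variants(
            templates, common_pos, np.array([1500]), "linked", carriers, rng
        )
        founder = truth["founder"].iloc[0]
        z = (assign == founder).astype(float)  # diploid dosage would be 2z
        y = cols[:, 0].astype(float)
        p_y, p_z = y.mean(), z.mean()
        expected = p_y * (1 - p_z) / ((1 - p_y) * p_z)
        assert pairwise_r2(y, 2 * z) == pytest.approx(expected, abs=1e-12)

    def test_unlinked_calibration(self):
        # carrier status independent of templates: correlation with the
        # founder indicator is near zero on average over repetitions
        r2s = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            assign = rng.integers(0, 5, size=400)
            templates = np.repeat(assign[:, None], 2, axis=1)[:, :, None].astype(np.int16)
            cols, _ = place_rare_variants(
                templates, np.array([1000]), np.array([1500]), "unlinked", 3, rng
            )
            z = (assign == 0).astype(float)
            r2s.append(pairwise_r2(cols[:, 0].astype(float), z))
        assert np.mean(r2s) < 0.02


class TestSimulateDataset:
    def test_realized_classes(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        counts = ds.variants["var_class"].value_counts()
        assert counts.get("common", 0) == SMALL["n_common"]
        assert counts.get("rare", 0) == SMALL["n_rare"]

    def test_rare_maf_below_threshold(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        maf = compute_maf(ds.genotypes)
        rare_mask = ds.variants["var_class"].values == "rare"
        assert (maf[rare_mask] < 0.01).all()

    def test_truth_covers_every_rare(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        rare_ids = set(ds.variants.loc[ds.variants.var_class == "rare", "variant_id"])
        assert set(ds.truth["variant_id"]) == rare_ids

    def test_deterministic_given_seed(self):
        a = simulate_dataset(SimulationConfig(**SMALL))
        b = simulate_dataset(SimulationConfig(**SMALL))
        assert (a.genotypes.dosages == b.genotypes.dosages).all()
        assert a.variants.equals(b.variants)

    def test_labels_cover_everyone(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        assert len(ds.labels) == ds.genotypes.n_individuals
        assert set(ds.labels) == {"pop1", "pop2"}

    def test_functional_fraction(self):
        cfg = SimulationConfig(**{**SMALL, "n_rare": 60, "n_individuals": 3100,
                                  "p_nonsynonymous": 0.3, "seed": 5})
        ds = simulate_dataset(cfg)
        rares = ds.variants[ds.variants.var_class == "rare"]
        frac = (rares["functional"] == "nonsynonymous").mean()
        # binomial tolerance: 4 sigma around 0.3 with n = 60
        assert abs(frac - 0.3) < 4 * np.sqrt(0.3 * 0.7 / 60)


class TestWriteDataset:
    def test_round_trip_and_files(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        paths = write_dataset(ds, tmp_path)
        for key in ("vcf", "annotation", "populations", "truth", "config"):
            assert paths[key].exists()
        g, variants, labels = load_inputs(tmp_path, 0.01, 0.05)
        for v in g.variant_ids:
            assert (g.column(v) == ds.genotypes.column(v)).all()
        assert (labels.reindex(list(g.individual_ids)) == ds.labels).all()

    def test_truth_rows(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        write_dataset(ds, tmp_path)
        import pandas as pd

        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth) == SMALL["n_rare"]

    def test_byte_deterministic(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(simulate_dataset(SimulationConfig(**SMALL)), tmp_path / sub)
        for name in ("genotypes.vcf", "annotation.tsv", "populations.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_linked_mode_raises_stage1_correlation(caplog):
    """Paired across seeds: linked-mode datasets must beat matched unlinked
    datasets on mean adjusted R^2 (light version of the acceptance check)."""
    from raretag.bin_correlation import Stage1Config, run_stage1

    caplog.set_level(logging.ERROR)
    diffs = []
    for seed in range(8):
        means = {}
        for mode in ("linked", "unlinked"):
            cfg = SimulationConfig(
                n_individuals=150, n_subpopulations=2, fst=0.05,
                chromosome_length=1_000_000, n_common=15, n_rare=12,
                ld_decay=1e-5, n_founders=12, rare_carrier_count=4,
                rare_mode=mode, seed=seed,
            )
            ds = simulate_dataset(cfg)
            s1 = Stage1Config(n_s=5, seed=seed, min_stratum_size=10**9)
            out = run_stage1(ds.genotypes, ds.variants, ds.labels, s1)
            rows = out[(out.stratum == "all") & (out.functional == "all")]
            means[mode] = rows["adjusted_R2"].mean()
        diffs.append(means["linked"] - means["unlinked"])
    assert np.mean(diffs) > 0
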