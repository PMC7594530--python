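"""Wright–Fisher sorting simulator: sampling, drift, selection, arithmetic."""

import numpy as np
import pytest
import scipy.stats

import karyosort as ks
from conftest import race_pair


class TestSampleGamete:
    def test_homozygote_yields_unique_haplotype(self):
        race = ks.swedish_race()
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert ks.sample_gamete(race.genotype(), rng) == race.gamete()

    def test_heterozygous_sites_segregate_evenly(self):
        _, p1, p2 = race_pair(2)
        f1 = ks.f1_hybrid(p1, p2)
        rng = np.random.default_rng(1)
        counts: dict[tuple, int] = {}
        for _ in range(20_000):
            key = ks.sample_gamete(f1, rng).alleles
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 4
        assert scipy.stats.chisquare(list(counts.values())).pvalue > 0.001


class TestNextGeneration:
    def test_homozygous_identical_population_is_static(self):
        race = ks.swedish_race()
        state = ks.PopulationState(0, tuple(race.genotype() for _ in range(6)))
        nxt = ks.next_generation(state, 6, rng=np.random.default_rng(2))
        assert nxt.generation == 1
        assert all(g == race.genotype() for g in nxt.individuals)

    def test_tiny_population_rejected(self):
        state = ks.PopulationState(0, (ks.spanish_race().genotype(),))
        with pytest.raises(ValueError, match="size"):
            ks.next_generation(state, 4, rng=np.random.default_rng(0))

    def test_monogamous_pairs_mode_runs(self):
        _, ra, rb = race_pair(4)
        cfg = ks.SimulationConfig(
            ra.architecture, ra, rb, sizes=(8,), generations=5, replicates=3,
            seed=5, mating="monogamous_pairs",
        )
        out = ks.run_simulation(cfg)
        assert out.mean_h.shape == (3, 6)


class TestDriftProperties:
    def test_allele_frequency_is_a_martingale(self):
        """Neutral single site: mean frequency stays at 1/2 (binomial theory)."""
        arch, ra, rb = race_pair(1, 3)
        cfg = ks.SimulationConfig(
            arch, ra, rb, sizes=(20,), generations=5, replicates=2000,
            seed=9, keep_populations=True,
        )
        out = ks.run_simulation(cfg)
        freqs = np.array(
            [np.mean([g[0] for g in out.populations[r][5]]) / 2.0 for r in range(2000)]
        )
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - 0.5) < 3 * se

    def test_selection_accelerates_homozygosity(self):
        """Underdominant fecundity (w = 0.42) purges heterozygotes faster."""
        arch, ra, rb = race_pair(2, 5)
        base = dict(sizes=(16,), generations=10, replicates=500)
        neutral = ks.run_simulation(
            ks.SimulationConfig(arch, ra, rb, seed=21, **base)
        )
        selected = ks.run_simulation(
            ks.SimulationConfig(
                arch, ra, rb, seed=22,
                fitness=ks.FitnessModel(mode="flat_hybrid", w=0.42), **base,
            )
        )
        assert selected.mean_h[:, 10].mean() < neutral.mean_h[:, 10].mean() * 0.7

    def test_fixed_fraction_monotone_and_absorbing(self):
        arch, ra, rb = race_pair(3, 7)
        cfg = ks.SimulationConfig(
            arch, ra, rb, sizes=(6,), generations=200, replicates=50, seed=31
        )
        out = ks.run_simulation(cfg)
        assert (np.diff(out.frac_sites_fixed, axis=1) >= 0).all()
        assert (out.fixation_generation >= 0).all()
        assert all(c != "unfixed" for c in out.final_class)

    def test_novel_karyotype_law(self):
        """P(parental outcome) = 2 / 2^F under neutral independent sites."""
        for n_sites, seed in ((2, 41), (4, 43)):
            arch, ra, rb = race_pair(n_sites)
            cfg = ks.SimulationConfig(
                arch, ra, rb, sizes=(8,), generations=400, replicates=400, seed=seed
            )
            out = ks.run_simulation(cfg)
            parental = sum(c.startswith("parental") for c in out.final_class)
            expected = 2.0 / 2**n_sites
            tol = 4 * np.sqrt(expected * (1 - expected) / 400)
            assert abs(parental / 400 - expected) < tol

    def test_seed_determinism(self):
        arch, ra, rb = race_pair(5)
        cfg = ks.SimulationConfig(arch, ra, rb, sizes=(10,), generations=10,
                                  replicates=4, seed=77)
        a, b = ks.run_simulation(cfg), ks.run_simulation(cfg)
        assert np.array_equal(a.mean_h, b.mean_h)
        assert np.array_equal(a.fixation_generation, b.fixation_generation)
        assert a.final_class == b.final_class


class TestDriftArithmetic:
    def test_harmonic_mean_of_experimental_sizes(self):
        n_eff = ks.harmonic_mean_Ne((8, 12, 24, 40))
        assert n_eff == pytest.approx(14.545, abs=0.001)
        assert round(n_eff) == 15

    def test_harmonic_mean_equal_and_skewed(self):
        assert ks.harmonic_mean_Ne((10, 10, 10)) == pytest.approx(10.0)
        assert ks.harmonic_mean_Ne((4, 400)) == pytest.approx(7.92, abs=0.005)

    def test_harmonic_mean_errors(self):
        with pytest.raises(ValueError):
            ks.harmonic_mean_Ne(())
        with pytest.raises(ValueError):
            ks.harmonic_mean_Ne((0, 5))

    @pytest.mark.parametrize("n_eff,expected", [(15, 60), (2, 8), (1, 4)])
    def test_4n_horizon(self, n_eff, expected):
        assert ks.neutral_fixation_expectation(n_eff) == expected

    def test_diffusion_mean_is_below_4n(self):
        assert ks.diffusion_fixation_time(15) == pytest.approx(60 * np.log(2), rel=1e-12)
        assert ks.diffusion_fixation_time(15) < ks.neutral_fixation_expectation(15)


class TestConfig:
    def test_config_validation(self):
        arch, ra, rb = race_pair(2)
        with pytest.raises(ValueError, match=">= 2"):
            ks.SimulationConfig(arch, ra, rb, sizes=(1,))
        with pytest.raises(ValueError, match="founder_mix"):
            ks.SimulationConfig(arch, ra, rb, founder_mix=(0.5, 0.5, 0.5))

    def test_sizes_recycle(self):
        arch, ra, rb = race_pair(2)
        cfg = ks.SimulationConfig(arch, ra, rb, sizes=(8, 12, 24, 40), generations=6)
        assert [cfg.size_at(t) for t in range(6)] == [8, 12, 24, 40, 8, 12]

    def test_config_from_document(self):
        doc = {
            "sizes": [8, 12], "generations": 4, "replicates": 2,
            "fitness": {"mode": "flat_hybrid", "w": 0.42}, "seed": 3,
        }
        cfg = ks.simulate.simulation_config_from_document(doc, seed=9)
        assert cfg.seed == 9  # explicit seed overrides the document
        assert cfg.race_b.name == "swedish"
        assert cfg.fitness.mode == "flat_hybrid"

    def test_founder_mix_population(self):
        arch, ra, rb = race_pair(3)
        cfg = ks.SimulationConfig(
            arch, ra, rb, sizes=(30,), generations=1, replicates=1,
            founder_mix=(0.5, 0.5, 0.0), seed=4, keep_populations=True,
        )
        out = ks.run_simulation(cfg)
        founders = out.genotypes_at(0, 0)
        assert all(g.h == 0 for g in founders)  # pure parental mixture
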