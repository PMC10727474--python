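import numpy as np
import pytest

from acdsim import dynamics as dy, genotype as gt
from acdsim.diffusion import FactorId


def small_cfg(**kw):
    defaults = dict(p_death=0.05, immune_alpha=0.0, mutation_rate=0.0)
    defaults.update(kw)
    return dy.StepConfig(**defaults)


class TestDeathPhase:
    def test_no_death_sources_leave_lattice_unchanged(self, rng):
        lat = dy.Lattice.full((10, 10), gt.make_archetype("CANCER_FULL"))
        out = dy.death_phase(lat, small_cfg(p_death=0.0), rng)
        assert out.alive.all()

    def test_certain_death_empties_the_lattice(self, rng):
        lat = dy.Lattice.full((10, 10), gt.Genotype())
        out = dy.death_phase(lat, small_cfg(p_death=1.0), rng)
        assert not out.alive.any()

    def test_vacancies_stay_vacant(self, rng):
        lat = dy.Lattice.full((6, 6), gt.Genotype())
        lat.alive[2, 3] = False
        out = dy.death_phase(lat, small_cfg(p_death=0.0), rng)
        assert not out.alive[2, 3]

    def test_empirical_death_rate_matches_binomial(self, rng):
        # ~1e5 wild-type cells, one phase: rate within 4 sigma of p_death
        p = 0.05
        lat = dy.Lattice.full((320, 320), gt.Genotype())
        out = dy.death_phase(lat, small_cfg(p_death=p), rng)
        n = lat.live_count
        died = n - out.live_count
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(died - n * p) < 4 * sigma

    def test_immune_detection_adds_to_mortality(self, rng):
        # fully mutated cells without evasion die at 1-(1-p)(1-alpha)
        code = 0b011111111  # all but immune_evade
        lat = dy.Lattice.full((320, 320), gt.Genotype.from_code(code))
        cfg = small_cfg(p_death=0.05, immune_alpha=0.18)
        p_tot = 1 - (1 - 0.05) * (1 - 0.18 * 8 / 9)
        out = dy.death_phase(lat, cfg, rng)
        n = lat.live_count
        died = n - out.live_count
        sigma = np.sqrt(n * p_tot * (1 - p_tot))
        assert abs(died - n * p_tot) < 4 * sigma


class TestBirthPhase:
    def lattice_with_gap(self):
        lat = dy.Lattice.full((1, 3), gt.Genotype())
        lat.geno[0, 0] = gt.make_archetype("CANCER_FULL").code
        lat.alive[0, 1] = False
        return lat

    def test_single_live_neighbour_is_forced(self, rng):
        lat = dy.Lattice.full((1, 2), gt.make_archetype("HT_WARBURG"))
        lat.alive[0, 0] = False
        fit = np.where(lat.alive, 1.0, np.nan)
        out = dy.birth_phase(lat, fit, rng)
        assert out.alive.all()
        assert out.geno[0, 0] == gt.make_archetype("HT_WARBURG").code

    def test_isolated_vacancy_stays_empty(self, rng):
        lat = dy.Lattice.full((3, 3), gt.Genotype())
        lat.alive[:] = False
        out = dy.birth_phase(lat, np.full((3, 3), np.nan), rng)
        assert not out.alive.any()

    def test_full_lattice_unchanged(self, rng):
        lat = dy.Lattice.full((4, 4), gt.Genotype())
        out = dy.birth_phase(lat, np.ones((4, 4)), rng)
        np.testing.assert_array_equal(out.geno, lat.geno)
        assert out.alive.all()

    def test_selection_is_fitness_proportional(self, rng):
        # two parents with fitness 3 and 1: the fitter wins ~75% of 1e4 fills
        lat = self.lattice_with_gap()
        fit = np.array([[3.0, np.nan, 1.0]])
        cancer = gt.make_archetype("CANCER_FULL").code
        wins = 0
        trials = 10_000
        for _ in range(trials):
            out = dy.birth_phase(lat, fit, rng)
            wins += out.geno[0, 1] == cancer
        se = np.sqrt(trials * 0.75 * 0.25)
        assert abs(wins - 0.75 * trials) < 4 * se

    def test_zero_fitness_parents_fall_back_to_uniform(self, rng):
        lat = self.lattice_with_gap()
        floor = 1e-9
        fit = np.array([[floor, np.nan, floor]])
        cancer = gt.make_archetype("CANCER_FULL").code
        wins = sum(
            dy.birth_phase(lat, fit, rng, floor=floor).geno[0, 1] == cancer
            for _ in range(2000)
        )
        se = np.sqrt(2000 * 0.25)
        assert abs(wins - 1000) < 4 * se


class TestMutationPhase:
    def test_zero_rate_is_identity(self, rng):
        lat = dy.Lattice.full((5, 5), gt.Genotype())
        out = dy.mutation_phase(lat, 0.0, rng)
        np.testing.assert_array_equal(out.geno, lat.geno)

    def test_only_live_cells_mutate(self, rng):
        lat = dy.Lattice.full((20, 20), gt.Genotype())
        lat.alive[5:, :] = False
        out = dy.mutation_phase(lat, 0.2, rng)
        np.testing.assert_array_equal(out.geno[5:, :], lat.geno[5:, :])
        assert (out.geno[:5, :] != 0).any()

    def test_empirical_rate_matches_bernoulli(self, rng):
        rate = 5e-3
        lat = dy.Lattice.full((100, 100), gt.Genotype())
        out = dy.mutation_phase(lat, rate, rng)
        lut = gt.mutated_fraction_lut()
        events = lut[out.geno].sum() * gt.N_LOCI
        n = lat.geno.size * gt.N_LOCI
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(events - n * rate) < 4 * sigma

    def test_mutation_is_one_way(self, rng):
        lat = dy.Lattice.full((10, 10), gt.Genotype.from_code(0b101010101))
        out = dy.mutation_phase(lat, 0.3, rng)
        assert (out.geno & lat.geno == lat.geno).all()


class TestStepAndRun:
    def test_site_conservation_through_a_step(self, rng):
        cfg = small_cfg(p_death=0.3, mutation_rate=1e-3)
        lat = dy.Lattice.full((20, 20), gt.make_archetype("CANCER_FULL"))
        kernels = cfg.build_kernels()
        out, m = dy.step(lat, cfg, kernels, rng)
        assert out.shape == (20, 20)
        assert m.live_count == out.alive.sum()
        assert m.live_count + (~out.alive).sum() == 400

    def test_metric_proportions_sum_to_one(self):
        cfg = small_cfg(mutation_rate=1e-3)
        lat = dy.Lattice.full((15, 15), gt.Genotype())
        ts = dy.run(lat, cfg, 20, seed=3)
        total = ts[["normal", "cancer", "hypertumour",
                    "partial_hypertumour", "other_mutant"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    @pytest.mark.parametrize("archetype,column", [
        ("NORMAL", "normal"),
        ("HT_WARBURG", "hypertumour"),
    ])
    def test_monotype_without_mutation_is_absorbing(self, archetype, column):
        lat = dy.Lattice.full((20, 20), gt.make_archetype(archetype))
        ts = dy.run(lat, small_cfg(), 50, seed=9)
        assert (ts[column] == 1.0).all()

    def test_heredity_without_mutation(self):
        # only the two seeded genotypes can ever appear
        lat = dy.Lattice.full((16, 16), gt.Genotype())
        lat.geno[4:8, 4:8] = gt.make_archetype("CANCER_FULL").code
        cfg = small_cfg(p_death=0.2)
        rand = np.random.default_rng(5)
        kernels = cfg.build_kernels()
        allowed = {0, gt.make_archetype("CANCER_FULL").code}
        for _ in range(30):
            lat, _ = dy.step(lat, cfg, kernels, rand)
            assert set(np.unique(lat.geno[lat.alive])) <= allowed

    def test_extinct_normals_never_recover(self):
        # mutation on, no normal cells anywhere: none can ever arise
        lat = dy.Lattice.full((20, 20), gt.Genotype(rec_gf1=True))
        ts = dy.run(lat, small_cfg(mutation_rate=1e-3), 100, seed=13)
        assert (ts["normal"] == 0.0).all()

    def test_same_seed_reproduces_bit_for_bit(self):
        lat = dy.Lattice.full((20, 20), gt.Genotype())
        lat.geno[8:12, 8:12] = gt.make_archetype("CANCER_FULL").code
        cfg = small_cfg(p_death=0.1, mutation_rate=1e-4)
        a = dy.run(lat, cfg, 30, seed=21)
        b = dy.run(lat, cfg, 30, seed=21)
        assert a.equals(b)

    def test_different_seeds_diverge(self):
        lat = dy.Lattice.full((20, 20), gt.Genotype())
        lat.geno[8:12, 8:12] = gt.make_archetype("CANCER_FULL").code
        cfg = small_cfg(p_death=0.1, mutation_rate=1e-4)
        a = dy.run(lat, cfg, 30, seed=21)
        b = dy.run(lat, cfg, 30, seed=22)
        assert not a.equals(b)

    def test_single_step_run_equals_run_of_length_one(self):
        lat = dy.Lattice.full((10, 10), gt.Genotype())
        ts = dy.run(lat, small_cfg(), 1, seed=7)
        assert len(ts) == 1
        assert ts["live_count"].iloc[0] <= 100

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="p_death"):
            dy.StepConfig(p_death=1.5)
        with pytest.raises(ValueError, match="n_steps"):
            dy.run(dy.Lattice.full((4, 4), gt.Genotype()), small_cfg(), 0, seed=1)
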