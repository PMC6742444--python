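import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from toxkil import dynamics
from toxkil.dynamics import (
    Allele,
    CorruptedStateError,
    Genotype,
    Lattice,
    StepOptions,
    VIABLE_PAIRS,
    initialise_lattice,
    is_viable,
    mutate_offspring,
    reproduction_sweep,
    reproductive_fitness,
    death_sweep,
    shuffle_positions,
    step,
    update_phenotypes,
)
from toxkil.params import LumpedParams, expand_lumped

from conftest import REGREG_KILLER, REG_KILLER, SENSITIVE


def _single_cell_lattice(genotype: Genotype, N: int = 8) -> Lattice:
    lattice = Lattice(N)
    lattice.place(np.array([(N // 2) * N + N // 2]), genotype)
    return lattice


def _expression_possible(toxin_gene, resistance_gene):
    """Brute-force: can toxin ever be expressed without resistance?

    Enumerates the reachable expression states over cue below/above the
    shared threshold and during/after the expression delay.
    """
    for above in (False, True):
        for delay_passed in (False, True):
            phi_r = resistance_gene == Allele.ON or (
                resistance_gene == Allele.REG and above
            )
            regreg = toxin_gene == Allele.REG and resistance_gene == Allele.REG
            phi_t = toxin_gene == Allele.ON or (
                toxin_gene == Allele.REG
                and above
                and (not regreg or delay_passed)
            )
            if phi_t and not phi_r:
                return True
    return False


class TestViability:
    @pytest.mark.parametrize(
        "tg,rg", list(itertools.product(Allele, Allele))
    )
    def test_matches_exhaustive_expression_enumeration(self, tg, rg):
        assert is_viable(tg, rg) == (not _expression_possible(tg, rg))

    def test_viable_set_is_the_six_known_pairs(self):
        viable = {
            (t, r)
            for t, r in itertools.product(Allele, Allele)
            if is_viable(t, r)
        }
        assert viable == set(VIABLE_PAIRS)

    def test_constitutive_killer_without_resistance_nonviable(self):
        assert not is_viable(Allele.ON, Allele.OFF)

    def test_reg_resistant_viable(self):
        assert is_viable(Allele.OFF, Allele.REG)


class TestPhenotypes:
    def test_threshold_rule_regulated_toxin(self, raw_serial):
        lattice = _single_cell_lattice(REG_KILLER)
        cue = np.full((8, 8), 0.9)
        update_phenotypes(lattice, cue, raw_serial)
        i, j = 4, 4
        assert lattice.phi_t[i, j] and lattice.phi_r[i, j] and lattice.phi_c[i, j]
        update_phenotypes(lattice, np.full((8, 8), 0.8), raw_serial)
        assert not lattice.phi_t[i, j]
        assert lattice.phi_r[i, j]  # resistance gene is constitutive

    def test_sensitive_never_expresses(self, raw_serial):
        lattice = _single_cell_lattice(SENSITIVE)
        update_phenotypes(lattice, np.ones((8, 8)), raw_serial)
        assert not lattice.phi_t.any()
        assert not lattice.phi_r.any()
        assert not lattice.phi_c.any()

    def test_regreg_delay_between_resistance_and_toxin(self, raw_serial):
        raw = dataclasses.replace(raw_serial, tau_delay=4)
        lattice = _single_cell_lattice(REGREG_KILLER)
        low, high = np.full((8, 8), 0.1), np.full((8, 8), 0.9)
        update_phenotypes(lattice, low, raw)
        i, j = 4, 4
        assert not lattice.phi_r[i, j]
        # cue crosses theta at t0: resistance immediate, toxin after delay
        for t in range(4):
            update_phenotypes(lattice, high, raw)
            assert lattice.phi_r[i, j]
            assert not lattice.phi_t[i, j], f"toxin expressed at t0+{t}"
        update_phenotypes(lattice, high, raw)
        assert lattice.phi_t[i, j]
        # dropping below theta resets the delay counter
        update_phenotypes(lattice, low, raw)
        assert lattice.delay[i, j] == 0
        update_phenotypes(lattice, high, raw)
        assert not lattice.phi_t[i, j] and lattice.phi_r[i, j]

    def test_zero_delay_expresses_immediately(self, raw_serial):
        raw = dataclasses.replace(raw_serial, tau_delay=0)
        lattice = _single_cell_lattice(REGREG_KILLER)
        update_phenotypes(lattice, np.full((8, 8), 0.9), raw)
        assert lattice.phi_t[4, 4] and lattice.phi_r[4, 4]

    def test_missing_theta_is_corrupted_state(self, raw_serial):
        lattice = _single_cell_lattice(REG_KILLER)
        lattice.theta[4, 4] = np.nan
        with pytest.raises(CorruptedStateError):
            update_phenotypes(lattice, np.ones((8, 8)), raw_serial)

    def test_expression_lag_delays_switch_and_resets_on_revert(self, raw_serial):
        lattice = _single_cell_lattice(REG_KILLER)
        low, high = np.full((8, 8), 0.1), np.full((8, 8), 0.9)
        i, j = 4, 4
        update_phenotypes(lattice, low, raw_serial, lag_steps=3)  # newborn
        assert not lattice.phi_t[i, j]
        for _ in range(2):
            update_phenotypes(lattice, high, raw_serial, lag_steps=3)
            assert not lattice.phi_t[i, j]
        # target reverts before the lag elapses: countdown resets
        update_phenotypes(lattice, low, raw_serial, lag_steps=3)
        assert lattice.lag_count[i, j] == 0
        for _ in range(2):
            update_phenotypes(lattice, high, raw_serial, lag_steps=3)
            assert not lattice.phi_t[i, j]
        update_phenotypes(lattice, high, raw_serial, lag_steps=3)
        assert lattice.phi_t[i, j]


class TestFitness:
    def test_costless_phenotype_has_unit_fitness(self, raw_serial):
        assert reproductive_fitness(False, False, False, 0.7, raw_serial) == 1.0

    def test_full_expression_example(self):
        raw = dataclasses.replace(
            expand_lumped(LumpedParams(6, 6, 0.125, 0.1, 0.1, 0.02)),
            b_T=0.1, C_R=0.1, C_C=0.02,
        )
        r = reproductive_fitness(True, True, True, 0.5, raw)
        assert r == pytest.approx(0.82)

    def test_cost_sum_above_one_clamps_to_zero(self, raw_serial):
        raw = dataclasses.replace(raw_serial, b_T=2.0, C_R=0.3, C_C=0.2)
        assert reproductive_fitness(True, True, True, 1.0, raw) == 0.0


class TestDeathSweep:
    def test_resistant_cells_only_die_basally(self, raw_serial, rng):
        lattice = Lattice(100)
        lattice.occupied[:] = True
        lattice.resist_gene[:] = Allele.ON
        lattice.phi_r[:] = True
        tox = np.full((100, 100), 10.0)  # lethal for sensitives
        raw = dataclasses.replace(raw_serial, delta=0.05)
        died = death_sweep(lattice, tox, raw, rng)
        freq = died.sum() / 10_000
        assert freq == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 1e4))

    def test_sensitive_death_rate_follows_toxin_law(self, raw_serial, rng):
        # delta + delta_tox*c = 0.01 + 0.05 over ~1e5 cells
        n_side = 317
        lattice = Lattice(n_side)
        lattice.occupied[:] = True
        raw = dataclasses.replace(raw_serial, delta=0.01, delta_tox=0.5)
        tox = np.full((n_side, n_side), 0.1)
        died = death_sweep(lattice, tox, raw, rng)
        n = n_side**2
        freq = died.sum() / n
        assert freq == pytest.approx(0.06, abs=3 * np.sqrt(0.06 * 0.94 / n))

    def test_death_probability_clamped_at_one(self, raw_serial, rng):
        lattice = Lattice(10)
        lattice.occupied[:] = True
        raw = dataclasses.replace(raw_serial, delta_tox=100.0)
        died = death_sweep(lattice, np.ones((10, 10)), raw, rng)
        assert died.all()


class TestReproductionSweep:
    def test_no_neighbours_no_births(self, rng):
        lattice = Lattice(16)
        bi, _, _, _ = reproduction_sweep(
            lattice, np.ones((16, 16)), 0.0693, rng
        )
        assert bi.size == 0

    def test_single_neighbour_fill_probability(self, rng):
        # cells on a 3-spaced grid: every empty site has exactly one
        # occupied neighbour with R = 1 -> fill prob 1 - exp(-gamma/8)
        N, gamma = 150, 0.8
        lattice = Lattice(N)
        lattice.occupied[::3, ::3] = True
        fitness = np.ones((N, N))
        expected = 1.0 - np.exp(-gamma / 8.0)
        n_empty = N * N - lattice.popsize
        fills = 0
        trials = 0
        for _ in range(6):
            bi, _, _, _ = reproduction_sweep(lattice, fitness, gamma, rng)
            fills += bi.size
            trials += n_empty
        freq = fills / trials
        assert freq == pytest.approx(
            expected, abs=3 * np.sqrt(expected * (1 - expected) / trials)
        )

    def test_parent_chosen_proportional_to_fitness(self, rng):
        # pairs of parents with R = 1 and R = 3 flank empty target sites;
        # conditional parent frequencies must approach 1/4 and 3/4
        N = 200
        lattice = Lattice(N)
        fitness = np.zeros((N, N))
        lattice.occupied[::4, ::4] = True  # R = 1 parents
        lattice.occupied[2::4, ::4] = True  # R = 3 parents
        fitness[::4, ::4] = 1.0
        fitness[2::4, ::4] = 3.0
        # target sites at rows 1 mod 4 see exactly one parent of each kind
        counts = {1.0: 0, 3.0: 0}
        for _ in range(40):
            bi, bj, pi, pj = reproduction_sweep(lattice, fitness, 50.0, rng)
            on_target = bi % 4 == 1
            for r in (1.0, 3.0):
                counts[r] += int((fitness[pi[on_target], pj[on_target]] == r).sum())
        n = counts[1.0] + counts[3.0]
        assert n > 50_000
        assert counts[3.0] / n == pytest.approx(
            0.75, abs=3 * np.sqrt(0.25 * 0.75 / n)
        )

    def test_zero_fitness_neighbourhood_never_fills(self, rng):
        lattice = Lattice(12)
        lattice.occupied[::2, ::2] = True
        bi, _, _, _ = reproduction_sweep(
            lattice, np.zeros((12, 12)), 10.0, rng
        )
        assert bi.size == 0


class TestMutation:
    def test_no_mutation_draws_child_equals_parent(self, raw_serial, rng):
        raw = raw_serial.without_mutations()
        tg = np.full(100, int(Allele.REG), dtype=np.int8)
        rg = np.full(100, int(Allele.ON), dtype=np.int8)
        pi = np.full(100, 0.8)
        th = np.full(100, 0.875)
        ntg, nrg, npi, nth, viable = mutate_offspring(tg, rg, pi, th, raw, rng)
        assert (ntg == tg).all() and (nrg == rg).all()
        assert (npi == pi).all() and (nth == th).all()
        assert viable.all()

    def test_viability_flag_matches_rule_under_heavy_mutation(self, raw_serial):
        rng = np.random.default_rng(5)
        raw = dataclasses.replace(raw_serial, mu_gain=0.3, mu_loss=0.3)
        n = 20_000
        pairs = np.array([(int(t), int(r)) for t, r in VIABLE_PAIRS])
        pick = rng.integers(0, 6, n)
        tg = pairs[pick, 0].astype(np.int8)
        rg = pairs[pick, 1].astype(np.int8)
        th = np.where(
            (tg == Allele.REG) | (rg == Allele.REG), rng.random(n), np.nan
        )
        ntg, nrg, _, nth, viable = mutate_offspring(
            tg, rg, rng.random(n), th, raw, rng
        )
        expected = np.array([is_viable(t, r) for t, r in zip(ntg, nrg)])
        np.testing.assert_array_equal(viable, expected)
        # every genotype change is observed, so the flag is exercised
        assert viable.sum() < n
        # viable regulating children always carry a threshold
        child_reg = (ntg == Allele.REG) | (nrg == Allele.REG)
        assert not np.isnan(nth[child_reg & viable]).any()
        assert np.isnan(nth[~child_reg]).all()

    def test_threshold_clamped_below_at_zero(self, raw_serial):
        rng = np.random.default_rng(6)
        raw = dataclasses.replace(
            raw_serial, mu=1.0, p_largemut=0.0, mu_gain=0.0, mu_loss=0.0
        )
        n = 4000
        tg = np.full(n, int(Allele.REG), dtype=np.int8)
        rg = np.full(n, int(Allele.ON), dtype=np.int8)
        _, _, npi, nth, _ = mutate_offspring(
            tg, rg, np.full(n, 0.02), np.full(n, 0.02), raw, rng
        )
        for arr in (npi, nth):
            assert arr.min() == 0.0  # negative steps clamp to exactly 0
            assert arr.max() <= 0.02 + raw.sigma_mu + 1e-12

    def test_large_mutation_resamples_uniformly(self, raw_serial):
        rng = np.random.default_rng(7)
        raw = dataclasses.replace(raw_serial, mu=1.0, p_largemut=1.0)
        n = 5000
        tg = np.full(n, int(Allele.ON), dtype=np.int8)
        rg = np.full(n, int(Allele.ON), dtype=np.int8)
        _, _, npi, _, _ = mutate_offspring(
            tg, rg, np.full(n, 0.9), np.full(n, np.nan), raw, rng
        )
        assert stats.kstest(npi, "uniform").pvalue > 1e-4

    def test_reg_gaining_child_draws_threshold_uniformly(self, raw_serial):
        rng = np.random.default_rng(8)
        # force every gene to gain: OFF -> ON/REG with certainty
        raw = dataclasses.replace(raw_serial, mu_gain=0.5, mu_loss=0.0, mu=0.0)
        n = 30_000
        tg = np.full(n, int(Allele.OFF), dtype=np.int8)
        rg = np.full(n, int(Allele.OFF), dtype=np.int8)
        ntg, nrg, npi, nth, viable = mutate_offspring(
            tg, rg, np.zeros(n), np.full(n, np.nan), raw, rng
        )
        gained_reg = ((ntg == Allele.REG) | (nrg == Allele.REG)) & viable
        assert gained_reg.sum() > 1000
        assert stats.kstest(nth[gained_reg], "uniform").pvalue > 1e-4
        gained_tox = (ntg != Allele.OFF) & viable
        assert stats.kstest(npi[gained_tox], "uniform").pvalue > 1e-4


class TestStep:
    def test_empty_lattice_is_fixed_point(self, raw_serial, rng):
        lattice = Lattice(16)
        before = lattice.copy()
        step(lattice, raw_serial, rng)
        before.step_count += 1
        assert lattice == before

    def test_toxin_never_expressed_without_resistance(self, raw_serial):
        rng = np.random.default_rng(9)
        lattice = initialise_lattice(48, 0.2, rng)
        for _ in range(150):
            step(lattice, raw_serial, rng)
            bad = lattice.occupied & lattice.phi_t & ~lattice.phi_r
            assert not bad.any()

    def test_composition_invariant_without_mutation(self, raw_serial):
        rng = np.random.default_rng(10)
        raw = raw_serial.without_mutations()
        lattice = Lattice(32)
        sites = rng.choice(32 * 32, 100, replace=False)
        lattice.place(sites, REG_KILLER)
        for _ in range(100):
            step(lattice, raw, rng)
        occ = lattice.occupied
        assert (lattice.toxin_gene[occ] == Allele.REG).all()
        assert (lattice.resist_gene[occ] == Allele.ON).all()
        assert (lattice.pi_t[occ] == 0.8).all()
        assert (lattice.theta[occ] == 0.875).all()

    def test_intrinsic_growth_rate_at_low_density(self):
        # well-mixed, death-free, cost-free: dn/dt ~ gamma * n while the
        # lattice is sparse, so the doubling time is ~ln2/gamma steps
        lumped = LumpedParams(6, 6, 1e-9, 0.1, 0.1, 0.1)
        raw = expand_lumped(lumped).without_mutations()
        options = StepOptions(well_mixed=True, mutations=False)
        rates = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            lattice = Lattice(128)
            lattice.place(rng.choice(128 * 128, 40, replace=False), SENSITIVE)
            pops = [lattice.popsize]
            for _ in range(55):
                step(lattice, raw, rng, options)
                pops.append(lattice.popsize)
            rates.append(np.polyfit(np.arange(56), np.log(pops), 1)[0])
        doubling = np.log(2) / np.mean(rates)
        assert doubling == pytest.approx(np.log(2) / raw.gamma, rel=0.1)

    def test_fixed_seed_runs_are_bit_identical(self, raw_serial):
        def run():
            rng = np.random.default_rng(123)
            lattice = initialise_lattice(32, 0.1, rng)
            for _ in range(50):
                step(lattice, raw_serial, rng)
            return lattice

        assert run() == run()


class TestInitialiseAndShuffle:
    def test_occupancy_count_is_floor_of_fraction(self, rng):
        lattice = initialise_lattice(64, 0.10, rng)
        assert lattice.popsize == int(0.10 * 64 * 64)

    def test_all_initial_genotypes_viable(self, rng):
        lattice = initialise_lattice(64, 0.3, rng)
        occ = lattice.occupied
        for t, r in zip(lattice.toxin_gene[occ], lattice.resist_gene[occ]):
            assert is_viable(Allele(t), Allele(r))

    def test_genotype_frequencies_uniform(self):
        rng = np.random.default_rng(11)
        lattice = initialise_lattice(192, 0.5, rng)
        occ = lattice.occupied
        key = lattice.genotype_key()[occ]
        counts = np.array(
            [(key == 3 * int(t) + int(r)).sum() for t, r in VIABLE_PAIRS]
        )
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            initialise_lattice(16, 0.0, rng)
        with pytest.raises(ValueError):
            initialise_lattice(16, 1.5, rng)

    def test_shuffle_preserves_cell_multiset(self, raw_serial):
        rng = np.random.default_rng(12)
        lattice = initialise_lattice(32, 0.2, rng)
        def multiset(lat):
            occ = lat.occupied
            cells = np.stack(
                [
                    lat.toxin_gene[occ],
                    lat.resist_gene[occ],
                    lat.pi_t[occ],
                    np.nan_to_num(lat.theta[occ], nan=-1.0),
                ]
            ).T
            return np.array(sorted(map(tuple, cells)))
        before = multiset(lattice)
        shuffle_positions(lattice, rng)
        np.testing.assert_array_equal(before, multiset(lattice))
        assert lattice.popsize == before.shape[0]

    def test_shuffle_destroys_spatial_memory(self):
        # after a shuffle, occupancy of a fixed site is ~independent of
        # its previous occupancy: P(occ now | occ before) ~ density
        rng = np.random.default_rng(13)
        lattice = initialise_lattice(128, 0.25, rng)
        before = lattice.occupied.copy()
        shuffle_positions(lattice, rng)
        cond = lattice.occupied[before].mean()
        n = int(before.sum())
        assert cond == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / n))
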