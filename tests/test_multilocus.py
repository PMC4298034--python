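"""Multilocus damage-rule model: penetrance rule, closed form, solver,
sampling, and exact family/twin predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import oracles
from dcmodel import (
    InvalidParameterError,
    MultilocusModel,
    NoSolutionError,
    ParentPair,
    PenetranceModel,
    Zygosity,
    damage_rule_penetrance,
    dz_twin_distribution,
    exact_family_prediction,
    exact_twin_distribution,
    family_prediction,
    family_stratum_probs,
    left_rate_closed_form,
    meiosis,
    mz_twin_distribution,
    sample_genotype,
    solve_equal_c,
    twin_distribution_by_parents,
)

DEFAULT = PenetranceModel()

c_vectors = st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=6)


class TestDamageRule:
    @pytest.mark.parametrize(
        "genotype, expected",
        [
            ([0, 0, 0, 0], 0.0),  # all DiDi: right-handed
            ([2, 1, 1, 1], 0.5),  # one CiCi dominates any number of hets
            ([1, 0, 0, 0], 0.25),  # a single heterozygous locus
            ([2, 2, 2], 0.5),  # multiple damaged loci: no further effect
            ([0], 0.0),
            ([2], 0.5),
        ],
    )
    def test_precedence(self, genotype, expected):
        assert damage_rule_penetrance(np.array(genotype), DEFAULT) == expected

    def test_empty_genotype_rejected(self):
        with pytest.raises(InvalidParameterError):
            damage_rule_penetrance(np.array([]), DEFAULT)

    def test_vectorized_batch(self):
        batch = np.array([[0, 0], [1, 0], [2, 1]])
        assert damage_rule_penetrance(batch, DEFAULT) == pytest.approx([0, 0.25, 0.5])


class TestClosedForm:
    def test_single_locus_matches_population_rate(self):
        assert left_rate_closed_form([0.2], DEFAULT) == pytest.approx(0.10, abs=1e-12)

    def test_no_chance_alleles_means_no_lefthanders(self):
        assert left_rate_closed_form([0.0] * 7, DEFAULT) == 0.0

    @given(c_values=c_vectors)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_equals_exhaustive_genotype_enumeration(self, c_values):
        expected = oracles.enumerate_left_rate(c_values, DEFAULT.as_array())
        assert left_rate_closed_form(c_values, DEFAULT) == pytest.approx(expected, abs=1e-12)

    @given(c_values=c_vectors, levels=st.tuples(*[st.floats(0, 1, allow_nan=False)] * 3))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_general_levels_equal_enumeration(self, c_values, levels):
        model = PenetranceModel(*levels)
        expected = oracles.enumerate_left_rate(c_values, model.as_array())
        assert left_rate_closed_form(c_values, model) == pytest.approx(expected, abs=1e-12)


class TestSolver:
    def test_published_single_locus_solution(self):
        assert solve_equal_c(1, 0.10).solved_c == pytest.approx(0.2, abs=1e-10)

    @given(p=st.floats(0.0, 0.5, allow_nan=False, exclude_max=True))
    @settings(derandomize=True, max_examples=40)
    def test_single_locus_solution_is_twice_prevalence(self, p):
        assert solve_equal_c(1, p).solved_c == pytest.approx(2 * p, abs=1e-9)

    def test_roundtrip_recovers_target(self):
        for n in (1, 2, 5, 10, 100, 1000):
            eq = solve_equal_c(n, 0.10)
            assert left_rate_closed_form([eq.solved_c] * n, DEFAULT) == pytest.approx(
                0.10, abs=1e-10
            )

    def test_solved_frequency_decreases_with_loci(self):
        cs = [solve_equal_c(n, 0.10).solved_c for n in (1, 2, 3, 4, 5, 10, 20, 50, 100, 200, 500, 1000)]
        assert all(a > b for a, b in zip(cs, cs[1:]))

    def test_solutions_track_published_table_at_its_numerical_accuracy(self):
        """The published frequency column was produced by a looser solve: the
        exact roots agree with it to ~2e-4 everywhere (and to all five
        printed decimals for most rows)."""
        printed = {1: 0.20000, 2: 0.11110, 3: 0.07715, 4: 0.05916, 5: 0.04780,
                   10: 0.02473, 20: 0.01256, 50: 0.00507, 100: 0.00254,
                   200: 0.00127, 500: 0.00051, 1000: 0.00026}
        for n, c_printed in printed.items():
            assert solve_equal_c(n, 0.10).solved_c == pytest.approx(c_printed, abs=2.1e-4)

    def test_zero_prevalence_gives_zero_frequency(self):
        assert solve_equal_c(5, 0.0).solved_c == 0.0

    def test_unattainable_prevalence_raises(self):
        with pytest.raises(NoSolutionError):
            solve_equal_c(3, 0.9)  # max attainable is 0.5


class TestSampling:
    def test_no_chance_alleles_all_homozygous_major(self, rng):
        model = MultilocusModel.equal(4, 0.0)
        assert not sample_genotype(model, rng, 100).any()

    def test_hwe_frequencies(self, rng):
        model = MultilocusModel.equal(1, 0.2)
        g = sample_genotype(model, rng, 200_000)
        het = (g == 1).mean()
        assert het == pytest.approx(0.32, abs=0.005)

    def test_fixed_seed_reproduces_sequence(self):
        model = MultilocusModel.equal(3, 0.1)
        a = sample_genotype(model, np.random.default_rng(5), 50)
        b = sample_genotype(model, np.random.default_rng(5), 50)
        assert (a == b).all()

    def test_meiosis_transmits_nothing_from_dd(self, rng):
        gamete = meiosis(np.zeros((10, 4), dtype=int), rng)
        assert not gamete.any()

    def test_meiosis_mendelian_transmission(self, rng):
        parent = np.ones((200_000, 1), dtype=int)  # heterozygous
        rate = meiosis(parent, rng).mean()
        assert rate == pytest.approx(0.5, abs=0.005)

    def test_two_dd_parents_make_righthanded_offspring(self, rng):
        p = np.zeros((50, 3), dtype=int)
        off = meiosis(p, rng) + meiosis(p, rng)
        assert damage_rule_penetrance(off, DEFAULT) == pytest.approx(np.zeros(50))


class TestExactPredictions:
    """The class-joint exact predictions must agree with the independent
    single-locus algebra at n=1 and with exhaustive enumeration beyond."""

    def test_single_locus_reduction_family(self):
        model = MultilocusModel.equal(1, 0.2)
        got = exact_family_prediction(model)
        want = family_prediction(DEFAULT, 0.2)
        for parents in ParentPair:
            assert got[parents] == pytest.approx(want[parents], abs=1e-12)

    def test_single_locus_reduction_twins(self):
        model = MultilocusModel.equal(1, 0.2)
        assert exact_twin_distribution(model, Zygosity.MZ).as_array() == pytest.approx(
            mz_twin_distribution(DEFAULT, 0.2).as_array(), abs=1e-12
        )
        assert exact_twin_distribution(model, Zygosity.DZ).as_array() == pytest.approx(
            dz_twin_distribution(DEFAULT, 0.2).as_array(), abs=1e-12
        )

    def test_single_locus_reduction_twins_by_parents(self):
        model = MultilocusModel.equal(1, 0.2)
        for parents in ParentPair:
            for zyg in Zygosity:
                got = exact_twin_distribution(model, zyg, parents)
                want = twin_distribution_by_parents(DEFAULT, 0.2, parents, zyg)
                assert got.as_array() == pytest.approx(want.as_array(), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3])
    def test_family_matches_exhaustive_enumeration(self, n):
        c = solve_equal_c(n, 0.10).solved_c
        model = MultilocusModel.equal(n, c)
        brute = oracles.multilocus_family_enumeration(c, n, DEFAULT.as_array())
        got = exact_family_prediction(model)
        strata = family_stratum_probs(model)
        for parents in ParentPair:
            assert got[parents] == pytest.approx(brute["family"][parents.value], abs=1e-12)
            assert strata[parents] == pytest.approx(brute["stratum_prob"][parents.value], abs=1e-12)
        assert exact_twin_distribution(model, Zygosity.MZ).as_array() == pytest.approx(
            brute["mz"], abs=1e-12
        )
        assert exact_twin_distribution(model, Zygosity.DZ).as_array() == pytest.approx(
            brute["dz"], abs=1e-12
        )

    def test_unequal_frequencies_match_enumeration(self):
        c_values = (0.12, 0.05, 0.02)
        model = MultilocusModel(c_values)
        assert model.population_left_rate() == pytest.approx(
            oracles.enumerate_left_rate(c_values, DEFAULT.as_array()), abs=1e-12
        )

    def test_more_loci_flatten_family_differences(self):
        """L x L offspring left-handedness falls and R x R rises as the same
        prevalence is spread over more loci."""
        f1 = exact_family_prediction(MultilocusModel.for_prevalence(1, 0.10))
        f50 = exact_family_prediction(MultilocusModel.for_prevalence(50, 0.10))
        assert f50.p_left_given_ll_parents < f1.p_left_given_ll_parents
        assert f50.p_left_given_rr_parents > f1.p_left_given_rr_parents

    def test_more_loci_raise_mz_discordance(self):
        d1 = exact_twin_distribution(MultilocusModel.for_prevalence(1, 0.10), Zygosity.MZ)
        d50 = exact_twin_distribution(MultilocusModel.for_prevalence(50, 0.10), Zygosity.MZ)
        assert d50.p_rl > d1.p_rl


def _scale_to_prevalence(direction: np.ndarray, target: float) -> np.ndarray:
    """Scale a frequency direction vector so the model hits ``target``."""
    f = lambda t: left_rate_closed_form(t * direction, DEFAULT) - target
    t = brentq(f, 0.0, 1.0 / direction.max(), xtol=1e-13)
    return t * direction


def test_unequal_frequencies_make_little_difference_at_matched_prevalence(rng):
    """Spreading 10% prevalence over unequal per-locus frequencies moves the
    family predictions by less than one percentage point relative to the
    equal-frequency model, as long as no single frequency is large."""
    for n in (2, 5, 10):
        equal = exact_family_prediction(MultilocusModel.for_prevalence(n, 0.10))
        for _ in range(3):
            direction = rng.uniform(0.2, 1.0, size=n)
            c_values = _scale_to_prevalence(direction, 0.10)
            if c_values.max() > 0.15:
                continue
            model = MultilocusModel(tuple(c_values))
            assert model.population_left_rate() == pytest.approx(0.10, abs=1e-10)
            got = exact_family_prediction(model)
            for parents in ParentPair:
                assert abs(got[parents] - equal[parents]) < 0.01
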