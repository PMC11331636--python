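"""Tests for the exhaustive design searches."""

from fractions import Fraction

import pytest
from scipy.stats import binom as _binom

from twostage import (
    AdmissibleConstraints,
    DesignParams,
    InfeasibleSearchError,
    SearchConfig,
    TwoStageDesign,
    alpha_no_stop,
    build_catalog,
    default_n_max,
    enumerate_feasible_designs,
    expected_sample_size,
    kim_modified,
    operating_characteristics,
    optimized_futility_design,
    pet,
    reject_probability,
    simon_minimax,
    simon_optimal,
    single_stage_design,
    type1_error,
)

# reduced problems where every family is feasible within n_max = 40
REDUCED = [
    DesignParams(0.10, 0.30, 0.05, 0.20),
    DesignParams(0.15, 0.35, 0.05, 0.20),
    DesignParams(0.20, 0.40, 0.05, 0.20),
]
SMALL_CONFIG = SearchConfig(n_max=40)


def brute_single_stage(params, cap=200):
    """Independent scan for the smallest single-stage design."""
    for n in range(1, cap + 1):
        for r in range(n + 1):
            if float(_binom.sf(r, n, params.p0)) <= params.alpha:
                if float(_binom.sf(r, n, params.pa)) >= 1 - params.beta:
                    return n, r
                break  # smallest alpha-valid r maximizes power; larger r only lose
    raise AssertionError("no design below cap")


class TestSingleStage:
    def test_worked_example(self, worked_params):
        assert single_stage_design(worked_params) == (62, 21)

    def test_extreme_separation_matches_brute_force(self):
        params = DesignParams(0.05, 0.80, 0.05, 0.20)
        assert single_stage_design(params) == brute_single_stage(params)

    @pytest.mark.parametrize("params", REDUCED)
    def test_matches_brute_force(self, params):
        assert single_stage_design(params) == brute_single_stage(params)

    def test_monotone_in_beta(self):
        ns = [
            single_stage_design(DesignParams(0.25, 0.40, 0.05, beta))[0]
            for beta in (0.30, 0.20, 0.10)
        ]
        assert ns == sorted(ns)


class TestEnumerateFeasibleDesigns:
    def test_contains_published_minimax(self, worked_params):
        found = any(
            d.astuple() == (16, 51, 20, 60)
            for d in enumerate_feasible_designs(worked_params, 60)
            if d.n == 60 and d.n1 == 51
        )
        assert found

    def test_small_n_max_is_empty(self, worked_params):
        assert list(enumerate_feasible_designs(worked_params, 20)) == []

    def test_yielded_designs_are_feasible_and_ordered(self):
        params = REDUCED[0]
        previous = None
        count = 0
        for d in enumerate_feasible_designs(params, 30):
            count += 1
            assert type1_error(d, params.p0) <= params.alpha
            assert reject_probability(d, params.pa) >= 1 - params.beta
            key = (d.n, d.n1, d.r1, d.r)
            if previous is not None:
                assert key > previous
            previous = key
        assert count > 0

    def test_invalid_n_max(self, worked_params):
        with pytest.raises(ValueError):
            list(enumerate_feasible_designs(worked_params, 1))


class TestSimonSearches:
    def test_optimal_worked_example(self, worked_params, default_config):
        assert simon_optimal(worked_params, default_config).astuple() == (5, 20, 23, 71)

    def test_minimax_worked_example(self, worked_params, default_config):
        assert simon_minimax(worked_params, default_config).astuple() == (16, 51, 20, 60)

    def test_minimax_n_never_exceeds_optimal_n(self, worked_params, default_config):
        assert (
            simon_minimax(worked_params, default_config).n
            <= simon_optimal(worked_params, default_config).n
        )

    @pytest.mark.parametrize("params", REDUCED)
    def test_optimal_certified_by_enumeration(self, params):
        best = simon_optimal(params, SMALL_CONFIG)
        best_en = expected_sample_size(best, params.p0)
        for d in enumerate_feasible_designs(params, SMALL_CONFIG.n_max):
            assert best_en <= expected_sample_size(d, params.p0) + 1e-12

    @pytest.mark.parametrize("params", REDUCED)
    def test_minimax_certified_by_enumeration(self, params):
        best = simon_minimax(params, SMALL_CONFIG)
        best_en = expected_sample_size(best, params.p0)
        for d in enumerate_feasible_designs(params, SMALL_CONFIG.n_max):
            assert best.n <= d.n
            if d.n == best.n:
                assert best_en <= expected_sample_size(d, params.p0) + 1e-12

    def test_infeasible_n_max_raises(self, worked_params):
        with pytest.raises(InfeasibleSearchError) as exc:
            simon_optimal(worked_params, SearchConfig(n_max=20))
        assert exc.value.constraint == "n_max"

    def test_default_n_max_envelope(self, worked_params):
        assert default_n_max(worked_params) == 124


class TestKimModified:
    def test_optimal_worked_example(self, worked_params, default_constraints, default_config):
        d = kim_modified(worked_params, default_constraints, default_config, "optimal")
        assert d.astuple() == (6, 24, 22, 67)

    def test_minimax_worked_example(self, worked_params, default_constraints, default_config):
        d = kim_modified(worked_params, default_constraints, default_config, "minimax")
        assert d.astuple() == (10, 40, 21, 62)

    def test_constraints_hold(self, worked_params, default_constraints, default_config):
        for variant in ("optimal", "minimax"):
            d = kim_modified(worked_params, default_constraints, default_config, variant)
            assert pet(d, worked_params.pa) <= default_constraints.pet_pa_bound_kim
            assert Fraction(1, 3) <= Fraction(d.n1, d.n) <= Fraction(2, 3)

    def test_vacuous_constraints_collapse_to_simon(self, worked_params, default_config):
        vacuous = AdmissibleConstraints(
            pet_pa_bound_kim=1.0,
            ratio_lower=Fraction(1, 1000),
            ratio_upper=Fraction(999, 1000),
        )
        assert (
            kim_modified(worked_params, vacuous, default_config, "optimal")
            == simon_optimal(worked_params, default_config)
        )
        assert (
            kim_modified(worked_params, vacuous, default_config, "minimax")
            == simon_minimax(worked_params, default_config)
        )

    @pytest.mark.parametrize("params", REDUCED)
    def test_optimal_certified_by_enumeration(self, params, default_constraints):
        best = kim_modified(params, default_constraints, SMALL_CONFIG, "optimal")
        best_en = expected_sample_size(best, params.p0)
        for d in enumerate_feasible_designs(params, SMALL_CONFIG.n_max):
            if pet(d, params.pa) > default_constraints.pet_pa_bound_kim:
                continue
            if not Fraction(1, 3) <= Fraction(d.n1, d.n) <= Fraction(2, 3):
                continue
            assert best_en <= expected_sample_size(d, params.p0) + 1e-12

    def test_unknown_variant(self, worked_params, default_constraints):
        with pytest.raises(ValueError):
            kim_modified(worked_params, default_constraints, SMALL_CONFIG, "fastest")

    def test_binding_constraint_reported(self, worked_params, default_config):
        # PET(pa) = B(r1, n1, pa) is strictly positive, so a zero bound
        # empties the constrained set while the base set stays non-empty
        tight = AdmissibleConstraints(pet_pa_bound_kim=0.0)
        with pytest.raises(InfeasibleSearchError) as exc:
            kim_modified(worked_params, tight, default_config, "optimal")
        assert exc.value.constraint == "pet_pa_bound_kim"


class TestOptimizedFutilityDesign:
    def test_worked_example(self, worked_params, default_constraints):
        d = optimized_futility_design(worked_params, default_constraints)
        assert d.astuple() == (10, 39, 21, 62)

    def test_non_binding_safety(self, worked_params, default_constraints):
        d = optimized_futility_design(worked_params, default_constraints)
        assert alpha_no_stop(d, worked_params.p0) <= worked_params.alpha

    def test_admissibility(self, worked_params, default_constraints):
        d = optimized_futility_design(worked_params, default_constraints)
        assert pet(d, worked_params.pa) <= default_constraints.pi_wrong
        assert (
            reject_probability(d, worked_params.pa)
            >= 1 - worked_params.beta - default_constraints.pow_loss
        )
        assert Fraction(1, 3) <= Fraction(d.n1, d.n) <= Fraction(2, 3)

    def test_certified_by_exhaustive_scan(self, worked_params, default_constraints):
        d = optimized_futility_design(worked_params, default_constraints)
        n, r = single_stage_design(worked_params)
        assert (d.n, d.r) == (n, r)
        best_pet = pet(d, worked_params.p0)
        pow_floor = 1 - worked_params.beta - default_constraints.pow_loss
        for n1 in range(1, n):
            if not Fraction(1, 3) <= Fraction(n1, n) <= Fraction(2, 3):
                continue
            for r1 in range(min(n1, r) + 1):
                cand = TwoStageDesign(r1=r1, n1=n1, r=r, n=n)
                if pet(cand, worked_params.pa) > default_constraints.pi_wrong:
                    continue
                if reject_probability(cand, worked_params.pa) < pow_floor:
                    continue
                assert pet(cand, worked_params.p0) <= best_pet + 1e-12

    def test_constraint_changes_leave_n_r_fixed(self, worked_params):
        base = optimized_futility_design(worked_params, AdmissibleConstraints())
        for kwargs in (
            dict(pow_loss=0.025, pi_wrong=0.025),
            dict(pow_loss=0.1, pi_wrong=0.1),
            dict(ratio_lower=Fraction(2, 5), ratio_upper=Fraction(3, 5)),
        ):
            d = optimized_futility_design(worked_params, AdmissibleConstraints(**kwargs))
            assert (d.n, d.r) == (base.n, base.r)

    def test_tightening_never_increases_pet_p0(self, worked_params):
        # ladder of progressively stricter (pi_wrong, pow_loss)
        pets = []
        for bound in (0.10, 0.05, 0.025, 0.0125):
            d = optimized_futility_design(
                worked_params, AdmissibleConstraints(pow_loss=bound, pi_wrong=bound)
            )
            pets.append(pet(d, worked_params.p0))
        assert pets == sorted(pets, reverse=True)

    def test_infeasible_pi_wrong(self, worked_params):
        with pytest.raises(InfeasibleSearchError) as exc:
            optimized_futility_design(
                worked_params, AdmissibleConstraints(pi_wrong=1e-12)
            )
        assert exc.value.constraint == "pi_wrong"

    def test_pow_loss_must_leave_power(self, worked_params):
        with pytest.raises(ValueError):
            optimized_futility_design(
                worked_params, AdmissibleConstraints(pow_loss=0.9)
            )


class TestAdmissibleConstraints:
    def test_ratio_bounds_ordering(self):
        with pytest.raises(ValueError):
            AdmissibleConstraints(ratio_lower=Fraction(2, 3), ratio_upper=Fraction(1, 3))

    def test_float_ratios_snap_to_rationals(self):
        c = AdmissibleConstraints(ratio_lower=1 / 3, ratio_upper=2 / 3)
        assert c.ratio_lower == Fraction(1, 3)
        assert c.ratio_upper == Fraction(2, 3)

    def test_string_ratios(self):
        c = AdmissibleConstraints(ratio_lower="1/4", ratio_upper="3/4")
        assert c.ratio_lower == Fraction(1, 4)

    def test_pi_wrong_bounds(self):
        with pytest.raises(ValueError):
            AdmissibleConstraints(pi_wrong=1.5)


class TestSearchConfig:
    def test_n_max_floor(self):
        with pytest.raises(ValueError):
            SearchConfig(n_max=1)

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            SearchConfig(tie_break_policy="random")


class TestBuildCatalog:
    def test_all_families_present(self, worked_params, default_constraints, default_config):
        catalog = build_catalog(worked_params, default_constraints, default_config)
        assert set(catalog.entries) == {
            "simon_optimal", "simon_minimax", "kim_optimal", "kim_minimax", "optimized",
        }
        assert catalog.single_stage == (62, 21)
        for name, (design, oc) in catalog.entries.items():
            assert design is not None, name
            recomputed = operating_characteristics(design, worked_params)
            assert recomputed == oc
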