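"""Tests for the coupled equilibrium solver and the K_diss inverse problem."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_gridsearch import brute_force_equilibrium, random_moderate_constants
from nucstab.errors import ConvergenceError
from nucstab.speciation import (
    EquilibriumConstants,
    decomposed_fraction,
    fit_kdiss,
    solve_equilibrium,
    speciation_table,
)

C0 = 1e-3


class TestSolveEquilibrium:
    def test_fast_hydrolysing_deoxy_compound_column(self, models, equilibria):
        """The 6IdU system: published 2 s.f. cells reproduced within 10%."""
        st_ = equilibria["6IdU"]
        assert st_.hydronium == pytest.approx(2.5e-4, rel=0.10)
        assert st_.base == pytest.approx(7.5e-4, rel=0.10)
        assert st_.base_anion == pytest.approx(2.5e-4, rel=0.10)
        assert st_.sugar_cation == pytest.approx(1.1e-19, rel=0.10)
        assert st_.hydroxide == pytest.approx(4.0e-11, rel=0.10)
        assert st_.sugar == pytest.approx(1.0e-3, rel=0.10)

    def test_stable_5_substituted_compound_column(self, equilibria):
        st_ = equilibria["5IdU"]
        assert st_.nucleoside == pytest.approx(5.8e-4, rel=0.10)
        assert st_.base_anion == pytest.approx(1.2e-5, rel=0.10)
        assert st_.hydroxide == pytest.approx(8.5e-10, rel=0.10)
        assert st_.hydronium == pytest.approx(1.2e-5, rel=0.10)
        assert st_.base == pytest.approx(4.1e-4, rel=0.10)
        assert st_.sugar == pytest.approx(4.2e-4, rel=0.10)
        assert st_.sugar_cation == pytest.approx(2.2e-21, rel=0.10)

    def test_ribo_compound_column(self, equilibria):
        st_ = equilibria["6IUrd"]
        assert st_.sugar_cation == pytest.approx(2.1e-24, rel=0.10)
        assert st_.base_anion == pytest.approx(2.5e-4, rel=0.10)

    def test_no_dissociation_limit_is_pure_water(self):
        c = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10, K_diss=0.0)
        st_ = solve_equilibrium(c, C0)
        assert st_.nucleoside == C0
        assert st_.hydronium == pytest.approx(1e-7, rel=1e-9)
        assert st_.hydroxide == pytest.approx(1e-7, rel=1e-9)
        assert st_.base == st_.base_anion == 0.0

    @pytest.mark.parametrize("name", ["5IdU", "6IdU", "6IUrd"])
    def test_balances_hold_at_solution(self, models, equilibria, name):
        st_ = equilibria[name]
        assert abs(st_.base_balance(C0)) < 1e-6
        assert abs(st_.sugar_balance(C0)) < 1e-6
        assert abs(st_.charge_balance()) < 1e-6
        assert st_.ion_product() == pytest.approx(
            models[name].constants.K_w, rel=1e-4)

    @pytest.mark.parametrize("name", ["5IdU", "6IdU", "6IUrd"])
    def test_defining_ratios_recover_the_input_constants(self, models,
                                                         equilibria, name):
        """K_a, K_b, K_diss recomputed from the solved state match inputs."""
        c = models[name].constants
        st_ = equilibria[name]
        assert st_.sugar * st_.hydronium / st_.sugar_cation == pytest.approx(
            c.K_a, rel=1e-9)
        assert st_.base * st_.hydroxide / st_.base_anion == pytest.approx(
            c.K_b, rel=1e-9)
        assert st_.base_anion * st_.sugar_cation / st_.nucleoside == \
            pytest.approx(c.K_diss, rel=1e-9)

    def test_missing_kdiss_rejected(self):
        c = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10)
        with pytest.raises(ValueError, match="K_diss"):
            solve_equilibrium(c, C0)

    def test_nonpositive_initial_rejected(self):
        c = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10, K_diss=1e-14)
        with pytest.raises(ValueError):
            solve_equilibrium(c, 0.0)

    def test_agrees_with_brute_force_extent_search(self):
        """Oracle equivalence on randomized small systems.

        The brute-force grid search knows nothing about the production
        solver's nested root-find structure.
        """
        rng = np.random.default_rng(20260930)
        for _ in range(5):
            c = random_moderate_constants(rng)
            exact = solve_equilibrium(c, C0)
            brute = brute_force_equilibrium(c, C0)
            for name, value in exact.as_dict().items():
                if value > 0:
                    assert getattr(brute, name) == pytest.approx(
                        value, rel=1e-6), name

    @pytest.mark.parametrize("name", ["5IdU", "6IdU", "6IUrd"])
    def test_agrees_with_brute_force_on_compound_systems(self, models, name):
        exact = solve_equilibrium(models[name].constants, C0)
        brute = brute_force_equilibrium(models[name].constants, C0)
        for field, value in exact.as_dict().items():
            if value > 0:
                assert getattr(brute, field) == pytest.approx(
                    value, rel=1e-6), field


class TestFitKdiss:
    def test_round_trip_on_the_published_residuals(self, models):
        for name, residual in (("5IdU", 5.8e-4), ("6IdU", 3.6e-10),
                               ("6IUrd", 2.4e-10)):
            c = models[name].constants
            st_ = solve_equilibrium(c, C0)
            assert st_.nucleoside == pytest.approx(residual, rel=1e-3)

    def test_recovers_order_of_magnitude_of_the_published_guesses(self, models):
        # cross-check against the direct ratio of the published cells
        assert models["6IdU"].K_diss == pytest.approx(7.6e-14, rel=0.10)
        assert models["5IdU"].K_diss == pytest.approx(4.6e-23, rel=0.10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=-24, max_value=-10))
    def test_identity_on_kdiss_across_fourteen_decades(self, log_kdiss):
        """fit_kdiss(solve_equilibrium(K)) == K to better than 0.1%."""
        base = EquilibriumConstants(K_a=2.3462e12, K_b=1.2562e-10)
        K = 10.0 ** log_kdiss
        st_ = solve_equilibrium(base.with_kdiss(K), C0)
        fitted = fit_kdiss(st_.nucleoside, base, C0)
        assert fitted == pytest.approx(K, rel=1e-3)

    def test_monotone_in_observed_residual(self):
        base = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10)
        residuals = [9.99e-4, 9.9e-4, 5e-4, 1e-6, 1e-10]
        fitted = [fit_kdiss(r, base, C0) for r in residuals]
        assert fitted == sorted(fitted)
        assert fitted[0] < 1e-18  # K_diss -> 0 as the residual -> C0

    def test_observed_out_of_range_rejected(self):
        base = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10)
        with pytest.raises(ValueError):
            fit_kdiss(C0, base, C0)
        with pytest.raises(ValueError):
            fit_kdiss(0.0, base, C0)


class TestDecomposedFraction:
    def test_42_percent_of_the_stable_compound_decomposes(self, equilibria):
        assert decomposed_fraction(equilibria["5IdU"], C0) == pytest.approx(
            0.42, abs=1e-9)

    def test_nearly_complete_decomposition_of_the_deoxy_compound(
            self, equilibria):
        assert decomposed_fraction(equilibria["6IdU"], C0) == pytest.approx(
            1.0, abs=1e-6)

    def test_no_dissociation_limit(self):
        c = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10, K_diss=0.0)
        assert decomposed_fraction(solve_equilibrium(c, C0), C0) == 0.0


class TestSpeciationTable:
    def test_row_labels_follow_the_reporting_convention(self, equilibria):
        table = speciation_table(equilibria["6IdU"], C0)
        assert list(table.index) == [
            "nucleoside [Nuc]", "base [A]", "base anion [A-]",
            "sugar moiety [R]", "sugar moiety cation [R+]",
            "[OH-]", "[H3O+]",
        ]
        assert table.attrs["decomposed_fraction"] == pytest.approx(1.0,
                                                                   abs=1e-6)

    def test_sn2_product_rows_appear_only_when_populated(self, equilibria):
        st_ = equilibria["6IUrd"]
        assert "6OHUrd [hydrNuc]" not in speciation_table(st_).index
        st_.hydr_nucleoside = 1.6e-4
        st_.iodide = 1.6e-4
        try:
            table = speciation_table(st_)
            assert "6OHUrd [hydrNuc]" in table.index
            assert "iodide anion [I-]" in table.index
        finally:
            st_.hydr_nucleoside = 0.0
            st_.iodide = 0.0
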