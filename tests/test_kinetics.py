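"""Tests for network construction, stiff integration, and derived times."""

import math

import numpy as np
import pytest

from nucstab.kinetics import (
    Reaction,
    ReactionNetwork,
    build_network,
    half_life,
    rate_sensitivity,
    simulate,
    time_to_equilibrium,
)
from nucstab.speciation import EquilibriumConstants, solve_equilibrium
from nucstab.thermo import BarrierSpec, ThermoContext, eyring_rate

C0 = 1e-3


class TestBuildNetwork:
    def test_species_counts(self, models):
        assert len(models["5IdU"].network.species) == 7
        assert len(models["6IdU"].network.species) == 7
        assert len(models["6IUrd"].network.species) == 9
        assert "hydrNuc" in models["6IUrd"].network.species
        assert "hydrNuc" not in models["5IdU"].network.species

    @pytest.mark.parametrize("name", ["5IdU", "6IdU", "6IUrd"])
    def test_detailed_balance_by_construction(self, models, name):
        """Every reversible reaction satisfies K = k_f/k_r exactly."""
        for rxn in models[name].network.reactions:
            if rxn.equilibrium_constant is not None and rxn.k_reverse > 0:
                assert rxn.k_forward / rxn.k_reverse == pytest.approx(
                    rxn.equilibrium_constant, rel=1e-12)

    @pytest.mark.parametrize("name", ["5IdU", "6IdU", "6IUrd"])
    def test_reactions_conserve_base_sugar_and_charge(self, models, name):
        for rxn in models[name].network.reactions:
            assert rxn.conserves_composition(), rxn.name

    def test_slow_step_is_the_eyring_rate_of_the_barrier(self, models, ctx):
        r1 = models["6IdU"].network.reactions[0]
        assert r1.k_forward == pytest.approx(
            eyring_rate(BarrierSpec(18.0), ctx))

    def test_inconsistent_reverse_rate_rejected(self):
        bad = Reaction("R1", ("Nuc",), ("Aminus", "Rplus"), 1.0, 2.0, 1.0)
        with pytest.raises(ValueError, match="does not match"):
            ReactionNetwork(
                "X", ("Nuc", "A", "Aminus", "R", "Rplus", "H3O", "OH"),
                (bad,), EquilibriumConstants(K_a=1e3, K_b=1e-6, K_diss=1.0))

    def test_unbalanced_reaction_rejected(self):
        bad = Reaction("Rx", ("Nuc",), ("A",), 1.0, 1.0, 1.0)  # loses sugar
        with pytest.raises(ValueError, match="composition"):
            ReactionNetwork(
                "X", ("Nuc", "A", "Aminus", "R", "Rplus", "H3O", "OH"),
                (bad,), EquilibriumConstants(K_a=1e3, K_b=1e-6, K_diss=1.0))

    def test_missing_kdiss_rejected(self, ctx):
        c = EquilibriumConstants(K_a=2.3e12, K_b=1.2e-10)
        with pytest.raises(ValueError, match="K_diss"):
            build_network("6IdU", BarrierSpec(18.0), c, ctx)


class TestSimulate:
    def test_zero_rate_network_stays_constant(self, models):
        m = models["6IdU"]
        frozen = m.network.scaled(("R1", "R2", "R3", "R4"), 0.0)
        traj = simulate(frozen, C0, 10.0)
        assert np.all(traj.species_series("Nuc") == C0)
        for sp in ("A", "Aminus", "H3O", "OH"):
            assert np.all(traj.species_series(sp) == 0.0)

    def test_terminal_state_matches_published_kinetics_column(self, traj_6idu):
        term = traj_6idu.terminal_state()
        assert term.base == pytest.approx(7.5e-4, rel=0.10)
        assert term.base_anion == pytest.approx(2.5e-4, rel=0.10)
        assert term.hydronium == pytest.approx(2.5e-4, rel=0.10)

    @pytest.mark.parametrize("fixture", ["traj_6idu", "traj_6iurd",
                                         "traj_5idu"])
    def test_conservation_along_trajectory(self, fixture, request):
        traj = request.getfixturevalue(fixture)
        residuals = traj.balance_residuals()
        assert residuals["base_balance"] < 1e-6
        assert residuals["sugar_balance"] < 1e-6
        assert residuals["charge_balance"] < 1e-6

    def test_concentrations_never_negative(self, traj_6idu):
        assert (traj_6idu.concentrations.to_numpy() >= 0).all()

    @pytest.mark.parametrize("fixture, name", [
        ("traj_6idu", "6IdU"),
        ("traj_5idu", "5IdU"),
        ("traj_6iurd_no_sn2", "6IUrd"),
    ])
    def test_terminal_state_matches_independent_equilibrium(
            self, fixture, name, request, models):
        """Kinetics relaxes onto the equilibrium solve for every species.

        For the ribo compound the SN2-free network is the one whose
        stationary state *is* the equilibrium system.
        """
        traj = request.getfixturevalue(fixture)
        eq = solve_equilibrium(models[name].constants, C0)
        term = traj.terminal_state().as_dict()
        for species, value in eq.as_dict().items():
            if value > 1e-22:
                assert term[species] == pytest.approx(value, rel=5e-3), species

    def test_ion_product_at_terminal_state(self, traj_6idu, models):
        term = traj_6idu.terminal_state()
        assert term.ion_product() == pytest.approx(
            models["6IdU"].constants.K_w, rel=1e-3)

    def test_sn2_channel_acidifies_and_makes_hydroxyuridine(self, traj_6iurd):
        term = traj_6iurd.terminal_state()
        assert term.hydr_nucleoside > 1e-5
        assert term.hydr_nucleoside == pytest.approx(term.iodide, rel=1e-9)

    def test_nonpositive_horizon_rejected(self, models):
        with pytest.raises(ValueError):
            simulate(models["6IdU"].network, C0, 0.0)

    def test_export_round_trips_through_csv(self, traj_6idu, tmp_path):
        path = tmp_path / "traj.csv"
        traj_6idu.to_csv(path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time_s"] + list(
            traj_6idu.network.species)
        assert frame["Nuc"].iloc[0] == pytest.approx(C0)


class TestHalfLife:
    def test_deoxy_compound_halves_within_seconds(self, traj_6idu):
        hl = half_life(traj_6idu)
        # +-30% of the published 1.4 s: the 0.1 kcal rounding of the
        # barrier alone moves the Eyring rate by 18%
        assert hl == pytest.approx(1.4, rel=0.30)

    def test_ribo_compound_halves_within_hours(self, traj_6iurd):
        hl = half_life(traj_6iurd)
        assert hl / 3600.0 == pytest.approx(13.8, rel=0.30)

    def test_stable_compound_has_no_half_life(self, traj_5idu):
        """58% of the substrate survives at equilibrium, so no crossing."""
        assert half_life(traj_5idu) is None
        assert traj_5idu.species_series("Nuc").min() > C0 / 2

    def test_crossing_is_interpolated_between_grid_points(self, models):
        # a 5x coarser output grid moves the interpolated crossing only
        # marginally
        traj = simulate(models["6IdU"].network, C0, 1e3, n_points=160)
        dense = simulate(models["6IdU"].network, C0, 1e3, n_points=800)
        assert half_life(traj) == pytest.approx(half_life(dense), rel=1e-3)


class TestTimeToEquilibrium:
    def test_already_equilibrated_trajectory_returns_zero(self, models):
        # start the clock on a system that has long since relaxed
        m = models["6IdU"]
        eq = solve_equilibrium(m.constants, C0)
        traj = simulate(m.network, C0, 1e3)
        late = traj.concentrations.iloc[-1]
        # build a 'trajectory' beginning at equilibrium by shifting: the
        # terminal state is equilibrium to ~1e-9, so deviation < rel_tol
        result = time_to_equilibrium(traj, eq, rel_tol=0.05)
        assert result.reached
        assert result.closest_relative_deviation < 1e-6
        assert late["Nuc"] == pytest.approx(eq.nucleoside, rel=1e-6)

    def test_stable_compound_equilibrates_over_centuries(self, traj_5idu,
                                                         models):
        eq = solve_equilibrium(models["5IdU"].constants, C0)
        result = time_to_equilibrium(traj_5idu, eq, rel_tol=0.05)
        assert result.reached
        years = result.time_s / (365.25 * 24 * 3600.0)
        # order of magnitude of the published ~126 years
        assert 126 / math.sqrt(10) < years < 126 * math.sqrt(10)

    def test_equilibration_takes_longer_than_the_half_life(self, traj_6idu,
                                                           models):
        eq = solve_equilibrium(models["6IdU"].constants, C0)
        result = time_to_equilibrium(traj_6idu, eq, rel_tol=0.05)
        assert result.reached
        assert result.time_s > half_life(traj_6idu)

    def test_unreached_equilibrium_reports_closest_approach(self, models):
        m = models["5IdU"]
        eq = solve_equilibrium(m.constants, C0)
        short = simulate(m.network, C0, 1e6)  # far below the century scale
        result = time_to_equilibrium(short, eq, rel_tol=0.05)
        assert not result.reached
        assert result.time_s is None
        assert result.closest_relative_deviation > 0.05


class TestRateSensitivity:
    def test_fast_step_factors_leave_observables_unchanged(self, models):
        """Half-life and terminal state vary < 1% over four decades."""
        table = rate_sensitivity(models["6IdU"].network, C0, 1e3,
                                 factors=(1e-2, 1.0, 1e2))
        ref = table[(table.reaction == "R2") & (table.factor == 1.0)].iloc[0]
        for _, row in table.iterrows():
            assert row.half_life_s == pytest.approx(ref.half_life_s,
                                                    rel=0.01)
            for sp in ("Nuc", "A", "Aminus", "H3O", "OH"):
                assert row[sp] == pytest.approx(ref[sp], rel=0.01), sp

    def test_factor_one_reproduces_the_reference_exactly(self, models):
        net = models["6IdU"].network
        assert net.scaled("R2", 1.0).reactions[1].k_forward == \
            net.reactions[1].k_forward

    def test_unknown_reaction_rejected(self, models):
        with pytest.raises(ValueError, match="unknown reaction"):
            models["6IdU"].network.scaled("R9", 2.0)
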