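"""Markov cohort engine: state space, stepping, conservation, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdcea.model_core import (
    DEATH,
    ESRD,
    ConfigurationError,
    ModelError,
    Subpopulation,
    build_state_space,
    cumulative_incidence,
    simulate_cohort,
    step_cohort,
)

from conftest import constant_transition_model


class TestStateSpace:
    def test_default_space_has_11_bins_and_2_absorbing_states(self):
        sp = build_state_space()
        assert sp.n_bins == 11
        assert sp.n_states == 13
        assert sp.bin_lowers == tuple(range(55, 0, -5))
        assert sp.state_names[-2:] == (ESRD, DEATH)

    def test_truncated_space(self):
        sp = build_state_space(top_egfr=29, floor_egfr=5)
        assert sp.n_bins == 5
        assert sp.n_states == 7

    def test_misaligned_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            build_state_space(top_egfr=57)

    def test_esrd_eligibility_is_fully_below_threshold(self):
        sp = build_state_space()
        assert sp.esrd_eligible == (10, 5)
        sp20 = build_state_space(esrd_entry_below=20)
        assert sp20.esrd_eligible == (15, 10, 5)

    def test_stage_mapping_follows_kdigo(self):
        sp = build_state_space()
        assert sp.stage(55) == 3 and sp.stage(30) == 3
        assert sp.stage(25) == 4 and sp.stage(15) == 4
        assert sp.stage(10) == 5 and sp.stage(5) == 5

    def test_bin_index_covers_range(self):
        sp = build_state_space()
        assert sp.bin_lowers[sp.bin_index(59)] == 55
        assert sp.bin_lowers[sp.bin_index(45)] == 45
        with pytest.raises(ConfigurationError):
            sp.bin_index(60)


class TestStepCohort:
    def test_absorbed_mass_stays_in_death(self, space):
        tm = constant_transition_model(space, p_progress=0.3, p_death=0.2)
        occ = np.zeros(space.n_states)
        occ[space.death_index] = 1.0
        new, inflow = step_cohort(occ, tm, 70)
        assert np.array_equal(new, occ)
        assert inflow == 0.0

    def test_direct_probability_application(self, space):
        tm = constant_transition_model(space, p_progress=0.01, p_death=0.002)
        occ = np.zeros(space.n_states)
        occ[0] = 1.0  # bin [55, 59]
        new, _ = step_cohort(occ, tm, 70)
        assert new[0] == pytest.approx(0.988)
        assert new[1] == pytest.approx(0.01)
        assert new[space.death_index] == pytest.approx(0.002)

    def test_identity_model_leaves_occupancy_unchanged(self, space):
        tm = constant_transition_model(space)
        occ = np.full(space.n_states, 1.0 / space.n_states)
        new, _ = step_cohort(occ, tm, 70)
        assert np.allclose(new, occ, atol=1e-15)

    def test_excess_exit_probability_raises_naming_state(self, space):
        tm = constant_transition_model(space, p_progress=0.7, p_death=0.4)
        occ = np.zeros(space.n_states)
        occ[0] = 1.0
        with pytest.raises(ModelError, match="egfr_55_59"):
            step_cohort(occ, tm, 70)

    @settings(max_examples=25, deadline=None)
    @given(
        pp=st.floats(0, 0.4),
        pe=st.floats(0, 0.2),
        pd=st.floats(0, 0.3),
        pde=st.floats(0, 0.9),
    )
    def test_conservation_under_random_models(self, pp, pe, pd, pde):
        space = build_state_space()
        tm = constant_transition_model(
            space, p_progress=pp, p_esrd=pe, p_death=pd, p_death_esrd=pde
        )
        occ = np.zeros(space.n_states)
        occ[3] = 0.6
        occ[space.esrd_index] = 0.3
        occ[space.death_index] = 0.1
        for _ in range(5):
            occ, _ = step_cohort(occ, tm, 70)
            assert abs(occ.sum() - 1.0) <= 1e-12


class TestSimulateCohort:
    def test_certain_death_absorbs_in_one_cycle(self, space, sub):
        tm = constant_transition_model(space, p_death=1.0, p_death_esrd=1.0)
        traj = simulate_cohort(sub, tm, 2)
        assert traj.occupancy[1, space.death_index] == pytest.approx(1.0)
        assert traj.terminated_at == 1

    def test_geometric_survival_closed_form(self, space, sub):
        q = 0.013
        tm = constant_transition_model(space, p_death=q)
        traj = simulate_cohort(sub, tm, 3)
        t = np.arange(traj.occupancy.shape[0])
        alive = 1.0 - traj.occupancy[:, space.death_index]
        assert np.allclose(alive, (1 - q) ** t, atol=1e-12)

    def test_conservation_every_cycle(self, usual_fit, sub):
        traj = simulate_cohort(sub, usual_fit.tm, 30)
        sums = traj.occupancy.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) <= 1e-12

    def test_absorbing_occupancy_monotone(self, usual_fit, sub):
        traj = simulate_cohort(sub, usual_fit.tm, 30)
        death = traj.occupancy[:, traj.space.death_index]
        assert np.all(np.diff(death) >= -1e-15)
        assert np.all(np.diff(traj.esrd_entries) >= -1e-15)

    def test_nonpositive_horizon_rejected(self, space, sub):
        tm = constant_transition_model(space)
        with pytest.raises(ConfigurationError):
            simulate_cohort(sub, tm, 0)


def oracle_incidences(pp, pe, pd, pd_esrd, T, start_bin):
    """Exhaustive path-sum of ESRD-entry and death probability by cycle T.

    Enumerates every monotone bin path by its departure times (the chain
    cannot revisit a bin), summing exact path probabilities; ESRD-to-death
    uses the geometric closed form.  Independent of the cohort engine.
    """
    nb = len(pp)
    totals = {"esrd": 0.0, "death": 0.0}

    def rec(b, t, prob):
        stay = 1.0 - pp[b] - pe[b] - pd[b]
        p_here = prob
        for u in range(t, T):
            totals["death"] += p_here * pd[b]
            entered = p_here * pe[b]
            totals["esrd"] += entered
            totals["death"] += entered * (1.0 - (1.0 - pd_esrd) ** (T - (u + 1)))
            if b + 1 < nb and pp[b] > 0:
                rec(b + 1, u + 1, p_here * pp[b])
            p_here *= stay

    rec(start_bin, 0, 1.0)
    return totals["esrd"], totals["death"]


class TestCumulativeIncidence:
    def test_matches_path_enumeration_oracle(self, toy_space, sub):
        pp = [0.08, 0.0]
        pe = [0.02, 0.05]
        pd = [0.01, 0.03]
        pde = 0.04
        tm = constant_transition_model(
            toy_space, p_death=0.0, n_ages=5
        )
        tm.p_progress[:, 0] = pp[0]
        tm.p_esrd[:, 0], tm.p_esrd[:, 1] = pe
        tm.p_death[:, 0], tm.p_death[:, 1] = pd
        tm.p_death[:, toy_space.esrd_index] = pde
        start = np.zeros(toy_space.n_states)
        start[0] = 1.0
        traj = simulate_cohort(sub, tm, 2, start_occupancy=start)
        esrd_oracle, death_oracle = oracle_incidences(pp, pe, pd, pde, 24, 0)
        assert cumulative_incidence(traj, ESRD, 2) == pytest.approx(esrd_oracle, abs=1e-10)
        assert cumulative_incidence(traj, DEATH, 2) == pytest.approx(death_oracle, abs=1e-10)

    def test_single_path_toy_matches_hand_computation(self, toy_space, sub):
        # all mass in the bottom bin, only exit is ESRD at 0.1/month:
        # entries by t follow 1 - 0.9^t
        tm = constant_transition_model(toy_space, p_esrd=0.1, n_ages=5)
        start = np.zeros(toy_space.n_states)
        start[1] = 1.0
        traj = simulate_cohort(sub, tm, 1, start_occupancy=start)
        assert cumulative_incidence(traj, ESRD, 0.5) == pytest.approx(1 - 0.9**6, abs=1e-12)

    def test_everywhere_positive_death_approaches_one(self, space, sub):
        tm = constant_transition_model(space, p_death=0.05, p_death_esrd=0.05)
        traj = simulate_cohort(sub, tm, 40)
        assert cumulative_incidence(traj, DEATH, 40) > 0.999999

    def test_zero_esrd_entry_gives_zero_incidence(self, space, sub):
        tm = constant_transition_model(space, p_progress=0.05, p_death=0.01)
        traj = simulate_cohort(sub, tm, 10)
        for h in (1, 5, 10):
            assert cumulative_incidence(traj, ESRD, h) == 0.0

    def test_horizon_beyond_trajectory_rejected(self, space, sub):
        tm = constant_transition_model(space, p_death=0.01)
        traj = simulate_cohort(sub, tm, 2)
        with pytest.raises(ConfigurationError):
            cumulative_incidence(traj, DEATH, 3)

    def test_esrd_counter_includes_later_deaths(self, toy_space, sub):
        # with high ESRD mortality the end-state ESRD occupancy undercounts
        # entries; the entry counter must not
        tm = constant_transition_model(toy_space, p_esrd=0.2, p_death_esrd=0.5, n_ages=5)
        start = np.zeros(toy_space.n_states)
        start[1] = 1.0
        traj = simulate_cohort(sub, tm, 2, start_occupancy=start)
        entries = cumulative_incidence(traj, ESRD, 2)
        assert entries > traj.occupancy[-1, toy_space.esrd_index] + 0.1


def test_trajectory_export_is_tidy(usual_fit, sub):
    traj = simulate_cohort(sub, usual_fit.tm, 1)
    df = traj.to_frame()
    assert set(df.columns) == {"cycle", "age", "state", "occupancy"}
    assert len(df) == 13 * 13  # 12 cycles + initial, 13 states
    assert df.groupby("cycle")["occupancy"].sum().round(12).eq(1.0).all()
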