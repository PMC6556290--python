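import numpy as np
import pytest

from esccsim import (CompartmentLayout, DomainError, HealthState, LifeTable,
                     ModelParameters, OnsetHazardParams, UNDETECTED,
                     UndefinedResultError, ValidationError,
                     build_transition_row, incidence, onset_hazard,
                     prevalence, run_cohort, stage_distribution)
from esccsim.hazards import rate_to_prob

from conftest import random_parameters


def _flat_life_table(q):
    return LifeTable(np.full(101, q))


def _inert_parameters(**overrides):
    """All percentage-valued transitions zero; onset handled by multiplier."""
    zeros = dict(p_md_to_sd=0.0, p_sd_to_u1=0.0, p_u1_u2=0.0, p_u2_u3=0.0,
                 p_u3_u4=0.0, det1=0.0, det2=0.0, det3=0.0, det4=0.0,
                 mort2=0.0, mort3=0.0, mort4=0.0)
    return ModelParameters.table1(**(zeros | overrides))


class TestRunCohort:
    def test_everything_off_cohort_stays_normal(self):
        traj = run_cohort(_inert_parameters(), _flat_life_table(0.0),
                          onset_multiplier=0.0)
        normal = traj.occupancy[:, traj.layout.normal]
        np.testing.assert_allclose(normal, 1.0, atol=1e-12)

    def test_zero_onset_multiplier_leaves_no_lesions(self, table1, life_table):
        traj = run_cohort(table1, life_table, onset_multiplier=0.0)
        disease = [i for s in HealthState
                   if s not in (HealthState.NORMAL, HealthState.DEATH)
                   for i in traj.layout.indices(s)]
        assert traj.occupancy[:, disease].max() == 0.0

    def test_no_skip_without_md_to_sd(self, life_table):
        traj = run_cohort(ModelParameters.table1(p_md_to_sd=0.0), life_table)
        L = traj.layout
        downstream = traj.occupancy[:, L.sd:L.death]
        assert downstream.max() == 0.0
        assert traj.new_detections.max() == 0.0

    def test_conservation_and_monotonicity(self, table1_trajectory):
        occ = table1_trajectory.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert occ.min() >= 0.0
        dead = occ[:, table1_trajectory.layout.death]
        assert np.all(np.diff(dead) >= 0.0)
        assert table1_trajectory.new_detections.min() >= 0.0

    def test_conservation_holds_for_random_parameter_draws(self, rng):
        lt = _flat_life_table(0.01)
        for params in random_parameters(rng, 25):
            traj = run_cohort(params, lt)  # raises ConservationError if broken
            np.testing.assert_allclose(traj.occupancy.sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_three_state_closed_form_oracle(self):
        """Constant competing hazards admit an exact geometric solution."""
        q = 0.01
        params = _inert_parameters(
            beta0=-4.0, beta1=0.0, beta2=0.0, beta3=0.0, alpha1=0.0)
        traj = run_cohort(params, _flat_life_table(q))
        p_on = rate_to_prob(np.exp(-4.0))
        p_prog = rate_to_prob(np.exp(params.bchmd_to_md.alpha0))
        a = 1.0 - p_on - q
        b = 1.0 - p_prog - q
        t = np.arange(traj.occupancy.shape[0])
        normal = a ** t
        bch = p_on * (a ** t - b ** t) / (a - b)
        L = traj.layout
        np.testing.assert_allclose(traj.occupancy[:, L.normal], normal,
                                   atol=1e-6)
        tunnels = traj.occupancy[:, L.tunnel0:L.tunnel0 + L.n_tunnels]
        np.testing.assert_allclose(tunnels.sum(axis=1), bch, atol=1e-6)

    def test_tunnel_expansion_matches_memoryless_model(self, life_table):
        """With alpha1 = 0 the duration tunnels add no memory."""
        params = ModelParameters.table1(alpha1=0.0)
        traj = run_cohort(params, life_table)
        L = traj.layout
        ages = np.arange(15.0, 100.0)
        p_on = rate_to_prob(np.asarray(onset_hazard(ages, params.onset)))
        p_prog = rate_to_prob(np.exp(params.bchmd_to_md.alpha0))
        q = life_table.qx[15:100]
        normal = np.empty(86)
        bch = np.empty(86)
        normal[0], bch[0] = 1.0, 0.0
        for t in range(85):
            normal[t + 1] = normal[t] * (1 - p_on[t] - q[t])
            bch[t + 1] = bch[t] * (1 - p_prog - q[t]) + normal[t] * p_on[t]
        tunnels = traj.occupancy[:, L.tunnel0:L.tunnel0 + L.n_tunnels]
        np.testing.assert_allclose(tunnels.sum(axis=1), bch, atol=1e-9)
        np.testing.assert_allclose(traj.occupancy[:, L.normal], normal,
                                   atol=1e-9)

    def test_restart_from_initial_occupancy(self, table1, life_table):
        full = run_cohort(table1, life_table)
        mid = full.occupancy[full.age_row(50)]
        resumed = run_cohort(table1, life_table, start_age=50, end_age=60,
                             init_occupancy=mid, layout=full.layout)
        np.testing.assert_allclose(resumed.occupancy[-1],
                                   full.occupancy[full.age_row(60)],
                                   atol=1e-12)


class TestTransitionRows:
    def test_death_is_absorbing(self, table1, life_table):
        row = build_transition_row(HealthState.DEATH, 50, 0, table1,
                                   life_table)
        assert row == {(HealthState.DEATH, 0): 1.0}

    def test_detected_stage1_has_background_mortality_only(self, table1,
                                                           life_table):
        row = build_transition_row(HealthState.D1, 62, 0, table1, life_table)
        assert set(row) == {(HealthState.D1, 0), (HealthState.DEATH, 0)}
        assert row[(HealthState.DEATH, 0)] == pytest.approx(life_table[62])

    def test_zero_hazards_give_identity_row(self, life_table):
        params = _inert_parameters()
        lt = _flat_life_table(0.0)
        for state in (HealthState.MD, HealthState.SD, HealthState.U3,
                      HealthState.D4):
            row = build_transition_row(state, 44, 0, params, lt,
                                       onset_multiplier=0.0)
            assert row == {(state, 0): 1.0}

    @pytest.mark.parametrize("state", list(HealthState))
    def test_rows_sum_to_one(self, state, table1, life_table):
        row = build_transition_row(state, 70, 5, table1, life_table)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_rows_reproduce_engine_step(self, life_table, rng):
        """A full transition matrix assembled from rows matches the engine."""
        (params,) = random_parameters(rng, 1)
        layout = CompartmentLayout()
        age = 55
        n = layout.n_compartments
        matrix = np.zeros((n, n))
        for i in range(n):
            state, dur = layout.state_of(i)
            row = build_transition_row(state, age, dur, params, life_table,
                                       layout=layout)
            for (to_state, to_dur), p in row.items():
                matrix[i, layout.index(to_state, to_dur)] += p
        occ = rng.dirichlet(np.ones(n))
        stepped = run_cohort(params, life_table, start_age=age,
                             end_age=age + 1, init_occupancy=occ,
                             layout=layout).occupancy[1]
        np.testing.assert_allclose(stepped, occ @ matrix, atol=1e-12)


class TestEpidemiologicalOutputs:
    def test_prevalence_zero_without_disease(self, table1, life_table):
        traj = run_cohort(table1, life_table, onset_multiplier=0.0)
        assert prevalence(traj, [HealthState.BCH_MD], 40, 69) == 0.0

    def test_prevalence_of_all_alive_states_is_one(self, table1_trajectory):
        alive = [s for s in HealthState if s is not HealthState.DEATH]
        assert prevalence(table1_trajectory, alive, 40, 69) == pytest.approx(
            1.0, abs=1e-12)

    def test_prevalence_requires_states_and_range(self, table1_trajectory):
        with pytest.raises(ValidationError):
            prevalence(table1_trajectory, [], 40, 69)
        with pytest.raises(DomainError):
            prevalence(table1_trajectory, [HealthState.SD], 10, 20)

    def test_incidence_zero_without_detection(self, life_table):
        params = ModelParameters.table1(det1=0.0, det2=0.0, det3=0.0,
                                        det4=0.0)
        traj = run_cohort(params, life_table)
        assert incidence(traj, 40, 84) == 0.0
        with pytest.raises(UndefinedResultError):
            stage_distribution(traj, 40, 84)

    def test_stage_distribution_single_detectable_stage(self, life_table):
        params = ModelParameters.table1(det2=0.0, det3=0.0, det4=0.0)
        traj = run_cohort(params, life_table)
        np.testing.assert_allclose(stage_distribution(traj, 15, 99),
                                   [1.0, 0.0, 0.0, 0.0])

    def test_stage_distribution_sums_to_one(self, table1_trajectory):
        dist = stage_distribution(table1_trajectory, 15, 99)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist > 0.0)

    def test_incidence_past_last_cycle_rejected(self, table1_trajectory):
        with pytest.raises(DomainError):
            incidence(table1_trajectory, 95, 100)

    def test_undetected_prevalence_includes_all_stages(self, table1_trajectory):
        total = prevalence(table1_trajectory, UNDETECTED, 45, 69)
        parts = sum(prevalence(table1_trajectory, [s], 45, 69)
                    for s in UNDETECTED)
        assert total == pytest.approx(parts, rel=1e-12)
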