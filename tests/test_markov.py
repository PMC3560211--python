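"""Markov cohort engine: back-calculation, transition matrices, conservation,
null-intervention equivalence, QALY accounting, discounting, and agreement
with an individual-level Monte-Carlo microsimulation of the same matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdprevent import (
    CohortCells,
    ComorbidRisks,
    DomainError,
    EpiScheduleConfig,
    HealthState,
    back_calculate_baseline_incidence,
    build_transition_matrix,
    discount,
    generate_epi_schedule,
    qalys,
    run_cohort,
)
from cvdprevent.analysis import LONG_TERM


class TestBackCalculation:
    def test_closed_form_example(self):
        assert back_calculate_baseline_incidence(0.01, 0.5, 0.8) == pytest.approx(
            0.01 / 0.9, rel=1e-12
        )

    def test_nobody_treated_is_identity(self):
        assert back_calculate_baseline_incidence(0.004, 0.0, 0.5) == 0.004

    def test_ineffective_drug_is_identity(self):
        assert back_calculate_baseline_incidence(0.004, 0.7, 1.0) == pytest.approx(0.004)

    def test_round_trip_recovers_observed(self, rng):
        for _ in range(1000):
            obs = rng.uniform(1e-5, 0.05)
            cov = rng.uniform(0.0, 1.0)
            rr = rng.uniform(0.3, 1.5)
            base = back_calculate_baseline_incidence(obs, cov, rr)
            forward = base * (cov * rr + (1 - cov))
            assert abs(forward - obs) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            back_calculate_baseline_incidence(0.01, 1.5, 0.8)
        with pytest.raises(DomainError):
            back_calculate_baseline_incidence(0.01, 0.5, -0.2)


class TestTransitionMatrix:
    def test_rows_sum_to_one_over_random_inputs(self, schedule, rng):
        for _ in range(1000):
            age = int(rng.integers(35, 101))
            sex = "male" if rng.random() < 0.5 else "female"
            cycle = int(rng.integers(0, 40))
            M = build_transition_matrix(
                age, sex, cycle, schedule,
                rr_ihd=rng.uniform(0.3, 1.2), rr_stroke=rng.uniform(0.3, 1.2),
            )
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= 0).all()

    def test_zero_rates_give_identity(self):
        cfg = EpiScheduleConfig(
            ihd_incidence_at_ref=(0.0, 0.0),
            stroke_incidence_at_ref=(0.0, 0.0),
            background_mortality_at_ref=(0.0, 0.0),
        )
        sched = generate_epi_schedule(config=cfg)
        M = build_transition_matrix(60, "male", 0, sched)
        np.testing.assert_allclose(M, np.eye(5), atol=1e-15)

    def test_null_rr_equals_comparator_matrix(self, schedule):
        M0 = build_transition_matrix(70, "female", 3, schedule)
        M1 = build_transition_matrix(70, "female", 3, schedule,
                                     rr_ihd=1.0, rr_stroke=1.0)
        np.testing.assert_allclose(M0, M1)

    def test_protective_rr_lowers_first_event_probability(self, schedule):
        M0 = build_transition_matrix(65, "male", 0, schedule)
        M1 = build_transition_matrix(65, "male", 0, schedule,
                                     rr_ihd=0.7, rr_stroke=0.7)
        W = HealthState.WELL
        assert M1[W, HealthState.IHD] < M0[W, HealthState.IHD]
        assert M1[W, HealthState.STROKE] < M0[W, HealthState.STROKE]

    def test_dead_is_absorbing(self, schedule):
        M = build_transition_matrix(90, "male", 10, schedule)
        np.testing.assert_array_equal(M[HealthState.DEAD],
                                      [0.0, 0.0, 0.0, 0.0, 1.0])

    def test_comorbid_multipliers_raise_second_event_rates(self, schedule):
        com_hi = ComorbidRisks(rr_stroke_in_ihd=(2.0, 2.0),
                               rr_ihd_in_stroke=(2.0, 2.0))
        com_lo = ComorbidRisks(rr_stroke_in_ihd=(1.0, 1.0),
                               rr_ihd_in_stroke=(1.0, 1.0))
        Mh = build_transition_matrix(70, "male", 0, schedule, comorbid=com_hi)
        Ml = build_transition_matrix(70, "male", 0, schedule, comorbid=com_lo)
        I, S, B = HealthState.IHD, HealthState.STROKE, HealthState.IHD_AND_STROKE
        assert Mh[I, B] > Ml[I, B]
        assert Mh[S, B] > Ml[S, B]


def _simple_cells(weights=(1000.0, 1000.0), ages=(55, 65), sexes=(0, 1)):
    return CohortCells.untreated(np.array(ages), np.array(sexes),
                                 np.array(weights))


class TestRunCohort:
    def test_conservation_every_cycle(self, schedule):
        cells = _simple_cells()
        trace = run_cohort(cells, schedule)
        totals = trace.occupancy_totals()
        np.testing.assert_allclose(totals, 2000.0, rtol=1e-9)

    def test_empty_cohort_gives_zero_trace(self, schedule):
        cells = CohortCells.untreated(np.array([50]), np.array([0]),
                                      np.array([0.0]))
        trace = run_cohort(cells, schedule)
        assert trace.total_qalys == 0.0
        assert trace.occupancy.sum() == 0.0

    def test_null_effect_scenario_equals_comparator(self, schedule, ctx):
        comp = run_cohort(_simple_cells(), schedule, ctx.cost_schedule)
        cells = _simple_cells()
        cells.rr_ihd[:] = 1.0
        cells.rr_stroke[:] = 1.0
        cells.treat_years[:] = LONG_TERM  # treated forever with a null drug
        null = run_cohort(cells, schedule, ctx.cost_schedule)
        np.testing.assert_allclose(null.occupancy, comp.occupancy, atol=1e-10)
        assert null.total_qalys == pytest.approx(comp.total_qalys, abs=1e-10)
        assert null.total_disease_cost == pytest.approx(comp.total_disease_cost,
                                                        rel=1e-12)
        assert null.total_gov_cost == 0.0  # null drug carries no cost here

    def test_protective_treatment_reduces_events_and_adds_qalys(self, schedule, ctx):
        comp = run_cohort(_simple_cells(), schedule, ctx.cost_schedule)
        cells = _simple_cells()
        cells.rr_ihd[:] = 0.7
        cells.rr_stroke[:] = 0.7
        cells.treat_years[:] = LONG_TERM
        treated = run_cohort(cells, schedule, ctx.cost_schedule)
        assert treated.events_ihd.sum() < comp.events_ihd.sum()
        assert treated.total_qalys > comp.total_qalys
        assert treated.total_disease_cost < comp.total_disease_cost

    def test_everyone_dead_or_100_by_end(self, schedule):
        trace = run_cohort(_simple_cells(ages=(84, 84)), schedule)
        final = trace.occupancy[-1]
        alive = final[:, : HealthState.DEAD].sum()
        assert alive < 2000.0 * 0.25  # most of an 84-year-old cohort dies

    def test_trace_long_format_export(self, schedule):
        trace = run_cohort(_simple_cells(), schedule)
        df = trace.to_frame()
        assert {"cycle", "age0", "sex", "WELL", "DEAD"} <= set(df.columns)
        total0 = df[df["cycle"] == 0][[s.name for s in HealthState]].to_numpy().sum()
        assert total0 == pytest.approx(2000.0)


class TestQALYs:
    def test_unit_weights_give_person_years(self):
        cfg = EpiScheduleConfig(
            ihd_incidence_at_ref=(0.0, 0.0), stroke_incidence_at_ref=(0.0, 0.0),
            background_mortality_at_ref=(0.0, 0.0),
            utility_at_35=1.0, utility_slope=0.0,
        )
        sched = generate_epi_schedule(config=cfg)
        trace = run_cohort(_simple_cells(weights=(10.0,), ages=(90,), sexes=(0,)),
                           sched, discount_rate=0.0)
        # nobody dies: 10 persons x 10 cycles (ages 90..99)
        assert trace.total_qalys == pytest.approx(100.0)
        assert qalys(trace, sched, discount_rate=0.0) == pytest.approx(100.0)

    def test_scalar_utility_scales_person_years(self):
        cfg = EpiScheduleConfig(
            ihd_incidence_at_ref=(0.0, 0.0), stroke_incidence_at_ref=(0.0, 0.0),
            background_mortality_at_ref=(0.0, 0.0),
            utility_at_35=0.8, utility_slope=0.0,
        )
        sched = generate_epi_schedule(config=cfg)
        trace = run_cohort(_simple_cells(weights=(1.0,), ages=(90,), sexes=(1,)),
                           sched, discount_rate=0.0)
        assert trace.total_qalys == pytest.approx(8.0)

    def test_matches_brute_force_summation_oracle(self, schedule):
        trace = run_cohort(_simple_cells(), schedule, discount_rate=0.03)
        dw = {
            HealthState.WELL: 0.0,
            HealthState.IHD: schedule.disability_weight_ihd,
            HealthState.STROKE: schedule.disability_weight_stroke,
            HealthState.IHD_AND_STROKE: 1 - (1 - schedule.disability_weight_ihd)
            * (1 - schedule.disability_weight_stroke),
        }
        total = 0.0
        for t in range(trace.n_cycles):
            for si, (age0, sex_idx) in enumerate(
                zip(trace.strata["age0"], trace.strata["sex_idx"])
            ):
                age = age0 + t
                if age >= 100:
                    continue
                u = schedule.utility_weight[age - 35, sex_idx]
                for state, w in dw.items():
                    total += (trace.occupancy[t, si, state] * u * (1 - w)
                              / 1.03**t)
        assert qalys(trace, schedule) == pytest.approx(total, rel=1e-12)
        assert trace.total_qalys == pytest.approx(total, rel=1e-12)


class TestDiscount:
    def test_base_year_and_one_period(self):
        assert discount(100.0, 0, 0.03) == pytest.approx(100.0)
        assert discount(103.0, 1, 0.03) == pytest.approx(100.0)

    def test_constant_stream_matches_annuity_closed_form(self):
        stream = sum(discount(1.0, t, 0.03) for t in range(1, 31))
        assert stream == pytest.approx((1 - 1.03**-30) / 0.03, abs=1e-10)

    @given(rate=st.floats(0.0, 0.2), years=st.integers(0, 80))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_inverse_of_compounding(self, rate, years):
        assert discount((1 + rate) ** years, years, rate) == pytest.approx(1.0)


class TestMicrosimulationAgreement:
    def test_cohort_matches_individual_monte_carlo(self, schedule):
        """Occupancies from the deterministic cohort engine agree with a
        2,000-person microsimulation of identical transition matrices within
        three binomial standard errors in at least 95% of state-cycle cells."""
        strata = [(55, "male", 0.8, 0.7), (65, "female", 1.0, 1.0)]
        n_per = 1000
        rng = np.random.default_rng(2024)

        ok = 0
        total = 0
        for age0, sex, rri, rrs in strata:
            n_cycles = 100 - age0
            # cohort side
            cells = CohortCells.untreated(
                np.array([age0]), np.array([0 if sex == "male" else 1]),
                np.array([float(n_per)]),
            )
            cells.rr_ihd[:] = rri
            cells.rr_stroke[:] = rrs
            cells.treat_years[:] = LONG_TERM
            trace = run_cohort(cells, schedule)

            # microsimulation side: same matrices, individual draws
            state = np.zeros(n_per, dtype=int)
            occ_micro = np.zeros((n_cycles, 5))
            for t in range(n_cycles):
                occ_micro[t] = np.bincount(state, minlength=5)
                age = age0 + t
                if age >= 100:
                    continue
                M = build_transition_matrix(age, sex, t, schedule,
                                            rr_ihd=rri, rr_stroke=rrs)
                cum = M.cumsum(axis=1)
                u = rng.random(n_per)
                state = (u[:, None] > cum[state]).sum(axis=1)

            for t in range(n_cycles):
                expected = trace.occupancy[t, 0]
                for s in range(5):
                    p = expected[s] / n_per
                    se = np.sqrt(n_per * p * (1 - p))
                    total += 1
                    if abs(occ_micro[t, s] - expected[s]) <= 3 * se + 1e-9:
                        ok += 1
        assert ok / total >= 0.95
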