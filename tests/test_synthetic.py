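"""Synthetic cohort generator: determinism, planted structure, filters."""

from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError

from collabcare import patterns as pat
from collabcare import segments as sg
from collabcare.selection import allowed_test_gap, filter_adherence, run_funnel
from collabcare.records import months_between
from collabcare.segments import classify_segment
from collabcare.synthetic import (
    DEFAULT_TRAJECTORIES,
    DEFAULT_TRANSITIONS,
    SimulationConfig,
    TrajectoryParams,
    TransitionModel,
    generate_cohort,
    generate_trajectory,
    separated_config,
)


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="pattern_mix"):
            SimulationConfig(pattern_mix={pat.SELF_CONTAINED: 0.5})

    def test_matrix_rows_stochastic(self):
        with pytest.raises(ValidationError, match="row"):
            TransitionModel(initial=(1, 0, 0), matrix=((0.5, 0.2, 0.2),) * 3)

    def test_unknown_pattern_label_in_mix(self):
        with pytest.raises(ValidationError, match="no transition matrix"):
            SimulationConfig(
                pattern_mix={"mystery": 1.0},
                transition_matrices=dict(DEFAULT_TRANSITIONS),
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(adherence_violation_rate=-0.1)


class TestDeterminism:
    def test_same_seed_identical(self):
        a = generate_cohort(SimulationConfig(n_patients=30, seed=5))
        b = generate_cohort(SimulationConfig(n_patients=30, seed=5))
        assert a.encounters == b.encounters
        assert a.measurements == b.measurements
        assert a.patients == b.patients
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=30, seed=5))
        b = generate_cohort(SimulationConfig(n_patients=30, seed=6))
        assert a.measurements != b.measurements


def test_degenerate_chain_all_physician():
    config = SimulationConfig(
        n_patients=1,
        pattern_mix={pat.SELF_CONTAINED: 1.0},
        transition_matrices={
            pat.SELF_CONTAINED: TransitionModel(
                initial=(1, 0, 0), matrix=((1, 0, 0), (1, 0, 0), (1, 0, 0))
            )
        },
        seed=11,
    )
    cohort = generate_cohort(config)
    assert {e.discipline for e in cohort.encounters} == {"P"}


def test_transition_frequencies_match_configured_matrices():
    """Empirical per-pattern transition frequencies converge to the chain
    (within 0.05 on rows with enough observed transitions)."""
    config = SimulationConfig(
        n_patients=500, seed=1, visit_interval_days=30.0, visit_jitter_days=0.0
    )
    cohort = generate_cohort(config)
    seqs: dict[str, list[tuple[str, ...]]] = {}
    per_patient: dict[str, list] = {}
    for e in cohort.encounters:
        per_patient.setdefault(e.patient_id, []).append(e)
    for pid, events in per_patient.items():
        events.sort(key=lambda e: e.date)
        seqs.setdefault(cohort.truth[pid].pattern, []).append(
            tuple(e.discipline for e in events)
        )
    idx = {"P": 0, "N": 1, "D": 2}
    for pattern, sequences in seqs.items():
        counts = np.zeros((3, 3))
        for s in sequences:
            for a, b in zip(s, s[1:]):
                counts[idx[a], idx[b]] += 1
        expected = np.asarray(DEFAULT_TRANSITIONS[pattern].matrix)
        for row in range(3):
            total = counts[row].sum()
            if total >= 100:
                emp = counts[row] / total
                assert np.abs(emp - expected[row]).max() <= 0.05, pattern


class TestTrajectories:
    def test_noise_free_series_classify_into_their_segment(self):
        rng = np.random.default_rng(0)
        for segment, params in DEFAULT_TRAJECTORIES.items():
            quiet = TrajectoryParams(baseline=params.baseline, slope=params.slope, noise_sd=0.0)
            series = generate_trajectory(segment, quiet, 18.0, rng)
            assert classify_segment(series).label == segment

    def test_constant_compensated_series(self):
        rng = np.random.default_rng(0)
        params = TrajectoryParams(baseline=6.2, slope=0.0, noise_sd=0.0)
        series = generate_trajectory(sg.COMPENSATED, params, 18.0, rng)
        assert all(v == 6.2 for _, v in series)

    def test_improving_series_ends_compensated(self):
        rng = np.random.default_rng(0)
        params = TrajectoryParams(baseline=9.5, slope=-0.2, noise_sd=0.0)
        series = generate_trajectory(sg.IMPROVED, params, 18.0, rng)
        out = classify_segment(series)
        assert out.label == sg.IMPROVED and out.slope < 0 and out.final < 7

    def test_constant_high_series(self):
        rng = np.random.default_rng(0)
        params = TrajectoryParams(baseline=10.0, slope=0.0, noise_sd=0.0)
        series = generate_trajectory(sg.HIGH, params, 18.0, rng)
        assert all(v > 9 for _, v in series)
        assert classify_segment(series).label == sg.HIGH

    def test_unknown_segment_error(self):
        with pytest.raises(ValueError, match="unknown segment"):
            generate_trajectory("worse", TrajectoryParams(baseline=7, slope=0, noise_sd=0),
                                18.0, np.random.default_rng(0))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            generate_trajectory(sg.COMPENSATED,
                                TrajectoryParams(baseline=6, slope=0, noise_sd=0),
                                6.0, np.random.default_rng(0))


class TestPlantedViolations:
    def test_violators_exceed_allowed_gap(self):
        config = SimulationConfig(n_patients=60, seed=3, adherence_violation_rate=1.0)
        cohort = generate_cohort(config)
        per_patient: dict[str, list] = {}
        for m in cohort.measurements:
            per_patient.setdefault(m.patient_id, []).append(m)
        for pid, rows in per_patient.items():
            rows.sort(key=lambda m: m.date)
            gaps = [
                (months_between(a.date, b.date), allowed_test_gap(a.value))
                for a, b in zip(rows, rows[1:])
            ]
            assert any(g > allowed for g, allowed in gaps), pid

    def test_adherence_filter_removal_rate_converges(self):
        rate = 0.3
        config = SimulationConfig(n_patients=1000, seed=9, adherence_violation_rate=rate)
        cohort = generate_cohort(config)
        adherent = filter_adherence(cohort.measurements)
        removed = 1 - len(adherent) / config.n_patients
        assert removed == pytest.approx(rate, abs=0.05)
        # removed patients are exactly the planted violators
        violators = {p for p, t in cohort.truth.items() if t.adherence_violator}
        assert set(m.patient_id for m in cohort.measurements) - adherent == violators

    def test_comorbidity_rate_exercises_filter(self):
        config = SimulationConfig(n_patients=400, seed=2, comorbidity_rate=0.25)
        cohort = generate_cohort(config)
        flagged = [p for p in cohort.patients if p.dcsi_count or p.cic_count]
        assert len(flagged) / 400 == pytest.approx(0.25, abs=0.06)
        _, report = run_funnel(cohort.patients, cohort.measurements)
        assert report.n_no_comorbidity == report.n_min_tests - len(flagged)


def test_truth_covers_exactly_generated_patients():
    cohort = generate_cohort(SimulationConfig(n_patients=25, seed=4))
    assert set(cohort.truth) == {p.patient_id for p in cohort.patients}
    event_ids = {e.patient_id for e in cohort.encounters} | {
        m.patient_id for m in cohort.measurements
    }
    assert event_ids <= set(cohort.truth)


def test_separated_config_recovers_planted_segments_with_noise():
    """At measurement noise 0.2% the segmentation recovers nearly all
    planted outcome labels."""
    from collabcare.selection import define_study_window, group_measurements
    from collabcare.segments import classify_patient

    cohort = generate_cohort(separated_config(n_patients=300, seed=7, noise_sd=0.2))
    grouped = group_measurements(cohort.measurements)
    hits = total = 0
    for pid, rows in grouped.items():
        window = define_study_window(rows)
        assert window is not None
        got = classify_patient(rows, window).label
        total += 1
        hits += got == cohort.truth[pid].segment
    assert hits / total >= 0.95
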