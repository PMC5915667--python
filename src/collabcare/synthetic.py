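"""Synthetic ECR cohort generator.

Emulates the extract the pipeline consumes: CVPA encounter events, HbA1c
test results, and a patient table — with per-patient planted ground truth
(collaboration pattern, outcome segment, adherence-violator flag) so every
downstream stage can be exercised and scored without real data.

Discipline sequences are realized either from per-pattern first-order
Markov chains (``transition_matrices``) or from per-pattern deterministic
sequence templates (``sequence_templates``; cycled to the patient's visit
count). Chains give realistic within-pattern variability; templates give
the sharply separated trajectories needed for clean cluster recovery —
first-order chains with ~50% leader self-referral necessarily produce
same-pattern sequences differing by far more than the 15% clustering
threshold, so recovery experiments use templates.

HbA1c trajectories are linear with Gaussian noise, truncated to [4, 20]%:
``value(t) = baseline + slope * t + N(0, sd)``. Test times follow the
band-driven protocol schedule (12/6/3 months by current decompensation
band) scaled by a sub-1 jitter factor so adherent patients always respect
the allowed gap; planted violators get their first inter-test gap pushed
beyond schedule + tolerance.

All sampling flows through one ``numpy`` generator seeded from the config;
per patient the draw order is fixed (pattern, segment, violator flag,
comorbidity flag, demographics, visit schedule, test schedule/values), so
equal configs produce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import segments as seg
from .records import (
    DISCIPLINES,
    MONTH_DAYS,
    ConfigurationError,
    EncounterRecord,
    Hba1cMeasurement,
    PatientRecord,
)
from .selection import TEST_SCHEDULE_MONTHS, allowed_test_gap, hba1c_band
from . import patterns as pat


class TransitionModel(BaseModel):
    """Initial-discipline distribution and 3×3 row-stochastic matrix over (P, N, D)."""

    model_config = ConfigDict(frozen=True)

    initial: tuple[float, float, float]
    matrix: tuple[
        tuple[float, float, float],
        tuple[float, float, float],
        tuple[float, float, float],
    ]

    @field_validator("initial")
    @classmethod
    def _initial_stochastic(cls, v):
        if any(p < 0 or p > 1 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("initial distribution must be probabilities summing to 1")
        return v

    @field_validator("matrix")
    @classmethod
    def _rows_stochastic(cls, v):
        for i, row in enumerate(v):
            if any(p < 0 or p > 1 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"matrix row {i} must be probabilities summing to 1")
        return v


class TrajectoryParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    baseline: float  # HbA1c % at t0
    slope: float  # % per month
    noise_sd: float = Field(ge=0.0)  # %


#: Stochastic per-pattern chains used as realistic defaults. The
#: self-contained chain is the identity matrix with a mixed start, so a
#: patient is all-physician or all-nurse depending on the first draw.
DEFAULT_TRANSITIONS: dict[str, TransitionModel] = {
    pat.SELF_CONTAINED: TransitionModel(
        initial=(0.7, 0.3, 0.0),
        matrix=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    ),
    pat.TACIT_LEADER: TransitionModel(
        initial=(1.0, 0.0, 0.0),
        matrix=((0.55, 0.45, 0), (0.9, 0.1, 0), (1, 0, 0)),
    ),
    pat.SHARED: TransitionModel(
        initial=(0.5, 0.5, 0.0),
        matrix=((0.35, 0.65, 0), (0.65, 0.35, 0), (1, 0, 0)),
    ),
    pat.PARTICIPATORY: TransitionModel(
        initial=(1 / 3, 1 / 3, 1 / 3),
        matrix=(
            (1 / 3, 1 / 3, 1 / 3),
            (1 / 3, 1 / 3, 1 / 3),
            (1 / 3, 1 / 3, 1 / 3),
        ),
    ),
    pat.EQUITABLY_CENTERED: TransitionModel(
        initial=(1.0, 0.0, 0.0),
        matrix=((0.5, 0.25, 0.25), (0.6, 0.1, 0.3), (0.6, 0.3, 0.1)),
    ),
    pat.HIERARCHICALLY_CENTERED: TransitionModel(
        initial=(1.0, 0.0, 0.0),
        matrix=((0.5, 0.3, 0.2), (0.55, 0.45, 0), (0.7, 0, 0.3)),
    ),
    pat.SELF_REFERRED_LEADER: TransitionModel(
        initial=(1.0, 0.0, 0.0),
        matrix=((0.78, 0.02, 0.2), (0.9, 0.1, 0), (0.95, 0, 0.05)),
    ),
}

#: Deterministic sequence archetypes realizing the seven patterns with all
#: cross-pattern normalized edit distances above 0.15 and within-pattern
#: variants within 0.15 (so a 15% complete-linkage cut recovers them).
ARCHETYPE_TEMPLATES: dict[str, tuple[str, ...]] = {
    pat.SELF_CONTAINED: ("PPPPPPPPPPPP", "NNNNNNNNNNNN"),
    pat.TACIT_LEADER: ("PPNPPNPPNPPN",),
    pat.SHARED: ("PNPNPNPNPNPN",),
    pat.PARTICIPATORY: ("PNDPNDPNDPND",),
    pat.EQUITABLY_CENTERED: ("PPNDPPNDPPND",),
    pat.HIERARCHICALLY_CENTERED: ("PNPPDPPNPPDP",),
    pat.SELF_REFERRED_LEADER: ("PPDPPPPDPPPP", "PPDPPPPDNPPP"),
}

#: Per-segment trajectory defaults chosen so a noise-free realization
#: classifies into its segment: stable below goal, declining from high to
#: below goal, stable inside the [7, 9] band, stable above 9.
DEFAULT_TRAJECTORIES: dict[str, TrajectoryParams] = {
    seg.COMPENSATED: TrajectoryParams(baseline=6.2, slope=0.0, noise_sd=0.2),
    seg.IMPROVED: TrajectoryParams(baseline=9.5, slope=-0.2, noise_sd=0.2),
    seg.MODERATE: TrajectoryParams(baseline=8.0, slope=0.0, noise_sd=0.2),
    seg.HIGH: TrajectoryParams(baseline=9.8, slope=0.0, noise_sd=0.2),
}

#: Pattern mix mirroring the reference cohort's non-outlier row totals
#: (41, 61, 24, 35, 21, 14, 17 of 213).
DEFAULT_PATTERN_MIX: dict[str, float] = {
    pat.SELF_CONTAINED: 41 / 213,
    pat.TACIT_LEADER: 61 / 213,
    pat.SHARED: 24 / 213,
    pat.PARTICIPATORY: 35 / 213,
    pat.EQUITABLY_CENTERED: 21 / 213,
    pat.HIERARCHICALLY_CENTERED: 14 / 213,
    pat.SELF_REFERRED_LEADER: 17 / 213,
}

#: Segment mix mirroring the reference cohort (114, 37, 43, 37 of 231).
DEFAULT_SEGMENT_MIX: dict[str, float] = {
    seg.COMPENSATED: 114 / 231,
    seg.IMPROVED: 37 / 231,
    seg.MODERATE: 43 / 231,
    seg.HIGH: 37 / 231,
}


class SimulationConfig(BaseModel):
    """Study conditions of a synthetic cohort (all rates and mixes validated)."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=231, ge=1)
    pattern_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    transition_matrices: dict[str, TransitionModel] = Field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )
    sequence_templates: Optional[dict[str, tuple[str, ...]]] = None
    segment_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SEGMENT_MIX))
    trajectory_params: dict[str, TrajectoryParams] = Field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    visit_interval_days: float = Field(default=114.0, gt=0)  # ≈ 4.8 CVPAs / 18 months
    visit_jitter_days: float = Field(default=20.0, ge=0)
    adherence_violation_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    comorbidity_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    horizon_months: float = Field(default=20.0, ge=10.0)
    adherence_tolerance_months: float = Field(default=4.0, ge=0.0)
    #: scheduled gap is multiplied by a draw from this range; keeping the
    #: upper end below 1 guarantees adherent patients stay within protocol.
    test_gap_factor_range: tuple[float, float] = (0.7, 0.95)
    #: None → band-driven 12/6/3-month schedule; a number → fixed gap.
    fixed_test_gap_months: Optional[float] = None
    start_date: date = date(2015, 1, 1)
    start_jitter_days: int = Field(default=0, ge=0)
    seed: int = 0

    @field_validator("pattern_mix", "segment_mix")
    @classmethod
    def _mix_valid(cls, v, info):
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError(f"{info.field_name}: probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"{info.field_name}: probabilities must sum to 1")
        return v

    @field_validator("test_gap_factor_range")
    @classmethod
    def _factors_valid(cls, v):
        lo, hi = v
        if not 0 < lo <= hi <= 1.0:
            raise ValueError("test_gap_factor_range must satisfy 0 < low <= high <= 1")
        return v

    @model_validator(mode="after")
    def _labels_covered(self):
        for label in self.pattern_mix:
            has_chain = label in self.transition_matrices
            has_template = self.sequence_templates and label in self.sequence_templates
            if not (has_chain or has_template):
                raise ValueError(
                    f"pattern_mix: no transition matrix or template for {label!r}"
                )
        for label in self.segment_mix:
            if label not in self.trajectory_params:
                raise ValueError(f"segment_mix: no trajectory parameters for {label!r}")
        return self


@dataclass(frozen=True)
class PlantedTruth:
    pattern: str
    segment: str
    adherence_violator: bool


@dataclass
class SyntheticCohort:
    encounters: list[EncounterRecord]
    measurements: list[Hba1cMeasurement]
    patients: list[PatientRecord]
    truth: dict[str, PlantedTruth]

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        event_ids = {e.patient_id for e in self.encounters} | {
            m.patient_id for m in self.measurements
        }
        if not event_ids <= ids:
            raise ConfigurationError(
                f"events reference unknown patients: {sorted(event_ids - ids)}"
            )
        if set(self.truth) != ids:
            raise ConfigurationError("truth must cover exactly the generated patients")


def separated_config(
    n_patients: int = 500, seed: int = 0, noise_sd: float = 0.0, **overrides
) -> SimulationConfig:
    """Config with sharply distinct pattern templates and a deterministic
    visit/test schedule — the conditions for planted-recovery experiments.

    Every patient gets tests at 0/5.4/10.8/16.2 months (study window 16.2
    months for all) and 11 CVPAs at a 45-day cadence, so same-pattern
    sequences are identical up to the templated variants.
    """
    trajectories = {
        label: TrajectoryParams(baseline=p.baseline, slope=p.slope, noise_sd=noise_sd)
        for label, p in DEFAULT_TRAJECTORIES.items()
    }
    defaults: dict = dict(
        n_patients=n_patients,
        pattern_mix={p: 1 / 7 for p in pat.PATTERNS},
        sequence_templates=dict(ARCHETYPE_TEMPLATES),
        segment_mix={s: 0.25 for s in seg.SEGMENTS},
        trajectory_params=trajectories,
        visit_interval_days=45.0,
        visit_jitter_days=0.0,
        fixed_test_gap_months=6.0,
        test_gap_factor_range=(0.9, 0.9),
        adherence_violation_rate=0.0,
        comorbidity_rate=0.0,
        horizon_months=20.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _measurement_times(
    params: TrajectoryParams,
    horizon_months: float,
    rng: np.random.Generator,
    *,
    fixed_gap_months: float | None,
    factor_range: tuple[float, float],
    violator: bool,
    tolerance_months: float,
) -> tuple[list[float], list[float]]:
    """Sequential (times, values): the next gap depends on the current value."""
    lo, hi = factor_range
    times: list[float] = []
    values: list[float] = []
    t = 0.0
    while t <= horizon_months + 1e-9:
        v = params.baseline + params.slope * t
        if params.noise_sd > 0:
            v += rng.normal(0.0, params.noise_sd)
        v = float(np.clip(v, 4.0, 20.0))
        times.append(t)
        values.append(v)
        if fixed_gap_months is not None:
            gap = fixed_gap_months * (lo if lo == hi else rng.uniform(lo, hi))
        else:
            gap = TEST_SCHEDULE_MONTHS[hba1c_band(v)] * (
                lo if lo == hi else rng.uniform(lo, hi)
            )
        if violator and len(times) == 1:
            gap = allowed_test_gap(v, tolerance_months) + rng.uniform(1.0, 3.0)
        t += gap
    return times, values


def generate_trajectory(
    segment: str,
    params: TrajectoryParams,
    window_months: float,
    rng: np.random.Generator,
    *,
    fixed_gap_months: float | None = None,
    factor_range: tuple[float, float] = (0.7, 0.95),
) -> list[tuple[float, float]]:
    """Simulate one HbA1c series over ``window_months`` for a segment.

    Test times follow the band-driven protocol schedule (or a fixed gap);
    with ``noise_sd == 0`` the series classifies into the requested
    segment under the default per-segment parameters.
    """
    if segment not in seg.SEGMENTS:
        raise ConfigurationError(f"unknown segment label {segment!r}")
    if window_months < 10:
        raise ConfigurationError("window_months must be at least 10")
    times, values = _measurement_times(
        params,
        window_months,
        rng,
        fixed_gap_months=fixed_gap_months,
        factor_range=factor_range,
        violator=False,
        tolerance_months=0.0,
    )
    return list(zip(times, values))


def _discipline_sequence(
    pattern: str,
    n_visits: int,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[str, ...]:
    templates = (config.sequence_templates or {}).get(pattern)
    if templates:
        idx = 0 if len(templates) == 1 else int(rng.integers(len(templates)))
        base = templates[idx]
        reps = -(-n_visits // len(base))
        return tuple((base * reps)[:n_visits])
    model = config.transition_matrices[pattern]
    init = np.asarray(model.initial)
    matrix = np.asarray(model.matrix)
    states = [int(rng.choice(3, p=init))]
    for _ in range(n_visits - 1):
        states.append(int(rng.choice(3, p=matrix[states[-1]])))
    return tuple(DISCIPLINES[s] for s in states)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    pattern_labels = list(config.pattern_mix)
    pattern_probs = np.asarray(list(config.pattern_mix.values()))
    segment_labels = list(config.segment_mix)
    segment_probs = np.asarray(list(config.segment_mix.values()))

    encounters: list[EncounterRecord] = []
    measurements: list[Hba1cMeasurement] = []
    patients: list[PatientRecord] = []
    truth: dict[str, PlantedTruth] = {}

    width = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        pattern = pattern_labels[int(rng.choice(len(pattern_labels), p=pattern_probs))]
        segment = segment_labels[int(rng.choice(len(segment_labels), p=segment_probs))]
        violator = bool(rng.random() < config.adherence_violation_rate)
        comorbid = bool(rng.random() < config.comorbidity_rate)

        age = float(np.clip(rng.normal(59.7, 12.6), 20, 89))
        sex = "M" if rng.random() < 0.576 else "F"
        years = float(max(rng.normal(4.6, 3.8), 0.0))
        dcsi = cic = 0
        if comorbid:
            if rng.random() < 0.5:
                dcsi = int(rng.integers(1, 4))
            else:
                cic = int(rng.integers(1, 4))
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=round(age, 1),
                sex=sex,
                years_with_t2dm=round(years, 1),
                dcsi_count=dcsi,
                cic_count=cic,
            )
        )

        start = config.start_date
        if config.start_jitter_days:
            start = start + timedelta(days=int(rng.integers(config.start_jitter_days + 1)))

        # CVPA visits at a jittered cadence from the first test date
        t_d = 0.0
        visit_days: list[int] = []
        horizon_days = config.horizon_months * MONTH_DAYS
        while t_d <= horizon_days:
            visit_days.append(int(round(t_d)))
            if config.visit_jitter_days > 0:
                step = rng.uniform(
                    config.visit_interval_days - config.visit_jitter_days,
                    config.visit_interval_days + config.visit_jitter_days,
                )
            else:
                step = config.visit_interval_days
            t_d += max(step, 1.0)
        disciplines = _discipline_sequence(pattern, len(visit_days), rng, config)
        for k, (day, disc) in enumerate(zip(visit_days, disciplines)):
            nxt_disc = disciplines[k + 1] if k + 1 < len(visit_days) else None
            nxt_date = (
                start + timedelta(days=visit_days[k + 1])
                if k + 1 < len(visit_days)
                else None
            )
            encounters.append(
                EncounterRecord(
                    patient_id=pid,
                    date=start + timedelta(days=day),
                    discipline=disc,
                    next_discipline=nxt_disc,
                    next_date=nxt_date,
                )
            )

        times, values = _measurement_times(
            config.trajectory_params[segment],
            config.horizon_months,
            rng,
            fixed_gap_months=config.fixed_test_gap_months,
            factor_range=config.test_gap_factor_range,
            violator=violator,
            tolerance_months=config.adherence_tolerance_months,
        )
        for t, v in zip(times, values):
            measurements.append(
                Hba1cMeasurement(
                    patient_id=pid,
                    date=start + timedelta(days=int(round(t * MONTH_DAYS))),
                    value=round(v, 2),
                )
            )
        truth[pid] = PlantedTruth(pattern, segment, violator)

    return SyntheticCohort(encounters, measurements, patients, truth)
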