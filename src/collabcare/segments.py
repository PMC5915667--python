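"""HbA1c evolution segments.

Each eligible patient's in-window HbA1c series is classified into exactly
one of four segments, evaluated in order:

1. **compensated** — every value below 7%, or a single excursion into the
   [7, 9]% band (inclusive) with the series mean still below 7%;
2. **improved** — strictly negative OLS slope and a final value below 7%,
   regardless of the starting level;
3. **highly decompensated** — some value reaching 9% or more, and not
   improved;
4. **moderately decompensated** — everything else.

The order makes the textual exclusions ("who do not belong to ...")
operational and the four predicates exhaustive. A value of exactly 9.0 is
treated as high (the band wording is contradictory at that point; treating
9.0 as high keeps the partition exhaustive and is applied consistently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import HBA1C_GOAL, HBA1C_HIGH, Hba1cMeasurement, StudyWindow, months_between

COMPENSATED = "compensated"
IMPROVED = "improved"
MODERATE = "moderately decompensated"
HIGH = "highly decompensated"

SEGMENTS = (COMPENSATED, IMPROVED, MODERATE, HIGH)


@dataclass(frozen=True)
class OutcomeSegment:
    label: str
    slope: float
    mean: float
    max_value: float
    final: float
    band_count: int  # measurements in [7, 9] inclusive


def series_slope(series: list[tuple[float, float]]) -> float:
    """Ordinary-least-squares slope of HbA1c (%) versus time (months)."""
    if len(series) < 2:
        raise ValueError("slope requires at least two points")
    t = np.asarray([p[0] for p in series], dtype=float)
    v = np.asarray([p[1] for p in series], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("slope undefined: all time points are equal")
    t = t - t.mean()
    return float(t @ (v - v.mean()) / (t @ t))


def classify_segment(series: list[tuple[float, float]]) -> OutcomeSegment:
    """Classify one (time-in-months, HbA1c%) series; see the module rules."""
    if len(series) < 2:
        raise ValueError("segment classification requires at least two measurements")
    series = sorted(series)
    values = [v for _, v in series]
    mean = float(np.mean(values))
    final = values[-1]
    band_count = sum(1 for v in values if HBA1C_GOAL <= v <= HBA1C_HIGH)
    above_high = any(v > HBA1C_HIGH for v in values)
    slope = series_slope(series)

    if not above_high and (
        all(v < HBA1C_GOAL for v in values) or (band_count == 1 and mean < HBA1C_GOAL)
    ):
        label = COMPENSATED
    elif slope < 0 and final < HBA1C_GOAL:
        label = IMPROVED
    elif any(v >= HBA1C_HIGH for v in values):
        label = HIGH
    else:
        label = MODERATE
    return OutcomeSegment(
        label=label,
        slope=slope,
        mean=mean,
        max_value=max(values),
        final=final,
        band_count=band_count,
    )


def classify_patient(
    measurements: list[Hba1cMeasurement], window: StudyWindow
) -> OutcomeSegment:
    """Classify a patient from dated measurements inside the study window."""
    series = [
        (months_between(window.t0, m.date), m.value)
        for m in measurements
        if window.t0 <= m.date <= window.t_end
    ]
    return classify_segment(series)


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0**decimals
    return np.floor(x * f + 0.5) / f


def segment_counts(labels) -> dict[str, dict[str, float]]:
    """Counts and percentages (one decimal) per segment label."""
    labels = list(labels)
    total = len(labels)
    out: dict[str, dict[str, float]] = {}
    for seg in SEGMENTS:
        n = sum(1 for l in labels if l == seg)
        pct = _round_half_up(100.0 * n / total, 1) if total else 0.0
        out[seg] = {"count": n, "percent": pct}
    return out
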