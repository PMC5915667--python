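from __future__ import annotations

from collections import Counter
from datetime import date, timedelta

import pytest

from collabcare.network import CollaborativeNetwork, DisciplineLog, network_metrics
from collabcare.records import Hba1cMeasurement


def make_measurements(pid: str, month_values: list[tuple[float, float]],
                      t0: date = date(2015, 1, 1)) -> list[Hba1cMeasurement]:
    """Measurements at month offsets (days = months * 30.44, rounded)."""
    return [
        Hba1cMeasurement(pid, t0 + timedelta(days=round(m * 30.44)), v)
        for m, v in month_values
    ]


def metrics_from_sequences(sequences: dict[str, str]):
    """NetworkMetrics straight from raw discipline strings."""
    from collabcare.network import build_network

    log = DisciplineLog({p: tuple(s) for p, s in sequences.items()})
    return network_metrics(build_network(log))


def network_from_counts(arcs: dict[tuple[str, str], int],
                        nodes: dict[str, int], n_patients: int = 1) -> CollaborativeNetwork:
    return CollaborativeNetwork(
        arc_counts=Counter(arcs), node_cvpa_counts=Counter(nodes), n_patients=n_patients
    )


@pytest.fixture
def reference_table():
    """Pattern × segment counts of the reference 231-patient cohort."""
    from collabcare import segments as sg
    from collabcare.stats import build_contingency

    counts = {
        "self-contained": (30, 3, 4, 4),
        "tacit leader": (23, 12, 15, 11),
        "shared": (14, 2, 4, 4),
        "participatory": (17, 10, 7, 1),
        "equitably centered": (7, 3, 5, 6),
        "hierarchically centered": (5, 1, 3, 5),
        "self-referred leader": (5, 2, 4, 6),
        "outlier": (13, 4, 1, 0),
    }
    pat_map: dict[str, str] = {}
    seg_map: dict[str, str] = {}
    i = 0
    for pattern, row in counts.items():
        for segment, k in zip(sg.SEGMENTS, row):
            for _ in range(k):
                pid = f"h{i:04d}"
                i += 1
                pat_map[pid] = pattern
                seg_map[pid] = segment
    return build_contingency(pat_map, seg_map)
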