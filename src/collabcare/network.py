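"""Discipline logs, collaborative networks and collaboration indices.

A *discipline log* maps each patient to the time-ordered sequence of
disciplines that attended their CVPAs. A *collaborative network* is the
directed graph over the triad {P, N, D} whose arcs count, over all
patients, every consecutive pair of attended visits — including self-loops
when the same discipline attends twice in a row. Three indices summarize
the network:

* participation index of d — share of all CVPAs attended by d;
* self-referral index of d — share of d's outgoing referrals going to d;
* referral index d→e (d≠e) — share of d's outgoing referrals going to e.

Referral arcs derive from observed consecutive attendances, not from the
recorded next-appointment field (which may go unfulfilled); a patient's
final CVPA emits no arc, so ``sum(arcs) == total CVPAs - n_patients``.
A discipline with no outgoing arc has *undefined* self-referral/referral
indices, reported as ``None`` rather than 0.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .records import DISCIPLINES, EncounterRecord, StudyWindow

logger = logging.getLogger(__name__)

#: Same-day tie-break rank (documented, configurable via build_discipline_log).
_DEFAULT_TIE_ORDER = {d: i for i, d in enumerate(DISCIPLINES)}


@dataclass
class DisciplineLog:
    """Per-patient ordered discipline sequences over the alphabet {P, N, D}."""

    sequences: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"patient {pid}: empty discipline sequence")

    @property
    def patients(self) -> list[str]:
        return sorted(self.sequences)

    def total_cvpas(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def subset(self, patient_ids) -> "DisciplineLog":
        return DisciplineLog({p: self.sequences[p] for p in patient_ids})


def build_discipline_log(
    encounters: list[EncounterRecord],
    windows: dict[str, StudyWindow],
    tie_order: tuple[str, ...] = DISCIPLINES,
) -> DisciplineLog:
    """Build the discipline log restricted to each patient's study window.

    Events are ordered by timestamp; same-day events are ordered by the
    fixed discipline rank (default P < N < D) and duplicate
    (date, discipline) pairs are collapsed. Eligible patients with no
    in-window CVPA are dropped with a warning.
    """
    rank = {d: i for i, d in enumerate(tie_order)}
    per_patient: dict[str, set[tuple]] = {pid: set() for pid in windows}
    for e in encounters:
        w = windows.get(e.patient_id)
        if w is not None and w.t0 <= e.date <= w.t_end:
            per_patient[e.patient_id].add((e.date, e.discipline))
    sequences: dict[str, tuple[str, ...]] = {}
    for pid in sorted(windows):
        events = sorted(per_patient[pid], key=lambda t: (t[0], rank[t[1]]))
        if not events:
            logger.warning("patient %s: no CVPA inside study window, excluded from log", pid)
            continue
        sequences[pid] = tuple(d for _, d in events)
    return DisciplineLog(sequences)


@dataclass
class CollaborativeNetwork:
    """Directed multiset of referral arcs plus per-discipline CVPA counts."""

    arc_counts: Counter = field(default_factory=Counter)
    node_cvpa_counts: Counter = field(default_factory=Counter)
    n_patients: int = 0

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(d for d in DISCIPLINES if self.node_cvpa_counts.get(d, 0) > 0)

    def total_cvpas(self) -> int:
        return sum(self.node_cvpa_counts.values())

    def outdegree(self, discipline: str) -> int:
        return sum(c for (a, _), c in self.arc_counts.items() if a == discipline)


def build_network(log: DisciplineLog) -> CollaborativeNetwork:
    """Aggregate a discipline log into a collaborative network."""
    net = CollaborativeNetwork(n_patients=len(log.sequences))
    for seq in log.sequences.values():
        net.node_cvpa_counts.update(seq)
        net.arc_counts.update(zip(seq, seq[1:]))
    return net


def participation_index(network: CollaborativeNetwork, discipline: str) -> float:
    """Percent of all CVPAs attended by ``discipline``."""
    total = network.total_cvpas()
    if total == 0:
        raise ValueError("participation index undefined on an empty network")
    return 100.0 * network.node_cvpa_counts.get(discipline, 0) / total

def self_referral_index(network: CollaborativeNetwork, discipline: str) -> float | None:
    """Percent of ``discipline``'s outgoing referrals that are self-loops.

    ``None`` when the discipline emits no referral at all (undefined,
    deliberately distinct from 0).
    """
    out = network.outdegree(discipline)
    if out == 0:
        return None
    return 100.0 * network.arc_counts.get((discipline, discipline), 0) / out

def referral_index(
    network: CollaborativeNetwork, from_discipline: str, to_discipline: str
) -> float | None:
    """Percent of ``from_discipline``'s outgoing referrals sent to ``to_discipline``."""
    if from_discipline == to_discipline:
        raise ValueError("referral index is defined for distinct disciplines; "
                         "use self_referral_index for self-loops")
    out = network.outdegree(from_discipline)
    if out == 0:
        return None
    return 100.0 * network.arc_counts.get((from_discipline, to_discipline), 0) / out


@dataclass
class NetworkMetrics:
    """The three index families plus the outgoing-arc weights.

    ``participation`` covers all three disciplines (0 for absent ones);
    ``self_referral``/``referral`` are ``None`` where the source
    discipline has no outgoing arc. ``outgoing_counts`` carries the raw
    denominators so weighted combinations (e.g. the nurse–dietitian
    interaction share) can be formed without the network.
    """

    participation: dict[str, float]
    self_referral: dict[str, float | None]
    referral: dict[tuple[str, str], float | None]
    outgoing_counts: dict[str, int]
    arc_counts: dict[tuple[str, str], int]
    total_cvpas: int = 0
    n_patients: int = 0

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(d for d in DISCIPLINES if self.participation.get(d, 0.0) > 0.0)


def network_metrics(network: CollaborativeNetwork) -> NetworkMetrics:
    """Compute all indices of a network at full precision."""
    participation = {d: participation_index(network, d) for d in DISCIPLINES}
    self_ref = {d: self_referral_index(network, d) for d in DISCIPLINES}
    referral = {
        (a, b): referral_index(network, a, b)
        for a in DISCIPLINES
        for b in DISCIPLINES
        if a != b
    }
    return NetworkMetrics(
        participation=participation,
        self_referral=self_ref,
        referral=referral,
        outgoing_counts={d: network.outdegree(d) for d in DISCIPLINES},
        arc_counts=dict(network.arc_counts),
        total_cvpas=network.total_cvpas(),
        n_patients=network.n_patients,
    )


def to_graph(network: CollaborativeNetwork, metrics: NetworkMetrics | None = None) -> nx.DiGraph:
    """networkx view with arc-count weights and optional index annotations."""
    g = nx.DiGraph()
    for d in network.present:
        attrs = {"cvpas": int(network.node_cvpa_counts[d])}
        if metrics is not None:
            attrs["participation"] = round(metrics.participation[d], 6)
            if metrics.self_referral[d] is not None:
                attrs["self_referral"] = round(metrics.self_referral[d], 6)
        g.add_node(d, **attrs)
    for (a, b), c in sorted(network.arc_counts.items()):
        g.add_edge(a, b, weight=int(c))
    return g


def write_graphml(network: CollaborativeNetwork, path, metrics: NetworkMetrics | None = None) -> None:
    nx.write_graphml(to_graph(network, metrics), path)


def to_dot(network: CollaborativeNetwork) -> str:
    """Minimal DOT export with arc counts as edge labels."""
    lines = ["digraph collaborative_network {"]
    for d in network.present:
        lines.append(f'  {d} [label="{d} ({network.node_cvpa_counts[d]})"];')
    for (a, b), c in sorted(network.arc_counts.items()):
        lines.append(f'  {a} -> {b} [label="{c}", weight={c}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
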