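"""Rule-based classification of cluster networks into collaboration patterns.

Seven team configurations are distinguished, split by how many disciplines
take part in the treatment:

* one discipline — **self-contained**;
* two disciplines — **tacit leader** (one discipline dominates and the
  other refers mostly to it) or **shared** (balanced participation,
  cross-referrals prevail);
* three disciplines — **self-referred leader** (physician keeps near-total
  control, one discipline nearly absent), **participatory** (no discipline
  dominates), **equitably centered** / **hierarchically centered**
  (physician-led; distinguished by whether nurse and dietitian interact
  with each other at all).

Every numeric decision flows through :class:`PatternThresholds`; the
classifier body contains no literal cut-offs. ``unclassified`` is a valid
outcome for metrics that fit no rule, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import TraceCluster
from .network import NetworkMetrics

SELF_CONTAINED = "self-contained"
TACIT_LEADER = "tacit leader"
SHARED = "shared"
PARTICIPATORY = "participatory"
EQUITABLY_CENTERED = "equitably centered"
HIERARCHICALLY_CENTERED = "hierarchically centered"
SELF_REFERRED_LEADER = "self-referred leader"
UNCLASSIFIED = "unclassified"
OUTLIER_LABEL = "outlier"

PATTERNS = (
    SELF_CONTAINED,
    TACIT_LEADER,
    SHARED,
    PARTICIPATORY,
    EQUITABLY_CENTERED,
    HIERARCHICALLY_CENTERED,
    SELF_REFERRED_LEADER,
)

_LEADER_BEARING = {
    TACIT_LEADER,
    EQUITABLY_CENTERED,
    HIERARCHICALLY_CENTERED,
    SELF_REFERRED_LEADER,
}


@dataclass(frozen=True)
class PatternLabel:
    label: str
    leader: str | None = None

    def __post_init__(self) -> None:
        if (self.leader is not None) != (self.label in _LEADER_BEARING):
            raise ValueError(
                f"label {self.label!r} and leader {self.leader!r} inconsistent: "
                "a leader is present iff the pattern is leader-bearing"
            )


@dataclass(frozen=True)
class PatternThresholds:
    """Percent cut-offs of the decision rules (defaults from the observed
    cluster index profiles: leaders above 65% participation, balanced
    two-discipline teams inside 50±10%, a participatory ceiling of 45%,
    near-total control above 70% participation with 65% self-referral and
    a discipline below 5%, supporting referrals above 70%, cross-referral
    majorities above 60%, and a 10% nurse–dietitian interaction floor)."""

    leader_participation_min: float = 65.0
    shared_band: tuple[float, float] = (40.0, 60.0)
    participatory_max_participation: float = 45.0
    dominant_participation_min: float = 70.0
    dominant_self_referral_min: float = 65.0
    minor_participation_max: float = 5.0
    cross_referral_majority: float = 60.0
    support_referral_min: float = 70.0
    nd_interaction_min: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.shared_band
        if not lo < hi:
            raise ValueError("shared_band lower bound must be below its upper bound")


DEFAULT_THRESHOLDS = PatternThresholds()


def nd_interaction_share(metrics: NetworkMetrics) -> float:
    """Percent of nurse+dietitian outgoing referrals exchanged between them."""
    out_n = metrics.outgoing_counts.get("N", 0)
    out_d = metrics.outgoing_counts.get("D", 0)
    if out_n + out_d == 0:
        return 0.0
    nd = metrics.arc_counts.get(("N", "D"), 0) + metrics.arc_counts.get(("D", "N"), 0)
    return 100.0 * nd / (out_n + out_d)


def classify_pattern(
    metrics: NetworkMetrics, thresholds: PatternThresholds = DEFAULT_THRESHOLDS
) -> PatternLabel:
    """Classify one cluster's indices into a collaboration pattern.

    Decision order (most specific first within each node count):
    one present discipline → self-contained; two → tacit leader, then
    shared; three → self-referred leader, then participatory, then the
    physician-centered split by nurse–dietitian interaction.
    """
    if metrics.total_cvpas == 0:
        raise ValueError("cannot classify metrics with zero CVPAs")
    t = thresholds
    present = metrics.present

    if len(present) == 1:
        return PatternLabel(SELF_CONTAINED)

    if len(present) == 2:
        leader = max(present, key=lambda d: metrics.participation[d])
        other = next(d for d in present if d != leader)
        support = metrics.referral.get((other, leader))
        if (
            metrics.participation[leader] >= t.leader_participation_min
            and support is not None
            and support >= t.support_referral_min
        ):
            return PatternLabel(TACIT_LEADER, leader=leader)
        lo, hi = t.shared_band
        cross_a = metrics.referral.get((leader, other))
        cross_b = metrics.referral.get((other, leader))
        if (
            all(lo <= metrics.participation[d] <= hi for d in present)
            and cross_a is not None
            and cross_b is not None
            and cross_a >= t.cross_referral_majority
            and cross_b >= t.cross_referral_majority
        ):
            return PatternLabel(SHARED)
        return PatternLabel(UNCLASSIFIED)

    # three disciplines present
    p_part = metrics.participation["P"]
    p_self = metrics.self_referral.get("P")
    min_part = min(metrics.participation[d] for d in present)
    max_part = max(metrics.participation[d] for d in present)
    if (
        p_part >= t.dominant_participation_min
        and p_self is not None
        and p_self >= t.dominant_self_referral_min
        and min_part <= t.minor_participation_max
    ):
        return PatternLabel(SELF_REFERRED_LEADER, leader="P")
    if max_part <= t.participatory_max_participation:
        return PatternLabel(PARTICIPATORY)
    if p_part == max_part:
        if nd_interaction_share(metrics) >= t.nd_interaction_min:
            return PatternLabel(EQUITABLY_CENTERED, leader="P")
        return PatternLabel(HIERARCHICALLY_CENTERED, leader="P")
    return PatternLabel(UNCLASSIFIED)


def assign_patient_patterns(
    clusters: list[TraceCluster], cluster_labels: dict[str, PatternLabel]
) -> dict[str, str]:
    """Propagate cluster labels to members; outlier-group members get
    the ``outlier`` label. Total over all patients in the clusters."""
    out: dict[str, str] = {}
    for cluster in clusters:
        if cluster.is_outlier_group:
            for pid in cluster.member_ids:
                out[pid] = OUTLIER_LABEL
        else:
            label = cluster_labels[cluster.cluster_id]
            for pid in cluster.member_ids:
                out[pid] = label.label
    return out
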