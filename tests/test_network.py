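"""Discipline logs, networks and the three collaboration indices."""

from __future__ import annotations

import random
from datetime import date, timedelta

import pytest

from collabcare.network import (
    DisciplineLog,
    build_discipline_log,
    build_network,
    network_metrics,
    participation_index,
    referral_index,
    self_referral_index,
    to_dot,
)
from collabcare.records import EncounterRecord, StudyWindow
from tests.oracles import indices_by_enumeration


def _window(pid, days=600):
    t0 = date(2015, 1, 1)
    return StudyWindow(pid, t0, t0 + timedelta(days=days), days / 30.44)


def _enc(pid, day, disc):
    return EncounterRecord(pid, date(2015, 1, 1) + timedelta(days=day), disc)


class TestDisciplineLog:
    def test_time_ordering(self):
        enc = [_enc("h1", 10, "P"), _enc("h1", 40, "N"), _enc("h1", 70, "P")]
        log = build_discipline_log(enc, {"h1": _window("h1")})
        assert log.sequences["h1"] == ("P", "N", "P")

    def test_row_order_irrelevant(self):
        enc = [_enc("h1", d, x) for d, x in [(10, "P"), (40, "N"), (70, "P")]]
        shuffled = enc[::-1]
        w = {"h1": _window("h1")}
        assert build_discipline_log(enc, w).sequences == build_discipline_log(shuffled, w).sequences

    def test_same_day_tie_break(self):
        enc = [_enc("h1", 10, "N"), _enc("h1", 10, "P")]
        log = build_discipline_log(enc, {"h1": _window("h1")})
        assert log.sequences["h1"] == ("P", "N")

    def test_window_restriction_and_exclusion(self):
        enc = [_enc("h1", 700, "P"), _enc("h2", 10, "D")]
        w = {"h1": _window("h1"), "h2": _window("h2")}
        log = build_discipline_log(enc, w)
        assert "h1" not in log.sequences and log.sequences["h2"] == ("D",)


class TestNetworkCounts:
    def test_pair_enumeration(self):
        net = build_network(DisciplineLog({"h1": ("P", "P", "N")}))
        assert dict(net.arc_counts) == {("P", "P"): 1, ("P", "N"): 1}
        assert dict(net.node_cvpa_counts) == {"P": 2, "N": 1}

    def test_single_event_no_arcs(self):
        net = build_network(DisciplineLog({"h1": ("D",)}))
        assert not net.arc_counts and dict(net.node_cvpa_counts) == {"D": 1}

    def test_two_patients(self):
        net = build_network(DisciplineLog({"h1": ("P", "N"), "h2": ("N", "P")}))
        assert dict(net.arc_counts) == {("P", "N"): 1, ("N", "P"): 1}
        assert dict(net.node_cvpa_counts) == {"P": 2, "N": 2}


class TestIndices:
    def test_participation_single_discipline(self):
        net = build_network(DisciplineLog({"h1": ("P", "P")}))
        assert participation_index(net, "P") == 100.0
        assert participation_index(net, "N") == 0.0

    @pytest.mark.parametrize(
        "sequences,expected",
        [({"h1": "PP", "h2": "NN"}, {"P": 50, "N": 50, "D": 0}),
         ({"h1": "PPN", "h2": "D"}, {"P": 50, "N": 25, "D": 25})],
    )
    def test_participation_ratio(self, sequences, expected):
        net = build_network(DisciplineLog({k: tuple(v) for k, v in sequences.items()}))
        for d, pct in expected.items():
            assert participation_index(net, d) == pct

    def test_self_referral(self):
        net = build_network(DisciplineLog({"h1": ("P", "P", "N")}))
        assert self_referral_index(net, "P") == 50.0

    def test_no_outgoing_is_none_not_zero(self):
        net = build_network(DisciplineLog({"h1": ("P",)}))
        assert self_referral_index(net, "P") is None
        assert referral_index(net, "P", "N") is None

    def test_referral_split(self):
        net = build_network(DisciplineLog({"h1": ("N", "P"), "h2": ("N", "P"), "h3": ("N", "P", "N", "D")}))
        assert referral_index(net, "N", "P") == 75.0
        assert referral_index(net, "N", "D") == 25.0

    def test_empty_network_error(self):
        net = build_network(DisciplineLog({}))
        with pytest.raises(ValueError):
            participation_index(net, "P")


def random_log(rng: random.Random, max_patients=6, max_len=8) -> dict[str, str]:
    n = rng.randint(1, max_patients)
    return {
        f"h{i}": "".join(rng.choice("PND") for _ in range(rng.randint(1, max_len)))
        for i in range(n)
    }


class TestOracleEquivalence:
    def test_random_logs_match_brute_force(self):
        rng = random.Random(20240915)
        for _ in range(300):
            sequences = random_log(rng)
            net = build_network(DisciplineLog({k: tuple(v) for k, v in sequences.items()}))
            m = network_metrics(net)
            oracle = indices_by_enumeration(sequences)
            assert m.participation == oracle["participation"]
            assert m.self_referral == oracle["self_referral"]
            assert m.referral == oracle["referral"]

    def test_conservation_and_normalization(self):
        rng = random.Random(7)
        for _ in range(200):
            sequences = random_log(rng)
            net = build_network(DisciplineLog({k: tuple(v) for k, v in sequences.items()}))
            assert sum(net.arc_counts.values()) == net.total_cvpas() - net.n_patients
            m = network_metrics(net)
            assert abs(sum(m.participation.values()) - 100.0) < 1e-9
            for d in "PND":
                if m.self_referral[d] is not None:
                    out_sum = m.self_referral[d] + sum(
                        m.referral[(d, e)] for e in "PND" if e != d
                    )
                    assert abs(out_sum - 100.0) < 1e-9

    def test_concatenation_property(self):
        rng = random.Random(99)
        for _ in range(50):
            log_a = {f"a{i}": s for i, s in enumerate(random_log(rng).values())}
            log_b = {f"b{i}": s for i, s in enumerate(random_log(rng).values())}
            na = build_network(DisciplineLog({k: tuple(v) for k, v in log_a.items()}))
            nb = build_network(DisciplineLog({k: tuple(v) for k, v in log_b.items()}))
            nu = build_network(DisciplineLog({k: tuple(v) for k, v in (log_a | log_b).items()}))
            assert nu.arc_counts == na.arc_counts + nb.arc_counts
            assert nu.node_cvpa_counts == na.node_cvpa_counts + nb.node_cvpa_counts


def test_dot_export_mentions_every_arc():
    net = build_network(DisciplineLog({"h1": ("P", "N", "P")}))
    dot = to_dot(net)
    assert "P -> N" in dot and "N -> P" in dot
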