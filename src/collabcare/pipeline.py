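"""End-to-end orchestration and reporting.

Stage order: selection funnel → discipline log → trace clustering →
per-cluster networks and indices → pattern classification → outcome
segmentation → contingency table → subgroup-vs-population comparisons.
All artifacts are written under the configured output directory and the
whole report is reproducible bit-for-bit for fixed inputs (the analysis
itself is deterministic; the seed only matters for simulation).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __about__
from .clustering import ClusteringConfig, TraceCluster, cluster_networks, cluster_traces
from .network import build_discipline_log, to_dot, write_graphml
from .patterns import DEFAULT_THRESHOLDS, PatternLabel, PatternThresholds, assign_patient_patterns, classify_pattern
from .records import EncounterRecord, Hba1cMeasurement, PatientRecord
from .segments import classify_patient
from .selection import group_measurements, run_funnel
from .stats import ContingencyTable, StatsOptions, build_contingency, run_all_comparisons

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Every knob of one pipeline run (paths, funnel, clustering, stats)."""

    model_config = ConfigDict(frozen=True)

    encounters_path: Path
    measurements_path: Path
    patients_path: Path
    output_dir: Optional[Path] = None
    min_tests: int = Field(default=2, ge=1)
    tolerance_months: float = Field(default=4.0, ge=0)
    window_target_months: float = Field(default=18.0, gt=0)
    window_halfwidth_months: float = Field(default=8.0, ge=0)
    similarity_threshold: float = 0.15
    outlier_fraction: float = 0.03
    linkage: str = "complete"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    alternative: str = "two-sided"
    continuity: bool = True
    fisher_fallback: bool = True
    reference: str = "total"
    holm: bool = False
    seed: int = 0

    def clustering(self) -> ClusteringConfig:
        return ClusteringConfig(
            similarity_threshold=self.similarity_threshold,
            outlier_fraction=self.outlier_fraction,
            linkage=self.linkage,
        )

    def stats_options(self) -> StatsOptions:
        return StatsOptions(
            alpha=self.alpha,
            alternative=self.alternative,
            continuity=self.continuity,
            fisher_fallback=self.fisher_fallback,
            reference=self.reference,
            holm=self.holm,
        )


@dataclass
class RunReport:
    funnel: dict
    cluster_sizes: dict[str, int]
    cluster_metrics: dict[str, dict]
    cluster_labels: dict[str, dict]
    patient_patterns: dict[str, str]
    patient_segments: dict[str, str]
    segment_summary: dict[str, dict]
    contingency_counts: dict
    comparisons: list[dict]
    config: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "funnel": self.funnel,
            "cluster_sizes": self.cluster_sizes,
            "cluster_metrics": self.cluster_metrics,
            "cluster_labels": self.cluster_labels,
            "patient_patterns": self.patient_patterns,
            "patient_segments": self.patient_segments,
            "segment_summary": self.segment_summary,
            "contingency_counts": self.contingency_counts,
            "comparisons": self.comparisons,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _metrics_dict(metrics) -> dict:
    return {
        "participation": {d: round(v, 6) for d, v in metrics.participation.items()},
        "self_referral": {
            d: (round(v, 6) if v is not None else None)
            for d, v in metrics.self_referral.items()
        },
        "referral": {
            f"{a}->{b}": (round(v, 6) if v is not None else None)
            for (a, b), v in metrics.referral.items()
        },
        "total_cvpas": metrics.total_cvpas,
        "n_patients": metrics.n_patients,
    }


def analyze(
    patients: list[PatientRecord],
    measurements: list[Hba1cMeasurement],
    encounters: list[EncounterRecord],
    config: RunConfig,
    thresholds: PatternThresholds = DEFAULT_THRESHOLDS,
) -> tuple[RunReport, dict[str, TraceCluster], dict]:
    """Run the analysis on in-memory records; returns the report plus the
    clusters and per-cluster networks for export."""
    windows, funnel = run_funnel(
        patients,
        measurements,
        min_count=config.min_tests,
        tolerance_months=config.tolerance_months,
        target_months=config.window_target_months,
        halfwidth_months=config.window_halfwidth_months,
    )

    if not encounters:
        raise PipelineError("discipline-log", "no encounter records")
    log = build_discipline_log(encounters, windows)
    if not log.sequences:
        raise PipelineError("discipline-log", "no in-window CVPAs for any eligible patient")

    clusters = cluster_traces(log, config.clustering())
    networks = cluster_networks(clusters, log)

    labels: dict[str, PatternLabel] = {}
    for cluster in clusters:
        if not cluster.is_outlier_group and cluster.member_ids:
            labels[cluster.cluster_id] = classify_pattern(
                networks[cluster.cluster_id][1], thresholds
            )
    patient_patterns = assign_patient_patterns(clusters, labels)

    grouped = group_measurements([m for m in measurements if m.patient_id in log.sequences])
    patient_segments = {
        pid: classify_patient(grouped[pid], windows[pid]).label for pid in log.sequences
    }

    from .segments import segment_counts

    table = build_contingency(patient_patterns, patient_segments)
    comparisons = run_all_comparisons(table, config.stats_options())

    report = RunReport(
        funnel=funnel.to_dict(),
        cluster_sizes={c.cluster_id: len(c.member_ids) for c in clusters},
        cluster_metrics={cid: _metrics_dict(m) for cid, (_, m) in networks.items()},
        cluster_labels={
            cid: {"label": lab.label, "leader": lab.leader} for cid, lab in labels.items()
        },
        patient_patterns=patient_patterns,
        patient_segments=patient_segments,
        segment_summary=segment_counts(patient_segments.values()),
        contingency_counts={
            row: {col: int(table.counts.loc[row, col]) for col in table.counts.columns}
            for row in table.counts.index
        },
        comparisons=[
            {
                "pattern": c.pattern,
                "segment": c.segment,
                "sub_count": c.result.sub_count,
                "sub_n": c.result.sub_n,
                "pop_count": c.result.pop_count,
                "pop_n": c.result.pop_n,
                "sub_percent": round(100 * c.result.sub_proportion, 1),
                "pop_percent": round(100 * c.result.reference_proportion, 1),
                "method": c.result.method,
                "statistic": round(c.result.statistic, 6),
                "p_value": round(c.result.p_value, 6),
                "significant": c.significant,
            }
            for c in comparisons
        ],
        config=json.loads(config.model_dump_json()),
        version=__about__.__version__,
    )
    return report, {c.cluster_id: c for c in clusters}, networks


def run_pipeline(config: RunConfig) -> RunReport:
    """Read inputs, run the analysis and write all artifacts."""
    from .io import read_encounters, read_measurements, read_patients

    for stage, path in (
        ("read-encounters", config.encounters_path),
        ("read-measurements", config.measurements_path),
        ("read-patients", config.patients_path),
    ):
        if not Path(path).exists():
            raise PipelineError(stage, f"input file {path} does not exist")
    encounters = read_encounters(config.encounters_path)
    measurements = read_measurements(config.measurements_path)
    patients = read_patients(config.patients_path)

    report, clusters, networks = analyze(patients, measurements, encounters, config)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "funnel.json").write_text(json.dumps(report.funnel, indent=2) + "\n")
        pd.DataFrame(
            [
                {
                    "patient_id": pid,
                    "cluster_id": next(
                        cid for cid, c in clusters.items() if pid in c.member_ids
                    ),
                    "pattern": report.patient_patterns[pid],
                    "segment": report.patient_segments[pid],
                }
                for pid in sorted(report.patient_patterns)
            ]
        ).to_csv(out / "assignments.csv", index=False)
        pd.DataFrame(
            [
                {"cluster_id": cid, **lab}
                for cid, lab in sorted(report.cluster_labels.items())
            ]
        ).to_csv(out / "cluster_labels.csv", index=False)
        pd.DataFrame(report.contingency_counts).T.to_csv(
            out / "contingency_counts.csv", index_label="pattern"
        )
        pd.DataFrame(report.comparisons).to_csv(out / "comparisons.csv", index=False)
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for cid, (net, metrics) in networks.items():
            write_graphml(net, net_dir / f"{cid}.graphml", metrics)
            (net_dir / f"{cid}.dot").write_text(to_dot(net))
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: RunReport) -> str:
    lines = ["# Collaboration-pattern analysis", ""]
    lines.append("## Selection funnel")
    for stage, n in report.funnel.items():
        lines.append(f"- {stage}: {n}")
    lines.append("")
    lines.append("## Clusters")
    for cid, size in sorted(report.cluster_sizes.items()):
        lab = report.cluster_labels.get(cid, {}).get("label", "outlier group")
        lines.append(f"- {cid}: {size} patients — {lab}")
    lines.append("")
    lines.append("## Outcome segments")
    for segment, info in report.segment_summary.items():
        lines.append(f"- {segment}: {info['count']} ({info['percent']}%)")
    lines.append("")
    lines.append("## Significant comparisons (subgroup vs population)")
    for c in report.comparisons:
        if c["significant"]:
            lines.append(
                f"- {c['pattern']} × {c['segment']}: {c['sub_percent']}% vs "
                f"{c['pop_percent']}% (p={c['p_value']:.4g}, {c['method']})"
            )
    return "\n".join(lines) + "\n"
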