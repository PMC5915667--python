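"""Pattern × segment contingency analysis.

Each collaboration-pattern subgroup is compared against the total study
population, one proportion test per (pattern, segment) pair. Following
the original analysis design, the reference population *contains* the
subgroup (an overlapping comparison); comparing against the complement is
available through ``StatsOptions.reference = "complement"``.

The default test is the two-proportion z-test with continuity correction
(the classical ``prop.test`` behaviour), falling back to Fisher's exact
test whenever some expected cell of the 2×2 table is below 5. Both the
sidedness (two-sided, or one-sided in the direction of the observed
difference) and the Fisher fallback are configurable, because reported
analyses differ in these choices. No multiplicity adjustment is applied
by default; Holm correction is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .patterns import OUTLIER_LABEL, PATTERNS, UNCLASSIFIED
from .segments import SEGMENTS, _round_half_up


@dataclass
class ContingencyTable:
    """Pattern (rows, outliers included) × segment (columns) counts."""

    counts: pd.DataFrame
    non_pattern_rows: tuple[str, ...] = (OUTLIER_LABEL, UNCLASSIFIED)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def pattern_rows(self) -> list[str]:
        return [r for r in self.counts.index if r not in self.non_pattern_rows]

    def row_percentages(self) -> pd.DataFrame:
        """Integer percentages within each row (half rounded up)."""
        tot = self.row_totals.replace(0, np.nan)
        pct = self.counts.div(tot, axis=0) * 100.0
        return pct.map(lambda x: int(_round_half_up(x)) if pd.notna(x) else 0)

    def total_percentages(self) -> dict[str, float]:
        """Column percentages of the grand total, one decimal."""
        g = self.grand_total
        return {
            c: _round_half_up(100.0 * self.column_totals[c] / g, 1) if g else 0.0
            for c in self.counts.columns
        }


def build_contingency(
    patient_patterns: dict[str, str], patient_segments: dict[str, str]
) -> ContingencyTable:
    """Cross-tabulate pattern × segment labels over the same patient set."""
    if set(patient_patterns) != set(patient_segments):
        only_p = sorted(set(patient_patterns) - set(patient_segments))
        only_s = sorted(set(patient_segments) - set(patient_patterns))
        raise ValueError(
            "pattern and segment maps cover different patients: "
            f"only in patterns {only_p}, only in segments {only_s}"
        )
    pids = sorted(patient_patterns)
    df = pd.crosstab(
        pd.Series([patient_patterns[p] for p in pids], name="pattern"),
        pd.Series([patient_segments[p] for p in pids], name="segment"),
    )
    row_order = [r for r in (*PATTERNS, UNCLASSIFIED, OUTLIER_LABEL) if r in df.index]
    row_order += [r for r in df.index if r not in row_order]
    df = df.reindex(index=row_order, columns=list(SEGMENTS), fill_value=0)
    return ContingencyTable(df.astype(int))


@dataclass(frozen=True)
class ProportionTestResult:
    sub_count: int
    sub_n: int
    pop_count: int
    pop_n: int
    method: str  # "two-proportion z with continuity correction" | "Fisher exact" | ...
    statistic: float
    p_value: float

    @property
    def sub_proportion(self) -> float:
        return self.sub_count / self.sub_n

    @property
    def reference_proportion(self) -> float:
        return self.pop_count / self.pop_n


def _expected_cells(x1: int, n1: int, x2: int, n2: int) -> np.ndarray:
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    total = table.sum()
    if total == 0:
        return table
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def compare_to_population(
    sub_count: int,
    sub_n: int,
    pop_count: int,
    pop_n: int,
    *,
    alternative: str = "two-sided",
    continuity: bool = True,
    fisher_fallback: bool = True,
) -> ProportionTestResult:
    """Proportion test of a subgroup against a reference population.

    ``alternative`` is ``"two-sided"`` or ``"one-sided"`` (in the
    direction of the observed difference). With ``fisher_fallback`` the
    z-test is replaced by Fisher's exact test when any expected cell of
    the 2×2 table is below 5.
    """
    if sub_n < 1 or pop_n < 1:
        raise ValueError("subgroup and reference sizes must be at least 1")
    if not (0 <= sub_count <= sub_n and 0 <= pop_count <= pop_n):
        raise ValueError("counts must satisfy 0 <= count <= n")
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    p1, p2 = sub_count / sub_n, pop_count / pop_n
    use_fisher = fisher_fallback and _expected_cells(
        sub_count, sub_n, pop_count, pop_n
    ).min() < 5.0

    if use_fisher:
        table = [[sub_count, sub_n - sub_count], [pop_count, pop_n - pop_count]]
        if alternative == "two-sided":
            fisher_alt = "two-sided"
        else:
            fisher_alt = "greater" if p1 >= p2 else "less"
        odds, p = sps.fisher_exact(table, alternative=fisher_alt)
        return ProportionTestResult(
            sub_count, sub_n, pop_count, pop_n, "Fisher exact", float(odds), float(p)
        )

    pooled = (sub_count + pop_count) / (sub_n + pop_n)
    se = np.sqrt(pooled * (1 - pooled) * (1 / sub_n + 1 / pop_n))
    diff = abs(p1 - p2)
    cc = 0.5 * (1 / sub_n + 1 / pop_n) if continuity else 0.0
    z = max(diff - min(cc, diff), 0.0) / se if se > 0 else 0.0
    tails = 2.0 if alternative == "two-sided" else 1.0
    p = min(tails * float(sps.norm.sf(z)), 1.0)
    method = "two-proportion z" + (" with continuity correction" if continuity else "")
    if alternative == "one-sided":
        method += " (one-sided)"
    return ProportionTestResult(sub_count, sub_n, pop_count, pop_n, method, float(z), p)


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    alternative: str = "two-sided"
    continuity: bool = True
    fisher_fallback: bool = True
    reference: str = "total"  # or "complement"
    holm: bool = False


@dataclass
class Comparison:
    pattern: str
    segment: str
    result: ProportionTestResult
    significant: bool = False
    p_adjusted: float | None = None


def run_all_comparisons(
    table: ContingencyTable, options: StatsOptions = StatsOptions()
) -> list[Comparison]:
    """One subgroup-vs-population test per (non-outlier pattern, segment)."""
    if options.reference not in ("total", "complement"):
        raise ValueError(f"unknown reference {options.reference!r}")
    comparisons: list[Comparison] = []
    grand = table.grand_total
    for pattern in table.pattern_rows():
        sub_n = int(table.row_totals[pattern])
        if sub_n == 0:
            continue
        for segment in table.counts.columns:
            sub_count = int(table.counts.loc[pattern, segment])
            pop_count, pop_n = int(table.column_totals[segment]), grand
            if options.reference == "complement":
                pop_count, pop_n = pop_count - sub_count, pop_n - sub_n
            res = compare_to_population(
                sub_count,
                sub_n,
                pop_count,
                pop_n,
                alternative=options.alternative,
                continuity=options.continuity,
                fisher_fallback=options.fisher_fallback,
            )
            comparisons.append(Comparison(pattern, segment, res))
    pvals = np.array([c.result.p_value for c in comparisons])
    if options.holm:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        for c, a in zip(comparisons, adj):
            c.p_adjusted = float(a)
            c.significant = a <= options.alpha
    else:
        for c, p in zip(comparisons, pvals):
            c.significant = p <= options.alpha
    return comparisons
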