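"""Group-level aggregation and inter-group comparison of connectivity measures.

Window-level connectivity values (directional coupling strengths and
directionality indices from both the phase-domain and the spectral-domain
analyses) are pooled per group and compared between cohorts with one-tailed
Wilcoxon rank-sum tests — exact (enumeration over rank assignments) for
small samples, normal approximation with tie correction otherwise. Cohort
composition tables (gender, smoking) are compared by Pearson's chi-square
without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sst

__all__ = [
    "GroupSample",
    "GroupSummary",
    "ComparisonRow",
    "ContingencyTable",
    "wilcoxon_rank_sum_one_tailed",
    "pearson_chi2",
    "summarize_group",
    "build_comparison_table",
    "DBI_MEASURES",
    "DTF_MEASURES",
]

# closed set of measures, three per oscillator pair (two strengths + d)
DBI_MEASURES = (
    "s_pulse->bre", "s_bre->pulse", "d_bre,pulse",
    "s_ECG->bre", "s_bre->ECG", "d_bre,ECG",
    "s_pulse->ECG", "s_ECG->pulse", "d_ECG,pulse",
)
DTF_MEASURES = (
    "ssDTF_perf->bre", "ssDTF_bre->perf", "d_bre,perf",
    "ssDTF_ECG->bre", "ssDTF_bre->ECG", "d_bre,ECG",
    "ssDTF_perf->ECG", "ssDTF_ECG->perf", "d_ECG,perf",
)

EXACT_LIMIT = 12  # exact enumeration when n_a + n_b <= this


@dataclass
class GroupSample:
    """Values of one measure for one group (per window or per subject)."""

    values: np.ndarray
    group: str
    measure: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        self.values = vals[~np.isnan(vals)]


@dataclass
class GroupSummary:
    sample: GroupSample
    median: float | None
    q1: float | None
    q3: float | None
    count: int


@dataclass
class ComparisonRow:
    """One row of the group-comparison table.

    ``p_h1a`` tests the alternative median(control) > median(t1d);
    ``p_h1b`` the reverse.
    """

    interaction: str
    measure: str
    median_control: float | None
    median_t1d: float | None
    p_h1a: float
    p_h1b: float
    n_control: int = 0
    n_t1d: int = 0


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ("control", "t1d")
    col_labels: tuple[str, ...] = ("yes", "no")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("grand total must be at least 1")


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """P(rank-sum of y as or more extreme than observed) by full enumeration.

    Midranks are assigned to ties; all C(n, n_y) assignments of the pooled
    ranks to group y are enumerated.
    """
    pooled = np.concatenate([x, y])
    ranks = sst.rankdata(pooled)  # midranks
    n = len(pooled)
    n_y = len(y)
    obs = ranks[len(x):].sum()
    total = comb(n, n_y)
    count = 0
    for idx in combinations(range(n), n_y):
        s = ranks[list(idx)].sum()
        if alternative == "greater":
            if s >= obs - 1e-12:
                count += 1
        else:
            if s <= obs + 1e-12:
                count += 1
    return count / total


def wilcoxon_rank_sum_one_tailed(
    a: GroupSample | np.ndarray,
    b: GroupSample | np.ndarray,
    alternative: str = "greater",
) -> float:
    """One-tailed rank-sum p-value for a shift of sample b relative to a.

    ``alternative="greater"`` tests whether b tends to exceed a. Exact
    enumeration over all rank assignments is used when ``n_a + n_b <= 12``
    (correct under ties via midranks); otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(a.values if isinstance(a, GroupSample) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, GroupSample) else b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if len(x) + len(y) <= EXACT_LIMIT:
        return _exact_rank_sum_p(x, y, alternative)
    res = sst.mannwhitneyu(y, x, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Classic Pearson chi-square test of homogeneity, no continuity correction."""
    counts = table.counts
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count; chi-square test undefined")
    stat, p, _, _ = sst.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def summarize_group(
    values_per_subject: dict[str, np.ndarray] | list[np.ndarray],
    group: str,
    measure: str,
    level: str = "window",
) -> GroupSummary:
    """Pool a measure over a group's subjects and summarize.

    ``level="window"`` pools every (significant) window value across
    subjects — the convention used for the main comparison tables;
    ``level="subject"`` first reduces each subject to their median. Missing
    values (NaN) are dropped. Quartiles use linear interpolation.
    """
    if isinstance(values_per_subject, dict):
        arrays = list(values_per_subject.values())
    else:
        arrays = list(values_per_subject)
    if level == "window":
        pooled = np.concatenate([np.asarray(v, dtype=float) for v in arrays]) if arrays else np.array([])
    elif level == "subject":
        meds = [np.nanmedian(np.asarray(v, dtype=float)) for v in arrays if len(np.asarray(v)) > 0]
        pooled = np.asarray(meds, dtype=float)
    else:
        raise ValueError("level must be 'window' or 'subject'")
    sample = GroupSample(values=pooled, group=group, measure=measure)
    vals = sample.values
    if len(vals) == 0:
        return GroupSummary(sample=sample, median=None, q1=None, q3=None, count=0)
    return GroupSummary(
        sample=sample,
        median=float(np.median(vals)),
        q1=float(np.percentile(vals, 25)),
        q3=float(np.percentile(vals, 75)),
        count=len(vals),
    )


_INTERACTIONS = {
    "dbi": ("Lungs-Pulse", "Lungs-Pulse", "Lungs-Pulse",
            "Lungs-Heart", "Lungs-Heart", "Lungs-Heart",
            "Heart-Pulse", "Heart-Pulse", "Heart-Pulse"),
    "dtf": ("Lungs-Perfusion", "Lungs-Perfusion", "Lungs-Perfusion",
            "Lungs-Heart", "Lungs-Heart", "Lungs-Heart",
            "Heart-Perfusion", "Heart-Perfusion", "Heart-Perfusion"),
}


def build_comparison_table(
    control: dict[str, dict[str, np.ndarray]],
    t1d: dict[str, dict[str, np.ndarray]],
    method: str = "dbi",
    level: str = "window",
    fdr: bool = False,
) -> list[ComparisonRow]:
    """Full inter-group comparison: one row per measure (nine per method).

    Inputs map measure id -> {subject_id -> window values}. Each row carries
    both group medians and the two one-tailed rank-sum p-values (H1a: control
    median greater; H1b: t1d median greater). With ``fdr=True`` a
    Benjamini-Hochberg adjustment is applied across the rows per alternative
    (off by default).
    """
    measures = {"dbi": DBI_MEASURES, "dtf": DTF_MEASURES}[method]
    rows: list[ComparisonRow] = []
    for meas, inter in zip(measures, _INTERACTIONS[method]):
        sc = summarize_group(control.get(meas, {}), "control", meas, level)
        st = summarize_group(t1d.get(meas, {}), "t1d", meas, level)
        if sc.count == 0 or st.count == 0:
            rows.append(
                ComparisonRow(inter, meas, sc.median, st.median, np.nan, np.nan,
                              sc.count, st.count)
            )
            continue
        p_a = wilcoxon_rank_sum_one_tailed(st.sample, sc.sample, "greater")
        p_b = wilcoxon_rank_sum_one_tailed(sc.sample, st.sample, "greater")
        rows.append(
            ComparisonRow(inter, meas, sc.median, st.median, p_a, p_b, sc.count, st.count)
        )
    if fdr:
        for attr in ("p_h1a", "p_h1b"):
            ps = np.array([getattr(r, attr) for r in rows])
            ok = ~np.isnan(ps)
            if ok.any():
                adj = sst.false_discovery_control(ps[ok])
                ps[ok] = adj
                for r, p in zip(np.array(rows, dtype=object)[ok], ps[ok]):
                    setattr(r, attr, float(p))
    return rows
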