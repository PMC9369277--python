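"""Nonparametric group comparisons: median (range), Kruskal-Wallis omnibus,
pairwise Mann-Whitney U post hoc, phase and medication stratification.

Conventions follow the study's analysis: two-tailed tests at the 5% level,
no multiple-testing correction by default (an optional Holm adjustment is
available), medians and ranges on specimen-level aggregated outcomes.
The Mann-Whitney implementation switches automatically between the exact
null distribution (both groups of size <= 8, tie-free) and the
tie-corrected normal approximation with continuity correction; exact
two-tailed p is twice the smaller tail, capped at 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 8

#: outcome short name -> column of the specimen outcome table
OUTCOME_COLUMNS = {
    "bvd": "bvd_vessels_per_mm2",
    "lvd": "lvd_vessels_per_mm2",
    "pct_cd31": "pct_cd31_area_pct",
    "pct_pdpn": "pct_pdpn_area_pct",
    "mature_ratio": "mature_ratio_fraction",
    "ihs": "ihs_score",
}

ENDOMETRIAL_GROUPS = ("control_endometrium", "eutopic_endometrium", "ectopic_endometrium")


@dataclass
class TestResult:
    test: str  # "mann_whitney_u" | "kruskal_wallis"
    statistic: float  # U (of the first group) or H
    p_two_tailed: float
    method: str  # "exact" | "normal_approx" | "chisq_approx"
    tie_correction_applied: bool
    n_per_group: Tuple[int, ...]


@dataclass
class GroupSummary:
    name: str
    n: int
    median: float
    min: float
    max: float


@dataclass
class ComparisonReport:
    """All statistics for one outcome in one stratum."""

    outcome: str
    stratum: str
    groups: List[GroupSummary]
    omnibus: Optional[TestResult]
    pairwise: Dict[Tuple[str, str], TestResult]
    significant: Dict[Tuple[str, str], bool]
    alpha: float
    warnings: List[str] = field(default_factory=list)

    def flag(self, group_a: str, group_b: str) -> Optional[bool]:
        for key in ((group_a, group_b), (group_b, group_a)):
            if key in self.significant:
                return self.significant[key]
        return None

    def median_of(self, group: str) -> Optional[float]:
        for g in self.groups:
            if g.name == group:
                return g.median
        return None


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
    use_continuity: bool = True,
) -> TestResult:
    """Two-tailed Mann-Whitney U for two independent samples.

    ``method="auto"`` uses the exact null distribution when both samples
    have at most 8 observations and the pooled data are tie-free, otherwise
    the tie-corrected normal approximation (with continuity correction by
    default). U is reported for the first sample, computed from midranks.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = _has_ties(np.concatenate([a, b]))
    if method == "auto":
        method = "exact" if (a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not ties) else "normal_approx"
    if method not in ("exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=scipy_method, use_continuity=use_continuity
    )
    return TestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_two_tailed=float(min(res.pvalue, 1.0)),
        method=method,
        tie_correction_applied=bool(ties and method == "normal_approx"),
        n_per_group=(int(a.size), int(b.size)),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared (k-1 df) p-value.

    All-tied data make the tie correction degenerate (0/0); by convention
    this returns H = 0, p = 1 with a warning.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    total_n = sum(g.size for g in arrays)
    if total_n < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 observations in total")
    pooled = np.concatenate(arrays)
    ties = _has_ties(pooled)
    if np.unique(pooled).size == 1:
        warnings.warn("all observations identical; returning H=0, p=1", RuntimeWarning)
        return TestResult("kruskal_wallis", 0.0, 1.0, "chisq_approx", True,
                          tuple(g.size for g in arrays))
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), "chisq_approx",
                      bool(ties), tuple(g.size for g in arrays))


def _holm(pvals: Dict[Tuple[str, str], float]) -> Dict[Tuple[str, str], float]:
    keys = sorted(pvals, key=lambda k: pvals[k])
    m = len(keys)
    adj: Dict[Tuple[str, str], float] = {}
    running = 0.0
    for i, k in enumerate(keys):
        running = max(running, (m - i) * pvals[k])
        adj[k] = min(1.0, running)
    return adj


def _compare_groups(
    outcome: str,
    stratum: str,
    data: Dict[str, np.ndarray],
    alpha: float,
    mwu_method: str,
    holm: bool,
    omnibus_when_two: bool = True,
) -> ComparisonReport:
    """Summaries + omnibus KW + pairwise MWU for named groups (NaN dropped)."""
    clean = {k: v[np.isfinite(v)] for k, v in data.items()}
    nonempty = {k: v for k, v in clean.items() if v.size > 0}
    summaries = [
        GroupSummary(k, int(v.size), float(np.median(v)), float(v.min()), float(v.max()))
        for k, v in nonempty.items()
    ]
    warns: List[str] = []
    if len(nonempty) < 2:
        warns.append(f"{outcome}/{stratum}: fewer than 2 nonempty groups; tests omitted")
        return ComparisonReport(outcome, stratum, summaries, None, {}, {}, alpha, warns)
    omnibus = None
    if len(nonempty) > 2 or omnibus_when_two:
        omnibus = kruskal_wallis(list(nonempty.values()))
    pairwise: Dict[Tuple[str, str], TestResult] = {}
    for ka, kb in combinations(nonempty, 2):
        pairwise[(ka, kb)] = mann_whitney_u(nonempty[ka], nonempty[kb], method=mwu_method)
    pvals = {k: t.p_two_tailed for k, t in pairwise.items()}
    if holm:
        pvals = _holm(pvals)
    significant = {k: bool(p < alpha) for k, p in pvals.items()}
    return ComparisonReport(outcome, stratum, summaries, omnibus, pairwise, significant, alpha, warns)


def compare_tissues(
    outcome_table: pd.DataFrame,
    outcomes: Sequence[str] = ("bvd", "lvd", "pct_cd31", "pct_pdpn", "mature_ratio", "ihs"),
    alpha: float = 0.05,
    stratify_by: str = "cycle_phase",
    include_pooled: bool = False,
    holm: bool = False,
    mwu_method: str = "auto",
) -> List[ComparisonReport]:
    """The study's report layout: per outcome x stratum, endometrial tissue
    groups (control / eutopic / ectopic endometrium) under a Kruskal-Wallis
    omnibus with pairwise Mann-Whitney post hoc, and the myometrium as an
    adenomyosis-vs-control pairwise comparison.

    ``outcome_table`` needs one row per specimen with group, tissue_type,
    cycle_phase and medication columns plus the outcome columns.
    """
    required = {"group", "tissue_type", stratify_by if stratify_by != "pooled" else "group"}
    missing = required - set(outcome_table.columns)
    if missing:
        raise ValueError(f"outcome table is missing columns {sorted(missing)}")

    if stratify_by == "pooled":
        strata = [("pooled", outcome_table)]
    else:
        strata = [(s, outcome_table[outcome_table[stratify_by] == s])
                  for s in sorted(outcome_table[stratify_by].unique())]
        if include_pooled:
            strata.append(("pooled", outcome_table))

    reports: List[ComparisonReport] = []
    for outcome in outcomes:
        col = OUTCOME_COLUMNS.get(outcome, outcome)
        if col not in outcome_table.columns:
            continue
        for stratum, sub in strata:
            endo = {
                g: sub.loc[sub["tissue_type"] == g, col].to_numpy(float)
                for g in ENDOMETRIAL_GROUPS
            }
            reports.append(
                _compare_groups(outcome, f"{stratum}/endometrium", endo, alpha,
                                mwu_method, holm)
            )
            if outcome == "mature_ratio":
                continue  # undefined in the myometrium
            myo = sub[sub["tissue_type"] == "myometrium"]
            myo_groups = {
                f"{g}_myometrium": myo.loc[myo["group"] == g, col].to_numpy(float)
                for g in ("adenomyosis", "control")
            }
            reports.append(
                _compare_groups(outcome, f"{stratum}/myometrium", myo_groups, alpha,
                                mwu_method, holm, omnibus_when_two=False)
            )
    return reports


def medication_subgroup(
    outcome_table: pd.DataFrame,
    outcomes: Sequence[str] = ("bvd", "lvd"),
    alpha: float = 0.05,
    mwu_method: str = "auto",
) -> List[ComparisonReport]:
    """Antiangiogenic-medication subgroup comparison on native endometrium.

    Pools both cycle phases and compares endometrial BVD and LVD between
    specimens from patients with vs without medication of antiangiogenic
    profile (NSAIDs, tranexamic acid).
    """
    endo = outcome_table[outcome_table["tissue_type"].isin(
        ("eutopic_endometrium", "control_endometrium"))]
    reports = []
    for outcome in outcomes:
        col = OUTCOME_COLUMNS.get(outcome, outcome)
        groups = {
            m: endo.loc[endo["medication"] == m, col].to_numpy(float)
            for m in ("none_other", "antiangiogenic")
        }
        reports.append(
            _compare_groups(outcome, "medication/endometrium", groups, alpha,
                            mwu_method, holm=False, omnibus_when_two=False)
        )
    return reports


def report_to_rows(report: ComparisonReport) -> List[Dict]:
    """Flatten a ComparisonReport for CSV output (one row per test)."""
    rows: List[Dict] = []
    base = {"outcome": report.outcome, "stratum": report.stratum, "alpha": report.alpha}
    med = {g.name: g for g in report.groups}
    if report.omnibus is not None:
        rows.append({
            **base, "test": "kruskal_wallis", "group_a": "|".join(med), "group_b": "",
            "statistic": report.omnibus.statistic, "p_two_tailed": report.omnibus.p_two_tailed,
            "method": report.omnibus.method, "significant": report.omnibus.p_two_tailed < report.alpha,
            "median_a": np.nan, "median_b": np.nan, "n_a": sum(g.n for g in report.groups), "n_b": 0,
        })
    for (ka, kb), t in report.pairwise.items():
        rows.append({
            **base, "test": "mann_whitney_u", "group_a": ka, "group_b": kb,
            "statistic": t.statistic, "p_two_tailed": t.p_two_tailed, "method": t.method,
            "significant": report.significant[(ka, kb)],
            "median_a": med[ka].median, "median_b": med[kb].median,
            "n_a": med[ka].n, "n_b": med[kb].n,
        })
    if not rows:
        rows.append({**base, "test": "none", "group_a": "", "group_b": "",
                     "statistic": np.nan, "p_two_tailed": np.nan, "method": "",
                     "significant": False, "median_a": np.nan, "median_b": np.nan,
                     "n_a": 0, "n_b": 0})
    return rows


def report_to_dict(report: ComparisonReport) -> Dict:
    """JSON-ready representation of a ComparisonReport."""
    return {
        "outcome": report.outcome,
        "stratum": report.stratum,
        "alpha": report.alpha,
        "groups": [
            {"name": g.name, "n": g.n, "median": g.median, "min": g.min, "max": g.max}
            for g in report.groups
        ],
        "omnibus": None if report.omnibus is None else {
            "test": report.omnibus.test, "statistic": report.omnibus.statistic,
            "p_two_tailed": report.omnibus.p_two_tailed, "method": report.omnibus.method,
            "tie_correction_applied": report.omnibus.tie_correction_applied,
            "n_per_group": list(report.omnibus.n_per_group),
        },
        "pairwise": [
            {
                "group_a": ka, "group_b": kb, "statistic": t.statistic,
                "p_two_tailed": t.p_two_tailed, "method": t.method,
                "significant": report.significant[(ka, kb)],
            }
            for (ka, kb), t in report.pairwise.items()
        ],
        "warnings": report.warnings,
    }
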