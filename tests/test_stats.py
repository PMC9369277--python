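"""Rank tests against independent oracles; report assembly and stratification."""
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adenoquant.stats import (
    ComparisonReport,
    compare_tissues,
    kruskal_wallis,
    mann_whitney_u,
    medication_subgroup,
    report_to_dict,
    report_to_rows,
)


def mwu_enumeration_oracle(a, b):
    """Exact two-tailed Mann-Whitney p by enumerating all labelings.

    U for the first sample from pair counts; the two-tailed p is twice the
    smaller tail (point mass included), capped at 1.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1, n = len(a), len(a) + len(b)

    def u_of(idx_set):
        xs = [pooled[i] for i in idx_set]
        ys = [pooled[i] for i in range(n) if i not in idx_set]
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_of(set(range(n1)))
    us = [u_of(set(c)) for c in combinations(range(n), n1)]
    total = len(us)
    lo = sum(u <= u_obs for u in us) / total
    hi = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2.0 * min(lo, hi))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="exact")
        assert r.p_two_tailed == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.statistic == 0.0
        assert r.p_two_tailed == pytest.approx(0.1)  # 2 * (1 / C(6,3))

    def test_swap_symmetry(self):
        a, b = [1.2, 3.4, 2.2, 8.0], [4.4, 5.5, 0.1]
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)
        assert r1.statistic + r2.statistic == len(a) * len(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_bounded_by_n1_n2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(1, 9))
            b = rng.normal(size=rng.integers(1, 9))
            r = mann_whitney_u(a, b)
            assert 0 <= r.statistic <= a.size * b.size

    def test_auto_switches_to_normal_approx_on_ties(self):
        r = mann_whitney_u([1, 1, 2, 3], [2, 4, 4, 5])
        assert r.method == "normal_approx" and r.tie_correction_applied

    def test_auto_switches_to_normal_approx_when_large(self):
        rng = np.random.default_rng(1)
        r = mann_whitney_u(rng.normal(size=9), rng.normal(size=5))
        assert r.method == "normal_approx"

    def test_exact_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            r = mann_whitney_u(a, b, method="exact")
            u_oracle, p_oracle = mwu_enumeration_oracle(a, b)
            assert r.statistic == pytest.approx(u_oracle), trial
            assert r.p_two_tailed == pytest.approx(p_oracle, abs=1e-12), trial

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=7) + 0.5
        p_raw = mann_whitney_u(a, b).p_two_tailed
        p_exp = mann_whitney_u(np.exp(a), np.exp(b)).p_two_tailed
        assert p_raw == pytest.approx(p_exp)


def kw_rank_formula_oracle(groups):
    """H computed directly from the rank-sum formula (no ties assumed)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_identical_constant_groups_degenerate(self):
        with pytest.warns(RuntimeWarning):
            r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert r.statistic == 0.0 and r.p_two_tailed == 1.0

    def test_matches_direct_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        r = kruskal_wallis(groups)
        assert r.statistic == pytest.approx(kw_rank_formula_oracle(groups))

    def test_two_groups_equals_squared_mwu_z(self):
        """For two tie-free groups, H = z^2 of the MWU normal approximation
        (no continuity correction) and the p-values agree."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 12)))
            b = rng.normal(size=int(rng.integers(3, 12)))
            kw = kruskal_wallis([a, b])
            mwu = mann_whitney_u(a, b, method="normal_approx", use_continuity=False)
            u = mwu.statistic
            mu = a.size * b.size / 2.0
            sd = np.sqrt(a.size * b.size * (a.size + b.size + 1) / 12.0)
            z = (u - mu) / sd
            assert kw.statistic == pytest.approx(z ** 2, abs=1e-9)
            assert kw.p_two_tailed == pytest.approx(mwu.p_two_tailed, abs=1e-6)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=6), rng.normal(size=5) + 1, rng.normal(size=7)]
        p_raw = kruskal_wallis(groups).p_two_tailed
        p_t = kruskal_wallis([np.exp(g) for g in groups]).p_two_tailed
        assert p_raw == pytest.approx(p_t)


def _outcome_table(rng, n_per_group=6, shift=None, phases=("proliferative",)):
    rows = []
    shift = shift or {}
    for phase in phases:
        for tissue in ("control_endometrium", "eutopic_endometrium",
                       "ectopic_endometrium", "myometrium"):
            group = "control" if tissue == "control_endometrium" else "adenomyosis"
            for i in range(n_per_group):
                rows.append({
                    "specimen_id": f"{tissue[:3]}{phase[:2]}{i}",
                    "group": group if tissue != "myometrium" or i % 2 else "control",
                    "tissue_type": tissue,
                    "cycle_phase": phase,
                    "medication": "none_other" if i % 3 else "antiangiogenic",
                    "bvd_vessels_per_mm2": rng.lognormal(3.0, 0.2) + shift.get(tissue, 0.0),
                    "lvd_vessels_per_mm2": rng.lognormal(2.0, 0.2),
                    "mature_ratio_fraction": (
                        np.nan if tissue == "myometrium" else rng.uniform(0.3, 0.7)),
                })
    return pd.DataFrame(rows)


class TestCompareTissues:
    def test_report_layout(self):
        rng = np.random.default_rng(5)
        table = _outcome_table(rng, phases=("proliferative", "secretory"))
        reports = compare_tissues(table, outcomes=("bvd", "lvd", "mature_ratio"))
        strata = {(r.outcome, r.stratum) for r in reports}
        assert ("bvd", "proliferative/endometrium") in strata
        assert ("bvd", "proliferative/myometrium") in strata
        # the mature ratio is never compared in the myometrium
        assert not any(r.outcome == "mature_ratio" and "myometrium" in r.stratum
                       for r in reports)
        endo = next(r for r in reports if (r.outcome, r.stratum) ==
                    ("bvd", "proliferative/endometrium"))
        assert endo.omnibus is not None and endo.omnibus.test == "kruskal_wallis"
        assert len(endo.pairwise) == 3
        for (ka, kb), t in endo.pairwise.items():
            assert endo.significant[(ka, kb)] == (t.p_two_tailed < endo.alpha)

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(6)
        table = _outcome_table(rng, n_per_group=8, shift={"ectopic_endometrium": 40.0})
        reports = compare_tissues(table, outcomes=("bvd",))
        endo = next(r for r in reports if r.stratum == "proliferative/endometrium")
        assert endo.flag("control_endometrium", "ectopic_endometrium") is True
        assert endo.median_of("ectopic_endometrium") > endo.median_of("control_endometrium")

    def test_single_specimen_groups_run_with_exact_p_one(self):
        rng = np.random.default_rng(7)
        table = _outcome_table(rng, n_per_group=1)
        reports = compare_tissues(table, outcomes=("bvd",))
        endo = next(r for r in reports if "endometrium" in r.stratum)
        for t in endo.pairwise.values():
            assert t.p_two_tailed == pytest.approx(1.0)

    def test_stratum_with_single_group_warns_and_omits_tests(self):
        table = pd.DataFrame({
            "specimen_id": ["a", "b"],
            "group": ["control", "control"],
            "tissue_type": ["control_endometrium"] * 2,
            "cycle_phase": ["proliferative"] * 2,
            "medication": ["none_other"] * 2,
            "bvd_vessels_per_mm2": [1.0, 2.0],
        })
        reports = compare_tissues(table, outcomes=("bvd",))
        endo = next(r for r in reports if "endometrium" in r.stratum)
        assert endo.omnibus is None and not endo.pairwise
        assert endo.warnings

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compare_tissues(pd.DataFrame({"bvd_vessels_per_mm2": [1.0]}))

    def test_holm_only_reduces_significance(self):
        rng = np.random.default_rng(8)
        table = _outcome_table(rng, n_per_group=8, shift={"ectopic_endometrium": 15.0})
        raw = compare_tissues(table, outcomes=("bvd",), holm=False)
        adj = compare_tissues(table, outcomes=("bvd",), holm=True)
        for r_raw, r_adj in zip(raw, adj):
            for key in r_raw.significant:
                assert not (r_adj.significant[key] and not r_raw.significant[key])

    def test_report_serialization_roundtrip(self):
        rng = np.random.default_rng(9)
        reports = compare_tissues(_outcome_table(rng), outcomes=("bvd",))
        for r in reports:
            d = report_to_dict(r)
            assert d["outcome"] == r.outcome
            rows = report_to_rows(r)
            assert all("p_two_tailed" in row for row in rows)


class TestMedicationSubgroup:
    def test_pooled_phase_endometrial_comparison(self):
        rng = np.random.default_rng(10)
        table = _outcome_table(rng, phases=("proliferative", "secretory"))
        reports = medication_subgroup(table)
        assert {r.outcome for r in reports} == {"bvd", "lvd"}
        for r in reports:
            assert r.stratum == "medication/endometrium"
            assert set(n for n, _ in [(g.name, g) for g in r.groups]) <= {
                "none_other", "antiangiogenic"}
            assert r.pairwise  # both subgroups nonempty here

    def test_single_subgroup_warns(self):
        rng = np.random.default_rng(11)
        table = _outcome_table(rng)
        table["medication"] = "none_other"
        reports = medication_subgroup(table)
        for r in reports:
            assert not r.pairwise and r.warnings
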