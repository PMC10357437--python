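"""qPCR normalization, group summaries, fold changes and t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strokemir.qpcr import (
    GroupSummary, QpcrError, fold_change, group_summary, relative_expression,
    t_test_from_summary, validate_targets,
)
from strokemir.simulate import CtSimConfig, simulate_ct


def make_ct(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "target", "replicate", "ct"])


def wells(sample, group, target, cts):
    return [(sample, group, target, i + 1, ct) for i, ct in enumerate(cts)]


REFS = ["cel-miR-39", "cel-miR-54", "cel-miR-238"]


def sample_block(sample, group, ref_ct=20.0, targets=()):
    rows = []
    for ref in REFS:
        rows += wells(sample, group, ref, [ref_ct] * 3)
    for target, ct in targets:
        rows += wells(sample, group, target, [ct] * 3)
    return rows


class TestRelativeExpression:
    def test_target_at_spikein_mean_is_zero(self):
        ct = make_ct(sample_block("s1", "stroke", 20.0, [("miR-x", 20.0)]))
        rel = relative_expression(ct)
        assert rel.loc[0, "rel_expr"] == pytest.approx(0.0)

    def test_one_cycle_lower_ct_is_one_unit_higher_expression(self):
        ct = make_ct(sample_block("s1", "stroke", 20.0, [("miR-x", 20.0)])
                     + sample_block("s2", "stroke", 20.0, [("miR-x", 19.0)]))
        rel = relative_expression(ct).set_index("sample_id")["rel_expr"]
        assert rel["s2"] - rel["s1"] == pytest.approx(1.0)

    def test_replicates_averaged_before_normalization(self):
        rows = []
        for ref in REFS:
            rows += wells("s1", "stroke", ref, [19.0, 20.0, 21.0])
        rows += wells("s1", "stroke", "miR-x", [18.0, 19.0, 20.0])
        rel = relative_expression(make_ct(rows))
        assert rel.loc[0, "rel_expr"] == pytest.approx(1.0)

    def test_missing_reference_names_sample(self):
        rows = sample_block("good", "stroke", targets=[("miR-x", 20.0)])
        rows += wells("bad", "stroke", "cel-miR-39", [20.0]) \
            + wells("bad", "stroke", "miR-x", [20.0])
        with pytest.raises(QpcrError, match="bad"):
            relative_expression(make_ct(rows))


class TestGroupSummary:
    def test_constant_values_have_zero_sem(self):
        rel = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "group": "stroke",
            "target": "miR-x", "rel_expr": [1.5, 1.5, 1.5],
        })
        (s,) = group_summary(rel)
        assert s.mean == 1.5 and s.sem == 0.0 and s.n == 3

    def test_two_sample_closed_form(self):
        rel = pd.DataFrame({
            "sample_id": ["a", "b"], "group": "healthy",
            "target": "miR-x", "rel_expr": [1.0, 3.0],
        })
        (s,) = group_summary(rel)
        assert s.mean == 2.0
        assert s.sem == pytest.approx(abs(1.0 - 3.0) / 2)

    def test_single_sample_group_rejected(self):
        rel = pd.DataFrame({
            "sample_id": ["a"], "group": "stroke", "target": "miR-x", "rel_expr": [1.0],
        })
        with pytest.raises(QpcrError, match="single sample"):
            group_summary(rel)


class TestFoldChange:
    def test_published_row_arithmetic(self):
        case = GroupSummary("m", "stroke", 0.87, 0.221, 20)
        control = GroupSummary("m", "healthy", -0.004, 0.139, 20)
        ddct, fc = fold_change(case, control)
        assert ddct == pytest.approx(0.874)
        assert fc == pytest.approx(1.83, abs=0.01)

    def test_identical_groups_give_unit_fold_change(self):
        s = GroupSummary("m", "stroke", 0.3, 0.1, 5)
        c = GroupSummary("m", "healthy", 0.3, 0.1, 5)
        assert fold_change(s, c) == (0.0, 1.0)

    def test_reciprocal_identity(self):
        s = GroupSummary("m", "stroke", -0.55, 0.2, 20)
        c = GroupSummary("m", "healthy", 0.0, 0.2, 20)
        _, f1 = fold_change(s, c)
        _, f2 = fold_change(c, s)
        assert f1 * f2 == pytest.approx(1.0)

    def test_mismatched_targets_rejected(self):
        s = GroupSummary("m1", "stroke", 0.0, 0.1, 5)
        c = GroupSummary("m2", "healthy", 0.0, 0.1, 5)
        with pytest.raises(QpcrError):
            fold_change(s, c)


class TestSummaryTTest:
    def test_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.5, 1, 12), rng.normal(0.0, 1.2, 15)
        case = GroupSummary("m", "stroke", x.mean(), x.std(ddof=1) / np.sqrt(12), 12)
        control = GroupSummary("m", "healthy", y.mean(), y.std(ddof=1) / np.sqrt(15), 15)
        t, df, p, degenerate = t_test_from_summary(case, control)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
        assert df == 25 and not degenerate

    def test_antisymmetric_under_group_swap(self):
        case = GroupSummary("m", "stroke", 0.58, 0.143, 20)
        control = GroupSummary("m", "healthy", 0.0, 0.164, 20)
        t1, _, p1, _ = t_test_from_summary(case, control)
        t2, _, p2, _ = t_test_from_summary(control, case)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_location_shift_invariance(self):
        a = GroupSummary("m", "stroke", 0.58, 0.143, 20)
        b = GroupSummary("m", "healthy", -0.0005, 0.164, 20)
        a2 = GroupSummary("m", "stroke", a.mean + 5, a.sem, a.n)
        b2 = GroupSummary("m", "healthy", b.mean + 5, b.sem, b.n)
        assert t_test_from_summary(a, b)[:3] == pytest.approx(
            t_test_from_summary(a2, b2)[:3])

    def test_identical_summaries(self):
        s = GroupSummary("m", "stroke", 1.0, 0.1, 10)
        c = GroupSummary("m", "healthy", 1.0, 0.1, 10)
        t, _, p, _ = t_test_from_summary(s, c)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_degenerate_cases(self):
        eq = t_test_from_summary(GroupSummary("m", "stroke", 1.0, 0.0, 5),
                                 GroupSummary("m", "healthy", 1.0, 0.0, 5))
        assert eq[2] == 1.0 and not eq[3]
        ne = t_test_from_summary(GroupSummary("m", "stroke", 2.0, 0.0, 5),
                                 GroupSummary("m", "healthy", 1.0, 0.0, 5))
        assert ne[2] == 0.0 and ne[3]


class TestPublishedValidation:
    def test_published_summary_statistics_reproduce_printed_row(self, validation_summaries):
        results = {r.target_name: r for r in validate_targets(validation_summaries)}
        r185 = results["hsa-miR-185-5p"]
        assert r185.fold_change == pytest.approx(1.83, abs=0.01)
        assert r185.p == pytest.approx(0.0019, abs=0.002)
        r7e = results["hsa-let-7e-5p"]
        assert r7e.p == pytest.approx(0.011, abs=0.002)
        assert r7e.df == 38

    def test_fold_change_is_two_to_the_ddct(self, validation_summaries):
        for r in validate_targets(validation_summaries):
            assert r.fold_change == pytest.approx(2.0 ** r.ddct, rel=1e-12)


class TestParameterRecovery:
    def test_planted_effect_recovered_within_three_sems(self):
        """Planted ddCt of 1.0 on 20 vs 20 synthetic samples comes back within
        3 combined SEMs of fold change 2.0."""
        cfg = CtSimConfig(effects={"miR-x": 1.0}, bio_sd={"miR-x": 0.6},
                          tech_sd=0.1, seed=42)
        ct, _ = simulate_ct(cfg)
        summaries = group_summary(relative_expression(ct))
        (res,) = validate_targets(summaries)
        sems = {s.group: s.sem for s in summaries}
        combined = np.hypot(sems["stroke"], sems["healthy"])
        assert abs(res.ddct - 1.0) < 3 * combined
        assert res.fold_change == pytest.approx(2.0 ** res.ddct)
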