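"""Meta-analysis engine: event tables, effect sizes, heterogeneity, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strokemir.catalog import MirnaReport, QualifiedGroup, StudyRecord
from strokemir.meta import (
    ContingencyTable, EffectSize,
    build_contingency, continuity_correct, dersimonian_laird, estimate_tau2,
    log_odds_ratio, pool_random_effects, reml_tau2, run_meta,
)


def closed_form_meta(studies):
    """Independent spreadsheet-style recomputation for small groups.

    ``studies`` is a list of (direction, n_case, n_control).  Uses only plain
    arithmetic, not the engine's helpers.
    """
    from scipy.stats import norm

    thetas, vs = [], []
    for direction, n1, n0 in studies:
        a, b, c, d = (n1, 0, 0, n0) if direction == "up" else (0, n1, n0, 0)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        thetas.append(math.log(a * d / (b * c)))
        vs.append(1 / a + 1 / b + 1 / c + 1 / d)
    u = [1 / v for v in vs]
    theta_f = sum(ui * ti for ui, ti in zip(u, thetas)) / sum(u)
    q = sum(ui * (ti - theta_f) ** 2 for ui, ti in zip(u, thetas))
    c_ = sum(u) - sum(ui**2 for ui in u) / sum(u)
    tau2 = max(0.0, (q - (len(u) - 1)) / c_)
    i2 = max(0.0, (q - (len(u) - 1)) / q) * 100 if q > 0 else 0.0
    w = [1 / (v + tau2) for v in vs]
    pooled = sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)
    se = math.sqrt(1 / sum(w))
    p = 2 * norm.sf(abs(pooled / se))
    return dict(pooled=pooled, se=se, tau2=tau2, i2=i2, q=q, p=p,
                weights=[wi / sum(w) for wi in w])


def make_group(studies, name="hsa-miR-x", specimen="serum"):
    members = []
    for i, (direction, n1, n0) in enumerate(studies):
        s = StudyRecord(f"s{i}", f"A{i}", 2000 + i, specimen, n1, n0)
        r = MirnaReport(f"s{i}", name, direction, canonical_name=name)
        members.append((s, r))
    return QualifiedGroup(name, specimen, tuple(members))


study_strategy = st.tuples(
    st.sampled_from(["up", "down"]),
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
)
group_strategy = st.lists(study_strategy, min_size=2, max_size=6)


class TestContingency:
    @pytest.mark.parametrize("direction,n1,n0,expected", [
        ("down", 31, 11, (0, 31, 11, 0)),
        ("up", 302, 302, (302, 0, 0, 302)),
        ("up", 1, 1, (1, 0, 0, 1)),
    ])
    def test_event_table_encoding(self, direction, n1, n0, expected):
        assert build_contingency(direction, n1, n0).cells() == expected

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            build_contingency("sideways", 5, 5)

    @pytest.mark.parametrize("cells,expected", [
        ((0, 31, 11, 0), (0.5, 31.5, 11.5, 0.5)),
        ((2, 3, 4, 5), (2, 3, 4, 5)),
        ((0, 0, 0, 0), (0.5, 0.5, 0.5, 0.5)),
    ])
    def test_continuity_all_cells_if_any_zero(self, cells, expected):
        assert continuity_correct(ContingencyTable(*cells)).cells() == expected


class TestEffectSize:
    def test_frozen_example(self):
        e = log_odds_ratio(ContingencyTable(0.5, 31.5, 11.5, 0.5))
        assert e.log_or == pytest.approx(-7.278629, abs=1e-5)
        assert e.variance == pytest.approx(4.118703, abs=1e-5)

    def test_symmetric_table(self):
        e = log_odds_ratio(ContingencyTable(1, 1, 1, 1))
        assert e.log_or == 0.0 and e.variance == 4.0

    def test_transposition_negates_log_or(self):
        t_up = continuity_correct(build_contingency("up", 31, 11))
        t_dn = continuity_correct(build_contingency("down", 31, 11))
        e_up, e_dn = log_odds_ratio(t_up), log_odds_ratio(t_dn)
        assert e_up.log_or == -e_dn.log_or
        assert e_up.variance == e_dn.variance

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            log_odds_ratio(ContingencyTable(0, 1, 1, 1))


class TestHeterogeneity:
    def test_identical_effects(self):
        het = dersimonian_laird([EffectSize(1.0, 2.0), EffectSize(1.0, 2.0)])
        assert het.tau2 == 0.0 and het.i2 == 0.0 and het.q == pytest.approx(0.0)

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            dersimonian_laird([EffectSize(1.0, 2.0)])

    @given(group_strategy, st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_tau2_invariant_under_common_shift(self, studies, shift):
        effects = []
        for direction, n1, n0 in studies:
            t = continuity_correct(build_contingency(direction, n1, n0))
            effects.append(log_odds_ratio(t))
        shifted = [EffectSize(e.log_or + shift, e.variance) for e in effects]
        h0, h1 = dersimonian_laird(effects), dersimonian_laird(shifted)
        assert h1.tau2 == pytest.approx(h0.tau2, abs=1e-9)
        assert h1.q == pytest.approx(h0.q, abs=1e-9)

    def test_reml_matches_independent_value_on_three_study_group(self):
        """REML fixed point reproduces the value of the reference R
        implementation (frozen: 76.503) on the conflicting serum triple."""
        g = make_group([("down", 146, 96), ("up", 10, 10), ("down", 34, 11)])
        r = run_meta(g, tau2_method="reml")
        assert r.heterogeneity.tau2 == pytest.approx(76.503, abs=1e-3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_tau2([EffectSize(1, 1), EffectSize(2, 1)], method="pm")


class TestPooling:
    def test_equal_effects_pool_to_common_value(self):
        effects = [EffectSize(1.7, 2.0), EffectSize(1.7, 3.0)]
        r = pool_random_effects(effects, 0.0)
        assert r.pooled_log_or == pytest.approx(1.7)

    def test_weights_normalized_and_pooled_bracketed(self):
        g = make_group([("up", 302, 302), ("up", 10, 11)])
        r = run_meta(g)
        assert sum(r.weights) == pytest.approx(1.0, abs=1e-12)
        los = [e.log_or for e in r.effects]
        assert min(los) <= r.pooled_log_or <= max(los)
        assert r.ci_low <= r.pooled_log_or <= r.ci_high
        assert 0 < r.p <= 1

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([EffectSize(1, 1), EffectSize(2, 1)], -0.1)


class TestRunMeta:
    @pytest.mark.parametrize("studies,pooled,tau2,i2", [
        # frozen from the published meta-analysis table
        ([("up", 302, 302), ("up", 10, 11)], 9.51, 17.89, 81.37),
        ([("down", 31, 11), ("down", 10, 10)], -6.69, 0.0, 0.0),
        ([("up", 106, 120), ("up", 139, 34)], 10.36, 0.0, 0.0),
        ([("up", 10, 10), ("down", 34, 11)], -0.64, 86.41, 95.41),
        ([("down", 106, 110), ("down", 148, 148)], -11.07, 0.0, 0.0),
        ([("down", 146, 96), ("up", 10, 10), ("down", 34, 11)], -4.08, 76.03, 94.87),
    ])
    def test_published_groups(self, studies, pooled, tau2, i2):
        r = run_meta(make_group(studies))
        assert r.pooled_log_or == pytest.approx(pooled, abs=0.005)
        assert r.heterogeneity.tau2 == pytest.approx(tau2, abs=0.005)
        assert r.heterogeneity.i2 == pytest.approx(i2, abs=0.005)

    def test_direction_and_significance_flags(self):
        r = run_meta(make_group([("down", 31, 11), ("down", 10, 10)]))
        assert r.direction == "down" and r.significant

    @given(group_strategy)
    @settings(max_examples=100, deadline=None)
    def test_sign_flip_symmetry(self, studies):
        """Reversing every direction negates the pooled effect exactly and
        leaves se, tau2, I2 and the weights unchanged."""
        flipped = [("down" if d == "up" else "up", n1, n0) for d, n1, n0 in studies]
        r0, r1 = run_meta(make_group(studies)), run_meta(make_group(flipped))
        assert r1.pooled_log_or == pytest.approx(-r0.pooled_log_or, abs=1e-12)
        assert r1.se == pytest.approx(r0.se, abs=1e-12)
        assert r1.heterogeneity.tau2 == pytest.approx(r0.heterogeneity.tau2, abs=1e-9)
        assert r1.heterogeneity.i2 == pytest.approx(r0.heterogeneity.i2, abs=1e-9)
        assert np.allclose(r1.weights, r0.weights, atol=1e-12)

    @given(group_strategy)
    @settings(max_examples=100, deadline=None)
    def test_closed_form_oracle(self, studies):
        """The engine agrees with an independent arithmetic recomputation."""
        r = run_meta(make_group(studies))
        o = closed_form_meta(studies)
        assert r.pooled_log_or == pytest.approx(o["pooled"], abs=1e-9)
        assert r.se == pytest.approx(o["se"], abs=1e-9)
        assert r.heterogeneity.tau2 == pytest.approx(o["tau2"], abs=1e-9)
        assert r.heterogeneity.i2 == pytest.approx(o["i2"], abs=1e-9)
        assert np.allclose(r.weights, o["weights"], atol=1e-9)

    def test_identical_input_multisets_give_identical_results(self):
        """Distinct miRNAs built from the same study pair share one result row
        (the published plasma pair prints three identical rows)."""
        pair = [("up", 106, 110), ("up", 148, 148)]
        r1 = run_meta(make_group(pair, name="hsa-miR-185-5p", specimen="plasma"))
        r2 = run_meta(make_group(pair, name="hsa-miR-222-3p", specimen="plasma"))
        assert r1.pooled_log_or == r2.pooled_log_or
        assert r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high
        assert r1.heterogeneity.tau2 == r2.heterogeneity.tau2
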