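import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilsource.datamodel import ValidationError
from soilsource.geodetector import (
    StratifiedVariable,
    assign_pathways,
    discretize_equal_interval,
    discretize_natural_breaks,
    factor_q,
    interaction_q,
)


def anova_q_oracle(y, labels):
    """Independent one-way decomposition: q = 1 - SSW/SST."""
    y = np.asarray(y, float)
    sst = np.sum((y - y.mean()) ** 2)
    ssw = sum(np.sum((y[labels == g] - y[labels == g].mean()) ** 2)
              for g in np.unique(labels))
    return 1.0 - ssw / sst


def exhaustive_jenks_ssd(values, k):
    """Best within-class SSD over all ordered partitions of sorted values."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def ssd(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(ssd(v[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        best = min(best, total)
    return best


def within_class_ssd(values, labels):
    v = np.asarray(values, float)
    return sum(float(np.sum((v[labels == g] - v[labels == g].mean()) ** 2))
               for g in np.unique(labels))


class TestEqualInterval:
    def test_half_open_boundaries(self):
        sv = discretize_equal_interval([0, 199.9, 200, 450], 200.0)
        assert list(sv.labels) == [0, 0, 1, 2]

    def test_single_interval(self):
        sv = discretize_equal_interval([10, 20, 30], 200.0)
        assert sv.n_strata == 1

    def test_matches_floor_formula(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 5000, 500)
        sv = discretize_equal_interval(v, 200.0)
        assert np.array_equal(sv.labels, np.floor(v / 200.0).astype(int))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            discretize_equal_interval([1.0], 0.0)


class TestNaturalBreaks:
    def test_obvious_gap(self):
        sv = discretize_natural_breaks([1, 1, 1, 10, 10, 10], k=2)
        assert sv.n_strata == 2
        assert len(set(sv.labels[:3])) == 1 and len(set(sv.labels[3:])) == 1
        assert sv.labels[0] != sv.labels[3]

    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 3), (3, 4)])
    def test_matches_exhaustive_enumeration(self, seed, k):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 100, 12)
        sv = discretize_natural_breaks(v, k)
        assert within_class_ssd(v, sv.labels) == pytest.approx(
            exhaustive_jenks_ssd(v, k), rel=1e-12)

    def test_k_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            sv = discretize_natural_breaks([1.0, 1.0, 2.0], k=5)
        assert sv.n_strata == 2

    def test_deterministic(self):
        v = np.random.default_rng(5).uniform(0, 10, 50)
        a = discretize_natural_breaks(v, 4)
        b = discretize_natural_breaks(v, 4)
        assert np.array_equal(a.labels, b.labels)

    def test_ties_share_a_class(self):
        v = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 9.0, 9.1])
        sv = discretize_natural_breaks(v, 3)
        assert len(set(sv.labels[v == 2.0])) == 1


class TestFactorQ:
    def test_hand_computed_two_strata(self):
        # SST = 17, SSW = 1 -> q = 16/17
        x = StratifiedVariable("x", np.array(["a", "a", "b", "b"]))
        r = factor_q([1, 2, 5, 6], x)
        assert r.q == pytest.approx(1 - 1 / 17, abs=1e-12)

    def test_single_stratum_gives_zero(self):
        x = StratifiedVariable("x", np.zeros(6, dtype=int))
        assert factor_q(np.arange(6.0), x).q == pytest.approx(0.0)

    def test_each_site_own_stratum_gives_one(self):
        x = StratifiedVariable("x", np.arange(6))
        r = factor_q(np.random.default_rng(0).normal(size=6), x)
        assert r.q == pytest.approx(1.0)
        assert r.n_singleton_strata == 6

    def test_constant_response_rejected(self):
        x = StratifiedVariable("x", np.array([0, 0, 1, 1]))
        with pytest.raises(ValidationError):
            factor_q([2.0, 2.0, 2.0, 2.0], x)

    def test_matches_anova_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 60)
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 8), size=n)
            r = factor_q(y, StratifiedVariable("x", labels))
            assert r.q == pytest.approx(anova_q_oracle(y, labels), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.1, 100), st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(9)
        y = rng.normal(size=30)
        labels = rng.integers(0, 4, size=30)
        x = StratifiedVariable("x", labels)
        q0 = factor_q(y, x).q
        q1 = factor_q(a * y + b, x).q
        assert q1 == pytest.approx(q0, abs=1e-9)

    def test_refining_a_stratification_never_decreases_q(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            y = rng.normal(size=40)
            labels = rng.integers(0, 4, size=40)
            q0 = factor_q(y, StratifiedVariable("x", labels)).q
            # split stratum 0 into two random halves
            refined = labels.astype(str).astype(object)
            idx = np.where(labels == 0)[0]
            half = rng.choice(idx, size=len(idx) // 2, replace=False)
            refined[half] = "0b"
            q1 = factor_q(y, StratifiedVariable("x", refined)).q
            assert q1 >= q0 - 1e-12

    def test_significance_is_probability(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=50)
        x = StratifiedVariable("x", rng.integers(0, 4, size=50))
        p = factor_q(y, x).significance()
        assert 0.0 <= p <= 1.0


class TestInteractionQ:
    def test_single_stratum_partner_never_enhances_nonlinearly(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        x1 = StratifiedVariable("x1", rng.integers(0, 3, size=30))
        x2 = StratifiedVariable("x2", np.zeros(30, dtype=int))
        r = interaction_q(y, x1, x2)
        assert r.q12 == pytest.approx(r.q1, abs=1e-12)
        assert r.category != "enhance_nonlinear"

    def test_self_interaction_exercises_weaken_branch(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30) + np.repeat([0, 2, 4], 10)
        x = StratifiedVariable("x", np.repeat([0, 1, 2], 10))
        r = interaction_q(y, x, x)
        assert r.q12 == pytest.approx(r.q1, abs=1e-12)
        assert r.category == "weaken_univariate"

    def test_pure_synergy_detected_as_nonlinear_enhancement(self):
        # 2x2 design, y = 1,2,3,9: joint strata explain everything while the
        # margins explain little -> q12 > q1 + q2 (verified by hand)
        y = np.array([1.0, 2.0, 3.0, 9.0] * 5)
        a = np.array([0, 0, 1, 1] * 5)
        b = np.array([0, 1, 0, 1] * 5)
        r = interaction_q(y, StratifiedVariable("a", a), StratifiedVariable("b", b))
        assert r.q12 == pytest.approx(1.0)
        assert r.q12 > r.q1 + r.q2
        assert r.category == "enhance_nonlinear"

    def test_overlay_never_below_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = rng.normal(size=50)
            x1 = StratifiedVariable("x1", rng.integers(0, 4, size=50))
            x2 = StratifiedVariable("x2", rng.integers(0, 4, size=50))
            r = interaction_q(y, x1, x2)
            assert r.q12 >= max(r.q1, r.q2) - 1e-12


class TestAssignPathways:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=[
            "element", "factory", "pathway_var", "q_factory", "q_pathway",
            "q12", "category"])

    def test_no_enhanced_pair_gives_empty_set(self):
        t = self._table([("Cd", "chemical_factory", "road", .3, .2, .4,
                          "enhance_bivariate")])
        assert assign_pathways(t) == {("Cd", "chemical_factory"): []}

    def test_single_enhanced_pair_gives_one_pathway(self):
        t = self._table([
            ("Cd", "chemical_factory", "road", .3, .1, .6, "enhance_nonlinear"),
            ("Cd", "chemical_factory", "river", .3, .1, .5, "enhance_bivariate"),
        ])
        assert assign_pathways(t) == {("Cd", "chemical_factory"): ["traffic_emission"]}

    def test_top_two_by_overlay_q(self):
        t = self._table([
            ("Cd", "chemical_factory", "road", .3, .1, .55, "enhance_nonlinear"),
            ("Cd", "chemical_factory", "river", .3, .1, .80, "enhance_nonlinear"),
            ("Cd", "chemical_factory", "deposition_Cd", .3, .1, .70,
             "enhance_nonlinear"),
            ("Cd", "chemical_factory", "altitude", .3, .1, .40,
             "enhance_nonlinear"),
        ])
        out = assign_pathways(t)
        assert out[("Cd", "chemical_factory")] == [
            "irrigation_water", "atmospheric_deposition"]
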