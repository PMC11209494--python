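import numpy as np
import pandas as pd
import pytest

from soilsource.datamodel import ValidationError, min_distances
from soilsource.enrichment import compute_enrichment
from soilsource.mlrd import (
    MLRDResults,
    SourceTerm,
    Transform,
    build_baseline_terms,
    build_terms,
    covariate_frame,
    fit_baseline_mlrd,
    pathway_effect_curve,
    quantify_contributions,
    split,
    stepwise_fit,
)
from soilsource.simulate import SimulationConfig, simulate
from conftest import true_pathway_map

ELEMENTS = ["Cd", "As", "Pb"]


@pytest.fixture(scope="module")
def prepared():
    """Simulated study with distances, enrichment and true candidate sets."""
    cfg = SimulationConfig(seed=3)
    st = simulate(cfg)
    dist = min_distances(st.samples, st.layers)
    enr = compute_enrichment(st.samples, st.background, ELEMENTS, "Mg")
    pm = true_pathway_map(cfg, ELEMENTS)
    return st, dist, enr, pm


class TestSplit:
    def test_109_sites_split_87_22(self):
        fit, test = split([f"s{i}" for i in range(109)], 0.8, seed=1)
        assert (len(fit), len(test)) == (87, 22)

    def test_ten_sites_split_8_2(self):
        fit, test = split(list(range(10)), 0.8, seed=0)
        assert (len(fit), len(test)) == (8, 2)

    def test_deterministic_and_disjoint_exhaustive(self):
        ids = list(range(50))
        a = split(ids, 0.8, seed=7)
        b = split(ids, 0.8, seed=7)
        assert a == b
        assert sorted(a[0] + a[1]) == ids

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValidationError):
            split([1, 2, 3], 0.8, seed=0)


class TestBuildTerms:
    def test_unassigned_source_falls_back_to_distance_only(self, prepared):
        st, dist, enr, _ = prepared
        pm = {("Cd", fac): [] for fac in
              ("chemical_factory", "metal_factory", "nonmetal_factory")}
        terms, _ = build_terms("Cd", pm, dist, st.samples)
        assert all(t.pathway is None for t in terms)

    def test_missing_element_warns_and_uses_all_pathways(self, prepared):
        st, dist, _, _ = prepared
        with pytest.warns(UserWarning, match="pathway map"):
            terms, _ = build_terms("Cd", {("As", "metal_factory"): []},
                                   dist, st.samples)
        pathways = {t.pathway for t in terms}
        assert {"traffic_emission", "irrigation_water",
                "atmospheric_deposition", "vertical_terrain"} <= pathways

    def test_assigned_pathways_shape_the_candidates(self, prepared):
        st, dist, _, _ = prepared
        pm = {("Cd", "nonmetal_factory"): ["atmospheric_deposition",
                                           "irrigation_water"],
              ("Cd", "chemical_factory"): [],
              ("Cd", "metal_factory"): []}
        terms, cov = build_terms("Cd", pm, dist, st.samples)
        nm = [t for t in terms if t.source == "nonmetal_factory"]
        assert {t.pathway for t in nm} == {"atmospheric_deposition",
                                           "irrigation_water"}
        # deposition covariate enters untransformed; river distance gets the grid
        dep = [t for t in nm if t.pathway == "atmospheric_deposition"]
        assert all(t.pathway_transform.kind == "identity" for t in dep)
        riv = [t for t in nm if t.pathway == "irrigation_water"]
        assert {t.pathway_transform.kind for t in riv} == {"power", "log", "identity"}

    def test_transform_labels_round_trip_values(self, prepared):
        st, dist, _, pm = prepared
        terms, cov = build_terms("Cd", pm, dist, st.samples)
        t = terms[0]
        v = t.values(cov)
        assert np.all(np.isfinite(v)) and len(v) == len(st.samples)


class TestStepwise:
    def test_exact_recovery_of_known_terms_without_noise(self, prepared):
        st, dist, _, _ = prepared
        cov = covariate_frame(st.samples, dist, "Cd")
        truth = [
            SourceTerm("chemical_factory", Transform("power", -1.5, 1.0),
                       "traffic_emission", "road", Transform("power", -0.5, 1.0)),
            SourceTerm("metal_factory", Transform("power", -1.0, 1.0),
                       "atmospheric_deposition", "deposition", Transform("identity")),
            SourceTerm("nonmetal_factory", Transform("log", offset=1.0)),
        ]
        coefs = np.array([5e4, 0.15, 0.02])
        X = np.column_stack([t.values(cov) for t in truth])
        y = pd.Series(X @ coefs, index=cov.index)
        pm = {("Cd", "chemical_factory"): ["traffic_emission"],
              ("Cd", "metal_factory"): ["atmospheric_deposition"],
              ("Cd", "nonmetal_factory"): []}
        cands, cov2 = build_terms("Cd", pm, dist, st.samples)
        res = stepwise_fit(y, cands, cov2, "Cd", split_seed=0)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-9)
        got = {t.name for t in res.terms}
        assert got == {t.name for t in truth}
        by_name = {t.name: t.coefficient for t in res.terms}
        for t, c in zip(truth, coefs):
            assert by_name[t.name] == pytest.approx(c, rel=1e-6)

    def test_pure_noise_rarely_accepted(self, prepared):
        st, dist, _, pm = prepared
        cands, cov = build_terms("Cd", pm, dist, st.samples)
        rng = np.random.default_rng(0)
        accepted = 0
        for s in range(20):
            y = pd.Series(rng.normal(size=len(cov)), index=cov.index)
            res = stepwise_fit(y, cands, cov, "Cd", split_seed=s)
            accepted += res.accepted
        assert accepted <= 1  # >= 95% flagged under the null

    def test_collinear_duplicate_enters_once(self, prepared):
        st, dist, _, _ = prepared
        cov = covariate_frame(st.samples, dist, "Cd")
        base = SourceTerm("chemical_factory", Transform("power", -1.0, 1.0))
        near = SourceTerm("chemical_factory", Transform("power", -1.0, 1.000001))
        rng = np.random.default_rng(1)
        y = pd.Series(3.0 * base.values(cov) + 1e-6 * rng.normal(size=len(cov)),
                      index=cov.index)
        res = stepwise_fit(y, [base, near], cov, "Cd", split_seed=0)
        assert len(res.terms) == 1

    def test_no_hidden_intercept(self, prepared):
        st, dist, enr, pm = prepared
        cands, cov = build_terms("Cd", pm, dist, st.samples)
        res = stepwise_fit(enr.excess_clipped["Cd"], cands, cov, "Cd",
                           split_seed=3)
        X = res.design_matrix().loc[res.fit_ids]
        beta = np.array([t.coefficient for t in res.terms])
        pred = res.predict().loc[res.fit_ids]
        assert np.allclose(pred.to_numpy(), X.to_numpy() @ beta, atol=1e-10)

    def test_statsmodels_refit_agrees_on_coefficients(self, prepared):
        st, dist, enr, pm = prepared
        cands, cov = build_terms("Cd", pm, dist, st.samples)
        res = stepwise_fit(enr.excess_clipped["Cd"], cands, cov, "Cd",
                           split_seed=3)
        if res.terms:
            np.testing.assert_allclose(
                res.ols_results.params.to_numpy(),
                [t.coefficient for t in res.terms], rtol=1e-6)


class TestContributions:
    def test_rows_sum_to_one_hundred(self, prepared):
        st, dist, enr, pm = prepared
        results = {}
        for e in ELEMENTS:
            cands, cov = build_terms(e, pm, dist, st.samples)
            results[e] = stepwise_fit(enr.excess_clipped[e], cands, cov, e,
                                      split_seed=3)
        table = quantify_contributions(results, enr)
        assert np.allclose(table.sum(axis=1), 100.0, atol=0.1)
        assert (table.to_numpy() >= 0).all()

    def test_zero_coefficients_give_pure_parent_material(self, prepared):
        st, dist, enr, pm = prepared
        cands, cov = build_terms("Cd", pm, dist, st.samples)
        res = stepwise_fit(enr.excess_clipped["Cd"], cands, cov, "Cd",
                          split_seed=3)
        zeroed = MLRDResults(
            element="Cd",
            terms=[],
            covariates=res.covariates, fit_ids=res.fit_ids,
            test_ids=res.test_ids, split_seed=3, fit_r2=np.nan,
            fit_r2_uncentered=np.nan, test_r2=np.nan, test_rmse=np.nan,
            accepted=False)
        table = quantify_contributions({"Cd": zeroed}, enr)
        assert table.loc["Cd", "parent_material"] == pytest.approx(100.0)

    def test_identical_sources_share_equally(self, prepared):
        st, dist, enr, _ = prepared
        cov = covariate_frame(st.samples, dist, "Cd")
        t1 = SourceTerm("chemical_factory", Transform("power", -1.0, 1.0),
                        coefficient=2.0)
        # same functional values assigned to a different source label
        cov2 = cov.copy()
        cov2["metal_factory"] = cov["chemical_factory"]
        t2 = SourceTerm("metal_factory", Transform("power", -1.0, 1.0),
                        coefficient=2.0)
        res = MLRDResults(
            element="Cd", terms=[t1, t2], covariates=cov2,
            fit_ids=list(cov.index[:87]), test_ids=list(cov.index[87:]),
            split_seed=0, fit_r2=1, fit_r2_uncentered=1, test_r2=1,
            test_rmse=0, accepted=True)
        table = quantify_contributions({"Cd": res}, enr)
        assert table.loc["Cd", "chemical_factory"] == pytest.approx(
            table.loc["Cd", "metal_factory"])


@pytest.fixture(scope="module")
def fitted(prepared):
    st, dist, enr, pm = prepared
    cands, cov = build_terms("Cd", pm, dist, st.samples)
    return stepwise_fit(enr.excess_clipped["Cd"], cands, cov, "Cd",
                        split_seed=3)


class TestEffectCurves:
    def test_unused_variable_rejected(self, fitted):
        used = {t.pathway_column for t in fitted.terms}
        unused = [v for v in ("road", "river", "deposition", "altitude")
                  if v not in used]
        if unused:
            with pytest.raises(ValidationError):
                pathway_effect_curve(fitted, unused[0])

    def test_finite_difference_matches_analytic_derivative(self, prepared):
        st, dist, _, _ = prepared
        cov = covariate_frame(st.samples, dist, "Cd")
        a, c = -1.5, 4.0e4
        term = SourceTerm("chemical_factory", Transform("power", -1.0, 1.0),
                          "traffic_emission", "road",
                          Transform("power", a, 1.0), coefficient=c)
        res = MLRDResults(
            element="Cd", terms=[term], covariates=cov,
            fit_ids=list(cov.index[:87]), test_ids=list(cov.index[87:]),
            split_seed=0, fit_r2=1, fit_r2_uncentered=1, test_r2=1,
            test_rmse=0, accepted=True)
        curve = pathway_effect_curve(res, "road",
                                     values=np.linspace(2000, 6000, 5))
        d_fac = float(cov["chemical_factory"].median())
        k = c * (d_fac + 1.0) ** -1.0
        # analytic increment of k*(d+1)^a over +1000 m
        d = curve["value"].to_numpy()
        exact = k * ((d + 1000 + 1.0) ** a - (d + 1.0) ** a)
        assert np.allclose(curve["increment_effect"], exact, rtol=1e-10)
        # decay term: prediction is monotone decreasing and flattens
        p = curve["prediction"].to_numpy()
        assert np.all(np.diff(p) < 0)
        assert np.all(np.diff(np.abs(curve["increment_effect"])) < 0)

    def test_power_decay_is_monotone(self, fitted):
        used = [t.pathway_column for t in fitted.terms
                if t.pathway_column in ("road", "river")]
        if used:
            curve = pathway_effect_curve(fitted, used[0])
            assert len(curve) == 50


class TestBaseline:
    def test_baseline_candidates_are_distance_only(self, prepared):
        st, dist, _, _ = prepared
        terms, _ = build_baseline_terms(dist, st.samples)
        assert all(t.pathway is None for t in terms)
        assert len({t.source for t in terms}) == 3

    def test_pathway_informed_model_beats_baseline_on_pathway_data(self, prepared):
        st, dist, enr, pm = prepared
        wins, total = 0, 0
        for e in ELEMENTS:
            cands, cov = build_terms(e, pm, dist, st.samples)
            rm = stepwise_fit(enr.excess_clipped[e], cands, cov, e, split_seed=3)
            rb = fit_baseline_mlrd(enr.excess_clipped[e], dist, st.samples, e,
                                   split_seed=3)
            wins += rm.test_r2 >= rb.test_r2 - 1e-9
            total += 1
        assert wins >= 2

    def test_empty_distance_set_rejected(self, prepared):
        st, _, enr, _ = prepared
        from soilsource.datamodel import DistanceSet

        empty = DistanceSet(pd.DataFrame(index=st.samples.data.index),
                            absent=list("abc"))
        with pytest.raises(ValidationError):
            fit_baseline_mlrd(enr.excess_clipped["Cd"], empty, st.samples)
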