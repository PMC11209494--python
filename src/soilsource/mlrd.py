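"""Distance-pathway multiple linear regression (modified PCA-MLRD).

The anthropogenic excess of an element is modelled, without intercept, as a
sum of source terms

    excess = sum_n  B_n * P_n * T(d_n)

where d_n is the shortest distance from a site to the nearest factory of
type n, T is a distance-decay transform (negative power or log), and P_n is
a pollution-pathway covariate assigned to that source: atmospheric
deposition flux, altitude, or a decay transform of the road/river distance.
The original distance-only formulation (no pathway covariates) is retained
as the baseline comparator.

Candidate terms are screened by forward stepwise selection with backward
elimination on a no-intercept linear model (enter p <= 0.05, remove
p >= 0.10, partial-F tests), fitted on a random 80% of sites and gated on
the held-out 20%: models with test R^2 <= 0.5 are flagged as rejected.
Distances receive a +1 m offset inside transforms so that a site lying on a
feature (d = 0) stays in the transform domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DistanceSet, FACTORY_CATEGORIES, SampleTable, ValidationError
from .enrichment import EnrichmentResult

__all__ = [
    "Transform",
    "SourceTerm",
    "covariate_frame",
    "build_terms",
    "build_baseline_terms",
    "split",
    "StepwiseMLRD",
    "MLRDResults",
    "stepwise_fit",
    "fit_baseline_mlrd",
    "quantify_contributions",
    "pathway_effect_curve",
    "DEFAULT_EXPONENTS",
]

DEFAULT_EXPONENTS = (-0.5, -1.0, -1.5, -2.0)
DISTANCE_OFFSET = 1.0  # meters; guards d = 0 inside log/negative powers

#: covariate-frame column used for each pathway name
PATHWAY_COLUMN = {
    "traffic_emission": "road",
    "irrigation_water": "river",
    "atmospheric_deposition": "deposition",
    "vertical_terrain": "altitude",
}
#: pathways whose covariate is itself a distance (and hence transformed)
DISTANCE_PATHWAYS = ("traffic_emission", "irrigation_water")


@dataclass(frozen=True)
class Transform:
    """A per-component transform: identity, log(d+delta) or (d+delta)^a."""

    kind: str  # "identity" | "log" | "power"
    exponent: float = 1.0
    offset: float = 0.0

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "identity":
            return v
        if self.kind == "log":
            return np.log(v + self.offset)
        if self.kind == "power":
            return (v + self.offset) ** self.exponent
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def label(self, var: str) -> str:
        if self.kind == "identity":
            return var
        if self.kind == "log":
            return f"log({var}+{self.offset:g})"
        return f"({var}+{self.offset:g})^{self.exponent:g}"


IDENTITY = Transform("identity")


def distance_transform_grid(
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    include_log: bool = True,
    include_identity: bool = True,
    offset: float = DISTANCE_OFFSET,
) -> list[Transform]:
    grid = [Transform("power", a, offset) for a in exponents]
    if include_log:
        grid.append(Transform("log", offset=offset))
    if include_identity:
        grid.append(IDENTITY)
    return grid


@dataclass(frozen=True)
class SourceTerm:
    """One candidate regressor: (pathway covariate) x (transformed source
    distance).  ``pathway`` is None for the distance-only baseline form."""

    source: str
    dist_transform: Transform
    pathway: str | None = None
    pathway_column: str | None = None
    pathway_transform: Transform | None = None
    coefficient: float | None = None

    @property
    def name(self) -> str:
        d = self.dist_transform.label(f"S[{self.source}]")
        if self.pathway is None:
            return d
        p = self.pathway_transform.label(self.pathway_column)
        return f"{p}*{d}"

    def values(self, cov: pd.DataFrame) -> np.ndarray:
        out = self.dist_transform(cov[self.source].to_numpy(float))
        if self.pathway is not None:
            out = out * self.pathway_transform(
                cov[self.pathway_column].to_numpy(float)
            )
        return out


def covariate_frame(
    samples: SampleTable, distances: DistanceSet, element: str | None = None
) -> pd.DataFrame:
    """Raw covariates per site: factory/road/river distances, altitude and —
    when ``element`` is given and measured — that element's deposition flux
    under the column name ``deposition``."""
    cols: dict[str, pd.Series] = {}
    for cat in distances.categories:
        name = "road" if cat == "road" else "river" if cat == "river" else cat
        cols[name] = distances[cat]
    cols["altitude"] = samples.data["altitude"]
    if element is not None and f"AD_{element}" in samples.data.columns:
        cols["deposition"] = samples.data[f"AD_{element}"]
    return pd.DataFrame(cols, index=samples.data.index)


def _pathway_components(
    pathway: str, cov: pd.DataFrame, grid: list[Transform]
) -> list[tuple[str, Transform]]:
    col = PATHWAY_COLUMN[pathway]
    if col not in cov.columns:
        return []
    if pathway in DISTANCE_PATHWAYS:
        return [(col, t) for t in grid]
    return [(col, IDENTITY)]


def build_terms(
    element: str,
    pathway_map: Mapping[tuple[str, str], list[str]] | None,
    distances: DistanceSet,
    samples: SampleTable,
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    include_log: bool = True,
    include_identity: bool = True,
) -> tuple[list[SourceTerm], pd.DataFrame]:
    """Candidate terms for one element, plus the covariate frame.

    For each factory type with features, one candidate per assigned pathway
    and per transform combination; a source with no assigned pathway falls
    back to distance-only candidates.  An element missing from the pathway
    map entirely gets all-pathway candidates, with a warning.
    """
    cov = covariate_frame(samples, distances, element)
    grid = distance_transform_grid(exponents, include_log, include_identity)
    factories = [c for c in FACTORY_CATEGORIES if c in distances.categories]
    if not factories:
        raise ValidationError("no factory category has features")
    all_pathways = [
        p for p, col in PATHWAY_COLUMN.items() if col in cov.columns
    ]
    terms: list[SourceTerm] = []
    for fac in factories:
        if pathway_map is None or (element, fac) not in pathway_map:
            if pathway_map is not None:
                warnings.warn(
                    f"no pathway map for ({element}, {fac}); "
                    "using all-pathway candidates",
                    stacklevel=2,
                )
            pathways = all_pathways
        else:
            pathways = pathway_map[(element, fac)]
        if not pathways:  # distance-only baseline form
            terms.extend(SourceTerm(fac, t) for t in grid)
            continue
        for pw in pathways:
            for col, pt in _pathway_components(pw, cov, grid):
                for dt in grid:
                    terms.append(SourceTerm(fac, dt, pw, col, pt))
    return terms, cov


def build_baseline_terms(
    distances: DistanceSet,
    samples: SampleTable,
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    include_log: bool = True,
    include_identity: bool = True,
) -> tuple[list[SourceTerm], pd.DataFrame]:
    """Distance-only candidates (original PCA-MLRD comparator)."""
    cov = covariate_frame(samples, distances)
    grid = distance_transform_grid(exponents, include_log, include_identity)
    factories = [c for c in FACTORY_CATEGORIES if c in distances.categories]
    if not factories:
        raise ValidationError("no factory category has features")
    return [SourceTerm(f, t) for f in factories for t in grid], cov


def split(site_ids: Sequence, fraction: float = 0.8, seed: int = 0
          ) -> tuple[list, list]:
    """Seeded uniform random fit/test split; fit size = floor(fraction*n)."""
    ids = list(site_ids)
    n = len(ids)
    if n < 5:
        raise ValidationError("need at least 5 sites to split")
    n_fit = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fit = [ids[i] for i in sorted(perm[:n_fit])]
    test = [ids[i] for i in sorted(perm[n_fit:])]
    return fit, test


# ---------------------------------------------------------------------------
# stepwise machinery


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


@dataclass
class MLRDResults:
    """Fitted apportionment regression for one element.

    ``accepted`` is False when the held-out R^2 fails the > 0.5 gate or no
    term entered; a rejected model still carries its diagnostics.
    """

    element: str
    terms: list[SourceTerm]
    covariates: pd.DataFrame
    fit_ids: list
    test_ids: list
    split_seed: int
    fit_r2: float
    fit_r2_uncentered: float
    test_r2: float
    test_rmse: float
    accepted: bool
    r2_gate: float = 0.5
    ols_results: object | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {t.name: t.coefficient for t in self.terms}, dtype=float
        )

    def design_matrix(self, cov: pd.DataFrame | None = None) -> pd.DataFrame:
        cov = self.covariates if cov is None else cov
        return pd.DataFrame(
            {t.name: t.values(cov) for t in self.terms}, index=cov.index
        )

    def predict(self, cov: pd.DataFrame | None = None) -> pd.Series:
        cov = self.covariates if cov is None else cov
        if not self.terms:
            return pd.Series(0.0, index=cov.index)
        X = self.design_matrix(cov)
        beta = np.array([t.coefficient for t in self.terms])
        return pd.Series(X.to_numpy() @ beta, index=cov.index)

    def source_values(self, cov: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-site predicted input per factory type (term values summed per
        source, negatives clipped at 0 — contributions are shares of
        cumulative input)."""
        cov = self.covariates if cov is None else cov
        out = pd.DataFrame(0.0, index=cov.index,
                           columns=list(FACTORY_CATEGORIES))
        for t in self.terms:
            out[t.source] += np.clip(t.coefficient * t.values(cov), 0.0, None)
        return out

    def summary(self) -> str:
        lines = [
            f"Apportionment regression: {self.element}",
            f"  sites: {len(self.fit_ids)} fit / {len(self.test_ids)} test "
            f"(split seed {self.split_seed})",
            f"  fit R2 = {self.fit_r2:.3f}  (uncentered {self.fit_r2_uncentered:.3f})",
            f"  test R2 = {self.test_r2:.3f}, test RMSE = {self.test_rmse:.4g}",
            f"  gate test R2 > {self.r2_gate}: "
            + ("ACCEPTED" if self.accepted else "REJECTED"),
            "  terms:",
        ]
        for t in self.terms:
            lines.append(f"    {t.coefficient: .6g} * {t.name}")
        if not self.terms:
            lines.append("    (none entered)")
        return "\n".join(lines)


class StepwiseMLRD:
    """No-intercept stepwise regression over candidate source terms.

    Parameters
    ----------
    y : per-site response (anthropogenic excess, mg/kg), indexed by site.
    candidates : candidate :class:`SourceTerm` list.
    covariates : raw covariate frame (see :func:`covariate_frame`).
    alpha_enter, alpha_remove : partial-F p-value thresholds (0.05 / 0.10).

    At most one term per (source, pathway-column) pair is retained, which is
    the collinearity guard the transform grid requires.
    """

    def __init__(
        self,
        y: pd.Series,
        candidates: Sequence[SourceTerm],
        covariates: pd.DataFrame,
        element: str = "y",
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.10,
    ) -> None:
        if len(candidates) < 2:
            raise ValidationError("need at least 2 candidate terms")
        self.y = y
        self.candidates = list(candidates)
        self.covariates = covariates.loc[y.index]
        self.element = element
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    def fit(self, split_seed: int = 0, fraction: float = 0.8,
            r2_gate: float = 0.5, max_steps: int = 100) -> MLRDResults:
        fit_ids, test_ids = split(list(self.y.index), fraction, split_seed)
        yf = self.y.loc[fit_ids].to_numpy(float)
        yt = self.y.loc[test_ids].to_numpy(float)
        Xall = np.column_stack(
            [t.values(self.covariates) for t in self.candidates]
        )
        fit_rows = self.y.index.get_indexer(fit_ids)
        test_rows = self.y.index.get_indexer(test_ids)
        Xf, Xt = Xall[fit_rows], Xall[test_rows]
        # unit-RMS column scaling for conditioning; coefficients unscaled later
        scale = np.sqrt((Xf ** 2).mean(axis=0))
        usable = scale > 0
        scale[~usable] = 1.0
        Xf = Xf / scale
        Xt = Xt / scale
        pairs = [(t.source, t.pathway_column) for t in self.candidates]

        sst_unc = float(yf @ yf)
        n = len(yf)
        m = len(self.candidates)
        G = Xf.T @ Xf
        bvec = Xf.T @ yf
        diagG = np.diag(G).copy()

        def sse_of(sel: list[int]) -> float:
            if not sel:
                return sst_unc
            Gs = G[np.ix_(sel, sel)]
            beta, *_ = np.linalg.lstsq(Gs, bvec[sel], rcond=None)
            return max(sst_unc - float(bvec[sel] @ beta), 0.0)

        def gains(sel: list[int]) -> np.ndarray:
            """SSE decrease from adding each candidate to ``sel``."""
            if not sel:
                denom = diagG.copy()
                numer = bvec.copy()
            else:
                Gs = G[np.ix_(sel, sel)]
                Gsa = G[np.ix_(sel, range(m))]
                W, *_ = np.linalg.lstsq(Gs, Gsa, rcond=None)
                beta, *_ = np.linalg.lstsq(Gs, bvec[sel], rcond=None)
                denom = diagG - np.einsum("km,km->m", Gsa, W)
                numer = bvec - beta @ Gsa
            out = np.zeros(m)
            ok = usable & (denom > 1e-10 * np.maximum(diagG, 1e-300))
            out[ok] = numer[ok] ** 2 / denom[ok]
            return out

        def forward(sel: list[int]) -> bool:
            df = n - len(sel) - 1
            if df <= 0:
                return False
            sse_now = sse_of(sel)
            g = gains(sel)
            used_pairs = {pairs[i] for i in sel}
            for j in sel:
                g[j] = -np.inf
            for j in range(m):
                if pairs[j] in used_pairs:
                    g[j] = -np.inf
            best_j = int(np.argmax(g))
            if not np.isfinite(g[best_j]) or g[best_j] <= 0:
                return False
            sse_j = max(sse_now - g[best_j], 0.0)
            F = g[best_j] / max(sse_j / df, 1e-300)
            if float(stats.f.sf(F, 1, df)) > self.alpha_enter:
                return False
            sel.append(best_j)
            return True

        def backward(sel: list[int]) -> bool:
            removed_any = False
            while len(sel) > 1:
                sse_full = sse_of(sel)
                df = n - len(sel)
                if df <= 0:
                    break
                worst_p, worst_i = -1.0, -1
                for i in sel:
                    sse_rest = sse_of([j for j in sel if j != i])
                    F = max(sse_rest - sse_full, 0.0) / max(sse_full / df, 1e-300)
                    p = float(stats.f.sf(F, 1, df))
                    if p > worst_p:
                        worst_p, worst_i = p, i
                if worst_p >= self.alpha_remove:
                    sel.remove(worst_i)
                    removed_any = True
                else:
                    break
            return removed_any

        def refine(sel: list[int]) -> bool:
            """Within-pair transform substitution (coordinate descent)."""
            any_change = True
            changed = False
            while any_change:
                any_change = False
                for pos in range(len(sel)):
                    i = sel[pos]
                    rest = sel[:pos] + sel[pos + 1:]
                    g = gains(rest)
                    mask = np.array([pairs[j] == pairs[i] and j not in rest
                                     for j in range(m)])
                    if not mask.any():
                        continue
                    cand = np.where(mask)[0]
                    best = cand[np.argmax(g[cand])]
                    if best != i and g[best] > g[i] * (1 + 1e-10):
                        sel[pos] = best
                        any_change = changed = True
            return changed

        def refine_joint(sel: list[int]) -> bool:
            """Two-pair joint substitution, to escape single-swap optima."""
            base = sse_of(sel)
            for p1 in range(len(sel)):
                for p2 in range(p1 + 1, len(sel)):
                    rest = [sel[t] for t in range(len(sel))
                            if t not in (p1, p2)]
                    var1 = [j for j in range(m)
                            if pairs[j] == pairs[sel[p1]] and j not in rest
                            and usable[j]]
                    mask2 = np.array([pairs[j] == pairs[sel[p2]]
                                      and j not in rest for j in range(m)])
                    for j1 in var1:
                        g = gains(rest + [j1])
                        mask2j = mask2.copy()
                        mask2j[j1] = False
                        if not mask2j.any():
                            continue
                        cand = np.where(mask2j)[0]
                        j2 = cand[np.argmax(g[cand])]
                        sse_j = sse_of(rest + [j1, int(j2)])
                        if sse_j < base * (1 - 1e-9):
                            sel[p1], sel[p2] = j1, int(j2)
                            return True
            return False

        selected: list[int] = []
        for _ in range(max_steps):
            entered = forward(selected)
            swapped = refine(selected) if selected else False
            if not entered and not swapped and len(selected) > 1:
                if refine_joint(selected):
                    swapped = refine(selected) or True
            removed = backward(selected)
            if sse_of(selected) <= 1e-12 * sst_unc:  # numerically exact
                refine(selected)
                break
            if not (entered or swapped or removed):
                break
        if selected:
            beta_s, sse_cur = _sse(Xf[:, selected], yf)
            beta = beta_s / scale[selected]
        else:
            beta, sse_cur = np.array([]), sst_unc
        terms = [
            replace(self.candidates[i], coefficient=float(b))
            for i, b in zip(selected, beta)
        ]
        sst_c = float(((yf - yf.mean()) ** 2).sum())
        fit_r2 = 1.0 - sse_cur / sst_c if sst_c > 0 else np.nan
        fit_r2_unc = 1.0 - sse_cur / sst_unc if sst_unc > 0 else np.nan
        if selected:
            pred_t = Xt[:, selected] @ beta_s
        else:
            pred_t = np.zeros_like(yt)
        sse_t = float(((yt - pred_t) ** 2).sum())
        sst_t = float(((yt - yt.mean()) ** 2).sum())
        test_r2 = 1.0 - sse_t / sst_t if sst_t > 0 else np.nan
        rmse = float(np.sqrt(sse_t / len(yt)))
        accepted = bool(terms) and np.isfinite(test_r2) and test_r2 > r2_gate
        if not terms:
            warnings.warn(
                f"no candidate term entered for {self.element}; model flagged",
                stacklevel=2,
            )
        ols = None
        if terms:
            import statsmodels.api as sm

            Xsel = pd.DataFrame(
                {t.name: t.values(self.covariates.loc[fit_ids])
                 for t in terms},
                index=fit_ids,
            )
            ols = sm.OLS(yf, Xsel, hasconst=False).fit()
        return MLRDResults(
            element=self.element,
            terms=terms,
            covariates=self.covariates,
            fit_ids=fit_ids,
            test_ids=test_ids,
            split_seed=split_seed,
            fit_r2=fit_r2,
            fit_r2_uncentered=fit_r2_unc,
            test_r2=test_r2,
            test_rmse=rmse,
            accepted=accepted,
            r2_gate=r2_gate,
            ols_results=ols,
        )


def stepwise_fit(
    y: pd.Series,
    candidates: Sequence[SourceTerm],
    covariates: pd.DataFrame,
    element: str = "y",
    split_seed: int = 0,
    **kwargs,
) -> MLRDResults:
    """Functional wrapper around :class:`StepwiseMLRD`."""
    fit_kwargs = {
        k: kwargs.pop(k) for k in ("fraction", "r2_gate", "max_steps")
        if k in kwargs
    }
    model = StepwiseMLRD(y, candidates, covariates, element, **kwargs)
    return model.fit(split_seed=split_seed, **fit_kwargs)


def fit_baseline_mlrd(
    y: pd.Series,
    distances: DistanceSet,
    samples: SampleTable,
    element: str = "y",
    split_seed: int = 0,
    **kwargs,
) -> MLRDResults:
    """Original distance-only PCA-MLRD comparator fit."""
    terms, cov = build_baseline_terms(distances, samples)
    return stepwise_fit(y, terms, cov, element, split_seed=split_seed, **kwargs)


def quantify_contributions(
    results: Mapping[str, MLRDResults],
    natural: EnrichmentResult,
) -> pd.DataFrame:
    """Percentage contribution of each factory-type source and of soil
    parent material, per element; rows sum to 100."""
    rows = {}
    for element, res in results.items():
        src = res.source_values().sum(axis=0)  # per source, clipped per site
        nat = float(natural.natural_part[element].clip(lower=0.0).sum())
        total = float(src.sum()) + nat
        if total <= 0:
            raise ValidationError(f"all-zero contributions for {element}")
        row = {f"{s}": 100.0 * v / total for s, v in src.items()}
        row["parent_material"] = 100.0 * nat / total
        rows[element] = row
    out = pd.DataFrame(rows).T
    out.index.name = "element"
    return out


_INCREMENT = {"road": 1000.0, "river": 1000.0, "deposition": 0.1,
              "altitude": 1.0}


def pathway_effect_curve(
    results: MLRDResults,
    variable: str,
    values: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Marginal effect of one pathway variable, other inputs at medians.

    Returns (value, prediction, increment_effect) where increment_effect is
    the finite-difference change in predicted excess per standard increment
    (1000 m for distances, 0.1 ug/m2/day for deposition, 1 m for altitude).
    """
    if variable not in _INCREMENT:
        raise ValidationError(f"unknown pathway variable {variable!r}")
    used = {t.pathway_column for t in results.terms}
    if variable not in used:
        raise ValidationError(
            f"variable {variable!r} is absent from the fitted model"
        )
    cov = results.covariates
    if values is None:
        lo, hi = cov[variable].min(), cov[variable].max()
        values = np.linspace(lo, hi, n_points)
    med = cov.median()
    frame = pd.DataFrame(
        {c: np.full(len(values), med[c]) for c in cov.columns}
    )
    frame[variable] = values
    pred = results.predict(frame).to_numpy()
    inc = _INCREMENT[variable]
    frame_up = frame.copy()
    frame_up[variable] = frame[variable] + inc
    effect = results.predict(frame_up).to_numpy() - pred
    return pd.DataFrame(
        {"value": values, "prediction": pred, "increment_effect": effect}
    )
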