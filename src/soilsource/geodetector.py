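"""Spatial stratified-heterogeneity analysis (GeoDetector style).

The factor detector measures how much of the spatial variance of a response
y is explained by a categorical stratification X of the sites:

    q = 1 - sum_h N_h * var_h / (N * var)

with population (divide-by-N) variances, so that q = 1 - SSW/SST exactly and
q is in [0, 1].  The interaction detector computes q on the overlay
(cross-classification) of two stratifications and classifies the pair:

    q12 > q1 + q2            -> enhance_nonlinear
    q12 = q1 + q2            -> independent
    max(q1,q2) < q12 <= q1+q2 -> enhance_bivariate
    min <= q12 <= max         -> weaken_univariate
    q12 < min(q1,q2)          -> weaken_nonlinear

Continuous explanatory variables are discretized first: distances by equal
200-m intervals, elevation and atmospheric deposition into 10 classes by
Jenks natural breaks.  Pollution pathways are then assigned per
(element, factory type): the up-to-two pathway variables whose interaction
with the factory-distance stratification is nonlinearly enhancing, ranked by
q12.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DistanceSet, SampleTable, ValidationError

__all__ = [
    "StratifiedVariable",
    "QResult",
    "InteractionResult",
    "discretize_equal_interval",
    "discretize_natural_breaks",
    "factor_q",
    "interaction_q",
    "pathway_interactions",
    "assign_pathways",
    "PATHWAY_OF_VARIABLE",
]

#: pathway interpretation of each explanatory variable
PATHWAY_OF_VARIABLE = {
    "road": "traffic_emission",
    "river": "irrigation_water",
    "deposition": "atmospheric_deposition",
    "altitude": "vertical_terrain",
}


@dataclass
class StratifiedVariable:
    """A categorical stratification of the sites."""

    name: str
    labels: np.ndarray  # one stratum label per site
    method: str = "categorical"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size == 0:
            raise ValidationError("stratification with zero sites")

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class QResult:
    variable: str
    dependent: str
    q: float
    strata_counts: dict
    strata_variances: dict
    n_total: int
    var_total: float
    n_singleton_strata: int = 0
    strata_means: dict = field(default_factory=dict)

    def significance(self) -> float:
        """Asymptotic p-value of q via the noncentral-F approximation
        (diagnostic only; no gate is applied downstream)."""
        L = len(self.strata_counts)
        N = self.n_total
        if L < 2 or N - L <= 0 or self.q >= 1.0 or self.var_total == 0:
            return np.nan
        F = (N - L) / (L - 1) * self.q / (1 - self.q)
        counts = np.array(list(self.strata_counts.values()), float)
        means = np.array([self.strata_means[k] for k in self.strata_counts], float)
        ncp = (
            (means ** 2).sum() - (np.sqrt(counts) * means).sum() ** 2 / N
        ) / self.var_total
        return float(stats.ncf.sf(F, L - 1, N - L, max(ncp, 0.0)))


@dataclass
class InteractionResult:
    x1: str
    x2: str
    q1: float
    q2: float
    q12: float
    category: str


def discretize_equal_interval(values, width: float = 200.0,
                              name: str = "distance") -> StratifiedVariable:
    """Half-open equal-width bins: stratum k covers [k*width, (k+1)*width)."""
    if width <= 0:
        raise ValidationError("interval width must be > 0")
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all() or (v < 0).any():
        raise ValidationError("values must be finite and >= 0")
    labels = np.floor(v / width).astype(int)
    return StratifiedVariable(name, labels, "equal_interval", {"width": width})


def _jenks_matrix(u: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    """DP for Fisher-Jenks optimal 1-D classification.

    Operates on sorted *unique* values ``u`` with multiplicities ``w`` so
    that tied observations always share a class.  cost(i, j) = min SSD of
    the first i unique values in j classes; prefix sums give O(1) segment
    SSD.  Returns the k class start-indices into ``u``.
    """
    n = len(u)
    csw = np.concatenate([[0.0], np.cumsum(w)])
    csum = np.concatenate([[0.0], np.cumsum(w * u)])
    csum2 = np.concatenate([[0.0], np.cumsum(w * u * u)])

    def ssd(a: int, b: int) -> float:  # unique values u[a:b]
        m = csw[b] - csw[a]
        s = csum[b] - csum[a]
        return (csum2[b] - csum2[a]) - s * s / m

    INF = np.inf
    cost = np.full((n + 1, k + 1), INF)
    back = np.zeros((n + 1, k + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best, arg = INF, j - 1
            for t in range(j - 1, i):
                c = cost[t, j - 1] + ssd(t, i)
                if c < best:
                    best, arg = c, t
            cost[i, j] = best
            back[i, j] = arg
    # recover class start indices
    breaks = []
    i = n
    for j in range(k, 0, -1):
        t = back[i, j]
        breaks.append(t)
        i = t
    return np.array(breaks[::-1])  # k start indices, first is 0


def discretize_natural_breaks(values, k: int = 10,
                              name: str = "covariate") -> StratifiedVariable:
    """Jenks/Fisher optimal natural-breaks classification into k classes.

    Minimizes the total within-class sum of squared deviations; deterministic
    for fixed input.  If fewer than k distinct values exist, k is reduced to
    the distinct count with a warning.
    """
    if k < 2:
        raise ValidationError("natural breaks need k >= 2")
    v = np.asarray(values, dtype=float)
    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) < k:
        warnings.warn(
            f"only {len(uniq)} distinct values; k reduced from {k}",
            stacklevel=2,
        )
        k = max(len(uniq), 1)
    starts = _jenks_matrix(uniq, counts.astype(float), k)
    # class of each unique value, then broadcast to observations
    cls_uniq = np.zeros(len(uniq), dtype=int)
    for c, s in enumerate(starts):
        cls_uniq[s:] = c
    labels = cls_uniq[np.searchsorted(uniq, v)]
    return StratifiedVariable(name, labels, "natural_breaks", {"k": k})


def _q_from_labels(y: np.ndarray, labels: np.ndarray, variable: str,
                   dependent: str) -> QResult:
    n = len(y)
    if n < 2:
        raise ValidationError("q-statistic needs >= 2 sites")
    var_total = float(np.var(y))  # population variance
    if var_total == 0:
        raise ValidationError("dependent variable is constant; q undefined")
    counts, variances, means = {}, {}, {}
    ssw = 0.0
    singletons = 0
    for lab in np.unique(labels):
        sub = y[labels == lab]
        counts[lab] = len(sub)
        variances[lab] = float(np.var(sub))  # 0 for singleton strata
        means[lab] = float(np.mean(sub))
        if len(sub) == 1:
            singletons += 1
        ssw += len(sub) * variances[lab]
    q = 1.0 - ssw / (n * var_total)
    return QResult(variable, dependent, float(q), counts, variances, n,
                   var_total, singletons, means)


def factor_q(y, x: StratifiedVariable, dependent: str = "y") -> QResult:
    """Factor detector: q = 1 - SSW/SST for response y under stratification x."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(x.labels):
        raise ValidationError("y and stratification lengths differ")
    return _q_from_labels(y, x.labels, x.name, dependent)


def _classify(q1: float, q2: float, q12: float, tol: float = 1e-12) -> str:
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "enhance_nonlinear"
    if q12 > max(q1, q2) + tol:
        return "enhance_bivariate"
    if q12 >= min(q1, q2) - tol:
        return "weaken_univariate"
    return "weaken_nonlinear"


def interaction_q(y, x1: StratifiedVariable, x2: StratifiedVariable,
                  dependent: str = "y") -> InteractionResult:
    """Interaction detector: q of the overlay (ordered label pairs) of x1, x2."""
    y = np.asarray(y, dtype=float)
    q1 = factor_q(y, x1, dependent).q
    q2 = factor_q(y, x2, dependent).q
    overlay = np.array(
        [f"{a}|{b}" for a, b in zip(x1.labels, x2.labels)], dtype=object
    )
    q12 = _q_from_labels(y, overlay, f"{x1.name}*{x2.name}", dependent).q
    return InteractionResult(x1.name, x2.name, q1, q2, q12,
                             _classify(q1, q2, q12))


# ---------------------------------------------------------------------------
# pathway assignment

_FACTORY_VAR = {
    "chemical_factory": "chemical_factory",
    "metal_factory": "metal_factory",
    "nonmetal_factory": "nonmetal_factory",
}


def build_stratifications(
    samples: SampleTable,
    distances: DistanceSet,
    elements: list[str],
    interval_width: float = 200.0,
    n_breaks: int = 10,
) -> dict[str, StratifiedVariable]:
    """Standard stratification set: distances on 200-m equal intervals;
    altitude and per-element deposition on 10-class natural breaks."""
    out: dict[str, StratifiedVariable] = {}
    for cat in distances.categories:
        out[cat] = discretize_equal_interval(
            distances[cat].to_numpy(float), interval_width, name=cat
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["altitude"] = discretize_natural_breaks(
            samples.data["altitude"].to_numpy(float), n_breaks, name="altitude"
        )
        for e in elements:
            col = f"AD_{e}"
            if col in samples.data.columns:
                out[f"deposition_{e}"] = discretize_natural_breaks(
                    samples.data[col].to_numpy(float), n_breaks,
                    name=f"deposition_{e}",
                )
    return out


def pathway_interactions(
    y_by_element: pd.DataFrame,
    strat: dict[str, StratifiedVariable],
    factory_categories: list[str] | None = None,
) -> pd.DataFrame:
    """Interaction results for every (element, factory type, pathway variable).

    ``y_by_element`` holds the dependent variable per element (by default the
    anthropogenic excess).  Pathway variables are road/river distances,
    altitude, and the element's own deposition.  Long-format output with
    columns element, factory, pathway_var, q_factory, q_pathway, q12,
    category.
    """
    factory_categories = factory_categories or [
        c for c in _FACTORY_VAR if c in strat
    ]
    rows = []
    for e in y_by_element.columns:
        y = y_by_element[e].to_numpy(float)
        pathway_vars = [v for v in ("road", "river", "altitude") if v in strat]
        if f"deposition_{e}" in strat:
            pathway_vars.append(f"deposition_{e}")
        for fac, pv in itertools.product(factory_categories, pathway_vars):
            res = interaction_q(y, strat[fac], strat[pv], dependent=e)
            rows.append(
                {
                    "element": e,
                    "factory": fac,
                    "pathway_var": pv,
                    "q_factory": res.q1,
                    "q_pathway": res.q2,
                    "q12": res.q12,
                    "category": res.category,
                }
            )
    return pd.DataFrame(rows)


def assign_pathways(interactions: pd.DataFrame, max_pathways: int = 2
                    ) -> dict[tuple[str, str], list[str]]:
    """Per (element, factory type): the up-to-``max_pathways`` pathway
    variables whose interaction with the factory distance is nonlinearly
    enhancing, ranked by overlay q.  Variables map to pathways via
    :data:`PATHWAY_OF_VARIABLE` (deposition_<el> -> atmospheric_deposition).
    An empty list means no pathway was detected for that pair."""
    out: dict[tuple[str, str], list[str]] = {}
    for (e, fac), grp in interactions.groupby(["element", "factory"], sort=False):
        enh = grp[grp["category"] == "enhance_nonlinear"]
        enh = enh.sort_values("q12", ascending=False).head(max_pathways)
        names = []
        for v in enh["pathway_var"]:
            key = "deposition" if v.startswith("deposition") else v
            names.append(PATHWAY_OF_VARIABLE.get(key, key))
        out[(e, fac)] = names
    return out
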