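"""End-to-end source apportionment: model and results objects.

:class:`SourceApportionment` bundles the data (sample table, feature layers,
background table) and configuration; :meth:`SourceApportionment.fit` runs
the chain

    enrichment -> (grouped) PCA -> GeoDetector pathway assignment ->
    stepwise distance-pathway regression -> contribution quantification

and returns a :class:`SourceApportionmentResults` carrying every
intermediate product, per-element regression diagnostics, the contribution
table, and a text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geodetector as gd
from .datamodel import (
    BackgroundTable,
    DistanceSet,
    FACTORY_CATEGORIES,
    FeatureLayer,
    SampleTable,
    describe,
    min_distances,
)
from .enrichment import EnrichmentResult, compute_enrichment
from .gpca import FactorModel, detect_mixed_factor, fit_pca, group_decompose
from .mlrd import (
    DEFAULT_EXPONENTS,
    MLRDResults,
    build_baseline_terms,
    build_terms,
    quantify_contributions,
    stepwise_fit,
)

__all__ = ["SourceApportionment", "SourceApportionmentResults",
           "contribution_ranges"]


class SourceApportionment:
    """Source-apportionment model for a set of soil samples.

    Parameters
    ----------
    samples : validated sample table (concentrations, coordinates,
        altitude, optional deposition columns).
    layers : feature layers by category (factories, roads, rivers).
    background : background / risk-screening table.
    elements : elements to apportion (default Cd, As, Pb).
    reference : crustal reference element(s); a sequence averages the
        per-reference excesses (two-reference variant).
    pca_elements : elements entering the factor analysis (default: all
        measured).
    """

    def __init__(
        self,
        samples: SampleTable,
        layers: Mapping[str, FeatureLayer] | Sequence[FeatureLayer],
        background: BackgroundTable,
        elements: Sequence[str] = ("Cd", "As", "Pb"),
        reference: str | Sequence[str] = "Mg",
        pca_elements: Sequence[str] | None = None,
        loading_threshold: float = 0.7,
        max_factor_elements: int = 3,
        interval_width: float = 200.0,
        n_breaks: int = 10,
        exponents: Sequence[float] = DEFAULT_EXPONENTS,
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.10,
        r2_gate: float = 0.5,
        split_fraction: float = 0.8,
    ) -> None:
        self.samples = samples
        if not isinstance(layers, Mapping):
            layers = {lyr.category: lyr for lyr in layers}
        self.layers = dict(layers)
        self.background = background
        self.elements = list(elements)
        self.reference = reference
        self.pca_elements = list(pca_elements or samples.elements)
        self.loading_threshold = loading_threshold
        self.max_factor_elements = max_factor_elements
        self.interval_width = interval_width
        self.n_breaks = n_breaks
        self.exponents = tuple(exponents)
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.r2_gate = r2_gate
        self.split_fraction = split_fraction

    # -- pipeline stages (usable individually) ---------------------------

    def compute_distances(self) -> DistanceSet:
        return min_distances(self.samples, self.layers)

    def compute_enrichment(self) -> EnrichmentResult:
        return compute_enrichment(
            self.samples, self.background, self.elements, self.reference
        )

    def compute_factors(self) -> FactorModel:
        model = fit_pca(self.samples, self.pca_elements,
                        threshold=self.loading_threshold)
        for fac in detect_mixed_factor(model, self.max_factor_elements):
            try:
                model = group_decompose(self.samples, model, fac,
                                        self.max_factor_elements)
            except Exception as exc:  # rejection keeps the parent factor
                warnings.warn(f"decomposition of {fac} failed: {exc}",
                              stacklevel=2)
        return model

    def fit(self, seed: int = 0) -> "SourceApportionmentResults":
        """Run the full chain.  ``seed`` drives the fit/test split."""
        distances = self.compute_distances()
        enrich = self.compute_enrichment()
        factors = self.compute_factors()

        strat = gd.build_stratifications(
            self.samples, distances, self.elements,
            self.interval_width, self.n_breaks,
        )
        # source identification: q of each factory distance on each factor
        q_rows = []
        leaf_scores = factors.leaf_scores()
        for f in leaf_scores.columns:
            for cat in FACTORY_CATEGORIES:
                if cat in strat:
                    q = gd.factor_q(leaf_scores[f].to_numpy(), strat[cat],
                                    dependent=f)
                    q_rows.append({"factor": f, "variable": cat, "q": q.q})
        q_sources = pd.DataFrame(q_rows)

        interactions = gd.pathway_interactions(enrich.excess_clipped, strat)
        pathway_map = gd.assign_pathways(interactions)

        models: dict[str, MLRDResults] = {}
        baselines: dict[str, MLRDResults] = {}
        for e in self.elements:
            terms, cov = build_terms(
                e, pathway_map, distances, self.samples, self.exponents
            )
            y = enrich.excess_clipped[e]
            models[e] = stepwise_fit(
                y, terms, cov, element=e, split_seed=seed,
                alpha_enter=self.alpha_enter, alpha_remove=self.alpha_remove,
                fraction=self.split_fraction, r2_gate=self.r2_gate,
            )
            bterms, bcov = build_baseline_terms(
                distances, self.samples, self.exponents
            )
            baselines[e] = stepwise_fit(
                y, bterms, bcov, element=e, split_seed=seed,
                alpha_enter=self.alpha_enter, alpha_remove=self.alpha_remove,
                fraction=self.split_fraction, r2_gate=self.r2_gate,
            )
        contributions = quantify_contributions(models, enrich)
        return SourceApportionmentResults(
            model=self, seed=seed, distances=distances, enrichment=enrich,
            factors=factors, q_sources=q_sources, interactions=interactions,
            pathway_map=pathway_map, models=models, baselines=baselines,
            contributions=contributions,
        )

    def describe(self) -> pd.DataFrame:
        return describe(self.samples, self.background)


@dataclass
class SourceApportionmentResults:
    """Everything the fitted chain produced."""

    model: SourceApportionment
    seed: int
    distances: DistanceSet
    enrichment: EnrichmentResult
    factors: FactorModel
    q_sources: pd.DataFrame
    interactions: pd.DataFrame
    pathway_map: dict
    models: dict[str, MLRDResults]
    baselines: dict[str, MLRDResults]
    contributions: pd.DataFrame

    @property
    def accepted(self) -> dict[str, bool]:
        return {e: r.accepted for e, r in self.models.items()}

    @property
    def test_r2(self) -> pd.DataFrame:
        return pd.DataFrame({
            "modified": {e: r.test_r2 for e, r in self.models.items()},
            "baseline": {e: r.test_r2 for e, r in self.baselines.items()},
        })

    def summary(self) -> str:
        lines = [
            "Heavy-metal source apportionment",
            "=" * 46,
            f"sites: {len(self.model.samples)}; apportioned elements: "
            + ", ".join(self.model.elements),
            f"crustal reference: {self.model.reference}; split seed: {self.seed}",
            "",
            "Factor solution (leaf factors): "
            + ", ".join(self.factors.leaf_factors()),
            f"cumulative explained variance: "
            f"{100 * self.factors.cumulative_explained:.1f}%",
            "",
            "Assigned pollution pathways:",
        ]
        for (e, fac), pws in sorted(self.pathway_map.items()):
            lines.append(f"  {e} / {fac}: {', '.join(pws) if pws else '(none)'}")
        lines.append("")
        lines.append("Regression diagnostics (test R2, modified vs baseline):")
        for e in self.model.elements:
            m, b = self.models[e], self.baselines[e]
            flag = "" if m.accepted else "  [REJECTED: test R2 <= gate]"
            lines.append(
                f"  {e}: modified {m.test_r2:.3f} | baseline {b.test_r2:.3f}{flag}"
            )
        lines.append("")
        lines.append("Contributions (% of cumulative input):")
        lines.append(self.contributions.round(1).to_string())
        return "\n".join(lines)

    def plot_contributions(self, ax=None):
        """Stacked-bar contribution plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.contributions.plot.bar(stacked=True, ax=ax)
        ax.set_ylabel("contribution (%)")
        ax.set_ylim(0, 100)
        return ax


def contribution_ranges(results: Sequence[SourceApportionmentResults]
                        ) -> pd.DataFrame:
    """Min-max contribution range across model variants (e.g. different
    crustal references / background tables)."""
    tables = [r.contributions for r in results]
    lo = pd.concat(tables).groupby(level=0).min()
    hi = pd.concat(tables).groupby(level=0).max()
    out = lo.round(1).astype(str) + "-" + hi.round(1).astype(str) + "%"
    out.index.name = "element"
    return out
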