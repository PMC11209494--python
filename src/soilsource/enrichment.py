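"""Parent-material quantification via enrichment factors.

The natural (parent-material) share of each element is estimated against a
crustal reference element assumed to be dominated by the soil matrix
(Mg, Ca or Zn).  With soil concentrations [M], [C] and background values
bg_M, bg_C:

    EF          = ([M]/[C])_soil / (bg_M/bg_C)
    M_excessive = [M] - [C] * (bg_M/bg_C)

EF ~ 1 indicates a purely lithogenic origin; M_excessive is the portion of
the measured concentration exceeding the crustal expectation, attributed to
anthropogenic input.  M_excessive can be negative when a site sits below the
crustal expectation; negatives are preserved in diagnostics but clipped to 0
when used as regression targets (cumulative anthropogenic input cannot be
negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BackgroundTable, SampleTable, ValidationError

__all__ = [
    "EnrichmentResult",
    "enrichment_factor",
    "excessive_content",
    "compute_enrichment",
    "select_reference",
]


class DomainError(ValueError):
    """An input falls outside the mathematical domain of the operation."""


def _check_positive(**named) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(arr > 0):
            raise DomainError(f"{name} must be strictly positive")


def enrichment_factor(conc_M, conc_C, bg_M, bg_C):
    """EF = (conc_M/conc_C) / (bg_M/bg_C); dimensionless, > 0."""
    _check_positive(conc_M=conc_M, conc_C=conc_C, bg_M=bg_M, bg_C=bg_C)
    return (np.asarray(conc_M, float) / np.asarray(conc_C, float)) / (bg_M / bg_C)


def excessive_content(conc_M, conc_C, bg_M, bg_C):
    """Anthropogenic excess: conc_M - conc_C*(bg_M/bg_C).  May be negative."""
    _check_positive(conc_M=conc_M, conc_C=conc_C, bg_M=bg_M, bg_C=bg_C)
    return np.asarray(conc_M, float) - np.asarray(conc_C, float) * (bg_M / bg_C)


@dataclass
class EnrichmentResult:
    """Per-site, per-element enrichment diagnostics.

    ``natural_part + excess`` reconstructs the measured concentration exactly.
    ``excess_clipped`` (negatives set to 0) is the regression target used by
    the apportionment model.
    """

    reference_elements: list[str]
    ef: pd.DataFrame
    excess: pd.DataFrame
    natural_part: pd.DataFrame

    @property
    def excess_clipped(self) -> pd.DataFrame:
        return self.excess.clip(lower=0.0)

    def to_csv(self, path) -> None:
        wide = pd.concat(
            {"EF": self.ef, "excess": self.excess, "natural": self.natural_part},
            axis=1,
        )
        wide.columns = [f"{stat}_{el}" for stat, el in wide.columns]
        wide.to_csv(path, index_label="site_id")


def compute_enrichment(
    samples: SampleTable,
    background: BackgroundTable,
    elements: Sequence[str],
    reference: str | Sequence[str] = "Mg",
) -> EnrichmentResult:
    """Enrichment factors and anthropogenic excess for ``elements``.

    ``reference`` may name one crustal reference element or several; with
    several (e.g. ``("Zn", "Mg")``) the per-reference excesses (and EFs) are
    averaged element-wise.
    """
    refs = [reference] if isinstance(reference, str) else list(reference)
    if not refs:
        raise ValidationError("at least one reference element required")
    for r in refs:
        if r not in samples.elements:
            raise ValidationError(f"reference element {r!r} not measured")
    conc = samples.concentrations(elements)
    ef_parts, ex_parts = [], []
    for r in refs:
        conc_C = samples.data[r].to_numpy(float)[:, None]
        bg_C = background.background(r)
        bg_M = np.array([background.background(e) for e in elements])[None, :]
        ef_parts.append(enrichment_factor(conc.to_numpy(float), conc_C, bg_M, bg_C))
        ex_parts.append(excessive_content(conc.to_numpy(float), conc_C, bg_M, bg_C))
    ef = pd.DataFrame(np.mean(ef_parts, axis=0), index=conc.index, columns=elements)
    excess = pd.DataFrame(np.mean(ex_parts, axis=0), index=conc.index, columns=elements)
    natural = conc - excess
    return EnrichmentResult(refs, ef, excess, natural)


def select_reference(
    samples: SampleTable,
    candidates: Sequence[str],
    background: BackgroundTable,
    apportioned: Sequence[str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Rank candidate crustal reference elements and pick the best.

    A good reference is spatially stable (low CV) and yields enrichment
    factors near 1 for the apportioned elements (low mean EF).  Candidates
    are ranked by the sum of their CV rank and mean-EF rank; the top-ranked
    candidate is returned together with the diagnostics table.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("empty candidate set")
    apportioned = list(apportioned or [e for e in samples.elements if e not in candidates])
    rows = {}
    for c in candidates:
        v = samples.data[c].to_numpy(float)
        cv = 100.0 * np.std(v, ddof=1) / np.mean(v)
        res = compute_enrichment(samples, background, apportioned, reference=c)
        rows[c] = {"cv_pct": cv, "mean_ef": float(res.ef.to_numpy().mean())}
    diag = pd.DataFrame(rows).T
    diag["rank"] = diag["cv_pct"].rank() + diag["mean_ef"].rank()
    diag = diag.sort_values("rank")
    return str(diag.index[0]), diag
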