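"""Correlation-matrix PCA with varimax rotation, grouped re-decomposition
(GPCA) of mixed factors, factor scores and IDW score surfaces.

The factor pipeline follows the conventions of classical exploratory PCA as
used in environmental geochemistry: inputs are z-scored, components with
eigenvalue > 1 are retained (strict Kaiser rule), loadings are varimax-
rotated with Kaiser row normalization, and factor scores are the regression
(least-squares) estimates, standardized to zero mean and unit variance.

A factor whose high-loading element set (|loading| > 0.7 by default) is
larger than ``max_elements`` is considered *mixed*: the elements it loads are
re-submitted to a fresh PCA of their own (GPCA), and the resulting
sub-factors (labelled ``<parent>-1``, ``<parent>-2``, ...) replace the parent
in the downstream source list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SampleTable, ValidationError

__all__ = [
    "FactorModel",
    "fit_pca",
    "major_loadings",
    "detect_mixed_factor",
    "group_decompose",
    "idw_surface",
    "idw_scores",
]


def _varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-12,
             max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation.  Returns (rotated loadings, rotation matrix R) with
    ``rotated = loadings @ R`` and R orthonormal."""
    L = loadings.copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.ones(p)
    if normalize:  # Kaiser normalization: rotate rows scaled to unit communality
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        # gradient of the varimax criterion
        tmp = LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / p
        u, s, vt = np.linalg.svd(L.T @ tmp)
        R = u @ vt
        new_var = s.sum()
        if new_var <= var * (1 + tol):
            break
        var = new_var
    out = (L @ R) * (h[:, None] if normalize else 1.0)
    return out, R


@dataclass
class FactorModel:
    """A fitted (possibly grouped) factor solution.

    Loadings/scores carry factor labels ``PCA1, PCA2, ...`` in descending
    eigenvalue order; sub-factors from a grouped decomposition are labelled
    ``PCA1-1, PCA1-2, ...`` and stored in ``subtrees``.
    """

    elements: list[str]
    eigenvalues: np.ndarray               # all eigenvalues, descending
    explained_variance_ratio: np.ndarray  # per retained factor
    loadings: pd.DataFrame                # element x retained factor (rotated)
    scores: pd.DataFrame                  # site x retained factor
    rotation: np.ndarray                  # orthonormal, rotated = unrotated @ R
    unrotated_loadings: pd.DataFrame
    threshold: float = 0.7
    subtrees: dict[str, "FactorModel"] = field(default_factory=dict)

    @property
    def factors(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def leaf_factors(self) -> list[str]:
        """Factor labels with decomposed parents replaced by their sub-factors."""
        out: list[str] = []
        for f in self.factors:
            if f in self.subtrees:
                out.extend(self.subtrees[f].factors)
            else:
                out.append(f)
        return out

    def leaf_scores(self) -> pd.DataFrame:
        cols = {}
        for f in self.factors:
            if f in self.subtrees:
                sub = self.subtrees[f]
                for sf in sub.factors:
                    cols[sf] = sub.scores[sf]
            else:
                cols[f] = self.scores[f]
        return pd.DataFrame(cols)

    def leaf_loadings(self) -> dict[str, pd.Series]:
        out = {}
        for f in self.factors:
            if f in self.subtrees:
                sub = self.subtrees[f]
                for sf in sub.factors:
                    out[sf] = sub.loadings[sf]
            else:
                out[f] = self.loadings[f]
        return out

    def tree_json(self) -> dict:
        return {
            f: (self.subtrees[f].tree_json() if f in self.subtrees else None)
            for f in self.factors
        }


def fit_pca(samples: SampleTable, elements: list[str] | None = None,
            threshold: float = 0.7, prefix: str = "PCA") -> FactorModel:
    """Standardized PCA with strict Kaiser retention and varimax rotation.

    Scores are regression estimates ``Z @ R_corr^{-1} @ L``, standardized to
    zero mean / unit variance per factor; for a correlation-matrix PCA these
    are mutually uncorrelated by construction.
    """
    elements = list(elements or samples.elements)
    if len(samples) < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if len(elements) < 2:
        raise ValidationError("PCA needs at least 2 elements")
    X = samples.concentrations(elements).to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [e for e, s in zip(elements, sd) if s == 0]
        raise ValidationError(f"constant element column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    R_corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R_corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1.0  # strict Kaiser rule
    k = max(int(keep.sum()), 1)
    labels = [f"{prefix}{i + 1}" for i in range(k)]
    L0 = eigvec[:, :k] * np.sqrt(eigval[:k])
    Lrot, R = _varimax(L0)
    # order rotated factors by explained variance (sum of squared loadings)
    ssl = (Lrot ** 2).sum(axis=0)
    order2 = np.argsort(ssl)[::-1]
    Lrot, R = Lrot[:, order2], R[:, order2]
    # sign convention: largest-magnitude loading positive
    signs = np.sign(Lrot[np.abs(Lrot).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    Lrot, R = Lrot * signs, R * signs
    # regression factor scores (exact for component models)
    W = np.linalg.solve(R_corr, Lrot)
    F = Z @ W
    F = F / F.std(axis=0, ddof=1)
    evr = (Lrot ** 2).sum(axis=0) / len(elements)
    return FactorModel(
        elements=elements,
        eigenvalues=eigval,
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(Lrot, index=elements, columns=labels),
        scores=pd.DataFrame(F, index=samples.data.index, columns=labels),
        rotation=R,
        unrotated_loadings=pd.DataFrame(L0, index=elements, columns=labels),
        threshold=threshold,
    )


def major_loadings(model: FactorModel, threshold: float | None = None
                   ) -> dict[str, list[str]]:
    """Elements with |rotated loading| strictly above the threshold, per factor."""
    thr = model.threshold if threshold is None else threshold
    out = {}
    for f in model.factors:
        col = model.loadings[f]
        members = [e for e in model.elements if abs(col[e]) > thr]
        if not members:
            warnings.warn(f"factor {f} has no loading above {thr}", stacklevel=2)
        out[f] = members
    return out


def detect_mixed_factor(model: FactorModel, max_elements: int = 3) -> list[str]:
    """Factors whose high-loading element set exceeds ``max_elements``,
    in explained-variance order."""
    major = major_loadings(model)
    return [f for f in model.factors if len(major[f]) > max_elements]


def group_decompose(samples: SampleTable, model: FactorModel, factor: str,
                    max_elements: int = 3) -> FactorModel:
    """Grouped PCA: re-decompose a mixed factor on its high-loading elements.

    The subset PCA must retain >= 2 sub-factors; otherwise the decomposition
    is rejected and the parent kept (with a warning).  Returns ``model`` with
    the sub-solution attached under ``subtrees[factor]``.
    """
    if factor not in detect_mixed_factor(model, max_elements):
        raise ValidationError(f"factor {factor!r} is not flagged as mixed")
    subset = major_loadings(model)[factor]
    if len(subset) < 3:
        raise ValidationError("grouped decomposition needs >= 3 elements")
    sub = fit_pca(samples, subset, threshold=model.threshold, prefix=f"{factor}-")
    if len(sub.factors) < 2:
        warnings.warn(
            f"subset PCA for {factor} retained < 2 factors; decomposition rejected",
            stacklevel=2,
        )
        return model
    model.subtrees[factor] = sub
    return model


def idw_surface(coords: np.ndarray, values: np.ndarray, grid_x, grid_y,
                power: float = 2.0) -> pd.DataFrame:
    """Inverse-distance-weighted interpolation onto a rectangular grid.

    All observations contribute with weight d^-power; a grid node coinciding
    with an observation takes that observation's value exactly.  Returns
    long-format (x, y, value).
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(coords) != len(values):
        raise ValidationError("coords and values lengths differ")
    if len(coords) == 0:
        raise ValidationError("need at least one observation")
    gx, gy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    if gx.size == 0:
        raise ValidationError("empty grid")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(pts))
    exact = d < 1e-12
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    for i in range(len(pts)):
        if exact[i].any():
            out[i] = values[np.argmax(exact[i])]
        else:
            out[i] = np.average(values, weights=w[i])
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "value": out})


def idw_scores(model: FactorModel, factor: str, grid_x, grid_y,
               coords: np.ndarray, power: float = 2.0) -> pd.DataFrame:
    """IDW surface of a (sub-)factor's scores; ``coords`` aligns with the
    model's site order."""
    leaf = model.leaf_scores()
    if factor in leaf.columns:
        vals = leaf[factor].to_numpy(float)
    elif factor in model.scores.columns:
        vals = model.scores[factor].to_numpy(float)
    else:
        raise KeyError(f"unknown factor {factor!r}")
    return idw_surface(np.asarray(coords, float), vals, grid_x, grid_y, power)
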