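"""Asset-based household wealth index.

Builds the standard DHS/MICS-style socioeconomic index: binary asset
ownership indicators are standardized, the first principal component
provides per-asset weights (factor scores), household scores are the
weighted sums re-standardized to mean 0 / sd 1, and households are ranked
and split into weighted quintiles and deciles (1 = poorest). A single
index is fitted to the whole sample; urban and rural households are never
scored separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .concentration import fractional_ranks

logger = logging.getLogger(__name__)

__all__ = [
    "HouseholdAssets",
    "WealthIndex",
    "StandardizedAssets",
    "PrincipalComponent",
    "standardize_assets",
    "first_component",
    "score_households",
    "assign_quantiles",
    "build_wealth_index",
]


@dataclass(frozen=True)
class HouseholdAssets:
    """One household's binary asset profile with survey metadata."""

    household_id: str
    assets: tuple[int, ...]
    weight: float
    residence: str
    stratum: str

    def __post_init__(self) -> None:
        if any(a not in (0, 1) for a in self.assets):
            raise ValueError(f"household {self.household_id}: assets must be 0/1")
        if not self.weight > 0:
            raise ValueError(f"household {self.household_id}: weight must be positive")


@dataclass
class WealthIndex:
    """Per-household wealth score with rank and quantile labels."""

    household_id: str
    score: float
    rank: int = 0
    fractional_rank: float = 0.0
    quintile: int = 0
    decile: int = 0


@dataclass(frozen=True)
class StandardizedAssets:
    """Standardized asset matrix plus the retained-column bookkeeping."""

    matrix: np.ndarray            # n_households x n_retained, mean 0 / sd 1 columns
    retained: tuple[int, ...]     # original column index of each retained column
    dropped: tuple[int, ...]      # constant columns removed before PCA
    means: np.ndarray
    sds: np.ndarray


@dataclass(frozen=True)
class PrincipalComponent:
    """Unit-norm first-PC loadings with explained-variance share."""

    loadings: np.ndarray
    explained_share: float
    orientation_flipped: bool


def _asset_matrix(households: Sequence[HouseholdAssets]) -> np.ndarray:
    return np.array([hh.assets for hh in households], dtype=float)


def standardize_assets(households: Sequence[HouseholdAssets]) -> StandardizedAssets:
    """Column-standardize the asset matrix (mean 0, sd 1, denominator N).

    Constant (zero-variance) columns carry no ranking information and are
    dropped with a logged warning; if every column is constant the input is
    degenerate and an error is raised.
    """
    if len(households) < 2:
        raise ValueError("standardization requires at least 2 households")
    X = _asset_matrix(households)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd, denominator N
    keep = sds > 0
    if not keep.any():
        raise ValueError("degenerate input: every asset column is constant")
    dropped = tuple(int(j) for j in np.flatnonzero(~keep))
    if dropped:
        logger.warning("dropping constant asset columns: %s", dropped)
    Z = (X[:, keep] - means[keep]) / sds[keep]
    return StandardizedAssets(
        matrix=Z,
        retained=tuple(int(j) for j in np.flatnonzero(keep)),
        dropped=dropped,
        means=means[keep],
        sds=sds[keep],
    )


def first_component(standardized: StandardizedAssets) -> PrincipalComponent:
    """First principal component of the standardized asset matrix.

    Because columns are standardized, this is the leading eigenvector of
    the sample correlation matrix. The sign is fixed by the orientation
    rule: scores must correlate nonnegatively with the household's total
    asset count, so that more assets means richer.
    """
    Z = standardized.matrix
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pca.components_[0]
    norm = np.linalg.norm(loadings)
    loadings = loadings / norm
    # population-variance explained share (matches the N-denominator convention)
    total_var = Z.var(axis=0).sum()
    explained = float(scores.var() / total_var)
    asset_count = Z.sum(axis=1)  # monotone in raw count since sds > 0
    flip = bool(np.corrcoef(scores, asset_count)[0, 1] < 0) if asset_count.std() > 0 else False
    if flip:
        loadings = -loadings
    return PrincipalComponent(
        loadings=loadings, explained_share=explained, orientation_flipped=flip
    )


def score_households(
    households: Sequence[HouseholdAssets],
    component: PrincipalComponent,
    standardized: StandardizedAssets | None = None,
) -> list[WealthIndex]:
    """Score, rank and fractionally rank households on the first PC.

    The score is the loading-weighted sum of standardized asset indicators,
    re-standardized to mean 0 / sd 1 over the scored sample. Ranks ascend
    in score with ties broken by household_id; fractional ranks use design
    weights (endpoint convention).
    """
    if standardized is None:
        standardized = standardize_assets(households)
    raw = standardized.matrix @ component.loadings
    sd = raw.std()
    scores = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    indices = [
        WealthIndex(household_id=hh.household_id, score=float(s))
        for hh, s in zip(households, scores)
    ]
    order = sorted(range(len(indices)), key=lambda i: (indices[i].score, indices[i].household_id))
    weights = np.array([households[i].weight for i in order])
    fr = fractional_ranks(weights)
    for rank0, i in enumerate(order):
        indices[i].rank = rank0 + 1
        indices[i].fractional_rank = float(fr[rank0])
    return indices


def assign_quantiles(
    indices: list[WealthIndex],
    weights: Sequence[float],
    k: int = 5,
    use_weights: bool = True,
    allow_any_k: bool = False,
) -> list[WealthIndex]:
    """Assign weighted k-quantile labels (1 = poorest, k = richest) in place.

    Walks households poorest -> richest accumulating weight; a household is
    assigned the group whose cumulative-weight band contains its weight
    midpoint, i.e. ``ceil(k * (cum_before + w/2) / W)``. Each group's total
    weight is then within one household's weight of W/k. ``weights`` is
    aligned with ``indices`` (not with rank order).
    """
    if k not in (5, 10) and not allow_any_k:
        raise ValueError(f"unsupported k={k}; use 5 or 10 (or allow_any_k=True)")
    w = np.asarray(weights, dtype=float)
    if use_weights is False:
        w = np.ones_like(w)
    order = sorted(range(len(indices)), key=lambda i: indices[i].rank)
    w_ord = w[order]
    W = w_ord.sum()
    cum = np.cumsum(w_ord)
    mid = cum - w_ord / 2.0
    labels = np.minimum(np.maximum(np.ceil(k * mid / W).astype(int), 1), k)
    attr = {5: "quintile", 10: "decile"}.get(k, f"q{k}")
    for pos, i in enumerate(order):
        setattr(indices[i], attr, int(labels[pos]))
    return indices


def build_wealth_index(
    households: Sequence[HouseholdAssets],
) -> tuple[list[WealthIndex], PrincipalComponent, StandardizedAssets]:
    """End-to-end index: standardize, extract PC1, score, label quantiles."""
    std = standardize_assets(households)
    comp = first_component(std)
    idx = score_households(households, comp, std)
    w = [hh.weight for hh in households]
    assign_quantiles(idx, w, k=5)
    assign_quantiles(idx, w, k=10)
    return idx, comp, std


def wealth_index_frame(indices: list[WealthIndex]) -> pd.DataFrame:
    """Tabular view of a scored sample (one row per household)."""
    return pd.DataFrame(
        {
            "household_id": [i.household_id for i in indices],
            "score": [i.score for i in indices],
            "rank": [i.rank for i in indices],
            "fractional_rank": [i.fractional_rank for i in indices],
            "quintile": [i.quintile for i in indices],
            "decile": [i.decile for i in indices],
        }
    )
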