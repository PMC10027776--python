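"""Weighted and unit-weight composite (sum) scores and their exact moments.

A composite is any weighted linear combination Y = w1*X1 + ... + wp*Xp of
item scores.  Its mean is the weighted sum of item means and its variance is
the quadratic form w'Cw in the item covariance matrix C; with unit weights
the variance is simply the grand sum of all elements of C.  These identities
are the backbone of internal-consistency reliability theory, so they are
implemented exactly (no sampling) and exposed both for raw and per-item
standardized scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, DimensionError, InputError

__all__ = [
    "ItemMatrix",
    "WeightVector",
    "CompositeMoments",
    "composite_scores",
    "composite_moments",
]


@dataclass
class ItemMatrix:
    """Persons x items response table.

    ``values`` holds the numeric responses (NaN where missing),
    ``item_labels`` the column identifiers, and ``missing_mask`` flags
    missing cells.  Use :meth:`from_dataframe` for pandas input.
    """

    values: np.ndarray
    item_labels: list[str]
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("item matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise InputError("item matrix needs at least one person and one item")
        self.item_labels = [str(c) for c in self.item_labels]
        if len(self.item_labels) != p:
            raise DimensionError(
                f"{len(self.item_labels)} labels for {p} item columns"
            )
        if len(set(self.item_labels)) != p:
            raise InputError("item labels must be unique")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise DimensionError("missing mask shape mismatch")
            self.missing_mask = self.missing_mask | np.isnan(self.values)
        retained = self.values[~self.missing_mask]
        if not np.all(np.isfinite(retained)):
            raise InputError("non-finite value in a retained (non-missing) cell")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ItemMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns))

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return pd.DataFrame(out, columns=self.item_labels)


@dataclass
class WeightVector:
    """Per-item real weights w1..wp; must match the item count, not all zero."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.size == 0:
            raise InputError("empty weight vector")
        if not np.all(np.isfinite(self.weights)):
            raise InputError("weights must be finite")
        if np.all(self.weights == 0):
            raise InputError("weights must not all be zero")

    @classmethod
    def unit(cls, p: int) -> "WeightVector":
        return cls(np.ones(p))

    def __len__(self) -> int:
        return self.weights.size


@dataclass
class CompositeMoments:
    """Mean and variance of a weighted composite (w'mu, w'Cw)."""

    mean: float
    variance: float


def _as_weights(weights, p: int) -> np.ndarray:
    w = weights if isinstance(weights, WeightVector) else WeightVector(weights)
    if len(w) != p:
        raise DimensionError(f"{len(w)} weights for {p} items")
    return w.weights


def composite_scores(
    items: ItemMatrix,
    weights=None,
    standardize_first: bool = False,
    impute_person_mean: bool = False,
) -> np.ndarray:
    """Per-person weighted composite scores.

    Parameters
    ----------
    items
        Persons x items responses.
    weights
        Per-item weights; ``None`` means unit weights (the plain sum score).
    standardize_first
        Standardize each item to mean 0, SD 1 before weighting, using the
        supplied sample's own mean and SD (denominator n-1).  This is the
        sample-specific standardization implicit in estimated factor scores;
        whether to use it for raw sum scores is an explicit analyst choice,
        so no default inference is made.
    impute_person_mean
        Replace a person's missing cells by that person's mean over the
        observed weighted items.  Off by default: the default policy is to
        fail on any missing cell among items with nonzero weight.
    """
    if isinstance(items, pd.DataFrame):
        items = ItemMatrix.from_dataframe(items)
    p = items.n_items
    w = np.ones(p) if weights is None else _as_weights(weights, p)

    x = items.values.astype(float).copy()
    mask = items.missing_mask
    active = w != 0
    # zero-weight items never contribute; neutralize their missing cells
    x[mask & ~active[None, :]] = 0.0
    if mask[:, active].any():
        if not impute_person_mean:
            rows = np.where(mask[:, active].any(axis=1))[0]
            raise InputError(
                f"missing cells among weighted items (e.g. row {rows[0]}); "
                "enable impute_person_mean or clean the data"
            )
        obs = ~mask & active[None, :]
        if (obs.sum(axis=1) == 0).any():
            raise InputError("a person has no observed weighted items to impute from")
        person_mean = np.nansum(np.where(obs, x, 0.0), axis=1) / obs.sum(axis=1)
        fill = mask & active[None, :]
        x[fill] = np.broadcast_to(person_mean[:, None], x.shape)[fill]

    if standardize_first:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if items.n_persons > 1 else np.zeros(p)
        bad = (sd == 0) & active
        if bad.any():
            label = items.item_labels[int(np.where(bad)[0][0])]
            raise DegenerateScaleError(
                f"item '{label}' has zero SD; cannot standardize"
            )
        x = x.copy()
        x[:, active] = (x[:, active] - mu[active]) / sd[active]

    return x @ w


def composite_moments(cov, means=None, weights=None) -> CompositeMoments:
    """Exact mean and variance of the weighted composite.

    ``mean = w'mu`` and ``variance = w'Cw``; with unit weights the variance
    is the sum of all elements of the covariance matrix.
    """
    if isinstance(cov, pd.DataFrame):
        cov = cov.to_numpy(dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise InputError("covariance matrix must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise InputError("covariance matrix is not symmetric")
    p = cov.shape[0]
    w = np.ones(p) if weights is None else _as_weights(weights, p)
    if means is None:
        mean = float("nan")
    else:
        means = np.asarray(means, dtype=float).ravel()
        if means.size != p:
            raise DimensionError(f"{means.size} means for {p} items")
        mean = float(w @ means)
    variance = float(w @ cov @ w)
    return CompositeMoments(mean=mean, variance=variance)
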