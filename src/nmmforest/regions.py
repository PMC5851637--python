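"""Direct empirical region-probability estimates and bivariate maps.

The probability of a dynamic class within a hyperrectangular region R of
parameter space is estimated by the sample mean of the 0/1 class indicator
over the database rows falling inside R.  Bivariate likelihood maps bin two
parameters into an equal-width grid over their sampled ranges and apply the
same estimator per cell (all other parameters free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import SEIZURE_LABELS
from .sampling import ParameterSpace

__all__ = [
    "NoSupportError",
    "RegionQuery",
    "region_probability",
    "bivariate_map",
    "LikelihoodMap",
]


class NoSupportError(ValueError):
    """Raised when a region contains no database rows (the estimate is
    undefined, which is distinct from an estimate of 0)."""


@dataclass
class RegionQuery:
    """Half-open interval constraints defining a hyperrectangle.

    ``constraints`` maps a parameter name to (lo, hi); either side may be
    None (unbounded).  A row is inside when lo <= x < hi on every
    constrained dimension.
    """

    constraints: dict = field(default_factory=dict)

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for name, (lo, hi) in self.constraints.items():
            if name not in df.columns:
                raise KeyError(f"parameter {name!r} not in database")
            x = df[name].to_numpy()
            if lo is not None:
                m &= x >= lo
            if hi is not None:
                m &= x < hi
        return m


def _positive_mask(df: pd.DataFrame, positive) -> np.ndarray:
    """Normalise a class predicate: label name(s), callable, or bool array."""
    if callable(positive):
        return np.asarray(positive(df), dtype=bool)
    if isinstance(positive, str):
        if positive == "seizure":
            return df["label"].isin(SEIZURE_LABELS).to_numpy()
        return (df["label"] == positive).to_numpy()
    if isinstance(positive, (list, tuple, set, frozenset)):
        return df["label"].isin(list(positive)).to_numpy()
    arr = np.asarray(positive, dtype=bool)
    if arr.shape != (len(df),):
        raise ValueError("boolean mask must align with the database rows")
    return arr


def region_probability(df, query: RegionQuery, positive):
    """Estimated class probability within a region, with its support.

    Returns ``(probability, count)`` where ``count`` is the number of rows
    inside the region.  Raises :class:`NoSupportError` on an empty region.
    ``df`` may be a DataFrame or a SimulationDatabase.
    """
    if hasattr(df, "df"):
        df = df.df
    if len(df) == 0:
        raise NoSupportError("empty database")
    inside = query.mask(df)
    count = int(inside.sum())
    if count == 0:
        raise NoSupportError(f"no rows inside region {query.constraints}")
    pos = _positive_mask(df, positive)
    return float(pos[inside].mean()), count


@dataclass
class LikelihoodMap:
    """bins x bins grid of class probabilities with per-cell counts."""

    param_i: str
    param_j: str
    edges_i: np.ndarray
    edges_j: np.ndarray
    counts: np.ndarray      # (bins, bins) ints
    probability: np.ndarray  # (bins, bins); NaN where the cell is empty

    def global_rate(self) -> float:
        """Count-weighted mean over non-empty cells (= the overall rate)."""
        filled = self.counts > 0
        return float(
            np.sum(self.probability[filled] * self.counts[filled])
            / self.counts.sum()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        nb_i, nb_j = self.counts.shape
        for bi in range(nb_i):
            for bj in range(nb_j):
                rows.append({
                    "bin_i": bi, "bin_j": bj,
                    "lo_i": self.edges_i[bi], "hi_i": self.edges_i[bi + 1],
                    "lo_j": self.edges_j[bj], "hi_j": self.edges_j[bj + 1],
                    "count": int(self.counts[bi, bj]),
                    "probability": self.probability[bi, bj],
                })
        return pd.DataFrame(rows)

    def plot(self, ax=None, **imshow_kwargs):  # pragma: no cover - thin wrapper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = (self.edges_j[0], self.edges_j[-1],
                  self.edges_i[0], self.edges_i[-1])
        im = ax.imshow(self.probability, origin="lower", extent=extent,
                       aspect="auto", **imshow_kwargs)
        ax.set_xlabel(self.param_j)
        ax.set_ylabel(self.param_i)
        return im


def bivariate_map(
    df,
    param_i: str,
    param_j: str,
    positive,
    bins: int = 20,
    space: ParameterSpace = None,
) -> LikelihoodMap:
    """Binned bivariate class-likelihood map.

    Bins are equal-width and half-open [lo, hi) with the final bin closed,
    over each parameter's configured range (or the data envelope).  Empty
    cells carry probability NaN, never a fabricated 0 or 1.
    """
    if hasattr(df, "df"):
        df = df.df
    for name in (param_i, param_j):
        if name not in df.columns:
            raise KeyError(f"parameter {name!r} not in database")
    pos = _positive_mask(df, positive)

    def edges_for(name):
        if space is not None:
            lo, hi = space.bounds(name)
        else:
            lo, hi = float(df[name].min()), float(df[name].max())
        return np.linspace(lo, hi, bins + 1)

    edges_i = edges_for(param_i)
    edges_j = edges_for(param_j)

    def bin_index(x, edges):
        idx = np.digitize(x, edges[1:-1])
        return np.clip(idx, 0, bins - 1)

    bi = bin_index(df[param_i].to_numpy(), edges_i)
    bj = bin_index(df[param_j].to_numpy(), edges_j)
    flat = bi * bins + bj
    counts = np.bincount(flat, minlength=bins * bins).reshape(bins, bins)
    pos_counts = np.bincount(flat, weights=pos, minlength=bins * bins)
    pos_counts = pos_counts.reshape(bins, bins)
    with np.errstate(invalid="ignore"):
        prob = np.where(counts > 0, pos_counts / np.maximum(counts, 1), np.nan)
    return LikelihoodMap(param_i, param_j, edges_i, edges_j, counts, prob)
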