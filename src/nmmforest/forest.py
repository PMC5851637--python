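"""Bootstrap-aggregated random forests and Gini variable importance.

Each of the B trees is grown on an n-point bootstrap resample of the data,
with a fresh random subset of ``mtry`` candidate split dimensions drawn at
every node.  The forest's class-probability estimate is the plain average
of the per-tree leaf proportions.

Variable importance VI(j) of a parameter j is, per tree, the sum of the
impurity decreases at all branch nodes that split on j divided by the
tree's branch-node count Nb, averaged over the forest.  The normalised
variable importance NVI(j) = VI(j) / max_i VI(i) ranks parameters on [0, 1]
with the most influential parameter at exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tree import ClassificationTree, TreeResults

__all__ = ["RandomForest", "ForestResults", "ImportanceTable"]


@dataclass
class ImportanceTable:
    """Per-parameter variable importance for a named classification target."""

    names: list
    vi: np.ndarray
    target: str = ""
    normalised: bool = False

    def __post_init__(self):
        self.vi = np.asarray(self.vi, dtype=float)
        if self.vi.shape != (len(self.names),):
            raise ValueError("vi length must match names")
        if np.any(self.vi < 0):
            raise ValueError("VI must be non-negative")

    def nvi(self) -> "ImportanceTable":
        """Normalise to the largest importance (max becomes exactly 1)."""
        vmax = self.vi.max() if self.vi.size else 0.0
        if vmax <= 0:
            raise ValueError("all-zero importance cannot be normalised")
        return ImportanceTable(self.names, self.vi / vmax, self.target, True)

    def __getitem__(self, name) -> float:
        return float(self.vi[self.names.index(name)])

    def to_series(self) -> pd.Series:
        label = "NVI" if self.normalised else "VI"
        return pd.Series(self.vi, index=self.names, name=f"{label}:{self.target}")

    def to_frame(self) -> pd.DataFrame:
        return self.to_series().to_frame().T


class RandomForest:
    """Random-forest classifier model over a parameter design.

    Parameters mirror :class:`~nmmforest.tree.ClassificationTree`; call
    :meth:`fit` to obtain a :class:`ForestResults`.
    """

    def __init__(self, X, y, feature_names=None, classes=None, bounds=None,
                 target: str = ""):
        self._tree_model = ClassificationTree(
            X, y, feature_names=feature_names, classes=classes, bounds=bounds
        )
        self.target = target

    @property
    def feature_names(self):
        return self._tree_model.feature_names

    @property
    def classes_(self):
        return self._tree_model.classes_

    def fit(
        self,
        B: int = 100,
        mtry: Optional[int] = None,
        min_leaf: int = 1,
        max_depth: Optional[int] = None,
        bootstrap: bool = True,
        criterion: str = "weighted",
        seed=0,
        compute_oob: bool = True,
    ) -> "ForestResults":
        """Fit B randomised trees.

        ``mtry`` defaults to floor(sqrt(p)).  With ``bootstrap=False``,
        ``mtry=p`` and ``B=1`` the forest degenerates to a single CART tree.
        Deterministic given ``seed``.
        """
        model = self._tree_model
        n = model.X.shape[0]
        p = model.X.shape[1]
        if B < 1:
            raise ValueError("B must be >= 1")
        if mtry is None:
            mtry = max(1, int(np.floor(np.sqrt(p))))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must be in [1, {p}]")
        K = len(model.classes_)

        seeds = np.random.SeedSequence(seed).spawn(B)
        trees: list[TreeResults] = []
        oob_proba_sum = np.zeros((n, K))
        oob_count = np.zeros(n)
        for b in range(B):
            rng = np.random.default_rng(seeds[b])
            if bootstrap:
                idx = rng.integers(0, n, size=n)
            else:
                idx = None
            tree = model.fit(
                min_leaf=min_leaf, max_depth=max_depth, criterion=criterion,
                mtry=mtry, rng=rng, sample_indices=idx,
            )
            trees.append(tree)
            if compute_oob and bootstrap:
                oob = np.ones(n, dtype=bool)
                oob[idx] = False
                if oob.any():
                    oob_proba_sum[oob] += tree.predict_proba(model.X[oob])
                    oob_count[oob] += 1

        oob_proba = None
        if compute_oob and bootstrap:
            with np.errstate(invalid="ignore"):
                oob_proba = oob_proba_sum / oob_count[:, None]
        return ForestResults(
            model=self, trees=trees, B=B, mtry=mtry, min_leaf=min_leaf,
            bootstrap=bootstrap, criterion=criterion, seed=seed,
            oob_proba=oob_proba,
        )


class ForestResults:
    """A fitted forest: ensemble predictions, OOB error and importances."""

    def __init__(self, model, trees, B, mtry, min_leaf, bootstrap,
                 criterion, seed, oob_proba=None):
        self.model = model
        self.trees = trees
        self.B = B
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.bootstrap = bootstrap
        self.criterion = criterion
        self.seed = seed
        self.oob_proba = oob_proba

    @property
    def classes_(self):
        return self.model.classes_

    @property
    def feature_names(self):
        return self.model.feature_names

    def predict_proba(self, X) -> np.ndarray:
        """Average of per-tree class-probability vectors (rows sum to 1)."""
        proba = self.trees[0].predict_proba(X)
        for tree in self.trees[1:]:
            proba += tree.predict_proba(X)
        return proba / self.B

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes_, dtype=object)[np.argmax(proba, axis=1)]

    @property
    def oob_error_(self) -> float:
        """Out-of-bag misclassification rate (rows with >= 1 OOB tree)."""
        if self.oob_proba is None:
            raise ValueError("OOB predictions were not computed")
        have = np.isfinite(self.oob_proba).all(axis=1)
        if not have.any():
            raise ValueError("no out-of-bag rows")
        pred = np.argmax(self.oob_proba[have], axis=1)
        return float(np.mean(pred != self.model._tree_model.y[have]))

    def variable_importance(self) -> ImportanceTable:
        """Mean over trees of (impurity decrease per feature) / Nb."""
        p = len(self.feature_names)
        vi = np.zeros(p)
        for tree in self.trees:
            vi += tree.variable_importance()
        return ImportanceTable(list(self.feature_names), vi / self.B,
                               target=self.model.target)

    def nvi(self) -> ImportanceTable:
        """Normalised variable importance; the top parameter scores 1."""
        return self.variable_importance().nvi()

    def to_json(self, path=None):
        """Persist the forest (metadata + all trees) as JSON."""
        payload = {
            "B": self.B,
            "mtry": self.mtry,
            "min_leaf": self.min_leaf,
            "bootstrap": self.bootstrap,
            "criterion": self.criterion,
            "seed": self.seed,
            "classes": [str(c) for c in self.classes_],
            "feature_names": list(self.feature_names),
            "trees": [json.loads(t.to_json()) for t in self.trees],
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def summary(self) -> str:
        vi = self.variable_importance()
        lines = [
            "Random forest results",
            "=====================",
            f"trees: {self.B}   mtry: {self.mtry}   min_leaf: {self.min_leaf}",
            f"classes: {', '.join(map(str, self.classes_))}",
        ]
        try:
            lines.append(f"out-of-bag error: {self.oob_error_:.4f}")
        except ValueError:
            pass
        try:
            nvi = vi.nvi()
            lines += ["", "normalised variable importance:"]
            order = np.argsort(nvi.vi)[::-1]
            for j in order:
                lines.append(f"  {nvi.names[j]:>8s}  {nvi.vi[j]:.3f}")
        except ValueError:
            lines.append("importance: all zero (no splits)")
        return "\n".join(lines)
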