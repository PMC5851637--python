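"""From-scratch CART classification trees over parameter space.

A tree recursively bisects the parameter box with axis-aligned splits
``x_j <= s`` (left) / ``x_j > s`` (right), chosen to minimise the Gini
impurity of the two children.  Leaves are hyperrectangular regions carrying
class counts and proportions; the predicted class of a point is the
majority class of the leaf it falls in.

The default split cost is the standard size-weighted Gini sum
``N_L * G_L + N_R * G_R`` with ``G = sum_k p_k (1 - p_k)``; a mean-Gini
variant (impurity divided by the node count, children summed unweighted) is
available via ``criterion="mean_gini"`` for comparison.

API follows the Model/Results convention: build a
:class:`ClassificationTree` from data, call :meth:`~ClassificationTree.fit`,
and work with the returned :class:`TreeResults`.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["gini_impurity", "best_split", "ClassificationTree", "TreeResults"]

_EPS_DECREASE = 1e-12   # relative guard against float-noise "improvements"
_BIG_NODE = 10_000      # above this, candidate thresholds are subsampled
_MAX_CANDIDATES = 256


def gini_impurity(counts) -> float:
    """Gini impurity sum_k p_k (1 - p_k) of a class-count vector.

    Zero iff the node is pure; maximal (1 - 1/K) at uniform proportions.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one count must be positive")
    p = counts / total
    return float(1.0 - np.dot(p, p))


def best_split(
    X,
    y,
    n_classes: int,
    min_leaf: int = 1,
    candidate_dims=None,
    criterion: str = "weighted",
    max_candidates: int = _MAX_CANDIDATES,
):
    """Best axis-aligned split of a node, or None.

    Scans midpoints between consecutive sorted distinct values on each
    candidate dimension (nodes above 10,000 samples evaluate an evenly
    subsampled set of at most ``max_candidates`` boundaries per dimension —
    an approximation for speed).  Both children must hold at least
    ``min_leaf`` samples.  Ties break to the lowest dimension index, then
    the smallest threshold.  Returns ``(dim, threshold, decrease)`` where
    ``decrease`` is the drop in total impurity cost, or None when no
    impurity-reducing split exists.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n = y.size
    if candidate_dims is None:
        candidate_dims = range(X.shape[1])
    if n < 2 * min_leaf:
        return None

    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    total = onehot.sum(axis=0)
    if criterion == "weighted":
        parent_cost = n * gini_impurity(total)
    elif criterion == "mean_gini":
        parent_cost = gini_impurity(total) / n
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if gini_impurity(total) == 0.0:
        return None

    best = None  # (cost, dim, threshold)
    for j in sorted(candidate_dims):
        xs = X[:, j]
        order = np.argsort(xs, kind="mergesort")
        xs_s = xs[order]
        cum = onehot[order].cumsum(axis=0)

        nl = np.arange(1, n)                      # left sizes at boundaries
        valid = xs_s[1:] > xs_s[:-1]
        valid &= (nl >= min_leaf) & (n - nl >= min_leaf)
        pos = np.flatnonzero(valid)
        if pos.size == 0:
            continue
        if n > _BIG_NODE and pos.size > max_candidates:
            keep = np.unique(
                np.linspace(0, pos.size - 1, max_candidates).round().astype(int)
            )
            pos = pos[keep]

        left = cum[pos]
        nls = (pos + 1).astype(float)
        nrs = n - nls
        sumsq_l = np.einsum("ik,ik->i", left, left)
        right = total[None, :] - left
        sumsq_r = np.einsum("ik,ik->i", right, right)
        if criterion == "weighted":
            cost = (nls - sumsq_l / nls) + (nrs - sumsq_r / nrs)
        else:
            cost = (1.0 - sumsq_l / nls**2) / nls + (1.0 - sumsq_r / nrs**2) / nrs

        k = int(np.argmin(cost))
        if best is None or cost[k] < best[0]:
            i = pos[k]
            mid = 0.5 * (xs_s[i] + xs_s[i + 1])
            if not np.isfinite(mid):
                # +inf sentinel values: keep the threshold finite so that
                # infinite coordinates always route right
                mid = xs_s[i]
            best = (float(cost[k]), j, float(mid))

    if best is None:
        return None
    cost, j, s = best
    if criterion == "weighted":
        decrease = parent_cost - cost
        if decrease <= _EPS_DECREASE * max(1.0, abs(parent_cost)):
            return None
        return j, s, float(decrease)
    # mean_gini: the split minimises the unweighted child sum, which can
    # exceed the parent's value; splitting stops only on purity/min_leaf.
    # The reported decrease stays in size-weighted units so that importances
    # remain non-negative and comparable.
    xs = X[:, j]
    left = xs <= s
    cl = np.bincount(y[left], minlength=n_classes)
    cr = np.bincount(y[~left], minlength=n_classes)
    weighted_decrease = (
        n * gini_impurity(total)
        - left.sum() * gini_impurity(cl)
        - (n - left.sum()) * gini_impurity(cr)
    )
    return j, s, float(max(weighted_decrease, 0.0))


@dataclass
class _Node:
    bounds_lo: np.ndarray
    bounds_hi: np.ndarray
    counts: np.ndarray
    depth: int
    feature: int = -1          # -1 marks a leaf
    threshold: float = np.nan
    left: int = -1
    right: int = -1

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def impurity(self) -> float:
        return gini_impurity(self.counts)


class ClassificationTree:
    """CART model over a rectangular parameter space.

    Parameters
    ----------
    X : (n, p) array or DataFrame of parameter values.
    y : length-n class labels (any hashable values).
    feature_names : optional names; taken from the DataFrame if present.
    bounds : optional (lower, upper) arrays of the root box; defaults to the
        data envelope.
    """

    def __init__(self, X, y, feature_names=None, classes=None, bounds=None):
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        y = np.asarray(y)
        if y.shape[0] != self.X.shape[0]:
            raise ValueError("X and y lengths differ")
        if classes is None:
            classes = sorted(pd.unique(y).tolist())
        self.classes_ = list(classes)
        code = {c: i for i, c in enumerate(self.classes_)}
        try:
            self.y = np.array([code[v] for v in y], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"label {exc} not in classes") from exc
        p = self.X.shape[1]
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(p)]
        )
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")
        if bounds is None:
            finite = np.where(np.isfinite(self.X), self.X, np.nan)
            lo = np.nanmin(finite, axis=0)
            hi = np.nanmax(finite, axis=0)
        else:
            lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        self.bounds_ = (lo, hi)

    def fit(
        self,
        min_leaf: int = 1000,
        max_depth: Optional[int] = None,
        max_leaves: Optional[int] = None,
        criterion: str = "weighted",
        mtry: Optional[int] = None,
        rng=None,
        sample_indices=None,
    ) -> "TreeResults":
        """Grow the tree and return a :class:`TreeResults`.

        Growth is best-first by impurity decrease, so ``max_leaves`` retains
        the most informative splits; without a limit the result equals
        depth-first growth.  ``mtry`` (with ``rng``) draws a fresh random
        subset of candidate dimensions at every node, as used inside random
        forests.  ``sample_indices`` fits on a resample of the data
        (bootstrap support).
        """
        if min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        p = self.X.shape[1]
        if mtry is not None:
            if not 1 <= mtry <= p:
                raise ValueError(f"mtry must be in [1, {p}]")
            if rng is None:
                rng = np.random.default_rng()
        if sample_indices is None:
            Xf, yf = self.X, self.y
        else:
            sample_indices = np.asarray(sample_indices, dtype=np.intp)
            Xf, yf = self.X[sample_indices], self.y[sample_indices]
        n, K = yf.size, len(self.classes_)

        nodes: list[_Node] = []
        train_leaf = np.zeros(n, dtype=np.intp)
        split_features: list[int] = []
        split_decreases: list[float] = []

        def make_node(idx, lo, hi, depth):
            counts = np.bincount(yf[idx], minlength=K).astype(float)
            node = _Node(bounds_lo=lo, bounds_hi=hi, counts=counts, depth=depth)
            nodes.append(node)
            return len(nodes) - 1, node

        def node_split(idx, depth):
            if max_depth is not None and depth >= max_depth:
                return None
            dims = (
                sorted(rng.choice(p, size=mtry, replace=False).tolist())
                if mtry is not None else None
            )
            return best_split(
                Xf[idx], yf[idx], K, min_leaf=min_leaf,
                candidate_dims=dims, criterion=criterion,
            )

        root_idx = np.arange(n, dtype=np.intp)
        lo, hi = self.bounds_
        _, root = make_node(root_idx, lo.copy(), hi.copy(), 0)
        train_leaf[:] = 0

        heap = []
        counter = 0
        split = node_split(root_idx, 0)
        if split is not None:
            heapq.heappush(heap, (-split[2], counter, 0, root_idx, split))
            counter += 1
        n_leaves = 1
        while heap and (max_leaves is None or n_leaves < max_leaves):
            _, _, node_id, idx, (j, s, dec) = heapq.heappop(heap)
            node = nodes[node_id]
            mask = Xf[idx, j] <= s
            idx_l, idx_r = idx[mask], idx[~mask]
            lo_l, hi_l = node.bounds_lo.copy(), node.bounds_hi.copy()
            lo_r, hi_r = node.bounds_lo.copy(), node.bounds_hi.copy()
            hi_l[j] = s
            lo_r[j] = s
            lid, _ = make_node(idx_l, lo_l, hi_l, node.depth + 1)
            rid, _ = make_node(idx_r, lo_r, hi_r, node.depth + 1)
            node.feature, node.threshold, node.left, node.right = j, s, lid, rid
            train_leaf[idx_l] = lid
            train_leaf[idx_r] = rid
            split_features.append(j)
            split_decreases.append(dec)
            n_leaves += 1
            for cid, cidx in ((lid, idx_l), (rid, idx_r)):
                csplit = node_split(cidx, nodes[cid].depth)
                if csplit is not None:
                    heapq.heappush(heap, (-csplit[2], counter, cid, cidx, csplit))
                    counter += 1

        return TreeResults(
            model=self,
            nodes=nodes,
            train_leaf=train_leaf,
            sample_indices=sample_indices,
            split_features=np.asarray(split_features, dtype=np.intp),
            split_decreases=np.asarray(split_decreases, dtype=float),
            criterion=criterion,
        )


class TreeResults:
    """A grown tree: nodes, regions, predictions and reports."""

    def __init__(self, model, nodes, train_leaf, sample_indices,
                 split_features, split_decreases, criterion):
        self.model = model
        self.nodes = nodes
        self.train_leaf = train_leaf
        self.sample_indices = sample_indices
        self.split_features = split_features
        self.split_decreases = split_decreases
        self.criterion = criterion

    # -- basic structure -------------------------------------------------
    @property
    def classes_(self):
        return self.model.classes_

    @property
    def feature_names(self):
        return self.model.feature_names

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaf_ids(self) -> np.ndarray:
        return np.array([i for i, nd in enumerate(self.nodes) if nd.feature < 0])

    @property
    def n_leaves(self) -> int:
        return int(self.leaf_ids.size)

    @property
    def n_branches(self) -> int:
        """Number of internal (branch) nodes, the Nb of the VI statistic."""
        return self.n_nodes - self.n_leaves

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes)

    # -- prediction ------------------------------------------------------
    def apply(self, X) -> np.ndarray:
        """Leaf node id for each row of X."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError("dimension mismatch")
        out = np.zeros(X.shape[0], dtype=np.intp)
        stack = [(0, np.arange(X.shape[0], dtype=np.intp))]
        while stack:
            node_id, idx = stack.pop()
            node = self.nodes[node_id]
            if node.feature < 0 or idx.size == 0:
                out[idx] = node_id
                continue
            mask = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Per-class leaf proportions for each row of X."""
        leaf = self.apply(X)
        counts = np.stack([self.nodes[i].counts for i in leaf])
        return counts / counts.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes_, dtype=object)[np.argmax(proba, axis=1)]

    # -- importance ------------------------------------------------------
    def importance_sums(self) -> np.ndarray:
        """Total impurity decrease attributed to each feature."""
        out = np.zeros(len(self.feature_names))
        np.add.at(out, self.split_features, self.split_decreases)
        return out

    def variable_importance(self) -> np.ndarray:
        """Per-feature impurity decrease divided by the branch count Nb."""
        if self.n_branches == 0:
            return np.zeros(len(self.feature_names))
        return self.importance_sums() / self.n_branches

    # -- region report ---------------------------------------------------
    def region_report(self, positive) -> pd.DataFrame:
        """Per-leaf share of space and of a positive class.

        ``positive`` is a boolean vector aligned with the *fitted* rows
        (after any resampling).  Under an LHS/uniform design the sample
        fraction of a leaf estimates its share of parameter-space volume.
        Columns: space_pct, density_pct (within-leaf positive rate),
        share_pct (leaf's share of all positives) and the leaf bounds.
        space_pct and share_pct each sum to 100.
        """
        positive = np.asarray(positive, dtype=bool)
        if positive.size != self.train_leaf.size:
            raise ValueError("positive mask must align with fitted rows")
        n = self.train_leaf.size
        total_pos = positive.sum()
        rows = []
        for lid in self.leaf_ids:
            in_leaf = self.train_leaf == lid
            n_leaf = int(in_leaf.sum())
            n_pos = int((in_leaf & positive).sum())
            node = self.nodes[lid]
            rule = self._rule_string(lid)
            rows.append({
                "leaf": int(lid),
                "rule": rule,
                "n": n_leaf,
                "space_pct": 100.0 * n_leaf / n,
                "density_pct": 100.0 * n_pos / n_leaf if n_leaf else np.nan,
                "share_pct": (100.0 * n_pos / total_pos) if total_pos else 0.0,
                "predicted": self.classes_[int(np.argmax(node.counts))],
            })
        return pd.DataFrame(rows)

    def _rule_string(self, node_id: int) -> str:
        lo, hi = self.model.bounds_
        node = self.nodes[node_id]
        parts = []
        for j, name in enumerate(self.feature_names):
            nlo, nhi = node.bounds_lo[j], node.bounds_hi[j]
            if nlo > lo[j] and nhi < hi[j]:
                parts.append(f"{nlo:.4g} < {name} <= {nhi:.4g}")
            elif nlo > lo[j]:
                parts.append(f"{name} > {nlo:.4g}")
            elif nhi < hi[j]:
                parts.append(f"{name} <= {nhi:.4g}")
        return " & ".join(parts) if parts else "(root)"

    # -- serialisation ---------------------------------------------------
    def _node_dict(self, node_id: int) -> dict:
        node = self.nodes[node_id]
        d = {
            "n": node.n,
            "counts": node.counts.astype(int).tolist(),
            "proportions": (node.counts / node.counts.sum()).tolist(),
            "impurity": node.impurity,
            "bounds_lo": node.bounds_lo.tolist(),
            "bounds_hi": node.bounds_hi.tolist(),
        }
        if node.feature >= 0:
            d["feature"] = self.feature_names[node.feature]
            d["threshold"] = node.threshold
            d["left"] = self._node_dict(node.left)
            d["right"] = self._node_dict(node.right)
        return d

    def to_json(self, path=None):
        """Nested-dict JSON export (dim, threshold, counts, children)."""
        payload = {
            "classes": [str(c) for c in self.classes_],
            "feature_names": self.feature_names,
            "criterion": self.criterion,
            "tree": self._node_dict(0),
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_dot(self, positive=None) -> str:
        """Graphviz DOT export; node labels show the share of parameter
        space and, when ``positive`` is given, the positive-class density."""
        n_root = self.nodes[0].n
        if positive is not None:
            positive = np.asarray(positive, dtype=bool)
        lines = ["digraph tree {", '  node [shape=box, style="rounded"];']
        for i, node in enumerate(self.nodes):
            space = 100.0 * node.n / n_root
            label = f"space {space:.0f}%"
            if positive is not None:
                # density over fitted rows routed through this node
                in_node = self._rows_through(i)
                dens = 100.0 * positive[in_node].mean() if in_node.size else 0.0
                label += f"\\ndensity {dens:.2g}%"
            if node.feature >= 0:
                label = f"{self.feature_names[node.feature]} <= {node.threshold:.3g}\\n" + label
            lines.append(f'  n{i} [label="{label}"];')
            if node.feature >= 0:
                lines.append(f"  n{i} -> n{node.left};")
                lines.append(f"  n{i} -> n{node.right};")
        lines.append("}")
        return "\n".join(lines)

    def _rows_through(self, node_id: int) -> np.ndarray:
        """Indices of fitted rows whose leaf lies under ``node_id``."""
        under = set()
        stack = [node_id]
        while stack:
            i = stack.pop()
            node = self.nodes[i]
            if node.feature < 0:
                under.add(i)
            else:
                stack.extend((node.left, node.right))
        return np.flatnonzero(np.isin(self.train_leaf, list(under)))

    def summary(self) -> str:
        y_fit = (
            self.model.y if self.sample_indices is None
            else self.model.y[self.sample_indices]
        )
        leaf_counts = np.stack([self.nodes[i].counts for i in self.train_leaf])
        train_pred = np.argmax(leaf_counts, axis=1)
        acc = float(np.mean(train_pred == y_fit))
        vi = self.variable_importance()
        order = np.argsort(vi)[::-1]
        lines = [
            "Classification tree results",
            "===========================",
            f"observations: {self.train_leaf.size}",
            f"classes:      {', '.join(map(str, self.classes_))}",
            f"leaves:       {self.n_leaves}   depth: {self.depth}   "
            f"branches: {self.n_branches}",
            f"criterion:    {self.criterion}",
            f"train accuracy: {acc:.4f}",
            "",
            "variable importance (impurity decrease / Nb):",
        ]
        for j in order:
            if vi[j] > 0:
                lines.append(f"  {self.feature_names[j]:>8s}  {vi[j]:.4f}")
        return "\n".join(lines)
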