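"""Random-Forest variable screening.

A bagged ensemble of regression trees ranks the candidate predictors by two
importance measures:

- %IncMSE: percent increase of out-of-bag (OOB) mean squared error when the
  predictor is permuted among each tree's OOB rows, averaged over trees (and
  over ``n_perm`` permutation draws);
- IncNodePurity: total reduction of the residual sum of squares attributed
  to splits on the predictor, summed over all trees.

Bagging and OOB bookkeeping are done here so the permutation importance is
defined identically regardless of the tree backend; the trees themselves are
scikit-learn ``DecisionTreeRegressor`` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RandomForest", "ImportanceReport", "fit_rf", "importance", "select_top_k"]


@dataclass
class RandomForest:
    """Bagged regression-tree ensemble with OOB bookkeeping.

    ``predict`` averages the member trees. Deterministic given the seed.
    """

    ntree: int
    mtry: int
    nodesize: int
    seed: int
    feature_names: list[str]
    trees: list = field(repr=False, default_factory=list)
    bootstrap_idx: list = field(repr=False, default_factory=list)
    x_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        out = np.zeros(len(x))
        for t in self.trees:
            out += t.predict(x)
        return out / len(self.trees)

    def oob_mask(self, tree_index: int, n: int) -> np.ndarray:
        m = np.ones(n, dtype=bool)
        m[self.bootstrap_idx[tree_index]] = False
        return m


def _split_xy(features, target_column: str = "agb"):
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != target_column]
        return features[cols].to_numpy(float), features[target_column].to_numpy(float), cols
    raise TypeError("expected a feature DataFrame with a target column")


def fit_rf(features: pd.DataFrame, ntree: int = 500, mtry: int = 3,
           nodesize: int = 10, seed: int = 0, target_column: str = "agb") -> RandomForest:
    """Fit the bagged ensemble (defaults: 500 trees, 3 candidate variables
    per split, terminal nodes of at least 10 observations)."""
    x, y, names = _split_xy(features, target_column)
    n, p = x.shape
    if ntree < 1 or not 1 <= mtry <= p or nodesize < 1:
        raise ValueError("invalid ntree/mtry/nodesize")
    if n < nodesize:
        raise ValueError("fewer rows than the terminal-node size")
    rng = np.random.default_rng(seed)
    model = RandomForest(ntree, mtry, nodesize, seed, names,
                         x_train=x, y_train=y)
    for _ in range(ntree):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=nodesize,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[idx], y[idx])
        model.trees.append(tree)
        model.bootstrap_idx.append(idx)
    return model


@dataclass
class ImportanceReport:
    """Per-variable importance table with ranks 1..p (1 = most important)."""

    table: pd.DataFrame  # columns: variable, inc_mse_pct, inc_node_purity, rank

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def top(self, k: int) -> list[str]:
        return select_top_k(self, k)


def _node_purity_gains(tree, p: int) -> np.ndarray:
    """Summed RSS reduction per feature over all internal nodes of a tree."""
    t = tree.tree_
    gains = np.zeros(p)
    left, right = t.children_left, t.children_right
    internal = left != -1
    w = t.weighted_n_node_samples
    # impurity is the node MSE, so w * impurity is the node RSS
    rss = w * t.impurity
    for node in np.flatnonzero(internal):
        gain = rss[node] - rss[left[node]] - rss[right[node]]
        gains[t.feature[node]] += gain
    return gains


def importance(model: RandomForest, features: pd.DataFrame | None = None,
               n_perm: int = 1, seed: int = 0,
               target_column: str = "agb") -> ImportanceReport:
    """OOB permutation importance (%IncMSE) and node-purity importance.

    %IncMSE for variable j = mean over trees of
    (OOB MSE with x_j permuted - baseline OOB MSE) / baseline * 100,
    averaged over ``n_perm`` permutation draws. A variable a tree never
    splits on contributes exactly zero for that tree.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if features is not None:
        x, y, names = _split_xy(features, target_column)
    else:
        x, y, names = model.x_train, model.y_train, model.feature_names
    n, p = x.shape
    rng = np.random.default_rng(seed)
    ratios = np.zeros((len(model.trees), p))
    for ti, tree in enumerate(model.trees):
        oob = model.oob_mask(ti, n)
        if not oob.any():
            continue
        x_oob = x[oob]
        y_oob = y[oob]
        base = float(np.mean((tree.predict(x_oob) - y_oob) ** 2))
        used = np.zeros(p, dtype=bool)
        used[tree.tree_.feature[tree.tree_.feature >= 0]] = True
        if base == 0:
            continue
        for j in np.flatnonzero(used):
            acc = 0.0
            for _ in range(n_perm):
                xp = x_oob.copy()
                xp[:, j] = xp[rng.permutation(len(xp)), j]
                acc += float(np.mean((tree.predict(xp) - y_oob) ** 2))
            ratios[ti, j] = (acc / n_perm - base) / base * 100.0
    inc_mse = ratios.mean(axis=0)
    purity = np.zeros(p)
    for tree in model.trees:
        purity += _node_purity_gains(tree, p)

    df = pd.DataFrame({
        "variable": names,
        "inc_mse_pct": inc_mse,
        "inc_node_purity": purity,
    })
    order = df.sort_values(
        by=["inc_mse_pct", "inc_node_purity", "variable"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    df["rank"] = 0
    df.loc[order, "rank"] = np.arange(1, p + 1)
    return ImportanceReport(df)


def select_top_k(report: ImportanceReport, k: int = 10) -> list[str]:
    """Top-k variables by %IncMSE; ties broken by IncNodePurity, then name."""
    if k <= 0:
        raise ValueError("k must be positive")
    df = report.table
    if k > len(df):
        raise ValueError(f"k={k} exceeds the {len(df)} candidate variables")
    return df.sort_values("rank").head(k)["variable"].tolist()
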