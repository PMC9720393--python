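"""Relative influence of farming practices on community composition.

Stagewise least-squares gradient boosting of shallow regression trees
(aggregated-boosted-tree style): each stage fits a depth-limited tree to
the current residuals on a random subsample and adds a shrunken copy of
its predictions.  The relative influence of a predictor is the sum of
squared-error improvements over all splits made on it, across all trees,
normalized to sum to 100%.

For a multivariate response (the grass/sedge/broadleaf shares of total
importance value per field), one model is fitted per response and the
per-response influence profiles averaged with equal weight, then
renormalized — the standard aggregation for guild-level composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .types import PracticeRecord, ValidationError

#: practice predictors used by default, with plot-style short labels
PREDICTOR_LABELS = {
    "rice_variety": "RV",
    "tillage_per_year": "T",
    "irrigation_1e3m3_ha": "I",
    "organic_fertilizer_1e3kg_ha": "OF",
    "green_manure_1e3kg_ha": "GM",
    "crayfish_kg_ha": "CF",
    "duckling_per_ha": "D",
    "hand_weeding_h_ha": "HW",
}


@dataclass
class ABTConfig:
    n_trees: int = 500
    shrinkage: float = 0.01
    max_depth: int = 3
    bag_fraction: float = 0.5
    min_samples_leaf: int = 2
    rng_seed: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not 0 < self.shrinkage <= 1:
            raise ValidationError("shrinkage must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValidationError("bag_fraction must be in (0, 1]")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")


@dataclass
class BoostedModel:
    """A fitted boosting ensemble for one response."""

    trees: list = field(repr=False, default_factory=list)
    init: float = 0.0
    shrinkage: float = 0.01
    columns: list[str] = field(default_factory=list)
    influence: pd.Series = None  # per original predictor, sums to 100
    loss_trace: np.ndarray = field(repr=False, default=None)

    def predict(self, x_encoded: np.ndarray) -> np.ndarray:
        pred = np.full(len(x_encoded), self.init)
        for tree in self.trees:
            pred += self.shrinkage * tree.predict(x_encoded)
        return pred


def _encode(x: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """One-hot encode object/categorical columns; map encoded → original."""
    encoded = pd.get_dummies(x, dtype=float)
    origin = {}
    for col in encoded.columns:
        src = next((c for c in x.columns if col == c or col.startswith(c + "_")), col)
        origin[col] = src
    return encoded.to_numpy(dtype=float), list(encoded.columns), origin


def _split_improvements(tree: DecisionTreeRegressor) -> np.ndarray:
    """Squared-error improvement of every split, attributed to its feature."""
    t = tree.tree_
    imp = np.zeros(tree.n_features_in_)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        gain = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        )
        imp[t.feature[node]] += max(gain, 0.0)
    return imp


def fit_boosted_trees(
    x: pd.DataFrame,
    y: Sequence[float],
    cfg: ABTConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> BoostedModel:
    """Fit one boosted ensemble and its per-predictor relative influence."""
    cfg = cfg or ABTConfig()
    cfg.validate()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValidationError("X and y must have the same number of observations")
    if n < 4:
        raise ValidationError("boosting needs at least 4 observations")
    if np.ptp(y) == 0:
        raise ValidationError("constant response: relative influence undefined")
    bag_size = max(int(round(cfg.bag_fraction * n)), 1)
    if bag_size < 2:
        raise ValidationError("bag_fraction × n must allow at least 2 observations")
    x_enc, columns, origin = _encode(x)
    if all(np.ptp(x_enc[:, j]) == 0 for j in range(x_enc.shape[1])):
        raise ValidationError("all covariates are constant: no usable splits")
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)

    model = BoostedModel(init=float(y.mean()), shrinkage=cfg.shrinkage, columns=columns)
    pred = np.full(n, model.init)
    raw_influence = np.zeros(len(columns))
    loss = np.empty(cfg.n_trees)
    for m in range(cfg.n_trees):
        bag = rng.choice(n, size=bag_size, replace=False) if bag_size < n else np.arange(n)
        resid = y - pred
        tree = DecisionTreeRegressor(
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x_enc[bag], resid[bag])
        pred += cfg.shrinkage * tree.predict(x_enc)
        raw_influence += _split_improvements(tree)
        model.trees.append(tree)
        loss[m] = float(((y - pred) ** 2).mean())
    model.loss_trace = loss

    per_col = pd.Series(raw_influence, index=columns)
    per_pred = per_col.groupby(per_col.index.map(origin.__getitem__)).sum()
    per_pred = per_pred.reindex(x.columns, fill_value=0.0)
    total = per_pred.sum()
    if total <= 0:
        raise ValidationError("no split improved the fit: influence undefined")
    model.influence = 100.0 * per_pred / total
    return model


@dataclass
class ABTResult:
    influence: pd.Series  # % per predictor, summing to 100
    per_response: pd.DataFrame  # predictors × responses, each column sums to 100
    models: dict = field(repr=False, default_factory=dict)
    config: ABTConfig = None

    def ranked(self) -> pd.Series:
        return self.influence.sort_values(ascending=False)


def practice_predictors(
    practices: Sequence[PracticeRecord], keys: Sequence[str]
) -> pd.DataFrame:
    """Predictor matrix for the given observation keys.

    Keys may be site ids or field labels ``site/field``; field-level keys
    replicate the site covariates across the site's fields.
    """
    by_site = {p.site_id: p for p in practices}
    rows = []
    for key in keys:
        site = str(key).split("/")[0]
        if site not in by_site:
            raise ValidationError(f"no practice record for observation {key!r}")
        p = by_site[site]
        rows.append({name: getattr(p, name) for name in PREDICTOR_LABELS})
    return pd.DataFrame(rows, index=pd.Index(keys, name="observation"))


def abt_relative_influence(
    practices: Sequence[PracticeRecord],
    guild_shares: pd.DataFrame,
    cfg: ABTConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ABTResult:
    """Aggregated relative influence of practices on guild composition.

    ``guild_shares`` is observations × guilds (percent of total IV per
    guild, one row per field or site).  One boosted model is fitted per
    guild; influence profiles are averaged with equal weight and
    renormalized to 100%.
    """
    cfg = cfg or ABTConfig()
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    x = practice_predictors(practices, guild_shares.index)
    models = {}
    per_response = {}
    for response in guild_shares.columns:
        model = fit_boosted_trees(x, guild_shares[response].to_numpy(), cfg, rng)
        models[response] = model
        per_response[response] = model.influence
    per_response = pd.DataFrame(per_response)
    agg = per_response.mean(axis=1)
    agg = 100.0 * agg / agg.sum()
    return ABTResult(influence=agg, per_response=per_response, models=models, config=cfg)
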