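"""Morphotype determinants: Shapley feature ranking and group statistics.

Which morphometric features most strongly separate experimental conditions?
A seeded gradient-boosted-tree classifier (condition vs control) is fitted
on the standardized per-cell feature matrix and each feature's contribution
to the model output is attributed with exact *interventional* Shapley
values computed directly on the tree structure: for a foreground sample x
and one background sample z, the value function is
``v(S) = f(x with features in S, z elsewhere)``, and for a decision tree
this game decomposes per leaf into an indicator product whose Shapley
values have a closed form.  For a leaf whose path constrains feature sets
P (satisfied by x only) and Q (satisfied by z only), the leaf contributes
``value * (|P|-1)! |Q|! / (|P|+|Q|)!`` to each feature in P and
``-value * |P|! (|Q|-1)! / (|P|+|Q|)!`` to each feature in Q; features
whose constraint both x and z satisfy are irrelevant, and a constraint
neither satisfies kills the leaf.  Averaging over a background set gives
attributions that satisfy local accuracy exactly:
``base + sum_i phi_i = f(x)``.  The brute-force enumeration
:func:`exact_shapley` is the independent oracle.

Group comparisons follow the classical recipe: one-way ANOVA, then
Dunnett's many-to-one comparisons against the control, with the
multivariate-t reference distribution evaluated by seeded Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core import ValidationError

log = logging.getLogger("fibromorph")

#: fixed classifier hyperparameters (documented; seeded per run)
GBT_PARAMS = dict(n_estimators=80, max_depth=3, learning_rate=0.1, subsample=1.0)


# ---------------------------------------------------------------------------
# exact Shapley oracle


def exact_shapley(value_function: Callable[[frozenset], float], n_features: int) -> np.ndarray:
    """Shapley values by full enumeration of all 2^n feature subsets.

    phi_i = sum_S |S|!(n-|S|-1)!/n! [v(S u {i}) - v(S)].  Intended as the
    independent oracle for the tree engine; n_features must be <= 10.
    """
    if n_features > 10:
        raise ValidationError("exact enumeration is limited to n_features <= 10")
    players = range(n_features)
    values = {}
    for r in range(n_features + 1):
        for s in combinations(players, r):
            values[frozenset(s)] = float(value_function(frozenset(s)))
    phi = np.zeros(n_features)
    fact = [factorial(k) for k in range(n_features + 1)]
    for i in players:
        for s, v in values.items():
            if i in s:
                continue
            w = fact[len(s)] * fact[n_features - len(s) - 1] / fact[n_features]
            phi[i] += w * (values[s | {i}] - v)
    return phi


# ---------------------------------------------------------------------------
# exact interventional tree Shapley


def _tree_leaves(tree, scale: float) -> list[tuple[float, np.ndarray, np.ndarray, np.ndarray]]:
    """Flatten an sklearn tree into leaves: (value, features, lows, highs).

    Each leaf is the conjunction of per-feature interval constraints
    ``low < x[f] <= high`` collected along its root path (sklearn splits
    send ``x <= threshold`` left).
    """
    t = tree.tree_
    leaves = []

    def walk(node: int, constraints: dict[int, list[float]]) -> None:
        f = t.feature[node]
        if f < 0:
            items = sorted(constraints.items())
            feats = np.array([k for k, _ in items], dtype=int)
            lows = np.array([v[0] for _, v in items])
            highs = np.array([v[1] for _, v in items])
            leaves.append((float(t.value[node].ravel()[0]) * scale, feats, lows, highs))
            return
        thr = float(t.threshold[node])
        lo, hi = constraints.get(f, [-np.inf, np.inf])
        constraints[f] = [lo, min(hi, thr)]
        walk(t.children_left[node], constraints)
        constraints[f] = [max(lo, thr), hi]
        walk(t.children_right[node], constraints)
        if lo == -np.inf and hi == np.inf:
            del constraints[f]
        else:
            constraints[f] = [lo, hi]

    walk(0, {})
    return leaves


class TreeShapExplainer:
    """Exact interventional Shapley attributions for boosted-tree models.

    Parameters
    ----------
    model : fitted ``GradientBoostingClassifier`` (binary)
        Attributions explain the decision function (log-odds), which is
        additive over trees.
    background : (m, p) array
        Background samples defining the interventional value function
        ``v(S) = mean_z f(x_S, z_{S^c})``.
    """

    def __init__(self, model: GradientBoostingClassifier, background: np.ndarray):
        if model.n_classes_ != 2:
            raise ValidationError("explainer supports binary classifiers")
        self.background = np.asarray(background, dtype=float)
        lr = model.learning_rate
        self.leaves = []
        for stage in model.estimators_:
            self.leaves.extend(_tree_leaves(stage[0], lr))
        # base value = v(empty set) = mean model output over the background
        self.base = float(np.mean(model.decision_function(self.background)))
        maxk = max((len(l[1]) for l in self.leaves), default=0)
        self._fact = np.array([factorial(k) for k in range(maxk + 2)], dtype=float)

    def shap_values(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """(phi, base): per-sample per-feature attributions and base value.

        ``base + phi.sum(axis=1)`` equals the model decision function on
        each sample exactly (up to float rounding).
        """
        X = np.asarray(X, dtype=float)
        Z = self.background
        n, p = X.shape
        m = Z.shape[0]
        phi = np.zeros((n, p))
        fact = self._fact
        for value, feats, lows, highs in self.leaves:
            A = (X[:, feats] > lows) & (X[:, feats] <= highs)  # (n, k)
            B = (Z[:, feats] > lows) & (Z[:, feats] <= highs)  # (m, k)
            pos = A[:, None, :] & ~B[None, :, :]               # x-only constraints
            neg = ~A[:, None, :] & B[None, :, :]               # z-only constraints
            dead = (~A[:, None, :] & ~B[None, :, :]).any(-1)   # leaf unreachable
            pc = pos.sum(-1)
            qc = neg.sum(-1)
            tot = pc + qc
            alive = ~dead
            wpos = np.where(
                alive & (pc > 0),
                fact[np.maximum(pc - 1, 0)] * fact[qc] / fact[tot],
                0.0,
            )
            wneg = np.where(
                alive & (qc > 0),
                fact[pc] * fact[np.maximum(qc - 1, 0)] / fact[tot],
                0.0,
            )
            phi[:, feats] += (value / m) * (
                (wpos[:, :, None] * pos).sum(1) - (wneg[:, :, None] * neg).sum(1)
            )
        return phi, self.base


# ---------------------------------------------------------------------------
# feature ranking


@dataclass
class ShapReport:
    """Feature ranking by mean absolute Shapley attribution.

    ``importance`` maps feature name -> pooled mean \|phi\|; ``ranking`` is
    the feature order (strongest first); ``phi`` holds per-sample
    attributions per comparison; ``accuracy`` is the cross-validated
    accuracy per comparison and ``reliable`` flags whether every model beat
    chance by a clear margin (rankings from near-chance models are suspect).
    """

    importance: pd.Series
    ranking: list[str]
    phi: dict[str, pd.DataFrame]
    accuracy: dict[str, float]
    chance: dict[str, float]
    reliable: bool
    seed: int
    dropped_features: list[str]


def rank_features_shap(
    matrix: pd.DataFrame,
    labels: Sequence[str] | None = None,
    control: str | None = None,
    feature_names: Sequence[str] | None = None,
    seed: int = 0,
    max_background: int = 64,
) -> ShapReport:
    """Rank features by Shapley attribution magnitude across conditions.

    Fits one seeded gradient-boosted-tree classifier per non-control
    condition (condition vs control; a plain binary fit when there are only
    two conditions), attributes the decision function with
    :class:`TreeShapExplainer`, and pools mean \|phi\| over comparisons.
    Features are standardized internally; constant features are dropped
    with a warning.  Model quality is reported so that rankings from
    near-chance classifiers can be flagged.
    """
    from .morphometry import FEATURE_NAMES

    if feature_names is None:
        feature_names = [f for f in FEATURE_NAMES if f in matrix.columns]
    if labels is None:
        labels = matrix["condition"]
    y = np.asarray(labels)
    conditions = sorted(set(y))
    if len(conditions) < 2:
        raise ValidationError("need >= 2 conditions to rank features")
    for cond in conditions:
        if (y == cond).sum() < 10:
            raise ValidationError(f"condition {cond!r} has fewer than 10 cells")
    if control is None:
        control = conditions[0]
    if control not in conditions:
        raise ValidationError(f"control condition {control!r} not in labels")

    X_all = matrix[list(feature_names)].to_numpy(dtype=float)
    sd = X_all.std(axis=0)
    keep = sd > 0
    dropped = [f for f, k in zip(feature_names, keep) if not k]
    if dropped:
        log.warning("rank_features_shap: dropping constant features %s", dropped)
    names = [f for f, k in zip(feature_names, keep) if k]
    X_all = (X_all[:, keep] - X_all[:, keep].mean(axis=0)) / sd[keep]

    rng = np.random.default_rng(seed)
    comparisons = [c for c in conditions if c != control]
    phi_frames: dict[str, pd.DataFrame] = {}
    accuracy: dict[str, float] = {}
    chance: dict[str, float] = {}
    pooled = np.zeros(len(names))
    reliable = True
    for cond in comparisons:
        sel = (y == cond) | (y == control)
        X = X_all[sel]
        yy = (y[sel] == cond).astype(int)
        model = GradientBoostingClassifier(random_state=seed, **GBT_PARAMS)
        cv = StratifiedKFold(n_splits=min(5, np.bincount(yy).min()), shuffle=True, random_state=seed)
        acc = float(cross_val_score(model, X, yy, cv=cv, scoring="accuracy").mean())
        model.fit(X, yy)
        ch = float(max(np.bincount(yy)) / len(yy))
        margin = 1.645 * np.sqrt(ch * (1 - ch) / len(yy))
        ok = acc > ch + margin
        reliable &= ok
        if not ok:
            log.warning(
                "rank_features_shap: comparison %r near chance (acc %.3f, chance %.3f); "
                "ranking unreliable", cond, acc, ch,
            )
        bg_idx = rng.choice(len(X), size=min(max_background, len(X)), replace=False)
        explainer = TreeShapExplainer(model, X[bg_idx])
        phi, _ = explainer.shap_values(X)
        phi_frames[cond] = pd.DataFrame(phi, columns=names)
        accuracy[cond] = acc
        chance[cond] = ch
        pooled += np.abs(phi).mean(axis=0)
    pooled /= len(comparisons)
    importance = pd.Series(pooled, index=names).sort_values(ascending=False)
    return ShapReport(
        importance=importance,
        ranking=list(importance.index),
        phi=phi_frames,
        accuracy=accuracy,
        chance=chance,
        reliable=reliable,
        seed=seed,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# ANOVA + Dunnett


@dataclass
class GroupStatsResult:
    """One-way ANOVA and Dunnett many-to-one comparisons vs control."""

    f_statistic: float
    anova_p: float
    group_means: pd.DataFrame
    dunnett: pd.DataFrame  # group, t, p_unadjusted, p_adjusted


def anova_f(groups: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p from explicit between/within sums of squares."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        raise ValidationError("zero within-group variance in all groups")
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    seed: int = 0,
    n_mc: int = 100_000,
) -> GroupStatsResult:
    """One-way ANOVA plus Dunnett's comparisons of each group vs control.

    The Dunnett adjusted p-value for comparison i is
    ``P(max_j |T_j| >= |t_i|)`` under the joint null of the comparison
    statistics (correlated through the shared control mean and pooled
    variance), evaluated by seeded Monte Carlo with ``n_mc`` draws of the
    group means and the pooled chi-square variance.  Identical groups give
    F = 0 and all p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if control not in groups:
        raise ValidationError(f"control group {control!r} not present")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, a in arrays.items():
        if a.size < 2:
            raise ValidationError(f"group {name!r} needs n >= 2")
    f_stat, p_anova = anova_f(arrays)
    names = [k for k in arrays if k != control]
    n0 = arrays[control].size
    ntot = sum(a.size for a in arrays.values())
    df = ntot - len(arrays)
    s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df
    x0 = arrays[control].mean()
    t_obs = np.array(
        [
            (arrays[g].mean() - x0) / np.sqrt(s2 * (1.0 / arrays[g].size + 1.0 / n0))
            if s2 > 0 else 0.0
            for g in names
        ]
    )
    rng = np.random.default_rng(seed)
    m0 = rng.normal(0.0, 1.0 / np.sqrt(n0), size=n_mc)
    sim_s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    max_t = np.zeros(n_mc)
    for g in names:
        ng = arrays[g].size
        mg = rng.normal(0.0, 1.0 / np.sqrt(ng), size=n_mc)
        tg = np.abs(mg - m0) / (sim_s * np.sqrt(1.0 / ng + 1.0 / n0))
        np.maximum(max_t, tg, out=max_t)
    p_adj = np.array([(np.count_nonzero(max_t >= abs(t)) + 1) / (n_mc + 1) for t in t_obs])
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)
    means = pd.DataFrame(
        {
            "group": list(arrays),
            "mean": [arrays[g].mean() for g in arrays],
            "sd": [arrays[g].std(ddof=1) for g in arrays],
            "n": [arrays[g].size for g in arrays],
        }
    )
    dunnett = pd.DataFrame(
        {
            "group": names,
            "t": t_obs,
            "p_unadjusted": p_unadj,
            "p_adjusted": np.minimum(p_adj, 1.0),
        }
    )
    return GroupStatsResult(
        f_statistic=f_stat, anova_p=p_anova, group_means=means, dunnett=dunnett
    )
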