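"""The 13 pattern-characterizing features.

Each unique pattern is summarized by features capturing its evolutionary
history and its position along the coding sequence:

========================  =====================================================
LOG_LIKE                  log-likelihood (nats) of the pattern under a
                          homogeneous two-state gain/loss Markov model fit to
                          the whole pattern collection (pruning algorithm)
ONES_KNOWN                fraction of 1s among non-missing entries
SANKOFF_G1L3              minimal parsimony cost, loss = 3 x gain
SANKOFF_G3L1              minimal parsimony cost, gain = 3 x loss
IN_AMPHIBIAN .. IN_PROTIST  1 iff the pattern has an intron in the group
LCA_AGE                   age (MY) of the MRCA of intron-bearing species
                          (Dollo parsimony: single origin at that node)
MED_POSITION              median human CDS offset (nt) of the occurrences
MED_REL_POSITION          median of offset / CDS length
========================  =====================================================

The gain/loss model is a deliberate simplification of branch-heterogeneous
intron-evolution models: one gain rate, one loss rate and a free root
distribution shared by all branches.  It preserves the feature's meaning —
how typical a pattern's history is relative to the bulk of introns — while
being fully reproducible from the pattern data alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .patterns import JUNCTION, MISSING, UniquePattern
from .phylo import CladeMap, Phylogeny

__all__ = [
    "FEATURE_NAMES",
    "BINARY_FEATURES",
    "GainLossModel",
    "FitError",
    "sankoff_cost",
    "dollo_lca_age",
    "clade_and_count_features",
    "fit_gain_loss",
    "pattern_log_likelihood",
    "position_features",
    "build_feature_table",
    "FeatureScaler",
]

FEATURE_NAMES = [
    "LOG_LIKE",
    "ONES_KNOWN",
    "SANKOFF_G1L3",
    "SANKOFF_G3L1",
    "IN_AMPHIBIAN",
    "IN_FISH",
    "IN_BIRD",
    "IN_FUNGI",
    "IN_PLANT",
    "IN_PROTIST",
    "LCA_AGE",
    "MED_POSITION",
    "MED_REL_POSITION",
]
BINARY_FEATURES = [f for f in FEATURE_NAMES if f.startswith("IN_")]

_CLADE_FOR_FEATURE = {
    "IN_AMPHIBIAN": "amphibian",
    "IN_FISH": "fish",
    "IN_BIRD": "bird",
    "IN_FUNGI": "fungi",
    "IN_PLANT": "plant",
    "IN_PROTIST": "protist",
}


class FitError(RuntimeError):
    """Optimizer failure; carries the best parameters seen so far."""

    def __init__(self, message: str, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics


def _tip_values(pattern: UniquePattern, tree: Phylogeny) -> np.ndarray:
    """Pattern values reordered to the tree's leaf order."""
    vals = np.empty(tree.n_leaves, dtype=np.int8)
    for i, name in enumerate(tree.taxa):
        vals[i] = pattern.values[pattern.species.index(name)]
    return vals


# -- parsimony -------------------------------------------------------------

def sankoff_cost(pattern: UniquePattern, tree: Phylogeny, gain_cost: float, loss_cost: float) -> float:
    """Minimal total cost of gains/losses explaining the tip states.

    Sankoff dynamic program on states {0 = absent, 1 = present}; transitions
    cost ``gain_cost`` for 0->1 and ``loss_cost`` for 1->0, staying costs 0.
    Missing tips (value 2) take either state at no cost; both root states
    are free.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("costs must be positive")
    tips = _tip_values(pattern, tree)
    INF = np.inf
    cost = np.zeros((tree.n_nodes, 2))
    trans = np.array([[0.0, gain_cost], [loss_cost, 0.0]])  # [parent, child]
    leaf_of_node = {int(tree.leaf_nodes[i]): i for i in range(tree.n_leaves)}
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            v = tips[leaf_of_node[node]]
            if v == MISSING:
                cost[node] = (0.0, 0.0)
            else:
                cost[node] = (0.0, INF) if v == 0 else (INF, 0.0)
        else:
            for s in (0, 1):
                cost[node, s] = sum(
                    min(cost[c, 0] + trans[s, 0], cost[c, 1] + trans[s, 1])
                    for c in kids
                )
    return float(cost[tree.root].min())


def dollo_lca_age(pattern: UniquePattern, tree: Phylogeny) -> float:
    """Age (MY) of the single origin of the intron under Dollo parsimony.

    Dollo allows one gain and unlimited losses, so the origin is the MRCA of
    all intron-bearing (value 1) species.
    """
    bearers = [s for s, v in zip(pattern.species, pattern.values) if v == JUNCTION]
    if not bearers:
        raise ValueError("pattern has no intron-bearing species")
    return tree.mrca_age(bearers)


def clade_and_count_features(pattern: UniquePattern, clades: CladeMap) -> dict[str, float]:
    """ONES_KNOWN and the six IN_<group> indicators."""
    vals = np.asarray(pattern.values)
    known = int((vals != MISSING).sum())
    if known == 0:
        raise ValueError("pattern is entirely missing; ONES_KNOWN undefined")
    out = {"ONES_KNOWN": float((vals == JUNCTION).sum()) / known}
    for feat, group in _CLADE_FOR_FEATURE.items():
        members = clades.get(group, set())
        out[feat] = float(any(
            pattern.values[pattern.species.index(m)] == JUNCTION
            for m in members if m in pattern.species
        ))
    return out


# -- two-state gain/loss Markov model --------------------------------------

@dataclass
class GainLossModel:
    """Homogeneous two-state CTMC on the tree: 0 -absent-> 1 at rate ``gain``
    (events/MY), 1 -> 0 at rate ``loss``; root state ~ (1-pi1, pi1)."""

    gain: float
    loss: float
    pi1: float
    total_log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if not (self.gain >= 0 and self.loss >= 0 and np.isfinite(self.gain + self.loss)):
            raise ValueError("rates must be finite and non-negative")
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must be a probability")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[i, j] = P(state j after time t | state i)."""
        s = self.gain + self.loss
        if s == 0:
            return np.eye(2)
        e = np.exp(-s * t)
        p1_inf = self.gain / s
        p01 = p1_inf * (1 - e)
        p11 = p1_inf + (1 - p1_inf) * e
        return np.array([[1 - p01, p01], [1 - p11, p11]])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"gain": self.gain, "loss": self.loss, "pi1": self.pi1,
                 "total_log_likelihood": self.total_log_likelihood},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GainLossModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _pattern_matrix(patterns: list[UniquePattern], tree: Phylogeny) -> np.ndarray:
    return np.stack([_tip_values(p, tree) for p in patterns])


def _log_likelihoods(tips: np.ndarray, tree: Phylogeny, model: GainLossModel) -> np.ndarray:
    """Pruning-algorithm log-likelihood for each row of ``tips``.

    Missing tips (2) contribute likelihood 1 in both states.  Vectorized over
    patterns; partial likelihoods are renormalized per node with the log of
    the scaling accumulated, so long trees do not underflow.
    """
    n_pat = tips.shape[0]
    partial = np.ones((tree.n_nodes, n_pat, 2))
    logscale = np.zeros(n_pat)
    leaf_of_node = {int(tree.leaf_nodes[i]): i for i in range(tree.n_leaves)}
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            col = tips[:, leaf_of_node[node]]
            partial[node, :, 0] = (col != 1)
            partial[node, :, 1] = (col != 0)
        else:
            acc = np.ones((n_pat, 2))
            for c in kids:
                P = model.transition_matrix(float(tree.edge_length[c]))
                acc *= partial[c] @ P.T
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            partial[node] = acc / mx[:, None]
            logscale += np.log(mx)
    root_like = partial[tree.root] @ np.array([1 - model.pi1, model.pi1])
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale


def pattern_log_likelihood(pattern: UniquePattern, tree: Phylogeny, model: GainLossModel) -> float:
    """LOG_LIKE feature: log P(tip values | tree, model) in nats (<= 0)."""
    return float(_log_likelihoods(_pattern_matrix([pattern], tree), tree, model)[0])


def fit_gain_loss(
    patterns: list[UniquePattern],
    tree: Phylogeny,
    weight_by_multiplicity: bool = True,
    *,
    n_starts: int = 4,
    seed: int = 0,
) -> GainLossModel:
    """Maximum-likelihood gain/loss rates and root distribution.

    Maximizes the (multiplicity-weighted) sum of pattern log-likelihoods by
    L-BFGS-B over (log gain, log loss, logit pi1), multi-started.  Identical
    tip vectors are pooled so each distinct vector is evaluated once.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    tips = _pattern_matrix(patterns, tree)
    weights = np.array(
        [p.multiplicity if weight_by_multiplicity else 1.0 for p in patterns], float
    )
    uniq, inverse = np.unique(tips, axis=0, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inverse, weights)

    def negloglik(theta: np.ndarray) -> float:
        model = GainLossModel(np.exp(theta[0]), np.exp(theta[1]), expit(theta[2]))
        ll = _log_likelihoods(uniq, tree, model)
        if not np.isfinite(ll).all():
            return 1e12
        return -float(w @ ll)

    rng = np.random.default_rng(seed)
    scale = tree.root_age or 1.0
    best = None
    diagnostics = []
    for k in range(n_starts):
        if k == 0:
            x0 = np.array([np.log(1.0 / scale), np.log(1.0 / scale), 0.0])
        else:
            x0 = np.array([
                np.log(rng.uniform(0.05, 5.0) / scale),
                np.log(rng.uniform(0.05, 5.0) / scale),
                rng.normal(0, 1),
            ])
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=[(-30, 5), (-30, 5), (-12, 12)])
        diagnostics.append({"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("gain/loss fit failed", best=best, diagnostics=diagnostics)
    model = GainLossModel(
        float(np.exp(best.x[0])), float(np.exp(best.x[1])), float(expit(best.x[2])),
        total_log_likelihood=-float(best.fun),
    )
    if not any(d["success"] for d in diagnostics):
        warnings.warn("gain/loss optimizer reported non-convergence; returning best-so-far")
    return model


# -- positions and the assembled table -------------------------------------

def position_features(pattern: UniquePattern) -> tuple[float, float]:
    """(MED_POSITION, MED_REL_POSITION) over the pattern's occurrences.

    Medians of even counts are the mean of the two middle values.
    """
    positions, relative = [], []
    for o in pattern.occurrences:
        if o.position is None or o.cds_length is None:
            raise ValueError(
                f"occurrence {o.set_id}:{o.column} lacks position metadata"
            )
        positions.append(o.position)
        relative.append(o.position / o.cds_length)
    if not positions:
        raise ValueError("pattern has no occurrences with recorded positions")
    return float(np.median(positions)), float(np.median(relative))


def build_feature_table(
    patterns: list[UniquePattern],
    tree: Phylogeny,
    clades: CladeMap,
    model: GainLossModel,
) -> pd.DataFrame:
    """One row of the 13 features per unique pattern (plus a 'label' column).

    Deterministic given its inputs; the index is the pattern string.
    """
    tips = _pattern_matrix(patterns, tree)
    loglike = _log_likelihoods(tips, tree, model)
    rows = []
    for i, p in enumerate(patterns):
        med_pos, med_rel = position_features(p)
        row = {"LOG_LIKE": float(loglike[i])}
        row.update(clade_and_count_features(p, clades))
        row["SANKOFF_G1L3"] = sankoff_cost(p, tree, 1.0, 3.0)
        row["SANKOFF_G3L1"] = sankoff_cost(p, tree, 3.0, 1.0)
        row["LCA_AGE"] = dollo_lca_age(p, tree)
        row["MED_POSITION"] = med_pos
        row["MED_REL_POSITION"] = med_rel
        row["label"] = p.label
        rows.append(row)
    index = pd.Index([p.pattern_string() for p in patterns], name="pattern")
    return pd.DataFrame(rows, index=index)[FEATURE_NAMES + ["label"]]


@dataclass
class FeatureScaler:
    """Z-scores continuous features, leaves the binary indicators as 0/1.

    Standardization parameters are estimated once on the training table and
    stored with the model so prediction uses the same transform.
    """

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "FeatureScaler":
        cont = [c for c in FEATURE_NAMES if c not in BINARY_FEATURES]
        mean = table[cont].mean()
        std = table[cont].std(ddof=0).replace(0.0, 1.0)
        return cls(mean=mean, std=std)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[FEATURE_NAMES].copy()
        out[self.mean.index] = (out[self.mean.index] - self.mean) / self.std
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "std": self.std.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=pd.Series(d["mean"]), std=pd.Series(d["std"]))
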