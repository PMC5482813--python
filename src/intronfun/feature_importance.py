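"""Feature-contribution battery.

Four complementary views of how much each feature drives the predictions:

1. **Mutual information** between each feature and the predicted labels
   (plug-in estimate; continuous features discretized into equal-frequency
   bins; bits).
2. **Leave-one-out performance**: retrain on 12 of the 13 features and
   measure Performance(F) = sum_p (Pr_F(p) - Pr_0(p))^2 against the
   full-feature predictions Pr_0 — the larger, the more the omitted feature
   mattered.
3. **Single-feature performance**: same distance when training on one
   feature alone — the smaller, the more that feature alone suffices.
4. **Sequential remove-two-add-one selection**: repeatedly drop the pair of
   kept features whose removal hurts Performance least, then re-admit the
   rejected feature that helps most; one net removal per iteration until a
   single feature survives.

All retrainings share one initialization scheme and seed so that distances
reflect the feature sets, not restart luck.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noisy_label_model import EMConfig, TrainingSet, fit_em, prob_functional

__all__ = [
    "ImportanceReport",
    "mutual_information",
    "subset_performance",
    "leave_one_out",
    "single_feature",
    "sequential_selection",
    "importance_battery",
]

#: restarts used for every retraining inside the battery
BATTERY_RESTARTS = 10
MI_BINS = 10


@dataclass
class ImportanceReport:
    mutual_info: pd.Series
    leave_one_out: pd.Series
    single_feature: pd.Series
    elimination_order: list[str]
    survivor: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "mutual_info_bits": self.mutual_info,
            "leave_one_out_distance": self.leave_one_out,
            "single_feature_distance": self.single_feature,
        })
        rank = {name: i for i, name in enumerate(self.elimination_order)}
        frame["elimination_rank"] = [rank.get(f, np.nan) for f in frame.index]
        return frame


def _discretize(values: np.ndarray, bins: int = MI_BINS) -> np.ndarray:
    values = np.asarray(values)
    if len(np.unique(values)) <= 2:
        return values.astype(int)
    binned = pd.qcut(values, q=bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def mutual_information(feature_values: np.ndarray, predicted_labels: np.ndarray,
                       bins: int = MI_BINS) -> float:
    """Plug-in mutual information I(X; Y) in bits (0 log 0 := 0).

    Continuous features are discretized into ``bins`` equal-frequency bins;
    binary features are used as-is.  A constant label vector carries no
    information: returns 0 with a warning.
    """
    y = np.asarray(predicted_labels).astype(int)
    if feature_values.shape[0] != y.shape[0]:
        raise ValueError("feature and label lengths differ")
    if len(np.unique(y)) < 2:
        warnings.warn("constant label vector; mutual information is 0")
        return 0.0
    x = _discretize(feature_values, bins)
    joint = pd.crosstab(x, y).to_numpy(float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


#: EM tolerance inside the battery; distances are insensitive below this and
#: hundreds of retrainings must stay tractable
BATTERY_TOL = 1e-6
BATTERY_MAX_ITER = 300


def _battery_config(config: EMConfig | None) -> EMConfig:
    base = config or EMConfig()
    # pure-noise subsets sit on a likelihood ridge where only theta11*p is
    # identifiable; their predictions stabilize long before (theta, w) do,
    # so the battery accepts the best restart instead of erroring
    return EMConfig(tol=max(base.tol, BATTERY_TOL),
                    max_iter=min(base.max_iter, BATTERY_MAX_ITER),
                    m_step_method=base.m_step_method,
                    learning_rate=base.learning_rate,
                    n_restarts=min(base.n_restarts, BATTERY_RESTARTS),
                    seed=base.seed, threshold=base.threshold,
                    require_convergence=False)


def _fit_subset(data: TrainingSet, names: list[str], config: EMConfig):
    cols = [data.feature_names.index(n) for n in names]
    sub = TrainingSet(x=data.x[:, cols], z=data.z, weights=data.weights,
                      feature_names=list(names))
    fit = fit_em(sub, config)
    return sub, fit


def _predictions(data: TrainingSet, names: list[str], config: EMConfig) -> np.ndarray:
    sub, fit = _fit_subset(data, names, config)
    return fit.params.theta11 * prob_functional(sub.x, fit.params)


def subset_performance(features_subset: list[str], full_predictions: np.ndarray,
                       data: TrainingSet, config: EMConfig | None = None) -> float:
    """Performance(F) = sum_p (Pr_F(p) - Pr_0(p))^2; larger = worse agreement."""
    if not features_subset:
        raise ValueError("feature subset must be non-empty")
    cfg = _battery_config(config)
    pr_f = _predictions(data, list(features_subset), cfg)
    return float(((pr_f - full_predictions) ** 2).sum())


def leave_one_out(data: TrainingSet, full_predictions: np.ndarray,
                  config: EMConfig | None = None) -> pd.Series:
    """Per feature: distance of the model retrained without it (higher = more important)."""
    names = data.feature_names
    return pd.Series({
        f: subset_performance([n for n in names if n != f], full_predictions, data, config)
        for f in names
    })


def single_feature(data: TrainingSet, full_predictions: np.ndarray,
                   config: EMConfig | None = None) -> pd.Series:
    """Per feature: distance of the model trained on it alone (lower = stronger alone)."""
    return pd.Series({
        f: subset_performance([f], full_predictions, data, config)
        for f in data.feature_names
    })


def sequential_selection(data: TrainingSet, config: EMConfig | None = None,
                         full_predictions: np.ndarray | None = None
                         ) -> tuple[list[str], str]:
    """Remove-two-add-one selection; returns (elimination order, survivor).

    Each iteration removes the pair of kept features whose joint removal
    raises Performance least, then re-admits the feature from the whole
    rejected set whose return lowers Performance most; 13 features thus take
    12 iterations to reach one survivor.
    """
    names = list(data.feature_names)
    if len(names) < 3:
        raise ValueError("sequential selection needs at least 3 features")
    cfg = _battery_config(config)
    if full_predictions is None:
        full_predictions = _predictions(data, names, cfg)

    cache: dict[frozenset, float] = {}

    def perf(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = subset_performance(list(subset), full_predictions, data, cfg)
        return cache[key]

    kept = list(names)
    rejected: list[str] = []
    elimination: list[str] = []
    while len(kept) > 1:
        if len(kept) == 2:
            best_pair = tuple(kept)  # only one pair; no scoring needed
        else:
            best_pair, best_cost = None, None
            for pair in itertools.combinations(kept, 2):
                cost = perf(tuple(f for f in kept if f not in pair))
                if best_cost is None or cost < best_cost:
                    best_pair, best_cost = pair, cost
        kept = [f for f in kept if f not in best_pair]
        rejected.extend(best_pair)
        if rejected:
            best_add, best_add_cost = None, None
            for f in rejected:
                cost = perf(tuple(kept + [f]))
                if best_add_cost is None or cost < best_add_cost:
                    best_add, best_add_cost = f, cost
            rejected.remove(best_add)
            kept.append(best_add)
        # elimination = rejected features in the order they (last) left the kept set
        elimination = [f for f in elimination if f in rejected]
        elimination.extend(f for f in rejected if f not in elimination)
    return elimination, kept[0]


def importance_battery(data: TrainingSet, config: EMConfig | None = None) -> ImportanceReport:
    """Run all four techniques on one training set."""
    cfg = _battery_config(config)
    sub, full_fit = _fit_subset(data, list(data.feature_names), cfg)
    p1 = prob_functional(sub.x, full_fit.params)
    full_predictions = full_fit.params.theta11 * p1
    # MI uses labels thresholded on p(y=1|x): thresholding the observed-label
    # marginal theta11*p at T = 0.5 is degenerate whenever theta11 <= T
    # (nothing would ever be predicted functional)
    predicted = (p1 > cfg.threshold).astype(int)
    mi = pd.Series({
        f: mutual_information(data.x[:, i], predicted)
        for i, f in enumerate(data.feature_names)
    })
    loo = leave_one_out(data, full_predictions, cfg)
    single = single_feature(data, full_predictions, cfg)
    order, survivor = sequential_selection(data, cfg, full_predictions)
    return ImportanceReport(mutual_info=mi, leave_one_out=loo,
                            single_feature=single,
                            elimination_order=order, survivor=survivor)
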