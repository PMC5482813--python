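"""Logistic regression with one-sided label noise, trained by EM.

The probability that pattern ``x`` is truly functional (hidden label
``y = 1``) is logistic::

    p(y=1 | x; w) = 1 / (1 + exp(-w.x + w0))

Note the sign convention: the offset ``w0`` enters the exponent with a plus
sign, so the logit is ``w.x - w0``.

The observed label ``z`` is a noisy, one-sided version of ``y``: a truly
functional pattern is annotated functional with probability ``theta11``
(theta_11 = p(z=1 | y=1)), while a truly non-functional pattern is never
annotated functional (theta_01 = 0, theta_00 = 1).  The observed-data
log-likelihood

    l(w, theta) = sum_t log sum_i p(z_t | y_t=i; theta) p(y_t=i | x_t; w)

is maximized by EM.  The E-step computes responsibilities
``c_t1 = p(y_t=1 | z_t, x_t)``; the M-step updates ``theta11`` in closed
form and maximizes a responsibility-weighted logistic objective ``L2(w)``
(concave) by Newton's method with step halving, falling back to gradient
ascent if the Hessian is singular.

Two derived quantities matter scientifically: ``theta11`` itself (the
fraction of truly functional patterns that are annotated) and
``P10 = p(y=1 | z=0)`` (the fraction of annotated-non-functional patterns
that are actually functional).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelParams",
    "TrainingSet",
    "EMConfig",
    "FitResult",
    "prob_functional",
    "observed_log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "classify",
    "predicted_scores",
    "estimate_p10",
    "save_model",
    "load_model",
    "DegenerateLabelsError",
    "EMConvergenceError",
]

NEG_INF = -np.inf


class DegenerateLabelsError(ValueError):
    """theta11 = 0 while some observed label is 1: impossible configuration."""


@dataclass
class ModelParams:
    """Logistic weights, offset and the label-noise parameter.

    Structural constants: theta01 = 0, theta00 = 1, theta10 = 1 - theta11.
    """

    w: np.ndarray
    w0: float
    theta11: float

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if not np.isfinite(self.w).all() or not np.isfinite(self.w0):
            raise ValueError("weights must be finite")
        if not 0.0 <= self.theta11 <= 1.0:
            raise ValueError("theta11 must lie in [0, 1]")

    @property
    def theta10(self) -> float:
        return 1.0 - self.theta11

    def to_dict(self) -> dict:
        return {"w": self.w.tolist(), "w0": self.w0, "theta11": self.theta11}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(w=np.asarray(d["w"], float), w0=float(d["w0"]), theta11=float(d["theta11"]))


@dataclass
class TrainingSet:
    """Feature matrix, observed binary labels and optional per-row weights."""

    x: np.ndarray
    z: np.ndarray
    weights: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.asarray(self.z).astype(int)
        if self.x.shape[0] != self.z.shape[0]:
            raise ValueError("x and z lengths differ")
        if self.x.shape[0] < 1:
            raise ValueError("empty training set")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.z.shape:
                raise ValueError("weights length differs from labels")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def w_or_ones(self) -> np.ndarray:
        return self.weights if self.weights is not None else np.ones(self.n)

    @classmethod
    def from_table(cls, table: pd.DataFrame, labels: np.ndarray, weights=None) -> "TrainingSet":
        return cls(x=table.to_numpy(float), z=np.asarray(labels),
                   weights=weights, feature_names=list(table.columns))


@dataclass
class EMConfig:
    tol: float = 1e-8               # absolute improvement of the observed log-likelihood
    max_iter: int = 2000
    m_step_method: str = "newton"   # or "gradient"
    learning_rate: float = 1e-3     # tau, gradient-ascent only
    m_step_max_iter: int = 50
    n_restarts: int = 100
    seed: int = 0
    threshold: float = 0.5
    require_convergence: bool = True  # error if no restart converges

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


@dataclass
class FitResult:
    params: ModelParams
    log_likelihood: float
    trajectory: list[float]
    responsibilities: np.ndarray
    restart_summary: pd.DataFrame = field(default=None, repr=False)
    n_iter: int = 0
    converged: bool = True


def _stable_sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def prob_functional(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """p(y=1 | x) = 1 / (1 + exp(-w.x + w0)), numerically stable."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != params.w.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match weights {params.w.shape[0]}"
        )
    return _stable_sigmoid(x @ params.w - params.w0)


def _z_marginal(p1: np.ndarray, z: np.ndarray, theta11: float) -> np.ndarray:
    """p(z_t | x_t): theta11*p1 when z=1, 1 - theta11*p1 when z=0."""
    return np.where(z == 1, theta11 * p1, 1.0 - theta11 * p1)


def observed_log_likelihood(data: TrainingSet, params: ModelParams) -> float:
    """Observed-data log-likelihood in nats (weighted if the set is weighted).

    theta11 = 0 with a positive label yields -inf (a defined sentinel).
    """
    p1 = prob_functional(data.x, params)
    pz = _z_marginal(p1, data.z, params.theta11)
    with np.errstate(divide="ignore"):
        terms = np.log(pz)
    return float(np.dot(data.w_or_ones, terms))


def e_step(data: TrainingSet, params: ModelParams) -> np.ndarray:
    """Responsibilities c[t, i] = p(y_t = i | z_t, x_t); rows sum to 1.

    One-sided noise forces c_t1 = 1 whenever z_t = 1.
    """
    p1 = prob_functional(data.x, params)
    c1 = np.empty(data.n)
    pos = data.z == 1
    if pos.any() and params.theta11 == 0.0:
        raise DegenerateLabelsError("theta11 = 0 but positive labels observed")
    c1[pos] = 1.0
    neg = ~pos
    # theta11*p -> 1 makes z=0 (almost) impossible; the posterior limit is 1
    denom = np.maximum(1.0 - params.theta11 * p1[neg], 1e-300)
    c1[neg] = np.minimum((1.0 - params.theta11) * p1[neg] / denom, 1.0)
    return np.column_stack([1.0 - c1, c1])


def _weighted_logistic_objective(beta: np.ndarray, design: np.ndarray,
                                 c1: np.ndarray, sw: np.ndarray) -> float:
    eta = design @ beta
    # sum_t sw_t [c1 log p + (1-c1) log(1-p)] in a softplus-stable form
    return float(np.dot(sw, c1 * eta - np.logaddexp(0.0, eta)))


def _maximize_l2(design: np.ndarray, c1: np.ndarray, sw: np.ndarray,
                 beta0: np.ndarray, config: EMConfig) -> np.ndarray:
    """Maximize the responsibility-weighted logistic objective L2.

    Newton with step halving by default (the objective is concave); gradient
    ascent with the configured learning rate either on request or when the
    Hessian solve fails.
    """
    beta = beta0.copy()
    obj = _weighted_logistic_objective(beta, design, c1, sw)
    method = config.m_step_method
    for _ in range(config.m_step_max_iter):
        p = _stable_sigmoid(design @ beta)
        grad = design.T @ (sw * (c1 - p))
        if method == "newton":
            h = sw * p * (1.0 - p)
            hess = design.T @ (design * h[:, None])
            try:
                step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
            except np.linalg.LinAlgError:
                warnings.warn("singular Hessian in M-step; falling back to gradient ascent")
                method = "gradient"
                continue
        else:
            step = config.learning_rate * grad
        # backtrack until the concave objective does not decrease
        for _ in range(40):
            cand = beta + step
            cand_obj = _weighted_logistic_objective(cand, design, c1, sw)
            if cand_obj >= obj - 1e-12:
                break
            step = step / 2.0
        else:
            return beta
        improvement = cand_obj - obj
        beta, obj = cand, cand_obj
        if abs(improvement) < 1e-12 and np.linalg.norm(grad) < 1e-8:
            break
    return beta


def m_step(data: TrainingSet, responsibilities: np.ndarray,
           current: ModelParams, config: EMConfig) -> ModelParams:
    """Closed-form theta11 update plus weighted-logistic maximization of w.

    theta11 = sum_t c_t1 1{z_t=1} / sum_t c_t1; w maximizes
    L2(w) = sum_t c_t1 log p_t + c_t0 log(1 - p_t).
    """
    c1 = responsibilities[:, 1]
    sw = data.w_or_ones
    denom = float(np.dot(sw, c1))
    theta11 = float(np.dot(sw, c1 * (data.z == 1)) / denom) if denom > 0 else 0.0
    design = np.column_stack([data.x, -np.ones(data.n)])  # last column carries -w0
    beta0 = np.append(current.w, current.w0)
    beta = _maximize_l2(design, c1, sw, beta0, config)
    return ModelParams(w=beta[:-1], w0=float(beta[-1]), theta11=theta11)


def _initial_weights(data: TrainingSet) -> tuple[np.ndarray, float]:
    """Plain logistic fit of z on x, used to initialize every restart."""
    if len(np.unique(data.z)) < 2:
        return np.zeros(data.x.shape[1]), 0.0
    lr = LogisticRegression(C=np.inf, max_iter=1000)  # unpenalized
    lr.fit(data.x, data.z, sample_weight=data.w_or_ones)
    return lr.coef_[0].copy(), float(-lr.intercept_[0])


def _run_em(data: TrainingSet, init: ModelParams, config: EMConfig) -> FitResult:
    # fused loop: p(y=1|x) is computed once per iteration and reused by the
    # log-likelihood, the E-step and the M-step (the public e_step/m_step
    # implement the identical updates)
    params = init
    sw = data.w_or_ones
    z1 = data.z == 1
    design = np.column_stack([data.x, -np.ones(data.n)])  # last column: -w0
    trajectory = [observed_log_likelihood(data, params)]
    converged = False
    for _ in range(config.max_iter):
        p1 = prob_functional(data.x, params)
        if z1.any() and params.theta11 == 0.0:
            raise DegenerateLabelsError("theta11 = 0 but positive labels observed")
        denom = np.maximum(1.0 - params.theta11 * p1, 1e-300)
        c1 = np.where(z1, 1.0,
                      np.minimum((1.0 - params.theta11) * p1 / denom, 1.0))
        denom = float(np.dot(sw, c1))
        theta11 = float(np.dot(sw, c1 * z1) / denom) if denom > 0 else 0.0
        beta = _maximize_l2(design, c1, sw, np.append(params.w, params.w0), config)
        params = ModelParams(w=beta[:-1], w0=float(beta[-1]), theta11=theta11)
        trajectory.append(observed_log_likelihood(data, params))
        if trajectory[-1] - trajectory[-2] < config.tol:
            converged = True
            break
    return FitResult(
        params=params,
        log_likelihood=trajectory[-1],
        trajectory=trajectory,
        responsibilities=e_step(data, params),
        n_iter=len(trajectory) - 1,
        converged=converged,
    )


def fit_em(data: TrainingSet, config: EMConfig | None = None) -> FitResult:
    """EM over random restarts; returns the best-likelihood solution.

    Weights are initialized from a plain logistic fit of z on x; theta11 is
    drawn uniformly in (0.05, 0.95) per restart.  The restart summary holds
    the mean, standard deviation and coefficient of variation (STD/mean) of
    every parameter across restarts — the robustness diagnostic of the
    training protocol.
    """
    config = config or EMConfig()
    if data.n < 2 or len(np.unique(data.z)) < 2:
        raise ValueError("need >= 2 rows with both label values present")
    rng = np.random.default_rng(config.seed)
    w_init, w0_init = _initial_weights(data)
    results: list[FitResult] = []
    for _ in range(config.n_restarts):
        theta0 = float(rng.uniform(0.05, 0.95))
        init = ModelParams(w=w_init.copy(), w0=w0_init, theta11=theta0)
        results.append(_run_em(data, init, config))
    if not any(r.converged for r in results):
        if config.require_convergence:
            raise EMConvergenceError("EM failed to converge in every restart",
                                     trajectories=[r.trajectory for r in results])
        warnings.warn("EM did not reach tolerance in any restart; using best-so-far")
    best = max(results, key=lambda r: r.log_likelihood)

    names = (data.feature_names or [f"x{i}" for i in range(data.x.shape[1])])
    rows = {}
    for i, name in enumerate(names):
        rows[f"w[{name}]"] = [r.params.w[i] for r in results]
    rows["w0"] = [r.params.w0 for r in results]
    rows["theta11"] = [r.params.theta11 for r in results]
    summary = pd.DataFrame(rows).agg(["mean", "std"]).T
    summary["cv"] = summary["std"] / summary["mean"].abs().replace(0.0, np.nan)
    best.restart_summary = summary
    return best


class EMConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectories=None):
        super().__init__(message)
        self.trajectories = trajectories or []


def classify(features: np.ndarray | pd.DataFrame, params: ModelParams,
             threshold: float = 0.5, *, on_true_label: bool = False) -> np.ndarray:
    """Binary functionality predictions.

    Default thresholds the observed-label marginal ``theta11 * p(y=1|x)``
    (the model's probability that z = 1); with ``on_true_label`` the hidden
    probability ``p(y=1|x)`` is thresholded instead.  Ties at the threshold
    are non-functional.
    """
    x = features.to_numpy(float) if isinstance(features, pd.DataFrame) else features
    p1 = prob_functional(x, params)
    score = p1 if on_true_label else params.theta11 * p1
    return (score > threshold).astype(int)


def predicted_scores(features: np.ndarray | pd.DataFrame, params: ModelParams) -> pd.DataFrame:
    """Both classification scores for each row: p(y=1|x) and theta11*p."""
    x = features.to_numpy(float) if isinstance(features, pd.DataFrame) else features
    p1 = prob_functional(x, params)
    index = features.index if isinstance(features, pd.DataFrame) else pd.RangeIndex(len(p1))
    return pd.DataFrame({"p_functional": p1, "p_observed_functional": params.theta11 * p1},
                        index=index)


def estimate_p10(data: TrainingSet, params: ModelParams) -> float:
    """P10 = mean over z=0 rows of p(y=1 | z=0, x).

    Per row, p(y=1|z=0,x) = (1-theta11) p1 / (1 - theta11 p1).
    """
    neg = data.z == 0
    if not neg.any():
        raise ValueError("P10 requires at least one z = 0 pattern")
    p1 = prob_functional(data.x[neg], params)
    denom = np.maximum(1.0 - params.theta11 * p1, 1e-300)
    post = np.minimum((1.0 - params.theta11) * p1 / denom, 1.0)
    sw = data.w_or_ones[neg]
    return float(np.dot(sw, post) / sw.sum())


def save_model(path, params: ModelParams, *, feature_names=None, scaler=None,
               threshold: float = 0.5, restart_summary: pd.DataFrame | None = None) -> None:
    payload = {
        "params": params.to_dict(),
        "threshold": threshold,
        "feature_names": feature_names,
        "scaler": scaler.to_dict() if scaler is not None else None,
        "restart_summary": restart_summary.reset_index().to_dict(orient="list")
        if restart_summary is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["params"] = ModelParams.from_dict(payload["params"])
    return payload
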