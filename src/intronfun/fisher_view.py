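"""Fisher-discriminant visualization of the feature space.

Features are standardized, projected onto the leading principal components
(seven by default), and a Fisher discriminant direction
``w ~ S_W^{-1} (m1 - m0)`` is computed in PC space between
functional-labeled and non-functional-labeled patterns.  Each pattern is
plotted at (projection on w, projection on the first principal direction of
the data after the w component is removed); the two axes are orthogonal in
PC space.  Partial-label patterns are projected but do not enter the
discriminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .evo_features import FeatureScaler, FEATURE_NAMES

__all__ = ["Embedding2D", "fisher_embed"]


@dataclass
class Embedding2D:
    coords: pd.DataFrame          # columns: x (fisher), y (orthogonal PC), label
    direction: np.ndarray         # unit fisher direction in PC space
    pca_components: np.ndarray    # (n_components, n_features) basis used
    feature_names: list[str]

    def to_tsv(self, path, predicted: np.ndarray | None = None) -> None:
        out = self.coords.copy()
        if predicted is not None:
            out["predicted"] = predicted
        out.to_csv(path, sep="\t", index_label="pattern")


def fisher_embed(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_components: int = 7,
) -> Embedding2D:
    """Project patterns to the Fisher-discriminant plane.

    ``labels`` holds 'functional' / 'non-functional' / 'partial' strings (or
    1/0 integers; anything else is treated as partial).  Both classes must be
    non-empty.  The fisher axis is oriented so the functional-class mean is
    positive; the orthogonal axis so its largest-magnitude loading is
    positive.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    is_pos = (labels == "functional") | (labels == 1) | (labels == "1")
    is_neg = (labels == "non-functional") | (labels == 0) | (labels == "0")
    if not is_pos.any() or not is_neg.any():
        raise ValueError("both functional and non-functional patterns are required")

    cols = [c for c in FEATURE_NAMES if c in features.columns] or list(features.columns)
    table = features[cols]
    scaler = FeatureScaler.fit(table) if cols == FEATURE_NAMES else None
    x = (scaler.transform(table) if scaler is not None else
         (table - table.mean()) / table.std(ddof=0).replace(0.0, 1.0)).to_numpy(float)

    n_components = min(n_components, x.shape[1], x.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    pcs = pca.fit_transform(x)

    m1 = pcs[is_pos.to_numpy()].mean(axis=0)
    m0 = pcs[is_neg.to_numpy()].mean(axis=0)
    centered1 = pcs[is_pos.to_numpy()] - m1
    centered0 = pcs[is_neg.to_numpy()] - m0
    s_w = centered1.T @ centered1 + centered0.T @ centered0
    ridge = 1e-6 * np.trace(s_w) / s_w.shape[0]
    try:
        w = np.linalg.solve(s_w, m1 - m0)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; ridge-regularizing")
        w = np.linalg.solve(s_w + ridge * np.eye(s_w.shape[0]), m1 - m0)
    w = w / np.linalg.norm(w)

    xs = pcs @ w
    if (pcs[is_pos.to_numpy()] @ w).mean() < 0:
        w, xs = -w, -xs

    residual = pcs - np.outer(xs, w)
    u = PCA(n_components=1, svd_solver="full").fit(residual).components_[0]
    u = u - (u @ w) * w          # enforce exact orthogonality to w
    u = u / np.linalg.norm(u)
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    ys = pcs @ u

    coords = pd.DataFrame({"x": xs, "y": ys, "label": labels.to_numpy()},
                          index=features.index)
    return Embedding2D(coords=coords, direction=w,
                       pca_components=pca.components_, feature_names=cols)
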