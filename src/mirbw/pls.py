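"""Partial least squares (PLS1) core, feature-relevance scores, fit metrics.

The regression engine is a deflation-based NIPALS PLS1: components are
extracted sequentially as t_a = X w_a with unit-norm weight vectors
w_a proportional to X'y, X deflated by its rank-one reconstruction after each
step. Coefficients for any number of components A follow from
B_A = W_A (P_A' W_A)^{-1} q_A, so one fit yields the whole component path.

Two relevance scores are defined on a fitted model:

* VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
  SSY_a = q_a^2 (t_a . t_a), the share of explained y-variance feature j
  carries through the projections; satisfies sum_j VIP_j^2 = p.
* BETA_j = |b_j| on the standardized predictor scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import ScaleTransform


@dataclass
class FeatureRanking:
    method: str  # "vip" | "beta"
    feature_ids: list[str]  # descending relevance
    scores: np.ndarray  # aligned with feature_ids, descending

    def __post_init__(self):
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("length mismatch")


@dataclass
class PlsModel:
    """Fitted PLS1 state.

    Weights ``W`` (p x A), x-loadings ``P`` (p x A), y-loadings ``q`` (A,),
    score norms t_a.t_a (A,). ``coefficients`` are on the (caller-scaled)
    predictor scale; intercept handling is via the stored column means.
    """

    feature_ids: list[str]
    n_components: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    score_norms: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    coef_path: np.ndarray  # (A, p): coefficients for 1..A components
    scale: ScaleTransform | None = None
    scores: np.ndarray | None = None  # (n, A) training scores; not serialized

    def to_json(self) -> str:
        payload = {
            "feature_ids": list(self.feature_ids),
            "n_components": int(self.n_components),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "score_norms": self.score_norms.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coefficients": self.coefficients.tolist(),
            "coef_path": self.coef_path.tolist(),
        }
        if self.scale is not None:
            payload["scale"] = {
                "feature_ids": list(self.scale.feature_ids),
                "means": self.scale.means.tolist(),
                "sds": self.scale.sds.tolist(),
            }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PlsModel":
        d = json.loads(text)
        scale = None
        if "scale" in d:
            s = d["scale"]
            scale = ScaleTransform(
                tuple(s["feature_ids"]),
                np.array(s["means"]),
                np.array(s["sds"]),
            )
        return cls(
            feature_ids=list(d["feature_ids"]),
            n_components=int(d["n_components"]),
            W=np.array(d["W"]),
            P=np.array(d["P"]),
            q=np.array(d["q"]),
            score_norms=np.array(d["score_norms"]),
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            coefficients=np.array(d["coefficients"]),
            coef_path=np.array(d["coef_path"]),
            scale=scale,
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_ids: Sequence[str] | None = None,
    scale: ScaleTransform | None = None,
) -> PlsModel:
    """NIPALS PLS1. Inputs are expected pre-scaled by the caller; the fit
    centers internally. Stops early (with a warning) on a degenerate
    deflated matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if n_components < 1 or n_components > min(p, n - 1):
        raise ValueError(f"n_components must be in [1, {min(p, n - 1)}]")
    ids = list(feature_ids) if feature_ids is not None else [f"x{j}" for j in range(p)]

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    cov_norm0 = float(np.linalg.norm(Xd)) * float(np.linalg.norm(yd))

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    tt = np.zeros(n_components)
    A = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= 1e-8 * max(cov_norm0, 1e-30):
            warnings.warn(
                f"rank-deficient at component {a + 1}; returning {a} components",
                stacklevel=2,
            )
            break
        w /= wn
        t = Xd @ w
        t_dot = float(t @ t)
        if t_dot <= 0:
            warnings.warn(
                f"degenerate score at component {a + 1}; returning {a} components",
                stacklevel=2,
            )
            break
        p_a = Xd.T @ t / t_dot
        q_a = float(yd @ t) / t_dot
        Xd -= np.outer(t, p_a)
        yd = yd - t * q_a
        W[:, a], P[:, a], T[:, a], q[a], tt[a] = w, p_a, t, q_a, t_dot
        A = a + 1
    if A == 0:
        raise ValueError("no PLS component could be extracted (zero covariance)")
    W, P, T, q, tt = W[:, :A], P[:, :A], T[:, :A], q[:A], tt[:A]

    # coefficient path: B_a = W_a (P_a' W_a)^-1 q_a for a = 1..A
    R = P.T @ W  # upper triangular in exact arithmetic
    coef_path = np.zeros((A, p))
    for a in range(1, A + 1):
        sol = np.linalg.solve(R[:a, :a], np.eye(a)) @ q[:a]
        coef_path[a - 1] = W[:, :a] @ sol
    return PlsModel(
        feature_ids=ids,
        n_components=A,
        W=W,
        P=P,
        q=q,
        score_norms=tt,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef_path[A - 1],
        coef_path=coef_path,
        scale=scale,
        scores=T,
    )


def predict(model: PlsModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Linear prediction; no refitting. ``n_components`` picks a point on the
    stored coefficient path (default: all fitted components)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_ids):
        raise ValueError("feature dimension mismatch")
    if model.scale is not None:
        X = model.scale.transform(X)
    A = model.n_components if n_components is None else n_components
    if A < 1 or A > model.n_components:
        raise ValueError("n_components outside fitted path")
    return model.y_mean + (X - model.x_mean) @ model.coef_path[A - 1]


def predict_path(model: PlsModel, X: np.ndarray) -> np.ndarray:
    """Predictions for every component count on the path: (A, n) array."""
    X = np.asarray(X, dtype=float)
    if model.scale is not None:
        X = model.scale.transform(X)
    return model.y_mean + model.coef_path @ (X - model.x_mean).T


def _ranked(method: str, ids: Sequence[str], scores: np.ndarray) -> FeatureRanking:
    # descending score; ties broken by ascending original feature index
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(
        method=method,
        feature_ids=[ids[i] for i in order],
        scores=scores[order],
    )


def vip_scores(model: PlsModel) -> FeatureRanking:
    """Variable importance in the projection; sum of squares equals p."""
    p = len(model.feature_ids)
    ssy = model.q**2 * model.score_norms  # explained y-SS per component
    total = ssy.sum()
    if total <= 0:
        raise ValueError("no explained variance: VIP undefined")
    Wn = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / total)
    return _ranked("vip", model.feature_ids, vip)


def beta_scores(model: PlsModel) -> FeatureRanking:
    """Absolute standardized regression coefficients."""
    return _ranked("beta", model.feature_ids, np.abs(model.coefficients))


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("rmse needs equal-length non-empty inputs")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("r2 needs equal-length inputs of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot
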