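"""Combinative hypergraph learning: closed-form projections and view weights.

Each hypergraph view i contributes a Laplacian-regularised ridge problem

    min_P  tr(P^T X^T Delta_i X P) + lam ||X P - Y||_F^2 + mu ||P||_F^2

whose minimiser is the closed form P_i = lam (X^T Delta_i X + lam X^T X +
mu I)^{-1} X^T Y; the system is solved by a symmetric positive-definite
factorisation (mu > 0 guarantees definiteness), never by explicit
inversion.  With the per-view objective values Theta_i fixed, the
combination weights B = [beta_1, beta_2] minimise sum_i beta_i Theta_i +
eta ||B||^2 on the probability simplex; the Lagrange stationarity solution

    beta_i = 1/2 + (sum_j Theta_j)/(4 eta) - Theta_i/(2 eta)

is projected onto the simplex whenever it leaves the non-negative orthant.
Query pairs are scored by S(x) = sum_i beta_i x P_i; the scalar ranking
score is the positive-class column minus the negative-class column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .hypergraph import Hypergraph, omega_regularizer
from .io import PairFeatureTable, ScoreMatrix

__all__ = [
    "CHLConfig",
    "FeatureStats",
    "CHLModel",
    "fit_projection",
    "view_objective",
    "combination_weights",
    "simplex_projection",
    "fit",
    "score",
    "score_pairs",
]


@dataclass
class CHLConfig:
    lam: float = 10.0   # empirical-loss weight lambda
    mu: float = 1.0     # projection regulariser
    eta: float = 1e3    # view-weight regulariser

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.mu > 0 and self.eta > 0):
            raise ValueError("lam, mu and eta must all be strictly positive")


@dataclass
class FeatureStats:
    """Column mean/scale from the training rows, for z-scoring queries."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def from_training(cls, X: np.ndarray) -> "FeatureStats":
        X = np.asarray(X, float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant columns pass through unscaled
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training "
                f"dimension {self.mean.shape[0]}"
            )
        return (X - self.mean) / self.scale


@dataclass
class CHLModel:
    P: list[np.ndarray]
    B: np.ndarray
    theta: np.ndarray
    eps: float
    config: CHLConfig
    feature_stats: FeatureStats

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, float).ravel()
        self.theta = np.asarray(self.theta, float).ravel()
        if len(self.P) != self.B.shape[0]:
            raise ValueError("one combination weight per hypergraph view required")
        if abs(self.B.sum() - 1.0) > 1e-10 or np.any(self.B < 0):
            raise ValueError("combination weights must lie on the probability simplex")


def fit_projection(
    X: np.ndarray, Y: np.ndarray, Delta: np.ndarray, cfg: CHLConfig
) -> np.ndarray:
    """Closed-form Laplacian-regularised ridge projection for one view."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    M = X.T @ Delta @ X + cfg.lam * (X.T @ X) + cfg.mu * np.eye(X.shape[1])
    rhs = cfg.lam * (X.T @ Y)
    P = scipy.linalg.solve(M, rhs, assume_a="pos")
    resid = np.linalg.norm(M @ P - rhs) / max(np.linalg.norm(rhs), 1e-300)
    assert resid <= 1e-8, f"stationarity residual {resid:g} exceeds 1e-8"
    return P


def view_objective(
    P: np.ndarray, X: np.ndarray, Y: np.ndarray, hg: Hypergraph, cfg: CHLConfig
) -> float:
    """Theta = Omega(P) + lam ||XP - Y||_F^2 + mu ||P||_F^2."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    P = np.asarray(P, float)
    omega = omega_regularizer(P, X, hg)
    r_emp = float(((X @ P - Y) ** 2).sum())
    phi = float((P ** 2).sum())
    return omega + cfg.lam * r_emp + cfg.mu * phi


def simplex_projection(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex {b >= 0, sum b = 1}."""
    v = np.asarray(v, float).ravel()
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, v.size + 1) > 0)[0][-1]
    tau = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - tau, 0.0)


def combination_weights(theta: Sequence[float], eta: float) -> tuple[np.ndarray, float]:
    """View weights from the Lagrange stationarity formula, clamped to the simplex.

    Returns (B, eps) where eps is the Lagrange multiplier
    -(sum Theta + 2 eta)/2 of the equality constraint.
    """
    if not eta > 0:
        raise ValueError("eta must be positive")
    theta = np.asarray(theta, float).ravel()
    m = theta.size
    eps = -(theta.sum() + 2.0 * eta) / m
    beta = 0.5 + theta.sum() / (4.0 * eta) - theta / (2.0 * eta) if m == 2 else (
        1.0 / m + theta.sum() / (2.0 * eta * m) - theta / (2.0 * eta)
    )
    if np.any(beta < 0):
        beta = simplex_projection(beta)
    beta = beta / beta.sum()
    return beta, float(eps)


def fit(
    Xtrain: np.ndarray,
    Ytrain: np.ndarray,
    hypergraphs: Sequence[Hypergraph],
    cfg: CHLConfig | None = None,
    feature_stats: FeatureStats | None = None,
) -> CHLModel:
    """Fit one projection per hypergraph view, then the combination weights.

    ``Xtrain`` is raw (unstandardised) unless ``feature_stats`` is supplied;
    the stats are always computed from (or supplied for) the training rows
    only and stored on the model for scoring.
    """
    cfg = cfg or CHLConfig()
    Xtrain = np.asarray(Xtrain, float)
    Ytrain = np.asarray(Ytrain, float)
    if feature_stats is None:
        feature_stats = FeatureStats.from_training(Xtrain)
        Xs = feature_stats.transform(Xtrain)
    else:
        Xs = np.asarray(Xtrain, float)
    for hg in hypergraphs:
        if hg.n_vertices != Xs.shape[0]:
            raise ValueError("hypergraph vertex count must match training rows")
    P = [fit_projection(Xs, Ytrain, hg.Delta, cfg) for hg in hypergraphs]
    theta = np.array(
        [view_objective(p, Xs, Ytrain, hg, cfg) for p, hg in zip(P, hypergraphs)]
    )
    B, eps = combination_weights(theta, cfg.eta)
    return CHLModel(P=P, B=B, theta=theta, eps=eps, config=cfg,
                    feature_stats=feature_stats)


def score(model: CHLModel, Xquery: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Scalar ranking scores for raw query feature rows.

    Combines the per-view projections, S = sum_i beta_i X P_i, and returns
    the positive-class minus negative-class column.
    """
    Xq = np.asarray(Xquery, float)
    if standardize:
        Xq = model.feature_stats.transform(Xq)
    S = sum(b * (Xq @ p) for b, p in zip(model.B, model.P))
    return S[:, 0] - S[:, 1]


def score_pairs(model: CHLModel, table: PairFeatureTable) -> ScoreMatrix:
    """Score a feature table, keeping its pair ordering."""
    return ScoreMatrix(score(model, table.X), list(table.pairs))
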