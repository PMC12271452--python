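"""Latent class analysis of the binary condition matrix.

A finite mixture of locally independent Bernoulli item profiles fitted by
expectation-maximisation: class c has mixing weight pi_c and item
probabilities rho_{cd}, the E-step computes responsibilities proportional to
pi_c * prod_d rho_{cd}^x (1-rho_{cd})^{1-x}, and the M-step updates both in
closed form.  The log-likelihood is nondecreasing at every iteration; fits
use multiple jittered starts and the best log-likelihood wins.  The class
count is chosen by information criteria (AIC = -2l + 2m, BIC = -2l +
m ln n, with m = (C-1) + C*D parameters), preferring BIC when they
disagree.  Hard assignments are maximum a posteriori responsibilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ehrclust.evaluation import DiseaseMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-6


class LatentClassAnalysis(BaseEstimator):
    """Bernoulli-mixture latent class model fitted by EM.

    Parameters
    ----------
    n_classes : int
        Number of latent classes C (>= 1).
    n_starts : int
        Random restarts; the best final log-likelihood is kept.
    tol : float
        Convergence threshold on the log-likelihood increase.
    max_iter : int
        EM iteration cap per start.
    random_state : int
        Seed for the jittered prevalence-based initialisation.

    Attributes
    ----------
    weights_ : (C,) mixing proportions.
    item_probs_ : (C, D) per-class item probabilities, clipped to
        [1e-6, 1 - 1e-6].
    log_likelihood_ : best final log-likelihood.
    ll_trace_ : per-iteration log-likelihoods of the winning start.
    n_parameters_, aic_, bic_, converged_ : fit diagnostics.
    """

    def __init__(
        self,
        n_classes: int = 2,
        n_starts: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _validate(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a nonempty 2-D array")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary")
        return X.astype(float)

    def _log_resp(self, X: np.ndarray, log_pi: np.ndarray, rho: np.ndarray) -> np.ndarray:
        # (n, C) joint log density log pi_c + sum_d x log rho + (1-x) log(1-rho)
        return (
            log_pi[None, :]
            + X @ np.log(rho).T
            + (1.0 - X) @ np.log(1.0 - rho).T
        )

    def fit(self, X, y=None) -> "LatentClassAnalysis":
        X = self._validate(X)
        n, D = X.shape
        C = int(self.n_classes)
        if C < 1:
            raise ValueError("n_classes must be >= 1")
        if C > n:
            raise ValueError("n_classes cannot exceed the number of patients")
        rng = np.random.default_rng(self.random_state)
        prevalence = np.clip(X.mean(axis=0), _EPS, 1 - _EPS)

        best: tuple[float, np.ndarray, np.ndarray, list[float], bool] | None = None
        for _ in range(max(self.n_starts, 1)):
            pi = np.full(C, 1.0 / C)
            rho = np.clip(
                prevalence[None, :] + rng.uniform(-0.1, 0.1, size=(C, D)), _EPS, 1 - _EPS
            )
            ll_prev = -np.inf
            trace: list[float] = []
            converged = False
            for _ in range(self.max_iter):
                joint = self._log_resp(X, np.log(pi), rho)
                ll = float(logsumexp(joint, axis=1).sum())
                trace.append(ll)
                resp = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
                nk = resp.sum(axis=0)
                pi = np.clip(nk / n, _EPS, None)
                pi = pi / pi.sum()
                rho = np.clip((resp.T @ X) / np.maximum(nk[:, None], _EPS), _EPS, 1 - _EPS)
                if ll - ll_prev < self.tol and np.isfinite(ll_prev):
                    converged = True
                    break
                ll_prev = ll
            if best is None or trace[-1] > best[0]:
                best = (trace[-1], pi, rho, trace, converged)

        assert best is not None
        self.log_likelihood_, self.weights_, self.item_probs_, self.ll_trace_, self.converged_ = best
        self.n_parameters_ = (C - 1) + C * D
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * self.log_likelihood_ + self.n_parameters_ * np.log(n)
        self.n_features_in_ = D
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        joint = self._log_resp(X, np.log(self.weights_), self.item_probs_)
        return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        """Maximum a posteriori class assignment."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        X = self._validate(X)
        joint = self._log_resp(X, np.log(self.weights_), self.item_probs_)
        return float(logsumexp(joint, axis=1).sum())


@dataclass
class LCAModel:
    """Fitted-model summary used by reports and the CLI."""

    n_classes: int
    weights: np.ndarray
    item_probs: np.ndarray
    log_likelihood: float
    n_parameters: int
    aic: float
    bic: float
    converged: bool
    ll_trace: list[float]
    conditions: list[str]
    estimator: LatentClassAnalysis


def fit_lca(
    matrix: DiseaseMatrix,
    n_classes: int,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> LCAModel:
    """Fit a latent class model to a disease matrix."""
    est = LatentClassAnalysis(
        n_classes=n_classes, n_starts=n_starts, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(matrix.values)
    return LCAModel(
        n_classes=n_classes,
        weights=est.weights_,
        item_probs=est.item_probs_,
        log_likelihood=est.log_likelihood_,
        n_parameters=est.n_parameters_,
        aic=est.aic_,
        bic=est.bic_,
        converged=est.converged_,
        ll_trace=est.ll_trace_,
        conditions=list(matrix.conditions),
        estimator=est,
    )


def select_classes(
    matrix: DiseaseMatrix,
    class_range,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """AIC/BIC per class count; the chosen count minimises BIC (ties: smaller C)."""
    rows = []
    models = {}
    for C in sorted(set(int(c) for c in class_range)):
        m = fit_lca(matrix, C, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed + C)
        models[C] = m
        rows.append(
            {"n_classes": C, "log_likelihood": m.log_likelihood, "aic": m.aic, "bic": m.bic}
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["bic"].idxmin(), "n_classes"])
    aic_choice = int(table.loc[table["aic"].idxmin(), "n_classes"])
    if aic_choice != chosen:
        logger.info("AIC prefers %d classes, BIC prefers %d; using BIC", aic_choice, chosen)
    return table, chosen


def class_profiles(model: LCAModel, top_n: int = 3) -> pd.DataFrame:
    """Top conditions per class by item probability, with class shares.

    Ties in item probability break lexicographically by condition name.
    """
    rows = []
    for c in range(model.n_classes):
        order = sorted(
            range(len(model.conditions)),
            key=lambda j: (-model.item_probs[c, j], model.conditions[j]),
        )
        for rank, j in enumerate(order[:top_n], start=1):
            rows.append(
                {
                    "class": c,
                    "share": float(model.weights[c]),
                    "rank": rank,
                    "condition": model.conditions[j],
                    "item_probability": float(model.item_probs[c, j]),
                }
            )
    return pd.DataFrame(rows)
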