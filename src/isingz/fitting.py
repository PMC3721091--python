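"""Parameter estimation: pseudo-likelihood and the conditional-logistic chain.

Two distinct fits live here.

*Pseudo-likelihood* (Besag) estimates the joint Ising model: each
neuron's exact conditional P(sigma_i | sigma_{j != i}; s) is a logistic
function of ``h_i(s) + 2 sum_{j != i} sigma_j J_ji``, so regressing
sigma_i on [C(s), {2 sigma_j}] recovers beta[:, i] and the column J[., i]
directly.  The two per-pair estimates are symmetrized by averaging and
the diagonal is zeroed.  The product of these conditionals is *not* a
normalized distribution over patterns.

The *conditional-logistic chain* instead fits the chain-rule
factorization P(sigma_1, ..., sigma_N; s) = prod_k P(sigma_k |
sigma_{j > k}; s), with neurons ordered by descending mean firing rate
(the lowest-rate neuron gets the stimulus-only conditional).  Each
conditional is approximated by its own logistic regression -- the fitted
weights need not, and in general do not, equal the Ising parameters
(Ising models are not projective) -- but the product is normalized by
construction, which is exactly what the missing-mass estimate needs.

All regressions are ridge-penalized iteratively reweighted least squares
(Newton) with a deterministic, fully specified iteration, so identical
inputs give bitwise-identical weights.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .ising_core import CovariateMatrix, IsingModel, SpikeRaster

logger = logging.getLogger("isingz")

DEFAULT_RIDGE = 1e-4
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


@dataclass
class FitReport:
    """Convergence bookkeeping for one logistic regression."""

    converged: bool
    n_iter: int
    deviance: float
    ridge: float
    grad_norm: float


@dataclass
class ChainModel:
    """Fitted conditional-logistic chain.

    ``ordering[k]`` is the original index of the neuron at chain position
    k (descending mean rate).  Position k has stimulus weights
    ``stim_weights[k]`` (length R) and one neighbor weight per neuron at
    a *later* position, entering the linear predictor as
    ``2 * sigma_j * K``; the last position is stimulus-only.
    """

    ordering: np.ndarray                      # (N,) original neuron indices
    stim_weights: list[np.ndarray]            # N arrays of length R
    neighbor_weights: list[np.ndarray]        # k-th has length N-1-k

    def __post_init__(self) -> None:
        self.ordering = np.asarray(self.ordering, dtype=np.int64)
        n = self.ordering.shape[0]
        if sorted(self.ordering.tolist()) != list(range(n)):
            raise ValueError("ordering must be a permutation of 0..N-1")
        if len(self.stim_weights) != n or len(self.neighbor_weights) != n:
            raise ValueError("need one weight set per chain position")
        for k in range(n):
            if self.neighbor_weights[k].shape != (n - 1 - k,):
                raise ValueError(
                    f"position {k} must have {n - 1 - k} neighbor weights")
        if n and self.neighbor_weights[-1].size != 0:
            raise ValueError("last position must be stimulus-only")

    @property
    def n_neurons(self) -> int:
        return self.ordering.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.stim_weights[0].shape[0]


def fit_logistic(design: np.ndarray, response: np.ndarray,
                 ridge: float = DEFAULT_RIDGE, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER) -> tuple[np.ndarray, FitReport]:
    """Ridge-penalized logistic regression by IRLS (Newton).

    Maximizes ``sum_t [y_t eta_t - log(1 + e^{eta_t})] - ridge/2 ||w||^2``
    with ``eta = design @ w`` to a max-abs gradient below ``tol``.  No
    intercept is added: the caller's design must span a constant if one
    is wanted.  Non-convergence is flagged in the report; weights are
    still returned with a warning.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design rows must match response length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design and response must be finite")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")

    p_cols = X.shape[1]
    w = np.zeros(p_cols)
    eta = X @ w
    grad_norm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (y - mu) - ridge * w
        grad_norm = float(np.max(np.abs(grad))) if p_cols else 0.0
        if grad_norm <= tol:
            converged = True
            break
        wvar = mu * (1.0 - mu)
        H = (X * wvar[:, None]).T @ X
        H[np.diag_indices_from(H)] += max(ridge, 1e-10)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # rank-deficient despite the added ridge: rescue with a
            # stronger penalty on this step only
            logger.warning("rank-deficient IRLS system; ridge rescue applied")
            H[np.diag_indices_from(H)] += 1e-6 * (1.0 + np.abs(H).max())
            step = np.linalg.solve(H, grad)
        # step halving guards the rare overshoot at extreme predictors
        pll_old = _penalized_ll(y, eta, w, ridge)
        scale = 1.0
        for _ in range(30):
            w_new = w + scale * step
            eta_new = X @ w_new
            if _penalized_ll(y, eta_new, w_new, ridge) >= pll_old - 1e-12:
                break
            scale *= 0.5
        w, eta = w_new, eta_new
        # a step below machine precision cannot move the gradient any
        # further: the solver conditioning sets the attainable floor
        if np.max(np.abs(scale * step)) <= 1e-10 * (1.0 + np.max(np.abs(w))):
            mu = expit(eta)
            grad = X.T @ (y - mu) - ridge * w
            grad_norm = float(np.max(np.abs(grad))) if p_cols else 0.0
            converged = True
            break
    else:
        it = max_iter
    if not converged:
        mu = expit(eta)
        grad = X.T @ (y - mu) - ridge * w
        grad_norm = float(np.max(np.abs(grad))) if p_cols else 0.0
        converged = grad_norm <= tol
        if not converged:
            warnings.warn(
                f"logistic regression did not converge in {max_iter} "
                f"iterations (grad norm {grad_norm:.2e}); weights returned",
                RuntimeWarning)
    deviance = float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))
    return w, FitReport(converged=converged, n_iter=it, deviance=deviance,
                        ridge=ridge, grad_norm=grad_norm)


def _penalized_ll(y: np.ndarray, eta: np.ndarray, w: np.ndarray,
                  ridge: float) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * ridge * np.sum(w * w))


def _check_degenerate(raster: SpikeRaster) -> None:
    means = raster.data.mean(axis=0)
    bad = np.flatnonzero((means == 0.0) | (means == 1.0))
    if bad.size:
        raise ValueError(
            f"neuron(s) {bad.tolist()} never spike or never stay silent; "
            "their conditional regressions are degenerate")


def fit_pseudolikelihood(raster: SpikeRaster, covariates: CovariateMatrix,
                         ridge: float = DEFAULT_RIDGE,
                         tol: float = DEFAULT_TOL,
                         max_iter: int = DEFAULT_MAX_ITER,
                         ) -> tuple[IsingModel, list[FitReport]]:
    """Pseudo-likelihood fit of the stimulus-driven Ising model.

    For each neuron i, sigma_i is regressed on ``[C(s), {2 sigma_j}_{j != i}]``
    so the fitted neighbor coefficients estimate J_ji directly.  J-hat is
    symmetrized by averaging the two per-pair estimates; the diagonal is
    zero by construction.
    """
    if raster.bins != covariates.bins:
        raise ValueError("raster and covariates must have the same bins")
    _check_degenerate(raster)
    L, N = raster.data.shape
    R = covariates.n_covariates
    S = raster.data.astype(float)
    beta = np.zeros((R, N))
    J_hat = np.zeros((N, N))
    reports: list[FitReport] = []
    others_idx = [np.delete(np.arange(N), i) for i in range(N)]
    for i in range(N):
        design = np.concatenate([covariates.data, 2.0 * S[:, others_idx[i]]],
                                axis=1)
        w, rep = fit_logistic(design, S[:, i], ridge=ridge, tol=tol,
                              max_iter=max_iter)
        beta[:, i] = w[:R]
        J_hat[others_idx[i], i] = w[R:]
        reports.append(rep)
    J = 0.5 * (J_hat + J_hat.T)
    np.fill_diagonal(J, 0.0)
    return IsingModel(beta=beta, J=J), reports


def order_neurons_by_rate(raster: SpikeRaster) -> np.ndarray:
    """Permutation of neurons by descending mean rate, ties by index."""
    rates = raster.data.mean(axis=0)
    # lexsort's last key is primary; negate for descending order
    return np.lexsort((np.arange(raster.neurons), -rates))


def fit_conditional_chain(raster: SpikeRaster, covariates: CovariateMatrix,
                          ridge: float = DEFAULT_RIDGE,
                          tol: float = DEFAULT_TOL,
                          max_iter: int = DEFAULT_MAX_ITER,
                          ) -> tuple[ChainModel, list[FitReport]]:
    """Fit the N conditional logistic regressions of the chain.

    After reordering neurons by rate, position k's design is
    ``[C(s), {2 sigma_j : j at positions > k}]`` (R + N - 1 - k columns);
    the last position regresses on the stimulus alone.
    """
    if raster.bins != covariates.bins:
        raise ValueError("raster and covariates must have the same bins")
    _check_degenerate(raster)
    N = raster.neurons
    R = covariates.n_covariates
    ordering = order_neurons_by_rate(raster)
    S = raster.data.astype(float)[:, ordering]    # columns in chain order
    stim_weights: list[np.ndarray] = []
    neighbor_weights: list[np.ndarray] = []
    reports: list[FitReport] = []
    for k in range(N):
        if k < N - 1:
            design = np.concatenate([covariates.data, 2.0 * S[:, k + 1:]],
                                    axis=1)
        else:
            design = covariates.data
        w, rep = fit_logistic(design, S[:, k], ridge=ridge, tol=tol,
                              max_iter=max_iter)
        stim_weights.append(w[:R])
        neighbor_weights.append(w[R:])
        reports.append(rep)
    return (ChainModel(ordering=ordering, stim_weights=stim_weights,
                       neighbor_weights=neighbor_weights), reports)


# ---------------------------------------------------------------------------
# Chain serialization
# ---------------------------------------------------------------------------

def save_chain_json(path, chain: ChainModel) -> None:
    """JSON layout: ordering plus, per position, the stimulus weights and
    neighbor weights keyed by the conditioned-on neuron's original id."""
    positions = []
    for k in range(chain.n_neurons):
        later = chain.ordering[k + 1:]
        positions.append({
            "neuron": int(chain.ordering[k]),
            "stim_weights": chain.stim_weights[k].tolist(),
            "neighbor_weights": {str(int(j)): float(w)
                                 for j, w in zip(later, chain.neighbor_weights[k])},
        })
    with open(path, "w") as fh:
        json.dump({"ordering": chain.ordering.tolist(),
                   "positions": positions}, fh)


def load_chain_json(path) -> ChainModel:
    with open(path) as fh:
        payload = json.load(fh)
    ordering = np.array(payload["ordering"], dtype=np.int64)
    stim_weights, neighbor_weights = [], []
    for k, pos in enumerate(payload["positions"]):
        stim_weights.append(np.array(pos["stim_weights"], dtype=float))
        later = ordering[k + 1:]
        nw = pos["neighbor_weights"]
        neighbor_weights.append(
            np.array([nw[str(int(j))] for j in later], dtype=float))
    return ChainModel(ordering=ordering, stim_weights=stim_weights,
                      neighbor_weights=neighbor_weights)
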