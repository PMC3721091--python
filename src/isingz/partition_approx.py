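"""Approximations to the stimulus-dependent partition function Z(s).

The partition function splits over observed and unobserved patterns,

    Z(s) = X(s) + Y(s),

where X(s) sums the unnormalized weights of the patterns seen in the
training data (few, and exactly computable in O(L N N_pat)) and Y(s)
sums the rest (many, but individually improbable for sparsely spiking
populations).  Writing the *missing mass* -- the total model probability
of the unobserved patterns -- as M(s) = Y(s)/Z(s) gives the inversion

    Y(s) = X(s) M(s) / (1 - M(s)),      Z(s) = X(s) / (1 - M(s)).

Two missing-mass estimates are provided: the constant Good-Turing count
estimate M_GT = (#patterns seen exactly once)/L, which corrects the bias
of X(s) but not its stimulus-driven variance, and the stimulus-modulated
conditional-logistic estimate M_CL(s) = 1 - sum_{observed} P_chain(sigma|s)
built from the normalized chain factorization fitted in
:mod:`isingz.fitting`.

Also here: Monte Carlo importance sampling with an independent-neuron
proposal (the stochastic baseline) and four deterministic baselines
(naive mean field, TAP, Bethe via loopy belief propagation, and a
low-firing-rate expansion), all in the {0,1} spin convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp, xlogy

from .fitting import ChainModel, fit_logistic
from .ising_core import (OPS, CovariateMatrix, IsingModel, PartitionSeries,
                         PatternTable, quadratic_energies)

logger = logging.getLogger("isingz")

_MM_METHODS = ("good_turing_constant", "conditional_logistic")

#: Pattern chunk for the n_pat x n_unique x N chain-probability tensor.
_CHAIN_CHUNK = 512


@dataclass
class MissingMassSeries:
    """Per-bin missing-mass estimates M(s) in [0, 1)."""

    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("missing-mass values must be 1-D")
        if self.method not in _MM_METHODS:
            raise ValueError(f"method must be one of {_MM_METHODS}")
        if np.any(self.values < 0):
            raise ValueError("missing mass cannot be negative")
        # M >= 1 is deliberately NOT rejected here; z_from_missing_mass
        # raises with the offending bins so a broken fit is diagnosable.

    def __len__(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Observed-pattern sum X(s)
# ---------------------------------------------------------------------------

def observed_sum_X(model: IsingModel, table: PatternTable,
                   covariates: CovariateMatrix) -> PartitionSeries:
    """X(s): the exact sum of Ising weights over the observed patterns.

    The quadratic energies are precomputed once per pattern; the
    stimulus part is one matrix product per unique covariate row.
    """
    if table.n_patterns == 0:
        raise ValueError("pattern table is empty")
    if table.patterns.shape[1] != model.n_neurons:
        raise ValueError("pattern dimension does not match the model")
    P = table.patterns.astype(float)              # (n_pat, N)
    q = quadratic_energies(P, model.J)
    uniq, inv = covariates.unique_rows()
    H = model.fields(uniq)                        # (U, N)
    logw = q[:, None] + P @ H.T                   # (n_pat, U)
    logX_u = logsumexp(logw, axis=0)
    OPS.add("missing_mass_path",
            H.shape[0] * table.n_patterns * model.n_neurons + covariates.bins)
    return PartitionSeries(log_values=logX_u[inv], method="X_only")


# ---------------------------------------------------------------------------
# Good-Turing
# ---------------------------------------------------------------------------

def good_turing(table: PatternTable) -> float:
    """Good-Turing estimate of the average missing mass: singletons / L."""
    return table.n_singletons / table.n_bins


def good_turing_series(table: PatternTable) -> MissingMassSeries:
    """Constant missing-mass series M(s) = M_GT in every bin."""
    return MissingMassSeries(values=np.full(table.n_bins, good_turing(table)),
                             method="good_turing_constant")


# ---------------------------------------------------------------------------
# Conditional-logistic chain probabilities and missing mass
# ---------------------------------------------------------------------------

def _chain_log_probs(chain: ChainModel, patterns: np.ndarray,
                     cov_rows: np.ndarray) -> np.ndarray:
    """log P_chain(sigma | s) for each (pattern, covariate row) pair.

    Returns an (n_pat, n_rows) matrix, computed in log space:
    the predictor at chain position k is l_k(s) + 2 sum_{j>k} sigma_j K,
    and log P = sum_k [sigma_k eta_k - softplus(eta_k)].
    """
    N = chain.n_neurons
    Q = np.asarray(patterns, dtype=float)[:, chain.ordering]   # (n_pat, N)
    Srows = np.asarray(cov_rows, dtype=float)
    if Srows.ndim == 1:
        Srows = Srows[None, :]
    Lmat = np.column_stack(chain.stim_weights)                 # (R, N)
    stim = Srows @ Lmat                                        # (U, N)
    A = np.zeros_like(Q)                                       # (n_pat, N)
    for k in range(N - 1):
        A[:, k] = 2.0 * (Q[:, k + 1:] @ chain.neighbor_weights[k])
    n_pat, U = Q.shape[0], stim.shape[0]
    out = np.empty((n_pat, U))
    for start in range(0, n_pat, _CHAIN_CHUNK):
        stop = min(start + _CHAIN_CHUNK, n_pat)
        eta = stim[None, :, :] + A[start:stop, None, :]        # (b, U, N)
        sp = np.logaddexp(0.0, eta)
        out[start:stop] = np.einsum("bn,bun->bu", Q[start:stop], eta) - sp.sum(axis=2)
    return out


def chain_pattern_prob(chain: ChainModel, pattern: np.ndarray,
                       covariate_row: np.ndarray) -> float:
    """P_chain(sigma | s): product of the fitted chain conditionals."""
    pattern = np.asarray(pattern)
    if pattern.shape[0] != chain.n_neurons:
        raise ValueError("pattern length does not match the chain")
    lp = _chain_log_probs(chain, pattern[None, :], np.asarray(covariate_row))
    return float(np.exp(lp[0, 0]))


def missing_mass_series(chain: ChainModel, table: PatternTable,
                        covariates: CovariateMatrix) -> MissingMassSeries:
    """Stimulus-modulated missing mass M_CL(s) = 1 - sum_obs P_chain.

    Tiny negative values from floating point are clipped to zero (a
    warning reports how many bins were clipped).  Values >= 1 are left
    in place for :func:`z_from_missing_mass` to reject: they signal a
    chain fit bad enough that no clip should hide it.
    """
    if table.patterns.shape[1] != chain.n_neurons:
        raise ValueError("pattern dimension does not match the chain")
    uniq, inv = covariates.unique_rows()
    lp = _chain_log_probs(chain, table.patterns, uniq)   # (n_pat, U)
    observed_mass = np.exp(logsumexp(lp, axis=0))
    M_u = 1.0 - observed_mass
    n_clip = int(np.sum(M_u < 0))
    if n_clip:
        logger.warning("clipped %d unique-row missing-mass values below 0",
                       n_clip)
        M_u = np.clip(M_u, 0.0, None)
    OPS.add("missing_mass_path",
            uniq.shape[0] * table.n_patterns * chain.n_neurons + covariates.bins)
    return MissingMassSeries(values=M_u[inv], method="conditional_logistic")


def z_from_missing_mass(X: PartitionSeries, M: MissingMassSeries) -> PartitionSeries:
    """Z(s) = X(s) / (1 - M(s)); algebraically identical to X + Y with
    Y = X M/(1-M), but with fewer operations."""
    if len(X) != len(M):
        raise ValueError("X and M series lengths differ")
    bad = np.flatnonzero(M.values >= 1.0)
    if bad.size:
        head = bad[:10].tolist()
        raise ValueError(
            f"missing mass >= 1 in {bad.size} bin(s) (first: {head}); "
            "the chain fit is broken -- refusing to invert")
    method = ("good_turing" if M.method == "good_turing_constant"
              else "conditional_logistic")
    return PartitionSeries(log_values=X.log_values - np.log1p(-M.values),
                           method=method)


# ---------------------------------------------------------------------------
# Importance sampling (independent-neuron proposal)
# ---------------------------------------------------------------------------

def fit_independent_proposal(raster, covariates: CovariateMatrix,
                             ridge: float = 1e-4) -> np.ndarray:
    """Stimulus-only logistic fits per neuron: the independent-neuron
    proposal weights (R x N) for importance sampling."""
    S = raster.data.astype(float)
    R = covariates.n_covariates
    beta = np.zeros((R, S.shape[1]))
    for i in range(S.shape[1]):
        w, _ = fit_logistic(covariates.data, S[:, i], ridge=ridge)
        beta[:, i] = w
    return beta


def importance_sampling_Z(model: IsingModel, covariates: CovariateMatrix,
                          n_samples: int, seed: int,
                          proposal_beta: np.ndarray | None = None,
                          ) -> PartitionSeries:
    """Monte Carlo Z(s) with an independent-Bernoulli proposal.

    Per *unique* covariate row s, draws n patterns sigma_k ~ q(.|s) with
    q the product of per-neuron logistic marginals (weights
    ``proposal_beta``; the model's own stimulus weights by default) and
    averages the weight ratios w(sigma_k)/q(sigma_k|s) in the linear
    domain with log-sum-exp stabilization.  ``mc_se`` holds the per-bin
    standard error of the mean ratio.  Fresh samples are drawn per
    unique row and broadcast to bins.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(seed)
    if proposal_beta is None:
        proposal_beta = model.beta
    uniq, inv = covariates.unique_rows()
    H = model.fields(uniq)                         # (U, N) target fields
    Hq = uniq @ proposal_beta                      # (U, N) proposal fields
    U, N = H.shape
    logZ_u = np.empty(U)
    se_u = np.empty(U)
    for u in range(U):
        p = expit(Hq[u])
        S = (rng.random((n_samples, N)) < p).astype(float)
        logw = S @ H[u] + quadratic_energies(S, model.J)
        # log q(sigma) = sigma.(h_q - softplus(h_q)) + (1-sigma).(-softplus)
        logq = S @ Hq[u] - np.sum(np.logaddexp(0.0, Hq[u]))
        lr = logw - logq
        m = lr.max()
        r = np.exp(lr - m)
        logZ_u[u] = m + np.log(r.mean())
        se_u[u] = np.exp(m) * r.std(ddof=1) / np.sqrt(n_samples)
    OPS.add("importance_sampling", U * n_samples * N + covariates.bins)
    return PartitionSeries(log_values=logZ_u[inv], method="importance_sampling",
                           mc_se=se_u[inv])


# ---------------------------------------------------------------------------
# Deterministic baselines: naive mean field, TAP, Bethe, low-rate
# ---------------------------------------------------------------------------

def _entropy01(m: np.ndarray) -> np.ndarray:
    """Binary entropy of Bernoulli(m), safe at m in {0, 1}."""
    return -(xlogy(m, m) + xlogy(1.0 - m, 1.0 - m))


def _nmf_fixed_point(H: np.ndarray, K: np.ndarray, max_iter: int, tol: float,
                     damping: float, onsager: bool) -> tuple[np.ndarray, np.ndarray]:
    """Damped magnetization iteration, optionally with the Onsager
    (TAP) reaction term; vectorized over the rows of H."""
    m = expit(H)
    conv = np.zeros(H.shape[0], dtype=bool)
    K2 = K * K
    for _ in range(max_iter):
        arg = H + m @ K
        if onsager:
            v = m * (1.0 - m)
            arg = arg + 0.5 * (1.0 - 2.0 * m) * (v @ K2)
        m_new = (1.0 - damping) * m + damping * expit(arg)
        delta = np.max(np.abs(m_new - m), axis=1)
        m = m_new
        conv = delta < tol
        if conv.all():
            break
    return m, conv


def _mean_field_logZ(H: np.ndarray, K: np.ndarray, m: np.ndarray,
                     onsager: bool) -> np.ndarray:
    quad = 0.5 * np.einsum("ui,ij,uj->u", m, K, m)
    logZ = np.sum(H * m + _entropy01(m), axis=1) + quad
    if onsager:
        v = m * (1.0 - m)
        logZ = logZ + 0.25 * np.einsum("ui,ij,uj->u", v, K * K, v)
    return logZ


def _bethe_logZ(H: np.ndarray, K: np.ndarray, max_iter: int, tol: float,
                damping: float) -> tuple[np.ndarray, np.ndarray]:
    """Loopy belief propagation on the fully connected pairwise graph.

    Messages are parametrized by their log odds mu[u, i, j] (from i to
    j), updated on a damped parallel schedule; log Z is the Bethe free
    energy of the fixed-point beliefs.
    """
    U, N = H.shape
    mu = np.zeros((U, N, N))
    conv = np.zeros(U, dtype=bool)
    eye = np.eye(N, dtype=bool)
    for _ in range(max_iter):
        inc = mu.sum(axis=1)                               # (U, j) total input
        # cavity field of i with the j->i message removed
        a = H[:, :, None] + inc[:, :, None] - np.swapaxes(mu, 1, 2)
        mu_new = np.logaddexp(0.0, a + K[None, :, :]) - np.logaddexp(0.0, a)
        mu_new[:, eye] = 0.0
        delta = np.max(np.abs(mu_new - mu), axis=(1, 2))
        mu = (1.0 - damping) * mu + damping * mu_new
        conv = delta < tol
        if conv.all():
            break
    inc = mu.sum(axis=1)
    b1 = expit(H + inc)                                    # singleton beliefs
    # pairwise beliefs from the two cavity fields a_{i\j}, a_{j\i}
    a_ij = H[:, :, None] + inc[:, :, None] - np.swapaxes(mu, 1, 2)  # (U,i,j)
    a_ji = np.swapaxes(a_ij, 1, 2)
    w11 = a_ij + a_ji + K[None, :, :]
    # unnormalized pairwise table: (00)=1, (10)=e^{a_ij}, (01)=e^{a_ji}, (11)
    mx = np.maximum.reduce([np.zeros_like(w11), a_ij, a_ji, w11])
    e00 = np.exp(-mx)
    e10 = np.exp(a_ij - mx)
    e01 = np.exp(a_ji - mx)
    e11 = np.exp(w11 - mx)
    norm = e00 + e10 + e01 + e11
    b00, b10, b01, b11 = e00 / norm, e10 / norm, e01 / norm, e11 / norm
    iu = np.triu_indices(N, k=1)
    # Bethe free energy: edge averages + edge entropies - (deg-1) node entropies
    edge_energy = np.sum(K[iu][None, :] * b11[:, iu[0], iu[1]], axis=1)
    pair_entropy = -(xlogy(b00, b00) + xlogy(b10, b10) +
                     xlogy(b01, b01) + xlogy(b11, b11))
    edge_entropy = np.sum(pair_entropy[:, iu[0], iu[1]], axis=1)
    node_entropy = np.sum(_entropy01(b1), axis=1)
    logZ = (np.sum(H * b1, axis=1) + edge_energy + edge_entropy
            - (N - 2) * node_entropy)
    return logZ, conv


def deterministic_Z(model: IsingModel, covariates: CovariateMatrix,
                    method: str, max_iter: int = 500, tol: float = 1e-8,
                    damping: float = 0.5) -> PartitionSeries:
    """Deterministic log Z approximations per unique stimulus row.

    ``nmf``
        Factorized variational lower bound: fixed point
        ``m_i = logistic(h_i + 2 sum_j J_ij m_j)`` and
        ``log Z = sum_i [h_i m_i + H(m_i)] + 2 sum_{i<j} J_ij m_i m_j``.
    ``tap``
        nmf plus the Onsager reaction correction to the fields and free
        energy (second order in the couplings).
    ``bethe``
        Loopy belief propagation on the fully connected pairwise graph
        with a damped parallel schedule; log Z from the Bethe free
        energy of the fixed-point beliefs.
    ``low_rate``
        Low-firing-rate expansion:
        ``log Z = sum_i log(1+e^{h_i}) + sum_{i<j} p_i p_j (e^{2 J_ij}-1)``
        with p_i = logistic(h_i); exact when J = 0 (as are all four).

    Non-converged bins are flagged in ``converged``; values are still
    returned.
    """
    if method not in ("nmf", "tap", "bethe", "low_rate"):
        raise ValueError("method must be one of nmf, tap, bethe, low_rate")
    uniq, inv = covariates.unique_rows()
    H = model.fields(uniq)
    K = 2.0 * model.J           # pairwise energy coefficient in {0,1} coding
    if method in ("nmf", "tap"):
        onsager = method == "tap"
        m, conv = _nmf_fixed_point(H, K, max_iter, tol, damping, onsager)
        logZ_u = _mean_field_logZ(H, K, m, onsager)
    elif method == "bethe":
        logZ_u, conv = _bethe_logZ(H, K, max_iter, tol, damping)
    else:
        p = expit(H)
        gain = np.expm1(K)      # zero on the diagonal since K_ii = 0
        logZ_u = (np.sum(np.logaddexp(0.0, H), axis=1)
                  + 0.5 * np.einsum("ui,ij,uj->u", p, gain, p))
        conv = np.ones(H.shape[0], dtype=bool)
    n_bad = int(np.sum(~conv))
    if n_bad:
        warnings.warn(f"{method}: {n_bad} unique stimulus row(s) did not "
                      f"converge within {max_iter} iterations", RuntimeWarning)
    return PartitionSeries(log_values=logZ_u[inv], method=method,
                           converged=conv[inv])
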