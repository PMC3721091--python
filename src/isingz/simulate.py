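"""Synthetic stimulus-driven Ising populations and validation protocols.

The default trial protocol mirrors a standard awake-recording simulation
setup: repeated 2500 ms trials discretized at 5 ms (500 bins per trial),
per-neuron stimulus drive h_n(t) built from 4th-order B-splines on knots
spaced 100 ms apart, spline weights chosen so fields stay in roughly
[-6, -2] and each neuron fires near 5 Hz on average, and a random
symmetric coupling matrix J drawn uniformly in [-J_max, J_max].  Rasters
are drawn from the resulting model by single-site Gibbs sampling.

Also here: the first ten Zernike polynomials (for place-field style
drive on the unit disc), a combinatorial forecast of the unique-pattern
count and Good-Turing missing mass for constant-rate Bernoulli
populations, and a calibration helper that searches J_max to stage a
requested Good-Turing missing mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import binom

from .ising_core import CovariateMatrix, IsingModel, SpikeRaster, build_pattern_table
from .partition_approx import good_turing

logger = logging.getLogger("isingz")


@dataclass
class TrialProtocol:
    """Parameters of the repeated-trial simulation protocol.

    Defaults are the package's reference conditions: 2500 ms trials at
    5 ms bins (500 bins/trial), 100 ms B-spline knot spacing, 5 Hz
    target mean rate.
    """

    trial_ms: int = 2500
    bin_ms: int = 5
    n_trials: int = 40
    knot_spacing_ms: int = 100
    target_mean_rate_hz: float = 5.0
    j_max: float = 0.25
    seed: int = 0
    n_neurons: int = 20

    def __post_init__(self) -> None:
        if self.trial_ms % self.bin_ms != 0:
            raise ValueError("trial_ms must be divisible by bin_ms")
        if self.trial_ms % self.knot_spacing_ms != 0:
            raise ValueError("knot spacing must divide the trial length")
        if self.n_trials < 1 or self.n_neurons < 1:
            raise ValueError("need at least one trial and one neuron")

    @property
    def bins_per_trial(self) -> int:
        return self.trial_ms // self.bin_ms

    @property
    def total_bins(self) -> int:
        return self.bins_per_trial * self.n_trials

    @property
    def bin_width_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def target_p(self) -> float:
        """Target per-bin spike probability."""
        return self.target_mean_rate_hz * self.bin_width_s


@dataclass
class BernoulliPopulationSpec:
    """Constant-rate Bernoulli population: N neurons, spike prob p, L bins."""

    N: int
    p: float
    L: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie strictly between 0 and 1")
        if self.N < 1 or self.L < 1:
            raise ValueError("N and L must be positive")


# ---------------------------------------------------------------------------
# Stimulus bases
# ---------------------------------------------------------------------------

def bspline_basis(protocol: TrialProtocol) -> CovariateMatrix:
    """4th-order B-spline basis tiling the trial, tiled across trials.

    Clamped knots at multiples of the knot spacing give
    ``trial_ms/knot_spacing + 3`` basis functions forming a partition of
    unity over the trial (rows sum to 1), evaluated at bin centers.
    """
    n_intervals = protocol.trial_ms // protocol.knot_spacing_ms
    degree = 3  # order 4
    knots = np.concatenate([
        np.zeros(degree),
        np.arange(n_intervals + 1) * protocol.knot_spacing_ms,
        np.full(degree, protocol.trial_ms),
    ]).astype(float)
    t = (np.arange(protocol.bins_per_trial) + 0.5) * protocol.bin_ms
    design = BSpline.design_matrix(t, knots, degree).toarray()
    tiled = np.tile(design, (protocol.n_trials, 1))
    labels = [f"bspline_{m:02d}" for m in range(design.shape[1])]
    return CovariateMatrix(data=tiled, column_labels=labels,
                           basis_kind="bspline_trial_time")


# (n, |m|, radial coefficients) for Noll indices 1..10; azimuthal factor
# cos(m theta) for positive Noll parity, sin otherwise, Noll normalization.
_ZERNIKE_TABLE = [
    # j, n, m (signed; >=0 -> cos, <0 -> sin)
    (1, 0, 0), (2, 1, 1), (3, 1, -1), (4, 2, 0), (5, 2, -2),
    (6, 2, 2), (7, 3, -1), (8, 3, 1), (9, 3, -3), (10, 3, 3),
]


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k) * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_basis(positions: np.ndarray) -> CovariateMatrix:
    """First 10 Zernike polynomials (Noll ordering and normalization)
    evaluated at (rho, theta) positions on the unit disc.

    Provided so synthetic place-field experiments can mirror
    position-driven drive: each neuron's field is a linear combination
    of these columns.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be an (L, 2) array of (rho, theta)")
    rho, theta = pos[:, 0], pos[:, 1]
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    cols = []
    for j, n, m in _ZERNIKE_TABLE:
        radial = _zernike_radial(n, m, rho)
        if m == 0:
            col = math.sqrt(n + 1) * radial
        elif m > 0:
            col = math.sqrt(2 * (n + 1)) * radial * np.cos(m * theta)
        else:
            col = math.sqrt(2 * (n + 1)) * radial * np.sin(-m * theta)
        cols.append(col)
    labels = [f"zernike_{j:02d}" for j, _, _ in _ZERNIKE_TABLE]
    return CovariateMatrix(data=np.column_stack(cols), column_labels=labels,
                           basis_kind="zernike_disc")


# ---------------------------------------------------------------------------
# Ground-truth model construction
# ---------------------------------------------------------------------------

def make_ground_truth(protocol: TrialProtocol) -> tuple[IsingModel, CovariateMatrix]:
    """Seeded ground-truth model and its covariate matrix.

    Spline weights are drawn uniformly in [-6, -2] (so the partition-of-
    unity basis keeps h_n(t) in that band), then shifted per neuron by a
    scalar offset -- found by root bisection under J = 0 -- so the mean
    firing probability hits the protocol's target rate.  J is uniform on
    [-J_max, J_max], symmetrized, zero diagonal.
    """
    rng = np.random.default_rng(protocol.seed)
    cov = bspline_basis(protocol)
    n_basis = cov.n_covariates
    N = protocol.n_neurons
    beta = rng.uniform(-6.0, -2.0, size=(n_basis, N))
    base = cov.data[:protocol.bins_per_trial]       # one trial's design
    p_target = protocol.target_p
    for i in range(N):
        h = base @ beta[:, i]

        def gap(delta: float) -> float:
            return float(expit(h + delta).mean() - p_target)

        lo, hi = -10.0, 10.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise ValueError(
                f"target mean rate {protocol.target_mean_rate_hz} Hz is "
                "unattainable within the field-offset search range")
        delta = brentq(gap, lo, hi, xtol=1e-10)
        beta[:, i] += delta     # partition of unity: shifts h_i(t) by delta
    J_upper = rng.uniform(-protocol.j_max, protocol.j_max, size=(N, N))
    J = np.triu(J_upper, k=1)
    J = J + J.T
    return IsingModel(beta=beta, J=J), cov


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def gibbs_sample(model: IsingModel, covariates: CovariateMatrix,
                 sweeps_per_bin: int = 10, burn_in: int = 20,
                 seed: int = 0, trial_length: int | None = None) -> SpikeRaster:
    """Draw a raster from the model by single-site Gibbs sampling.

    For each bin the sampler runs ``burn_in + sweeps_per_bin`` full
    sweeps of the exact Ising conditionals, warm-started from the
    previous bin's state (consecutive bins share similar fields, so warm
    starts mix fast), and records the final state.  The first bin of a
    chain is initialized from independent draws at logistic(h).

    If ``trial_length`` is given (bins per trial, dividing L), trials
    are treated as independent chains and sampled in parallel -- each
    trial's first bin gets the independent initialization.  The output
    is bitwise-reproducible for a given seed.
    """
    if sweeps_per_bin < 1:
        raise ValueError("sweeps_per_bin must be at least 1")
    H = model.fields(covariates)
    L, N = H.shape
    rng = np.random.default_rng(seed)
    if trial_length is None:
        n_chains, chain_len = 1, L
        Hc = H[None, :, :]                     # (chains, bins, N)
    else:
        if L % trial_length != 0:
            raise ValueError("trial_length must divide the number of bins")
        n_chains, chain_len = L // trial_length, trial_length
        Hc = H.reshape(n_chains, trial_length, N)
    total_sweeps = burn_in + sweeps_per_bin
    out = np.empty((n_chains, chain_len, N), dtype=np.uint8)
    J2 = 2.0 * model.J
    state = (rng.random((n_chains, N)) < expit(Hc[:, 0, :])).astype(float)
    for b in range(chain_len):
        h_b = Hc[:, b, :]                      # (chains, N)
        for _ in range(total_sweeps):
            for i in range(N):
                x = h_b[:, i] + state @ J2[:, i]
                state[:, i] = rng.random(n_chains) < expit(x)
        out[:, b, :] = state.astype(np.uint8)
    return SpikeRaster(data=out.reshape(L, N),
                       bin_width=covariates_bin_width(covariates),
                       trial_length=trial_length)


def covariates_bin_width(covariates: CovariateMatrix,
                         default: float = 0.005) -> float:
    # CovariateMatrix carries no bin width; rasters default to 5 ms.
    return default


def simulate_protocol(protocol: TrialProtocol,
                      sweeps_per_bin: int = 10, burn_in: int = 20,
                      hold_rates: bool = True, max_rate_iters: int = 6,
                      ) -> tuple[IsingModel, CovariateMatrix, SpikeRaster]:
    """Ground-truth model, covariates and Gibbs-sampled raster in one call.

    The offset search in :func:`make_ground_truth` fixes mean rates under
    J = 0, but couplings shift the realized rates (strong positive
    couplings can run away entirely).  With ``hold_rates`` the per-neuron
    field offsets are re-balanced self-consistently -- simulate, compare
    each neuron's empirical spike probability to the target, nudge its
    offset by the damped logit difference -- until every neuron's rate is
    within 10% of the protocol target (or ``max_rate_iters`` is
    exhausted).  The same seed is reused for every iteration, so the
    output is deterministic in (seed, protocol).
    """
    model, cov = make_ground_truth(protocol)
    p_target = protocol.target_p

    def draw(m: IsingModel) -> SpikeRaster:
        r = gibbs_sample(m, cov, sweeps_per_bin=sweeps_per_bin,
                         burn_in=burn_in, seed=protocol.seed + 1,
                         trial_length=protocol.bins_per_trial)
        r.bin_width = protocol.bin_width_s
        return r

    raster = draw(model)
    if hold_rates and protocol.j_max > 0:
        for _ in range(max_rate_iters):
            p_emp = np.clip(raster.data.mean(axis=0), 1e-5, 1 - 1e-5)
            if np.all(np.abs(p_emp - p_target) <= 0.1 * p_target):
                break
            nudge = 0.8 * (np.log(p_target / (1 - p_target))
                           - np.log(p_emp / (1 - p_emp)))
            model = IsingModel(beta=model.beta + nudge[None, :], J=model.J,
                               field_offset=model.field_offset)
            raster = draw(model)
    return model, cov, raster


# ---------------------------------------------------------------------------
# Bernoulli pattern-count forecast
# ---------------------------------------------------------------------------

def bernoulli_pattern_forecast(spec: BernoulliPopulationSpec,
                               ) -> tuple[float, float]:
    """Approximate upper bound on the unique-pattern count, and the
    implied Good-Turing missing-mass forecast, for a constant-rate
    Bernoulli population.

    For each spike count K the number of unique K-spike patterns is
    bounded by ``min{C(N, K), Binom(K; N, p) * L}``; summing over K
    forecasts the pattern count.  Where the binomial branch is the
    active bound every observation of a K-spike pattern is (worst case)
    a new, hence singleton, pattern, so summing the binomial
    probabilities over those K forecasts the Good-Turing missing mass.
    Both are order-of-magnitude forecasts, not exact counts.
    """
    K = np.arange(spec.N + 1)
    pmf = binom.pmf(K, spec.N, spec.p)
    n_comb = np.array([math.comb(spec.N, int(k)) for k in K], dtype=float)
    expected_counts = pmf * spec.L
    n_pat = float(np.minimum(n_comb, expected_counts).sum())
    binomial_active = expected_counts < n_comb
    m_gt = float(pmf[binomial_active].sum())
    return n_pat, m_gt


# ---------------------------------------------------------------------------
# Missing-mass calibration
# ---------------------------------------------------------------------------

def calibrate_missing_mass(protocol: TrialProtocol, target: float,
                           rel_tol: float = 0.2, rate_hi_factor: float = 8.0,
                           max_iter: int = 12,
                           ) -> tuple[TrialProtocol, IsingModel,
                                      CovariateMatrix, SpikeRaster, float]:
    """Adjust the rate offset so the simulated Good-Turing missing mass
    hits ``target`` within ``rel_tol`` relative error.

    The missing mass of a fixed-length recording is governed almost
    entirely by the population firing rate (pattern diversity grows
    steeply with the per-bin spike probability), while the coupling
    strength moves it only marginally once rates are held at the
    protocol target.  The calibration therefore keeps the protocol's
    J_max and bisects a scalar multiplier on the target rate -- the
    per-neuron field offsets shift accordingly -- between 1 and
    ``rate_hi_factor``.  The same seed is used for every evaluation, so
    the spline draw and the noise stream are held fixed.  Returns the
    calibrated protocol with the model, covariates, raster and achieved
    missing mass of the final evaluation.
    """

    def evaluate(factor: float):
        proto = replace(protocol,
                        target_mean_rate_hz=protocol.target_mean_rate_hz * factor)
        model, cov, raster = simulate_protocol(proto)
        m = good_turing(build_pattern_table(raster))
        logger.info("calibration: rate=%.2f Hz -> M_GT=%.4f",
                    proto.target_mean_rate_hz, m)
        return proto, model, cov, raster, m

    lo, hi = 1.0, float(rate_hi_factor)
    base = evaluate(lo)
    if abs(base[4] - target) <= rel_tol * target:
        return base
    if base[4] > target:
        raise ValueError(
            f"missing mass at the protocol rate is already {base[4]:.4f} > "
            f"target {target:.4f}; lower the rate or lengthen the data")
    hi_eval = evaluate(hi)
    if abs(hi_eval[4] - target) <= rel_tol * target:
        return hi_eval
    if hi_eval[4] < target:
        raise ValueError(
            f"missing mass reaches only {hi_eval[4]:.4f} < target "
            f"{target:.4f} at {hi:.0f}x the protocol rate")
    mid_eval = hi_eval
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mid_eval = evaluate(mid)
        if abs(mid_eval[4] - target) <= rel_tol * target:
            return mid_eval
        if mid_eval[4] < target:
            lo = mid
        else:
            hi = mid
    return mid_eval
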