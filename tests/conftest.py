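"""Shared fixtures: small random models and datasets built at test time."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import isingz as iz


def random_model(rng: np.random.Generator, n_neurons: int, n_cov: int = 3,
                 j_scale: float = 0.3, h_loc: float = -1.0) -> iz.IsingModel:
    """A random stimulus-driven Ising model with symmetric couplings."""
    beta = rng.normal(loc=h_loc, scale=1.0, size=(n_cov, n_neurons))
    J = rng.normal(scale=j_scale, size=(n_neurons, n_neurons))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return iz.IsingModel(beta=beta, J=J)


def random_covariates(rng: np.random.Generator, n_bins: int,
                      n_cov: int = 3) -> iz.CovariateMatrix:
    return iz.CovariateMatrix(data=rng.normal(scale=0.5, size=(n_bins, n_cov)))


def all_patterns(n: int) -> np.ndarray:
    """All 2^n binary patterns in the canonical little-endian order."""
    return np.array([[(k >> i) & 1 for i in range(n)]
                     for k in range(1 << n)], dtype=np.uint8)


def naive_log_partition(model: iz.IsingModel, cov: iz.CovariateMatrix) -> np.ndarray:
    """Per-bin log Z by direct per-bin summation over every pattern --
    the independent oracle for exact_partition."""
    H = model.fields(cov)
    out = np.empty(cov.bins)
    pats = list(itertools.product([0, 1], repeat=model.n_neurons))
    for t in range(cov.bins):
        terms = [iz.log_weight(np.array(p), H[t], model.J) for p in pats]
        m = max(terms)
        out[t] = m + np.log(sum(np.exp(x - m) for x in terms))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated dataset (6 neurons, trial drive),
    shared by fitting/approximation tests."""
    proto = iz.TrialProtocol(trial_ms=500, bin_ms=5, n_trials=60,
                             knot_spacing_ms=100, n_neurons=6, j_max=0.3,
                             seed=7, target_mean_rate_hz=20.0)
    model, cov, raster = iz.simulate_protocol(proto)
    return {"protocol": proto, "model": model, "cov": cov, "raster": raster}
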