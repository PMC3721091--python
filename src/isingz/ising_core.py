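"""Core data types and exact computations for stimulus-driven Ising models.

A stimulus-driven pairwise maximum-entropy (Ising) model assigns each
binary spike pattern sigma in {0,1}^N the probability

    P(sigma | s) = exp(h(s) . sigma + sigma^T J sigma) / Z(s),

where the per-bin fields h(s) = C(s) beta are a linear function of a
stimulus covariate matrix C(s) (L x R) through fitted weights beta
(R x N), and J is a symmetric N x N coupling matrix with zero diagonal.
The normalizer Z(s) -- the stimulus-dependent partition function -- is a
sum over all 2^N patterns and must in principle be recomputed for every
unique stimulus value observed.

This module defines the containers shared by the whole package
(:class:`SpikeRaster`, :class:`CovariateMatrix`, :class:`IsingModel`,
:class:`PatternTable`, :class:`PartitionSeries`), the pattern energy and
conditional-spike primitives, exact enumeration of Z(s), and plain-text /
npz / JSON I/O.

Conventions fixed here and relied on everywhere else:

* spins are {0,1}; the {-1,+1} convention is refused, never converted;
* J is stored exactly symmetric with zero diagonal, so the pairwise
  energy equals 2 * sum_{i<j} sigma_i sigma_j J_ij;
* all partition values are carried in log space;
* per-bin quantities are computed once per *unique* covariate row and
  broadcast back to bins (trial-structured protocols have at most
  bins-per-trial unique rows, which is what makes 20-neuron exact
  enumeration desk-scale);
* pattern keys are little-endian bit-packed integers (neuron 0 is the
  least significant bit) for N <= 64 and little-endian packed byte
  strings otherwise, so serialized tables are portable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("isingz")

#: Largest N for which exact enumeration of the 2^N patterns is permitted.
DEFAULT_ENUMERATION_CAP = 24

#: Patterns are enumerated in blocks of this many rows to bound memory.
_PATTERN_BLOCK = 1 << 14

#: Unique covariate rows are processed in chunks of this many columns.
_ROW_CHUNK = 128


class OpCounter:
    """Accumulates floating-point operation counts per computational path.

    Scaling claims (linear in L and N_pat for the missing-mass path versus
    exponential in N for exact enumeration) are verified from these counts
    rather than from wall-clock time.
    """

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def add(self, key: str, n: int) -> None:
        self.counts[key] = self.counts.get(key, 0) + int(n)

    def reset(self) -> None:
        self.counts.clear()

    def snapshot(self) -> dict[str, int]:
        return dict(self.counts)


#: Global operation counter; reset it around a controlled sweep.
OPS = OpCounter()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Binned binary spike raster, L time bins by N neurons.

    Parameters
    ----------
    data : ndarray of shape (L, N)
        Binary spike indicators, entries in {0, 1}.
    bin_width : float
        Bin width in seconds (default 5 ms).
    trial_length : int, optional
        Bins per trial for trial-structured data; must divide L.
    """

    data: np.ndarray
    bin_width: float = 0.005
    trial_length: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("raster must be a 2-D L x N array with L, N >= 1")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("raster entries must all be 0 or 1 "
                             "({-1,+1} spin coding is not accepted)")
        self.data = self.data.astype(np.uint8)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.trial_length is not None:
            if self.bins % self.trial_length != 0:
                raise ValueError("trial_length must divide the number of bins")

    @property
    def bins(self) -> int:
        return self.data.shape[0]

    @property
    def neurons(self) -> int:
        return self.data.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in Hz."""
        return self.data.mean(axis=0) / self.bin_width


@dataclass
class CovariateMatrix:
    """Stimulus design matrix C(s), one row per time bin.

    Rows align 1:1 with the bins of the companion :class:`SpikeRaster`.
    """

    data: np.ndarray
    column_labels: list[str] = field(default_factory=list)
    basis_kind: str = "custom"

    _BASIS_KINDS = ("bspline_trial_time", "zernike_disc", "custom")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("covariates must be a 2-D L x R array with R >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("covariate entries must be finite")
        if not self.column_labels:
            self.column_labels = [f"c{j}" for j in range(self.data.shape[1])]
        if len(self.column_labels) != self.data.shape[1]:
            raise ValueError("column_labels length must match the number of columns")
        if self.basis_kind not in self._BASIS_KINDS:
            raise ValueError(f"basis_kind must be one of {self._BASIS_KINDS}")

    @property
    def bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.data.shape[1]

    def unique_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Deduplicated covariate rows and the bin -> unique-row index.

        Returns ``(U, inverse)`` with ``U`` of shape (n_unique, R) and
        ``self.data == U[inverse]``.  Every per-bin quantity in this
        package is computed once per unique row and broadcast.
        """
        uniq, inv = np.unique(self.data, axis=0, return_inverse=True)
        return uniq, inv.ravel()


@dataclass
class IsingModel:
    """Stimulus weights beta (R x N) and symmetric couplings J (N x N).

    The per-bin fields are ``h(s) = C(s) @ beta + field_offset``.  The
    optional ``field_offset`` exists only to absorb any nonzero diagonal
    of J handed to the constructor (sigma_i^2 = sigma_i for {0,1} spins,
    so a self-coupling is a constant field); a warning is logged when
    that happens.
    """

    beta: np.ndarray
    J: np.ndarray
    field_offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.beta.ndim != 2:
            raise ValueError("beta must be an R x N matrix")
        n = self.beta.shape[1]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be {n} x {n} to match beta")
        if not np.allclose(self.J, self.J.T, rtol=0, atol=1e-8):
            raise ValueError("J must be symmetric")
        J = 0.5 * (self.J + self.J.T)
        diag = np.diag(J).copy()
        offset = np.zeros(n) if self.field_offset is None else np.asarray(
            self.field_offset, dtype=float).copy()
        if offset.shape != (n,):
            raise ValueError("field_offset must have length N")
        if np.any(diag != 0):
            logger.warning("nonzero diagonal of J absorbed into the fields "
                           "(sigma_i^2 = sigma_i for {0,1} spins)")
            offset += diag
            np.fill_diagonal(J, 0.0)
        self.J = J
        self.field_offset = offset

    @property
    def n_neurons(self) -> int:
        return self.beta.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]

    def fields(self, covariates: CovariateMatrix | np.ndarray) -> np.ndarray:
        """Per-bin fields h(s) = C(s) @ beta (+ any absorbed offset)."""
        C = covariates.data if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, dtype=float)
        if C.shape[-1] != self.n_covariates:
            raise ValueError("covariate row length does not match beta")
        return C @ self.beta + self.field_offset


def _pack_keys(data: np.ndarray) -> np.ndarray:
    """Little-endian bit-packed pattern keys (neuron 0 = least significant).

    Returns a uint64 vector for N <= 64, otherwise an array of packed
    byte strings.
    """
    n = data.shape[1]
    if n <= 64:
        weights = (np.uint64(1) << np.arange(n, dtype=np.uint64))
        return data.astype(np.uint64) @ weights
    packed = np.packbits(data, axis=1, bitorder="little")
    return np.array([row.tobytes() for row in packed], dtype=object)


@dataclass
class PatternTable:
    """Unique observed spike patterns with counts and per-bin index.

    ``patterns`` are ordered canonically by ascending packed-integer key;
    ``bin_index[t]`` points to the pattern observed in bin t, so
    ``patterns[bin_index]`` reconstructs the raster.
    """

    patterns: np.ndarray          # (n_pat, N) uint8
    counts: np.ndarray            # (n_pat,) int
    bin_index: np.ndarray         # (L,) int

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        if self.patterns.shape[0] != self.counts.shape[0]:
            raise ValueError("counts must have one entry per pattern")
        if self.counts.sum() != self.bin_index.shape[0]:
            raise ValueError("counts must sum to the number of bins")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_bins(self) -> int:
        return self.bin_index.shape[0]

    @property
    def n_singletons(self) -> int:
        """Number of patterns observed exactly once."""
        return int(np.sum(self.counts == 1))

    def keys(self) -> np.ndarray:
        return _pack_keys(self.patterns)


_SERIES_METHODS = ("exact", "X_only", "good_turing", "conditional_logistic",
                   "importance_sampling", "nmf", "tap", "bethe", "low_rate")


@dataclass
class PartitionSeries:
    """Per-bin partition-function estimates, stored as log values.

    Parameters
    ----------
    log_values : ndarray of shape (L,)
        log Z(s) per bin.
    method : str
        One of ``exact, X_only, good_turing, conditional_logistic,
        importance_sampling, nmf, tap, bethe, low_rate``.
    mc_se : ndarray, optional
        Per-bin Monte Carlo standard errors (linear scale), for sampled
        estimators.
    converged : ndarray of bool, optional
        Per-bin fixed-point convergence flags, for iterative estimators.
    """

    log_values: np.ndarray
    method: str
    mc_se: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.log_values.ndim != 1:
            raise ValueError("log_values must be 1-D")
        if not np.all(np.isfinite(self.log_values)):
            raise ValueError("log partition values must be finite")
        if self.method not in _SERIES_METHODS:
            raise ValueError(f"method must be one of {_SERIES_METHODS}")

    @property
    def values(self) -> np.ndarray:
        """Partition values on the linear scale (always positive)."""
        return np.exp(self.log_values)

    def __len__(self) -> int:
        return self.log_values.shape[0]


# ---------------------------------------------------------------------------
# Energies and exact computations
# ---------------------------------------------------------------------------

def log_weight(pattern: np.ndarray, h_row: np.ndarray, J: np.ndarray) -> float:
    """Unnormalized log weight h . sigma + sigma^T J sigma of one pattern.

    For symmetric J with zero diagonal the quadratic term equals
    ``2 * sum_{i<j} sigma_i sigma_j J_ij``.
    """
    sigma = np.asarray(pattern, dtype=float)
    h_row = np.asarray(h_row, dtype=float)
    J = np.asarray(J, dtype=float)
    n = sigma.shape[0]
    if h_row.shape != (n,) or J.shape != (n, n):
        raise ValueError("pattern, h_row and J dimensions do not match")
    return float(sigma @ h_row + sigma @ J @ sigma)


def _pattern_block(start: int, stop: int, n: int) -> np.ndarray:
    """Rows ``start:stop`` of the canonical 2^N pattern enumeration."""
    idx = np.arange(start, stop, dtype=np.uint64)[:, None]
    bits = (idx >> np.arange(n, dtype=np.uint64)[None, :]) & np.uint64(1)
    return bits.astype(float)


def quadratic_energies(patterns: np.ndarray, J: np.ndarray) -> np.ndarray:
    """sigma^T J sigma for each row of ``patterns``."""
    P = np.asarray(patterns, dtype=float)
    return np.einsum("pi,ij,pj->p", P, J, P, optimize=True)


def exact_partition(model: IsingModel, covariates: CovariateMatrix,
                    n_cap: int = DEFAULT_ENUMERATION_CAP) -> PartitionSeries:
    """Exact Z(s) per bin by log-sum-exp enumeration over all 2^N patterns.

    The quadratic energies sigma^T J sigma are computed once per pattern
    block and reused across all unique covariate rows; results are
    broadcast back to bins.  Refuses N above ``n_cap`` (use one of the
    approximations instead).
    """
    n = model.n_neurons
    if n > n_cap:
        raise ValueError(
            f"exact enumeration over 2^{n} patterns exceeds the cap of "
            f"N={n_cap}; use an approximation (conditional_logistic, "
            "good_turing, importance_sampling, ...) instead")
    uniq, inv = covariates.unique_rows()
    H = model.fields(uniq)                     # (U, N)
    n_unique = H.shape[0]
    n_pat_total = 1 << n
    chunk_lse: list[np.ndarray] = []
    for start in range(0, n_pat_total, _PATTERN_BLOCK):
        stop = min(start + _PATTERN_BLOCK, n_pat_total)
        P = _pattern_block(start, stop, n)
        q = quadratic_energies(P, model.J)     # (b,)
        for cstart in range(0, n_unique, _ROW_CHUNK):
            Hc = H[cstart:cstart + _ROW_CHUNK]
            logw = q[:, None] + P @ Hc.T       # (b, u)
            part = logsumexp(logw, axis=0)
            if start == 0:
                chunk_lse.append(part)
            else:
                block_i = start // _PATTERN_BLOCK
                idx = cstart // _ROW_CHUNK
                chunk_lse[idx] = np.logaddexp(chunk_lse[idx], part)
    logZ_u = np.concatenate(chunk_lse)
    OPS.add("exact_enumeration", n_unique * n_pat_total * n + covariates.bins)
    return PartitionSeries(log_values=logZ_u[inv], method="exact")


def pattern_probability(model: IsingModel, pattern: np.ndarray,
                        h_row: np.ndarray, Z_value: float) -> float:
    """P(sigma | s) = exp(log weight - log Z) for one pattern and bin."""
    if Z_value <= 0:
        raise ValueError("partition value must be positive")
    return float(np.exp(log_weight(pattern, h_row, model.J) - np.log(Z_value)))


def conditional_spike_prob(model: IsingModel, neuron: int,
                           others: np.ndarray, h_row: np.ndarray) -> float:
    """P(sigma_i = 1 | sigma_{j != i}; s), the exact Ising conditional.

    A logistic function of ``h_i(s) + 2 sum_{j != i} sigma_j J_ji``.
    ``others`` is a full-length pattern whose entry at ``neuron`` is
    ignored.
    """
    sigma = np.asarray(others, dtype=float).copy()
    sigma[neuron] = 0.0
    x = h_row[neuron] + 2.0 * float(sigma @ model.J[:, neuron])
    from scipy.special import expit
    return float(expit(x))


def build_pattern_table(raster: SpikeRaster) -> PatternTable:
    """Unique observed patterns, counts, singleton count and bin index.

    Patterns are ordered canonically by ascending little-endian packed
    key, so tables built from permuted data agree after sorting.
    """
    keys = _pack_keys(raster.data)
    uniq_keys, first_idx, inverse, counts = np.unique(
        keys, return_index=True, return_inverse=True, return_counts=True)
    patterns = raster.data[first_idx].astype(np.uint8)
    return PatternTable(patterns=patterns, counts=counts,
                        bin_index=inverse.ravel())


# ---------------------------------------------------------------------------
# I/O: delimited text, npz container, model JSON
# ---------------------------------------------------------------------------

def save_dataset_npz(path, raster: SpikeRaster, covariates: CovariateMatrix) -> None:
    """Write raster + covariates to a named-array npz container."""
    np.savez_compressed(
        path,
        spikes=raster.data,
        covariates=covariates.data,
        bin_width=np.array(raster.bin_width),
        trial_length=np.array(-1 if raster.trial_length is None else raster.trial_length),
        column_labels=np.array(covariates.column_labels),
        basis_kind=np.array(covariates.basis_kind),
    )


def load_dataset_npz(path) -> tuple[SpikeRaster, CovariateMatrix]:
    with np.load(path, allow_pickle=False) as f:
        trial_length = int(f["trial_length"])
        raster = SpikeRaster(
            data=f["spikes"],
            bin_width=float(f["bin_width"]),
            trial_length=None if trial_length < 0 else trial_length,
        )
        cov = CovariateMatrix(
            data=f["covariates"],
            column_labels=[str(x) for x in f["column_labels"]],
            basis_kind=str(f["basis_kind"]),
        )
    return raster, cov


def save_raster_csv(path, raster: SpikeRaster, sep: str = "\t") -> None:
    """Headered delimited text, bins as rows, one column per neuron."""
    df = pd.DataFrame(raster.data,
                      columns=[f"n{j}" for j in range(raster.neurons)])
    df.to_csv(path, sep=sep, index=False)


def load_raster_csv(path, bin_width: float = 0.005,
                    trial_length: int | None = None, sep: str = "\t") -> SpikeRaster:
    df = pd.read_csv(path, sep=sep)
    return SpikeRaster(data=df.to_numpy(), bin_width=bin_width,
                       trial_length=trial_length)


def save_covariates_csv(path, covariates: CovariateMatrix, sep: str = "\t") -> None:
    df = pd.DataFrame(covariates.data, columns=covariates.column_labels)
    df.to_csv(path, sep=sep, index=False)


def load_covariates_csv(path, basis_kind: str = "custom", sep: str = "\t") -> CovariateMatrix:
    df = pd.read_csv(path, sep=sep)
    return CovariateMatrix(data=df.to_numpy(),
                           column_labels=list(df.columns),
                           basis_kind=basis_kind)


def save_model_json(path, model: IsingModel,
                    column_labels: Sequence[str] | None = None) -> None:
    payload = {
        "beta": model.beta.tolist(),
        "J": model.J.tolist(),
        "column_labels": list(column_labels) if column_labels is not None
        else [f"c{j}" for j in range(model.n_covariates)],
    }
    if np.any(model.field_offset != 0):
        payload["field_offset"] = model.field_offset.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path) -> tuple[IsingModel, list[str]]:
    with open(path) as fh:
        payload = json.load(fh)
    model = IsingModel(beta=np.array(payload["beta"], dtype=float),
                       J=np.array(payload["J"], dtype=float),
                       field_offset=np.array(payload["field_offset"], dtype=float)
                       if "field_offset" in payload else None)
    return model, list(payload.get("column_labels", []))


def save_series_csv(path, series: PartitionSeries, sep: str = "\t") -> None:
    """Partition series as delimited text: bin, log Z, method, optional SE."""
    cols = {"bin": np.arange(len(series)),
            "log_Z": series.log_values,
            "method": series.method}
    if series.mc_se is not None:
        cols["mc_se"] = series.mc_se
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def load_series_csv(path, sep: str = "\t") -> PartitionSeries:
    df = pd.read_csv(path, sep=sep)
    method = str(df["method"].iloc[0])
    mc_se = df["mc_se"].to_numpy() if "mc_se" in df.columns else None
    return PartitionSeries(log_values=df["log_Z"].to_numpy(),
                           method=method, mc_se=mc_se)
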