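"""Error metrics and the end-to-end experiment driver.

Accuracy of a partition-function estimate is quantified by the
distribution, over stimuli, of the ratio Z_est(s) / Z_ref(s).  This
ratio equals the factor by which every pattern probability is mis-scaled
(P_ref(sigma|s)/P_est(sigma|s) = Z_est(s)/Z_ref(s)), so its 99% bounds
(0.005 and 0.995 quantiles) summarize normalization error directly.

:func:`run_experiment` drives the full pipeline -- simulate, split, fit
(pseudo-likelihood + chain), compute every requested Z series, summarize
ratios against the exact reference (or against the conditional-logistic
reference when N exceeds the enumeration cap) -- and emits a
machine-readable report including the missing-mass estimates and
operation counts per method.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import fitting, partition_approx, simulate
from .ising_core import (DEFAULT_ENUMERATION_CAP, OPS, PartitionSeries,
                         build_pattern_table, exact_partition)

logger = logging.getLogger("isingz")

REPORT_SCHEMA_VERSION = 1

_QUANTILES = (0.005, 0.05, 0.95, 0.995)


@dataclass
class RatioSummary:
    """Summary of a ratio distribution: mean, tail quantiles, and the
    worst 99%-bound deviation from 1."""

    mean: float
    q005: float
    q05: float
    q95: float
    q995: float
    max_abs_deviation: float

    @property
    def band_width(self) -> float:
        return self.q995 - self.q005


def ratio_distribution(numerator: PartitionSeries,
                       denominator: PartitionSeries) -> RatioSummary:
    """Bin-wise exp(log Za - log Zb) summarized per :class:`RatioSummary`.

    Quantiles use linear interpolation of order statistics (numpy's
    default, type-7 convention).
    """
    if len(numerator) != len(denominator):
        raise ValueError("series lengths differ")
    ratios = np.exp(numerator.log_values - denominator.log_values)
    q005, q05, q95, q995 = np.quantile(ratios, _QUANTILES)
    return RatioSummary(mean=float(ratios.mean()),
                        q005=float(q005), q05=float(q05),
                        q95=float(q95), q995=float(q995),
                        max_abs_deviation=float(max(abs(q005 - 1.0),
                                                    abs(q995 - 1.0))))


_KNOWN_METHODS = ("exact", "x_only", "gt", "cl", "is",
                  "nmf", "tap", "bethe", "low_rate")


class ExperimentError(RuntimeError):
    """Raised with the failing stage's name when a pipeline stage aborts."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"experiment stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name: str):
    import contextlib

    @contextlib.contextmanager
    def guard():
        try:
            yield
        except ExperimentError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise ExperimentError(name, exc) from exc

    return guard()


def run_experiment(config: dict) -> dict:
    """Simulate, fit, estimate Z by every requested method, and report.

    Config keys (all optional unless noted):

    ``protocol``
        Mapping of :class:`~isingz.simulate.TrialProtocol` fields.
    ``methods``
        List drawn from ``exact, x_only, gt, cl, is, nmf, tap, bethe,
        low_rate`` (required).
    ``train_frac``
        Fraction of trials used for fitting and the pattern table
        (default 1.0; Z series are evaluated on the remaining trials
        when < 1).
    ``is_samples``
        Importance-sampling draws per unique stimulus row (default 5000).
    ``seed``
        Overrides the protocol seed.
    ``exact_cap``
        Enumeration cap (default 24); requesting ``exact`` above it is
        refused.
    ``target_missing_mass``
        If set, the simulation is calibrated (rate-offset search) so the
        training data's Good-Turing missing mass hits this value within
        ``calibration_rel_tol`` (default 0.2) relative error.
    """
    methods = list(config.get("methods", []))
    if not methods:
        raise ExperimentError("config", ValueError("no methods requested"))
    for m in methods:
        if m not in _KNOWN_METHODS:
            raise ExperimentError("config",
                                  ValueError(f"unknown method '{m}'"))
    proto_kwargs = dict(config.get("protocol", {}))
    if "seed" in config:
        proto_kwargs["seed"] = int(config["seed"])
    protocol = simulate.TrialProtocol(**proto_kwargs)
    cap = int(config.get("exact_cap", DEFAULT_ENUMERATION_CAP))
    if "exact" in methods and protocol.n_neurons > cap:
        raise ExperimentError(
            "config", ValueError(
                f"exact enumeration refused for N={protocol.n_neurons} "
                f"(cap {cap})"))
    train_frac = float(config.get("train_frac", 1.0))
    if not (0.0 < train_frac <= 1.0):
        raise ExperimentError("config",
                              ValueError("train_frac must be in (0, 1]"))

    OPS.reset()
    with _stage("simulate"):
        if "target_missing_mass" in config:
            protocol, model_true, cov, raster, _ = \
                simulate.calibrate_missing_mass(
                    protocol, float(config["target_missing_mass"]),
                    rel_tol=float(config.get("calibration_rel_tol", 0.2)))
        else:
            model_true, cov, raster = simulate.simulate_protocol(protocol)

    with _stage("split"):
        n_train_trials = max(1, round(train_frac * protocol.n_trials))
        split = n_train_trials * protocol.bins_per_trial
        train_raster = simulate.SpikeRaster(
            data=raster.data[:split], bin_width=raster.bin_width,
            trial_length=protocol.bins_per_trial)
        train_cov = simulate.CovariateMatrix(
            data=cov.data[:split], column_labels=cov.column_labels,
            basis_kind=cov.basis_kind)
        if split < raster.bins:
            eval_cov = simulate.CovariateMatrix(
                data=cov.data[split:], column_labels=cov.column_labels,
                basis_kind=cov.basis_kind)
        else:
            eval_cov = train_cov

    with _stage("fit"):
        model_hat, pl_reports = fitting.fit_pseudolikelihood(
            train_raster, train_cov)
        table = build_pattern_table(train_raster)
        need_chain = "cl" in methods or protocol.n_neurons > cap
        chain = None
        if need_chain:
            chain, _ = fitting.fit_conditional_chain(train_raster, train_cov)

    series: dict[str, PartitionSeries] = {}
    mm_extra: dict[str, float] = {"m_gt": partition_approx.good_turing(table)}
    with _stage("partition"):
        X = partition_approx.observed_sum_X(model_hat, table, eval_cov)
        M_cl = None
        if need_chain:
            M_cl = partition_approx.missing_mass_series(chain, table, eval_cov)
            mm_extra["m_cl_mean"] = float(M_cl.values.mean())
        for m in methods:
            if m == "exact":
                series[m] = exact_partition(model_hat, eval_cov, n_cap=cap)
            elif m == "x_only":
                series[m] = X
            elif m == "gt":
                series[m] = partition_approx.z_from_missing_mass(
                    X, partition_approx.MissingMassSeries(
                        values=np.full(len(X), mm_extra["m_gt"]),
                        method="good_turing_constant"))
            elif m == "cl":
                series[m] = partition_approx.z_from_missing_mass(X, M_cl)
            elif m == "is":
                proposal = partition_approx.fit_independent_proposal(
                    train_raster, train_cov)
                series[m] = partition_approx.importance_sampling_Z(
                    model_hat, eval_cov,
                    n_samples=int(config.get("is_samples", 5000)),
                    seed=protocol.seed + 1000, proposal_beta=proposal)
            else:
                series[m] = partition_approx.deterministic_Z(
                    model_hat, eval_cov, method=m)

    with _stage("evaluate"):
        if "exact" in series:
            ref_name, ref = "exact", series["exact"]
        else:
            if "cl" not in series:
                raise ValueError("need 'exact' (N <= cap) or 'cl' as the "
                                 "reference method")
            ref_name, ref = "cl", series["cl"]
        blocks = {}
        for m in methods:
            blocks[m] = {"ratio_vs": ref_name,
                         "summary": asdict(ratio_distribution(series[m], ref))}

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "protocol": asdict(protocol),
        "train_frac": train_frac,
        "n_eval_bins": len(ref),
        "n_patterns_train": int(table.n_patterns),
        "missing_mass": mm_extra,
        "fit_converged": all(r.converged for r in pl_reports),
        "methods": blocks,
        "op_counts": OPS.snapshot(),
    }
    return report
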