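"""Calibrated (shrunken) estimates of the population-effect distribution.

A random-effects fit gives each study an empirical-Bayes style estimate of
its own population effect,

    gamma_i = mu_hat + (tau2_hat / (tau2_hat + v_i)) * (y_i - mu_hat),

i.e. the point estimate shrunk toward the pooled mean by a factor that
grows with the study's sampling noise.  The empirical distribution of the
gamma_i estimates the distribution of population effects across studies,
and the headline statistic is the proportion of that distribution at or
below a threshold q — here, the multi-laboratory replication estimate.
Uncertainty for the proportion comes from a bias-corrected and accelerated
(BCa) bootstrap that resamples whole studies and refits everything per
replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MetaDataset
from .meta import RandomEffectsMeta, RandomEffectsResults

__all__ = [
    "CalibratedEstimates",
    "ProportionResult",
    "calibrate_estimates",
    "prop_below_threshold",
    "bca_ci_for_proportion",
]


@dataclass(frozen=True)
class CalibratedEstimates:
    """Shrunken study-level estimates aligned with the source dataset."""

    values: np.ndarray
    source_fit: RandomEffectsResults

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def prop_below(self, q: float) -> float:
        return prop_below_threshold(self, q)


@dataclass(frozen=True)
class ProportionResult:
    """Proportion of calibrated effects <= threshold, with BCa 95% CI.

    ``ci_estimable`` is False (bounds None) when the bootstrap distribution
    is too degenerate for the BCa construction — mirroring reports that omit
    the interval in that case.
    """

    phat: float
    ci_low: float | None
    ci_high: float | None
    ci_estimable: bool
    threshold: float
    n_boot: int
    seed: int


def calibrate_estimates(
    dataset: MetaDataset, fit: RandomEffectsResults
) -> CalibratedEstimates:
    """Shrink each study's estimate toward the pooled mean.

    With ``tau2 = 0`` every calibrated value collapses to ``mu``; as
    ``v_i -> 0`` the calibrated value approaches the raw estimate.
    """
    y, v = dataset.estimates, dataset.variances
    if fit.k != len(dataset):
        raise ValueError("fit and dataset have mismatched study counts")
    shrink = fit.tau2 / (fit.tau2 + v)
    gamma = fit.mu + shrink * (y - fit.mu)
    return CalibratedEstimates(values=gamma, source_fit=fit)


def prop_below_threshold(cal: CalibratedEstimates, q: float) -> float:
    """Share of calibrated population effects at least as small as q
    (inclusive: ``gamma_i <= q``)."""
    if len(cal) == 0:
        raise ValueError("empty calibrated set")
    if not np.isfinite(q):
        raise ValueError("threshold must be finite")
    return float(np.mean(cal.values <= q))


def _phat_statistic(y, v, q: float, tau2_method: str) -> float:
    """Refit + recalibrate + count, on one (re)sample of studies."""
    ds = MetaDataset.from_arrays(np.asarray(y), np.asarray(v))
    fit = RandomEffectsMeta(ds).fit(tau2_method=tau2_method)
    cal = calibrate_estimates(ds, fit)
    return prop_below_threshold(cal, q)


def bca_ci_for_proportion(
    dataset: MetaDataset,
    q: float,
    n_boot: int = 1000,
    seed: int | None = None,
    tau2_method: str = "PM",
    method: str = "BCa",
) -> ProportionResult:
    """Proportion-below-threshold with a bootstrap 95% CI.

    Studies are resampled with replacement (the only resampling level
    available from study-level data); each replicate refits the
    meta-analysis with the same tau2 estimator, recalibrates and recounts.
    ``method`` is "BCa" (default; bias correction from the bootstrap
    distribution, acceleration from the leave-one-out jackknife) or
    "percentile" (kept for cross-checking coverage).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable interval")
    y, v = dataset.estimates, dataset.variances
    phat = _phat_statistic(y, v, q, tau2_method)
    if len(dataset) < 2:
        return ProportionResult(
            phat=phat,
            ci_low=None,
            ci_high=None,
            ci_estimable=False,
            threshold=q,
            n_boot=n_boot,
            seed=-1 if seed is None else seed,
        )

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        # a bootstrap distribution concentrated on one value triggers
        # degenerate-data warnings; we convert that case to an omitted CI
        warnings.simplefilter("ignore")
        try:
            boot = stats.bootstrap(
                (y, v),
                statistic=lambda ys, vs: _phat_statistic(ys, vs, q, tau2_method),
                paired=True,
                vectorized=False,
                n_resamples=n_boot,
                confidence_level=0.95,
                method=method,
                random_state=rng,
            )
            lo = float(boot.confidence_interval.low)
            hi = float(boot.confidence_interval.high)
        except Exception:
            lo = hi = float("nan")

    estimable = np.isfinite(lo) and np.isfinite(hi)
    if estimable:
        lo, hi = float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
    return ProportionResult(
        phat=phat,
        ci_low=lo if estimable else None,
        ci_high=hi if estimable else None,
        ci_estimable=bool(estimable),
        threshold=q,
        n_boot=n_boot,
        seed=-1 if seed is None else seed,
    )
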