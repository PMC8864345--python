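"""Cross-phenomenon comparison of meta-analytic and multi-laboratory
replication (MLR) estimates.

Three layers:

* :func:`correlate_estimates` — Pearson correlation between the naive
  pooled means and the MLR estimates across phenomena, with a Fisher-z
  confidence interval, a t-based two-sided p-value, and the least-squares
  line of MLR on meta-analysis estimates.
* :func:`sensitivity_summary` — headline statistics of the worst-case
  publication-bias analysis over the phenomena where the naive estimate
  exceeds the MLR estimate and the worst case is estimable.
* :func:`run_full_comparison` — orchestrates the per-phenomenon fits,
  calibrated proportions and sensitivity analyses into one deterministic
  report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import ProportionResult, bca_ci_for_proportion
from .data import PhenomenonPair
from .meta import RandomEffectsMeta, RandomEffectsResults
from .pubbias import SensitivityResult, classify_studies, corrected_estimate, worst_case_estimate

__all__ = [
    "AnalysisConfig",
    "CorrelationResult",
    "SensitivitySummary",
    "ComparisonReport",
    "correlate_estimates",
    "sensitivity_summary",
    "run_full_comparison",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full pipeline, recorded in every report."""

    tau2_method: str = "PM"
    interval_method: str = "wald_z"
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    eta_list: tuple[float, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of MLR on meta-analytic estimates."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class SensitivitySummary:
    """Headline worst-case statistics over the filtered phenomena.

    The filter keeps phenomena whose naive pooled mean strictly exceeds
    the MLR estimate and whose worst-case analysis is estimable (at least
    one non-affirmative study).  ``mean_ratio`` is the mean of the
    per-phenomenon worst/naive ratios; ``ratio_of_means`` is
    mean_worst_case / mean_naive — the two differ and both are reported.
    ``median_phat`` is taken over every phenomenon with a defined
    proportion-below metric; ``median_phat_included`` restricts to the
    filtered set.
    """

    n_analyzed: int
    mean_naive: float | None
    mean_worst_case: float | None
    mean_ratio: float | None
    ratio_of_means: float | None
    mean_abs_diff: float | None
    prop_worst_exceeds_mlr: float | None
    prop_worst_exceeds_null: float | None
    median_phat: float | None
    median_phat_included: float | None


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if abs(r) >= 1.0:  # perfect correlation: the transform degenerates
        return float(r), float(r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r*sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def correlate_estimates(
    pairs: list[PhenomenonPair], fits: list[RandomEffectsResults]
) -> CorrelationResult:
    """Correlate naive meta-analytic means with MLR estimates across
    phenomena."""
    if len(pairs) != len(fits):
        raise ValueError("pairs and fits must be aligned")
    n = len(pairs)
    if n < 3:
        raise ValueError("correlation needs at least 3 phenomena")
    ma = np.array([f.mu for f in fits])
    mlr = np.array([p.mlr_estimate for p in pairs])
    if np.allclose(ma.var(), 0) or np.allclose(mlr.var(), 0):
        raise ValueError("zero variance on one axis; correlation undefined")
    r = float(stats.pearsonr(ma, mlr).statistic)
    lo, hi = fisher_ci(r, n)
    slope, intercept = np.polyfit(ma, mlr, 1)
    return CorrelationResult(
        r=r,
        ci_low=lo,
        ci_high=hi,
        p_value=correlation_p_value(r, n),
        slope=float(slope),
        intercept=float(intercept),
        n=n,
    )


def sensitivity_summary(
    pairs: list[PhenomenonPair],
    naive_fits: list[RandomEffectsResults],
    sensitivity_results: list[SensitivityResult],
    phat_results: list[ProportionResult | None],
) -> SensitivitySummary:
    """Aggregate the worst-case analysis across phenomena.

    All four inputs are aligned by position (one entry per phenomenon;
    ``phat_results`` entries may be None when the metric was not
    computed).
    """
    if not len(pairs) == len(naive_fits) == len(sensitivity_results) == len(
        phat_results
    ):
        raise ValueError("inputs must be aligned by phenomenon")

    included: list[int] = []
    for i, (pair, fit, sens) in enumerate(zip(pairs, naive_fits, sensitivity_results)):
        if sens.estimable and fit.mu > pair.mlr_estimate:
            included.append(i)

    phat_all = [p.phat for p in phat_results if p is not None]
    median_all = float(np.median(phat_all)) if phat_all else None

    if not included:
        return SensitivitySummary(
            n_analyzed=0,
            mean_naive=None,
            mean_worst_case=None,
            mean_ratio=None,
            ratio_of_means=None,
            mean_abs_diff=None,
            prop_worst_exceeds_mlr=None,
            prop_worst_exceeds_null=None,
            median_phat=median_all,
            median_phat_included=None,
        )

    naive = np.array([naive_fits[i].mu for i in included])
    worst = np.array([sensitivity_results[i].worst_case_mu for i in included])
    mlr = np.array([pairs[i].mlr_estimate for i in included])
    phat_inc = [
        phat_results[i].phat for i in included if phat_results[i] is not None
    ]

    mean_naive = float(naive.mean())
    mean_worst = float(worst.mean())
    return SensitivitySummary(
        n_analyzed=len(included),
        mean_naive=mean_naive,
        mean_worst_case=mean_worst,
        mean_ratio=float(np.mean(worst / naive)),
        ratio_of_means=float(mean_worst / mean_naive) if mean_naive != 0 else None,
        mean_abs_diff=float(np.mean(np.abs(naive - worst))),
        prop_worst_exceeds_mlr=float(np.mean(worst > mlr)),
        prop_worst_exceeds_null=float(np.mean(worst > 0)),
        median_phat=median_all,
        median_phat_included=float(np.median(phat_inc)) if phat_inc else None,
    )


@dataclass
class ComparisonReport:
    """Full deterministic output of :func:`run_full_comparison`."""

    per_phenomenon: pd.DataFrame
    correlation: CorrelationResult | None
    summary: SensitivitySummary
    config: AnalysisConfig
    corrected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                f = float(obj)
                return None if not np.isfinite(f) else f
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        payload = {
            "config": clean(asdict(self.config)),
            "correlation": clean(asdict(self.correlation))
            if self.correlation is not None
            else None,
            "summary": clean(asdict(self.summary)),
            "per_phenomenon": clean(
                self.per_phenomenon.to_dict(orient="records")
            ),
            "corrected": clean(self.corrected.to_dict(orient="records")),
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            "Meta-analysis vs. MLR comparison",
            "=" * 44,
            f"phenomena                 {len(self.per_phenomenon)}",
        ]
        if self.correlation is not None:
            c = self.correlation
            lines += [
                f"Pearson r (MA vs MLR)     {c.r:.2f} "
                f"[{c.ci_low:.2f}, {c.ci_high:.2f}], p = {c.p_value:.3f}",
                f"OLS: MLR = {c.intercept:.2f} + {c.slope:.2f} * MA",
            ]
        lines.append(f"included in worst-case    {s.n_analyzed}")
        if s.n_analyzed:
            lines += [
                f"mean naive estimate       d = {s.mean_naive:.2f}",
                f"mean worst-case estimate  d = {s.mean_worst_case:.2f}",
                f"mean worst/naive ratio    {100 * s.mean_ratio:.0f}%",
                f"mean |naive - worst|      d = {s.mean_abs_diff:.2f}",
                f"worst-case > MLR          {100 * s.prop_worst_exceeds_mlr:.0f}%",
                f"worst-case > 0            {100 * s.prop_worst_exceeds_null:.0f}%",
            ]
        if s.median_phat is not None:
            lines.append(
                f"median % effects <= MLR   {100 * s.median_phat:.0f}%"
            )
        return "\n".join(lines)


def _child_seed(seed: int, index: int) -> int:
    """Stable per-phenomenon bootstrap seed below 2^31."""
    return int((seed * 100_003 + 7919 * (index + 1)) % (2**31 - 1))


def run_full_comparison(
    pairs: list[PhenomenonPair],
    config: AnalysisConfig | None = None,
    compute_phat_ci: bool = True,
) -> ComparisonReport:
    """Run the whole pipeline on a suite of phenomenon pairs.

    Per phenomenon: naive random-effects fit, affirmative counts,
    calibrated proportion at/below the MLR estimate (with BCa CI unless
    ``compute_phat_ci`` is False), worst-case estimate, optional
    eta-corrected estimates, and the inclusion flag for the summary
    filter.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = AnalysisConfig()
    order = np.argsort([p.phenomenon_id for p in pairs], kind="stable")
    pairs = [pairs[i] for i in order]

    fits: list[RandomEffectsResults] = []
    sens: list[SensitivityResult] = []
    phats: list[ProportionResult | None] = []
    rows = []
    corrected_rows = []
    for i, pair in enumerate(pairs):
        try:
            fit = RandomEffectsMeta(pair.meta).fit(
                tau2_method=config.tau2_method,
                interval_method=config.interval_method,
            )
            cls = classify_studies(pair.meta, alpha=config.alpha)
            wc = worst_case_estimate(
                pair.meta, tau2_method=config.tau2_method, alpha=config.alpha
            )
            if pair.meta.k >= 2:
                pr = bca_ci_for_proportion(
                    pair.meta,
                    q=pair.mlr_estimate,
                    n_boot=config.n_boot,
                    seed=_child_seed(config.seed, i),
                    tau2_method=config.tau2_method,
                ) if compute_phat_ci else ProportionResult(
                    phat=fit.calibrate().prop_below(pair.mlr_estimate),
                    ci_low=None,
                    ci_high=None,
                    ci_estimable=False,
                    threshold=pair.mlr_estimate,
                    n_boot=0,
                    seed=-1,
                )
            else:
                pr = None
            for eta in config.eta_list:
                ce = corrected_estimate(
                    pair.meta,
                    eta=eta,
                    tau2_method=config.tau2_method,
                    alpha=config.alpha,
                )
                corrected_rows.append(
                    {
                        "phenomenon_id": pair.phenomenon_id,
                        "eta": eta,
                        "corrected_mu": ce.corrected_mu,
                    }
                )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for phenomenon {pair.phenomenon_id!r}: {exc}"
            ) from exc

        fits.append(fit)
        sens.append(wc)
        phats.append(pr)
        rows.append(
            {
                "phenomenon_id": pair.phenomenon_id,
                "k": pair.meta.k,
                "naive_mu": fit.mu,
                "naive_ci_low": fit.ci_low,
                "naive_ci_high": fit.ci_high,
                "tau2": fit.tau2,
                "mlr_estimate": pair.mlr_estimate,
                "n_affirmative": cls.n_affirmative,
                "n_nonaffirmative": cls.n_nonaffirmative,
                "phat": None if pr is None else pr.phat,
                "phat_ci_low": None if pr is None else pr.ci_low,
                "phat_ci_high": None if pr is None else pr.ci_high,
                "phat_ci_estimable": False if pr is None else pr.ci_estimable,
                "worst_case_mu": wc.worst_case_mu,
                "worst_case_estimable": wc.estimable,
                "included": bool(wc.estimable and fit.mu > pair.mlr_estimate),
            }
        )

    correlation = None
    if len(pairs) >= 3:
        ma = np.array([f.mu for f in fits])
        mlr = np.array([p.mlr_estimate for p in pairs])
        if ma.var() > 0 and mlr.var() > 0:
            correlation = correlate_estimates(pairs, fits)

    summary = sensitivity_summary(pairs, fits, sens, phats)
    return ComparisonReport(
        per_phenomenon=pd.DataFrame(rows),
        correlation=correlation,
        summary=summary,
        config=config,
        corrected=pd.DataFrame(corrected_rows),
    )
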