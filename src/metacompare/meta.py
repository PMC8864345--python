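"""Random-effects meta-analysis engine.

The model is the standard normal–normal hierarchy: study ``i`` measures a
population effect ``theta_i ~ N(mu, tau2)`` with known sampling variance
``v_i``, so ``y_i ~ N(mu, v_i + tau2)``.  The pooled mean uses
inverse-variance weights ``w_i* = 1/(v_i + tau2_hat)``.

Heterogeneity ``tau2`` can be estimated by DerSimonian–Laird (DL, closed
form), Paule–Mandel (PM, moment estimating equation solved by bracketed
root-finding) or restricted maximum likelihood (REML, bounded
maximization).  Confidence intervals for the pooled mean are either plain
Wald-z or Hartung–Knapp–Sidik–Jonkman (HKSJ: rescaled variance with a
t(k-1) critical value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import MetaDataset

__all__ = [
    "RandomEffectsMeta",
    "RandomEffectsResults",
    "cochran_q",
    "estimate_tau2",
    "fit_random_effects",
    "TAU2_METHODS",
    "INTERVAL_METHODS",
]

TAU2_METHODS = ("PM", "DL", "REML")
INTERVAL_METHODS = ("wald_z", "hksj")

#: upper bracket for tau2 root-finding / maximization (SMD^2 units); far
#: above any plausible between-study variance on the d scale
_TAU2_MAX = 100.0
_PM_TOL = 1e-8


def _check_arrays(y: np.ndarray, v: np.ndarray) -> None:
    if y.size == 0:
        raise ValueError("empty dataset")
    if np.any(v <= 0):
        raise ValueError("all variances must be > 0")


def cochran_q(dataset: MetaDataset) -> float:
    """Cochran's Q statistic, the weighted dispersion around the
    fixed-effect mean: ``Q = sum w_i (y_i - ybar_w)^2`` with ``w_i = 1/v_i``.
    """
    y, v = dataset.estimates, dataset.variances
    _check_arrays(y, v)
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    k = y.size
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - (k - 1)) / c))


def _gen_q(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Generalized Q at candidate tau2 (Paule–Mandel estimating function)."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu) ** 2))


def _tau2_pm(y: np.ndarray, v: np.ndarray) -> float:
    k = y.size
    target = k - 1
    if _gen_q(0.0, y, v) <= target:
        return 0.0
    f = lambda t: _gen_q(t, y, v) - target
    hi = _TAU2_MAX
    # _gen_q is decreasing in tau2; widen the bracket in the (pathological)
    # case it has not crossed the target at the default upper bound
    n_widen = 0
    while f(hi) > 0:
        hi *= 10.0
        n_widen += 1
        if n_widen > 6:
            raise RuntimeError(
                "Paule-Mandel estimating equation did not bracket a root "
                f"(gen Q at tau2={hi:g} still exceeds k-1={target})"
            )
    return float(optimize.brentq(f, 0.0, hi, xtol=_PM_TOL))


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Negative restricted log-likelihood (constants dropped)."""
    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    mu = np.sum(w * y) / sw
    return float(
        0.5 * np.sum(np.log(v + tau2))
        + 0.5 * np.log(sw)
        + 0.5 * np.sum(w * (y - mu) ** 2)
    )


def _tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        _reml_nll,
        bounds=(0.0, _TAU2_MAX),
        args=(y, v),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML optimization failed: {res.message}")
    tau2 = float(res.x)
    # bounded Brent never evaluates the boundary exactly; snap to 0 when the
    # likelihood is monotone decreasing in tau2
    if _reml_nll(0.0, y, v) <= res.fun:
        tau2 = 0.0
    return tau2


def estimate_tau2(dataset: MetaDataset, method: str = "PM") -> float:
    """Between-study variance estimate ``tau2_hat >= 0``.

    With a single study heterogeneity is unidentified; returns 0 with a
    warning.
    """
    if method not in TAU2_METHODS:
        raise ValueError(f"unknown tau2 method {method!r}; choose from {TAU2_METHODS}")
    y, v = dataset.estimates, dataset.variances
    _check_arrays(y, v)
    if y.size < 2:
        warnings.warn(
            "tau2 is not identified with k < 2 studies; returning 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    if method == "DL":
        return _tau2_dl(y, v)
    if method == "PM":
        return _tau2_pm(y, v)
    return _tau2_reml(y, v)


@dataclass(frozen=True)
class RandomEffectsResults:
    """Fitted random-effects summary (the pooled estimate and diagnostics).

    Attributes
    ----------
    mu : float
        Pooled mean effect (SMD).
    tau2 : float
        Between-study variance estimate (SMD^2).
    se_mu : float
        Standard error of ``mu`` (HKSJ-rescaled if requested).
    ci_low, ci_high : float
        95% confidence bounds for ``mu``.
    k : int
        Number of studies.
    q_stat : float
        Cochran's Q heterogeneity statistic.
    """

    mu: float
    tau2: float
    se_mu: float
    ci_low: float
    ci_high: float
    k: int
    q_stat: float
    tau2_method: str
    interval_method: str
    low_k: bool = False
    dataset: MetaDataset | None = field(default=None, repr=False, compare=False)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def conf_int(self) -> tuple[float, float]:
        return self.ci

    # -- downstream analyses hang off the results object ------------------
    def calibrate(self):
        """Shrunken ("calibrated") study-level population-effect estimates."""
        from .calibrate import calibrate_estimates

        self._require_dataset()
        return calibrate_estimates(self.dataset, self)

    def classify(self, alpha: float = 0.05):
        from .pubbias import classify_studies

        self._require_dataset()
        return classify_studies(self.dataset, alpha=alpha)

    def _require_dataset(self) -> None:
        if self.dataset is None:
            raise ValueError("results were built without a dataset reference")

    def summary(self) -> str:
        lines = [
            "Random-effects meta-analysis",
            "=" * 44,
            f"phenomenon      {self.dataset.phenomenon_id if self.dataset else '-'}",
            f"k studies       {self.k}",
            f"pooled mu (d)   {self.mu: .4f}",
            f"se(mu)          {self.se_mu: .4f}",
            f"95% CI          [{self.ci_low: .4f}, {self.ci_high: .4f}]"
            f"  ({self.interval_method})",
            f"tau2            {self.tau2: .4f}  ({self.tau2_method})",
            f"Cochran Q       {self.q_stat: .4f}",
        ]
        if self.low_k:
            lines.append("note: single-study passthrough fit")
        return "\n".join(lines)


class RandomEffectsMeta:
    """Random-effects meta-analysis model for one phenomenon.

    Parameters
    ----------
    dataset : MetaDataset
        Study-level estimates and variances (SMD scale).

    Examples
    --------
    >>> from metacompare import MetaDataset, RandomEffectsMeta
    >>> d = MetaDataset.from_arrays([0.2, 0.4], [0.01, 0.01])
    >>> res = RandomEffectsMeta(d).fit(tau2_method="DL")
    >>> round(res.mu, 3)
    0.3
    """

    def __init__(self, dataset: MetaDataset):
        self.dataset = dataset

    @classmethod
    def from_arrays(cls, estimates, variances, labels=None, phenomenon_id=""):
        return cls(
            MetaDataset.from_arrays(estimates, variances, labels, phenomenon_id)
        )

    @classmethod
    def from_dataframe(
        cls,
        df,
        estimate_col: str = "estimate",
        variance_col: str = "variance",
        label_col: str | None = "study_label",
        phenomenon_id: str = "",
    ):
        labels = df[label_col] if label_col and label_col in df else None
        return cls.from_arrays(
            df[estimate_col].to_numpy(),
            df[variance_col].to_numpy(),
            labels=None if labels is None else list(labels.astype(str)),
            phenomenon_id=phenomenon_id,
        )

    def fit(
        self,
        tau2_method: str = "PM",
        interval_method: str = "wald_z",
        tau2: float | None = None,
    ) -> RandomEffectsResults:
        """Fit the model.

        Parameters
        ----------
        tau2_method : {"PM", "DL", "REML"}
            Heterogeneity estimator (ignored when ``tau2`` is given).
        interval_method : {"wald_z", "hksj"}
            95% CI construction for the pooled mean.
        tau2 : float, optional
            Fix the between-study variance instead of estimating it.
        """
        if interval_method not in INTERVAL_METHODS:
            raise ValueError(
                f"unknown interval method {interval_method!r}; "
                f"choose from {INTERVAL_METHODS}"
            )
        ds = self.dataset
        y, v = ds.estimates, ds.variances
        _check_arrays(y, v)
        k = y.size

        if k == 1:
            mu, se = float(y[0]), float(np.sqrt(v[0]))
            z = stats.norm.ppf(0.975)
            return RandomEffectsResults(
                mu=mu,
                tau2=0.0,
                se_mu=se,
                ci_low=mu - z * se,
                ci_high=mu + z * se,
                k=1,
                q_stat=0.0,
                tau2_method=tau2_method,
                interval_method="wald_z",
                low_k=True,
                dataset=ds,
            )

        if tau2 is None:
            tau2 = estimate_tau2(ds, method=tau2_method)
        elif tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        w = 1.0 / (v + tau2)
        sw = np.sum(w)
        mu = float(np.sum(w * y) / sw)
        se = float(1.0 / np.sqrt(sw))

        if interval_method == "hksj":
            # Knapp-Hartung: rescale the variance by the weighted residual
            # mean square and use a t(k-1) critical value
            q_gen = np.sum(w * (y - mu) ** 2)
            se = float(np.sqrt(q_gen / ((k - 1) * sw)))
            crit = stats.t.ppf(0.975, k - 1)
        else:
            crit = stats.norm.ppf(0.975)

        return RandomEffectsResults(
            mu=mu,
            tau2=float(tau2),
            se_mu=se,
            ci_low=mu - crit * se,
            ci_high=mu + crit * se,
            k=k,
            q_stat=cochran_q(ds),
            tau2_method=tau2_method,
            interval_method=interval_method,
            dataset=ds,
        )


def fit_random_effects(
    dataset: MetaDataset,
    tau2_method: str = "PM",
    interval_method: str = "wald_z",
    tau2: float | None = None,
) -> RandomEffectsResults:
    """Functional wrapper around :class:`RandomEffectsMeta`."""
    return RandomEffectsMeta(dataset).fit(
        tau2_method=tau2_method, interval_method=interval_method, tau2=tau2
    )
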