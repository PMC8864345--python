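"""Publication-bias sensitivity analysis under a significance-based
selection model.

The assumed selection process: statistically significant studies in the
expected (positive) direction — "affirmative" studies — are eta >= 1 times
more likely to be published than "non-affirmative" studies (non-significant
or negative), with no further selection on the size of the point estimate.
Under that model a bias-corrected pooled estimate up-weights each published
non-affirmative study by eta, exactly counteracting the selection.  The
worst case (eta -> infinity) is an ordinary meta-analysis of the
non-affirmative studies alone; it needs no estimate of the actual severity
of selection and is therefore a bound, not a correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MetaDataset
from .meta import RandomEffectsMeta, RandomEffectsResults, estimate_tau2

__all__ = [
    "StudyClassification",
    "SensitivityResult",
    "classify_studies",
    "corrected_estimate",
    "worst_case_estimate",
]


@dataclass(frozen=True)
class StudyClassification:
    """Affirmative / non-affirmative split of one dataset.

    A study is affirmative iff its two-sided p-value (normal reference,
    z = y/sqrt(v)) is below ``alpha`` AND the estimate is positive.
    """

    affirmative: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "affirmative", np.asarray(self.affirmative, dtype=bool)
        )

    @property
    def n_affirmative(self) -> int:
        return int(np.sum(self.affirmative))

    @property
    def n_nonaffirmative(self) -> int:
        return int(np.sum(~self.affirmative))


@dataclass(frozen=True)
class SensitivityResult:
    """Selection-corrected and worst-case pooled estimates.

    ``eta`` is the selection ratio (``inf`` for the worst case);
    ``estimable`` is False when the dataset has no non-affirmative study,
    in which case ``worst_case_mu`` is None.
    """

    eta: float
    corrected_mu: float | None
    worst_case_mu: float | None
    n_affirmative: int
    n_nonaffirmative: int
    estimable: bool
    tau2: float | None = None
    worst_case_fit: RandomEffectsResults | None = None


def classify_studies(dataset: MetaDataset, alpha: float = 0.05) -> StudyClassification:
    """Split studies into affirmative (significant positive) vs. the rest."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y, v = dataset.estimates, dataset.variances
    z_crit = stats.norm.ppf(1 - alpha / 2)
    z = y / np.sqrt(v)
    return StudyClassification(affirmative=(z > z_crit), alpha=alpha)


def corrected_estimate(
    dataset: MetaDataset,
    eta: float,
    tau2_method: str = "PM",
    alpha: float = 0.05,
) -> SensitivityResult:
    """Pooled estimate corrected for a known selection ratio ``eta``.

    tau2 is estimated once on the full published dataset; the correction
    then multiplies each non-affirmative study's inverse-variance weight
    ``1/(v_i + tau2)`` by eta.  ``eta = 1`` reproduces the naive
    random-effects mean exactly.
    """
    if not np.isfinite(eta) or eta < 1:
        raise ValueError("eta must be finite and >= 1")
    cls = classify_studies(dataset, alpha=alpha)
    y, v = dataset.estimates, dataset.variances
    if len(dataset) >= 2:
        tau2 = estimate_tau2(dataset, method=tau2_method)
    else:
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    w = np.where(cls.affirmative, w, eta * w)
    mu = float(np.sum(w * y) / np.sum(w))
    return SensitivityResult(
        eta=float(eta),
        corrected_mu=mu,
        worst_case_mu=None,
        n_affirmative=cls.n_affirmative,
        n_nonaffirmative=cls.n_nonaffirmative,
        estimable=True,
        tau2=float(tau2),
    )


def worst_case_estimate(
    dataset: MetaDataset,
    tau2_method: str = "PM",
    alpha: float = 0.05,
    interval_method: str = "wald_z",
) -> SensitivityResult:
    """Worst-case pooled estimate: meta-analyse only the non-affirmative
    studies (the eta -> infinity limit of the correction).

    Not estimable (no exception) when every study is affirmative; with a
    single non-affirmative study the fit is the passthrough.
    """
    cls = classify_studies(dataset, alpha=alpha)
    if cls.n_nonaffirmative == 0:
        return SensitivityResult(
            eta=np.inf,
            corrected_mu=None,
            worst_case_mu=None,
            n_affirmative=cls.n_affirmative,
            n_nonaffirmative=0,
            estimable=False,
        )
    subset = dataset.subset(~cls.affirmative)
    fit = RandomEffectsMeta(subset).fit(
        tau2_method=tau2_method, interval_method=interval_method
    )
    return SensitivityResult(
        eta=np.inf,
        corrected_mu=None,
        worst_case_mu=fit.mu,
        n_affirmative=cls.n_affirmative,
        n_nonaffirmative=cls.n_nonaffirmative,
        estimable=True,
        tau2=fit.tau2,
        worst_case_fit=fit,
    )
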