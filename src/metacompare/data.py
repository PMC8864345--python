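"""Core containers for study-level effect data.

Everything downstream works on the standardized-mean-difference (SMD,
Cohen's d) scale: each study contributes a point estimate ``y_i`` and its
sampling variance ``v_i``.  A :class:`MetaDataset` is one meta-analysis
(one phenomenon); a :class:`PhenomenonPair` couples that dataset with the
single high-precision summary estimate from the corresponding
multi-laboratory replication (MLR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["StudyRecord", "MetaDataset", "PhenomenonPair"]


@dataclass(frozen=True)
class StudyRecord:
    """One study's effect estimate on the SMD scale.

    Parameters
    ----------
    estimate : float
        Point estimate (Cohen's d), sign-harmonized so the hypothesized
        direction is positive.
    variance : float
        Sampling variance of the estimate (SMD^2 units); must be > 0.
    label : str
        Free-text study identifier, unique within a dataset.
    """

    estimate: float
    variance: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate):
            raise ValueError(f"study {self.label!r}: estimate must be finite")
        if not (np.isfinite(self.variance) and self.variance > 0):
            raise ValueError(
                f"study {self.label!r}: variance must be finite and > 0, "
                f"got {self.variance!r}"
            )

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of studies forming one meta-analysis."""

    studies: tuple[StudyRecord, ...]
    phenomenon_id: str = ""
    #: True when all estimates have been sign-harmonized so that the
    #: hypothesized direction of the effect is positive.
    direction_harmonized: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) == 0:
            raise ValueError("a MetaDataset needs at least one study")
        labels = [s.label for s in self.studies if s.label]
        if len(labels) != len(set(labels)):
            raise ValueError(
                f"duplicate study labels in phenomenon {self.phenomenon_id!r}"
            )

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([s.estimate for s in self.studies], dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return np.array([s.variance for s in self.studies], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.studies]

    @classmethod
    def from_arrays(
        cls,
        estimates: Sequence[float],
        variances: Sequence[float],
        labels: Iterable[str] | None = None,
        phenomenon_id: str = "",
    ) -> "MetaDataset":
        y = np.asarray(estimates, dtype=float)
        v = np.asarray(variances, dtype=float)
        if y.shape != v.shape or y.ndim != 1:
            raise ValueError("estimates and variances must be 1-D and aligned")
        if labels is None:
            labels = [f"study_{i + 1}" for i in range(len(y))]
        studies = tuple(
            StudyRecord(float(yi), float(vi), str(lab))
            for yi, vi, lab in zip(y, v, labels, strict=True)
        )
        return cls(studies=studies, phenomenon_id=phenomenon_id)

    def subset(self, mask: Sequence[bool]) -> "MetaDataset":
        """A new dataset keeping the studies where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.k,):
            raise ValueError("mask length must equal the number of studies")
        kept = tuple(s for s, m in zip(self.studies, mask) if m)
        if not kept:
            raise ValueError("subset would be empty")
        return MetaDataset(studies=kept, phenomenon_id=self.phenomenon_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phenomenon_id": self.phenomenon_id,
                "study_label": self.labels,
                "estimate": self.estimates,
                "variance": self.variances,
            }
        )


@dataclass(frozen=True)
class PhenomenonPair:
    """One phenomenon: its meta-analysis plus the MLR summary estimate."""

    meta: MetaDataset
    mlr_estimate: float
    mlr_variance: float
    phenomenon_id: str = ""
    #: optional simulation ground truth (mu_true, tau2_true, eta, ...) kept
    #: for recovery tests; empty for real data
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mlr_variance) and self.mlr_variance > 0):
            raise ValueError("mlr_variance must be finite and > 0")
        if not np.isfinite(self.mlr_estimate):
            raise ValueError("mlr_estimate must be finite")
        if not self.phenomenon_id:
            object.__setattr__(self, "phenomenon_id", self.meta.phenomenon_id)
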