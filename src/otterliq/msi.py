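"""Microsatellite instability calling from per-locus repeat metrics.

Each microsatellite locus is summarized by three metrics (normalized
percent lower, mean lower, mean log-likelihood) computed upstream from
reads spanning the repeat. A k-nearest-neighbor vote (k = 100) against a
labeled reference panel gives the probability that the locus is unstable:
features are standardized by the reference center/spread, distances are
Euclidean in the standardized 3-space, and the probability is the
fraction of unstable labels among the k nearest reference loci. A sample
is MSI-high when strictly more than 50% of its loci are unstable
(per-locus probability strictly above 0.5); otherwise it is
microsatellite stable (MSS).

The read-level computation of the three metrics is out of scope here;
features are inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "MsiLocusFeatures",
    "MsiReference",
    "MsiCall",
    "MsiClassifier",
    "locus_probability",
    "call_sample",
]

FEATURE_NAMES = ("percent_lower_norm", "mean_lower", "mean_loglik")


@dataclass(frozen=True)
class MsiLocusFeatures:
    """The three per-locus instability metrics."""

    locus_id: str
    percent_lower_norm: float
    mean_lower: float
    mean_loglik: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite for {self.locus_id!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


class MsiReference:
    """Labeled reference panel with its feature-scaling parameters.

    Scaling (per-feature center and spread) is computed from the pooled
    reference at construction and applied to both reference and query
    points before distance computation. Features with zero spread fall
    back to a unit scale.
    """

    def __init__(
        self,
        records: Sequence[tuple[MsiLocusFeatures, str]],
        center: np.ndarray | None = None,
        spread: np.ndarray | None = None,
    ):
        if not records:
            raise ValidationError("reference must be non-empty")
        labels = [label for _, label in records]
        bad = set(labels) - {"stable", "unstable"}
        if bad:
            raise ValidationError(f"unknown labels {sorted(bad)}")
        if len(set(labels)) < 2:
            raise ValidationError("reference must contain both stable and unstable loci")
        self.features = np.stack([f.as_array() for f, _ in records])
        self.unstable = np.array([label == "unstable" for label in labels])
        self.locus_ids = [f.locus_id for f, _ in records]
        if center is None:
            center = self.features.mean(axis=0)
        if spread is None:
            spread = self.features.std(axis=0)
        spread = np.where(np.asarray(spread) > 0, spread, 1.0)
        self.center = np.asarray(center, dtype=float)
        self.spread = np.asarray(spread, dtype=float)
        self._scaled = (self.features - self.center) / self.spread

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def unstable_fraction(self) -> float:
        return float(self.unstable.mean())

    def standardize(self, features: MsiLocusFeatures) -> np.ndarray:
        return (features.as_array() - self.center) / self.spread


def locus_probability(
    features: MsiLocusFeatures, reference: MsiReference, k: int = 100
) -> float:
    """KNN probability that a locus is unstable.

    The fraction of unstable labels among the k reference loci nearest in
    standardized Euclidean distance. Distance ties at the k-th rank are
    broken by reference insertion order (stable sort).
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if len(reference) < k:
        raise ConfigurationError(
            f"reference has {len(reference)} loci, fewer than k = {k}"
        )
    q = reference.standardize(features)
    d2 = ((reference._scaled - q) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    return float(reference.unstable[order[:k]].mean())


@dataclass(frozen=True)
class MsiCall:
    """Sample-level MSI status with its per-locus evidence."""

    per_locus_probabilities: Mapping[str, float]
    fraction_unstable: float
    status: str  # "MSI-high" | "MSS"


def call_sample(
    per_locus: Mapping[str, float],
    locus_threshold: float = 0.5,
    sample_threshold: float = 0.5,
) -> MsiCall:
    """Aggregate per-locus probabilities into a sample call.

    A locus is unstable iff its probability is strictly above
    ``locus_threshold``; the sample is MSI-high iff the unstable fraction
    is strictly above ``sample_threshold`` (exactly half unstable is MSS).
    """
    if not per_locus:
        raise ValidationError("cannot call a sample with no loci")
    unstable = sum(p > locus_threshold for p in per_locus.values())
    fraction = unstable / len(per_locus)
    return MsiCall(
        per_locus_probabilities=dict(per_locus),
        fraction_unstable=fraction,
        status="MSI-high" if fraction > sample_threshold else "MSS",
    )


class MsiClassifier:
    """Model-style wrapper: a reference panel plus k, applied to samples."""

    def __init__(self, reference: MsiReference, k: int = 100):
        if len(reference) < k:
            raise ConfigurationError(
                f"reference has {len(reference)} loci, fewer than k = {k}"
            )
        self.reference = reference
        self.k = k

    def predict_proba(self, loci: Iterable[MsiLocusFeatures]) -> dict[str, float]:
        return {
            f.locus_id: locus_probability(f, self.reference, self.k) for f in loci
        }

    def call(
        self,
        loci: Iterable[MsiLocusFeatures],
        locus_threshold: float = 0.5,
        sample_threshold: float = 0.5,
    ) -> MsiCall:
        return call_sample(self.predict_proba(loci), locus_threshold, sample_threshold)
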