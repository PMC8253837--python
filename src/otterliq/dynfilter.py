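"""Dynamic Bayesian variant-filtering threshold.

The filter converts a clinical prior into a per-variant evidence bar. From
fixed post-test odds (how confident a reported variant must be), historical
pre-test odds (how often a variant in this gene/cancer cohort is real) and
the assay sensitivity, the required specificity follows from Bayes'
theorem:

    specificity = 1 - pre_test_odds * sensitivity / post_test_odds

That specificity is then pushed through a beta-binomial model of the
background alt-allele error at the locus to obtain the minimum alternate
read count that keeps the false-call rate at or below 1 - specificity for
a given depth. Higher pre-test odds (well-known hotspot genes) lower the
bar; noisier contexts (larger error rate or overdispersion) raise it.

The beta-binomial null is parameterized by its mean error rate ``e`` and
overdispersion ``rho`` (alpha = e (1 - rho) / rho, beta =
(1 - e)(1 - rho) / rho); rho = 0 degenerates to Binomial(depth, e).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .datatypes import VariantRecord
from .exceptions import ConfigurationError, InfeasibleModelError, ValidationError

__all__ = [
    "FilterModel",
    "required_specificity",
    "min_alt_reads",
    "apply_filter",
]


@dataclass(frozen=True)
class FilterModel:
    """Parameters of the dynamic filtering threshold.

    Parameters
    ----------
    post_test_probability
        Target probability that a called variant is real; post-test odds
        are p / (1 - p).
    pre_test_odds
        Default historical odds that a variant here is real. May be None
        when every gene is covered by a per-gene odds map.
    sensitivity
        Assay sensitivity at the relevant limit of detection, in (0, 1].
    error_rate
        Mean background alt-allele fraction of the null error model.
    overdispersion
        Beta-binomial rho in [0, 1); 0 gives a pure binomial null.
    context_error_rates
        Optional map of sequence context (e.g. trinucleotide) to a
        (error_rate, overdispersion) pair overriding the global values.
    """

    post_test_probability: float
    pre_test_odds: float | None
    sensitivity: float
    error_rate: float
    overdispersion: float = 0.0
    context_error_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.post_test_probability < 1.0:
            raise ValidationError(
                f"post_test_probability must be in (0, 1), got {self.post_test_probability}"
            )
        if self.pre_test_odds is not None and self.pre_test_odds <= 0:
            raise ValidationError(
                f"pre_test_odds must be positive, got {self.pre_test_odds}"
            )
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValidationError(
                f"sensitivity must be in (0, 1], got {self.sensitivity}"
            )
        if not 0.0 < self.error_rate < 1.0:
            raise ValidationError(
                f"error_rate must be in (0, 1), got {self.error_rate}"
            )
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValidationError(
                f"overdispersion must be in [0, 1), got {self.overdispersion}"
            )

    @property
    def post_test_odds(self) -> float:
        p = self.post_test_probability
        return p / (1.0 - p)

    def rates_for(self, context: str | None = None) -> tuple[float, float]:
        """(error_rate, overdispersion) for a sequence context, or the global pair."""
        if context is not None and context in self.context_error_rates:
            return self.context_error_rates[context]
        return self.error_rate, self.overdispersion


def required_specificity(
    model: FilterModel, pre_test_odds: float | None = None
) -> float:
    """Specificity implied by the pre/post-test odds and sensitivity.

    ``pre_test_odds`` overrides the model default (per-gene/per-exon odds).
    Raises :class:`InfeasibleModelError` when the implied specificity falls
    outside (0, 1) — the prior is then too strong for any threshold to
    reach the target post-test odds.
    """
    odds = model.pre_test_odds if pre_test_odds is None else pre_test_odds
    if odds is None:
        raise ConfigurationError("no pre-test odds supplied and model has no default")
    if odds <= 0:
        raise ValidationError(f"pre_test_odds must be positive, got {odds}")
    spec = 1.0 - odds * model.sensitivity / model.post_test_odds
    if not 0.0 < spec < 1.0:
        raise InfeasibleModelError(
            f"specificity {spec:.6g} outside (0, 1): pre_test_odds * sensitivity "
            f"/ post_test_odds = {odds * model.sensitivity / model.post_test_odds:.6g}"
        )
    return spec


def _null_distribution(depth: int, error_rate: float, overdispersion: float):
    if overdispersion <= 0.0:
        return stats.binom(depth, error_rate)
    a = error_rate * (1.0 - overdispersion) / overdispersion
    b = (1.0 - error_rate) * (1.0 - overdispersion) / overdispersion
    return stats.betabinom(depth, a, b)


def min_alt_reads(
    depth: int,
    error_rate: float,
    overdispersion: float,
    specificity: float,
) -> int:
    """Minimum alternate-read count to call a variant at ``depth``.

    The smallest integer k with P(X >= k) <= 1 - specificity under the
    null error model. Returns ``depth + 1`` when no count up to the full
    depth is sufficient (the locus is uncallable at this depth).
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if specificity <= 0.0:
        return 0
    dist = _null_distribution(depth, error_rate, overdispersion)
    alpha = 1.0 - specificity

    def tail(k: int) -> float:
        # P(X >= k); non-increasing in k, and 0 beyond the support
        return 0.0 if k > depth else float(dist.sf(k - 1))

    # binary search for the smallest k with tail(k) <= alpha
    lo, hi = 0, depth + 1  # tail(depth + 1) = 0 <= alpha always holds
    while lo < hi:
        mid = (lo + hi) // 2
        if tail(mid) <= alpha:
            hi = mid
        else:
            lo = mid + 1
    return lo


def apply_filter(
    variants: Iterable[VariantRecord],
    model: FilterModel,
    per_gene_pre_odds: Mapping[str, float] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition variants into (passed, failed) by the dynamic threshold.

    A variant passes iff its alt-read count reaches the minimum count for
    its depth, computed at the specificity implied by its gene's pre-test
    odds (``per_gene_pre_odds``, falling back to the model default). A
    gene missing from the map with no model default is a configuration
    error.
    """
    passed: list[VariantRecord] = []
    failed: list[VariantRecord] = []
    spec_cache: dict[float, float] = {}
    threshold_cache: dict[tuple[int, float], int] = {}
    for v in variants:
        if per_gene_pre_odds is not None and v.gene in per_gene_pre_odds:
            odds = per_gene_pre_odds[v.gene]
        elif model.pre_test_odds is not None:
            odds = model.pre_test_odds
        else:
            raise ConfigurationError(
                f"gene {v.gene!r} absent from pre-test odds map and model has no default"
            )
        if odds not in spec_cache:
            spec_cache[odds] = required_specificity(model, odds)
        spec = spec_cache[odds]
        key = (v.depth, spec)
        if key not in threshold_cache:
            threshold_cache[key] = min_alt_reads(
                v.depth, model.error_rate, model.overdispersion, spec
            )
        (passed if v.alt_reads >= threshold_cache[key] else failed).append(v)
    return passed, failed
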