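"""Consistency between detected variant allele fractions and the ctFE.

A somatic variant in a diploid region can be detected at a VAF at or below
the circulating tumor fraction of the sample, so a VAF below the ctFE is
*consistent*; a VAF within a tolerance band of the ctFE (the larger of
20% of the ctFE and an absolute 0.02) is *within tolerance*; a VAF above
the ctFE outside the band is *inconsistent*. Germline variants and
variants in amplified regions are excluded before comparison, since both
break the VAF-below-purity expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from statistics import median
from typing import Iterable, Sequence

from .datatypes import VariantRecord
from .exceptions import ValidationError

__all__ = [
    "ConsistencyLabel",
    "ConsistencyCall",
    "CohortSummary",
    "eligible_vafs",
    "classify",
    "summarize",
    "summarize_variants",
]


class ConsistencyLabel(str, Enum):
    CONSISTENT = "consistent"
    WITHIN_TOLERANCE = "within_tolerance"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class ConsistencyCall:
    label: ConsistencyLabel
    vaf_used: float
    ctfe: float


def eligible_vafs(variants: Iterable[VariantRecord]) -> list[float]:
    """VAFs of variants that are neither germline nor in an amplified region."""
    return [
        v.vaf
        for v in variants
        if not v.is_germline and not v.in_amplified_region
    ]


def classify(
    vaf: float,
    ctfe: float,
    rel_tol: float = 0.20,
    abs_tol: float = 0.02,
) -> ConsistencyCall:
    """Classify one (VAF, ctFE) pair.

    The tolerance band is two-sided and is the more permissive of
    ``rel_tol * ctfe`` and ``abs_tol``; it takes precedence over the
    below/above split, so ``vaf == ctfe`` is always within tolerance.
    """
    for name, x in (("vaf", vaf), ("ctfe", ctfe)):
        if not 0.0 <= x <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {x}")
    band = max(rel_tol * ctfe, abs_tol)
    if abs(vaf - ctfe) <= band:
        label = ConsistencyLabel.WITHIN_TOLERANCE
    elif vaf < ctfe:
        label = ConsistencyLabel.CONSISTENT
    else:
        label = ConsistencyLabel.INCONSISTENT
    return ConsistencyCall(label=label, vaf_used=vaf, ctfe=ctfe)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level concordance fractions, computed separately for the
    maximal and the median VAF of each sample.

    ``*_concordant`` is the fraction of samples labeled consistent or
    within tolerance; ``*_le_ctfe`` is the fraction with VAF <= ctFE.
    """

    n_samples: int
    max_vaf_concordant: float
    median_vaf_concordant: float
    max_vaf_le_ctfe: float
    median_vaf_le_ctfe: float


def summarize(
    samples: Sequence[tuple[float, float, float]],
    rel_tol: float = 0.20,
    abs_tol: float = 0.02,
) -> CohortSummary:
    """Summarize a cohort of (max_vaf, median_vaf, ctfe) triples."""
    if len(samples) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(samples)
    ok = (ConsistencyLabel.CONSISTENT, ConsistencyLabel.WITHIN_TOLERANCE)
    max_conc = med_conc = max_le = med_le = 0
    for max_vaf, med_vaf, ctfe in samples:
        max_conc += classify(max_vaf, ctfe, rel_tol, abs_tol).label in ok
        med_conc += classify(med_vaf, ctfe, rel_tol, abs_tol).label in ok
        max_le += max_vaf <= ctfe
        med_le += med_vaf <= ctfe
    return CohortSummary(
        n_samples=n,
        max_vaf_concordant=max_conc / n,
        median_vaf_concordant=med_conc / n,
        max_vaf_le_ctfe=max_le / n,
        median_vaf_le_ctfe=med_le / n,
    )


def summarize_variants(
    variants: Iterable[VariantRecord],
    ctfe: float,
    rel_tol: float = 0.20,
    abs_tol: float = 0.02,
) -> tuple[list[ConsistencyCall], ConsistencyCall | None, ConsistencyCall | None]:
    """Per-variant calls plus the max-VAF and median-VAF sample-level calls.

    Returns (per_variant_calls, max_vaf_call, median_vaf_call); the sample
    level calls are None when no variant survives the eligibility filter.
    """
    vafs = eligible_vafs(variants)
    calls = [classify(v, ctfe, rel_tol, abs_tol) for v in vafs]
    if not vafs:
        return calls, None, None
    return (
        calls,
        classify(max(vafs), ctfe, rel_tol, abs_tol),
        classify(median(vafs), ctfe, rel_tol, abs_tol),
    )
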