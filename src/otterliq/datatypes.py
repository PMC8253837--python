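"""Core domain types: genomic intervals, copy-ratio segments, variants.

Coordinates are 0-based half-open (BED convention) throughout. Segmented
copy-ratio data arrives from an upstream binning/segmentation tool (CNVkit
``.cns`` tables); one :class:`CopyRatioSegment` corresponds to one CBS
segment with its log2 copy ratio and the number of coverage bins it spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

from .exceptions import ValidationError

__all__ = [
    "GenomicInterval",
    "CopyRatioSegment",
    "SegmentSet",
    "VariantClassification",
    "VariantRecord",
]

#: Allowed discrepancy between a stated VAF and alt_reads/depth.
VAF_CONSISTENCY_TOL = 0.01


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``contig``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValidationError("contig must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CopyRatioSegment:
    """One segmented copy-ratio observation.

    Parameters
    ----------
    interval
        Genomic span of the segment.
    log2_ratio
        log2(normalized sample coverage / normalized pool coverage).
    n_bins
        Number of coverage bins the segmenter merged into this segment;
        used as the weight of the segment in the tumor-fraction loss.
    weight
        Optional upstream segment weight. Carried through I/O but not used
        by the estimator, whose weighting is defined in terms of bins only.
    extras
        Unrecognized columns from the source table, preserved verbatim on
        write and ignored by all computation.
    """

    interval: GenomicInterval
    log2_ratio: float
    n_bins: int
    weight: float | None = None
    extras: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_ratio):
            raise ValidationError(f"log2_ratio must be finite, got {self.log2_ratio}")
        if self.n_bins < 1:
            raise ValidationError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.weight is not None and self.weight < 0:
            raise ValidationError(f"weight must be non-negative, got {self.weight}")

    @property
    def contig(self) -> str:
        return self.interval.contig


class SegmentSet(Sequence[CopyRatioSegment]):
    """An ordered collection of copy-ratio segments for one sample."""

    def __init__(
        self, segments: Sequence[CopyRatioSegment], sample_id: str = "sample"
    ):
        self._segments: tuple[CopyRatioSegment, ...] = tuple(segments)
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self._segments)

    def __getitem__(self, i):  # type: ignore[override]
        if isinstance(i, slice):
            return SegmentSet(self._segments[i], self.sample_id)
        return self._segments[i]

    def __iter__(self) -> Iterator[CopyRatioSegment]:
        return iter(self._segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return (
            self._segments == other._segments and self.sample_id == other.sample_id
        )

    def __repr__(self) -> str:
        return f"SegmentSet(n={len(self)}, sample_id={self.sample_id!r})"

    @property
    def segments(self) -> tuple[CopyRatioSegment, ...]:
        return self._segments


class VariantClassification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    OTHER = "other"


@dataclass(frozen=True)
class VariantRecord:
    """A called small variant with its allele-fraction evidence.

    ``vaf`` may be omitted, in which case it is computed as
    ``alt_reads / depth``. When both are supplied they must agree to within
    0.01 — the stated VAF is then kept as-is (it may come from a caller
    that counts reads slightly differently).
    """

    gene: str
    interval: GenomicInterval
    ref: str
    alt: str
    alt_reads: int
    depth: int
    vaf: float | None = None
    is_germline: bool = False
    in_amplified_region: bool = False
    classification: VariantClassification = VariantClassification.OTHER

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if self.alt_reads < 0:
            raise ValidationError(f"alt_reads must be >= 0, got {self.alt_reads}")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if self.vaf is None:
            object.__setattr__(self, "vaf", self.alt_reads / self.depth)
        else:
            if not 0.0 <= self.vaf <= 1.0:
                raise ValidationError(f"vaf must be in [0, 1], got {self.vaf}")
            if abs(self.vaf - self.alt_reads / self.depth) > VAF_CONSISTENCY_TOL:
                raise ValidationError(
                    f"vaf {self.vaf} inconsistent with "
                    f"alt_reads/depth = {self.alt_reads}/{self.depth}"
                )
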