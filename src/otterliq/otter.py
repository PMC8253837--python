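"""Off-Target Tumor Estimation Routine (OTTER).

Estimates the circulating tumor fraction of a plasma sample from segmented
copy-ratio data alone. Given CBS segments with log2 copy ratios CR_i and
bin counts l_i, the routine evaluates, over a grid of candidate tumor
fractions t and a small set of integer copy states c, the expected log2
copy ratio of a segment at state c in a sample of purity t,

    E(t, c) = log2( (2 (1 - t) + t c) / 2 ),

assigns each segment to its nearest state, and accumulates the bin-weighted
squared error into a loss curve over t. The estimate is the grid argmin.

The model assumes a diploid normal background (copy state 2 has expected
ratio exactly 0 at every purity) and clonal, integer copy states in the
tumor. Aliasing between (t, c=3) and (t/2, c=4) is inherent to the model;
ties are broken toward the smaller tumor fraction and flagged.

The canonical entry points are :class:`OtterModel` / :class:`OtterResults`;
the module-level functions expose each stage for testing and reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datatypes import CopyRatioSegment, SegmentSet
from .exceptions import ValidationError

__all__ = [
    "TumorFractionGrid",
    "CopyStateSet",
    "ExpectationMatrix",
    "OtterResults",
    "OtterFit",
    "OtterModel",
    "DEFAULT_MIN_BINS",
    "DEFAULT_EXCLUDED_CONTIGS",
    "DEFAULT_FLOOR",
    "filter_segments",
    "expected_log2_ratio",
    "build_expectation_matrix",
    "segment_assignment",
    "total_loss",
    "estimate_tumor_fraction",
]

DEFAULT_MIN_BINS = 100
#: Contigs excluded by default: sex chromosomes (historically difficult to
#: sequence / copy number confounded by patient sex) plus mitochondria.
DEFAULT_EXCLUDED_CONTIGS = frozenset({"X", "Y", "M", "MT"})
DEFAULT_FLOOR = -8.0
#: Loss-curve range below which the curve is reported as flat.
DEFAULT_FLAT_TOL = 1e-9
#: Relative/absolute tolerance for detecting argmin ties on the loss curve.
_TIE_TOL = 1e-12


def _normalize_contig(contig: str) -> str:
    c = contig.lower()
    if c.startswith("chr"):
        c = c[3:]
    if c == "m":
        c = "mt"
    return c


@dataclass(frozen=True)
class TumorFractionGrid:
    """Strictly increasing candidate tumor fractions in (0, 1)."""

    values: np.ndarray

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValidationError("tumor-fraction grid must be non-empty")
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValidationError("grid values must lie strictly in (0, 1)")
        if np.any(np.diff(arr) <= 0):
            raise ValidationError("grid values must be strictly increasing")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def default(cls) -> "TumorFractionGrid":
        # 1% to 99% in 1% increments; divide integers to keep values exact.
        return cls(np.arange(1, 100) / 100.0)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "TumorFractionGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TumorFractionGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class CopyStateSet:
    """Ordered distinct integer copy states; must bracket the diploid state 2."""

    values: np.ndarray

    def __init__(self, values: Iterable[int]):
        arr = np.asarray(sorted(set(int(v) for v in values)), dtype=int)
        if arr.size == 0 or np.any(arr < 0):
            raise ValidationError("copy states must be non-negative integers")
        if 2 not in arr:
            raise ValidationError("copy-state set must include the diploid state 2")
        if arr.size < 2:
            raise ValidationError("copy-state set must include a state other than 2")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def default(cls) -> "CopyStateSet":
        return cls(range(5))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyStateSet):
            return NotImplemented
        return np.array_equal(self.values, other.values)


def filter_segments(
    s: SegmentSet,
    min_bins: int = DEFAULT_MIN_BINS,
    excluded_contigs: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS,
) -> tuple[SegmentSet, int]:
    """Drop short segments and segments on excluded contigs.

    A segment is removed when it has fewer than ``min_bins`` bins or lies
    on an excluded contig. Contig matching is alias-aware ("X" matches
    "chrX", "M" matches "chrMT"). Returns the retained set (order
    preserved) and the number of segments removed.
    """
    if min_bins < 1:
        raise ValidationError(f"min_bins must be >= 1, got {min_bins}")
    excluded = {_normalize_contig(c) for c in excluded_contigs}
    kept = [
        seg
        for seg in s
        if seg.n_bins >= min_bins and _normalize_contig(seg.contig) not in excluded
    ]
    return SegmentSet(kept, s.sample_id), len(s) - len(kept)


def expected_log2_ratio(t: float, c: int, floor: float = DEFAULT_FLOOR) -> float:
    """Expected log2 copy ratio of a segment at copy state ``c`` and purity ``t``.

    Computed as ``log2(1 + t (c - 2) / 2)``, which equals
    ``log2((2 (1 - t) + t c) / 2)`` but is exactly zero for c = 2 in
    floating point. Arguments at or below ``2**floor`` are clipped to
    ``floor`` so a fully deleted state at high purity stays finite.
    """
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"tumor fraction must be in [0, 1], got {t}")
    if c < 0:
        raise ValidationError(f"copy state must be >= 0, got {c}")
    arg = 1.0 + t * (c - 2) / 2.0
    if arg <= 2.0**floor:
        return float(floor)
    # np.log2 rather than math.log2 so scalar and vectorized evaluations
    # of the same (t, c) agree bitwise
    return float(np.log2(arg))


def _expectation_entries(
    tvals: np.ndarray, cvals: np.ndarray, floor: float
) -> np.ndarray:
    arg = 1.0 + np.multiply.outer(tvals, (cvals - 2) / 2.0)
    lo = 2.0**floor
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arg <= lo, floor, np.log2(np.maximum(arg, lo)))
    return out


@dataclass(frozen=True)
class ExpectationMatrix:
    """|T| x |C| grid of expected log2 copy ratios E[t, c]."""

    entries: np.ndarray
    grid: TumorFractionGrid
    states: CopyStateSet
    floor: float

    def row(self, t_index: int) -> np.ndarray:
        return self.entries[t_index]


def build_expectation_matrix(
    grid: TumorFractionGrid | None = None,
    states: CopyStateSet | None = None,
    floor: float = DEFAULT_FLOOR,
) -> ExpectationMatrix:
    """Evaluate the expectation model at every (t, c) grid point."""
    grid = grid or TumorFractionGrid.default()
    states = states or CopyStateSet.default()
    entries = _expectation_entries(grid.values, states.values, floor)
    entries.flags.writeable = False
    return ExpectationMatrix(entries=entries, grid=grid, states=states, floor=floor)


def segment_assignment(
    segment: CopyRatioSegment,
    t: float,
    E_row: Sequence[float],
    states: CopyStateSet | None = None,
) -> tuple[int, float]:
    """Nearest copy state for one segment at purity ``t``, and its weighted error.

    ``E_row`` holds the expected ratios for each state in ascending state
    order; ties resolve to the smaller copy state. The error is the minimal
    squared distance multiplied by the segment's bin count.
    """
    states = states or CopyStateSet.default()
    row = np.asarray(E_row, dtype=float)
    if row.shape != (len(states),):
        raise ValidationError(
            f"expected {len(states)} state expectations, got {row.shape}"
        )
    d = (segment.log2_ratio - row) ** 2
    idx = int(np.argmin(d))  # argmin takes the first minimum: smallest state
    return int(states.values[idx]), float(d[idx] * segment.n_bins)


def total_loss(
    s: SegmentSet,
    t: float,
    E_row: Sequence[float],
    states: CopyStateSet | None = None,
) -> float:
    """Sum of per-segment weighted errors at purity ``t`` (0 for an empty set)."""
    return float(sum(segment_assignment(seg, t, E_row, states)[1] for seg in s))


@dataclass
class OtterResults:
    """Fitted tumor-fraction estimate with its full loss curve and diagnostics.

    Attributes
    ----------
    tumor_fraction
        The grid argmin of the loss curve.
    loss_curve
        Bin-weighted squared-error loss at every grid value, aligned with
        ``grid.values``.
    state_assignments
        Per retained segment, the copy state minimizing the squared
        distance at the estimated tumor fraction.
    n_segments_used, n_segments_filtered
        Segment counts after/removed-by filtering.
    qc_flags
        Subset of {"flat_loss", "no_segments", "tie_broken"}.
    """

    tumor_fraction: float
    loss_curve: np.ndarray
    state_assignments: np.ndarray
    n_segments_used: int
    n_segments_filtered: int
    qc_flags: frozenset[str]
    grid: TumorFractionGrid
    states: CopyStateSet
    model: "OtterModel | None" = field(default=None, repr=False, compare=False)

    @property
    def min_loss(self) -> float:
        return float(self.loss_curve.min())

    def summary(self) -> str:
        lines = [
            "OTTER tumor fraction fit",
            "=" * 40,
            f"{'tumor fraction (ctFE)':30s} {self.tumor_fraction:.4f}",
            f"{'loss at estimate':30s} {self.min_loss:.6g}",
            f"{'segments used':30s} {self.n_segments_used}",
            f"{'segments filtered':30s} {self.n_segments_filtered}",
            f"{'grid':30s} [{self.grid.values[0]:.2f}, "
            f"{self.grid.values[-1]:.2f}] n={len(self.grid)}",
            f"{'copy states':30s} {list(map(int, self.states.values))}",
            f"{'qc flags':30s} {sorted(self.qc_flags) or 'none'}",
        ]
        return "\n".join(lines)

    def plot_loss_curve(self, ax=None):
        """Plot the loss curve over the tumor-fraction grid (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid.values, self.loss_curve, lw=1.5)
        ax.axvline(self.tumor_fraction, color="crimson", ls="--", lw=1)
        ax.set_xlabel("tumor fraction t")
        ax.set_ylabel("loss")
        ax.set_title(f"OTTER loss curve (t̂ = {self.tumor_fraction:.2f})")
        return ax


#: Spec-facing alias: a completed fit.
OtterFit = OtterResults


def estimate_tumor_fraction(
    s: SegmentSet,
    grid: TumorFractionGrid | None = None,
    states: CopyStateSet | None = None,
    floor: float = DEFAULT_FLOOR,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> OtterResults:
    """Grid minimization of the bin-weighted squared-error loss.

    ``s`` must already be filtered. Degenerate inputs are flagged, never
    raised: an empty set yields flag ``no_segments`` with the estimate
    pinned at the smallest grid value; a loss curve whose range is below
    ``flat_tol`` yields ``flat_loss``; argmin ties yield ``tie_broken``
    with the smallest tied tumor fraction reported.
    """
    grid = grid or TumorFractionGrid.default()
    states = states or CopyStateSet.default()
    E = build_expectation_matrix(grid, states, floor)
    flags: set[str] = set()

    if len(s) == 0:
        flags.update({"no_segments", "flat_loss"})
        return OtterResults(
            tumor_fraction=float(grid.values[0]),
            loss_curve=np.zeros(len(grid)),
            state_assignments=np.empty(0, dtype=int),
            n_segments_used=0,
            n_segments_filtered=0,
            qc_flags=frozenset(flags),
            grid=grid,
            states=states,
        )

    cr = np.array([seg.log2_ratio for seg in s])
    bins = np.array([seg.n_bins for seg in s])
    # (n_segments, |T|, |C|) squared distances; min over states, weight, sum.
    d = (cr[:, None, None] - E.entries[None, :, :]) ** 2
    min_d = d.min(axis=2)
    loss = (min_d * bins[:, None]).sum(axis=0)

    i_hat = int(np.argmin(loss))  # first minimum: smallest tied t
    ties = np.isclose(loss, loss[i_hat], rtol=_TIE_TOL, atol=_TIE_TOL)
    if int(ties.sum()) > 1:
        flags.add("tie_broken")
    if float(loss.max() - loss.min()) < flat_tol:
        flags.add("flat_loss")

    assignments = states.values[np.argmin(d[:, i_hat, :], axis=1)]
    return OtterResults(
        tumor_fraction=float(grid.values[i_hat]),
        loss_curve=loss,
        state_assignments=assignments,
        n_segments_used=len(s),
        n_segments_filtered=0,
        qc_flags=frozenset(flags),
        grid=grid,
        states=states,
    )


class OtterModel:
    """Tumor-fraction model over a set of copy-ratio segments.

    Holds the data and the fit configuration; :meth:`fit` runs segment
    filtering followed by the grid minimization and returns an
    :class:`OtterResults`.

    Parameters
    ----------
    segments
        Unfiltered segments for one sample.
    grid, states
        Candidate tumor fractions and copy states; default to the 1–99%
        grid in 1% steps and states {0, 1, 2, 3, 4}.
    floor
        Floor for expected log2 ratios whose argument underflows.
    min_bins
        Segments with fewer bins are discarded before fitting.
    excluded_contigs
        Contigs whose segments are discarded (alias-aware matching).
    """

    def __init__(
        self,
        segments: SegmentSet,
        *,
        grid: TumorFractionGrid | None = None,
        states: CopyStateSet | None = None,
        floor: float = DEFAULT_FLOOR,
        min_bins: int = DEFAULT_MIN_BINS,
        excluded_contigs: Iterable[str] = DEFAULT_EXCLUDED_CONTIGS,
        flat_tol: float = DEFAULT_FLAT_TOL,
    ):
        self.segments = segments
        self.grid = grid or TumorFractionGrid.default()
        self.states = states or CopyStateSet.default()
        self.floor = floor
        self.min_bins = min_bins
        self.excluded_contigs = frozenset(excluded_contigs)
        self.flat_tol = flat_tol

    @classmethod
    def from_cns(cls, path, **kwargs) -> "OtterModel":
        """Build the model straight from a CNVkit-style ``.cns`` table."""
        from .io import read_segments

        return cls(read_segments(path), **kwargs)

    def fit(self) -> OtterResults:
        used, n_filtered = filter_segments(
            self.segments, self.min_bins, self.excluded_contigs
        )
        results = estimate_tumor_fraction(
            used, self.grid, self.states, self.floor, self.flat_tol
        )
        results.n_segments_filtered = n_filtered
        results.model = self
        return results
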