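"""Synthetic data with known ground truth for every toolkit stage.

The generators invert the analysis models: copy-ratio segments are drawn
from the tumor-fraction expectation model plus Gaussian noise on the log2
scale; variant read counts are binomial at a true VAF (true somatic
variants) or beta-binomial at the background error rate (null sites);
MSI references are two Gaussian clouds in the 3-D feature space at a
controlled separation. Every generator takes an explicit seed and owns
its generator — identical inputs give bitwise-identical outputs.

Noise is segment-level on the log2 scale, not read-level: the estimator
consumes nothing below the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import (
    CopyRatioSegment,
    GenomicInterval,
    SegmentSet,
    VariantRecord,
)
from .exceptions import ValidationError
from .msi import MsiLocusFeatures, MsiReference
from .otter import DEFAULT_FLOOR, expected_log2_ratio

__all__ = [
    "TruthRecord",
    "simulate_segments",
    "simulate_variants",
    "simulate_msi_reference",
    "simulate_msi_loci",
]

_BIN_SIZE = 10_000  # nominal bases per coverage bin for synthetic intervals


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated copy-number profile.

    ``cn_profile`` lists (copy_state, n_bins, contig) per segment;
    ``noise_sd`` is the Gaussian sd on the log2 scale.
    """

    tumor_fraction_true: float
    cn_profile: tuple[tuple[int, int, str], ...]
    noise_sd: float
    seed: int
    floor: float = DEFAULT_FLOOR

    def __init__(
        self,
        tumor_fraction_true: float,
        cn_profile: Sequence[tuple[int, int, str]],
        noise_sd: float = 0.0,
        seed: int = 0,
        floor: float = DEFAULT_FLOOR,
    ):
        if not 0.0 <= tumor_fraction_true <= 1.0:
            raise ValidationError(
                f"tumor fraction must be in [0, 1], got {tumor_fraction_true}"
            )
        if noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
        if not cn_profile:
            raise ValidationError("cn_profile must be non-empty")
        object.__setattr__(self, "tumor_fraction_true", float(tumor_fraction_true))
        object.__setattr__(
            self, "cn_profile", tuple((int(c), int(n), str(ctg)) for c, n, ctg in cn_profile)
        )
        object.__setattr__(self, "noise_sd", float(noise_sd))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "floor", float(floor))


def simulate_segments(
    truth: TruthRecord, sample_id: str = "synthetic"
) -> tuple[SegmentSet, TruthRecord]:
    """Draw one segment per profile entry from the expectation model.

    log2_ratio = E(t_true, c) + Normal(0, noise_sd); intervals are laid
    out contiguously per contig at a nominal bin size.
    """
    rng = np.random.default_rng(truth.seed)
    offsets: dict[str, int] = {}
    segments = []
    for c, n_bins, contig in truth.cn_profile:
        mu = expected_log2_ratio(truth.tumor_fraction_true, c, truth.floor)
        noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        start = offsets.get(contig, 0)
        end = start + n_bins * _BIN_SIZE
        offsets[contig] = end
        segments.append(
            CopyRatioSegment(
                interval=GenomicInterval(contig, start, end),
                log2_ratio=float(mu + noise),
                n_bins=n_bins,
                extras={"true_state": c},
            )
        )
    return SegmentSet(segments, sample_id), truth


def simulate_variants(
    n: int,
    depth_model: tuple[float, float] = (2000.0, 20.0),
    vaf_true: float = 0.05,
    error_rate: float = 1e-3,
    rho: float = 0.0,
    n_null: int = 0,
    seed: int = 0,
) -> list[VariantRecord]:
    """Simulate true somatic variants followed by null background sites.

    The first ``n`` records are true variants with alt reads ~
    Binomial(depth, vaf_true) (genes VAR1..); the remaining ``n_null`` are
    background sites with alt reads ~ BetaBinomial(depth, e, rho) (genes
    NULL1..; binomial when rho = 0). Depths are drawn from a negative
    binomial with the given (mean, dispersion); flags default to false.
    """
    if not 0.0 <= vaf_true <= 1.0:
        raise ValidationError(f"vaf_true must be in [0, 1], got {vaf_true}")
    if not 0.0 <= rho < 1.0:
        raise ValidationError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    mean_depth, dispersion = depth_model

    def draw_depth() -> int:
        p = dispersion / (dispersion + mean_depth)
        return max(1, int(rng.negative_binomial(dispersion, p)))

    records = []
    pos = 0
    for i in range(n):
        depth = draw_depth()
        alt = int(rng.binomial(depth, vaf_true))
        pos += 1000
        records.append(
            VariantRecord(
                gene=f"VAR{i + 1}",
                interval=GenomicInterval("chr1", pos, pos + 1),
                ref="A",
                alt="T",
                alt_reads=alt,
                depth=depth,
            )
        )
    for i in range(n_null):
        depth = draw_depth()
        if rho > 0:
            a = error_rate * (1.0 - rho) / rho
            b = (1.0 - error_rate) * (1.0 - rho) / rho
            p = rng.beta(a, b)
        else:
            p = error_rate
        alt = int(rng.binomial(depth, p))
        pos += 1000
        records.append(
            VariantRecord(
                gene=f"NULL{i + 1}",
                interval=GenomicInterval("chr2", pos, pos + 1),
                ref="C",
                alt="G",
                alt_reads=alt,
                depth=depth,
            )
        )
    return records


def _msi_clouds(
    n_stable: int, n_unstable: int, separation: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # separation is a per-feature offset in within-class SD units, so the
    # class centers sit sqrt(3) * separation apart in Euclidean distance
    stable = rng.normal(0.0, 1.0, size=(n_stable, 3))
    unstable = rng.normal(0.0, 1.0, size=(n_unstable, 3)) + separation
    return stable, unstable


def simulate_msi_reference(
    n_per_class: int, separation: float = 6.0, seed: int = 0
) -> MsiReference:
    """Two 3-D unit-variance Gaussian clouds offset by ``separation``
    within-class SDs on every feature; scaling parameters come from the
    pooled sample."""
    rng = np.random.default_rng(seed)
    stable, unstable = _msi_clouds(n_per_class, n_per_class, separation, rng)
    records = []
    for i, x in enumerate(stable):
        records.append(
            (MsiLocusFeatures(f"S{i + 1}", x[0], x[1], x[2]), "stable")
        )
    for i, x in enumerate(unstable):
        records.append(
            (MsiLocusFeatures(f"U{i + 1}", x[0], x[1], x[2]), "unstable")
        )
    return MsiReference(records)


def simulate_msi_loci(
    n: int, separation: float = 6.0, unstable_fraction: float = 0.5, seed: int = 0
) -> tuple[list[MsiLocusFeatures], list[str]]:
    """Held-out query loci from the same two-cloud model; returns
    (features, true_labels)."""
    rng = np.random.default_rng(seed)
    labels = ["unstable" if rng.random() < unstable_fraction else "stable" for _ in range(n)]
    feats = []
    for i, label in enumerate(labels):
        x = rng.normal(0.0, 1.0, size=3)
        if label == "unstable":
            x = x + separation
        feats.append(MsiLocusFeatures(f"Q{i + 1}", x[0], x[1], x[2]))
    return feats, labels
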