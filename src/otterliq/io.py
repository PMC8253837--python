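"""Readers and writers for the tabular formats the toolkit touches.

Segments arrive as CNVkit-style ``.cns`` tables (tab-separated, columns
``chromosome  start  end  gene  log2  depth  probes  weight``; gene, depth
and weight optional). Variants arrive either as a reference TSV dialect or
as VCF (via cyvcf2, imported lazily). MSI features are a simple TSV. All
coordinates are treated as 0-based half-open.

Unknown extra columns on segment tables are preserved on write and
ignored by computation. Parsing is locale-independent (decimal points
only).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CopyRatioSegment,
    GenomicInterval,
    SegmentSet,
    VariantClassification,
    VariantRecord,
)
from .exceptions import FormatError, ParseError, ValidationError
from .msi import MsiLocusFeatures, MsiReference
from .otter import OtterResults, TumorFractionGrid, CopyStateSet

__all__ = [
    "read_segments",
    "write_segments",
    "read_variants",
    "write_fit_report",
    "read_fit_report",
    "read_msi_features",
    "read_msi_reference",
    "write_msi_features",
]

_CNS_REQUIRED = ("chromosome", "start", "end", "log2")
_CNS_KNOWN = ("chromosome", "start", "end", "gene", "log2", "depth", "probes", "weight")
_VARIANT_TSV_COLUMNS = (
    "gene",
    "contig",
    "pos",
    "ref",
    "alt",
    "vaf",
    "alt_reads",
    "depth",
    "is_germline",
    "in_amplified_region",
)

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


def _parse_bool(value: object, column: str, line: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ParseError(f"cannot interpret {value!r} as boolean in column {column}", line)


def read_segments(path: str | Path, dialect: str = "cns") -> SegmentSet:
    """Read a CNVkit-style ``.cns`` table into a :class:`SegmentSet`.

    The ``probes`` column (synonym ``bins``) supplies the per-segment bin
    count; it is mandatory because the estimator weights segments by it.
    Rows with missing or non-numeric log2 or bin count are rejected with
    the offending line number.
    """
    if dialect != "cns":
        raise FormatError(f"unknown segment dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _CNS_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "probes" in df.columns:
        bins_col = "probes"
    elif "bins" in df.columns:
        bins_col = "bins"
    else:
        raise FormatError(f"{path}: missing required column 'probes' (or 'bins')")

    extra_cols = [c for c in df.columns if c not in _CNS_KNOWN and c != bins_col]
    segments = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based, after the header
        try:
            log2 = float(row["log2"])
        except ValueError:
            raise ParseError(f"non-numeric log2 value {row['log2']!r}", line) from None
        if not np.isfinite(log2):
            raise ParseError(f"non-finite log2 value {row['log2']!r}", line)
        try:
            n_bins = int(row[bins_col])
        except ValueError:
            raise ParseError(
                f"non-integer bin count {row[bins_col]!r}", line
            ) from None
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise ParseError(
                f"non-integer coordinates {row['start']!r}..{row['end']!r}", line
            ) from None
        weight = None
        if "weight" in df.columns and str(row["weight"]).strip() != "":
            try:
                weight = float(row["weight"])
            except ValueError:
                raise ParseError(f"non-numeric weight {row['weight']!r}", line) from None
        extras = {c: row[c] for c in extra_cols}
        if "gene" in df.columns:
            extras["gene"] = row["gene"]
        try:
            segments.append(
                CopyRatioSegment(
                    interval=GenomicInterval(str(row["chromosome"]), start, end),
                    log2_ratio=log2,
                    n_bins=n_bins,
                    weight=weight,
                    extras=extras,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), line) from None
    return SegmentSet(segments, sample_id=path.stem)


def write_segments(s: SegmentSet, path: str | Path) -> None:
    """Write a :class:`SegmentSet` back to the ``.cns`` dialect.

    Inverse of :func:`read_segments` on valid tables; extra columns
    captured at read time are emitted verbatim.
    """
    path = Path(path)
    extra_cols: list[str] = []
    for seg in s:
        for c in seg.extras:
            if c != "gene" and c not in extra_cols:
                extra_cols.append(c)
    has_gene = any("gene" in seg.extras for seg in s)
    has_weight = any(seg.weight is not None for seg in s)
    cols = ["chromosome", "start", "end"]
    if has_gene:
        cols.append("gene")
    cols += ["log2", "probes"]
    if has_weight:
        cols.append("weight")
    cols += extra_cols
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for seg in s:
            row: list[object] = [seg.interval.contig, seg.interval.start, seg.interval.end]
            if has_gene:
                row.append(seg.extras.get("gene", ""))
            row += [repr(float(seg.log2_ratio)), seg.n_bins]
            if has_weight:
                row.append("" if seg.weight is None else repr(float(seg.weight)))
            row += [seg.extras.get(c, "") for c in extra_cols]
            writer.writerow(row)


def _variants_from_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in _VARIANT_TSV_COLUMNS if c not in ("vaf",)]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            pos = int(row["pos"])
            alt_reads = int(row["alt_reads"])
            depth = int(row["depth"])
        except ValueError as exc:
            raise ParseError(f"non-integer field: {exc}", line) from None
        vaf = None
        if "vaf" in df.columns and str(row["vaf"]).strip() not in ("", "NA", "nan"):
            try:
                vaf = float(row["vaf"])
            except ValueError:
                raise ParseError(f"non-numeric vaf {row['vaf']!r}", line) from None
        classification = VariantClassification.OTHER
        if "classification" in df.columns and str(row["classification"]).strip():
            try:
                classification = VariantClassification(row["classification"].strip())
            except ValueError:
                raise ParseError(
                    f"unknown classification {row['classification']!r}", line
                ) from None
        try:
            records.append(
                VariantRecord(
                    gene=str(row["gene"]),
                    interval=GenomicInterval(
                        str(row["contig"]), pos, pos + max(1, len(row["ref"]))
                    ),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    alt_reads=alt_reads,
                    depth=depth,
                    vaf=vaf,
                    is_germline=_parse_bool(row["is_germline"], "is_germline", line),
                    in_amplified_region=_parse_bool(
                        row["in_amplified_region"], "in_amplified_region", line
                    ),
                    classification=classification,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from None
    return records


def _variants_from_vcf(path: Path) -> list[VariantRecord]:
    # cyvcf2 is optional; the TSV dialect has no VCF dependency.
    from cyvcf2 import VCF

    records = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        depth = int(info.get("DP", 0))
        alt_reads = int(info.get("AO", 0))
        vaf = info.get("VAF")
        records.append(
            VariantRecord(
                gene=str(info.get("GENE", "")),
                interval=GenomicInterval(rec.CHROM, rec.start, rec.end),
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else "",
                alt_reads=alt_reads,
                depth=depth,
                vaf=float(vaf) if vaf is not None else None,
                is_germline="GERMLINE" in info,
                in_amplified_region="AMP_REGION" in info,
            )
        )
    return records


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variants from the reference TSV dialect or from VCF.

    TSV columns: gene, contig, pos, ref, alt, vaf, alt_reads, depth,
    is_germline, in_amplified_region (vaf optional — recomputed from the
    counts when absent). VCF carries VAF/GERMLINE/AMP_REGION/GENE/DP/AO
    in INFO.
    """
    path = Path(path)
    if dialect == "tsv":
        return _variants_from_tsv(path)
    if dialect == "vcf":
        return _variants_from_vcf(path)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def write_fit_report(
    fit: OtterResults, path: str | Path, header_extra: dict | None = None
) -> None:
    """Write a fit report: a JSON header line plus the loss-curve TSV.

    Floats are serialized with ``repr`` so the report round-trips
    bitwise: reading it back reproduces the estimate and the loss curve
    exactly as written.
    """
    if fit.loss_curve is None or len(fit.loss_curve) == 0:
        raise ValidationError("cannot write a report for an incomplete fit")
    header = {
        "tumor_fraction": fit.tumor_fraction,
        "n_segments_used": fit.n_segments_used,
        "n_segments_filtered": fit.n_segments_filtered,
        "qc_flags": sorted(fit.qc_flags),
        "states": [int(c) for c in fit.states.values],
    }
    if header_extra:
        header.update(header_extra)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("t\tloss\n")
        for t, loss in zip(fit.grid.values, fit.loss_curve):
            fh.write(f"{float(t)!r}\t{float(loss)!r}\n")


def read_fit_report(path: str | Path) -> OtterResults:
    """Read a fit report back into an :class:`OtterResults` (loss curve +
    header fields; per-segment assignments are not serialized)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise FormatError(f"{path}: missing report header line")
        header = json.loads(first[2:])
        body = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if list(body.columns) != ["t", "loss"]:
        raise FormatError(f"{path}: expected loss-curve columns (t, loss)")
    return OtterResults(
        tumor_fraction=float(header["tumor_fraction"]),
        loss_curve=body["loss"].to_numpy(),
        state_assignments=np.empty(0, dtype=int),
        n_segments_used=int(header["n_segments_used"]),
        n_segments_filtered=int(header["n_segments_filtered"]),
        qc_flags=frozenset(header.get("qc_flags", [])),
        grid=TumorFractionGrid(body["t"].to_numpy()),
        states=CopyStateSet(header.get("states", range(5))),
    )


_MSI_COLUMNS = ("locus_id", "percent_lower_norm", "mean_lower", "mean_loglik")


def read_msi_features(path: str | Path) -> list[MsiLocusFeatures]:
    """Read an MSI feature TSV (locus_id plus the three metrics)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in _MSI_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        MsiLocusFeatures(
            locus_id=str(row.locus_id),
            percent_lower_norm=float(row.percent_lower_norm),
            mean_lower=float(row.mean_lower),
            mean_loglik=float(row.mean_loglik),
        )
        for row in df.itertuples()
    ]


def read_msi_reference(path: str | Path) -> MsiReference:
    """Read a labeled MSI reference TSV (feature columns plus ``label``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in _MSI_COLUMNS + ("label",):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = [
        (
            MsiLocusFeatures(
                locus_id=str(row.locus_id),
                percent_lower_norm=float(row.percent_lower_norm),
                mean_lower=float(row.mean_lower),
                mean_loglik=float(row.mean_loglik),
            ),
            str(row.label),
        )
        for row in df.itertuples()
    ]
    return MsiReference(records)


def write_msi_features(
    loci: Sequence[MsiLocusFeatures],
    path: str | Path,
    labels: Iterable[str] | None = None,
) -> None:
    cols = list(_MSI_COLUMNS) + (["label"] if labels is not None else [])
    label_list = list(labels) if labels is not None else None
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for i, f in enumerate(loci):
            row: list[object] = [
                f.locus_id,
                repr(float(f.percent_lower_norm)),
                repr(float(f.mean_lower)),
                repr(float(f.mean_loglik)),
            ]
            if label_list is not None:
                row.append(label_list[i])
            writer.writerow(row)
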