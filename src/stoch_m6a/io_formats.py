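"""Readers and writers for the plain-text formats the pipeline touches.

One coordinate convention is used everywhere inside the package: 0-based,
half-open intervals, with coverage vectors stored 5'->3' in *transcript*
orientation (minus-strand tracks are reversed at load time so that all
downstream windowing is strand-agnostic). GFF3 input (1-based, closed) is
converted on read; BED output is natively 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

PILEUP_COLUMNS = ["transcript_id", "pos", "ref", "a_count", "g_count", "other_count"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True, order=True)
class TranscriptAnnotation:
    """A named, stranded genomic interval (by default a CDS).

    Coordinates are 0-based half-open on the genome; ``length`` is the
    transcript length in nucleotides.
    """

    transcript_id: str
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.transcript_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_transcript(self, genomic_pos: int) -> int:
        """Map a genomic position into transcript (5'->3') coordinates."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos


@dataclass
class CoverageTrack:
    """Per-base read depth for one transcript in one sample.

    ``depth`` is indexed in transcript orientation (position 0 is the 5' end
    of the transcript, regardless of genomic strand).
    """

    transcript_id: str
    sample_role: str  # "IP" or "input"
    replicate_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise ValueError(f"{self.transcript_id}: negative depth")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class GenomicIntervalRecord:
    """A BED6-style record (0-based, half-open)."""

    seqid: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

_ID_ATTRIBUTES = ("ID", "Name", "locus_tag", "gene_id")


def read_annotation(
    path: str | Path, feature_type: str = "CDS"
) -> dict[str, TranscriptAnnotation]:
    """Read a GFF3 file, keeping records of ``feature_type``.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Returns a mapping transcript_id -> annotation, ordered as in the file.

    Raises
    ------
    FormatError
        On a malformed line (the message names the line number) or a
        duplicate transcript id.
    """
    annotations: dict[str, TranscriptAnnotation] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated GFF3 fields")
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise FormatError(f"{path}:{lineno}: malformed GFF3 line ({exc})")
            if feature.featuretype != feature_type:
                continue
            tid = None
            for key in _ID_ATTRIBUTES:
                if key in feature.attributes:
                    tid = feature.attributes[key][0]
                    break
            if tid is None:
                raise FormatError(
                    f"{path}:{lineno}: feature has none of {_ID_ATTRIBUTES}"
                )
            if tid in annotations:
                raise FormatError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
            try:
                annotations[tid] = TranscriptAnnotation(
                    transcript_id=tid,
                    seqid=feature.seqid,
                    start=feature.start - 1,  # 1-based closed -> 0-based half-open
                    end=feature.end,
                    strand=feature.strand,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
    return annotations


def write_annotation(
    annotations: Mapping[str, TranscriptAnnotation],
    path: str | Path,
    feature_type: str = "CDS",
    source: str = "stoch_m6a",
) -> None:
    """Write annotations as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates: GFF3 1-based closed\n")
        for ann in annotations.values():
            fh.write(
                "\t".join(
                    [
                        ann.seqid,
                        source,
                        feature_type,
                        str(ann.start + 1),
                        str(ann.end),
                        ".",
                        ann.strand,
                        ".",
                        f"ID={ann.transcript_id}",
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | Path, to_rna: bool = True) -> dict[str, str]:
    """Read FASTA sequences; by default transliterate T->U (RNA alphabet)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if to_rna:
            seq = seq.replace("T", "U")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def _read_bedgraph_frame(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                seqid, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value")
            rows.append((seqid, start, end, value))
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "value"])


def read_coverage(
    path: str | Path,
    annotations: Mapping[str, TranscriptAnnotation],
    sample_role: str,
    replicate_id: str = "rep1",
    seqid_lengths: Mapping[str, int] | None = None,
) -> dict[str, CoverageTrack]:
    """Read a bedGraph into per-transcript depth vectors.

    Every annotated position receives exactly one depth value; positions
    absent from the bedGraph get depth 0. Minus-strand transcripts are
    reversed into transcript orientation.
    """
    frame = _read_bedgraph_frame(path)
    if seqid_lengths is not None:
        for seqid, group in frame.groupby("seqid"):
            if seqid in seqid_lengths and group["end"].max() > seqid_lengths[seqid]:
                raise FormatError(
                    f"{path}: interval extends past end of {seqid} "
                    f"({int(group['end'].max())} > {seqid_lengths[seqid]})"
                )
    by_seqid = {seqid: g for seqid, g in frame.groupby("seqid")}
    tracks: dict[str, CoverageTrack] = {}
    for tid, ann in annotations.items():
        depth = np.zeros(ann.length, dtype=float)
        group = by_seqid.get(ann.seqid)
        if group is not None:
            sel = group[(group["end"] > ann.start) & (group["start"] < ann.end)]
            for s, e, v in zip(sel["start"], sel["end"], sel["value"]):
                depth[max(s, ann.start) - ann.start : min(e, ann.end) - ann.start] = v
        if ann.strand == "-":
            depth = depth[::-1]
        tracks[tid] = CoverageTrack(tid, sample_role, replicate_id, depth)
    return tracks


def write_bedgraph(
    tracks: Mapping[str, CoverageTrack],
    annotations: Mapping[str, TranscriptAnnotation],
    path: str | Path,
) -> None:
    """Write transcript-oriented tracks back out as a genomic bedGraph.

    Assumes transcripts do not overlap on the genome (true for the
    synthetic layouts this package generates).
    """
    lines: list[tuple[str, int, int, float]] = []
    for tid, track in tracks.items():
        ann = annotations[tid]
        depth = track.depth if ann.strand == "+" else track.depth[::-1]
        # run-length encode
        pos = 0
        n = depth.size
        while pos < n:
            run_end = pos + 1
            while run_end < n and depth[run_end] == depth[pos]:
                run_end += 1
            if depth[pos] != 0:
                lines.append((ann.seqid, ann.start + pos, ann.start + run_end, float(depth[pos])))
            pos = run_end
    lines.sort()
    with open(path, "w") as fh:
        for seqid, start, end, value in lines:
            value_str = f"{int(value)}" if value == int(value) else f"{value:g}"
            fh.write(f"{seqid}\t{start}\t{end}\t{value_str}\n")


# ---------------------------------------------------------------------------
# Peaks (BED6 + TSV table)
# ---------------------------------------------------------------------------


def peak_to_genomic(peak, ann: TranscriptAnnotation) -> tuple[int, int]:
    """Project transcript-space peak coordinates onto the genome."""
    if ann.strand == "+":
        return ann.start + peak.start, ann.start + peak.end
    return ann.end - peak.end, ann.end - peak.start


def write_peaks_bed(
    peakset,
    annotations: Mapping[str, TranscriptAnnotation],
    path: str | Path,
) -> None:
    """Write a PeakSet as BED6 (0-based half-open genomic coordinates).

    The name column encodes transcript id and transcript-space coordinates
    so that `read_peaks_bed` round-trips losslessly; the score column is the
    POI rounded to 3 decimals.
    """
    records = []
    for peak in peakset:
        ann = annotations[peak.transcript_id]
        gstart, gend = peak_to_genomic(peak, ann)
        records.append(
            (
                ann.seqid,
                gstart,
                gend,
                f"{peak.transcript_id}:{peak.start}-{peak.end}",
                round(peak.poi, 3),
                ann.strand,
            )
        )
    records.sort()
    with open(path, "w") as fh:
        fh.write("# BED6; coordinates 0-based half-open; score = POI (3 dp)\n")
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_peaks_bed(path: str | Path, annotations: Mapping[str, TranscriptAnnotation]):
    """Read a BED6 peak file written by `write_peaks_bed` back into Peaks."""
    from .peak_calling import Peak, PeakSet

    peaks = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            name, score = parts[3], float(parts[4])
            tid, span = name.rsplit(":", 1)
            if tid not in annotations:
                raise FormatError(f"{path}:{lineno}: unknown transcript {tid!r}")
            start, end = (int(x) for x in span.split("-"))
            peaks.append(
                Peak(
                    transcript_id=tid,
                    start=start,
                    end=end,
                    pom_ip=float("nan"),
                    pom_input=float("nan"),
                    poi=score,
                    replicate_ids=frozenset(),
                )
            )
    return PeakSet(peaks=peaks)


def write_peak_table(
    peakset,
    annotations: Mapping[str, TranscriptAnnotation],
    path: str | Path,
) -> None:
    """Write the full peak table as TSV (transcript and genomic coordinates)."""
    rows = []
    for peak in peakset:
        ann = annotations[peak.transcript_id]
        gstart, gend = peak_to_genomic(peak, ann)
        rows.append(
            {
                "transcript_id": peak.transcript_id,
                "start": peak.start,
                "end": peak.end,
                "seqid": ann.seqid,
                "genomic_start": gstart,
                "genomic_end": gend,
                "strand": ann.strand,
                "pom_ip": peak.pom_ip,
                "pom_input": peak.pom_input,
                "poi": peak.poi,
                "motifs": ";".join(f"{m}@{o}" for m, o in peak.motifs),
                "replicates": ",".join(sorted(peak.replicate_ids)),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "seqid", "genomic_start",
            "genomic_end", "strand", "pom_ip", "pom_input", "poi",
            "motifs", "replicates",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path):
    from .peak_calling import Peak, PeakSet

    frame = pd.read_csv(path, sep="\t", dtype={"motifs": str, "replicates": str})
    peaks = []
    for row in frame.itertuples(index=False):
        motifs = tuple(
            (m.split("@")[0], int(m.split("@")[1]))
            for m in str(row.motifs).split(";")
            if m and m != "nan"
        )
        reps = frozenset(str(row.replicates).split(",")) if isinstance(row.replicates, str) else frozenset()
        peaks.append(
            Peak(
                transcript_id=row.transcript_id,
                start=int(row.start),
                end=int(row.end),
                pom_ip=float(row.pom_ip),
                pom_input=float(row.pom_input),
                poi=float(row.poi),
                replicate_ids=reps,
                motifs=motifs,
            )
        )
    return PeakSet(peaks=peaks)


# ---------------------------------------------------------------------------
# Pileups and count tables
# ---------------------------------------------------------------------------


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a per-adenosine deamination pileup TSV.

    Columns: transcript_id, pos (0-based), ref, a_count, g_count, other_count.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing pileup columns {sorted(missing)}")
    for col in ("a_count", "g_count", "other_count"):
        if (frame[col] < 0).any():
            raise FormatError(f"{path}: negative counts in {col}")
    return frame[PILEUP_COLUMNS].copy()


def write_pileup(frame: pd.DataFrame, path: str | Path) -> None:
    frame[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.Series:
    """Read a two-column TSV (gene_id, count) into a Series."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 columns (gene_id, count)")
    gene_col, count_col = frame.columns[0], frame.columns[1]
    if frame[gene_col].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    return frame.set_index(gene_col)[count_col].astype(int)


def write_counts(counts: pd.Series, path: str | Path) -> None:
    counts.rename("count").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
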