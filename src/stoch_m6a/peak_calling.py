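"""Sliding-window m6A peak calling from IP/input coverage.

The caller scores 50-nt windows (25-nt step) on each transcript with the
peak-over-median statistic (POM): the mean coverage inside the window
divided by the median coverage across the whole transcript. Windows with
mean coverage < 10 or POM < 3 are discarded, windows enriched in *both* IP
and input ("shared regions") are discarded, and the surviving IP windows are
scored with peak-over-input (POI = POM_IP / POM_input); windows with
POI > 3 are retained and coalesced into peaks. Peaks from biological
replicates are merged by interval union, and peaks can finally be restricted
to those containing one of the known bacterial m6A motifs (GCCAU, UGCCAG,
CAGAUC; exact matching on the transcript sense strand).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack

log = logging.getLogger(__name__)

DEFAULT_MOTIFS: tuple[str, ...] = ("GCCAU", "UGCCAG", "CAGAUC")
RNA_ALPHABET = frozenset("ACGU")

WINDOW_SIZE = 50
WINDOW_STEP = 25
MIN_WINDOW = 10  # truncated terminal windows shorter than this are skipped
MIN_COVERAGE = 10.0
MIN_POM = 3.0
MIN_POI = 3.0


@dataclass(frozen=True)
class WindowScore:
    """POM score for one sliding window (transcript coordinates, half-open)."""

    transcript_id: str
    start: int
    end: int
    mean_cov: float
    median_cov: float
    pom: float  # NaN when the transcript median is 0 (undefined)


@dataclass(frozen=True)
class Peak:
    """A coalesced run of retained windows on one transcript.

    ``poi`` is the maximum window POI within the peak; ``pom_ip`` and
    ``pom_input`` come from that maximal window.
    """

    transcript_id: str
    start: int
    end: int
    pom_ip: float
    pom_input: float
    poi: float
    replicate_ids: frozenset[str] = frozenset()
    motifs: tuple[tuple[str, int], ...] = ()
    condition: str | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PeakSet:
    """An ordered collection of peaks for one condition."""

    peaks: list[Peak] = field(default_factory=list)
    condition: str | None = None

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def transcript_ids(self) -> set[str]:
        return {p.transcript_id for p in self.peaks}

    def by_transcript(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.transcript_id, []).append(p)
        return out

    def sorted(self) -> "PeakSet":
        return PeakSet(
            peaks=sorted(self.peaks, key=lambda p: (p.transcript_id, p.start, p.end)),
            condition=self.condition,
        )


def iter_windows(
    length: int, window: int = WINDOW_SIZE, step: int = WINDOW_STEP,
    min_window: int = MIN_WINDOW,
) -> Iterator[tuple[int, int]]:
    """Enumerate sliding windows: starts 0, step, 2*step, ...

    The terminal window is truncated at the transcript end; enumeration
    stops once a window reaches the end (later starts would only produce
    windows contained in it). Truncated windows shorter than ``min_window``
    are skipped.
    """
    for start in range(0, length, step):
        end = min(start + window, length)
        if end - start >= min_window:
            yield start, end
        if end == length:
            break


def compute_pom(
    track: CoverageTrack,
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    zero_median_policy: str = "drop",
) -> list[WindowScore]:
    """Score every sliding window on a transcript with POM.

    POM = (mean coverage in the window) / (median coverage across the whole
    transcript, zeros included). When the transcript median is 0 the POM is
    undefined: with ``zero_median_policy='drop'`` (default) every window gets
    POM = NaN and is excluded downstream; with ``'pseudo'`` the smallest
    positive per-base depth is used as a pseudo-median instead.
    """
    depth = track.depth
    median = float(np.median(depth))
    if median == 0.0 and zero_median_policy == "pseudo":
        positive = depth[depth > 0]
        if positive.size:
            median = float(positive.min())
    scores = []
    for start, end in iter_windows(track.length, window, step):
        mean_cov = float(depth[start:end].mean())
        pom = mean_cov / median if median > 0 else math.nan
        scores.append(WindowScore(track.transcript_id, start, end, mean_cov, median, pom))
    if median == 0.0 and scores:
        log.warning(
            "%s: transcript median coverage is 0; POM undefined for all windows",
            track.transcript_id,
        )
    return scores


def filter_windows(
    scores: Iterable[WindowScore],
    min_cov: float = MIN_COVERAGE,
    min_pom: float = MIN_POM,
) -> list[WindowScore]:
    """Keep windows with mean coverage >= min_cov AND POM >= min_pom.

    Windows failing either threshold (coverage < 10 or POM < 3 at the
    defaults) are discarded; undefined (NaN) POM is always discarded.
    """
    return [
        s
        for s in scores
        if not math.isnan(s.pom) and s.mean_cov >= min_cov and s.pom >= min_pom
    ]


def _coalesce(
    windows: list[tuple[int, int, float, float, float]],
    transcript_id: str,
    replicate_ids: frozenset[str],
    condition: str | None,
) -> list[Peak]:
    """Merge overlapping/adjacent retained windows into peaks (max-POI score)."""
    if not windows:
        return []
    windows = sorted(windows)
    peaks: list[Peak] = []
    cur_start, cur_end, best = windows[0][0], windows[0][1], windows[0]
    for win in windows[1:]:
        start, end = win[0], win[1]
        if start <= cur_end:  # overlap or touch
            cur_end = max(cur_end, end)
            if win[2] > best[2]:
                best = win
        else:
            peaks.append(
                Peak(transcript_id, cur_start, cur_end, best[3], best[4], best[2],
                     replicate_ids, (), condition)
            )
            cur_start, cur_end, best = start, end, win
    peaks.append(
        Peak(transcript_id, cur_start, cur_end, best[3], best[4], best[2],
             replicate_ids, (), condition)
    )
    return peaks


def call_peaks(
    ip: CoverageTrack,
    input_: CoverageTrack,
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    min_cov: float = MIN_COVERAGE,
    min_pom: float = MIN_POM,
    min_poi: float = MIN_POI,
    zero_median_policy: str = "drop",
    condition: str | None = None,
) -> list[Peak]:
    """Call peaks on one transcript for one replicate.

    Candidate windows pass the coverage/POM filter in the IP sample; windows
    that also pass it in the matched input are discarded as shared regions.
    Each survivor is scored with POI = POM_IP / POM_input using the raw input
    POM for that window (whatever its magnitude); candidates whose input POM
    is 0 or undefined are dropped with a warning. Windows with POI > min_poi
    are retained and coalesced into peaks.
    """
    if ip.transcript_id != input_.transcript_id:
        raise ValueError("IP and input tracks are for different transcripts")
    if ip.length != input_.length:
        raise ValueError(f"{ip.transcript_id}: IP/input length mismatch")
    if ip.length < step:
        log.info("%s: shorter than window step (%d nt); skipped", ip.transcript_id, step)
        return []

    ip_scores = compute_pom(ip, window, step, zero_median_policy)
    in_scores = compute_pom(input_, window, step, zero_median_policy)
    in_by_window = {(s.start, s.end): s for s in in_scores}
    shared = {(s.start, s.end) for s in filter_windows(in_scores, min_cov, min_pom)}

    retained: list[tuple[int, int, float, float, float]] = []
    for cand in filter_windows(ip_scores, min_cov, min_pom):
        key = (cand.start, cand.end)
        if key in shared:
            continue
        input_pom = in_by_window[key].pom
        if math.isnan(input_pom) or input_pom == 0.0:
            log.warning(
                "%s:[%d,%d): input POM undefined or zero; candidate dropped",
                ip.transcript_id, cand.start, cand.end,
            )
            continue
        poi = cand.pom / input_pom
        if poi > min_poi:
            retained.append((cand.start, cand.end, poi, cand.pom, input_pom))

    return _coalesce(retained, ip.transcript_id, frozenset({ip.replicate_id}), condition)


def call_peaks_all(
    ip_tracks: Mapping[str, CoverageTrack],
    input_tracks: Mapping[str, CoverageTrack],
    condition: str | None = None,
    **params,
) -> PeakSet:
    """Call peaks over a whole transcriptome (one replicate).

    Transcripts are processed in sorted-id order so output is independent of
    mapping iteration order. Transcripts missing from either sample are
    skipped with a warning.
    """
    peaks: list[Peak] = []
    for tid in sorted(ip_tracks):
        if tid not in input_tracks:
            log.warning("%s: no matched input track; skipped", tid)
            continue
        peaks.extend(call_peaks(ip_tracks[tid], input_tracks[tid], condition=condition, **params))
    return PeakSet(peaks=peaks, condition=condition).sorted()


def merge_replicates(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Merge per-replicate peak sets into one set of unique peaks.

    Overlapping/adjacent intervals on a transcript are coalesced; the merged
    peak carries the union of replicate ids, the maximum POI, and the
    POM pair of the maximal window.
    """
    conditions = {ps.condition for ps in peaksets if ps.condition is not None}
    if len(conditions) > 1:
        raise ValueError(f"cannot merge peak sets from different conditions: {conditions}")
    condition = conditions.pop() if conditions else None

    by_transcript: dict[str, list[Peak]] = {}
    for ps in peaksets:
        for p in ps:
            by_transcript.setdefault(p.transcript_id, []).append(p)

    merged: list[Peak] = []
    for tid in sorted(by_transcript):
        peaks = sorted(by_transcript[tid], key=lambda p: (p.start, p.end))
        cur = peaks[0]
        cur_reps = set(cur.replicate_ids)
        for p in peaks[1:]:
            if p.start <= cur.end:
                cur_reps |= p.replicate_ids
                best = p if p.poi > cur.poi else cur
                cur = replace(
                    best,
                    start=cur.start,
                    end=max(cur.end, p.end),
                    motifs=(),
                )
            else:
                merged.append(replace(cur, replicate_ids=frozenset(cur_reps), condition=condition))
                cur, cur_reps = p, set(p.replicate_ids)
        merged.append(replace(cur, replicate_ids=frozenset(cur_reps), condition=condition))
    return PeakSet(peaks=merged, condition=condition)


def scan_motifs(
    sequence: str, motifs: Sequence[str] = DEFAULT_MOTIFS
) -> list[tuple[str, int]]:
    """Find all exact (possibly overlapping) motif occurrences.

    Matching is on the transcript sense strand over the RNA alphabet
    {A, C, G, U}; occurrences are returned sorted by offset.
    """
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    hits: list[tuple[str, int]] = []
    for motif in motifs:
        if set(motif) - RNA_ALPHABET:
            raise ValueError(f"motif {motif!r} is not over the RNA alphabet")
        pos = sequence.find(motif)
        while pos != -1:
            hits.append((motif, pos))
            pos = sequence.find(motif, pos + 1)
    return sorted(hits, key=lambda h: (h[1], h[0]))


def filter_peaks_by_motif(
    peakset: PeakSet,
    sequences: Mapping[str, str],
    motifs: Sequence[str] = DEFAULT_MOTIFS,
) -> PeakSet:
    """Keep peaks containing at least one motif occurrence entirely inside them.

    Containment is strict: an occurrence at offset o with motif length m is
    inside peak [start, end) iff start <= o and o + m <= end. Matched motifs
    are recorded on the retained peaks.
    """
    scan_cache: dict[str, list[tuple[str, int]]] = {}
    retained: list[Peak] = []
    for peak in peakset:
        if peak.transcript_id not in sequences:
            raise KeyError(f"no sequence for transcript {peak.transcript_id!r}")
        if peak.transcript_id not in scan_cache:
            scan_cache[peak.transcript_id] = scan_motifs(sequences[peak.transcript_id], motifs)
        inside = tuple(
            (m, o)
            for m, o in scan_cache[peak.transcript_id]
            if peak.start <= o and o + len(m) <= peak.end
        )
        if inside:
            retained.append(replace(peak, motifs=inside))
    return PeakSet(peaks=retained, condition=peakset.condition)
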