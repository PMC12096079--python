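"""Cross-cutting statistics: overlaps, concordance, metagene profiles,
expression grouping, and recovery metrics against planted truth.

These are the comparisons that turn the two callers' outputs into the
biological claims: how well replicates agree (percent shared), whether
antibody peaks and deamination sites land on the same positions, where along
the CDS the modified motifs sit (10-bin metagene ratio with a Mann-Whitney
test between conditions), and whether methylation tracks expression (RPKM
tertiles, log2 fold-change flags, Pearson correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .etam_calling import called_site_set
from .io_formats import TranscriptAnnotation
from .peak_calling import PeakSet, scan_motifs
from .synthetic_data import SyntheticTruth

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Set overlaps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    percent_shared: float  # NaN when the denominator is empty


def transcript_overlap(
    set_a: Iterable[str], set_b: Iterable[str], denominator: str = "union"
) -> OverlapReport:
    """Replicate/condition concordance of methylated-transcript identities.

    percent shared = 100 * |A intersect B| / |total|, where the total is the
    union by default ('first'/'second' use one set's size instead, for
    asymmetric reproduction of published percentages).
    """
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    totals = {"union": len(union), "first": len(a), "second": len(b)}
    if denominator not in totals:
        raise ValueError(f"unknown denominator {denominator!r}")
    total = totals[denominator]
    percent = 100.0 * len(inter) / total if total else math.nan
    return OverlapReport(len(a), len(b), len(inter), len(union), percent)


def peaks_encompassing_sites(
    peakset: PeakSet, sites: pd.DataFrame | set[tuple[str, int]]
) -> tuple[int, int]:
    """Cross-method concordance: peaks containing persistent-A sites.

    A site is inside a peak iff start <= pos < end (half-open). Returns
    (number of peaks containing >= 1 site, number of sites inside any peak);
    a peak with two sites counts once in the first figure, twice in the
    second.
    """
    site_set = sites if isinstance(sites, set) else called_site_set(sites)
    trees: dict[str, IntervalTree] = {}
    for peak in peakset:
        trees.setdefault(peak.transcript_id, IntervalTree()).addi(
            peak.start, peak.end, peak
        )
    peaks_hit: set[tuple[str, int, int]] = set()
    n_sites_in_peaks = 0
    for tid, pos in site_set:
        tree = trees.get(tid)
        if tree is None:
            continue
        hits = tree[pos]  # intervaltree uses half-open intervals
        if hits:
            n_sites_in_peaks += 1
            for hit in hits:
                peaks_hit.add((tid, hit.begin, hit.end))
    return len(peaks_hit), n_sites_in_peaks


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Per-bin ratio of modified motif occurrences to all motif occurrences.

    Each transcript is rescaled to unit length and cut into ``n_bins`` equal
    bins; a motif occurrence at relative position p falls in bin
    floor(p * n_bins). A motif is "modified" iff it lies entirely inside a
    called peak. Numerators and denominators are pooled across transcripts.
    """

    condition: str | None
    numerators: np.ndarray
    denominators: np.ndarray
    modified_positions: list[float] = field(default_factory=list)
    all_positions: list[float] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return int(self.denominators.size)

    @property
    def bins(self) -> np.ndarray:
        """Bin ratios; NaN for bins with no motif occurrences."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.denominators > 0, self.numerators / self.denominators, np.nan
            )


def metagene_profile(
    peakset: PeakSet,
    sequences: Mapping[str, str],
    motifs: Sequence[str],
    n_bins: int = 10,
    transcript_ids: Iterable[str] | None = None,
) -> MetageneProfile:
    """Build the pooled motif-ratio metagene profile for one condition."""
    peaks_by_tid = peakset.by_transcript()
    tids = sorted(transcript_ids) if transcript_ids is not None else sorted(sequences)
    num = np.zeros(n_bins, dtype=int)
    den = np.zeros(n_bins, dtype=int)
    modified_positions: list[float] = []
    all_positions: list[float] = []
    for tid in tids:
        seq = sequences[tid]
        length = len(seq)
        peaks = peaks_by_tid.get(tid, [])
        for motif, offset in scan_motifs(seq, motifs):
            p = offset / length
            b = int(p * n_bins)  # p in [0, 1) so b in [0, n_bins)
            den[b] += 1
            all_positions.append(p)
            if any(pk.start <= offset and offset + len(motif) <= pk.end for pk in peaks):
                num[b] += 1
                modified_positions.append(p)
    return MetageneProfile(peakset.condition, num, den, modified_positions, all_positions)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact for tie-free samples with both sizes <= 8; otherwise the normal
    approximation with tie and continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        log.warning("Mann-Whitney needs >= 2 observations per sample; returning NaN")
        return math.nan
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def compare_profiles(
    profile_a: MetageneProfile, profile_b: MetageneProfile, unit: str = "positions"
) -> float:
    """Test whether two conditions' modification distributions differ.

    ``unit='positions'`` (default) compares the transcript-relative positions
    of modified motifs; ``unit='bins'`` compares the 10 bin ratios instead
    (NaN bins dropped).
    """
    if unit == "positions":
        return mann_whitney(profile_a.modified_positions, profile_b.modified_positions)
    if unit == "bins":
        a = profile_a.bins[~np.isnan(profile_a.bins)]
        b = profile_b.bins[~np.isnan(profile_b.bins)]
        return mann_whitney(a, b)
    raise ValueError(f"unknown test unit {unit!r}")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def compute_rpkm(
    counts: pd.Series,
    lengths: Mapping[str, int],
    library_size: int | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Reads-per-kilobase-per-million normalisation.

    rpkm = count / ((length/1000) * (library_size/1e6)); library size
    defaults to the column sum. log2_rpkm adds ``pseudocount`` before the
    log so zero counts stay finite.
    """
    if library_size is None:
        library_size = int(counts.sum())
    if library_size <= 0:
        raise ValueError("library size must be positive")
    lengths_nt = pd.Series({g: lengths[g] for g in counts.index}, dtype=float)
    rpkm = counts / ((lengths_nt / 1e3) * (library_size / 1e6))
    return pd.DataFrame(
        {
            "raw_count": counts,
            "rpkm": rpkm,
            "log2_rpkm": np.log2(rpkm + pseudocount),
        }
    )


GROUP_LABELS = {3: ("low", "mid", "high")}


def expression_groups(log2_rpkm: pd.Series, k: int = 3) -> pd.Series:
    """Split genes into k near-equal expression groups (default tertiles).

    Genes are sorted ascending by (value, gene id) — the id tie-break makes
    the partition deterministic — and group sizes differ by at most one,
    with the remainder assigned to the lowest group(s).
    """
    n = len(log2_rpkm)
    if n < k:
        raise ValueError(f"need at least {k} genes to form {k} groups")
    order = sorted(log2_rpkm.index, key=lambda g: (log2_rpkm[g], str(g)))
    base, rem = divmod(n, k)
    labels = GROUP_LABELS.get(k, tuple(f"g{i + 1}" for i in range(k)))
    assignment: dict[str, str] = {}
    idx = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        for g in order[idx : idx + size]:
            assignment[g] = labels[i]
        idx += size
    return pd.Series(assignment, name="expression_group").loc[log2_rpkm.index]


def expression_comparison(
    ctrl_rpkm: pd.Series,
    stress_rpkm: pd.Series,
    pseudocount: float = 0.01,
    de_threshold: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-gene log2 fold change with a |log2FC| >= 1 DE flag, plus Pearson r.

    Both inputs are RPKM series; the pseudocount is added before the log.
    Returns (frame indexed by shared genes with log2fc/de_flag, r on
    log2 RPKM over the shared genes).
    """
    shared = ctrl_rpkm.index.intersection(stress_rpkm.index)
    if shared.empty:
        raise ValueError("no shared genes between conditions")
    log_ctrl = np.log2(ctrl_rpkm.loc[shared] + pseudocount)
    log_stress = np.log2(stress_rpkm.loc[shared] + pseudocount)
    log2fc = log_stress - log_ctrl
    frame = pd.DataFrame(
        {"log2fc": log2fc, "de_flag": np.abs(log2fc) >= de_threshold}
    )
    if log_ctrl.nunique() <= 1 or log_stress.nunique() <= 1:
        r = 1.0 if (log_ctrl == log_stress).all() else math.nan
    else:
        r = float(stats.pearsonr(log_ctrl, log_stress).statistic)
    return frame, r


@dataclass
class MethylationByExpression:
    """Methylated-transcript counts per expression group, per condition."""

    counts: pd.DataFrame  # rows: condition, columns: group label
    tracked: dict[str, dict] = field(default_factory=dict)


def methylation_by_expression(
    methylated_by_condition: Mapping[str, set[str]],
    groups_by_condition: Mapping[str, pd.Series],
    tracked_subset: set[str] | None = None,
    baseline_condition: str | None = None,
) -> MethylationByExpression:
    """Cross-tabulate methylation status against expression groups.

    A transcript is methylated iff it carries >= 1 peak. When a
    ``tracked_subset`` is given (e.g. the highly expressed methylated
    transcripts of a baseline condition), each non-baseline condition
    reports how many of those transcripts retain vs. lose methylation and
    how they redistribute over that condition's expression groups.
    """
    conditions = sorted(methylated_by_condition)
    all_labels: list[str] = []
    for cond in conditions:
        for lab in pd.unique(groups_by_condition[cond]):
            if lab not in all_labels:
                all_labels.append(lab)
    counts = pd.DataFrame(0, index=conditions, columns=all_labels)
    for cond in conditions:
        groups = groups_by_condition[cond]
        for tid in methylated_by_condition[cond]:
            if tid in groups.index:
                counts.loc[cond, groups[tid]] += 1
    result = MethylationByExpression(counts=counts)
    if tracked_subset is not None:
        for cond in conditions:
            if cond == baseline_condition:
                continue
            methylated = methylated_by_condition[cond]
            groups = groups_by_condition[cond]
            retained = tracked_subset & methylated
            redistribution = {lab: 0 for lab in all_labels}
            for tid in tracked_subset:
                if tid in groups.index:
                    redistribution[groups[tid]] += 1
            result.tracked[cond] = {
                "retained": len(retained),
                "lost": len(tracked_subset) - len(retained),
                "redistribution": redistribution,
            }
    return result


# ---------------------------------------------------------------------------
# Recovery against planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float  # NaN when nothing was called
    recall: float  # NaN when the truth is empty
    n_true_positive_calls: int
    n_called: int
    n_truth: int


def peak_recovery_metrics(peakset: PeakSet, truth: SyntheticTruth) -> RecoveryMetrics:
    """Precision/recall of called peaks against planted truth intervals.

    A called peak is a true positive iff it overlaps a truth interval by at
    least 1 nt; a truth interval is recovered iff some called peak overlaps
    it.
    """
    truth_by_tid: dict[str, list[tuple[int, int]]] = {}
    for p in truth.planted_peaks:
        truth_by_tid.setdefault(p.transcript_id, []).append(p.interval)
    tp_calls = 0
    recovered: set[tuple[str, int, int]] = set()
    for peak in peakset:
        hit = False
        for ts, te in truth_by_tid.get(peak.transcript_id, []):
            if peak.start < te and ts < peak.end:
                hit = True
                recovered.add((peak.transcript_id, ts, te))
        tp_calls += hit
    n_called, n_truth = len(peakset), len(truth.planted_peaks)
    precision = tp_calls / n_called if n_called else math.nan
    recall = len(recovered) / n_truth if n_truth else math.nan
    return RecoveryMetrics(precision, recall, tp_calls, n_called, n_truth)


def site_recovery_metrics(
    called_sites: set[tuple[str, int]], truth_sites: Iterable[tuple[str, int]]
) -> RecoveryMetrics:
    """Precision/recall of called persistent-A sites (exact-position match)."""
    truth_set = set(truth_sites)
    tp = len(called_sites & truth_set)
    precision = tp / len(called_sites) if called_sites else math.nan
    recall = tp / len(truth_set) if truth_set else math.nan
    return RecoveryMetrics(precision, recall, tp, len(called_sites), len(truth_set))
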