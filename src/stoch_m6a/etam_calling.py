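"""Base-resolution persistent-A calling from deamination pileups.

A deaminase converts unmethylated adenosines to inosine (read as G), so a
reference A whose pileup keeps a high A fraction after treatment is a
"persistent A". A site is called when its depth is at least 20 reads and at
least 50% of them still read A (both thresholds inclusive, configurable).

Without a demethylase-treated control branch, a persistent A may be either
m6A or a structured (conversion-resistant) adenosine; the caller's output is
the union of the two and downstream analyses must treat it as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MIN_FRACTION = 0.5
MIN_DEPTH = 20

SITE_COLUMNS = [
    "transcript_id", "pos", "ref", "a_count", "g_count", "other_count",
    "total_count", "persistence", "called",
]


def call_persistent_sites(
    pileup: pd.DataFrame,
    min_frac: float = MIN_FRACTION,
    min_depth: int = MIN_DEPTH,
    denominator: str = "ag",
    replicate_id: str | None = None,
) -> pd.DataFrame:
    """Call persistent-A sites from a per-adenosine pileup.

    Parameters
    ----------
    pileup
        Rows of (transcript_id, pos, ref, a_count, g_count, other_count);
        only ref == 'A' rows are considered.
    min_frac, min_depth
        Inclusive thresholds: called iff total_count >= min_depth and
        persistence >= min_frac.
    denominator
        'ag' (default): persistence = A / (A + G), the conversion axis;
        'total': persistence = A / (A + G + other).

    Rows whose denominator is 0 are excluded (never divided).
    """
    if denominator not in ("ag", "total"):
        raise ValueError(f"unknown denominator {denominator!r}")
    table = pileup.loc[pileup["ref"] == "A"].copy()
    total = table["a_count"] + table["g_count"]
    if denominator == "total":
        total = total + table["other_count"]
    table["total_count"] = total
    table = table.loc[table["total_count"] > 0].copy()
    table["persistence"] = table["a_count"] / table["total_count"]
    table["called"] = (table["total_count"] >= min_depth) & (
        table["persistence"] >= min_frac
    )
    if replicate_id is not None:
        table["replicate_id"] = replicate_id
    return table.sort_values(["transcript_id", "pos"]).reset_index(drop=True)


def called_site_set(table: pd.DataFrame) -> set[tuple[str, int]]:
    """The (transcript_id, pos) set of called sites in a site table."""
    called = table.loc[table["called"]]
    return set(zip(called["transcript_id"], called["pos"].astype(int)))


@dataclass(frozen=True)
class ConsensusReport:
    """Replicate agreement between two persistent-A site tables."""

    n_rep1: int
    n_rep2: int
    overlap: frozenset[tuple[str, int]]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)


def replicate_consensus(table1: pd.DataFrame, table2: pd.DataFrame) -> ConsensusReport:
    """Exact-position intersection of called sites between two replicates."""
    s1, s2 = called_site_set(table1), called_site_set(table2)
    return ConsensusReport(n_rep1=len(s1), n_rep2=len(s2), overlap=frozenset(s1 & s2))


@dataclass
class ControlReport:
    """Detection status of designated always-methylated control positions."""

    detected: list[tuple[str, int]] = field(default_factory=list)
    missing: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_controls(self) -> int:
        return len(self.detected) + len(self.missing)

    @property
    def all_detected(self) -> bool:
        return not self.missing

    def summary(self) -> str:
        return f"{len(self.detected)}/{self.n_controls} control sites detected"


def check_control_sites(
    table: pd.DataFrame, controls: list[tuple[str, int]]
) -> ControlReport:
    """Check that every control position was called persistent.

    Raises ValueError if a control position is not a reference A in the
    pileup (a coordinate mistake, not a detection failure).
    """
    rows = {
        (tid, int(pos)): bool(called)
        for tid, pos, called in zip(table["transcript_id"], table["pos"], table["called"])
    }
    report = ControlReport()
    for tid, pos in controls:
        key = (tid, int(pos))
        if key not in rows:
            raise ValueError(f"control position {tid}:{pos} is not a reference A in the pileup")
        (report.detected if rows[key] else report.missing).append(key)
    return report
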