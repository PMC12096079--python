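"""Synthetic transcriptomes with planted m6A signal, for end-to-end testing.

The generator emulates the two data modalities the pipeline consumes:

* antibody-enrichment coverage — per-base IP and input depth where the IP
  depth is locally multiplied by an enrichment factor inside planted 50-nt
  windows, each centred on one of the bacterial m6A motifs, over
  negative-binomial background noise scaled per transcript by a log-normal
  expression level;
* deamination pileups — per-adenosine (A, G) read counts where unmethylated
  adenosines convert A->G at a high rate and planted sites remain
  persistently A, mimicking a TadA-style deaminase readout. A designated
  rRNA-like transcript carries two always-persistent control positions
  (0-based 1617 and 2029, the analogues of the 23S rRNA m6A sites at
  1-based 1618 and 2030).

Everything is driven by one integer seed; fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, TranscriptAnnotation

_BASES = np.array(list("ACGU"))

CONTROL_TRANSCRIPT_ID = "SYN23S"


class ConfigError(ValueError):
    """Simulation configuration is inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the generator's study conditions: 200 transcripts, 50
    planted single-window peaks at 8-fold IP enrichment over a mean input
    depth of 20x, two replicates, 99% A->G conversion with planted sites 95%
    persistent, and pileup depth ~ Poisson(100).
    """

    seed: int = 7
    n_transcripts: int = 200
    transcript_length_range: tuple[int, int] = (300, 1500)
    expression_log_mean: float = 4.0  # log2-RPKM scale
    expression_log_sd: float = 1.0
    planted_peak_count: int = 50
    enrichment_factor: float = 8.0
    background_dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    noise: str = "nb"  # {"nb", "poisson", "exact"}
    base_depth: float = 20.0
    n_replicates: int = 2
    peak_width: int = 50
    motifs: tuple[str, ...] = ("GCCAU", "UGCCAG", "CAGAUC")
    planted_site_count: int = 30
    conversion_rate: float = 0.99
    persistent_fraction: float = 0.95
    pileup_depth_mean: float = 100.0
    pileup_depth_dispersion: float | None = None  # None = Poisson depth
    control_transcript_length: int = 2904
    control_positions: tuple[int, ...] = (1617, 2029)

    def validate(self) -> None:
        if self.enrichment_factor < 1:
            raise ConfigError("enrichment_factor must be >= 1")
        if not (0 < self.conversion_rate <= 1):
            raise ConfigError("conversion_rate must be in (0, 1]")
        if not (0 <= self.persistent_fraction <= 1):
            raise ConfigError("persistent_fraction must be in [0, 1]")
        if self.noise not in ("nb", "poisson", "exact"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        lo, hi = self.transcript_length_range
        if lo > hi or lo < max(self.peak_width, 2 * max(len(m) for m in self.motifs)):
            raise ConfigError("transcript_length_range too short to host a motif window")
        if self.planted_peak_count > self.n_transcripts:
            raise ConfigError("more planted peaks than transcripts")
        if max(self.control_positions, default=0) >= self.control_transcript_length:
            raise ConfigError("control position outside the control transcript")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("transcript_length_range", "motifs", "control_positions"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class PlantedPeak:
    transcript_id: str
    start: int
    end: int
    motif: str
    enrichment: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for recovery tests."""

    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    planted_sites: list[tuple[str, int]] = field(default_factory=list)
    control_sites: list[tuple[str, int]] = field(default_factory=list)
    expression_log2: dict[str, float] = field(default_factory=dict)
    motif_inventory: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_peaks": [dataclasses.asdict(p) for p in self.planted_peaks],
            "planted_sites": [list(s) for s in self.planted_sites],
            "control_sites": [list(s) for s in self.control_sites],
            "expression_log2": self.expression_log2,
            "motif_inventory": {
                tid: [[m, o] for m, o in hits] for tid, hits in self.motif_inventory.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            planted_peaks=[PlantedPeak(**p) for p in d["planted_peaks"]],
            planted_sites=[(tid, int(pos)) for tid, pos in d["planted_sites"]],
            control_sites=[(tid, int(pos)) for tid, pos in d["control_sites"]],
            expression_log2={k: float(v) for k, v in d.get("expression_log2", {}).items()},
            motif_inventory={
                tid: [(m, int(o)) for m, o in hits]
                for tid, hits in d.get("motif_inventory", {}).items()
            },
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)].copy()


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, TranscriptAnnotation], dict[str, str], SyntheticTruth]:
    """Generate annotations, sequences and ground truth.

    Transcripts are laid head-to-tail (100-nt gaps) on one synthetic
    chromosome with random strands. Planted peaks are one window wide,
    window-aligned, and each carries one motif at its centre; motifs also
    occur by chance elsewhere and the full motif inventory is recorded in
    the truth object.
    """
    from .peak_calling import scan_motifs

    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_transcripts
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    width = int(np.ceil(np.log10(max(n, 2))) + 1)

    annotations: dict[str, TranscriptAnnotation] = {}
    seq_arrays: dict[str, np.ndarray] = {}
    truth = SyntheticTruth()
    cursor = 0
    for i in range(n):
        tid = f"synt{i + 1:0{width}d}"
        length = int(lengths[i])
        annotations[tid] = TranscriptAnnotation(
            tid, "chrSim", cursor, cursor + length, str(strands[i])
        )
        cursor += length + 100
        seq_arrays[tid] = _random_sequence(rng, length)
        truth.expression_log2[tid] = float(
            rng.normal(config.expression_log_mean, config.expression_log_sd)
        )

    # rRNA-like control transcript for the deamination assay
    ctrl_len = config.control_transcript_length
    annotations[CONTROL_TRANSCRIPT_ID] = TranscriptAnnotation(
        CONTROL_TRANSCRIPT_ID, "chrSim", cursor, cursor + ctrl_len, "+"
    )
    ctrl_seq = _random_sequence(rng, ctrl_len)
    for pos in config.control_positions:
        ctrl_seq[pos] = "A"
        truth.control_sites.append((CONTROL_TRANSCRIPT_ID, int(pos)))
    seq_arrays[CONTROL_TRANSCRIPT_ID] = ctrl_seq
    truth.expression_log2[CONTROL_TRANSCRIPT_ID] = float(config.expression_log_mean)

    # plant enrichment windows, one per chosen transcript, motif at centre
    mrna_ids = [t for t in annotations if t != CONTROL_TRANSCRIPT_ID]
    w = config.peak_width
    eligible = [t for t in mrna_ids if annotations[t].length >= w]
    if config.planted_peak_count > len(eligible):
        raise ConfigError("not enough transcripts long enough to host a planted peak")
    chosen = rng.choice(np.array(sorted(eligible)), size=config.planted_peak_count, replace=False)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tid in chosen:
        tid = str(tid)
        length = annotations[tid].length
        n_starts = (length - w) // 25 + 1
        start = int(rng.integers(0, n_starts)) * 25
        motif = str(rng.choice(np.array(config.motifs)))
        mstart = start + (w - len(motif)) // 2
        seq_arrays[tid][mstart : mstart + len(motif)] = list(motif)
        occupied.setdefault(tid, []).append((mstart, mstart + len(motif)))
        truth.planted_peaks.append(
            PlantedPeak(tid, start, start + w, motif, config.enrichment_factor)
        )

    # plant persistent-A sites, avoiding planted motif spans
    for _ in range(config.planted_site_count):
        for _attempt in range(1000):
            tid = str(rng.choice(np.array(mrna_ids)))
            pos = int(rng.integers(0, annotations[tid].length))
            spans = occupied.get(tid, [])
            if any(s <= pos < e for s, e in spans):
                continue
            if (tid, pos) in truth.planted_sites:
                continue
            break
        else:  # pragma: no cover - would need a pathological config
            raise ConfigError("could not place planted sites without motif collisions")
        seq_arrays[tid][pos] = "A"
        truth.planted_sites.append((tid, pos))
    truth.planted_sites.sort()

    sequences = {tid: "".join(arr) for tid, arr in seq_arrays.items()}
    truth.motif_inventory = {
        tid: scan_motifs(seq, config.motifs) for tid, seq in sequences.items()
    }
    return annotations, sequences, truth


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if config.noise == "exact":
        return np.rint(mean)
    if config.noise == "poisson" or not math.isfinite(config.background_dispersion):
        return rng.poisson(mean).astype(float)
    size = config.background_dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_coverage(
    annotations: Mapping[str, TranscriptAnnotation],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> dict[tuple[str, str], dict[str, CoverageTrack]]:
    """Simulate IP and input coverage for every replicate.

    Per-transcript input mean depth is ``base_depth * 2**(e - mu)`` where e
    is the transcript's log2 expression and mu the population mean, so the
    typical transcript sits at ``base_depth``. IP depth uses the same mean
    multiplied by the enrichment factor inside planted windows. Each
    (role, replicate) track is an independent draw.

    Returns a mapping (sample_role, replicate_id) -> {transcript_id -> track}.
    """
    config.validate()
    peaks_by_tid: dict[str, list[PlantedPeak]] = {}
    for p in truth.planted_peaks:
        peaks_by_tid.setdefault(p.transcript_id, []).append(p)

    out: dict[tuple[str, str], dict[str, CoverageTrack]] = {}
    for rep_index in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep_index}"
        for role_index, role in enumerate(("input", "IP")):
            rng = np.random.default_rng([config.seed, 211, rep_index, role_index])
            tracks: dict[str, CoverageTrack] = {}
            for tid in sorted(annotations):
                ann = annotations[tid]
                mu = config.base_depth * 2.0 ** (
                    truth.expression_log2[tid] - config.expression_log_mean
                )
                mean = np.full(ann.length, mu, dtype=float)
                if role == "IP":
                    for peak in peaks_by_tid.get(tid, []):
                        mean[peak.start : peak.end] *= peak.enrichment
                tracks[tid] = CoverageTrack(tid, role, rep_id, _draw_counts(rng, mean, config))
            out[(role, rep_id)] = tracks
    return out


def simulate_etam_pileup(
    sequences: Mapping[str, str],
    truth: SyntheticTruth,
    config: SimulationConfig,
    replicate_index: int = 1,
) -> pd.DataFrame:
    """Simulate a per-adenosine deamination pileup for one replicate.

    For every reference A the total depth is drawn (Poisson by default, or
    negative binomial when ``pileup_depth_dispersion`` is set) and the
    A-count is Binomial(total, 1 - conversion_rate) at background positions,
    Binomial(total, persistent_fraction) at planted and control sites.
    """
    config.validate()
    persistent = set(truth.planted_sites) | set(truth.control_sites)
    for tid, pos in sorted(persistent):
        if tid not in sequences:
            raise ConfigError(f"planted site on unknown transcript {tid!r}")
        if sequences[tid][pos] != "A":
            raise ConfigError(f"planted site {tid}:{pos} is not on an A")

    rng = np.random.default_rng([config.seed, 307, replicate_index])
    rows = []
    for tid in sorted(sequences):
        seq = sequences[tid]
        positions = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") == b"A")
        if positions.size == 0:
            continue
        if config.pileup_depth_dispersion is None:
            totals = rng.poisson(config.pileup_depth_mean, size=positions.size)
        else:
            size = config.pileup_depth_dispersion
            p = size / (size + config.pileup_depth_mean)
            totals = rng.negative_binomial(size, p, size=positions.size)
        p_a = np.where(
            [ (tid, int(pos)) in persistent for pos in positions ],
            config.persistent_fraction,
            1.0 - config.conversion_rate,
        )
        a_counts = rng.binomial(totals, p_a)
        for pos, total, a in zip(positions, totals, a_counts):
            rows.append((tid, int(pos), "A", int(a), int(total - a), 0))
    return pd.DataFrame(rows, columns=["transcript_id", "pos", "ref", "a_count", "g_count", "other_count"])


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Run the full generator and write every output file.

    Writes FASTA + GFF3 + per-sample bedGraphs + per-replicate pileup TSVs +
    truth JSON + the config itself; returns {relative filename: role}.
    """
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations, sequences, truth = simulate_transcriptome(config)
    manifest: dict[str, str] = {}

    io_formats.write_fasta(sequences, outdir / "transcripts.fa")
    manifest["transcripts.fa"] = "sequences"
    io_formats.write_annotation(annotations, outdir / "annotation.gff3")
    manifest["annotation.gff3"] = "annotation"
    truth.save(outdir / "truth.json")
    manifest["truth.json"] = "truth"

    for (role, rep_id), tracks in simulate_coverage(annotations, truth, config).items():
        name = f"{role.lower()}_{rep_id}.bedgraph"
        io_formats.write_bedgraph(tracks, annotations, outdir / name)
        manifest[name] = f"coverage:{role}:{rep_id}"

    for rep_index in range(1, config.n_replicates + 1):
        pileup = simulate_etam_pileup(sequences, truth, config, rep_index)
        name = f"etam_pileup_rep{rep_index}.tsv"
        io_formats.write_pileup(pileup, outdir / name)
        manifest[name] = f"pileup:rep{rep_index}"

    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
    manifest["sim_config.json"] = "config"
    return manifest
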