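# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based, half-open. Coverage vectors and peak
coordinates are *transcript-oriented*: position 0 is the transcript's 5'
end, and minus-strand bedGraph coverage is reversed at load time, so every
downstream computation (windowing, motif scanning, metagene binning) is
strand-agnostic. GFF3 input (1-based, closed) is converted on read; BED
output is natively 0-based half-open; peak tables report both transcript
and genomic projections because published peak lists use either convention.

## Peak calling (POM / POI)

For each transcript, windows of `window = 50` nt slide with `step = 25` nt
starting at 0. The terminal window is truncated at the transcript end, and
enumeration stops at the first window that reaches the end — later starts
would only produce sub-windows of it (a 60-nt transcript therefore yields
[0,50) and [25,60), not a redundant [50,60)). Truncated windows shorter
than 10 nt are skipped; transcripts shorter than the step are skipped and
logged.

Scores and filters, in order:

1. **POM** = mean window coverage / median coverage of the whole transcript
   (zeros included). A transcript with median 0 has undefined POM; by
   default all its windows are dropped (`zero_median_policy="drop"`), or the
   smallest positive per-base depth can serve as a pseudo-median
   (`"pseudo"`). Dropping is the conservative default for genuinely sparse
   transcripts.
2. **Coverage/POM filter**: a window is kept iff mean coverage ≥ 10 *and*
   POM ≥ 3 (both inclusive). The filter is conjunctive: a deep window with
   weak enrichment is as uninformative as a shallow one with apparently
   strong enrichment, and "coverage" here means the window mean, the unit
   used throughout the procedure.
3. **Shared-region exclusion**: a window passing the filter in *both* IP
   and input of the same replicate reflects input-driven structure, not
   antibody enrichment, and is discarded.
4. **POI** = POM_IP / POM_input at the same window, using the raw input POM
   whatever its magnitude; candidates whose input POM is 0 or undefined are
   dropped with a warning rather than assigned an infinite score. Windows
   with POI > 3 (strict) are retained.
5. **Coalescing**: overlapping or adjacent retained windows on one
   transcript merge into a single peak scored by its maximal window's POI
   (peak counts, not window counts, are the reported unit).

Replicate merging is interval union per transcript with union of replicate
provenance, again max-POI scored. Motif filtering retains a peak iff at
least one motif occurrence lies *entirely* inside [start, end); matching is
exact, overlap-tolerant, on the sense strand over {A,C,G,U} (DNA input is
transliterated T→U on load). The default motif set is GCCAU, UGCCAG,
CAGAUC; the set is configurable since variant spellings of the second motif
circulate in the literature.

POM and POI are scale-free: multiplying a track by k > 0 changes neither
(mean and median scale together), so only the absolute coverage filter is
depth-sensitive. On transcripts up to 200 nt the caller is tested for exact
agreement with an independent explicit-loop enumerator over 1,000 random
fixtures.

## Persistent-A calling

From a per-adenosine pileup of (A, G, other) counts, persistence =
a_count / (a_count + g_count) by default — A→G conversion is the only
signal axis, so other bases are treated as sequencing noise; persistence
over the full depth is available (`denominator="total"`). A site is called
iff depth ≥ 20 and persistence ≥ 0.5, both inclusive ("at least"
semantics). Zero-depth rows are excluded, never divided. No
demethylase-treated branch exists: called sites are m⁶A or
conversion-resistant (structured) adenosines, and the API documents the
union explicitly. Replicate consensus is the exact-position intersection of
called sites. Control checking verifies that designated always-methylated
positions (the synthetic analogue of the 23S rRNA sites, 0-based 1617 and
2029) are called, and errors if a control position is not a reference A.

## Comparative statistics

* **Percent shared** = 100·|A∩B|/|A∪B| by default; the denominator is
  switchable to either single set (`first`/`second`) because published
  percentages do not always state their total. The union makes the
  statistic symmetric and equal to 100 iff the sets are equal.
* **Peaks encompassing sites**: a site at position p is inside peak
  [start, end) iff start ≤ p < end; both the number of peaks containing ≥ 1
  site and the number of sites inside any peak are reported (one peak with
  two sites counts once and twice respectively). Interval lookup uses an
  interval tree per transcript.
* **Metagene profile**: each transcript is rescaled to unit length and cut
  into 10 bins; a motif occurrence at relative position p = offset/length
  falls in bin ⌊10p⌋. The profile is the pooled ratio (modified motifs) /
  (all motifs) per bin, where "modified" means entirely inside a called
  peak; bins with no motifs are NaN. Pooling is additive over transcripts.
* **Condition comparison** uses a two-sided Mann–Whitney U test. The
  sampling unit is configurable: the transcript-relative positions of
  modified motifs (default — more observations, tests the positional
  distribution directly) or the 10 bin ratios (`unit="bins"`). The test is
  exact for tie-free samples with both sizes ≤ 8 and otherwise the normal
  approximation with tie and continuity correction; it is verified against
  full permutation enumeration for all sizes up to 8, and its simulated
  type-I error at α = 0.05 is checked to lie in [0.04, 0.06].
* **Expression**: RPKM = count / ((length/10³)·(library size/10⁶));
  log₂ RPKM uses a +0.01 RPKM pseudocount so zero counts stay finite.
  Expression groups sort genes ascending by (value, id) — the id tie-break
  makes the partition deterministic — into k groups whose sizes differ by
  ≤ 1, remainder to the lowest group. Differential expression is flagged at
  |log₂FC| ≥ 1; Pearson r is computed on log₂ RPKM over shared genes.
  Groups are recomputed per condition by default; `--inherit-groups` reuses
  the control partition.
* **Recovery metrics**: a called peak is a true positive iff it overlaps a
  planted interval by ≥ 1 nt (peaks) or matches the exact position (sites);
  precision = TP/called (NaN when nothing is called), recall =
  recovered/truth (NaN when the truth is empty).

## Synthetic data model

The generator emulates the statistical structure of the two assays, not
their biochemistry:

* Transcripts (default 200, lengths uniform on 300–1500 nt) are laid
  head-to-tail with 100-nt gaps on one synthetic chromosome with random
  strands; sequences are i.i.d. uniform over {A,C,G,U}, so motifs also
  occur by chance and the full motif inventory is recorded in the truth
  object.
* Expression is log-normal (log₂ sd 1.0 by default, a typical
  between-gene spread for bacterial RNA-seq); a transcript's mean input
  depth is `base_depth · 2^(e − μ)`, so the typical transcript sits at
  `base_depth` (default 20×, a realistic mRNA coverage for a bacterial
  library).
* Per-base counts are negative-binomial (dispersion/size 10, a standard
  overdispersed sequencing model; Poisson and exact-mean modes are
  available for calibration work). IP tracks multiply the mean by the
  enrichment factor (default 8) inside planted windows; every
  (role, replicate) track is an independent draw from seed-derived
  substreams.
* Planted peaks (default 50) are exactly one window (50 nt) wide and
  window-aligned so truth↔call matching is unambiguous, each with one motif
  written at its centre.
* Deamination pileups draw per-A depth from Poisson(100) — the depth
  distribution of a real deamination library is library-dependent, and a
  Poisson around the target mean is the neutral default; a
  negative-binomial option (`pileup_depth_dispersion`) covers overdispersed
  libraries. A-counts are Binomial(depth, 1 − c) at background positions
  (conversion c = 0.99) and Binomial(depth, f) at planted/control sites
  (persistent fraction f = 0.95). At these settings the background
  false-positive probability per site is the binomial tail
  P[Bin(n, 0.01) ≥ n/2], which is vanishingly small at depth ≈ 100 — the
  calibration tests check the observed count against this closed form.

What the generator does **not** emulate: antibody specificity and
off-target binding, fragment-size effects and positional autocorrelation of
real IP coverage, sequence-dependent conversion efficiency, RNA structure,
and overlapping genes. Passing recovery tests therefore demonstrates that
the *pipeline logic* is correct and calibrated under its stated noise
model, not that the thresholds are optimal for any particular real library.

## Determinism and problem sizes

Every stochastic step derives from one integer seed through named
`numpy.random.Generator` substreams, so a fixed seed gives byte-identical
output files and results independent of dict iteration order. The bundled
test suite and the acceptance script run the study at its default sizes
(200 transcripts, 2 replicates, 10,000 background adenosines, 10,000
rank-sum null draws), which a scientist can rerun on a laptop in seconds;
all sizes scale up through `SimulationConfig`.

## Known limitations

* The peak caller reports hard-threshold calls only; there is no FDR
  control, by design of the procedure it implements.
* Persistent-A calling cannot separate m⁶A from structured adenosines
  without a demethylase-treated branch, which is out of scope.
* bedGraph loading assumes non-overlapping intervals per position (last
  value wins); genomic projection of peaks assumes non-overlapping
  transcripts, which holds for generated data but may not for real
  annotations with nested genes.
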