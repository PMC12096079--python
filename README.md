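# stoch-m6a

Tools for asking whether N6-methyladenosine (m⁶A) in bacterial mRNA is
written by a sequence-specific enzyme or deposited stochastically. The
package implements the two complementary detection methods used to address
that question and the comparative statistics that connect them:

* **Antibody-enrichment peak calling (m⁶A-seq / MeRIP-seq).** For each
  transcript, a 50-nt sliding window (step 25 nt) is scored with the
  *peak-over-median* statistic, POM = mean window coverage / median
  transcript coverage. Windows with mean coverage < 10 or POM < 3 are
  discarded, windows enriched in both the IP and the matched input library
  are discarded as shared regions, and survivors are scored with
  *peak-over-input*, POI = POM_IP / POM_input. Windows with POI > 3 are
  coalesced into peaks, replicate peak sets are merged by interval union,
  and peaks can be restricted to those containing one of the bacterial m⁶A
  motifs (GCCAU, UGCCAG, CAGAUC; exact matching on the sense strand).
* **Deamination-based base-resolution calling (eTAM-style).** A deaminase
  converts unmethylated A to inosine (read as G); a reference adenosine is
  called a *persistent A* when its pileup has depth ≥ 20 and ≥ 50% of
  reads still support A. Without a demethylase-treated control, persistent
  A = m⁶A ∪ structured adenosines, and the caller documents itself as such.
* **Comparative statistics.** Replicate concordance
  (% shared = 100·|A∩B|/|A∪B|), peaks-encompassing-sites cross-method
  concordance, 10-bin metagene motif-ratio profiles with a two-sided
  Mann–Whitney test between conditions, RPKM expression tertiles, log₂
  fold-change (±1) differential-expression flags with Pearson correlation,
  and precision/recall against planted ground truth.
* **A synthetic-data generator** that plants enrichment windows (each
  centred on a motif) and persistent-A sites — including two
  always-persistent control positions mimicking the 23S rRNA m⁶A sites at
  positions 1618/2030 — so the whole pipeline is testable end to end with a
  machine-readable truth table.

The package is aimed at epitranscriptomics researchers who have per-base
coverage tracks (bedGraph), annotation (GFF3), sequences (FASTA) and
per-site pileup/count tables (TSV), i.e. everything downstream of read
mapping.

## Worked example

Simulate a small study, call peaks and persistent sites, and check
concordance:

```sh
stoch-m6a simulate --outdir sim --seed 7 --n-transcripts 200 \
    --planted-peak-count 50
stoch-m6a callpeaks --ip sim/ip_rep1.bedgraph --ip sim/ip_rep2.bedgraph \
    --input sim/input_rep1.bedgraph --input sim/input_rep2.bedgraph \
    --gff sim/annotation.gff3 --fasta sim/transcripts.fa --outdir peaks
stoch-m6a etam-call --pileup sim/etam_pileup_rep1.tsv \
    --pileup sim/etam_pileup_rep2.tsv --outdir etam
stoch-m6a concordance --peaks peaks/peaks_unfiltered.tsv \
    --sites etam/sites_rep1.tsv --outdir conc
```

The same analysis through the library:

```python
>>> import stoch_m6a as sm
>>> cfg = sm.SimulationConfig(seed=7)
>>> ann, seqs, truth = sm.simulate_transcriptome(cfg)
>>> cov = sm.simulate_coverage(ann, truth, cfg)
>>> reps = [sm.call_peaks_all(cov[("IP", r)], cov[("input", r)])
...         for r in ("rep1", "rep2")]
>>> final = sm.filter_peaks_by_motif(sm.merge_replicates(reps), seqs)
>>> m = sm.peak_recovery_metrics(final, truth)
>>> print(f"precision {m.precision:.3f} recall {m.recall:.3f}")
precision 1.000 recall 1.000
```

At the default study conditions (50 planted single-window peaks at 8-fold
IP enrichment over a mean input depth of 20×, two replicates) the caller
recovers every planted peak with no false positives; with the enrichment
factor set to 1 it calls essentially nothing (the printed numbers above are
actual output).

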