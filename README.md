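# riteseq

Histone turnover from pooled barcode-ChIP sequencing.

## The problem

In a RITE (Recombination-Induced Tag Exchange) pulse-chase, Cre-mediated
recombination swaps the epitope tag on the sole histone H3 gene from HA to
T7, so chromatin-bound "old" histones carry HA and newly deposited "new"
histones carry T7. Crossing the RITE histone into a pooled yeast
deletion-mutant library and arresting the pool in G0 lets replication-independent
**histone turnover** be read out per mutant in one experiment: ChIP against
each tag enriches chromatin, and the strain-identifying UpTag/DownTag
barcodes of the deletion collection report how much of each strain's
chromatin came down with old vs. new histone. The per-clone statistic is the
ratio of new over old ChIP signal at the barcode,

    ratio(tag, t) = RPM_T7(tag, t) / RPM_HA(tag, t),      t = 1, 3 days

computed for both barcodes (UpTag, DownTag) and both chase timepoints,
where RPM is reads per million within one (tag × indexed sample) bin.

`riteseq` is for computational biologists running or reanalyzing such
pooled chromatin screens: it implements the complete computational path
from multiplexed FASTQ to filtered per-clone turnover calls, plus a
ground-truth simulator so every stage is testable without real data.

## What the pipeline does

1. **Demultiplex** — the first 4 nt of each read must match a sample index
   exactly (optionally also the next two primer bases).
2. **Tag classification** — UpTag vs. DownTag amplicon by Hamming distance
   to the common primers U1 (18 nt) / D1 (17 nt).
3. **Barcode matching** — exact 11-nt seed lookup at the expected barcode
   anchor (offset 22 for UpTag, 21 for DownTag, jitter ±1); unmatched reads
   fall back to optimal local alignment, admitting only alignments of
   length ≥ 10, identity ≥ 90%, starting within 2 bases of the anchor and
   ending ≤ 5 bases before the barcode's 3′ end. Ties are reported as
   ambiguous, never guessed.
4. **Quantification** — RPM per bin, T7/HA ratios, then three filters:
   clones missing either barcode; clones whose UP/DOWN count ratio is
   extreme against the empirical null built from **decoy** (unused) barcode
   pairs (two-sided empirical p < 0.01 in any sample); and a concordance
   filter keeping only clones whose four ratios agree (sample SD < 0.17).
   HA-only and T7-only constitutive control strains report the screen's
   separation and dynamic range.
5. **Simulation** — multinomial read sampling per sample from per-clone
   abundances and new-histone fractions, with substitution (and optional
   indel) errors, decoy reads, switch-failure and tag-discordant clones.

## Worked example

```python
import riteseq as rs

catalog  = rs.make_catalog(n_strains=20, n_decoys=100, seed=7)
sheet    = rs.default_sample_sheet()        # HA/T7 at t0, t1, t3 + input
primers  = rs.PrimerSet()
manifest = rs.make_manifest(catalog, sheet, seed=7, depth=50_000, error_rate=0.01)

reads, truth = rs.simulate_reads(catalog, manifest, sheet, primers)
counts, stats = rs.process_reads(reads, catalog, sheet, primers)
print(f"assigned {stats.assigned}/{stats.total} reads "
      f"({100*stats.assigned_fraction():.2f}%)")

result = rs.quantify_screen(counts, sheet)
print(result.summary())

per_clone, summary = rs.parameter_recovery_report(
    result.records, truth, manifest, catalog, sheet)
print(f"recovery: rmse={summary['rmse_vs_expected']:.4f} "
      f"coverage(3SE)={summary['coverage_3se']:.2f}")
```

prints

```
assigned 335675/350000 reads (95.91%)
clones: 20, included: 15
exclusions: SD_FILTER=5, none=15
controls: neg_mean=0.0000 pos_mean=466366.71 dynamic_range=55969285863.6 separated=True
concordance r: up_t1_vs_down_t1=0.989, up_t3_vs_down_t3=0.990, up_t1_vs_up_t3=0.913, down_t1_vs_down_t3=0.924
recovery: rmse=0.0314 coverage(3SE)=1.00
```

At 1% per-base error about 4% of reads lose their index (4 nt, zero
mismatches allowed) and the rest assign almost completely, most through the
exact seed and the remainder through the alignment fallback. The SD < 0.17
concordance filter removes the T7-only control (its ratio is huge and
noisy by construction) and clones whose turnover changed too much between
t1 and t3; UpTag and DownTag ratios of the surviving clones agree with
r ≈ 0.99. Estimated mean ratios sit within 3 binomial standard errors of
the measurement-model expectation for every evaluable clone here. The
astronomical dynamic range reflects that the simulator models no
non-specific ChIP background (see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
riteseq simulate --out sim --seed 7 --depth 50000
riteseq count    --catalog sim/catalog.tsv --sample-sheet sim/sample_sheet.tsv \
                 --primers sim/primers.yaml --fastq sim/reads.fastq --out counts
riteseq quantify --catalog sim/catalog.tsv --sample-sheet sim/sample_sheet.tsv \
                 --counts counts/counts.tsv --decoy-counts counts/decoy_counts.tsv \
                 --out turnover
```

`turnover/` then holds `turnover.tsv` (per-clone ratios, SD, inclusion and
exclusion reasons), `qc.json` (control separation, concordance
correlations, decoy-null summaries, bin totals) and diagnostic plots.

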