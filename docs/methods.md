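# Methods

## Measurement model

Each clone *i* in the pooled screen carries an abundance weight
*a<sub>i</sub>* (its representation in the pool), a tag-switch efficiency
*e<sub>i</sub>* ∈ [0,1] and a new-histone fraction *f<sub>i</sub>(t)* ∈
[0, *e<sub>i</sub>*] at chromatin near its barcodes at chase timepoint *t*
(*f* is monotone non-decreasing in *t*; cells that never switched tags
cannot deposit new-tag histone, which is how a recombination-failure clone
depresses its apparent turnover). ChIP against the old (HA) or new (T7)
tag pulls a clone's barcode in proportion to

| sample | expected read weight of clone *i* |
|---|---|
| HA ChIP at *t* | *a<sub>i</sub>* (1 − *f<sub>i</sub>(t)*) |
| T7 ChIP at *t* | *a<sub>i</sub>* *f<sub>i</sub>(t)* |
| input | *a<sub>i</sub>* |

and sequencing each indexed sample is one multinomial draw at the
configured depth over all barcodes (both tag kinds plus decoys).

Counts are normalized to reads per million (RPM) within each
(tag kind × sample) bin, and the turnover statistic is

ratio(tag, t) = (RPM<sub>T7</sub> + pc) / (RPM<sub>HA</sub> + pc),

with pseudocount pc = 0.5 RPM. Under the model the expectation is
(*f*/(1 − *f*)) · *C<sub>t</sub>* where
*C<sub>t</sub>* = Σ*a*(1 − *f*) / Σ*a f* is a per-timepoint pool factor:
relative-abundance sequencing measures turnover only up to a common scale,
which is why screens of this design report ratios relative to controls or
a reference strain. `parameter_recovery_report` therefore scores estimates
against the model expectation (including *C<sub>t</sub>*), with
delta-method binomial standard errors computed from the expected bin
shares and depths; the weak multinomial covariance between bins within a
sample is neglected.

## Read model and matching

Reads are `index(4) + U1(18) or D1(17) + barcode(≤20) + downstream
context`, so barcodes anchor at 0-based offset 22 (UpTag) / 21 (DownTag);
anchors are recomputed if non-standard primers are supplied. Internally
all coordinates are 0-based half-open; user-facing reports are 1-based.

* **Index**: exact 4-nt match; optional strict mode also requires the next
  two bases to begin U1 or D1. N never matches anything, anywhere.
* **Tag**: Hamming distance to U1 and D1 over the primer span, at most 2
  mismatches, strictly smaller distance wins; ties or over-budget reads
  are TAG_AMBIGUOUS. The distance threshold is a pinned choice (the assay
  defines no value); positions past the read end count as mismatches.
* **Exact path**: the read segment at anchor+j (j = 0, +1, −1, in that
  order; first offset with any hit wins) must equal a barcode's
  min(11, len) prefix with zero mismatches. Multiple hits at one offset
  are BARCODE_AMBIGUOUS.
* **Fallback**: optimal local alignment (match +1, mismatch −1, gap −2
  linear — pinned scores; the published constraints do the real filtering)
  between the window starting 2 bases before the anchor and each same-tag
  barcode. A candidate is admissible iff one of its *optimal-score*
  alignments has ≥ 10 columns, identity (matches/columns) ≥ 0.90, read
  start within ±2 of the anchor, and ends ≤ 5 bases before the barcode
  3′ end. All co-optimal alignments are enumerated because they can differ
  in identity and end position exactly at these boundaries (e.g. trimming
  a terminal mismatch preserves the score but drops identity below 90%).
  The best admissible candidate wins by (identity, then alignment length);
  remaining ties between strains are BARCODE_AMBIGUOUS. Decoy barcodes
  compete on equal terms — false assignment to them is the quantity the
  error calibration measures.

Every read lands in exactly one outcome (ASSIGNED, NO_INDEX,
TAG_AMBIGUOUS, TOO_SHORT, NO_BARCODE, BARCODE_AMBIGUOUS); the partition
identity is asserted across the test suite. Matching is deterministic and
ignores base qualities. A numba-compiled kernel scores all candidate
barcodes per read and a provable score bound (an admissible alignment
scores ≥ min_len·(3·min_identity − 2)) shortlists candidates before the
exact co-optimal enumeration; neither shortcut changes results, which the
suite checks against an independent exhaustive alignment enumerator and
against Biopython's aligner scores.

## Filters

Applied in order; the first failing filter is recorded as the exclusion
reason.

1. **MISSING_TAG** — both barcodes must be identified (a tag with zero
   reads across the four ChIP design samples, or absent from the catalog,
   is unidentified).
2. **DECOY_OUTLIER** — for every indexed sample, log₂(UP RPM / DOWN RPM)
   (pseudocounted) of each clone is compared against the empirical
   distribution of the same statistic over decoy pairs; a clone with
   two-sided empirical p < α = 0.01 in *any* sample is excluded. The
   p-value is the plain empirical proportion
   p = min(1, 2·min(#{null ≤ x}, #{null ≥ x})/n) — with a continuity
   correction the smallest attainable p over a ~100-pair decoy set would
   exceed 0.01 and the filter could never fire. The filter deactivates
   (with a warning) below 20 decoy pairs.
3. **SD_FILTER** — the sample SD (n−1 denominator) over the four ratios
   (UpTag/DownTag × t1/t3) must be < 0.17. SD is computed on linear
   ratios; whether the original cutoff was applied on a transformed scale
   is not documented, so the threshold is a parameter (`max_sd`).

Zero-HA cells are rescued by the pseudocount and flagged (`zero_ha`)
rather than dropped; with pseudocount 0 they would be infinite and are
excluded as ZERO_DENOMINATOR. Input and pre-switch (t0) samples flow
through counting and the decoy filter but never enter the turnover ratio.
The mean of the four ratios (plain mean; no alternative weighting is
documented) is the clone's reported turnover.

## Simulator

Defaults emulate the screen's stated conditions: 20 strains including one
HA-only and one T7-only constitutive control and one switch-failure clone
(e = 0.05); 100 decoy pairs; log-normal abundances (σ = 0.5);
*f*(t1) ~ U(0.05, 0.35) with an increment U(0.02, 0.12) by t3 and
*f*(t0) = 0; per-base substitution rate 1%; decoy read share 0.2%
(index hopping / chimeric amplification at a single rate, no PCR
mechanism); read length 50 nt so a full 20-nt barcode fits behind the
index and primer; single-nucleotide indels available but off by default
(the gapped aligner path is exercised by dedicated fixtures instead).
Discordant clones — UpTag and DownTag reporting different truths, as a
barcode-specific artifact would — are injected on request by offsetting
the DownTag ratio by 0.45 (beyond twice the SD cutoff). Everything is
deterministic per seed, to the FASTQ byte.

Deliberately not modeled (so passing tests bound only what they test):
non-specific ChIP background or antibody cross-reactivity — hence the
simulated control dynamic range is astronomically larger than any real
screen's; ChIP efficiency biases; locus-level turnover heterogeneity
within a clone; growth competition (the assayed pool is G0-arrested).
Real data would also carry quality-correlated and context-dependent
errors rather than i.i.d. substitutions.

## Statistical checks and problem sizes

The acceptance suite runs a 100-seed Monte-Carlo batch (20 strains, 100
decoy pairs, 4 ChIP samples, 2×10⁴ reads/sample, 1% errors, two
discordant clones) and checks: ≥ 95% of ordinary clones within 3
propagated binomial SEs of expectation; discordant clones removed by the
SD filter in ≥ 90% of runs; the switch-failure clone below the pool
median ratio in ≥ 95% of runs; control separation in ≥ 99% of runs; and
the conservation/normalization identities in every run. Recovery RMSE is
shown to decrease monotonically over depths 2×10³ → 1.6×10⁴ → 1.28×10⁵
(6 seeds each). The noiseless round trip uses the full 7-sample design at
10⁵ reads/sample. These sizes are the package's chosen study conditions;
the thresholds are fixed first and the simulations sized to make the
checks statistically decisive.

## Known limitations

* The catalog carries one sequence per (strain, tag); variant barcode
  sequences from re-sequenced collections must be resolved upstream.
* Tag classification is primer-based; amplicon pools sequenced in
  separate lanes would instead classify by lane, which is not modeled.
* The decoy null is empirical and unsmoothed; with few decoy pairs its
  p-values are coarse (the filter therefore requires ≥ 20 pairs).
* Pearson concordance excludes control strains by default; including
  them would saturate r toward 1 through their extreme ratios.
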