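# Methods

## Problem

Ion-semiconductor sequencing estimates homopolymer length from the signal
of a single nucleotide flow, so its error rate rises steeply once a run of
identical bases exceeds five repetitions. In a tumour-first BRCA1/2 testing
workflow this produces a blind spot: a real germline frameshift inside a
coding homopolymer can be filtered away by the variant caller and the
patient reported tumour-negative. `hpaudit` implements a systematic audit
of that blind spot: enumerate every coding homopolymer of ≥ 6 bp in BRCA1/2,
measure per-sample insertion and deletion VAFs directly from the aligned
reads at each region, and flag samples whose VAF is an outlier relative to
a control population.

## Region catalogue

`regions.find_runs` scans a coding sequence for maximal runs of one base
with `min_length = 6` (the default reflects the consensus that accuracy
drops sharply beyond five repetitions; the parameter is exposed).
BRCA2 runs starting downstream of c.9976 are excluded because truncating
variants beyond codon 3326 are not considered high-risk; the cutoff is
inclusive-keep (`cds_start <= 9976` retained). Coding coordinates are
lifted to GRCh37 through an exon structure; all 29 catalogued runs
(5 in BRCA1, 24 in BRCA2) are intra-exonic, and runs spanning a splice
junction are rejected rather than guessed at. The shipped catalogue
(`data/brca12_homopolymers_grch37.tsv`) carries 1-based inclusive
coordinates with the run base in coding-strand sense (BRCA1 is
minus-strand; complement for the genomic strand). One genomic end
coordinate (BRCA2 c.988_994) is derived from the 7-bp coding interval via
same-exon offset arithmetic; the loader validates every row (coding span,
genomic span and stated length must agree) and refuses inconsistent
catalogues rather than correcting them silently.

## VAF extraction

`vaf_extraction.count_indels_at_region` is an explicit CIGAR-walk pileup
over a region *footprint* = one flank base immediately 5' of the stretch
plus the run itself. Per footprint position it tallies reads opening an
insertion there, reads deleted there, and depth (reads aligned or deleted
at the position, as recorded in the alignment). Because a 1-bp indel
inside a homopolymer has many equivalent alignments, every indel event is
left-aligned against the reference before tallying: insertions shift to
open after the 5' flank base, deletions to start at the first run base.
The per-region summary is

    vaf_ins = max_p ins_reads[p] / anchor_depth
    vaf_del = max_p del_reads[p] / anchor_depth

where the anchor is the first base of the stretch — the same numbers a
reviewer reads off a genome-browser pileup at the run start. Using the
per-position *maximum* (not a sum) matches that manual counting convention
and is the only supported mode; the per-position arrays are retained on
the `PileupCounts` object for audit. A read carrying both an insertion
and a deletion in the footprint increments both tallies.

Read filters: duplicates, secondary, supplementary and QC-fail alignments
are excluded; `mapq_min = 1`, `baseq_min = 0`. These mirror a browser's
default view; whether a manual audit would include soft-clipped or
low-mapq reads is a judgement call, so both knobs are configurable rather
than asserted. Regions with anchor depth < 100 are not evaluable. No
downsampling is applied.

## Outlier model

Background indel VAFs at homopolymers are small, strictly positive and
heavily skewed, so per-(region, type) cells are normalized by robust
standardization in the COPA tradition:

    z_i = (x_i − median(x)) / (1.4826 · MAD(x))

fitted on the 46-sample control cohort (patients with an already-identified
extra-homopolymer pathogenic variant — LOH, not a second point mutation, is
the typical second hit, so their homopolymers are presumed wild-type; no
iterative control cleaning is done). The decision threshold is
`mu + k·sigma` with `k = 3`, where `mu` is the mean and `sigma` the
1.4826·MAD of the *normalized* control values (`sigma = 1` by construction
whenever MAD > 0; `mu` absorbs the skew). A study sample's VAF is projected
through the control centre/scale and flagged when its z exceeds the
threshold. Candidates must additionally pass

* `vaf >= 0.15` (boundary kept),
* `vaf > max(control VAFs)` for the cell (strict),
* anchor depth `>= 100`.

A call is validated only when all four flags hold; the full near-miss audit
table is always emitted. Insertions and deletions are modelled as separate
distributions per region. Degenerate cells (MAD = 0 or < 3 evaluable
controls) waive the z filter and rely on the raw filters alone, logged.

With thresholds held fixed, raising `min_vaf`, `min_depth` or `k_sigma`
never increases the validated-call count (tested). Note the caveat:
`min_depth` also gates which control records enter the *fit*, so refitting
at a different `min_depth` changes the thresholds themselves and the
end-to-end count need not be monotone.

An alternative normalization, `rank-int`, applies a Blom rank-based
inverse-normal transform (offset 3/8, average ranks for ties) to the
controls. Projecting a study value by inserting it into the control ranks
would cap the achievable score at Φ⁻¹((n+0.625)/(n+1.25)) ≈ 2.2 for
n = 46 — below any μ+3σ threshold — so the projection instead uses the
monotone piecewise-linear map from control values to their normal scores,
extrapolated linearly beyond the control range. Robust-z is the default;
on clear outliers the two modes agree (tested).

Sample evaluability: a study sample is dropped from the prevalence
denominator when more than `max_failed_regions` (default 0) of its regions
fall below 100X — with the default, any failing region excludes the
sample.

## Prevalence and reporting

Prevalence = (study samples with ≥ 1 *confirmed* validated call) /
(evaluable study samples), with the headline percentage rounded half-up to
one decimal (1/155 → 0.6%). Confirmation status comes from an external
assay (e.g. Sanger) supplied as a table; the package does not model the
confirmation itself. A Wilson 95% interval is attached as a package
extension — the audited procedure defines only the point estimate. The
report emits a per-call table with display-only HGVS-style labels
(3'-most run position per the HGVS 3' rule, `dup` for insertions) and a
JSON run summary with counts, config hash and seed. Distribution
summaries per region × type × cohort use linearly interpolated quartiles
and Tukey 1.5·IQR whiskers clamped to the observed range, with outlying
(sample, VAF) points listed; `plot_distributions` renders the
control-vs-study boxplots.

## Synthetic cohorts

The generator's defaults are the audited study conditions: 46 controls,
157 study samples, per-sample median depth uniform on 1045–6989X with
log-normal (σ = 0.35) spread across regions, a 1% chance per region of
dropping below 100X, and one injected germline carrier. Carrier tumour
VAF is truncated-normal(0.5, 0.05) on [0, 1]; with probability 0.3 the
carrier has LOH and the mean lifts to uniform(0.70, 0.90), reflecting that
known germline homopolymeric variants present at tumour VAF ≥ 50% and up
to ~86%. Controls are carrier-free by construction.

Background VAFs are Beta-distributed per (region, type) with mean
`m(L) = min(0.015·(L−4), 0.12)` (insertions scaled by 0.6) — error grows
with run length — and variance `φ·m·(1−m)`. Two presets:

* **clean** (default), φ = 1/301 (concentration 300): the worst cell
  (8-mer deletions, mean 0.06) has P(VAF > 0.15) ≈ 4·10⁻⁷, so a
  carrier-free cohort is expected to produce essentially no validated
  calls (tested: ≤ 0.1 per cohort over 100 seeds) and carrier recovery is
  clean.
* **heavy**, φ = 0.25 (concentration 3): P(VAF > 0.15) reaches ~0.13 per
  draw, a deliberately extreme regime in which the cascade nominates many
  false outliers — the qualitative point that statistical nomination
  without orthogonal confirmation is not a diagnosis.

Observed VAFs are binomial draws at the realized depth, so sampling noise
scales correctly with coverage. A single seed drives everything;
per-sample substreams are spawned by counter, so cohorts are reproducible
under reordering.

What the generator does *not* emulate: flow-space/ionogram signal, strand
bias, FFPE artefacts, indel-length spectra beyond 1 bp at read level, and
correlations between regions within a sample. Passing tests therefore
demonstrate the pipeline's arithmetic and its statistical behaviour under
the stated model, not caller performance on real ion-semiconductor data.

Read-level fixtures (`simulate_reads`, `write_fixture_bundle`) place each
region on its own small contig (run flanked by a 4-base cycle, boundary
bases forced off the run base) and emit reads with explicit left-aligned
1-bp CIGAR indels, the event category recorded in each read name as a
truth ledger; the pileup must recover the ledgered counts exactly
(tested). The benchmark cohort used by `analysis/04_prevalence_report.py`
injects seven fixed candidate VAFs (five study outliers in four samples;
two upfront-tested germline variants at 75.80%/85.87%) over the clean
background, plants two study samples with 9 and 16 sub-100X regions,
and reproduces the 0.6% (1/155) prevalence arithmetic end to end. The
synthetic coding-sequence fixtures used for region-discovery demos are
labelled synthetic: real run positions planted in a cycle filler, plus a
decoy BRCA2 run downstream of c.9976 so the inclusion policy is exercised.

## Numerical choices

* MAD consistency constant 1.4826 throughout.
* Rounding of headline percentages: decimal half-up (never banker's).
* Quartiles: linear interpolation (numpy default).
* Boundary conventions: `vaf >= 0.15` kept, `vaf > control max` strict,
  `depth >= 100` kept, BRCA2 cutoff `cds_start <= 9976` kept.
* Zero depth yields missing VAFs, never zero.
* Left-shift of an indel stops at a reference window edge or an `N`.

## Problem sizes in the test suite

The default suite simulates cohorts at the full 203-sample × 29-region
scale (cheap, as the matrix-level generator is vectorized) and uses 100
seeded replicates for the null-calibration and sensitivity properties;
read-level checks use 100 randomized read sets of 25 reads and bundles of
5 samples × 29 toy contigs at 150–200 reads per region. These sizes were
chosen to make the statistical assertions sharp while keeping the whole
suite under a minute of compute.

## Known limitations

* The catalogue is fixed to BRCA1/2 GRCh37 coordinates; other genes or
  builds require a user-supplied catalogue or gene models.
* The pileup counts 1-bp-resolution events; multi-base indels are counted
  at their left-aligned positions but their length spectrum is not
  modelled.
* The rank-INT projection's tail extrapolation makes extreme-value scores
  depend on the spacing of the top control values; robust-z is the
  recommended default.
* Prevalence confidence intervals assume independent samples and exact
  confirmation status.
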