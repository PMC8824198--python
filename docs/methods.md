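# Methods

`scgscreen` implements the computational screening steps around
single-amplified genomes (SAGs) obtained by flow-sorting individual
bacterial cells, amplifying each genome by multiple displacement
amplification (MDA), and screening wells by 16S rRNA gene V4 amplicon
sequencing before committing cells to shotgun sequencing. This note
records the models, conventions and numerical choices behind each stage,
and what the synthetic-data generators do and do not emulate.

## Amplification-curve QC (`mda_curves`)

**Model.** MDA of a successfully deposited cell produces a sigmoidal rise
in SYBR Green fluorescence; empty wells stay flat. Each well's trace
(a reading every 3 minutes over 7.5 h, 151 points) is fit by least
squares (`scipy.optimize.curve_fit`) to a four-parameter logistic

    f(t) = baseline + amplitude / (1 + exp(-rate * (t - midpoint)))

with `rate` (per minute) playing the role of the amplification rate
constant k. The four-parameter logistic is the simplest sigmoid with an
identifiable rate; no baseline drift or multi-phase amplification is
modeled.

**Initialization and bounds.** baseline = min(values), amplitude =
max - min, midpoint = half-rise time of a 5-point moving-average
smoothed trace, rate = 0.05/min; bounds rate in [0, 10] and amplitude
>= 0. These start values are robust on flat, saturated and partially
risen traces.

**Degenerate fits.** A fit is declared non-sigmoidal (`converged=False`)
when any of these holds:

- the optimizer fails;
- the observed value range is zero (exactly constant trace);
- amplitude < 5% of the observed value range;
- amplitude < 5 x the residual RMS;
- the fitted midpoint lies outside the sampled time window.

The signal-to-noise floor (5 x residual RMS, `FitConfig.min_amplitude_snr`)
is essential: on a noise-only trace the observed range is itself noise, so
a range-relative floor alone admits steep fits that ride a single noise
excursion and carry arbitrarily large rates. Requiring the fitted rise to
dwarf the residual scatter removes these while leaving genuine curves
(amplitude ~ 100 x noise sd at 1% noise) untouched. With this rule the
amplified/flat call attains sensitivity and specificity 1.0 on 200
synthetic wells at 1% noise (see `scripts/acceptance.py`).

**Amplified call.** A well is called amplified iff the fit converged and
`rate >= k_min` with `k_min = 0.1`/min, boundary inclusive.

**Threshold time.** Reported as the time the fitted curve first reaches
baseline + 10% of amplitude, which has the closed form
`midpoint - ln((1-f)/f)/rate` (f = 0.1, so `midpoint - ln(9)/rate`). The
10% convention is a package choice (the fraction is configurable); the
inflection time is recovered with f = 0.5.

**Association with PCR outcome.** Wells are cross-tabulated as
(sigmoidal vs flat) x (16S PCR positive vs negative) and tested with
Fisher's exact test; the two-sided p sums hypergeometric probabilities of
all tables with the observed margins that are no more probable than the
observed table, and the conditional maximum-likelihood odds ratio is
reported. Both are delegated to `scipy.stats`; the test suite checks the
p-value against an explicit hypergeometric enumeration for every 2x2
table with total <= 30.

## Single-cell ASV triage (`asv_filter`)

A well that truly received one cell should be dominated by a single
amplicon sequence variant (ASV) that exactly matches the bulk community
profile of the same sample. Cells are classified in this fixed order:

1. **MIXTURE** — no ASV reaches the dominance threshold (>= 70% of the
   well's amplicon reads, boundary inclusive, configurable). Evaluated
   first, so a mixed well dominated by a contaminant genus counts as a
   mixture.
2. **PASS** — the dominant ASV is character-identical (case-insensitive,
   equal length, no N-tolerance, no reverse complement — amplicons share
   orientation) to a community ASV.
3. **CONTAMINANT** — the dominant ASV is absent from the community and
   its genus is on a user-supplied kit-contaminant ("kitome") list. No
   list is hard-coded.
4. **RARE_UNMATCHED** — everything else: plausible rare taxa missed by
   community profiling. A missing genus label at step 3 falls through to
   this category with a logged warning.

Ties in the dominance test break to the lexicographically smallest ASV
id. Report percentages round half-up to one decimal; the failure-category
percentages use the failing cells (positives minus passes) as
denominator, which is the only reading that reproduces the published
flowchart arithmetic (e.g. 260/395 = 65.8%).

**Plate accumulation.** Unique-ASV counts are computed for the union of
every combination of plates at every subset size; an exhaustive sweep is
refused above 20 plates unless a seeded per-size subsample of
combinations is requested.

## Coverage profiling (`coverage_profile`)

- **Breadth and depth.** Breadth = percent of reference positions with
  depth >= 1 (configurable); mean depth is over all positions. Depth
  tables are the samtools-depth dialect (reference, 1-based position,
  depth), with omitted zero-depth positions filled in on read.
- **Pileup and rarefaction.** Rarefaction operates on mapped-read
  intervals (BED, 0-based half-open): reads are drawn uniformly without
  replacement at each requested count, 10 replicates by default, and
  breadth is recomputed from the pileup. Because a fixed read maps
  deterministically, subsampling placements reproduces the
  subsample-and-remap statistic without re-running an aligner.
- **Gain rate.** Breadth gain in percentage points per 1000 additional
  reads, rounded to 2 significant figures for reporting (a 20.5-point
  gain from 100,000 to 1,000,000 reads is 0.023 %/1000 reads).
- **Feature-relative depth.** Mean depth over each feature class (16S
  rRNA genes, oriC) divided by the mean depth of the background
  (positions outside every feature); normalization by the genome-wide
  mean is available as a config alternative. Group tables are emitted for
  stock ANOVA/Tukey routines; the tests themselves are not re-implemented.
- **Read partition.** Hierarchical assignment fractions (reference
  genome, then pangenome, then protein classifier, remainder
  unclassified); stages consume only still-unassigned reads and the
  fractions sum to exactly 1.
- **Theoretical coverage.** n_reads x read_len / genome_len.

## CTn network (`mge_network`)

- **Percent length aligned (PLA).** For an ordered contig pair, hits'
  query intervals are strand-normalized to (min, max), converted to
  closed 1-based intervals, merged (overlapping or adjacent), and summed;
  directional PLA(a->b) = 100 x merged length / len(a). The pair value is
  the maximum of the two directions — the denominator and the
  combination rule are package conventions (min/mean exposed in config),
  chosen liberal to mirror the reciprocal-search framing.
- **Graph.** Every contig is a node; an edge with weight PLA is added iff
  PLA >= 20 (inclusive). Self-hits are discarded. No identity or e-value
  pre-filters by default.
- **Markov clustering.** Native dense-matrix MCL with inflation 2,
  expansion 2: self-loops with weight equal to each node's maximum
  incident edge weight (1 for isolated nodes), column normalization, then
  alternating matrix power and entrywise power + renormalization, pruning
  entries below 1e-5, until the max-norm change falls below 1e-6 (at most
  200 iterations; non-convergence is flagged on a still-usable partial
  result). Clusters are read off attractor rows (positive diagonal mass);
  attractors claiming a common node merge; fully pruned columns become
  singletons. Nodes are ordered lexicographically, so the partition is
  deterministic. Edges carry PLA weights (not binarized) into MCL;
  whether to binarize is genuinely open, and weighting was chosen to
  preserve similarity information — cluster granularity can differ from a
  binarized run. The implementation is verified against an independently
  written dense MCL on random graphs and against planted-partition
  fixtures.

## Prophage regions (`phage_regions`)

Predictions are grouped by best-protein-hit accession (case-sensitive
exact key); each group's representative is the contig with the longest
predicted phage region (ties to the smallest contig id). Host-genome
nucleotide hits are significant iff identity > 98% AND length > 14 kb
(both strict, applied per hit, not per merged span). Significant regions
are extended by 5 kb of flank, clipped at sequence ends. Coverage curves
are normalized to reads-per-million total sample reads (the per-million
scale is a package convention). Within-group average nucleotide
identities are consumed from an upstream ANI tool's matrix (symmetry
enforced within 0.1), never recomputed.

## Synthetic data (`fixtures`)

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

- **Curves.** Amplified wells: logistic parameters drawn uniformly from
  baseline 800-1200 a.u., amplitude 3000-8000 a.u., rate 0.12-0.35/min,
  midpoint 150-340 min; flat wells: baseline only. Gaussian noise with sd
  = 1% of amplitude by default. Rates sit above the 0.1/min call
  threshold because the planted dichotomy is amplified vs flat, and
  midpoints put 10%-rise threshold times in the empirically observed
  100-300 min window.
- **ASV datasets.** Community ASVs are unique random 215-mers (the
  uniform trimmed V4 read length) with plausible gut genera; PASS cells
  reuse a community ASV at >= 70% abundance, CONTAMINANT/RARE_UNMATCHED
  cells are dominated by a fresh non-community ASV labeled with a listed
  contaminant genus or an unlisted genus respectively, and MIXTURE cells
  split reads between two community ASVs with the maximum below 65% (so
  integer rounding can never push them over the 70% boundary).
- **Read placements.** Uniform starts, or MDA-like bias: per-window
  lognormal weights (200 windows, sigma 1.5 by default) with starts
  sampled proportionally — reproducing patchy breadth; sigma -> 0
  recovers the uniform model.
- **CTn hit tables.** Within-cluster pairs get reciprocal hits covering
  80% of each query; cross-cluster pairs 5% (or none), so the PLA >= 20
  threshold separates planted clusters exactly.

**What the fixtures do not emulate** — real sequencing reads, chimeras,
basecall errors, chimeric ASVs, intragenomic 16S polymorphism, taxonomy
misassignment, or alignment artifacts. Passing tests therefore
demonstrate the correctness of the screening arithmetic and clustering
conventions on data satisfying each stage's assumptions, not robustness
to upstream noise sources.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 200-well curve batches at 1% noise, 100-replicate rate-recovery
studies, exhaustive Fisher enumeration to table total 30, 1000 fuzzed
interval instances, 50 random MCL graphs with up to 12 nodes, 4-plate
exhaustive accumulation, and triage cohorts of 723 and 664 cells with a
few hundred reads each. These sizes make every check exact or tightly
converged while keeping the full suite around a minute on one CPU.

## Known limitations

- The original sigmoid parameterization behind the published rate
  threshold is not fully specified upstream; our logistic `rate` is a
  declared convention, so the numerical meaning of the 0.1 cutoff may
  differ from the original instrument pipeline.
- PLA denominator/symmetrization and MCL self-loop, pruning and weighting
  conventions are package choices where the upstream description is
  silent; cluster counts on real data may differ under other conventions.
- The dominance filter reads "70% of total ASVs" as relative read
  abundance (the only reading consistent with a single dominant variant),
  not as a fraction of ASV richness.
- ANOVA/Tukey comparisons on depth and accumulation tables are left to
  stock statistical routines; this package emits the per-group tables.
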