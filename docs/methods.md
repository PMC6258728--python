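# Methods

## Scope and shape

`ximega` is a library-first package: the importable API plus the narrative
scripts in `examples/` are the primary interface, with a thin `ximega` CLI
for shell use. Six components cover the pipeline: `synthetic_data` (inputs
with ground truth), `matrix`/`matrix_io` (contact-matrix model, I/O,
balancing, correlation), `megadomain` (PC1 analysis and population
mixing), `insulation` (insulation scores, boundaries, variance tests),
`allelic` (peak/gene classification and distribution tests), `fourc`
(viewpoint profiles), and `pipeline`/`cli` (orchestration).

## Generative models

### Contact maps

The synthetic Xi contact map is built from a deterministic expected-value
matrix and an independent Poisson draw per upper-triangle cell (mirrored
to keep symmetry). For bins i, j the expectation is proportional to

    |i − j|^(−α) · (1 − t)^(#TAD borders strictly between i and j)
                 · (1 − s)   if i, j straddle the megadomain border,

scaled so the full-matrix total equals `total_reads`. The diagonal follows
the decay law at distance 1. Conventions: a TAD border `b` separates bins
`b−1` and `b`; the megadomain border bin belongs to the left domain.

Defaults model a chromosome-scale map at moderate depth: `n_bins = 100`
(≈ the X chromosome at 1–2 Mb bins), `bin_size = 1 Mb`, decay exponent
α = 1.0 (the canonical contact-probability scaling at Mb scales),
border bin 50 (mid-chromosome, as *Dxz4* sits mid-X), megadomain strength
s = 0.6 (strong but not saturating, so mixtures remain informative), and
`total_reads = 5e5` — the per-chromosome share of a 25–50 M read
genome-wide library. Capture-region analyses use `n_bins = 60` at 25 kb
with TAD borders at bins {10, 25, 33} and TAD strength 0.7; the residual
TAD strength of the Xi is not a measured quantity, so it is a free
parameter with these defaults.

Population mixtures are generated at the expected-count level:
`E_f = (1−f)·E(s=0) + f·E(s)`, then Poisson-sampled. Mixing aligned reads
from two libraries has exactly this expectation, so the linear-in-f
behavior of downstream statistics is preserved. `megadomain.mix_reads`
additionally offers read-level (multinomial) mixing of two observed maps.

What the generator does **not** emulate: fragment-level Hi-C chemistry,
distance-dependent noise correlations, translocations/CNVs, mappability
structure, or SNP-density variation in allele assignment. Passing tests
demonstrate correctness of the estimators under a clean count model, not
robustness to those artifacts.

### Allelic tables and 4C profiles

Each feature draws a Poisson total per replicate; allele-A (Xa) reads are
binomial with success probability `xa_skew` (default 0.95) for silenced
features and 0.5 for escape features (default escape fraction 0.05,
matching the observation that the large majority of X peaks/genes are
Xa-skewed). 4C profiles are Poisson draws around power-law decay peaks at
the viewpoint (and optionally an insertion site on a trans chromosome)
over a uniform background.

## Balancing

`kr_balance` implements the Knight–Ruiz inner–outer Newton iteration with
a conjugate-gradient inner solve (vector bounds 0.1/3 per outer step, eta
forcing sequence capped at 0.1). Convergence: squared residual of unit
row sums below `tol²` (default `tol = 1e-6`), at most `max_iter = 3000`
outer iterations, else a convergence error carrying the residual. Bins
with fewer than `min_nnz = 1` nonzero cells or raw row sum below 10 are
masked beforehand (an explicit stand-in for the masking interactive
browsers apply implicitly; recorded in output metadata). The balanced
matrix is rescaled so unmasked row sums equal the mean unmasked raw row
sum, keeping the count scale interpretable. `sqrt_vc_balance` divides each
cell by the square root of the product of its row and column sums, the
normalization used for capture-region maps.

## Correlation and PC1

Correlation cell (i, j) is the Pearson correlation of balanced rows i and
j restricted to unmasked columns *excluding columns i and j*; without that
exclusion the diagonal dominates and swamps the compartment-scale signal.
PC1 column-centers the unmasked correlation matrix and takes the leading
eigenvector of its covariance (centering rows vs columns is equivalent for
a symmetric matrix up to transposition; we center columns and fix the
convention here). The eigenvector has unit norm; its sign is oriented so
the mean score after the designated border bin is nonnegative, making
repeated runs byte-identical.

The sharp-transition statistic is |PC1 slope| divided by the pooled
root-mean-square of first differences within the flank windows (default 10
bins a side, threshold 3). The **uncentered** RMS is deliberate: a
megadomain-free map still yields a smooth PC1 curve whose local steps have
small variance but nonzero mean, and dividing by a centered SD would flag
every smooth gradient as a sharp border. Against the RMS of local steps, a
smooth curve scores ≈ 2 and a genuine border scores an order of magnitude
higher; a zero-noise step is reported at a cap of 1e12.

## Insulation

Window geometry for bin i with `w = square_span / bin_size` (default
125 kb, i.e. w = 5 at 25 kb): crossing contacts are the `w × w` square
`[i−w, i) × (i, i+w]`; same-side contacts are the upper triangles
(diagonal included — intra-bin contacts do not cross the locus) of the two
within-side `w × w` squares. The score is `log2(raw / mean(raw))`, the
mean taken over scored bins *after* masking (bins within w of the matrix
edge, within `edge_exclude_bins = 6` of the region edge, masked in the
balanced matrix, or with zero flank). Zero-crossover bins are masked with
a `zero_crossover` flag rather than scored −∞, keeping variance statistics
finite. A constant raw track is normalized to exactly zero (the ratio is
mathematically 1; computing it through the mean would leave ~1e-16
round-off). Raw ratios are scale-free, so tracks are invariant under
global rescaling of the matrix.

Boundaries are local minima within ± `delta_span/bin_size` bins (default
75 kb) whose depth — mean of the window's other scores minus the bin's
score — reaches `min_depth` (default 0.1); the full window must fit inside
the track, and ties break toward the lower index. The F-test on insulation
variance is two-sided (conservative when no direction is pre-specified)
with (n−1, n−1) degrees of freedom on unmasked scores.

## Allelic rules

`Xi:Xa ratio` denominates by `reads_Xa` (with r = +∞ when reads_Xa = 0);
the alternative Xi-share-of-total reading is available via the threshold
parameters. The boundary r = 1/3 goes to Xa-specific and r = 3 to
Xi-specific, with the open interval between them biallelic; records with
fewer than 10 allelic reads are `insufficient` (zero/zero never divides).
Restored-peak ratios compare reads-per-million within each (replicate,
genotype) library, since raw counts are not comparable across libraries
of different depth. The escapee filter sums allelic reads across
replicates per genotype (≥ 12 in every required genotype) and optionally
applies an `fpm` floor per replicate (default > 0; the fold-change CDF
comparison conventionally uses > 1 — both are exposed). Bonferroni
correction multiplies by the number of comparisons actually run in the
invocation. Statistical machinery (Wilcoxon signed-rank, Mann–Whitney,
two-sample KS, F distribution, OLS) comes from `scipy.stats`.

## 4C

Insertion localization scales to per-million, smooths with a running mean
(`smooth_bins = 3`), excludes the entire viewpoint chromosome by default,
and takes the global argmax; fold is signal over the median of positive
smoothed bins genome-wide excluding the candidate's own smoothed
neighborhood (so a lone peak is not its own background), with threshold 10
by default. There is no field-standard numeric cutoff for a "strong" trans
peak; the fold-over-median rule is this package's explicit criterion and
is surfaced in the output. Superloop enrichment is mean per-million signal
in a target bin interval over the mean of two flanking intervals;
"Xi-specific" requires the Xi profile to clear `min_fold = 3` while the
paired Xa profile stays below it. Repetitive-read tracks are a distinct
allele label, never merged into composite.

## Determinism and problem sizes

All sampling goes through `numpy.random.default_rng`; pipeline runs fan a
single seed out to stages via SHA-256 (`pipeline.derive_seed`, < 2³¹), so
any stage re-run in isolation is byte-reproducible. The test suite and
`scripts/acceptance.py` use desk-scale problem sizes — 100-bin chromosome
maps at 5e5 reads, 60-bin capture regions, 10-seed ensembles for recovery
rates, 100-seed ensembles for localization rates, 200 draws for test
calibration — chosen so the full suite completes in a few minutes while
keeping binomial noise on reported rates small relative to the margins
they are compared against.

## Known limitations

- The Pearson/PC1 step is O(n³) with a per-pair column exclusion; fine to
  a few hundred bins, not intended for genome-wide 5 kb maps.
- KR masking is a coverage heuristic (min 1 nonzero, row sum ≥ 10), not a
  reimplementation of any particular browser's undocumented rules.
- Multi-chromosome balancing, .hic binary output, loop (dot) calling,
  directionality index, and differential-expression fitting are out of
  scope; fold changes are consumed as inputs.
- The mixing analysis assumes megadomain strength is comparable across
  conditions; if the positive subpopulation's strength differs, the
  estimated fraction absorbs the difference (only relative strength is
  identifiable).
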