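# ximega

Analysis toolkit for allele-specific chromosome architecture of the
inactive X chromosome (Xi): megadomain quantification from Hi-C, insulation
scores and TAD boundaries from capture Hi-C, allele-specific ATAC/RNA
classification, and 4C viewpoint profiling — together with a synthetic-data
generator that emulates the statistical structure of every input, so the
whole pipeline runs and is testable with known ground truth and no external
downloads.

It is written for computational biologists studying X-chromosome
inactivation (XCI) in hybrid cell systems, where strain-specific variants
assign each read to the active X (Xa) or the inactive X (Xi).

## The statistics at the core

**Megadomain quantification.** The Xi folds into two multi-megabase
"megadomains" separated at the *Dxz4* locus. Given a binned contact matrix
`A`, the pipeline is: Knight–Ruiz balancing (find `x` with
`diag(x)·A·diag(x)` having equal row sums), Pearson correlation of the
balanced rows, then PCA. The first principal component (PC1) is
piecewise-constant with opposite signs over the two megadomains, so the
**PC1 slope** at the border bin `b`,

    slope = PC1[b+1] − PC1[b−1],

measures megadomain strength. In a mixed population the slope is linear in
the megadomain-positive cell fraction `f`; ordinary least squares of slope
on `f` supports estimating `f` for an unknown sample and the assay's
detection limit (smallest `f` whose predicted slope clears the `f = 0`
prediction by `k` residual SDs).

**Insulation.** For bin `i` and window `w` bins, the raw insulation score
is the ratio of contacts crossing `i` (one end in `[i−w, i)`, the other in
`(i, i+w]`) to contacts staying on one side; the reported score is
`log2(raw_i / mean(raw))`. TAD boundaries are local minima of the track;
the variance of the track over a region measures global insulation
strength and is compared between conditions with a two-sided F-test.

**Allelic classification.** With `r = reads_Xi / reads_Xa` and ≥ 10 allelic
reads: `r ≤ 1/3` → Xa-specific, `r ≥ 3` → Xi-specific, otherwise
biallelic. A wild-type Xa-specific peak is *restored* in a deletion line
when mutant-Xi / wild-type-Xa (depth-normalized) exceeds 1/2, and
*concordant* when restored in every replicate. A gene *escapes* XCI when
≥ 10% of its allelic reads come from the Xi in at least one replicate
(genes with < 12 summed allelic reads are filtered).

**4C.** Viewpoint interaction profiles decay with genomic distance; the
strongest smoothed trans-chromosome peak localizes a transgene insertion
site, and target-over-flank enrichment per allele scores Xi-specific
superloops (e.g. *Dxz4*–*Firre*).

## Worked example

```
$ python examples/megadomain_timecourse.py
megadomain-negative (day 0-like):
  PC1 slope at border bin 50: +0.0120
  sharp transition: False (statistic 1.7, threshold 3)
  PC1 explains 38.4% of variance
megadomain-positive (day 10-like):
  PC1 slope at border bin 50: +0.0822
  sharp transition: True (statistic 14.9, threshold 3)
  PC1 explains 47.2% of variance
```

The positive map's PC1 slope is ~7× the negative map's, and only the
positive map shows a border step that dwarfs local PC1 fluctuations
(statistic 14.9 vs threshold 3): the two-megadomain partition is present.
The mixture analysis builds on this:

```
$ python examples/mixing_sensitivity.py
...
linear fit: slope 0.0695, intercept +0.0118, r^2 0.9962
held-out 25% mixture estimated at 23.4% (interval 18.0%-28.7%)
detection limit (2 SD): megadomains present in >= 5.4% of cells are detectable
```

The slope is linear in the positive fraction (r² ≈ 0.996), a blinded 25%
mixture is read back within 2 points, and at this read depth the assay
would notice megadomains present in as little as ~5% of cells.

Other capabilities: `examples/insulation_boundaries.py` (boundary calls and
the F-test on insulation variance), `examples/allelic_analysis.py` (peak
classes, restored peaks, escapees), `examples/fourc_insertion.py`
(insertion localization and superloop labeling). A thin CLI mirrors the
library (`ximega simulate | balance | pc1 | mix | mixfit | insulate |
classify-peaks | restored | escapees | compare | fourc-locate | report`).

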