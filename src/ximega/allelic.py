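"""Allele-specific ATAC-peak and RNA-expression analyses.

In an interspecific hybrid cell line every informative read maps to either
the active X (Xa) or the inactive X (Xi).  The operations here classify
accessibility peaks by allelic skew, detect peaks whose Xi accessibility is
restored in a deletion line, call genes escaping X inactivation, and run
the distributional comparisons (Wilcoxon signed-rank on Xi expression
levels, Kolmogorov-Smirnov on fold-change CDFs).

Input tables are pandas DataFrames with columns
``feature_id, chrom, start, end, reads_xa, reads_xi, replicate, genotype``
(gene tables may add ``fpm``).  Counts within a (replicate, genotype)
library can be depth-normalized to reads-per-million before cross-library
ratios are formed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError, JoinError

__all__ = [
    "validate_table",
    "classify_peaks",
    "restored_peaks",
    "classify_escapees",
    "xi_expression_density_compare",
    "fold_change_cdf_test",
]

REQUIRED_COLUMNS = ["feature_id", "reads_xa", "reads_xi", "replicate", "genotype"]

CLASSES = ("Xa_specific", "biallelic", "Xi_specific", "insufficient")


def validate_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"table missing columns: {missing}")
    if (t["reads_xa"] < 0).any() or (t["reads_xi"] < 0).any():
        raise FormatError("negative allelic read counts")
    if t.duplicated(subset=["feature_id", "replicate", "genotype"]).any():
        raise FormatError("(feature_id, replicate, genotype) not unique")
    return t


def classify_peaks(t: pd.DataFrame, min_allelic_reads: int = 10,
                   ratio_threshold: float = 1 / 3) -> pd.DataFrame:
    """Classify each record by its Xi:Xa read ratio.

    With r = reads_xi / reads_xa (+inf when reads_xa = 0):

    * total allelic reads < ``min_allelic_reads``      -> insufficient
    * r <= ratio_threshold                             -> Xa_specific
    * r >= 1 / ratio_threshold                         -> Xi_specific
    * ratio_threshold < r < 1/ratio_threshold          -> biallelic

    Returns the table with a ``peak_class`` column; thresholds are recorded
    in ``result.attrs``.
    """
    validate_table(t)
    out = t.copy()
    xa = out["reads_xa"].to_numpy(dtype=float)
    xi = out["reads_xi"].to_numpy(dtype=float)
    total = xa + xi
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(xa > 0, xi / np.maximum(xa, 1e-300), np.inf)
    upper = 1.0 / ratio_threshold
    cls = np.full(total.shape, "biallelic", dtype=object)
    cls[r <= ratio_threshold] = "Xa_specific"
    cls[r >= upper] = "Xi_specific"
    cls[total < min_allelic_reads] = "insufficient"
    out["peak_class"] = cls
    out.attrs["min_allelic_reads"] = min_allelic_reads
    out.attrs["ratio_threshold"] = ratio_threshold
    return out


def _library_scale(t: pd.DataFrame) -> pd.Series:
    """Reads-per-million scale factor per (replicate, genotype) library."""
    totals = t.groupby(["replicate", "genotype"])[["reads_xa", "reads_xi"]].sum().sum(axis=1)
    return 1e6 / totals


def restored_peaks(wt: pd.DataFrame, mut: pd.DataFrame, ratio: float = 0.5,
                   min_allelic_reads: int = 10,
                   ratio_threshold: float = 1 / 3,
                   depth_normalize: bool = True):
    """Find wild-type Xa-specific peaks whose Xi accessibility is restored
    in a mutant (deletion) line.

    Wild-type classification pools allelic reads across wt replicates; for
    each peak Xa-specific in wild-type and each mutant replicate, the peak
    is *restored* when mutant Xi reads / wild-type Xa reads > ``ratio``
    (reads depth-normalized to per-million within each library by default).
    *Concordant* peaks are restored in every mutant replicate.

    Returns (per_replicate_table, concordant_feature_ids).
    """
    validate_table(wt)
    validate_table(mut)
    wt_pooled = (wt.groupby("feature_id", as_index=False)[["reads_xa", "reads_xi"]]
                 .sum())
    wt_pooled["replicate"] = "pooled"
    wt_pooled["genotype"] = wt["genotype"].iloc[0]
    wt_cls = classify_peaks(wt_pooled, min_allelic_reads=min_allelic_reads,
                            ratio_threshold=ratio_threshold)
    xa_specific = set(wt_cls.loc[wt_cls["peak_class"] == "Xa_specific", "feature_id"])

    missing = set(wt["feature_id"]) ^ set(mut["feature_id"])
    if missing:
        raise JoinError("feature_ids do not match between tables",
                        offenders=sorted(missing))

    if depth_normalize:
        wt_scale = _library_scale(wt)
        mut_scale = _library_scale(mut)
    wt_xa = {}
    for fid, grp in wt.groupby("feature_id"):
        if depth_normalize:
            vals = [row.reads_xa * wt_scale[(row.replicate, row.genotype)]
                    for row in grp.itertuples()]
        else:
            vals = grp["reads_xa"].tolist()
        wt_xa[fid] = float(np.mean(vals))

    rows = []
    for row in mut.itertuples():
        if row.feature_id not in xa_specific:
            continue
        mut_xi = row.reads_xi * (mut_scale[(row.replicate, row.genotype)]
                                 if depth_normalize else 1.0)
        denom = wt_xa[row.feature_id]
        restored = bool(denom > 0 and mut_xi / denom > ratio)
        rows.append({"feature_id": row.feature_id, "replicate": row.replicate,
                     "genotype": row.genotype, "mut_xi_norm": mut_xi,
                     "wt_xa_norm": denom, "restored": restored})
    per_rep = pd.DataFrame(rows, columns=["feature_id", "replicate", "genotype",
                                          "mut_xi_norm", "wt_xa_norm", "restored"])
    if per_rep.empty:
        concordant = []
    else:
        by_peak = per_rep.groupby("feature_id")["restored"].all()
        concordant = sorted(by_peak.index[by_peak])
    per_rep.attrs["ratio"] = ratio
    per_rep.attrs["depth_normalized"] = depth_normalize
    return per_rep, concordant


def classify_escapees(t: pd.DataFrame, xi_fraction: float = 0.10,
                      min_allelic_reads: int = 12,
                      fpm_floor: float = 0.0,
                      required_genotypes: list[str] | None = None) -> pd.DataFrame:
    """Call genes escaping X inactivation, per condition (genotype).

    Filtering: allelic reads are summed across replicates within each
    genotype, and a gene is kept only when that sum reaches
    ``min_allelic_reads`` in every required genotype and (when an ``fpm``
    column is present) fpm > ``fpm_floor`` in every replicate.  A kept gene
    is an escapee in a condition when reads_xi / (reads_xi + reads_xa) >=
    ``xi_fraction`` in at least one replicate of that condition.

    Returns a gene x genotype boolean DataFrame with the shared-escapee
    overlap in ``attrs['overlap']``.
    """
    validate_table(t)
    genotypes = required_genotypes or sorted(t["genotype"].unique())
    pooled = (t[t["genotype"].isin(genotypes)]
              .groupby(["feature_id", "genotype"])[["reads_xa", "reads_xi"]].sum())
    pooled_total = pooled["reads_xa"] + pooled["reads_xi"]
    passing = set(t["feature_id"])
    for g in genotypes:
        tot = pooled_total.xs(g, level="genotype")
        passing &= set(tot.index[tot >= min_allelic_reads])
    if "fpm" in t.columns:
        low = t.groupby("feature_id")["fpm"].min()
        passing &= set(low.index[low > fpm_floor])
    kept = t[t["feature_id"].isin(passing)].copy()
    if kept.empty:
        flags = pd.DataFrame(columns=genotypes, dtype=bool)
    else:
        total = kept["reads_xa"] + kept["reads_xi"]
        with np.errstate(invalid="ignore"):
            kept["xi_frac"] = np.where(total > 0, kept["reads_xi"] / total, 0.0)
        kept["is_esc"] = kept["xi_frac"] >= xi_fraction
        flags = (kept.pivot_table(index="feature_id", columns="genotype",
                                  values="is_esc", aggfunc="any", fill_value=False)
                 .reindex(columns=genotypes, fill_value=False).astype(bool))
    flags.attrs["xi_fraction"] = xi_fraction
    flags.attrs["min_allelic_reads"] = min_allelic_reads
    flags.attrs["fpm_floor"] = fpm_floor
    flags.attrs["overlap"] = sorted(flags.index[flags.all(axis=1)]) if len(flags) else []
    return flags


def xi_expression_density_compare(a: pd.DataFrame, b: pd.DataFrame,
                                  n_comparisons: int = 1,
                                  paired: bool = True):
    """Compare per-gene Xi expression fractions between two conditions.

    Computes Xi fraction reads_xi / (reads_xi + reads_xa) per gene (reads
    pooled across replicates within each table), then a Wilcoxon
    signed-rank test across genes matched by feature_id (or a Mann-Whitney
    rank-sum when ``paired=False``, labeled as such).  The p-value is
    Bonferroni-multiplied by ``n_comparisons`` and capped at 1.
    """
    fa = _xi_fraction_by_gene(a)
    fb = _xi_fraction_by_gene(b)
    if paired:
        common = fa.index.intersection(fb.index)
        if common.size < 5:
            raise DegenerateInputError("fewer than 5 matched genes")
        x, y = fa[common].to_numpy(), fb[common].to_numpy()
        diffs = x - y
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(x, y)
        test = "wilcoxon_signed_rank"
        n = int(common.size)
    else:
        if min(fa.size, fb.size) < 5:
            raise DegenerateInputError("fewer than 5 genes per condition")
        stat, p = stats.mannwhitneyu(fa.to_numpy(), fb.to_numpy(),
                                     alternative="two-sided")
        test = "mann_whitney_rank_sum"
        n = int(min(fa.size, fb.size))
    return {"test": test, "statistic": float(stat), "p_value": float(p),
            "p_bonferroni": float(min(p * n_comparisons, 1.0)),
            "n_comparisons": n_comparisons, "n_genes": n}


def _xi_fraction_by_gene(t: pd.DataFrame) -> pd.Series:
    validate_table(t)
    pooled = t.groupby("feature_id")[["reads_xa", "reads_xi"]].sum()
    total = pooled["reads_xa"] + pooled["reads_xi"]
    pooled = pooled[total > 0]
    return pooled["reads_xi"] / (pooled["reads_xa"] + pooled["reads_xi"])


def fold_change_cdf_test(fc_autosomal, fc_x):
    """Two-sample KS test on fold-change distributions.

    Compares the autosomal and X-linked fold-change lists; returns the KS
    statistic (sup-distance of the empirical CDFs), the asymptotic p-value,
    and the empirical CDF tables ready for plotting.
    """
    fa = np.asarray(list(fc_autosomal), dtype=float)
    fx = np.asarray(list(fc_x), dtype=float)
    fa = fa[~np.isnan(fa)]
    fx = fx[~np.isnan(fx)]
    if fa.size == 0 or fx.size == 0:
        raise DegenerateInputError("empty fold-change list")
    res = stats.ks_2samp(fa, fx, method="asymp")
    cdf = {
        "autosomal": pd.DataFrame({"value": np.sort(fa),
                                   "cdf": np.arange(1, fa.size + 1) / fa.size}),
        "x_linked": pd.DataFrame({"value": np.sort(fx),
                                  "cdf": np.arange(1, fx.size + 1) / fx.size}),
    }
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "cdf": cdf}
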