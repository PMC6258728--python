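"""Megadomain quantification via PC1 of the contact correlation matrix.

The inactive X partitions into two multi-Mb "megadomains" separated at the
Dxz4 locus.  The first principal component (PC1) of the Pearson
correlation matrix of the balanced contact map is piecewise-constant with
opposite signs over the two domains, so the *PC1 slope* — the difference
of PC1 scores between the bins flanking the border bin — quantifies
megadomain strength.  In a mixed cell population the slope varies linearly
with the megadomain-positive fraction, which supports a regression-based
sensitivity analysis: estimate the positive fraction of an unknown sample
from its slope, and derive the smallest fraction the assay can detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, MaskedBinError, ParameterError
from .matrix import ContactMatrix, CorrelationMatrix

__all__ = [
    "PC1Track",
    "MixingFit",
    "pc1",
    "pc1_slope",
    "detect_border",
    "sharp_transition_test",
    "mix_reads",
    "mixing_regression",
    "estimate_positive_fraction",
    "detection_limit",
]

#: statistic reported when flank noise is exactly zero but the step is not
SHARP_STAT_CAP = 1e12


@dataclass
class PC1Track:
    """First principal component of the correlation matrix, per bin.

    ``scores`` is the unit-norm leading eigenvector (NaN on masked bins),
    sign-oriented so that the mean score after the designated border bin is
    nonnegative.
    """

    scores: np.ndarray
    mask: np.ndarray
    explained_fraction: float
    orientation: str
    bin_size: int = 1_000_000
    chrom: str = "chrX"
    start_coord: int = 0


@dataclass
class MixingFit:
    """OLS fit of PC1 slope against megadomain-positive fraction."""

    fractions: np.ndarray
    slopes: np.ndarray
    intercept: float
    slope_coefficient: float
    r_squared: float
    residual_sd: float


def pc1(corr: CorrelationMatrix, border_bin: int | None = None) -> PC1Track:
    """Leading eigenvector of the column-centered correlation matrix.

    The unmasked submatrix is column-centered and its covariance
    eigendecomposed; the per-bin loadings of the leading eigenvector are
    the PC1 scores.  When ``border_bin`` is given the sign is fixed so the
    mean score over bins strictly after the border is >= 0; otherwise the
    overall mean is made nonnegative.
    """
    keep = corr.mask
    if keep.sum() < 3:
        raise DegenerateInputError("need >= 3 unmasked bins for PC1")
    sub = corr.values[np.ix_(keep, keep)]
    centered = sub - sub.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise DegenerateInputError("correlation matrix has no variance after centering")
    cov = centered.T @ centered / max(centered.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    explained = float(evals[-1] / evals.sum()) if evals.sum() > 0 else 0.0

    n = corr.n_bins
    scores = np.full(n, np.nan)
    scores[keep] = lead
    idx = np.flatnonzero(keep)
    if border_bin is not None:
        after = idx[idx > border_bin]
        ref = np.nanmean(scores[after]) if after.size else np.nansum(scores)
        orientation = f"mean_after_bin_{border_bin}_nonnegative"
    else:
        ref = np.nansum(scores)
        orientation = "mean_nonnegative"
    if ref < 0:
        scores = -scores
    return PC1Track(scores=scores, mask=keep.copy(), explained_fraction=explained,
                    orientation=orientation, bin_size=corr.bin_size,
                    chrom=corr.chrom, start_coord=corr.start_coord)


def pc1_slope(track: PC1Track, border_bin: int) -> float:
    """PC1 score at border_bin+1 minus PC1 score at border_bin-1.

    With chromosome-wide 1 Mb binning and the border bin containing Dxz4,
    this is the difference between the scores of the flanking bins.
    """
    lo, hi = border_bin - 1, border_bin + 1
    if lo < 0 or hi >= track.scores.size:
        raise ParameterError("border bin flanks fall outside the track")
    if not (track.mask[lo] and track.mask[hi]):
        raise MaskedBinError(f"flanking bin {lo if not track.mask[lo] else hi} is masked")
    return float(track.scores[hi] - track.scores[lo])


def detect_border(track: PC1Track) -> int:
    """Convenience border detector: argmax of |first difference| of PC1.

    Returns the bin index b such that the step between b and b+1 is the
    largest absolute first difference; ties break toward the lower index.
    """
    s = track.scores
    diffs = np.abs(np.diff(s))
    diffs = np.where(np.isnan(diffs), -np.inf, diffs)
    return int(np.argmax(diffs))


def sharp_transition_test(track: PC1Track, border_bin: int, flank_bins: int = 10,
                          threshold: float = 3.0):
    """Test for a sharp PC1 transition at the border bin.

    The statistic is |pc1_slope| divided by the pooled root-mean-square of
    first differences within ``flank_bins``-bin windows on each side of
    the border (excluding the border step itself).  The uncentered RMS is
    the right scale here: a smooth gradient has border step comparable to
    its local steps (statistic near 2), while a genuine megadomain border
    has a step far exceeding the flank steps.  Returns
    (decision, statistic).
    """
    s = track.scores
    n = s.size
    left = s[max(border_bin - 1 - flank_bins, 0):border_bin]
    right = s[border_bin + 1:min(border_bin + 1 + flank_bins + 1, n)]
    if left.size < 3 or right.size < 3:
        raise DegenerateInputError("flank windows too small for transition test")
    diffs = np.concatenate([np.diff(left), np.diff(right)])
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size < 2:
        raise DegenerateInputError("not enough unmasked flank differences")
    slope = abs(pc1_slope(track, border_bin))
    sd = float(np.sqrt(np.mean(diffs ** 2)))
    stat = min(slope / sd, SHARP_STAT_CAP) if sd > 0 else (0.0 if slope == 0 else SHARP_STAT_CAP)
    return bool(stat > threshold), float(stat)


def mix_reads(a: ContactMatrix, b: ContactMatrix, fraction_b: float,
              total_reads: int | None = None, seed: int = 0,
              resample: bool = True) -> ContactMatrix:
    """Mix two contact maps at the read level.

    Cells are multinomially resampled with probabilities
    (1-fraction_b)*p_a + fraction_b*p_b where p_x is x normalized to sum 1,
    which emulates pooling aligned reads from the two libraries.  With
    ``resample=False`` and fraction 0 or 1, the corresponding input is
    returned untouched.
    """
    if a.counts.shape != b.counts.shape or a.bin_size != b.bin_size:
        raise ParameterError("matrices must share shape and bin size")
    if not 0 <= fraction_b <= 1:
        raise ParameterError("fraction_b must be in [0,1]")
    if not resample:
        if fraction_b == 0:
            return a
        if fraction_b == 1:
            return b
        raise ParameterError("resample=False only valid for fraction 0 or 1")
    n = a.n_bins
    iu, ju = np.triu_indices(n)
    pa = a.counts[iu, ju].astype(float)
    pb = b.counts[iu, ju].astype(float)
    if pa.sum() == 0 or pb.sum() == 0:
        raise ParameterError("cannot mix an empty matrix")
    p = (1 - fraction_b) * pa / pa.sum() + fraction_b * pb / pb.sum()
    if total_reads is None:
        total_reads = int(round((1 - fraction_b) * pa.sum() + fraction_b * pb.sum()))
    rng = np.random.default_rng(seed)
    sampled = rng.multinomial(int(total_reads), p / p.sum())
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = sampled
    counts[ju, iu] = sampled
    return ContactMatrix(counts, bin_size=a.bin_size, chrom=a.chrom,
                         allele=a.allele)


def mixing_regression(fractions, slopes) -> MixingFit:
    """Ordinary least squares of PC1 slope on megadomain-positive fraction."""
    fractions = np.asarray(fractions, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if fractions.size != slopes.size or fractions.size < 2:
        raise ParameterError("need >= 2 (fraction, slope) pairs of equal length")
    if np.unique(fractions).size < 2:
        raise ParameterError("fractions must not all be identical")
    res = stats.linregress(fractions, slopes)
    pred = res.intercept + res.slope * fractions
    resid = slopes - pred
    dof = max(fractions.size - 2, 1)
    residual_sd = float(np.sqrt((resid ** 2).sum() / dof))
    return MixingFit(fractions=fractions, slopes=slopes,
                     intercept=float(res.intercept),
                     slope_coefficient=float(res.slope),
                     r_squared=float(res.rvalue ** 2),
                     residual_sd=residual_sd)


def estimate_positive_fraction(fit: MixingFit, observed_slope: float,
                               k_sd: float = 2.0):
    """Invert the mixing fit to estimate the megadomain-positive fraction.

    Returns a dict with the point estimate (clamped to [0,1], flagged when
    clamping occurred), a +/- k_sd delta-method interval, and the strength
    of the observed signal relative to a fully positive population.
    """
    if fit.slope_coefficient == 0:
        raise ParameterError("mixing fit has zero slope; fraction not identifiable")
    raw = (observed_slope - fit.intercept) / fit.slope_coefficient
    est = float(np.clip(raw, 0.0, 1.0))
    half = k_sd * fit.residual_sd / abs(fit.slope_coefficient)
    slope_at_one = fit.intercept + fit.slope_coefficient
    relative = observed_slope / slope_at_one if slope_at_one != 0 else np.inf
    return {
        "estimate": est,
        "raw_estimate": float(raw),
        "clamped": bool(raw != est),
        "interval": (float(max(raw - half, 0.0)), float(min(raw + half, 1.0))),
        "relative_strength": float(relative),
    }


def detection_limit(fit: MixingFit, k_sd: float = 2.0,
                    noise_sd: float | None = None) -> float:
    """Smallest positive fraction distinguishable from zero.

    The smallest f whose predicted slope exceeds the predicted slope at
    f=0 by ``k_sd`` times the slope noise: f = k_sd * sd / |slope_coef|.
    """
    sd = fit.residual_sd if noise_sd is None else noise_sd
    if sd is None or sd < 0:
        raise ParameterError("noise estimate must be nonnegative")
    if fit.slope_coefficient == 0:
        raise ParameterError("mixing fit has zero slope")
    if sd == 0:
        return 0.0
    return float(k_sd * sd / abs(fit.slope_coefficient))
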