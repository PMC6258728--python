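"""Insulation scores, boundary calling, and variance comparison.

The insulation score of a bin measures how strongly the locus blocks
contacts crossing it: the raw score is the ratio of contacts crossing the
bin (one end within ``w`` bins to the left, the other within ``w`` bins to
the right) to contacts nearby that do not cross it (both ends in the same
side window).  Scores are log2-normalized by the regional mean, so TAD
interiors sit near zero and boundaries are strong local minima.  The
variance of the score track over a region summarizes global insulation
strength — flatter tracks (smaller variance) mean weaker domains — and is
compared between conditions with a two-sided F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .matrix import BalancedMatrix

__all__ = [
    "InsulationParams",
    "InsulationTrack",
    "FTestResult",
    "insulation_track",
    "call_boundaries",
    "variance_f_test",
]


@dataclass
class InsulationParams:
    """Window geometry for insulation scoring.

    ``square_span`` is the bp extent of the crossing-contact window on each
    side of the scored bin (default 125 kb), ``delta_span`` the bp span used
    for boundary-depth evaluation (default 75 kb), and ``edge_exclude_bins``
    the count of region-edge bins dropped because their windows fall partly
    outside the captured region (default 6).
    """

    square_span: int = 125_000
    delta_span: int = 75_000
    aggregation: str = "sum"
    edge_exclude_bins: int = 6

    def __post_init__(self):
        if self.square_span <= 0 or self.delta_span <= 0:
            raise ParameterError("spans must be positive")
        if self.edge_exclude_bins < 0:
            raise ParameterError("edge_exclude_bins must be >= 0")
        if self.aggregation != "sum":
            raise ParameterError("only 'sum' aggregation is supported")

    def window_bins(self, bin_size: int) -> int:
        if self.square_span % bin_size:
            raise ParameterError("square_span must be a multiple of bin_size")
        return self.square_span // bin_size

    def delta_bins(self, bin_size: int) -> int:
        if self.delta_span % bin_size:
            raise ParameterError("delta_span must be a multiple of bin_size")
        return self.delta_span // bin_size


@dataclass
class InsulationTrack:
    """Per-bin log2-normalized insulation scores with masking flags."""

    scores: np.ndarray
    raw: np.ndarray
    mask: np.ndarray
    params: InsulationParams
    bin_size: int
    chrom: str = "chrX"
    start_coord: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.scores.size

    def unmasked_scores(self) -> np.ndarray:
        return self.scores[self.mask]


@dataclass
class FTestResult:
    variance_a: float
    variance_b: float
    f_statistic: float
    df_a: int
    df_b: int
    p_value: float


def insulation_track(b: BalancedMatrix, params: InsulationParams | None = None) -> InsulationTrack:
    """Compute the insulation-score track of a balanced matrix.

    For bin i with window w = square_span / bin_size:

    * crossover(i) = sum of values over rows i-w..i-1 x cols i+1..i+w
      (contacts crossing the bin);
    * flank(i) = sum over the upper triangles (diagonal included) of the
      two within-side w x w squares (contacts staying on one side);
    * raw(i) = crossover(i) / flank(i);
    * score(i) = log2(raw(i) / mean of raw over scored bins).

    Bins within w of the matrix edge, within ``edge_exclude_bins`` of the
    region edge, masked in the input, or with zero flank or zero crossover
    are masked (zero-crossover bins get a "zero_crossover" flag in meta
    rather than a -inf score).
    """
    if params is None:
        params = InsulationParams()
    w = params.window_bins(b.bin_size)
    n = b.n_bins
    if n <= 2 * w + 2 * params.edge_exclude_bins:
        raise DegenerateInputError(
            f"matrix of {n} bins too small for window {w} with "
            f"{params.edge_exclude_bins} edge bins excluded")
    V = np.where(np.isnan(b.values), 0.0, b.values)
    raw = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    zero_crossover = []
    lo = max(w, params.edge_exclude_bins)
    hi = n - max(w, params.edge_exclude_bins)
    for i in range(lo, hi):
        if not b.mask[i]:
            continue
        cross = V[i - w:i, i + 1:i + w + 1].sum()
        left = np.triu(V[i - w:i, i - w:i]).sum()
        right = np.triu(V[i + 1:i + w + 1, i + 1:i + w + 1]).sum()
        flank = left + right
        if flank == 0:
            continue
        if cross == 0:
            zero_crossover.append(i)
            continue
        raw[i] = cross / flank
        mask[i] = True
    if not mask.any():
        raise DegenerateInputError("no scoreable bins after masking")
    mean_raw = raw[mask].mean()
    scores = np.full(n, np.nan)
    if np.all(raw[mask] == raw[mask][0]):
        scores[mask] = 0.0  # constant raw track: exactly self-normalized
    else:
        scores[mask] = np.log2(raw[mask] / mean_raw)
    return InsulationTrack(scores=scores, raw=raw, mask=mask, params=params,
                           bin_size=b.bin_size, chrom=b.chrom,
                           start_coord=b.start_coord,
                           meta={"window_bins": w, "log_base": 2,
                                 "flank_geometry": "within-side upper triangles, diagonal included",
                                 "normalized_after_masking": True,
                                 "zero_crossover_bins": zero_crossover})


def call_boundaries(track: InsulationTrack, delta_span: int | None = None,
                    min_depth: float = 0.1):
    """Call TAD boundaries as local minima of the insulation track.

    A bin is a boundary when it is the minimum within +/- d bins
    (d = delta_span / bin_size) and the mean score of its +/- d window
    (excluding itself) exceeds its own score by at least ``min_depth``.
    Ties break toward the lower index.  Returns a list of (bin, depth).
    """
    d = (track.params if delta_span is None else
         InsulationParams(square_span=track.params.square_span,
                          delta_span=delta_span,
                          edge_exclude_bins=track.params.edge_exclude_bins)
         ).delta_bins(track.bin_size)
    s = track.scores
    n = track.n_bins
    if track.mask.sum() < 2 * d + 1:
        raise DegenerateInputError("too few unmasked bins for boundary calling")
    boundaries = []
    for i in range(d, n - d):  # full +/- d window must fit
        if not track.mask[i]:
            continue
        lo, hi = i - d, i + d + 1
        window = s[lo:hi]
        wmask = track.mask[lo:hi]
        vals = window[wmask]
        if vals.size < 3:
            continue
        if s[i] > vals.min():
            continue
        # tie toward lower index: skip if an earlier bin in the window ties
        tie_idx = np.flatnonzero(wmask & (window == vals.min())) + lo
        if tie_idx[0] < i:
            continue
        flank_vals = np.concatenate([window[:i - lo][wmask[:i - lo]],
                                     window[i - lo + 1:][wmask[i - lo + 1:]]])
        if flank_vals.size == 0:
            continue
        depth = float(flank_vals.mean() - s[i])
        if depth >= min_depth:
            boundaries.append((i, depth))
    return boundaries


def variance_f_test(track_a, track_b) -> FTestResult:
    """Two-sided F-test comparing insulation-score variances.

    Accepts InsulationTrack objects or plain score arrays.  The statistic
    is var_a / var_b on unmasked scores, with a two-sided p-value from the
    F distribution on (n_a - 1, n_b - 1) degrees of freedom.  A decrease in
    variance corresponds to a loss of insulation.
    """
    a = track_a.unmasked_scores() if isinstance(track_a, InsulationTrack) else np.asarray(track_a, float)
    b = track_b.unmasked_scores() if isinstance(track_b, InsulationTrack) else np.asarray(track_b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise DegenerateInputError("each track needs >= 3 unmasked scores")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0:
        raise DegenerateInputError("zero variance in denominator track")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = float(min(2 * min(cdf, 1 - cdf), 1.0))
    return FTestResult(variance_a=va, variance_b=vb, f_statistic=f,
                       df_a=dfa, df_b=dfb, p_value=p)
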