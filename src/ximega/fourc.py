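"""4C viewpoint interaction profiles: binning, insertion localization,
superloop scoring.

A 4C experiment reports genome-wide contact counts of a single viewpoint
locus.  Signal decays steeply with genomic distance from the viewpoint, so
a strong peak on a *trans* chromosome marks the integration site of a
transgene carrying the viewpoint sequence, and allele-resolved profiles
let very-long-range point contacts ("superloops", e.g. Dxz4-Firre) be
scored per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "FourCProfile",
    "LocusCall",
    "bin_profile",
    "locate_insertion",
    "superloop_score",
]

#: fold reported when the background median is zero but the peak is not
FOLD_CAP = 1e12


@dataclass
class FourCProfile:
    """Binned genome-wide interaction counts anchored at one viewpoint.

    ``counts`` maps chromosome name -> per-bin count vector; allele is one
    of composite / repetitive / alleleA / alleleB.
    """

    counts: dict[str, np.ndarray]
    bin_size: int
    viewpoint: tuple[str, int]
    allele: str = "composite"

    def __post_init__(self):
        self.counts = {c: np.asarray(v, dtype=float) for c, v in self.counts.items()}
        for c, v in self.counts.items():
            if np.any(v < 0):
                raise FormatError(f"negative counts on {c}")
        if self.viewpoint[0] not in self.counts:
            raise ParameterError("viewpoint chromosome absent from profile")

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def per_million(self) -> dict[str, np.ndarray]:
        total = self.library_size
        if total == 0:
            raise DegenerateInputError("empty 4C profile")
        return {c: v * (1e6 / total) for c, v in self.counts.items()}


@dataclass
class LocusCall:
    chrom: str
    bin: int
    signal: float
    fold: float
    passes_threshold: bool


def bin_profile(records, bin_size: int, chrom_sizes: dict[str, int],
                viewpoint: tuple[str, int], allele: str = "composite") -> FourCProfile:
    """Bin bedGraph records into a FourCProfile.

    ``records`` is an iterable of (chrom, start, end, value) or a DataFrame
    with those columns.  A record straddling bins is split pro-rata by
    overlap length; 0-based half-open coordinates.
    """
    if isinstance(records, pd.DataFrame):
        records = records[["chrom", "start", "end", "value"]].itertuples(index=False)
    counts = {c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()}
    for lineno, rec in enumerate(records, 1):
        chrom, start, end, value = rec
        if chrom not in counts:
            raise FormatError(f"record {lineno}: unknown chromosome {chrom!r}")
        start, end, value = int(start), int(end), float(value)
        if value < 0 or end <= start:
            raise FormatError(f"record {lineno}: invalid interval or negative value")
        length = end - start
        b0, b1 = start // bin_size, (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            counts[chrom][b] += value * (hi - lo) / length
    return FourCProfile(counts=counts, bin_size=bin_size, viewpoint=viewpoint,
                        allele=allele)


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v.copy()
    kernel = np.ones(window) / window
    # running mean with edge shrinkage (same-length output)
    padded = np.convolve(v, kernel, mode="same")
    norm = np.convolve(np.ones_like(v), kernel, mode="same")
    return padded / norm


def locate_insertion(p: FourCProfile, smooth_bins: int = 3,
                     exclude_cis: bool = True, min_fold: float = 10.0) -> LocusCall:
    """Locate a transgene insertion site from the strongest trans peak.

    Counts are scaled to per-million and mean-smoothed over
    ``smooth_bins``; the candidate is the global argmax over eligible bins
    (the whole viewpoint chromosome excluded when ``exclude_cis``); fold is
    candidate signal over the median of positive smoothed bins genome-wide.
    Ties break toward the lexicographically smaller (chrom, bin).
    """
    pm = p.per_million()
    smoothed = {c: _smooth(v, smooth_bins) for c, v in pm.items()}
    cis = p.viewpoint[0]
    eligible = {c: v for c, v in smoothed.items() if not (exclude_cis and c == cis)}
    if not eligible:
        raise DegenerateInputError("no eligible chromosomes after cis exclusion")
    best = None
    for c in sorted(eligible):
        v = eligible[c]
        b = int(np.argmax(v))
        if best is None or v[b] > best[2]:
            best = (c, b, float(v[b]))
    # background = median positive smoothed signal genome-wide, excluding
    # the candidate's own smoothed neighborhood so a lone peak is not its
    # own background
    pool = []
    halo = max(smooth_bins, 1)
    for c, v in smoothed.items():
        if c == best[0]:
            keep = np.ones(v.size, dtype=bool)
            keep[max(best[1] - halo, 0):best[1] + halo + 1] = False
            v = v[keep]
        pool.append(v[v > 0])
    allpos = np.concatenate(pool) if pool else np.array([])
    background = float(np.median(allpos)) if allpos.size else 0.0
    if background > 0:
        fold = best[2] / background
    else:
        fold = FOLD_CAP if best[2] > 0 else 0.0
    fold = min(fold, FOLD_CAP)
    return LocusCall(chrom=best[0], bin=best[1], signal=best[2], fold=float(fold),
                     passes_threshold=bool(fold >= min_fold))


def superloop_score(p: FourCProfile, target: tuple[str, int, int],
                    local_background: tuple[tuple[str, int, int], tuple[str, int, int]],
                    paired: FourCProfile | None = None,
                    min_fold: float = 3.0):
    """Enrichment of 4C signal in a target interval over its local flanks.

    ``target`` and each flank are (chrom, start_bin, end_bin) half-open bin
    intervals on the same chromosome.  Enrichment is mean per-million
    signal in the target divided by the mean of the two flank means.  With
    a ``paired`` profile for the other allele, also reports the ratio of
    the two enrichments and the label "Xi-specific" when this profile's
    enrichment >= ``min_fold`` while the paired one's is below it.
    """
    chrom, t0, t1 = target
    flanks = list(local_background)
    for fc, f0, f1 in flanks:
        if fc != chrom:
            raise ParameterError("background flanks must share the target chromosome")
        if not (f1 <= t0 or f0 >= t1):
            raise ParameterError("target and background intervals overlap")

    def enrich(profile: FourCProfile) -> float:
        pm = profile.per_million()
        if chrom not in pm:
            raise ParameterError(f"chromosome {chrom!r} absent from profile")
        target_mean = float(pm[chrom][t0:t1].mean())
        flank_means = [float(pm[chrom][f0:f1].mean()) for _, f0, f1 in flanks]
        bg = float(np.mean(flank_means))
        if bg == 0:
            raise DegenerateInputError("zero background on both flanks")
        return target_mean / bg

    e = enrich(p)
    result = {"enrichment": e, "min_fold": min_fold}
    if paired is not None:
        e_pair = enrich(paired)
        result["paired_enrichment"] = e_pair
        result["ratio"] = e / e_pair if e_pair > 0 else np.inf
        result["label"] = ("Xi-specific" if e >= min_fold and e_pair < min_fold
                           else "not Xi-specific")
    return result
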