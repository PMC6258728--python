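"""Synthetic allele-specific data with known ground truth.

Generates the four input classes the analyses consume:

* contact matrices with power-law distance decay, TADs, and a
  two-megadomain partition at a border bin (the inactive-X architecture);
* differentiation time-course mixtures of megadomain-negative and
  megadomain-positive populations;
* allelic peak/gene count tables with a controllable active-X skew and
  escape fraction;
* viewpoint-anchored 4C profiles with an optional trans insertion peak.

Every sampler is Poisson/binomial over a deterministic expected-value
construction, so the expectation is available in closed form for oracle
tests, and ground truth (domain borders, mixture fractions, feature
classes, insertion bins) is always returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import ContactMatrix

__all__ = [
    "XiModelParams",
    "AllelicTableParams",
    "FourCParams",
    "expected_contact_matrix",
    "simulate_contact_matrix",
    "simulate_time_course",
    "simulate_allelic_peaks",
    "simulate_fourc_profile",
]


@dataclass
class XiModelParams:
    """Generative model of one chromosome's contact map.

    Expected contacts decay as |i-j|^-decay_exponent, attenuated by
    ``tad_strength`` for each TAD border strictly between the bins and by
    ``megadomain_strength`` when the bins straddle ``border_bin``.  Strength
    0 means no structure, 1 means complete depletion of crossing contacts.
    Defaults mirror a chromosome-scale map at moderate read depth: 100 bins,
    1 Mb bins, border at bin 50, megadomain strength 0.6, 5e5 read pairs.
    """

    n_bins: int = 100
    bin_size: int = 1_000_000
    decay_exponent: float = 1.0
    border_bin: int = 50
    megadomain_strength: float = 0.6
    tad_borders: tuple[int, ...] = ()
    tad_strength: float = 0.0
    total_reads: float = 5e5
    seed: int = 0
    chrom: str = "chrX"
    allele: str = "alleleB"

    def __post_init__(self):
        self.tad_borders = tuple(self.tad_borders)
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if not 0 <= self.border_bin < self.n_bins:
            raise ParameterError("border_bin out of range")
        if not 0 <= self.megadomain_strength <= 1:
            raise ParameterError("megadomain_strength must be in [0,1]")
        if not 0 <= self.tad_strength <= 1:
            raise ParameterError("tad_strength must be in [0,1]")
        if self.decay_exponent <= 0:
            raise ParameterError("decay_exponent must be > 0")
        if self.total_reads <= 0:
            raise ParameterError("total_reads must be > 0")
        if any(b < 0 or b >= self.n_bins for b in self.tad_borders):
            raise ParameterError("tad_borders out of range")
        if list(self.tad_borders) != sorted(set(self.tad_borders)):
            raise ParameterError("tad_borders must be strictly increasing")


def expected_contact_matrix(params: XiModelParams,
                            megadomain_strength: float | None = None) -> np.ndarray:
    """Closed-form expected matrix, scaled so the full-matrix total is
    ``total_reads``.  Deterministic; the sampling oracle for all tests."""
    s = params.megadomain_strength if megadomain_strength is None else megadomain_strength
    n = params.n_bins
    i = np.arange(n)
    dist = np.abs(i[:, None] - i[None, :]).astype(float)
    # diagonal follows the decay law at distance 1
    np.fill_diagonal(dist, 1.0)
    base = dist ** -params.decay_exponent
    E = base.copy()
    for b in params.tad_borders:
        # border b lies strictly between i and j when min < b < max... the
        # boundary sits between bins b-1 and b: crossing means i < b <= j
        crosses = (np.minimum(i[:, None], i[None, :]) < b) & (np.maximum(i[:, None], i[None, :]) >= b)
        E = np.where(crosses, E * (1.0 - params.tad_strength), E)
    straddle = ((i[:, None] <= params.border_bin) & (i[None, :] > params.border_bin)) | \
               ((i[None, :] <= params.border_bin) & (i[:, None] > params.border_bin))
    E = np.where(straddle, E * (1.0 - s), E)
    E *= params.total_reads / E.sum()
    return E


def _sample_symmetric_poisson(E: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = E.shape[0]
    iu, ju = np.triu_indices(n)
    sampled = rng.poisson(E[iu, ju])
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = sampled
    counts[ju, iu] = sampled
    return counts


def simulate_contact_matrix(params: XiModelParams,
                            rng: np.random.Generator | None = None) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix from the expected map."""
    E = expected_contact_matrix(params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    counts = _sample_symmetric_poisson(E, rng)
    return ContactMatrix(counts, bin_size=params.bin_size, chrom=params.chrom,
                         allele=params.allele)


@dataclass
class TimeCoursePoint:
    fraction: float
    matrix: ContactMatrix


def simulate_time_course(params: XiModelParams,
                         positive_fractions: list[float]) -> list[TimeCoursePoint]:
    """Mixtures of a megadomain-negative and a megadomain-positive population.

    For fraction f the expected map is (1-f) * E[strength=0] + f *
    E[strength=params.megadomain_strength], Poisson-sampled; this matches
    read-level mixing of the two libraries in expectation.  Ground-truth
    fractions ride along in the returned records.
    """
    for f in positive_fractions:
        if not 0 <= f <= 1:
            raise ParameterError("positive fractions must lie in [0,1]")
    E_neg = expected_contact_matrix(params, megadomain_strength=0.0)
    E_pos = expected_contact_matrix(params)
    rng = np.random.default_rng(params.seed)
    out = []
    for f in positive_fractions:
        E = (1.0 - f) * E_neg + f * E_pos
        counts = _sample_symmetric_poisson(E, rng)
        m = ContactMatrix(counts, bin_size=params.bin_size, chrom=params.chrom,
                          allele=params.allele)
        out.append(TimeCoursePoint(fraction=float(f), matrix=m))
    return out


@dataclass
class AllelicTableParams:
    """Allelic count-table generator settings.

    ``xa_skew`` is the expected active-X (allele A) share of allelic reads
    for silenced features; escape features are biallelic (share 0.5).
    Defaults emulate a chromosome where the large majority of accessible
    peaks are Xa-specific, with a small escape fraction.
    """

    n_features: int = 1000
    mean_reads: float = 50.0
    xa_skew: float = 0.95
    escape_fraction: float = 0.05
    n_replicates: int = 2
    seed: int = 0
    chrom: str = "chrX"
    genotype: str = "wt"

    def __post_init__(self):
        if not 0 <= self.xa_skew <= 1:
            raise ParameterError("xa_skew must be in [0,1]")
        if not 0 <= self.escape_fraction <= 1:
            raise ParameterError("escape_fraction must be in [0,1]")
        if self.n_features <= 0 or self.n_replicates <= 0:
            raise ParameterError("counts must be positive")
        if self.mean_reads <= 0:
            raise ParameterError("mean_reads must be > 0")


def simulate_allelic_peaks(params: AllelicTableParams) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an allelic count table plus its ground-truth classes.

    Each feature draws a total ~ Poisson(mean_reads) per replicate, with
    allele-A (Xa) reads ~ Binomial(total, xa_skew) for silenced features and
    Binomial(total, 0.5) for escape features.  Returns (table, truth) where
    ``truth`` maps feature_id -> {"silenced", "escape"}.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_features
    is_escape = rng.random(n) < params.escape_fraction
    feature_ids = [f"peak_{k:05d}" for k in range(n)]
    rows = []
    for rep in range(1, params.n_replicates + 1):
        totals = rng.poisson(params.mean_reads, size=n)
        p = np.where(is_escape, 0.5, params.xa_skew)
        xa = rng.binomial(totals, p)
        xi = totals - xa
        start = np.arange(n) * 10_000
        rows.append(pd.DataFrame({
            "feature_id": feature_ids,
            "chrom": params.chrom,
            "start": start,
            "end": start + 500,
            "reads_xa": xa,
            "reads_xi": xi,
            "replicate": f"rep{rep}",
            "genotype": params.genotype,
        }))
    table = pd.concat(rows, ignore_index=True)
    truth = pd.Series(np.where(is_escape, "escape", "silenced"),
                      index=pd.Index(feature_ids, name="feature_id"), name="truth")
    return table, truth


@dataclass
class FourCParams:
    """Genome model and rates for 4C profile simulation.

    The genome is a set of equal-length chromosomes; interaction counts
    decay as a power law away from the viewpoint on the cis chromosome,
    with a second (weaker) decay peak at the insertion site if one is given
    and a uniform background everywhere.
    """

    chroms: tuple[str, ...] = ("chrX", "chr14", "chr3")
    bins_per_chrom: int = 200
    bin_size: int = 100_000
    decay_exponent: float = 1.2
    viewpoint_reads: float = 2e4
    insertion_reads: float = 2e3
    background_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.bins_per_chrom < 2:
            raise ParameterError("bins_per_chrom must be >= 2")
        if self.decay_exponent <= 0:
            raise ParameterError("decay_exponent must be > 0")
        if min(self.viewpoint_reads, self.insertion_reads) < 0 or self.background_rate < 0:
            raise ParameterError("rates must be nonnegative")


def _decay_peak(n_bins: int, center: int, total: float, alpha: float) -> np.ndarray:
    d = np.abs(np.arange(n_bins) - center).astype(float)
    d[center] = 1.0
    lam = d ** -alpha
    lam[center] = 1.0
    return lam * (total / lam.sum())


def simulate_fourc_profile(viewpoint_bin: int, insertion_bin: int | None,
                           params: FourCParams,
                           viewpoint_chrom: str | None = None,
                           insertion_chrom: str | None = None,
                           allele: str = "composite"):
    """Simulate a 4C profile; returns (FourCProfile, ground_truth dict)."""
    from .fourc import FourCProfile

    vp_chrom = viewpoint_chrom or params.chroms[0]
    if vp_chrom not in params.chroms:
        raise ParameterError(f"viewpoint chromosome {vp_chrom!r} not in genome model")
    if not 0 <= viewpoint_bin < params.bins_per_chrom:
        raise ParameterError("viewpoint_bin outside genome model")
    ins_chrom = None
    if insertion_bin is not None:
        ins_chrom = insertion_chrom or next(c for c in params.chroms if c != vp_chrom)
        if ins_chrom == vp_chrom:
            raise ParameterError("insertion chromosome must differ from viewpoint chromosome")
        if not 0 <= insertion_bin < params.bins_per_chrom:
            raise ParameterError("insertion_bin outside genome model")
    rng = np.random.default_rng(params.seed)
    counts = {}
    for chrom in params.chroms:
        lam = np.full(params.bins_per_chrom, params.background_rate, dtype=float)
        if chrom == vp_chrom:
            lam += _decay_peak(params.bins_per_chrom, viewpoint_bin,
                               params.viewpoint_reads, params.decay_exponent)
        if ins_chrom is not None and chrom == ins_chrom:
            lam += _decay_peak(params.bins_per_chrom, insertion_bin,
                               params.insertion_reads, params.decay_exponent)
        counts[chrom] = rng.poisson(lam)
    profile = FourCProfile(counts=counts, bin_size=params.bin_size,
                           viewpoint=(vp_chrom, viewpoint_bin * params.bin_size),
                           allele=allele)
    truth = {"viewpoint": (vp_chrom, viewpoint_bin),
             "insertion": (ins_chrom, insertion_bin) if ins_chrom else None}
    return profile, truth
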