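"""Contact-matrix data model, rebinning, masking, balancing, correlation.

The central objects are binned, symmetric, per-chromosome contact matrices
for a single allele (composite, alleleA or alleleB).  Two balancing schemes
are provided:

* Knight-Ruiz (KR) matrix balancing — the standard Hi-C normalization that
  rescales a symmetric nonnegative matrix ``A`` to ``diag(x) A diag(x)``
  with equal row sums.  Implemented as the inner-outer Newton iteration with
  a conjugate-gradient inner solve.
* sqrt-vanilla-coverage — each cell divided by the square root of the
  product of its row and column sums; the normalization used for
  capture-region (Hi-C^2) maps.

Low-coverage bins are masked *before* balancing and propagate as NaN rows
and columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConvergenceError, DegenerateInputError, FormatError, ParameterError

__all__ = [
    "ContactMatrix",
    "BalancedMatrix",
    "CorrelationMatrix",
    "coarsen",
    "kr_balance",
    "sqrt_vc_balance",
    "pearson_correlation",
]


@dataclass
class ContactMatrix:
    """Symmetric nonnegative binned contact counts for one chromosome.

    Bins are 0-based, half-open ``[start, start + bin_size)``; bin ``i``
    covers ``[start_coord + i*bin_size, start_coord + (i+1)*bin_size)``.
    """

    counts: np.ndarray
    bin_size: int = 1_000_000
    chrom: str = "chrX"
    start_coord: int = 0
    allele: str = "composite"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise FormatError("contact matrix must be square")
        if self.counts.shape[0] < 2:
            raise FormatError("contact matrix must have dimension >= 2")
        if np.any(self.counts < 0):
            raise FormatError("contact matrix has negative counts")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-8, atol=1e-8):
            raise FormatError("contact matrix is not symmetric")
        # enforce exact symmetry so downstream sums are exact
        self.counts = (self.counts + self.counts.T) / 2
        if np.allclose(self.counts, np.round(self.counts)):
            self.counts = np.round(self.counts)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class BalancedMatrix:
    """Contact matrix after KR or sqrt-vanilla-coverage normalization.

    ``values`` carries NaN on masked rows/columns; ``scaling`` is the
    per-bin factor vector (NaN where masked); ``mask`` is True for valid
    bins.
    """

    values: np.ndarray
    scaling: np.ndarray
    mask: np.ndarray
    method: str
    bin_size: int
    chrom: str
    start_coord: int = 0
    allele: str = "composite"
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class CorrelationMatrix:
    """Pearson correlation of balanced-matrix rows (NaN where undefined)."""

    values: np.ndarray
    mask: np.ndarray
    bin_size: int
    chrom: str
    start_coord: int = 0
    allele: str = "composite"

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum ``factor`` x ``factor`` blocks into coarser bins.

    The trailing partial block is kept, so total counts are conserved
    exactly.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return replace(m, counts=m.counts.copy())
    n = m.n_bins
    n_out = -(-n // factor)
    if n_out < 2:
        raise ParameterError("coarsening factor would leave fewer than 2 bins")
    out = np.zeros((n_out, n_out), dtype=m.counts.dtype)
    edges = [min(i * factor, n) for i in range(n_out + 1)]
    for i in range(n_out):
        for j in range(n_out):
            out[i, j] = m.counts[edges[i]:edges[i + 1], edges[j]:edges[j + 1]].sum()
    return ContactMatrix(out, bin_size=m.bin_size * factor, chrom=m.chrom,
                         start_coord=m.start_coord, allele=m.allele)


def coverage_mask(counts: np.ndarray, min_nnz: int = 1, min_row_sum: float = 10.0) -> np.ndarray:
    """True for bins retained for balancing.

    A bin is masked when its row has fewer than ``min_nnz`` nonzero cells or
    a raw row sum below ``min_row_sum`` (coverage floor).
    """
    nnz = (counts > 0).sum(axis=1)
    rowsum = counts.sum(axis=1)
    return (nnz >= min_nnz) & (rowsum >= min_row_sum)


def _kr_core(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Knight-Ruiz balancing vector for a fully supported symmetric matrix.

    Returns x with diag(x) @ A @ diag(x) having unit row sums to within
    ``tol`` (max absolute deviation).  Inner-outer Newton scheme with a CG
    inner iteration and the standard eta forcing sequence.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise ConvergenceError(
                f"KR balancing did not converge in {max_outer} outer iterations",
                residual=float(np.sqrt(rout)))
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = ((Delta - y[big]) / ap[big]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 10 * n:  # CG stall guard
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def kr_balance(m: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000,
               min_nnz: int = 1, min_row_sum: float = 10.0) -> BalancedMatrix:
    """Knight-Ruiz balance a contact matrix.

    Low-coverage bins are masked before balancing; on the retained
    submatrix the KR scaling vector x is computed so diag(x) A diag(x) has
    equal row sums (max relative deviation <= tol).  The result is rescaled
    so unmasked row sums equal the mean unmasked raw row sum, preserving
    the count scale of the input.
    """
    keep = coverage_mask(m.counts, min_nnz=min_nnz, min_row_sum=min_row_sum)
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 bins pass the coverage mask")
    A = m.counts[np.ix_(keep, keep)].astype(float)
    x_sub = _kr_core(A, tol=tol, max_outer=max_iter)
    balanced_sub = x_sub[:, None] * A * x_sub[None, :]
    target = m.counts[keep].sum(axis=1).mean()
    balanced_sub *= target  # unit row sums -> mean raw row sum

    n = m.n_bins
    values = np.full((n, n), np.nan)
    values[np.ix_(keep, keep)] = balanced_sub
    scaling = np.full(n, np.nan)
    scaling[keep] = x_sub * np.sqrt(target)
    return BalancedMatrix(values=values, scaling=scaling, mask=keep, method="KR",
                          bin_size=m.bin_size, chrom=m.chrom,
                          start_coord=m.start_coord, allele=m.allele,
                          meta={"tol": tol, "min_nnz": min_nnz,
                                "min_row_sum": min_row_sum,
                                "row_sum_target": float(target)})


def sqrt_vc_balance(m: ContactMatrix, min_nnz: int = 1,
                    min_row_sum: float = 0.0) -> BalancedMatrix:
    """Square-root vanilla-coverage normalization.

    values[i, j] = counts[i, j] / sqrt(rowsum_i * rowsum_j) over unmasked
    bins; zero-coverage rows are masked.  This is the 'Coverage (Sqrt)'
    normalization used for capture-region maps.
    """
    keep = coverage_mask(m.counts, min_nnz=min_nnz, min_row_sum=min_row_sum)
    keep &= m.counts.sum(axis=1) > 0
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 bins with coverage")
    sub = m.counts[np.ix_(keep, keep)].astype(float)
    rowsum = sub.sum(axis=1)
    scale = 1.0 / np.sqrt(rowsum)
    sub_values = scale[:, None] * sub * scale[None, :]
    n = m.n_bins
    values = np.full((n, n), np.nan)
    values[np.ix_(keep, keep)] = sub_values
    scaling = np.full(n, np.nan)
    scaling[keep] = scale
    return BalancedMatrix(values=values, scaling=scaling, mask=keep,
                          method="sqrt_vc", bin_size=m.bin_size, chrom=m.chrom,
                          start_coord=m.start_coord, allele=m.allele)


def pearson_correlation(b: BalancedMatrix) -> CorrelationMatrix:
    """Pearson correlation of balanced-matrix rows.

    Cell (i, j) is the correlation of rows i and j restricted to unmasked
    columns excluding columns i and j themselves (the self and partner
    columns would otherwise dominate through the diagonal).  Rows constant
    over the retained columns yield undefined correlations and are masked.
    """
    keep = b.mask.copy()
    if keep.sum() < 3:
        raise DegenerateInputError("need at least 3 unmasked bins for correlation")
    n = b.n_bins
    idx = np.flatnonzero(keep)
    values = np.full((n, n), np.nan)
    defined = keep.copy()
    for ii, i in enumerate(idx):
        values[i, i] = 1.0
        for j in idx[ii + 1:]:
            cols = idx[(idx != i) & (idx != j)]
            xi = b.values[i, cols]
            xj = b.values[j, cols]
            sx = xi.std()
            sy = xj.std()
            if sx == 0 or sy == 0 or cols.size < 2:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            values[i, j] = values[j, i] = np.clip(r, -1.0, 1.0)
    # rows that produced no defined off-diagonal value are masked
    for i in idx:
        off = np.delete(values[i], i)
        if np.all(np.isnan(off)):
            defined[i] = False
            values[i, :] = np.nan
            values[:, i] = np.nan
    return CorrelationMatrix(values=values, mask=defined, bin_size=b.bin_size,
                             chrom=b.chrom, start_coord=b.start_coord,
                             allele=b.allele)
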