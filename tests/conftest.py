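import numpy as np
import pytest

from ximega.matrix import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20231111)


@pytest.fixture
def random_symmetric(rng):
    """Factory for random strictly positive symmetric contact matrices."""

    def make(n: int, low: float = 1.0, high: float = 50.0) -> ContactMatrix:
        a = rng.uniform(low, high, size=(n, n))
        return ContactMatrix((a + a.T) / 2, bin_size=1_000_000)

    return make


def sinkhorn_oracle(A: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Independent fixed-point balancing oracle.

    Alternately rescales rows and columns of a positive symmetric matrix
    until every row sum equals 1 to within ``tol``; returns the balanced
    matrix.  Deliberately naive: used only to pin down KR results.
    """
    r = np.ones(A.shape[0])
    c = np.ones(A.shape[0])
    for _ in range(max_iter):
        r = 1.0 / (A @ c)
        c = 1.0 / (A.T @ r)
        B = r[:, None] * A * c[None, :]
        if np.abs(B.sum(axis=1) - 1).max() < tol and np.abs(B.sum(axis=0) - 1).max() < tol:
            return B
    raise RuntimeError("Sinkhorn oracle did not converge")


def insulation_oracle(values: np.ndarray, w: int):
    """Naive per-bin window summation for insulation raw scores.

    Explicit O(n * w^2) double loops over cells; crossing square is rows
    i-w..i-1 x cols i+1..i+w, flanks are the within-side upper triangles
    including the diagonal.
    """
    n = values.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        cross = 0.0
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                cross += values[a, b]
        flank = 0.0
        for a in range(i - w, i):
            for b in range(a, i):
                flank += values[a, b]
        for a in range(i + 1, i + w + 1):
            for b in range(a, i + w + 1):
                flank += values[a, b]
        if flank > 0 and cross > 0:
            raw[i] = cross / flank
    return raw
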