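"""Reading and writing contact matrices.

Three on-disk forms:

* ``dense``   — whitespace-delimited square text matrix.
* ``triplet`` — sparse ``i<TAB>j<TAB>count`` records (0-based bins); the
  upper/lower triangle is mirrored and duplicate records are summed.
* ``binned_container`` — minimal HDF5 layout compatible with the cooler
  single-resolution schema (``bins`` and ``pixels`` tables).

Every writer emits a sidecar JSON (``<path>.json``) with bin_size, chrom,
start_coord and allele so matrices round-trip with their metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import FormatError
from .matrix import ContactMatrix

__all__ = ["read_matrix", "write_matrix"]

_FORMATS = ("dense", "triplet", "binned_container")


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def read_matrix(path, format: str = "dense", bin_size: int | None = None,
                chrom: str | None = None, n_bins: int | None = None,
                start_coord: int | None = None,
                allele: str | None = None) -> ContactMatrix:
    """Read a contact matrix; explicit arguments override sidecar metadata."""
    if format not in _FORMATS:
        raise FormatError(f"unknown matrix format {format!r}")
    path = Path(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    bin_size = bin_size if bin_size is not None else meta.get("bin_size", 1_000_000)
    chrom = chrom if chrom is not None else meta.get("chrom", "chrX")
    start_coord = start_coord if start_coord is not None else meta.get("start_coord", 0)
    allele = allele if allele is not None else meta.get("allele", "composite")

    if format == "dense":
        counts = np.loadtxt(path, ndmin=2)
        if counts.shape[0] != counts.shape[1]:
            raise FormatError(f"dense matrix in {path} is not square")
        if np.any(counts < 0):
            raise FormatError(f"negative counts in {path}")
        if not np.allclose(counts, counts.T, rtol=1e-6, atol=1e-6):
            raise FormatError(f"dense matrix in {path} is asymmetric beyond tolerance")
    elif format == "triplet":
        counts = _read_triplet(path, n_bins=n_bins or meta.get("n_bins"))
    else:
        counts, bin_size, chrom, start_coord, allele = _read_container(
            path, bin_size, chrom, start_coord, allele)
    return ContactMatrix(counts, bin_size=bin_size, chrom=chrom,
                         start_coord=start_coord, allele=allele)


def _read_triplet(path: Path, n_bins: int | None) -> np.ndarray:
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'i j count'")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if c < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if i < 0 or j < 0:
                raise FormatError(f"{path}:{lineno}: negative bin index")
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if not rows:
        raise FormatError(f"{path}: no triplet records")
    dim = n_bins if n_bins is not None else max(max(rows), max(cols)) + 1
    if max(max(rows), max(cols)) >= dim:
        raise FormatError(f"{path}: triplet index exceeds declared dimension {dim}")
    counts = np.zeros((dim, dim))
    for i, j, c in zip(rows, cols, vals):
        counts[i, j] += c
        if i != j:
            counts[j, i] += c
    return counts


def _read_container(path, bin_size, chrom, start_coord, allele):
    import h5py

    with h5py.File(path, "r") as f:
        bin_size = int(f.attrs.get("bin-size", bin_size))
        chrom = f.attrs.get("chrom", chrom)
        if isinstance(chrom, bytes):
            chrom = chrom.decode()
        start_coord = int(f.attrs.get("start-coord", start_coord))
        allele = f.attrs.get("allele", allele)
        if isinstance(allele, bytes):
            allele = allele.decode()
        n = f["bins/start"].shape[0]
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        c = f["pixels/count"][:]
    counts = np.zeros((n, n))
    np.add.at(counts, (b1, b2), c)
    upper_mirror = b1 != b2
    np.add.at(counts, (b2[upper_mirror], b1[upper_mirror]), c[upper_mirror])
    return counts, bin_size, chrom, start_coord, allele


def write_matrix(m: ContactMatrix, path, format: str = "dense",
                 method: str | None = None) -> Path:
    """Write a contact matrix plus its metadata sidecar; returns the path."""
    if format not in _FORMATS:
        raise FormatError(f"unknown matrix format {format!r}")
    path = Path(path)
    counts = m.counts
    integral = np.allclose(counts, np.round(counts))
    if format == "dense":
        fmt = "%d" if integral else "%.10g"
        np.savetxt(path, counts, fmt=fmt, delimiter="\t")
    elif format == "triplet":
        with open(path, "w") as fh:
            iu, ju = np.triu_indices(m.n_bins)
            for i, j in zip(iu, ju):
                c = counts[i, j]
                if c != 0:
                    fh.write(f"{i}\t{j}\t{int(c) if integral else c}\n")
    else:
        _write_container(m, path)
    meta = {"bin_size": m.bin_size, "chrom": m.chrom,
            "start_coord": m.start_coord, "allele": m.allele,
            "n_bins": m.n_bins}
    if method:
        meta["method"] = method
    _sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def _write_container(m: ContactMatrix, path):
    import h5py

    n = m.n_bins
    iu, ju = np.triu_indices(n)
    keep = m.counts[iu, ju] != 0
    starts = m.start_coord + np.arange(n, dtype=np.int64) * m.bin_size
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = m.bin_size
        f.attrs["chrom"] = m.chrom
        f.attrs["start-coord"] = m.start_coord
        f.attrs["allele"] = m.allele
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.full(n, m.chrom.encode()))
        bins.create_dataset("start", data=starts)
        bins.create_dataset("end", data=starts + m.bin_size)
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu[keep].astype(np.int64))
        pixels.create_dataset("bin2_id", data=ju[keep].astype(np.int64))
        pixels.create_dataset("count", data=m.counts[iu, ju][keep])
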