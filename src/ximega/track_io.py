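"""bedGraph / BED / TSV writers for per-bin tracks and interval calls."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["write_bedgraph", "read_bedgraph", "write_bed", "write_fourc_bedgraph"]


def write_bedgraph(path, chrom: str, values, bin_size: int, start_coord: int = 0,
                   skip_nan: bool = True) -> Path:
    """Write a per-bin value track as bedGraph (0-based half-open bins)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if skip_nan and np.isnan(v):
                continue
            start = start_coord + i * bin_size
            fh.write(f"{chrom}\t{start}\t{start + bin_size}\t{v:.6g}\n")
    return path


def read_bedgraph(path) -> pd.DataFrame:
    """Read bedGraph into a DataFrame (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bed(path, intervals) -> Path:
    """Write (chrom, start, end, name[, score]) tuples as BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
    return path


def write_fourc_bedgraph(path, profile) -> Path:
    """Write a multi-chromosome 4C profile as one bedGraph."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(profile.counts):
            for i, v in enumerate(profile.counts[chrom]):
                if v == 0:
                    continue
                start = i * profile.bin_size
                fh.write(f"{chrom}\t{start}\t{start + profile.bin_size}\t{v:.6g}\n")
    return path
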