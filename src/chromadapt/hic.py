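"""Binned Hi-C contact matrices.

A :class:`ContactMatrix` is a square symmetric matrix of non-negative
interaction strengths for one chromosome at a fixed bin size, with
0-based half-open bin coordinates.  On disk it is a dense tab-separated
text matrix next to a JSON sidecar recording chromosome and bin size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import InputError


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    matrix: np.ndarray
    #: tolerance for the symmetry check, relative to the matrix scale
    sym_rtol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("contact matrix must be square")
        if self.bin_size <= 0:
            raise InputError("bin_size must be positive")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise InputError("contact matrix must be finite and non-negative")
        if not np.allclose(m, m.T, rtol=self.sym_rtol, atol=0):
            raise InputError(f"contact matrix for {self.chrom} is not symmetric")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def masked_bins(self) -> np.ndarray:
        """Boolean mask of all-zero rows (unmappable / empty bins)."""
        return ~self.matrix.any(axis=1)

    # -- disk round trip -------------------------------------------------

    def write(self, prefix: str | Path) -> None:
        """Write ``<prefix>.matrix.tsv`` and ``<prefix>.json``."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".matrix.tsv"), self.matrix,
                   delimiter="\t", fmt="%.6g")
        prefix.with_suffix(".json").write_text(json.dumps(
            {"chrom": self.chrom, "bin_size": self.bin_size,
             "n_bins": self.n_bins}))

    @classmethod
    def read(cls, prefix: str | Path) -> "ContactMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        m = np.loadtxt(prefix.with_suffix(".matrix.tsv"), delimiter="\t",
                       ndmin=2)
        return cls(chrom=meta["chrom"], bin_size=int(meta["bin_size"]),
                   matrix=m)
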