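"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* ppm axes are stored **descending** (NMR display convention, high field on
  the right).  All region windows are half-open intervals ``[lo, hi)`` in
  *ascending* ppm semantics regardless of storage order.
* ``SpectraSet`` couples an aligned sample x data-point intensity matrix with
  a shared ppm axis and per-sample metadata; ``FeatureTable`` holds the
  metabolite relative integrals that all statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("subject_id", "disease", "timepoint", "response")

__all__ = [
    "META_COLUMNS",
    "Spectrum1D",
    "SpectraSet",
    "FeatureTable",
    "window_mask",
]


def window_mask(ppm: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of axis points falling in ``[lo, hi)`` (ascending ppm)."""
    if not lo < hi:
        raise ValueError(f"empty window [{lo}, {hi})")
    return (ppm >= lo) & (ppm < hi)


@dataclass
class Spectrum1D:
    """One processed 1D spectrum: ppm axis, intensities, sample identity."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D and equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return self.ppm.size

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(self.ppm.copy(), self.intensity.copy(), self.sample_id)


@dataclass
class SpectraSet:
    """Aligned sample x point matrix with a shared ppm axis and metadata.

    ``meta`` is indexed by ``sample_id`` and carries at least the columns in
    :data:`META_COLUMNS`.
    """

    ppm: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.ppm.size:
            raise ValueError("matrix column count must equal len(ppm)")
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError("meta rows must match matrix rows")
        if self.meta.index.has_duplicates:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)

    def spectrum(self, sample_id: str) -> Spectrum1D:
        i = self.meta.index.get_loc(sample_id)
        return Spectrum1D(self.ppm, self.matrix[i], sample_id)

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.ppm.copy(), self.matrix.copy(), self.meta.copy())

    # -- TSV round trip (matrix TSV: first row = ppm axis, one row/sample) --
    def to_tsv(self, matrix_path, meta_path) -> None:
        df = pd.DataFrame(self.matrix, index=self.meta.index,
                          columns=[f"{p:.6f}" for p in self.ppm])
        df.index.name = "sample_id"
        df.to_csv(matrix_path, sep="\t", float_format="%.8g")
        self.meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, meta_path) -> "SpectraSet":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        ppm = np.array([float(c) for c in df.columns])
        return cls(ppm, df.to_numpy(dtype=float), meta.loc[df.index])


@dataclass
class FeatureTable:
    """Sample x metabolite relative-integral matrix plus sample metadata.

    ``flags`` marks entries whose noise-corrected integral came out negative
    (they are retained, not clipped).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    flags: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("metabolite names must be unique")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, mask) -> "FeatureTable":
        fl = self.flags.loc[mask] if self.flags is not None else None
        return FeatureTable(self.values.loc[mask].copy(),
                            self.meta.loc[mask].copy(), fl)

    def to_tsv(self, path) -> None:
        out = pd.concat(
            [self.meta.add_prefix("meta_"), self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_cols = [c for c in df.columns if c.startswith("meta_")]
        meta = df[meta_cols].rename(columns=lambda c: c[len("meta_"):])
        values = df.drop(columns=meta_cols)
        return cls(values, meta)
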