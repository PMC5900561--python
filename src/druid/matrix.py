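"""Feature-by-time abundance containers and their TSV round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXON_COUNT = "exon_count"
INTRON_COVERAGE = "intron_coverage"
_KINDS = (EXON_COUNT, INTRON_COVERAGE)


@dataclass
class AbundanceMatrix:
    """Features x time points of non-negative abundances.

    ``data`` is a DataFrame whose index holds feature ids and whose columns
    are time points in hours (floats, strictly increasing). ``kind`` records
    whether values are exon read counts or intron mean coverages; counts may
    be real-valued when they are model expectations rather than sampled reads.
    """

    data: pd.DataFrame
    kind: str = EXON_COUNT

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.data = self.data.copy()
        self.data.columns = [float(c) for c in self.data.columns]
        tps = np.asarray(self.data.columns, dtype=float)
        if np.any(np.diff(tps) <= 0):
            raise ValueError("time points must be strictly increasing")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_points(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_times(self, keep: list[float]) -> "AbundanceMatrix":
        keep = [float(t) for t in keep]
        missing = [t for t in keep if t not in set(self.time_points)]
        if missing:
            raise KeyError(f"time points not in matrix: {missing}")
        return AbundanceMatrix(self.data[sorted(keep)], kind=self.kind)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = EXON_COUNT) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, kind=kind)


@dataclass
class GenomePartition:
    """Per-time-point totals of mapped reads assigned to each source genome.

    ``totals``: DataFrame indexed by genome label, columns = time points in
    hours. Labels are constant across time points by construction.
    """

    totals: pd.DataFrame

    def __post_init__(self) -> None:
        self.totals = self.totals.copy()
        self.totals.columns = [float(c) for c in self.totals.columns]
        if (self.totals.to_numpy() < 0).any():
            raise ValueError("genome totals must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.totals.index)

    @property
    def time_points(self) -> np.ndarray:
        return np.asarray(self.totals.columns, dtype=float)

    def label_totals(self, label: str) -> pd.Series:
        if label not in self.totals.index:
            raise KeyError(f"genome label {label!r} not in partition {self.labels}")
        return self.totals.loc[label]

    def to_tsv(self, path: str | Path) -> None:
        out = self.totals.copy()
        out.index.name = "genome_label"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomePartition":
        return cls(pd.read_csv(path, sep="\t", index_col=0))
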