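"""Experiment design: time points, growth, normalization mode, thresholds.

Defaults are the standard design of a mammalian 4SU course: harvests at
1, 2, 4, 8, 12 and 24 h, a 24-h doubling time, gene filter of >=1 read at
every time point with >=5 at one or more, intron mean-coverage filter of
0.5 reads, and k-means with four clusters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

NORMALIZATION_MODES = ("intron", "spikein", "none")
MODELS = ("bounded_growth", "exponential_decay")


@dataclass
class ExperimentDesign:
    time_points: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    doubling_time_hours: float = 24.0
    normalization_mode: str = "intron"
    genome_label_map: dict[str, str] = field(default_factory=dict)
    spikein_labeled_label: str | None = None
    spikein_unlabeled_label: str | None = None
    strandedness: str = "reverse"
    gene_filter_min_all: float = 1.0
    gene_filter_min_any: float = 5.0
    intron_min_coverage: float = 0.5
    kmeans_k: int = 4
    seed: int = 0
    weights_scheme: str = "poisson"
    min_spikein_reads: float = 10_000.0
    select_cluster: int | None = None
    model: str = "bounded_growth"

    def __post_init__(self) -> None:
        self.time_points = tuple(float(t) for t in self.time_points)
        if len(self.time_points) < 3:
            raise ValueError(
                f"need >=3 time points for fitting, got {len(self.time_points)}"
            )
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")
        if self.doubling_time_hours is not None and self.doubling_time_hours <= 0:
            raise ValueError("doubling time must be positive")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}"
            )
        if self.normalization_mode == "spikein" and not self.spikein_labeled_label:
            raise ValueError("spikein mode requires spikein_labeled_label")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")

    @property
    def gamma(self) -> float:
        """Growth-dilution constant applied during fitting: ln(2)/delta in
        spike-in mode (growth information is lost with exogenous standards
        and must be corrected for); 0 in intron mode (no correction applied)
        and for shutoff fits."""
        if self.model == "exponential_decay":
            return 0.0
        if self.normalization_mode == "spikein" and self.doubling_time_hours:
            return math.log(2) / self.doubling_time_hours
        return 0.0

    def replace(self, **kwargs) -> "ExperimentDesign":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        """Load a flat key/value YAML config; unknown keys are rejected."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "time_points" in raw:
            raw["time_points"] = tuple(raw["time_points"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = self.to_dict()
        d["time_points"] = list(d["time_points"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
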