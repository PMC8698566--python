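"""Run configuration: every printed cutoff of the analysis in one place.

Defaults follow the published workflow: membership > 0.4 for hard assignment,
cluster counts scanned over 2..10, hypergeometric alphas of 0.001 for
subcellular compartments and 0.05 for molecular types, Fisher retention at
p < 0.001 with odds ratio > 2, per-dataset marker alpha 0.05, paired
differential-expression alpha 0.01, and a 1% cross-type interaction fraction
(with the 5% "figure4" preset).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

#: Mapping of the two compartments without a dedicated cascade row onto the
#: plasma-membrane / cytoplasm / nucleus grid.
DEFAULT_ROW_MAP = {
    "extracellular space": "plasma membrane",
    "other/unknown": "cytoplasm",
}


@dataclass
class Config:
    # table filters
    min_unique_peptides: int = 2
    require_all_replicates: bool = True

    # preprocessing
    median_center: bool = True
    replicate_average: str = "arithmetic"  # or "geometric"
    zscore_ddof: int = 1

    # clustering
    membership_threshold: float = 0.4
    k_range: tuple[int, int] = (2, 10)
    fuzzifier: float | None = None  # None -> estimated from (N, D)
    max_iter: int = 300
    tol: float = 1e-6
    n_restarts: int = 5

    # enrichment / association
    alpha_compartment: float = 0.001
    alpha_type: float = 0.05
    alpha_pair: float = 0.05
    alpha_type_edge: float = 0.05
    alpha_concept: float = 0.001
    odds_ratio_floor: float = 2.0
    alpha_marker: float = 0.05
    alpha_paired: float = 0.01
    type_edge_fraction: float = 0.01  # "figure4" preset: 0.05
    universe: str = "labeled"  # or "quantified"
    paired_test: str = "paired"  # or "unpaired" (as printed)
    welch: bool = False

    # cascade defaults
    cascade_terminal_type: str | None = "transcription regulator"
    compartment_row_map: dict = field(default_factory=lambda: dict(DEFAULT_ROW_MAP))

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.membership_threshold < 1:
            raise ParameterError("membership_threshold must lie in (0, 1)")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ParameterError(f"invalid k_range {self.k_range}")
        for name in ("alpha_compartment", "alpha_type", "alpha_pair",
                     "alpha_type_edge", "alpha_concept", "alpha_marker",
                     "alpha_paired", "type_edge_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.fuzzifier is not None and self.fuzzifier <= 1:
            raise ParameterError("fuzzifier must exceed 1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
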