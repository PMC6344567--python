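"""Pipeline configuration: every tunable constant in one serializable place.

Defaults mirror the published operating point of the analysis this package
implements: candidate probability strictly above 0.5, junction concordance
of at least 25%, 11-residue peptide flanks, 8-11-mer epitopes at a strong-
binder rank below 0.5%, fusion fraction as span counts per 10 million
mapped paired reads with a high/low survival split at 2.7 and a 2x rule
against matched normal controls.  The configuration is echoed into every
run summary so outputs alone reconstruct the parameterization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .align import Scoring
from .types import FusionNeoError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    probability_threshold: float = 0.5
    concordance_threshold: float = 25.0
    concordance_inclusive: bool = True
    max_arm: int = 250
    flank_aa: int = 11
    peptide_lengths: tuple[int, ...] = (8, 9, 10, 11)
    strong_rank: float = 0.5
    inframe_kmer: int = 8
    ff_mode: str = "span_sum"  # or "fusion_count"
    ff_threshold: float = 2.7
    control_multiplier: float = 2.0
    excluded_families: tuple[str, ...] = ("SRGAP2",)
    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    min_recommended_reads: int = 40_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise FusionNeoError("probability_threshold must lie in [0, 1]")
        if not (0.0 <= self.concordance_threshold <= 100.0):
            raise FusionNeoError("concordance_threshold must lie in [0, 100]")
        if self.strong_rank <= 0 or self.ff_threshold < 0 or self.control_multiplier <= 0:
            raise FusionNeoError("thresholds out of range")
        if self.ff_mode not in ("span_sum", "fusion_count"):
            raise FusionNeoError(f"unknown ff_mode {self.ff_mode!r}")
        if any(k < 8 or k > 11 for k in self.peptide_lengths):
            raise FusionNeoError("peptide lengths must lie in 8..11")
        self.peptide_lengths = tuple(int(k) for k in self.peptide_lengths)
        self.excluded_families = tuple(self.excluded_families)

    @property
    def scoring(self) -> Scoring:
        return Scoring(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["peptide_lengths"] = list(self.peptide_lengths)
        data["excluded_families"] = list(self.excluded_families)
        return data

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FusionNeoError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
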