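"""Pipeline settings with defaults matching the published analysis
parameters: k = 10 co-expression neighbors, minimum module size 5, 1000
cross-talk permutations at alpha 0.05, 400 Cox resamples on 90% of the
training samples, GeneRank damping d = 0.70, top-5% selection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineSettings"]


@dataclass
class PipelineSettings:
    # co-expression network
    k_neighbors: int = 10
    ranking: str = "absolute"  # or "signed"
    # module detection
    min_module_size: int = 5
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    k_core_param: int = 2
    # cross-talk permutation test
    n_permutations: int = 1000
    crosstalk_alpha: float = 0.05
    # resampled Cox
    n_rep: int = 400
    sample_fraction: float = 0.9
    cox_alpha: float = 0.05
    # GeneRank
    damping: float = 0.70
    top_fraction: float = 0.05
    generank_method: str = "direct"
    generank_tol: float = 1e-10
    # master seed; per-stage seeds are derived at fixed offsets
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.ranking not in ("absolute", "signed"):
            raise ValueError("ranking must be 'absolute' or 'signed'")
        if not 0 <= self.damping < 1:
            raise ValueError("damping must be in [0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    # fixed offsets keep each stage reproducible when rerun alone
    _STAGE_OFFSETS = {"crosstalk": 1, "resample": 2, "simulate": 3, "randomsets": 4}

    def stage_seed(self, stage: str) -> int | None:
        if self.seed is None:
            return None
        return (int(self.seed) + 1000003 * self._STAGE_OFFSETS[stage]) % (2**31)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineSettings":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown settings: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineSettings":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
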