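"""Analysis configuration and reproducible per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "stage_seed", "load_config", "dump_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from one master seed.

    Uses a CRC of the stage name so adding new stages never perturbs the
    seeds of existing ones. Result fits in 31 bits.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the end-to-end aggression-network analysis.

    Defaults follow the emulated study protocol: a 60-s win cooldown per
    ordered actor->target pair, four 6-day observation quarters, EC
    regularizer epsilon = 0.01 (small against typical row totals of tens
    of events while guaranteeing an irreducible chain), rank-focus window
    Delta in [1, 5], and aggression chains up to six edges.
    """

    cooldown_seconds: float = 60.0
    window_days: float | None = 6.0  # None = single whole-study window
    excluded_ids: tuple[str, ...] = ()
    epsilon: float = 0.01
    bootstrap_replicates: int = 0  # 0 disables the bootstrap stage
    null_replicates: int = 100
    max_chain_length: int = 6
    delta_range: tuple[int, int] = (1, 5)
    t_baseline: str = "interior"  # or "first"
    density_directed: bool = True
    recompute_ranks_per_window: bool = True
    rerank_null_samples: bool = False  # sensitivity analysis only
    rerank_bootstrap: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cooldown_seconds <= 0:
            raise ValueError("cooldown_seconds must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.t_baseline not in ("interior", "first"):
            raise ValueError("t_baseline must be 'interior' or 'first'")
        object.__setattr__(self, "excluded_ids", tuple(self.excluded_ids))
        object.__setattr__(self, "delta_range", tuple(self.delta_range))

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.rng_seed, stage)

    def with_updates(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_ids"] = list(d["excluded_ids"])
        d["delta_range"] = list(d["delta_range"])
        return d


def load_config(path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML mapping (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def dump_config(cfg: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
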