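"""Run configuration: YAML blocks validated before any stage runs.

The experiment ``mode`` fixes the sector geometry: ``object`` uses the
70 x 50 mm arena with two 20-mm choice circles, ``odor`` the 150 x 50 mm
arena split into longitudinal thirds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .arena import ArenaConfig, OBJECT_ARENA_MM, ODOR_ARENA_MM
from .errors import ConfigurationError
from .simulate import SimParams
from .tracking import TrackingConfig

_MODES = {"object": "two_circles", "odor": "three_thirds"}

_KNOWN_BLOCKS = {"mode", "seed", "arena", "sim", "tracking", "metrics", "stats"}


@dataclass
class RunConfig:
    mode: str = "object"
    seed: int = 0
    arena: ArenaConfig = None  # type: ignore[assignment]
    sim: SimParams = None  # type: ignore[assignment]
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    min_dwell: int = 2
    speed_floor: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(
                f"invalid value for key 'mode': {self.mode!r} (expected object|odor)"
            )
        length, width = OBJECT_ARENA_MM if self.mode == "object" else ODOR_ARENA_MM
        if self.arena is None:
            self.arena = ArenaConfig(length, width, mode=_MODES[self.mode])
        if self.arena.mode != _MODES[self.mode]:
            raise ConfigurationError(
                f"arena mode {self.arena.mode!r} contradicts experiment mode {self.mode!r}"
            )
        if self.sim is None:
            self.sim = SimParams(
                arena_length_mm=self.arena.length_mm,
                arena_width_mm=self.arena.width_mm,
                seed=self.seed,
            )
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_BLOCKS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        mode = data.get("mode", "object")
        seed = int(data.get("seed", 0))
        arena = None
        if "arena" in data:
            try:
                arena = ArenaConfig(**data["arena"])
            except TypeError as exc:
                raise ConfigurationError(f"bad arena block: {exc}") from exc
        sim = None
        if "sim" in data:
            try:
                sim = SimParams(**data["sim"])
            except TypeError as exc:
                raise ConfigurationError(f"bad sim block: {exc}") from exc
        try:
            tracking = TrackingConfig(**data.get("tracking", {}))
        except TypeError as exc:
            raise ConfigurationError(f"bad tracking block: {exc}") from exc
        mblock = data.get("metrics", {})
        sblock = data.get("stats", {})
        for blk, allowed in ((mblock, {"min_dwell", "speed_floor"}), (sblock, {"alpha"})):
            extra = set(blk) - allowed
            if extra:
                raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(
            mode=mode,
            seed=seed,
            arena=arena,
            sim=sim,
            tracking=tracking,
            min_dwell=int(mblock.get("min_dwell", 2)),
            speed_floor=float(mblock.get("speed_floor", 1.0)),
            alpha=float(sblock.get("alpha", 0.05)),
        )

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "arena": asdict(self.arena),
            "sim": asdict(self.sim),
            "tracking": asdict(self.tracking),
            "metrics": {"min_dwell": self.min_dwell, "speed_floor": self.speed_floor},
            "stats": {"alpha": self.alpha},
        }

    def dump(self, path: str | Path) -> None:
        """Echo the fully-resolved configuration for reproducibility."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
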