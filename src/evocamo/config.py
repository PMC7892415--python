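"""Run configuration, seeding, and screen geometry.

A single :class:`RunConfig` snapshot plus a master seed fully determines a
pipeline run.  The master seed is expanded into independent per-component
substreams with :func:`numpy.random.SeedSequence.spawn`, so the engine, the
synthetic player, mutation, and movie synthesis never share random state.

Screen geometry defaults describe the touchscreen exhibit the simulated game
emulates: a 478 x 269 mm panel at 1237 x 820 px viewed from roughly 60 cm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

#: Target speeds in screen pixels per second, by speed class.
SPEED_CLASSES = {"fast": 600.0, "medium": 450.0, "slow": 300.0}

#: Trial timeout: the player has this many seconds to catch a target.
DEFAULT_TIMEOUT_S = 5.0


# ---------------------------------------------------------------------------
# Screen geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelGeometry:
    """Pixel <-> physical-unit conversions for a flat screen viewed head-on.

    The horizontal pixel pitch (``screen_mm[0] / screen_px[0]``) is applied to
    both axes: the exhibit screen's printed target size of 38.6 mm for 100 px
    is only consistent with the horizontal pitch, so square pixels at that
    pitch are assumed.
    """

    screen_mm: tuple[float, float] = (478.0, 269.0)
    screen_px: tuple[int, int] = (1237, 820)
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        if min(*self.screen_mm, *self.screen_px, self.viewing_distance_mm) <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.screen_mm[0] / self.screen_px[0]

    def px_to_mm(self, px: float) -> float:
        return px * self.mm_per_px

    def mm_to_deg(self, extent_mm: float) -> float:
        """Visual angle (degrees) subtended by ``extent_mm`` at the viewing
        distance: ``2 * atan(e / 2d)``."""
        return math.degrees(2.0 * math.atan(extent_mm / (2.0 * self.viewing_distance_mm)))

    def px_to_deg(self, px: float) -> float:
        return self.mm_to_deg(self.px_to_mm(px))

    def px_per_s_to_mm_per_s(self, px_per_s: float) -> float:
        return self.px_to_mm(px_per_s)

    def px_per_s_to_deg_per_s(self, px_per_s: float) -> float:
        return self.mm_to_deg(self.px_to_mm(px_per_s))


def pixel_geometry(
    screen_mm: tuple[float, float] = (478.0, 269.0),
    screen_px: tuple[int, int] = (1237, 820),
    viewing_distance_mm: float = 600.0,
) -> PixelGeometry:
    """Build the conversion helper for a screen/viewing geometry."""
    return PixelGeometry(tuple(screen_mm), tuple(screen_px), viewing_distance_mm)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full configuration of an evolutionary run.

    Defaults follow the exhibit protocol: 128 targets per generation, each
    played 5 times with a 5 s timeout, three speed classes, four replicates.
    """

    population_size: int = 128
    plays_per_bug: int = 5
    timeout_s: float = DEFAULT_TIMEOUT_S
    speeds_px_s: dict[str, float] = field(default_factory=lambda: dict(SPEED_CLASSES))
    generations: int = 40
    replicates: int = 4
    mutation_rate: float = 0.05
    max_depth: int = 8
    player_kind: str = "perceptual"  # {"perceptual", "null"}
    player_params: dict[str, float] = field(default_factory=dict)
    gabor_preset: str = "preset5"
    emd_params: dict[str, float] = field(
        default_factory=lambda: {
            "spacing_px": 2,
            "delay_time_constant_s": 0.033,
            "frame_rate": 60.0,
        }
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError(
                f"population_size must be even and >= 2 (selection halves the "
                f"population), got {self.population_size}"
            )
        if self.plays_per_bug < 1:
            raise ValueError(f"plays_per_bug must be >= 1, got {self.plays_per_bug}")
        if self.timeout_s <= 0:
            raise ValueError(f"timeout_s must be > 0, got {self.timeout_s}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"mutation_rate must lie in [0, 1], got {self.mutation_rate}")
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")
        if self.player_kind not in ("perceptual", "null"):
            raise ValueError(f"player_kind must be 'perceptual' or 'null', got {self.player_kind!r}")
        for cls, v in self.speeds_px_s.items():
            if v <= 0:
                raise ValueError(f"speed for class {cls!r} must be > 0, got {v}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


def load_config(path: str) -> RunConfig:
    """Load a YAML config; missing keys take the exhibit-protocol defaults,
    unknown keys are rejected with the offending names."""
    return RunConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def spawn_rngs(master_seed: int, labels: list[str]) -> dict[str, np.random.Generator]:
    """Derive one independent Generator per label from a master seed.

    Labels are sorted before spawning so the mapping does not depend on call
    order.
    """
    labels = sorted(labels)
    children = np.random.SeedSequence(master_seed).spawn(len(labels))
    return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def child_seed(master_seed: int, *tokens) -> int:
    """Deterministic sub-seed (< 2**31) from a master seed and context tokens.

    Tokens are hashed with CRC32 of their string form, so the derivation is
    stable across processes and platforms (unlike builtin ``hash``).
    """
    import zlib

    hashed = [zlib.crc32(str(t).encode()) % (2**31) for t in tokens]
    ss = np.random.SeedSequence([master_seed] + hashed)
    return int(ss.generate_state(1)[0] % (2**31))
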