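"""The evolutionary game loop: score, truncate, reproduce.

Each generation holds 128 targets ("bugs") of one speed class.  Every bug is
played a fixed number of times (default 5) and its fitness is the arithmetic
mean of its capture times in seconds — longer is fitter, because a target
that survives pursuit longer is better protected.  Trials that exceed the
timeout enter the mean at the timeout value (censored trials cannot be
removed from an online evolutionary score).  Selection removes the lower
half by fitness; the surviving half is copied unchanged into the next
generation and copied again with mutation to fill the other half
(overlapping replacement with elitism).

The control ("null") run uses the identical machinery but a genome-blind
lognormal capture-time model, so any systematic pattern change it produces
must come from drift or algorithmic bias rather than selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, child_seed
from .genome import PatternGenome, mutate_genome, random_genome
from .player import CaptureTimeModel, NullPlayer, PerceptualPlayer

__all__ = [
    "BugRecord",
    "GenerationRecord",
    "EvolutionLog",
    "init_population",
    "score_population",
    "select_and_reproduce",
    "run_evolution",
    "run_null_model",
]


@dataclass
class BugRecord:
    """One target in one generation: genome, speed class, and its trial log."""

    genome: PatternGenome
    speed_class: str
    capture_times: list[float] = field(default_factory=list)
    required_plays: int = 5

    @property
    def plays(self) -> int:
        return len(self.capture_times)

    @property
    def fitness(self) -> float | None:
        """Mean capture time (s); defined once the bug has its required plays."""
        if self.plays < self.required_plays:
            return None
        return float(np.mean(self.capture_times))

    def fresh_copy(self) -> "BugRecord":
        return BugRecord(self.genome, self.speed_class, [], self.required_plays)


@dataclass
class GenerationRecord:
    generation_index: int
    population: list[BugRecord]
    speed_class: str
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if any(b.speed_class != self.speed_class for b in self.population):
            raise ValueError("all bugs in a generation must share the speed class")


@dataclass
class EvolutionLog:
    generations: list[GenerationRecord]
    config: dict
    master_seed: int
    speed_class: str
    replicate_id: int

    def fitness_series(self) -> list[float]:
        return [
            float(np.mean([b.fitness for b in g.population]))
            for g in self.generations
        ]


# ---------------------------------------------------------------------------
# Population operations
# ---------------------------------------------------------------------------

def init_population(
    n: int,
    seed: int,
    speed_class: str = "fast",
    max_depth: int = 8,
    plays_per_bug: int = 5,
    replicate_id: int = 0,
) -> GenerationRecord:
    """Generation 0: ``n`` completely random genomes (``n`` even, >= 2)."""
    if n < 2 or n % 2:
        raise ValueError(
            f"population size must be even and >= 2 (selection removes the "
            f"bottom half), got {n}"
        )
    base = np.random.SeedSequence(seed).generate_state(n)
    bugs = [
        BugRecord(random_genome(int(s % 2**31), max_depth), speed_class,
                  required_plays=plays_per_bug)
        for s in base
    ]
    return GenerationRecord(0, bugs, speed_class, replicate_id)


def score_population(
    gen: GenerationRecord,
    player: CaptureTimeModel,
    plays_per_bug: int = 5,
    timeout_s: float = 5.0,
    rng: np.random.Generator | None = None,
) -> GenerationRecord:
    """Play every bug exactly ``plays_per_bug`` times and record its times.

    Times above the timeout are stored as the timeout value.  The player must
    return strictly positive times.
    """
    if plays_per_bug < 1:
        raise ValueError(f"plays_per_bug must be >= 1, got {plays_per_bug}")
    if timeout_s <= 0:
        raise ValueError(f"timeout_s must be > 0, got {timeout_s}")
    rng = np.random.default_rng() if rng is None else rng
    for bug in gen.population:
        bug.required_plays = plays_per_bug
        bug.capture_times = []
        for _ in range(plays_per_bug):
            t = float(player(bug, rng))
            if t <= 0:
                raise ValueError(
                    f"capture-time model returned non-positive time {t} for "
                    f"genome {bug.genome.genome_id}"
                )
            bug.capture_times.append(min(t, timeout_s))
    return gen


def select_and_reproduce(
    scored: GenerationRecord,
    rng: np.random.Generator,
    mutation_rate: float = 0.05,
    max_depth: int = 8,
) -> GenerationRecord:
    """Truncation selection with overlapping replacement.

    The fitness-top half (ties broken by genome id, ascending — deterministic)
    survives unchanged; each survivor also contributes one mutated copy.  All
    bugs start the new generation with empty trial slates.
    """
    unscored = [b for b in scored.population if b.fitness is None]
    if unscored:
        raise ValueError(
            f"{len(unscored)} bugs have fewer than their required plays; "
            "score the generation before selecting"
        )
    ranked = sorted(
        scored.population, key=lambda b: (-b.fitness, b.genome.genome_id)
    )
    survivors = ranked[: len(ranked) // 2]
    elites = [b.fresh_copy() for b in survivors]
    mutants = [
        BugRecord(
            mutate_genome(b.genome, rng, mutation_rate, max_depth),
            b.speed_class,
            required_plays=b.required_plays,
        )
        for b in survivors
    ]
    return GenerationRecord(
        scored.generation_index + 1,
        elites + mutants,
        scored.speed_class,
        scored.replicate_id,
    )


# ---------------------------------------------------------------------------
# Whole runs
# ---------------------------------------------------------------------------

def _make_player(config: RunConfig) -> CaptureTimeModel:
    params = dict(config.player_params)
    if config.player_kind == "null":
        return NullPlayer(
            timeout_s=config.timeout_s,
            mean_s=params.get("mean_s", 1.2),
            sd_s=params.get("sd_s", 0.4),
            plays_per_bug=config.plays_per_bug,
        )
    kwargs = {}
    for key in ("k", "s_max", "log_noise_sd"):
        if key in params:
            kwargs[key] = params[key]
    if "t0" in params:
        kwargs["t0"] = dict(params["t0"])
    return PerceptualPlayer(timeout_s=config.timeout_s, **kwargs)


def _run_single(
    config: RunConfig,
    player: CaptureTimeModel,
    speed_class: str,
    replicate_id: int,
    n_generations: int,
) -> EvolutionLog:
    seed = child_seed(config.master_seed, "engine", replicate_id, speed_class)
    rng = np.random.default_rng(seed)
    gen = init_population(
        config.population_size,
        child_seed(config.master_seed, "init", replicate_id, speed_class),
        speed_class,
        config.max_depth,
        config.plays_per_bug,
        replicate_id,
    )
    generations = []
    for _ in range(n_generations):
        score_population(gen, player, config.plays_per_bug, config.timeout_s, rng)
        generations.append(gen)
        gen = select_and_reproduce(gen, rng, config.mutation_rate, config.max_depth)
    return EvolutionLog(generations, config.to_dict(), config.master_seed,
                        speed_class, replicate_id)


def run_evolution(config: RunConfig) -> list[EvolutionLog]:
    """Run the full design: one independently evolving population per
    (replicate, speed class), each fully determined by the master seed."""
    logs = []
    for replicate_id in range(config.replicates):
        for speed_class in config.speeds_px_s:
            player = _make_player(config)
            logs.append(
                _run_single(config, player, speed_class, replicate_id,
                            config.generations)
            )
    return logs


def run_null_model(
    config: RunConfig,
    mean_s: float = 1.2,
    sd_s: float = 0.4,
    n_generations: int = 40,
    speed_class: str = "fast",
    replicate_id: int = 0,
) -> EvolutionLog:
    """Control run: identical engine, but capture times are genome-blind
    lognormal draws with bug-level moments (``mean_s``, ``sd_s``); the
    per-trial variance is the bug-level variance times ``plays_per_bug``.
    Defaults to the 40-generation control protocol."""
    player = NullPlayer(
        timeout_s=config.timeout_s, mean_s=mean_s, sd_s=sd_s,
        plays_per_bug=config.plays_per_bug,
    )
    return _run_single(config, player, speed_class, replicate_id, n_generations)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def log_to_frame(log: EvolutionLog):
    """Bug-level tidy rows (replicate, speed, generation, genome_id, fitness,
    plays) for CSV export."""
    import pandas as pd

    rows = [
        {
            "replicate_id": log.replicate_id,
            "speed_class": log.speed_class,
            "generation": g.generation_index,
            "genome_id": b.genome.genome_id,
            "fitness": b.fitness,
            "plays": b.plays,
        }
        for g in log.generations
        for b in g.population
    ]
    return pd.DataFrame(rows)


def archive_genomes(log: EvolutionLog, directory: str) -> None:
    """Write per-generation genome archives as plain-text S-expressions."""
    import os

    from .genome import serialize_genome

    os.makedirs(directory, exist_ok=True)
    for g in log.generations:
        path = os.path.join(
            directory,
            f"rep{log.replicate_id}_{log.speed_class}_gen{g.generation_index:03d}.txt",
        )
        with open(path, "w") as fh:
            for b in g.population:
                fh.write(f"{b.genome.genome_id}\t{serialize_genome(b.genome)}\n")
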