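"""Mutate/accept evolutionary search over genome space.

A single lineage is evolved: each generation every genome bit is flipped
independently with probability ``p`` and the proposal replaces the incumbent
iff its fitness does not decrease (Δf >= 0, so neutral drift is accepted).
When the accepted fitness reaches the threshold (1.0 for synchronous runs)
the generation count since the last reset is recorded as one "discovery"
and the lineage restarts from a fresh uniform-random genome.  ``p = 0.5``
makes every proposal an independent uniform sample of genome space and
serves as the random-search control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .network import Context, Genome

__all__ = [
    "EvolutionConfig",
    "EvolutionRecord",
    "StasisPeriods",
    "mutate",
    "evolve",
    "evolve_trace",
    "stasis_periods",
]


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary search run."""

    contexts: Sequence[Context]
    p: float
    max_generations: int = 100_000_000
    max_discoveries: int = 1_000_000_000
    seed: int = 0
    fitness_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not self.contexts:
            raise ValueError("at least one context is required")
        if not 0.0 <= self.p <= 0.5:
            raise ValueError(f"mutation rate p must be in [0, 0.5], got {self.p}")
        if not 0.0 < self.fitness_threshold <= 1.0:
            raise ValueError("fitness threshold must be in (0, 1]")
        ns = {c.n for c in self.contexts}
        if len(ns) != 1:
            raise ValueError("all contexts must share the same gene count")

    @property
    def n(self) -> int:
        return self.contexts[0].n


@dataclass
class EvolutionRecord:
    """Outcome of an evolutionary run."""

    discoveries: np.ndarray
    total_generations: int
    final_genome: Genome | None
    fitness_trace: np.ndarray | None = None

    @property
    def mean_discovery(self) -> float:
        return float(np.mean(self.discoveries)) if len(self.discoveries) else float("nan")


@dataclass
class StasisPeriods:
    """Run lengths of constant-fitness segments between fitness increments."""

    periods: np.ndarray


def _context_arrays(contexts: Sequence[Context]) -> tuple[np.ndarray, np.ndarray]:
    inits = np.array([c.initial.value for c in contexts], dtype=np.int64)
    targets = np.array([c.target.value for c in contexts], dtype=np.int64)
    return inits, targets


def mutate(genome: Genome, p: float, rng: np.random.Generator) -> Genome:
    """Flip each genome bit independently with probability ``p``.

    Returns a new genome; the input is unchanged.  ``p = 0.5`` produces a
    uniform-random genome regardless of the input.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"mutation rate p must be in [0, 0.5], got {p}")
    flips = rng.random(genome.N) < p
    return Genome(genome.n, np.where(flips, 1 - genome.bits, genome.bits))


def _kernel_seed(seed: int) -> int:
    """Fold an arbitrary integer seed into the kernel RNG's 32-bit range."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % 2_147_483_647)


def _discovery_cap(config: EvolutionConfig) -> int:
    """Size of the preallocated discovery buffer (bounds kernel memory)."""
    return int(min(config.max_discoveries, config.max_generations + 1,
                   2_000_000))


def evolve(config: EvolutionConfig) -> EvolutionRecord:
    """Run the mutate/accept loop until the generation or discovery budget.

    Every generation counts toward the discovery clock, accepted or not,
    whether or not any bit actually flipped.
    """
    if config.max_generations <= 0:
        return EvolutionRecord(np.empty(0, dtype=np.int64), 0, None)
    inits, targets = _context_arrays(config.contexts)
    disc, ndisc, total, last_fit, found = _kernels.evolve_sync(
        config.n, config.p, inits, targets, config.fitness_threshold,
        config.max_generations, _discovery_cap(config),
        _kernel_seed(config.seed),
    )
    final = Genome(config.n, np.asarray(last_fit).copy()) if found else None
    return EvolutionRecord(np.asarray(disc).copy(), int(total), final)


def collect_fit_genomes(contexts: Sequence[Context], p: float, count: int,
                        seed: int = 0,
                        max_generations_each: int = 100_000_000) -> list[Genome]:
    """Evolve ``count`` independent maximally fit genomes (one per lineage)."""
    seeds = np.random.SeedSequence(seed).generate_state(count) % 2_147_483_647
    genomes = []
    for s in seeds:
        rec = evolve(EvolutionConfig(
            contexts=list(contexts), p=p,
            max_generations=max_generations_each,
            max_discoveries=1, seed=int(s)))
        if rec.final_genome is None:
            raise RuntimeError("generation budget exhausted before discovery")
        genomes.append(rec.final_genome)
    return genomes


def evolve_trace(config: EvolutionConfig) -> EvolutionRecord:
    """Run a single epoch (until first discovery or budget), keeping the
    per-generation accepted-fitness trace for stasis analysis."""
    inits, targets = _context_arrays(config.contexts)
    trace = np.zeros(config.max_generations + 1, dtype=np.float64)
    gens, bits, reached = _kernels.evolve_sync_traced(
        config.n, config.p, inits, targets, config.fitness_threshold,
        config.max_generations, _kernel_seed(config.seed), trace,
    )
    disc = np.array([gens], dtype=np.int64) if reached else np.empty(0, dtype=np.int64)
    return EvolutionRecord(
        discoveries=disc,
        total_generations=int(gens),
        final_genome=Genome(config.n, np.asarray(bits).copy()),
        fitness_trace=trace[: gens + 1],
    )


def stasis_periods(fitness_trace: Sequence[float]) -> StasisPeriods:
    """Split a fitness trace at strict increases; return the lengths of the
    constant segments (the periods of stasis between fitness increments).

    A trace ending exactly at an increment (the usual case: the run stops
    when the threshold is hit) contributes no trailing period for the final
    value; a trace still in stasis at the end counts that trailing segment.
    """
    trace = np.asarray(fitness_trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("fitness trace must be non-empty")
    rises = np.flatnonzero(np.diff(trace) > 0)
    bounds = np.concatenate(([0], rises + 1, [trace.size]))
    periods = np.diff(bounds)
    if rises.size and rises[-1] == trace.size - 2:
        periods = periods[:-1]
    return StasisPeriods(periods=periods[periods > 0])
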