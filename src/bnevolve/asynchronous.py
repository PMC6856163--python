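"""Asynchronous single-gene updating and its stochastic fitness variant.

Instead of updating all genes simultaneously, one uniformly chosen gene per
step reads its truth-table row for the current state and updates alone.
Fitness is evaluated over a fixed window: from each context's initial state
the dynamics are iterated ``T = 2N`` single-gene updates and the product
fitness is taken over all visited (post-update) states, so the measure is a
noisy, bounded estimate rather than an exact limit-cycle average.  Runs
terminate when the accepted fitness exceeds a threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .evolve import (
    EvolutionConfig,
    EvolutionRecord,
    _context_arrays,
    _discovery_cap,
    _kernel_seed,
)
from .network import Context, ExpressionState, Genome

__all__ = ["AsyncConfig", "step_asynchronous", "fitness_async", "evolve_async"]


@dataclass
class AsyncConfig:
    """Parameters of the asynchronous fitness evaluation.

    ``t_async`` is the number of single-gene updates per context; ``None``
    means the default 2N (twice the genome length).
    """

    t_async: int | None = None
    fitness_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.t_async is not None and self.t_async < 1:
            raise ValueError("t_async must be >= 1")
        if not 0.0 < self.fitness_threshold < 1.0:
            raise ValueError("async fitness threshold must be in (0, 1)")

    def resolve_t(self, n: int) -> int:
        return self.t_async if self.t_async is not None else 2 * n * (1 << n)


def step_asynchronous(genome: Genome, state: ExpressionState,
                      rng: np.random.Generator) -> ExpressionState:
    """Update one uniformly chosen gene; all other genes keep their level."""
    if genome.n != state.n:
        raise ValueError(f"genome has n={genome.n} genes but state has n={state.n}")
    n, m = genome.n, 1 << genome.n
    g = int(rng.integers(n))
    bit = int(genome.bits[g * m + state.value])
    shift = n - 1 - g
    return ExpressionState(n, (state.value & ~(1 << shift)) | (bit << shift))


def fitness_async(genome: Genome, contexts: Sequence[Context],
                  config: AsyncConfig | None = None,
                  seed: int = 0) -> float:
    """Stochastic window fitness under asynchronous updating.

    For each context, performs ``t_async`` single-gene updates from the
    initial state and applies the product fitness over genes and contexts
    with the time average taken over the visited states (initial state
    excluded).  Reproducible for a fixed seed.
    """
    config = config or AsyncConfig()
    contexts = list(contexts)
    if not contexts:
        raise ValueError("at least one context is required")
    for c in contexts:
        if c.n != genome.n:
            raise ValueError(f"context has n={c.n} genes but genome has n={genome.n}")
    inits, targets = _context_arrays(contexts)
    return float(_kernels.async_fitness(
        genome.bits, genome.n, inits, targets,
        config.resolve_t(genome.n), _kernel_seed(seed),
    ))


def evolve_async(config: EvolutionConfig,
                 async_config: AsyncConfig | None = None) -> EvolutionRecord:
    """Mutate/accept search driven by the asynchronous fitness.

    Same loop as :func:`bnevolve.evolve.evolve` but each proposal is scored
    with one fresh asynchronous evaluation, the incumbent's stored (noisy)
    score is re-used for the comparison, and an epoch ends when the accepted
    fitness strictly exceeds ``async_config.fitness_threshold``.
    """
    async_config = async_config or AsyncConfig()
    if config.max_generations <= 0:
        return EvolutionRecord(np.empty(0, dtype=np.int64), 0, None)
    inits, targets = _context_arrays(config.contexts)
    disc, ndisc, total, last_fit, found = _kernels.evolve_async(
        config.n, config.p, inits, targets,
        async_config.resolve_t(config.n), async_config.fitness_threshold,
        config.max_generations, _discovery_cap(config),
        _kernel_seed(config.seed),
    )
    final = Genome(config.n, np.asarray(last_fit).copy()) if found else None
    return EvolutionRecord(np.asarray(disc).copy(), int(total), final)
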