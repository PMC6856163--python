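"""Exhaustive and Monte-Carlo census of maximally fit genomes.

For small gene counts the whole genome space can be enumerated (n = 3 gives
2**24 ≈ 1.7e7 configurations) and the genomes whose dynamics carry every
context's initial state onto its target as a point attractor counted
exactly.  For larger n the space is astronomically large and a uniform
Monte-Carlo density estimate with a binomial confidence interval stands in.

The f = 1 test is purely combinatorial here — reach the target within 2**n
synchronous steps and the target maps to itself — no floating-point fitness
enters the inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import _kernels
from .evolve import _context_arrays, _kernel_seed
from .network import Context

__all__ = ["ExhaustiveCount", "DensityEstimate", "enumerate_fit", "density_estimate"]

_MAX_FREE_BITS = 24  # n * 2**n beyond this needs force=True


@dataclass(frozen=True)
class ExhaustiveCount:
    """Exact census of f = 1 genomes in the full space of 2**N configurations."""

    n: int
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total


@dataclass(frozen=True)
class DensityEstimate:
    """Monte-Carlo estimate of the f = 1 genome density."""

    n: int
    hits: int
    samples: int
    ci_low: float
    ci_high: float

    @property
    def fraction(self) -> float:
        return self.hits / self.samples


def _validate_contexts(contexts: Sequence[Context]) -> int:
    contexts = list(contexts)
    if not contexts:
        raise ValueError("at least one context is required")
    ns = {c.n for c in contexts}
    if len(ns) != 1:
        raise ValueError("all contexts must share the same gene count")
    return contexts[0].n


def enumerate_fit(contexts: Sequence[Context], force: bool = False,
                  chunk_bits: int = 21) -> ExhaustiveCount:
    """Count, over every genome configuration, those with f = 1.

    Enumerates all 2**N genomes (equivalently all transition maps of the
    2**n states reachable from truth tables), checking for each whether
    every context's initial state reaches its target and the target is a
    fixed point.  Refuses n with N = n * 2**n > 24 unless ``force``.
    """
    n = _validate_contexts(contexts)
    m = 1 << n
    N = n * m
    if N > _MAX_FREE_BITS and not force:
        raise ValueError(
            f"exhaustive enumeration over 2**{N} genomes refused for n={n}; "
            "pass force=True to override"
        )
    if N > _MAX_FREE_BITS:
        warnings.warn(f"enumerating 2**{N} genomes; this may take a very long time")
    inits, targets = _context_arrays(contexts)
    total = 1 << N
    count = 0
    chunk = min(total, 1 << chunk_bits)
    idx = np.arange(chunk, dtype=np.int64)
    for lo in range(0, total, chunk):
        genomes = np.arange(lo, lo + chunk, dtype=np.uint64)
        # transition map per genome: bit (g*m + s) of the genome integer is
        # gene g's next level in state s; gene 0 is the MSB of the state
        nxt = np.empty((chunk, m), dtype=np.int64)
        for s in range(m):
            v = np.zeros(chunk, dtype=np.int64)
            for g in range(n):
                v = (v << 1) | ((genomes >> np.uint64(g * m + s)) & np.uint64(1)).astype(np.int64)
            nxt[:, s] = v
        ok = np.ones(chunk, dtype=bool)
        for init, target in zip(inits, targets):
            state = np.full(chunk, init, dtype=np.int64)
            for _ in range(m):
                state = nxt[idx, state]
            ok &= (state == target) & (nxt[:, target] == target)
        count += int(ok.sum())
    return ExhaustiveCount(n=n, count=count, total=total)


def density_estimate(contexts: Sequence[Context], samples: int,
                     seed: int = 0, ci_level: float = 0.95) -> DensityEstimate:
    """Fraction of uniformly sampled genomes with f = 1, with a
    Clopper-Pearson binomial confidence interval."""
    n = _validate_contexts(contexts)
    if samples < 1:
        raise ValueError("samples must be >= 1")
    inits, targets = _context_arrays(contexts)
    hits = int(_kernels.count_fit_samples(n, inits, targets, samples,
                                          _kernel_seed(seed)))
    low, high = proportion_confint(hits, samples, alpha=1 - ci_level,
                                   method="beta")
    return DensityEstimate(n=n, hits=hits, samples=samples,
                           ci_low=float(low), ci_high=float(high))
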