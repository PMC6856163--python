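"""Numba kernels for the mutate/accept evolution loops.

These loops dominate runtime: a single sweep can simulate tens of millions
of generations, each requiring a fresh fitness evaluation (attractor search
for every context).  States are carried as integers with the first gene as
MSB; genomes as flat uint8 arrays of n concatenated truth-table columns.

Randomness uses numba's per-thread NumPy-compatible generator, seeded once
per kernel call, so a (seed, config) pair fully determines a run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sync_fitness",
    "async_fitness",
    "evolve_sync",
    "evolve_sync_traced",
    "evolve_async",
    "count_fit_samples",
]


@njit(cache=False)
def _sync_context_fitness(bits, n, m, init, target, cnt):
    """Fitness factor of one context: run to the attractor, time-average."""
    s = init
    for _ in range(m):
        ns = 0
        for g in range(n):
            ns = (ns << 1) | bits[g * m + s]
        s = ns
    # s is on the cycle; accumulate per-gene on-counts around it
    for g in range(n):
        cnt[g] = 0
    s0 = s
    T = 0
    while True:
        for g in range(n):
            cnt[g] += (s >> (n - 1 - g)) & 1
        T += 1
        ns = 0
        for g in range(n):
            ns = (ns << 1) | bits[g * m + s]
        s = ns
        if s == s0:
            break
    f = 1.0
    for g in range(n):
        mean = cnt[g] / T
        if (target >> (n - 1 - g)) & 1:
            f *= mean
        else:
            f *= 1.0 - mean
    return f


@njit(cache=False)
def _sync_fitness(bits, n, m, inits, targets, cnt):
    f = 1.0
    for x in range(inits.shape[0]):
        f *= _sync_context_fitness(bits, n, m, inits[x], targets[x], cnt)
        if f == 0.0:
            return 0.0
    return f


@njit(cache=False)
def sync_fitness(bits, n, inits, targets):
    """Synchronous limit-cycle fitness of one genome over contexts."""
    m = 1 << n
    cnt = np.empty(n, np.int64)
    return _sync_fitness(bits, n, m, inits, targets, cnt)


@njit(cache=False)
def _async_context_fitness(bits, n, m, init, target, t_async, cnt):
    """One context under asynchronous updating: t_async single-gene updates.

    The time average runs over the t_async post-update states (the initial
    state itself is excluded).
    """
    for g in range(n):
        cnt[g] = 0
    s = init
    for _ in range(t_async):
        g = np.random.randint(0, n)
        bit = bits[g * m + s]
        shift = n - 1 - g
        s = (s & ~(1 << shift)) | (np.int64(bit) << shift)
        for gg in range(n):
            cnt[gg] += (s >> (n - 1 - gg)) & 1
    f = 1.0
    for g in range(n):
        mean = cnt[g] / t_async
        if (target >> (n - 1 - g)) & 1:
            f *= mean
        else:
            f *= 1.0 - mean
    return f


@njit(cache=False)
def _async_fitness(bits, n, m, inits, targets, t_async, cnt):
    f = 1.0
    for x in range(inits.shape[0]):
        f *= _async_context_fitness(bits, n, m, inits[x], targets[x], t_async, cnt)
    return f


@njit(cache=False)
def async_fitness(bits, n, inits, targets, t_async, seed):
    """Stochastic asynchronous fitness (one sampled update sequence per context)."""
    np.random.seed(seed)
    m = 1 << n
    cnt = np.empty(n, np.int64)
    return _async_fitness(bits, n, m, inits, targets, t_async, cnt)


@njit(cache=False)
def _randomize(bits):
    for i in range(bits.size):
        bits[i] = 1 if np.random.random() < 0.5 else 0


@njit(cache=False)
def _mutate_into(src, dst, p):
    for i in range(src.size):
        if np.random.random() < p:
            dst[i] = 1 - src[i]
        else:
            dst[i] = src[i]


@njit(cache=False)
def evolve_sync(n, p, inits, targets, threshold, max_generations,
                max_discoveries, seed):
    """Mutate/accept search with synchronous fitness; reset on discovery.

    Starts from a uniform-random genome.  Each generation proposes a copy
    with every bit flipped independently with probability p, accepts it iff
    its fitness is >= the current fitness, and, whenever the accepted
    fitness reaches ``threshold``, records the generation count since the
    last reset and restarts from a fresh random genome.

    Returns (discoveries, n_discoveries, total_generations, last_fit_genome,
    found_any).
    """
    np.random.seed(seed)
    m = 1 << n
    N = n * m
    cnt = np.empty(n, np.int64)
    bits = np.empty(N, np.uint8)
    prop = np.empty(N, np.uint8)
    last_fit = np.zeros(N, np.uint8)
    disc = np.empty(max_discoveries, np.int64)
    ndisc = 0
    found_any = False

    _randomize(bits)
    fcur = _sync_fitness(bits, n, m, inits, targets, cnt)
    gen_since = 0
    while fcur >= threshold and ndisc < max_discoveries:
        disc[ndisc] = 0
        ndisc += 1
        last_fit[:] = bits
        found_any = True
        _randomize(bits)
        fcur = _sync_fitness(bits, n, m, inits, targets, cnt)

    total = 0
    while total < max_generations and ndisc < max_discoveries:
        total += 1
        gen_since += 1
        _mutate_into(bits, prop, p)
        fp = _sync_fitness(prop, n, m, inits, targets, cnt)
        if fp >= fcur:
            bits[:] = prop
            fcur = fp
            while fcur >= threshold and ndisc < max_discoveries:
                disc[ndisc] = gen_since
                ndisc += 1
                last_fit[:] = bits
                found_any = True
                gen_since = 0
                _randomize(bits)
                fcur = _sync_fitness(bits, n, m, inits, targets, cnt)
    return disc[:ndisc], ndisc, total, last_fit, found_any


@njit(cache=False)
def evolve_sync_traced(n, p, inits, targets, threshold, max_generations, seed,
                       trace):
    """Single epoch (until first discovery or budget) recording fitness.

    ``trace[0]`` is the initial genome's fitness; ``trace[g]`` the accepted
    fitness after generation g.  Returns (generations_used, final_genome,
    reached_threshold).
    """
    np.random.seed(seed)
    m = 1 << n
    N = n * m
    cnt = np.empty(n, np.int64)
    bits = np.empty(N, np.uint8)
    prop = np.empty(N, np.uint8)
    _randomize(bits)
    fcur = _sync_fitness(bits, n, m, inits, targets, cnt)
    trace[0] = fcur
    if fcur >= threshold:
        return 0, bits, True
    gen = 0
    while gen < max_generations:
        gen += 1
        _mutate_into(bits, prop, p)
        fp = _sync_fitness(prop, n, m, inits, targets, cnt)
        if fp >= fcur:
            bits[:] = prop
            fcur = fp
        trace[gen] = fcur
        if fcur >= threshold:
            return gen, bits, True
    return gen, bits, False


@njit(cache=False)
def evolve_async(n, p, inits, targets, t_async, threshold, max_generations,
                 max_discoveries, seed):
    """Mutate/accept search with stochastic asynchronous fitness.

    The incumbent's noisy fitness is stored and re-used for comparisons (one
    fresh evaluation per proposal); a run epoch terminates when the accepted
    fitness exceeds ``threshold`` (strict), after which the genome is
    re-randomized.
    """
    np.random.seed(seed)
    m = 1 << n
    N = n * m
    cnt = np.empty(n, np.int64)
    bits = np.empty(N, np.uint8)
    prop = np.empty(N, np.uint8)
    last_fit = np.zeros(N, np.uint8)
    disc = np.empty(max_discoveries, np.int64)
    ndisc = 0
    found_any = False

    _randomize(bits)
    fcur = _async_fitness(bits, n, m, inits, targets, t_async, cnt)
    gen_since = 0
    while fcur > threshold and ndisc < max_discoveries:
        disc[ndisc] = 0
        ndisc += 1
        last_fit[:] = bits
        found_any = True
        _randomize(bits)
        fcur = _async_fitness(bits, n, m, inits, targets, t_async, cnt)

    total = 0
    while total < max_generations and ndisc < max_discoveries:
        total += 1
        gen_since += 1
        _mutate_into(bits, prop, p)
        fp = _async_fitness(prop, n, m, inits, targets, t_async, cnt)
        if fp >= fcur:
            bits[:] = prop
            fcur = fp
            while fcur > threshold and ndisc < max_discoveries:
                disc[ndisc] = gen_since
                ndisc += 1
                last_fit[:] = bits
                found_any = True
                gen_since = 0
                _randomize(bits)
                fcur = _async_fitness(bits, n, m, inits, targets, t_async, cnt)
    return disc[:ndisc], ndisc, total, last_fit, found_any


@njit(cache=False)
def count_fit_samples(n, inits, targets, samples, seed):
    """Count uniform-random genomes whose every context hits its target as
    a point attractor (f = 1), without floating-point fitness."""
    np.random.seed(seed)
    m = 1 << n
    N = n * m
    bits = np.empty(N, np.uint8)
    hits = 0
    for _ in range(samples):
        _randomize(bits)
        ok = True
        for x in range(inits.shape[0]):
            s = inits[x]
            for _ in range(m):
                ns = 0
                for g in range(n):
                    ns = (ns << 1) | bits[g * m + s]
                s = ns
            if s != targets[x]:
                ok = False
                break
            # target must be a fixed point
            ns = 0
            for g in range(n):
                ns = (ns << 1) | bits[g * m + s]
            if ns != s:
                ok = False
                break
        if ok:
            hits += 1
    return hits
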