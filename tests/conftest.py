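import numpy as np
import pytest

from bnevolve import N3, NEOCORTEX, Genome


@pytest.fixture
def neocortex_contexts():
    return list(NEOCORTEX.contexts)


@pytest.fixture
def n3_contexts():
    return list(N3.contexts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genome(n, columns):
    """Build a genome from explicit per-gene truth-table columns."""
    return Genome(n, np.concatenate([np.asarray(c, dtype=np.uint8)
                                     for c in columns]))


@pytest.fixture
def cycle_genome_n2():
    """n=2 genome whose dynamics form the single 4-cycle 00->10->01->11->00."""
    return make_genome(2, [[1, 1, 0, 0], [0, 1, 1, 0]])


def brute_force_transition(genome):
    """Independent tabulation of the full state-transition function."""
    n, m = genome.n, 1 << genome.n
    bits = [int(b) for b in genome.bits]
    nxt = []
    for state in range(m):
        out = 0
        for g in range(n):
            out += bits[g * m + state] << (n - 1 - g)
        nxt.append(out)
    return nxt


def brute_force_cycles(nxt):
    """All cycle state-sets of a functional graph, by walking each node."""
    cycles = set()
    for start in range(len(nxt)):
        seen = {}
        v, i = start, 0
        while v not in seen:
            seen[v] = i
            v, i = nxt[v], i + 1
        cycle = []
        u = v
        while True:
            cycle.append(u)
            u = nxt[u]
            if u == v:
                break
        cycles.add(frozenset(cycle))
    return cycles
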