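"""Genome/state encoding, synchronous dynamics, attractors and fitness."""

import networkx as nx
import numpy as np
import pytest

from bnevolve import (
    Context,
    Genome,
    context_fitness,
    encode_state,
    export_landscape,
    find_attractor,
    fitness,
    landscape_to_dot,
    random_genome,
    step_synchronous,
    transition_map,
)

from conftest import brute_force_cycles, brute_force_transition, make_genome


@pytest.mark.parametrize("pattern,value", [
    ("01010", 10),
    ("00000", 0),
    ("10101", 21),
    ("11", 3),
])
def test_encode_state_positional_binary(pattern, value):
    state = encode_state(pattern)
    assert state.value == value
    assert state.to_string() == pattern


@pytest.mark.parametrize("bad", ["", "01a10", "2", "01 0"])
def test_encode_state_rejects_malformed(bad):
    with pytest.raises(ValueError):
        encode_state(bad)


@pytest.mark.parametrize("n", range(2, 9))
def test_encode_decode_roundtrip_all_patterns(n):
    for v in range(1 << n):
        pattern = format(v, f"0{n}b")
        assert encode_state(pattern).value == v
        assert encode_state(pattern).to_string() == pattern


@pytest.mark.parametrize("n", [2, 3, 5])
def test_constant_genomes_have_constant_fixed_points(n, rng):
    m = 1 << n
    zeros = Genome(n, np.zeros(n * m, dtype=np.uint8))
    ones = Genome(n, np.ones(n * m, dtype=np.uint8))
    for _ in range(5):
        s = encode_state(format(rng.integers(m), f"0{n}b"))
        assert step_synchronous(zeros, s).value == 0
        assert step_synchronous(ones, s).value == m - 1


def test_step_hand_example_n2():
    # gene a column rows 0..3 = [0,0,0,1], gene b = [0,1,1,0]
    g = make_genome(2, [[0, 0, 0, 1], [0, 1, 1, 0]])
    assert step_synchronous(g, encode_state("11")).to_string() == "10"


def test_step_dimension_mismatch():
    g = make_genome(2, [[0, 0, 0, 1], [0, 1, 1, 0]])
    with pytest.raises(ValueError):
        step_synchronous(g, encode_state("111"))


def test_constant_network_point_attractor():
    g = Genome(5, np.zeros(160, dtype=np.uint8))
    traj = find_attractor(g, encode_state("00000"))
    assert traj.attractor.T == 1
    assert traj.attractor.states[0].to_string() == "00000"


def test_four_cycle_attractor(cycle_genome_n2):
    traj = find_attractor(cycle_genome_n2, encode_state("00"))
    cycle = [s.to_string() for s in traj.attractor.states]
    assert traj.attractor.T == 4
    # ordered cycle, phase free: consecutive states follow the dynamics
    idx = cycle.index("00")
    assert cycle[idx:] + cycle[:idx] == ["00", "10", "01", "11"]


@pytest.mark.parametrize("n", [3, 4, 5])
def test_attractor_matches_bruteforce_oracle(n, rng):
    """find_attractor's cycles equal those of a full-transition-map oracle."""
    m = 1 << n
    for _ in range(300):
        g = random_genome(n, rng)
        oracle_cycles = brute_force_cycles(brute_force_transition(g))
        init = encode_state(format(rng.integers(m), f"0{n}b"))
        traj = find_attractor(g, init)
        assert traj.attractor.state_set() in oracle_cycles
        # structural invariants of the returned cycle
        states = traj.attractor.states
        assert 1 <= len(states) <= m
        assert len({s.value for s in states}) == len(states)
        for i, s in enumerate(states):
            assert step_synchronous(g, s).value == states[(i + 1) % len(states)].value
        # trajectory tail contains the attractor
        tail = {s.value for s in traj.states}
        assert traj.attractor.state_set() <= tail


def test_find_attractor_deterministic(rng):
    g = random_genome(5, rng)
    a = find_attractor(g, encode_state("01100"))
    b = find_attractor(g, encode_state("01100"))
    assert [s.value for s in a.states] == [s.value for s in b.states]


def test_worked_fitness_example():
    """Limit cycle {11000,00011,01011} vs target 01010: per-gene correct
    proportions 2/3, 2/3, 3/3, 2/3, 1/3; context fitness 8/81."""
    cycle = [encode_state(s) for s in ("11000", "00011", "01011")]
    target = encode_state("01010")
    T = len(cycle)
    props = []
    for g in range(5):
        on = sum(s.bit(g) for s in cycle)
        props.append((on if target.bit(g) else T - on) / T)
    assert props == [2 / 3, 2 / 3, 3 / 3, 2 / 3, 1 / 3]
    assert context_fitness(cycle, target) == pytest.approx(8 / 81, abs=1e-15)


def test_fitness_zero_when_gene_always_wrong(neocortex_contexts):
    g = Genome(5, np.zeros(160, dtype=np.uint8))
    assert fitness(g, [neocortex_contexts[0]]) == 0.0


def _perfect_neocortex_genome():
    """Genome mapping 00000->01010 and 10000->10101 as point attractors."""
    cols = np.zeros((5, 32), dtype=np.uint8)
    for init_s, tgt_s in (("00000", "01010"), ("10000", "10101")):
        init, tgt = encode_state(init_s), encode_state(tgt_s)
        for g in range(5):
            cols[g, init.value] = tgt.bit(g)
            cols[g, tgt.value] = tgt.bit(g)
    return Genome(5, cols.reshape(-1))


def test_fitness_one_iff_point_attractor_mapping(neocortex_contexts, rng):
    assert fitness(_perfect_neocortex_genome(), neocortex_contexts) == 1.0
    for _ in range(300):
        g = random_genome(5, rng)
        f = fitness(g, neocortex_contexts)
        assert 0.0 <= f <= 1.0
        nxt = brute_force_transition(g)
        hits = True
        for ctx in neocortex_contexts:
            s = ctx.initial.value
            for _ in range(32):
                s = nxt[s]
            hits &= s == ctx.target.value and nxt[s] == s
        assert (f == 1.0) == hits


def test_fitness_requires_contexts(rng):
    with pytest.raises(ValueError):
        fitness(random_genome(3, rng), [])


def test_fitness_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        fitness(random_genome(3, rng), [Context.from_strings("0000", "0101")])


def test_landscape_structure(rng):
    for _ in range(20):
        g = random_genome(4, rng)
        graph = export_landscape(g)
        assert graph.number_of_nodes() == 16
        assert all(d == 1 for _, d in graph.out_degree())
        n_components = nx.number_weakly_connected_components(graph)
        assert n_components == len(brute_force_cycles(brute_force_transition(g)))


def test_landscape_constant_genome():
    g = Genome(3, np.zeros(24, dtype=np.uint8))
    graph = export_landscape(g)
    assert graph.number_of_nodes() == 8
    assert all(v == "000" for _, v in graph.edges())
    flagged = [u for u, d in graph.nodes(data=True) if d["attractor"]]
    assert flagged == ["000"]
    dot = landscape_to_dot(graph)
    assert '"000"' in dot and dot.startswith("digraph")


def test_landscape_single_cycle(cycle_genome_n2):
    graph = export_landscape(cycle_genome_n2)
    assert all(d["attractor"] for _, d in graph.nodes(data=True))
    assert nx.number_weakly_connected_components(graph) == 1


def test_landscape_size_guard():
    g = Genome(17, np.zeros(17 * (1 << 17), dtype=np.uint8))
    with pytest.raises(ValueError):
        export_landscape(g)


def test_transition_map_matches_oracle(rng):
    g = random_genome(5, rng)
    assert list(transition_map(g)) == brute_force_transition(g)


def test_genome_validation():
    with pytest.raises(ValueError):
        Genome(5, np.zeros(159, dtype=np.uint8))
    with pytest.raises(ValueError):
        Genome(5, np.full(160, 2, dtype=np.uint8))
    g = Genome.from_string("0" * 160)
    assert g.n == 5 and g.N == 160
    assert Genome.from_string(g.to_string()).n == 5
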