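"""Core representations and synchronous dynamics of Boolean gene networks.

A network of ``n`` genes with binary expression levels is specified by a
"genome" of ``N = n * 2**n`` bits: one truth-table column of length ``2**n``
per gene, concatenated in gene order.  Row ``r`` of each column gives the
gene's next expression level when the current network state encodes to the
integer ``r`` (first-listed gene = most significant bit).  Under synchronous
updating all genes read the current state and switch simultaneously, so the
dynamics form a deterministic map on the ``2**n`` states; every trajectory
settles into a point attractor (fixed point) or a limit cycle.

Fitness of a genome against a set of developmental contexts (initial state,
target state pairs) is the product, over contexts and genes, of the
time-averaged proportion of attractor states in which the gene matches its
target level::

    f = prod_x prod_g ( 1 - (1/T) * sum_t |s'_{g,x} - s_{g,x,t}| )

where the inner sum runs over the ``T`` states of the attractor reached from
context ``x``'s initial state.  ``f = 1`` exactly when every initial state
maps onto its target as a point attractor; limit cycles whose time-averaged
expression approximates the target earn partial credit, which is what makes
the fitness landscape climbable ("attractor scaffolding").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Genome",
    "ExpressionState",
    "Context",
    "Attractor",
    "Trajectory",
    "encode_state",
    "step_synchronous",
    "transition_map",
    "find_attractor",
    "context_fitness",
    "fitness",
    "export_landscape",
    "landscape_to_dot",
]


@dataclass(frozen=True)
class ExpressionState:
    """One pattern of ``n`` binary gene expression levels.

    ``value`` encodes the pattern as an integer with the first-listed gene
    as the most significant bit, so state string ``"01010"`` has value 10.
    """

    n: int
    value: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 genes, got n={self.n}")
        if not 0 <= self.value < (1 << self.n):
            raise ValueError(
                f"state value {self.value} out of range for n={self.n}"
            )

    def to_string(self) -> str:
        return format(self.value, f"0{self.n}b")

    def bit(self, gene: int) -> int:
        """Expression level of gene ``gene`` (0 = first listed)."""
        return (self.value >> (self.n - 1 - gene)) & 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.to_string()}]"


def encode_state(pattern: str) -> ExpressionState:
    """Parse an n-character 0/1 string into an :class:`ExpressionState`.

    The leftmost character is the first-listed gene and maps to the most
    significant bit of the integer encoding.
    """
    if not pattern or any(c not in "01" for c in pattern):
        raise ValueError(f"state pattern must be a non-empty 0/1 string, got {pattern!r}")
    return ExpressionState(n=len(pattern), value=int(pattern, 2))


@dataclass(frozen=True)
class Context:
    """A developmental scenario: an initial state and a target attractor state."""

    initial: ExpressionState
    target: ExpressionState

    def __post_init__(self) -> None:
        if self.initial.n != self.target.n:
            raise ValueError(
                f"initial ({self.initial.n} genes) and target "
                f"({self.target.n} genes) differ in size"
            )

    @property
    def n(self) -> int:
        return self.initial.n

    @classmethod
    def from_strings(cls, initial: str, target: str) -> "Context":
        return cls(encode_state(initial), encode_state(target))


@dataclass
class Genome:
    """The N = n * 2**n bit network specification.

    ``bits[g * 2**n + r]`` is gene ``g``'s next expression level when the
    current state encodes to row ``r``.
    """

    n: int
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 genes, got n={self.n}")
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        expected = self.n * (1 << self.n)
        if self.bits.ndim != 1 or self.bits.size != expected:
            raise ValueError(
                f"genome for n={self.n} requires {expected} bits, "
                f"got {self.bits.size}"
            )
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("genome bits must all be 0 or 1")

    @property
    def N(self) -> int:
        return self.bits.size

    def column(self, gene: int) -> np.ndarray:
        """Truth-table column (length 2**n) of one gene."""
        m = 1 << self.n
        return self.bits[gene * m : (gene + 1) * m]

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str, n: int | None = None) -> "Genome":
        if not s or any(c not in "01" for c in s):
            raise ValueError("genome string must be a non-empty 0/1 string")
        if n is None:
            n = _infer_n(len(s))
        return cls(n=n, bits=np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    def copy(self) -> "Genome":
        return Genome(self.n, self.bits.copy())


def _infer_n(length: int) -> int:
    for n in range(2, 28):
        if n * (1 << n) == length:
            return n
    raise ValueError(f"no gene count n satisfies n * 2**n == {length}")


@dataclass(frozen=True)
class Attractor:
    """An ordered cycle of states; length 1 means a point attractor."""

    states: tuple[ExpressionState, ...]

    @property
    def T(self) -> int:
        return len(self.states)

    @property
    def is_point(self) -> bool:
        return self.T == 1

    def state_set(self) -> frozenset[int]:
        """Phase-invariant identity of the cycle."""
        return frozenset(s.value for s in self.states)


@dataclass(frozen=True)
class Trajectory:
    """States visited from an initial condition, plus the attractor reached."""

    states: tuple[ExpressionState, ...]
    attractor: Attractor


def _check_pair(genome: Genome, state: ExpressionState) -> None:
    if genome.n != state.n:
        raise ValueError(
            f"genome has n={genome.n} genes but state has n={state.n}"
        )


def step_synchronous(genome: Genome, state: ExpressionState) -> ExpressionState:
    """Advance one synchronous step: every gene reads its truth-table row."""
    _check_pair(genome, state)
    n, m = genome.n, 1 << genome.n
    nxt = 0
    for g in range(n):
        nxt = (nxt << 1) | int(genome.bits[g * m + state.value])
    return ExpressionState(n, nxt)


def transition_map(genome: Genome) -> np.ndarray:
    """The full state-transition function as an array of 2**n next values."""
    n, m = genome.n, 1 << genome.n
    cols = genome.bits.reshape(n, m).astype(np.int64)
    nxt = np.zeros(m, dtype=np.int64)
    for g in range(n):
        nxt = (nxt << 1) | cols[g]
    return nxt


def find_attractor(genome: Genome, initial: ExpressionState) -> Trajectory:
    """Run the dynamics until the attractor is identified.

    Iterates 2**n synchronous steps (enough to guarantee the trajectory has
    entered its attractor), then continues until the first state repetition;
    the cycle is stored starting from the first repeated state.
    """
    _check_pair(genome, initial)
    n, m = genome.n, 1 << genome.n
    nxt = transition_map(genome)
    visited = [initial.value]
    s = initial.value
    for _ in range(m):
        s = int(nxt[s])
        visited.append(s)
    # s is now on the cycle; walk once around it
    cycle = [s]
    t = int(nxt[s])
    while t != s:
        cycle.append(t)
        t = int(nxt[t])
    visited.extend(cycle[1:] + [s])
    return Trajectory(
        states=tuple(ExpressionState(n, v) for v in visited),
        attractor=Attractor(tuple(ExpressionState(n, v) for v in cycle)),
    )


def context_fitness(attractor: Attractor | Sequence[ExpressionState],
                    target: ExpressionState) -> float:
    """Fitness contribution of one context given its attractor cycle.

    Product over genes of the proportion of cycle states in which the gene
    matches its target level (the time-averaged "correctness").
    """
    states = attractor.states if isinstance(attractor, Attractor) else tuple(attractor)
    T = len(states)
    if T == 0:
        raise ValueError("attractor must contain at least one state")
    n = target.n
    f = 1.0
    for g in range(n):
        on = sum(s.bit(g) for s in states)
        mean = on / T
        f *= mean if target.bit(g) else 1.0 - mean
    return f


def fitness(genome: Genome, contexts: Iterable[Context]) -> float:
    """Eq.-of-merit for the genome over a set of contexts; value in [0, 1].

    Equals 1 exactly when every context's initial state maps onto its target
    as a point attractor; equals 0 when any gene is wrong in every state of
    some context's attractor.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("at least one context is required")
    f = 1.0
    for ctx in contexts:
        if ctx.n != genome.n:
            raise ValueError(
                f"context has n={ctx.n} genes but genome has n={genome.n}"
            )
        traj = find_attractor(genome, ctx.initial)
        f *= context_fitness(traj.attractor, ctx.target)
    return f


_MAX_LANDSCAPE_N = 16


def export_landscape(genome: Genome) -> nx.DiGraph:
    """The full state-transition graph: 2**n nodes, out-degree exactly 1.

    Nodes are state strings; attractor (cycle) nodes carry ``attractor=True``
    and an ``attractor_id`` shared by members of the same cycle.
    """
    if genome.n > _MAX_LANDSCAPE_N:
        raise ValueError(
            f"landscape export limited to n <= {_MAX_LANDSCAPE_N} "
            f"(2**{genome.n} states requested)"
        )
    n, m = genome.n, 1 << genome.n
    nxt = transition_map(genome)
    g = nx.DiGraph()
    labels = [format(v, f"0{n}b") for v in range(m)]
    for v in range(m):
        g.add_node(labels[v], attractor=False)
    for v in range(m):
        g.add_edge(labels[v], labels[int(nxt[v])])
    for aid, cycle in enumerate(_cycles_of_map(nxt)):
        for v in cycle:
            g.nodes[labels[v]]["attractor"] = True
            g.nodes[labels[v]]["attractor_id"] = aid
    return g


def _cycles_of_map(nxt: np.ndarray) -> list[list[int]]:
    """All cycles of a functional graph, each as an ordered list of states."""
    m = len(nxt)
    color = np.full(m, -1, dtype=np.int64)  # -1 unvisited, else walk id
    on_cycle = np.zeros(m, dtype=bool)
    cycles: list[list[int]] = []
    for start in range(m):
        if color[start] != -1:
            continue
        path = []
        v = start
        while color[v] == -1:
            color[v] = start
            path.append(v)
            v = int(nxt[v])
        if color[v] == start and not on_cycle[v]:
            # walked into a fresh cycle; extract it starting at v
            cyc = [v]
            u = int(nxt[v])
            while u != v:
                cyc.append(u)
                u = int(nxt[u])
            for u in cyc:
                on_cycle[u] = True
            cycles.append(cyc)
    return cycles


def landscape_to_dot(graph: nx.DiGraph) -> str:
    """Render a landscape graph as Graphviz DOT text."""
    lines = ["digraph landscape {"]
    for node, data in graph.nodes(data=True):
        attrs = 'shape=doublecircle, style=filled, fillcolor="#ffd27f"' \
            if data.get("attractor") else "shape=circle"
        lines.append(f'  "{node}" [{attrs}];')
    for u, v in graph.edges():
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
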