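"""Boolean-function statistics: minimal-DNF complexity, canalization, bias,
and attractor census.

The complexity of one gene's update rule (a truth table on n inputs) is the
minimum number of product terms in an equivalent disjunctive-normal-form
expression, normalized by 2**n.  The minimum is exact: every product term
over the n inputs is enumerated (3**n of them), those implied by the
function are reduced to the prime implicants (the Quine-McCluskey prime
set), and a branch-and-bound exact set cover over the function's true rows
finds the fewest-term cover (Petrick-equivalent).

Conventions: the constant-false function needs 0 terms (empty disjunction)
and the constant-true function 1 term (the empty product), keeping the term
count monotone under adding minterms.

A function is canalizing when fixing some *other* gene's input to a
specific level forces the output to a constant; constant functions are
vacuously canalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .network import Genome, transition_map, _cycles_of_map

__all__ = [
    "TruthTable",
    "ComplexityReport",
    "minimal_dnf_terms",
    "complexity",
    "is_canalizing",
    "network_has_canalizing",
    "canalizing_fraction",
    "bias",
    "count_attractors",
    "complexity_report",
    "genome_complexity",
]

_MAX_DNF_INPUTS = 8
_MAX_ATTRACTOR_N = 16


@dataclass(frozen=True)
class TruthTable:
    """One gene's update rule: outputs for the 2**n_inputs state rows."""

    n_inputs: int
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.outputs) != 1 << self.n_inputs:
            raise ValueError(
                f"truth table on {self.n_inputs} inputs needs "
                f"{1 << self.n_inputs} outputs, got {len(self.outputs)}"
            )
        if any(o not in (0, 1) for o in self.outputs):
            raise ValueError("truth table outputs must be 0 or 1")

    @classmethod
    def from_genome(cls, genome: Genome, gene: int) -> "TruthTable":
        return cls(genome.n, tuple(int(b) for b in genome.column(gene)))

    def ones_mask(self) -> int:
        """Bitmask over rows: bit r set iff outputs[r] == 1."""
        mask = 0
        for r, o in enumerate(self.outputs):
            if o:
                mask |= 1 << r
        return mask


@lru_cache(maxsize=8)
def _term_covers(n: int) -> tuple[tuple[int, ...], tuple[tuple[tuple[int, int], ...], ...]]:
    """All 3**n product terms over n inputs, as row-coverage bitmasks.

    Returns (covers, literals): covers[k] has bit r set iff term k is
    satisfied by input row r; literals[k] is the term itself as a tuple of
    (input_index, required_level) pairs (empty tuple = the constant-true
    empty product).  Terms are generated per care-set and literal polarity.
    """
    m = 1 << n
    # row mask for "input i equals v" (input 0 is the MSB of the row index,
    # matching the gene ordering used throughout)
    lit = [[0, 0] for _ in range(n)]
    for r in range(m):
        for i in range(n):
            lit[i][(r >> (n - 1 - i)) & 1] |= 1 << r
    full = (1 << m) - 1
    covers: list[int] = []
    literals: list[tuple[tuple[int, int], ...]] = []
    for care in range(1 << n):
        base: list[tuple[int, tuple[tuple[int, int], ...]]] = [(full, ())]
        for i in range(n):
            if care & (1 << i):
                base = [(b & lit[i][v], lits + ((i, v),))
                        for b, lits in base for v in (0, 1)]
        for b, lits in base:
            covers.append(b)
            literals.append(lits)
    return tuple(covers), tuple(literals)


def _prime_implicants(f: int, n: int) -> list[tuple[int, int]]:
    """(coverage, index) of the prime implicants of the ones-mask f."""
    covers, _ = _term_covers(n)
    implicants = [(c, k) for k, c in enumerate(covers) if c and c & ~f == 0]
    implicants.sort(key=lambda ck: -ck[0].bit_count())
    primes: list[tuple[int, int]] = []
    for c, k in implicants:
        if not any(c | p == p for p, _ in primes):
            primes.append((c, k))
    return primes


def _min_cover(universe: int, sets: list[int]) -> list[int]:
    """Indices (into ``sets``) of an exact minimum cover of the universe,
    found by branch and bound over the hardest-to-cover rows."""
    best: list[int] = [i for i, s in enumerate(sets) if s & universe]
    # any row-by-row cover works as the initial bound
    def search(uncovered: int, used: list[int], avail: list[int]) -> None:
        nonlocal best
        if len(used) >= len(best):
            return
        if uncovered == 0:
            best = list(used)
            return
        avail = [i for i in avail if sets[i] & uncovered]
        if not avail:
            return
        max_cov = max((sets[i] & uncovered).bit_count() for i in avail)
        need = -(-uncovered.bit_count() // max_cov)
        if len(used) + need >= len(best):
            return
        # branch on the uncovered row with the fewest candidate sets
        pick: list[int] | None = None
        u = uncovered
        while u:
            row = u & -u
            cands = [i for i in avail if sets[i] & row]
            if pick is None or len(cands) < len(pick):
                pick = cands
                if len(cands) <= 1:
                    break
            u &= u - 1
        for i in sorted(pick, key=lambda i: -(sets[i] & uncovered).bit_count()):
            used.append(i)
            search(uncovered & ~sets[i], used, avail)
            used.pop()

    search(universe, [], list(range(len(sets))))
    return best


def minimal_dnf(table: TruthTable) -> list[tuple[tuple[int, int], ...]]:
    """An exact fewest-term DNF cover of the table.

    Each term is a tuple of (input_index, required_level) literals; the
    empty tuple is the constant-true empty product.  The disjunction of the
    returned terms evaluates identically to the table on every row.
    """
    n = table.n_inputs
    if n > _MAX_DNF_INPUTS:
        raise ValueError(
            f"minimal-DNF search limited to {_MAX_DNF_INPUTS} inputs, got {n}"
        )
    f = table.ones_mask()
    if f == 0:
        return []
    if f == (1 << (1 << n)) - 1:
        return [()]
    _, literals = _term_covers(n)
    primes = _prime_implicants(f, n)
    chosen = _min_cover(f, [c for c, _ in primes])
    return [literals[primes[i][1]] for i in chosen]


def minimal_dnf_terms(table: TruthTable) -> int:
    """Exact minimum number of product terms in a DNF for the table."""
    n = table.n_inputs
    if n > _MAX_DNF_INPUTS:
        raise ValueError(
            f"minimal-DNF search limited to {_MAX_DNF_INPUTS} inputs, got {n}"
        )
    f = table.ones_mask()
    if f == 0:
        return 0
    if f == (1 << (1 << n)) - 1:
        return 1
    primes = _prime_implicants(f, n)
    return len(_min_cover(f, [c for c, _ in primes]))


def complexity(table: TruthTable) -> float:
    """Minimal DNF terms normalized by 2**n_inputs; value in [0, 1]."""
    return minimal_dnf_terms(table) / (1 << table.n_inputs)


def _canalizing_row_masks(n: int) -> np.ndarray:
    """masks[i, v]: uint64 bitmask of rows where gene i's level equals v."""
    m = 1 << n
    masks = np.zeros((n, 2), dtype=np.uint64)
    for r in range(m):
        for i in range(n):
            v = (r >> (n - 1 - i)) & 1
            masks[i, v] |= np.uint64(1 << r)
    return masks


def is_canalizing(genome: Genome, gene: int) -> bool:
    """True iff some *other* gene's level, fixed to 0 or 1, forces this
    gene's output constant.  Constant functions are vacuously canalizing."""
    n, m = genome.n, 1 << genome.n
    if m > 64:
        raise ValueError("canalizing check limited to n <= 6")
    if not 0 <= gene < n:
        raise ValueError(f"gene index {gene} out of range for n={n}")
    col = genome.column(gene)
    packed = np.uint64(0)
    for r in range(m):
        if col[r]:
            packed |= np.uint64(1 << r)
    masks = _canalizing_row_masks(n)
    for i in range(n):
        if i == gene:
            continue
        for v in (0, 1):
            sub = packed & masks[i, v]
            if sub == 0 or sub == masks[i, v]:
                return True
    return False


def network_has_canalizing(genome: Genome) -> bool:
    """True iff at least one of the network's genes is canalizing."""
    return any(is_canalizing(genome, g) for g in range(genome.n))


def canalizing_fraction(n: int, samples: int, seed: int = 0,
                        batch: int = 100_000) -> float:
    """Fraction of uniform-random n-gene networks containing at least one
    canalizing gene (vectorized over bit-packed truth-table columns)."""
    m = 1 << n
    if m > 64:
        raise ValueError("canalizing check limited to n <= 6")
    rng = np.random.default_rng(seed)
    masks = _canalizing_row_masks(n)
    hits = 0
    done = 0
    while done < samples:
        b = min(batch, samples - done)
        # a uniform-random truth-table column is a uniform m-bit integer
        packed = rng.integers(0, 1 << m, size=(b, n), dtype=np.uint64)
        net_flag = np.zeros(b, dtype=bool)
        for g in range(n):
            col = packed[:, g]
            for i in range(n):
                if i == g:
                    continue
                for v in (0, 1):
                    sub = col & masks[i, v]
                    net_flag |= (sub == 0) | (sub == masks[i, v])
        hits += int(net_flag.sum())
        done += b
    return hits / samples


def bias(genome: Genome) -> float:
    """Proportion of 1s among all N truth-table bits."""
    return float(genome.bits.mean())


def count_attractors(genome: Genome) -> int:
    """Number of distinct attractor cycles over all 2**n initial states."""
    if genome.n > _MAX_ATTRACTOR_N:
        raise ValueError(f"attractor census limited to n <= {_MAX_ATTRACTOR_N}")
    return len(_cycles_of_map(transition_map(genome)))


def genome_complexity(genome: Genome) -> np.ndarray:
    """Per-gene normalized minimal-DNF complexity of a genome."""
    return np.array([
        complexity(TruthTable.from_genome(genome, g)) for g in range(genome.n)
    ])


@dataclass
class ComplexityReport:
    """Per-gene and network-level Boolean-function statistics."""

    n: int
    terms: np.ndarray            # per-gene minimal DNF term counts
    complexities: np.ndarray     # terms / 2**n
    canalizing: np.ndarray       # per-gene flags
    bias: float
    attractor_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": np.arange(self.n),
            "min_dnf_terms": self.terms,
            "complexity": self.complexities,
            "canalizing": self.canalizing,
        })


def complexity_report(genome: Genome) -> ComplexityReport:
    """Full per-gene statistics plus network bias and attractor count."""
    terms = np.array([
        minimal_dnf_terms(TruthTable.from_genome(genome, g))
        for g in range(genome.n)
    ])
    flags = np.array([is_canalizing(genome, g) for g in range(genome.n)])
    return ComplexityReport(
        n=genome.n,
        terms=terms,
        complexities=terms / (1 << genome.n),
        canalizing=flags,
        bias=bias(genome),
        attractor_count=count_attractors(genome),
    )
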