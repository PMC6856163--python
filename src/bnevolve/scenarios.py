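"""Canonical developmental scenarios and random genome/context generation.

The "neocortex" scenario models arealization of the embryonic neocortex by
five interacting genes (Fgf8, Emx2, Pax6, Coup-tf1, Sp8, listed MSB first):
differential Fgf8 expression defines two contexts, with initial state
[00000] mapping to target point attractor [01010] in the posterior domain
and [10000] mapping to [10101] in the anterior domain.  The "n3" scenario
is its three-gene analogue used for exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Context, ExpressionState, Genome

__all__ = ["CanonicalScenario", "NEOCORTEX", "N3", "SCENARIOS",
           "random_genome", "random_contexts"]


@dataclass(frozen=True)
class CanonicalScenario:
    """A named gene count + context set used across experiments."""

    name: str
    n: int
    contexts: tuple[Context, ...]

    def __post_init__(self) -> None:
        if any(c.n != self.n for c in self.contexts):
            raise ValueError("scenario contexts must match its gene count")


def _ctx(initial: str, target: str) -> Context:
    return Context.from_strings(initial, target)


NEOCORTEX = CanonicalScenario(
    name="neocortex", n=5,
    contexts=(_ctx("00000", "01010"), _ctx("10000", "10101")),
)

N3 = CanonicalScenario(
    name="n3", n=3,
    contexts=(_ctx("000", "010"), _ctx("100", "101")),
)

SCENARIOS = {s.name: s for s in (NEOCORTEX, N3)}


def random_genome(n: int, rng: np.random.Generator | int | None = None) -> Genome:
    """Uniform-random genome: each of the N = n * 2**n bits i.i.d. Bernoulli(1/2)."""
    if n < 2:
        raise ValueError(f"need at least 2 genes, got n={n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Genome(n, rng.integers(0, 2, size=n * (1 << n), dtype=np.uint8))


def random_contexts(n: int, X: int,
                    rng: np.random.Generator | int | None = None
                    ) -> list[Context]:
    """X contexts with all initial states and all target states unique."""
    m = 1 << n
    if X > m:
        raise ValueError(f"cannot draw {X} unique states from {m}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    inits = rng.choice(m, size=X, replace=False)
    targets = rng.choice(m, size=X, replace=False)
    return [
        Context(ExpressionState(n, int(i)), ExpressionState(n, int(t)))
        for i, t in zip(inits, targets)
    ]
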