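"""Sweeps over mutation rate, target distance and context count, with the
summary statistics used to characterize them.

Each sweep condition runs independent mutate/accept searches until a
requested number of discoveries is collected and summarizes the discovery
times by their mean μ with a percentile-bootstrap confidence interval
(1024 resamples by default).  The dependence of μ on the mutation rate p is
summarized by ordinary least squares of ln μ on p, i.e. the exponential law
μ(p) = exp(slope * p + intercept); discovery-time distributions are further
characterized by a log-normal maximum-likelihood fit.

Evolutionary speed-up is a ratio of mean discovery times: the p = 0.5
random-sampling control mean divided by the mean at a low mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .asynchronous import AsyncConfig, evolve_async
from .evolve import EvolutionConfig, evolve
from .network import Context, ExpressionState, encode_state
from .scenarios import NEOCORTEX, random_contexts

__all__ = [
    "SweepResult",
    "ExponentialFit",
    "LognormalFit",
    "run_discoveries",
    "sweep_mutation_rates",
    "sweep_target_distance",
    "sweep_contexts",
    "speedup",
    "fit_exponential",
    "bootstrap_mean_ci",
    "fit_lognormal",
]

_DEFAULT_BUDGET = 2_000_000_000


def bootstrap_mean_ci(samples: Sequence[float], resamples: int = 1024,
                      level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the mean."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(resamples, x.size))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class SweepResult:
    """Discovery times per condition of a one-parameter sweep."""

    param: str
    conditions: list[Hashable]
    discoveries: dict[Hashable, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def mean(self, condition: Hashable) -> float:
        return float(np.mean(self.discoveries[condition]))

    def median(self, condition: Hashable) -> float:
        return float(np.median(self.discoveries[condition]))

    def ci(self, condition: Hashable, resamples: int = 1024,
           level: float = 0.95, seed: int = 0) -> tuple[float, float]:
        return bootstrap_mean_ci(self.discoveries[condition], resamples,
                                 level, seed)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            lo, hi = self.ci(c)
            rows.append({
                self.param: c,
                "runs": len(self.discoveries[c]),
                "mean": self.mean(c),
                "median": self.median(c),
                "ci_low": lo,
                "ci_high": hi,
            })
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({self.param: c, "run": np.arange(len(d)),
                          "discovery_generations": d})
            for c, d in self.discoveries.items()
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ExponentialFit:
    """OLS fit of ln μ = slope * p + intercept over sweep conditions."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_values: tuple[float, ...]

    def predict_mu(self, p: float) -> float:
        return float(np.exp(self.slope * p + self.intercept))


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood log-normal parameters for discovery times."""

    log_mean: float
    log_sd: float
    normality_pvalue: float


def run_discoveries(contexts: Sequence[Context], p: float, discoveries: int,
                    seed: int = 0, mode: Literal["sync", "async"] = "sync",
                    async_config: AsyncConfig | None = None,
                    max_generations: int = _DEFAULT_BUDGET) -> np.ndarray:
    """Collect a batch of discovery times at one mutation rate."""
    config = EvolutionConfig(contexts=list(contexts), p=p,
                             max_generations=max_generations,
                             max_discoveries=discoveries, seed=seed)
    if mode == "async":
        rec = evolve_async(config, async_config)
    else:
        rec = evolve(config)
    if len(rec.discoveries) < discoveries:
        raise RuntimeError(
            f"generation budget exhausted after {len(rec.discoveries)} of "
            f"{discoveries} discoveries at p={p}"
        )
    return rec.discoveries


def _spawn_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(k) % 2_147_483_647]


def sweep_mutation_rates(p_values: Sequence[float], runs_per_p: int,
                         contexts: Sequence[Context] | None = None,
                         mode: Literal["sync", "async"] = "sync",
                         seed: int = 0,
                         async_config: AsyncConfig | None = None) -> SweepResult:
    """Independent discovery batches at each mutation rate."""
    contexts = list(contexts) if contexts is not None else NEOCORTEX.contexts
    seeds = _spawn_seeds(seed, len(p_values))
    disc = {
        float(p): run_discoveries(contexts, float(p), runs_per_p, seed=s,
                                  mode=mode, async_config=async_config)
        for p, s in zip(p_values, seeds)
    }
    return SweepResult(param="p", conditions=[float(p) for p in p_values],
                       discoveries=disc,
                       metadata={"mode": mode, "runs_per_p": runs_per_p,
                                 "seed": seed})


def target_at_distance(h: int, base_target: str = "01010",
                       n: int | None = None) -> ExpressionState:
    """Target state at exact Hamming distance h from the base target,
    flipping the leftmost h bits (the default convention; any bit choice is
    a valid experimental variant)."""
    base = encode_state(base_target)
    n = n or base.n
    if not 1 <= h <= n:
        raise ValueError(f"Hamming distance h must be in [1, {n}], got {h}")
    flip = int("1" * h + "0" * (n - h), 2)
    return ExpressionState(n, base.value ^ flip)


def sweep_target_distance(h_values: Sequence[int], p: float, runs: int,
                          seed: int = 0,
                          posterior: Context | None = None,
                          anterior_initial: str = "10000") -> SweepResult:
    """Vary the Hamming distance h between the two target states.

    The posterior context is fixed (default 00000 -> 01010); the anterior
    context starts from ``anterior_initial`` and targets a state at exact
    distance h from the posterior target.
    """
    posterior = posterior or NEOCORTEX.contexts[0]
    seeds = _spawn_seeds(seed, len(h_values))
    disc: dict[Hashable, np.ndarray] = {}
    targets_used = {}
    for h, s in zip(h_values, seeds):
        tgt = target_at_distance(int(h), posterior.target.to_string())
        ctx = [posterior, Context(encode_state(anterior_initial), tgt)]
        disc[int(h)] = run_discoveries(ctx, p, runs, seed=s)
        targets_used[int(h)] = tgt.to_string()
    return SweepResult(param="h", conditions=[int(h) for h in h_values],
                       discoveries=disc,
                       metadata={"p": p, "runs": runs, "seed": seed,
                                 "anterior_targets": targets_used})


def sweep_contexts(X_values: Sequence[int], p_values: Sequence[float],
                   runs: int, n: int = 5, seed: int = 0,
                   context_sets: dict[int, list[Context]] | None = None
                   ) -> SweepResult:
    """Vary the number of contexts X at each mutation rate.

    Context sets default to the canonical two neocortex contexts for X = 2
    and seeded random sets (all initial and target states unique) otherwise;
    the sets used are recorded in the result metadata.
    """
    sets_used: dict[int, list[Context]] = {}
    rng = np.random.default_rng(seed)
    for X in X_values:
        if context_sets and X in context_sets:
            ctx = list(context_sets[X])
        elif X == 2 and n == 5:
            ctx = NEOCORTEX.contexts
        else:
            ctx = random_contexts(n, X, rng)
        inits = [c.initial.value for c in ctx]
        if len(set(inits)) != len(inits):
            raise ValueError(f"duplicate initial states in the X={X} context set")
        sets_used[int(X)] = ctx
    conditions = [(int(X), float(p)) for X in X_values for p in p_values]
    seeds = _spawn_seeds(seed, len(conditions))
    disc: dict[Hashable, np.ndarray] = {}
    for (X, p), s in zip(conditions, seeds):
        disc[(X, p)] = run_discoveries(sets_used[X], p, runs, seed=s)
    meta_sets = {
        X: [(c.initial.to_string(), c.target.to_string()) for c in ctx]
        for X, ctx in sets_used.items()
    }
    return SweepResult(param="(X, p)", conditions=conditions, discoveries=disc,
                       metadata={"runs": runs, "seed": seed,
                                 "context_sets": meta_sets})


def speedup(slow_times: Sequence[float], fast_times: Sequence[float]) -> float:
    """Ratio of mean discovery times: control (slow) over scaffolded (fast)."""
    return float(np.mean(slow_times) / np.mean(fast_times))


def fit_exponential(sweep: SweepResult, p_min: float = 0.0) -> ExponentialFit:
    """OLS of ln(mean discovery time) against p over conditions with p > p_min."""
    ps = [c for c in sweep.conditions if float(c) > p_min]
    if len(ps) < 3:
        raise ValueError(
            f"exponential fit needs at least 3 conditions above p_min={p_min}"
        )
    x = np.array([float(p) for p in ps])
    y = np.array([np.log(sweep.mean(p)) for p in ps])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return ExponentialFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        p_values=tuple(float(p) for p in ps),
    )


def fit_lognormal(discovery_times: Sequence[float]) -> LognormalFit:
    """ML log-normal parameters plus a normality test on log-times.

    The goodness-of-fit p-value is from D'Agostino-Pearson normality of
    ln(times); a constant sample returns log_sd 0 and p-value 0.
    """
    x = np.asarray(discovery_times, dtype=np.float64)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("discovery times must be positive")
    logs = np.log(x)
    log_mean = float(logs.mean())
    if np.all(x == x[0]):
        return LognormalFit(log_mean, 0.0, 0.0)
    log_sd = float(logs.std())
    if x.size < 8:
        return LognormalFit(log_mean, log_sd, 0.0)
    _, pval = scipy.stats.normaltest(logs)
    return LognormalFit(log_mean, log_sd, float(pval))
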