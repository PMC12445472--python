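"""Threshold search: PSO, differential evolution, and exhaustive enumeration.

All three maximize a batch objective ``objective(T, V) -> fitness`` over the
2k-dimensional integer space of admissible threshold vectors.  The
metaheuristics search a continuous relaxation of ``[1, L - 2]**2k`` and map
every candidate through :func:`repair_candidate` (round, clip, sort,
de-duplicate) before evaluation, so every evaluated point is a valid
strictly-increasing integer threshold vector.

Defaults follow a standard, widely reported configuration: population 30,
up to 1000 iterations, DE/rand/1/bin with F = 0.8 and CR = 0.9, PSO with
c1 = c2 = 2 and inertia decreasing linearly from 0.9 to 0.4.  Termination
adds a stagnation rule (stop after ``stagnation_patience`` iterations
without global-best improvement), recorded in every result.  The default
patience of 300 covers enough of the inertia schedule that the swarm
reaches its low-inertia contraction phase before a stall can trigger a
stop; much shorter patience windows terminate PSO while it is still
oscillating coarsely and cost it the final refinement steps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .entropy import ThresholdVector

__all__ = [
    "OptimizerConfig",
    "OptimizerResult",
    "repair_candidate",
    "repair_batch",
    "pso_optimize",
    "de_optimize",
    "exhaustive_search",
]

Objective = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 30
    max_iterations: int = 1000
    de_mutation_F: float = 0.8
    de_crossover_CR: float = 0.9
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_inertia_start: float = 0.9
    pso_inertia_end: float = 0.4
    stagnation_patience: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1 or self.max_iterations < 1:
            raise ValueError("population and max_iterations must be positive")
        if not (0.0 <= self.de_crossover_CR <= 1.0):
            raise ValueError("de_crossover_CR must lie in [0, 1]")
        if self.stagnation_patience < 1:
            raise ValueError("stagnation_patience must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OptimizerResult:
    best_X: ThresholdVector
    best_fitness: float
    iterations_used: int
    trace: tuple[tuple[int, float], ...]

    def trace_csv(self) -> str:
        """Convergence trace as ``iteration,best_fitness`` CSV text."""
        lines = ["iteration,best_fitness"]
        lines += [f"{i},{f!r}" for i, f in self.trace]
        return "\n".join(lines) + "\n"


def _check_k_fits(k: int, levels: int) -> None:
    if k < 1:
        raise ValueError("k must be positive")
    if k > levels - 2:
        raise ValueError(
            f"cannot place {k} distinct thresholds in [1, {levels - 2}]"
        )


def repair_batch(raw: np.ndarray, k: int, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Map raw 2k-vectors onto valid integer threshold pairs (T, V).

    Each half is rounded half-up, clipped to ``[1, L - 2]``, sorted, and
    made strictly increasing by pushing duplicates upward (cascading), with
    a final downward cap so the top value stays within range.
    """
    _check_k_fits(k, levels)
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] != 2 * k:
        raise ValueError(f"raw vectors must have length {2 * k}, got {raw.shape[1]}")

    def fix(half: np.ndarray) -> np.ndarray:
        vals = np.floor(half + 0.5).astype(np.int64)
        np.clip(vals, 1, levels - 2, out=vals)
        vals.sort(axis=1)
        for i in range(1, k):
            vals[:, i] = np.maximum(vals[:, i], vals[:, i - 1] + 1)
        for i in range(k - 1, -1, -1):
            np.minimum(vals[:, i], levels - 2 - (k - 1 - i), out=vals[:, i])
        return vals

    return fix(raw[:, :k].copy()), fix(raw[:, k:].copy())


def repair_candidate(raw: Sequence[float], levels: int) -> ThresholdVector:
    """Repair a single raw 2k-vector into a valid :class:`ThresholdVector`."""
    raw = np.asarray(raw, dtype=float).ravel()
    if raw.size % 2 != 0 or raw.size == 0:
        raise ValueError("raw candidate must have even positive length")
    k = raw.size // 2
    T, V = repair_batch(raw[None, :], k, levels)
    return ThresholdVector(rows=tuple(T[0]), cols=tuple(V[0]), levels=levels)


def _lex_key(T: np.ndarray, V: np.ndarray, i: int) -> tuple:
    return tuple(T[i]) + tuple(V[i])


def _best_index(fit: np.ndarray, T: np.ndarray, V: np.ndarray) -> int:
    """Index of the maximal fitness, ties broken toward lexicographically smaller X."""
    best = fit.max()
    cand = np.flatnonzero(fit == best)
    if cand.size == 1:
        return int(cand[0])
    return int(min(cand, key=lambda i: _lex_key(T, V, i)))


def _result(tv: tuple, fit: float, levels: int, iterations: int,
            trace: list[tuple[int, float]]) -> OptimizerResult:
    k = len(tv) // 2
    X = ThresholdVector(rows=tv[:k], cols=tv[k:], levels=levels)
    return OptimizerResult(best_X=X, best_fitness=float(fit),
                           iterations_used=iterations, trace=tuple(trace))


def pso_optimize(objective: Objective, k: int, levels: int,
                 config: OptimizerConfig | None = None) -> OptimizerResult:
    """Global-best PSO over the continuous relaxation of the threshold space.

    Velocities are clamped to ``+/-(L - 3) / 2`` per dimension and positions
    reflected at the bounds; the inertia weight is interpolated linearly
    from ``pso_inertia_start`` to ``pso_inertia_end`` across
    ``max_iterations``.  Fully reproducible from ``config.seed``.
    """
    config = config or OptimizerConfig()
    _check_k_fits(k, levels)
    rng = np.random.default_rng(config.seed)
    dims = 2 * k
    lo, hi = 1.0, float(levels - 2)
    vmax = max((levels - 3) / 2.0, 0.5)
    pop = config.population

    x = rng.uniform(lo, hi, size=(pop, dims))
    v = np.zeros((pop, dims))
    T, V = repair_batch(x, k, levels)
    fit = np.asarray(objective(T, V), dtype=float)
    pbest_x, pbest_f = x.copy(), fit.copy()
    gi = _best_index(fit, T, V)
    gbest_x = x[gi].copy()
    gbest_f = float(fit[gi])
    gbest_tv = _lex_key(T, V, gi)

    iteration = 1
    stall = 0
    trace = [(iteration, gbest_f)]
    denom = max(config.max_iterations - 1, 1)
    while iteration < config.max_iterations and stall < config.stagnation_patience:
        inertia = config.pso_inertia_start + (
            config.pso_inertia_end - config.pso_inertia_start
        ) * min((iteration - 1) / denom, 1.0)
        r1 = rng.random((pop, dims))
        r2 = rng.random((pop, dims))
        v = (inertia * v
             + config.pso_c1 * r1 * (pbest_x - x)
             + config.pso_c2 * r2 * (gbest_x - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        over = x > hi
        x[over] = 2 * hi - x[over]
        v[over] *= -1.0
        under = x < lo
        x[under] = 2 * lo - x[under]
        v[under] *= -1.0
        np.clip(x, lo, hi, out=x)

        T, V = repair_batch(x, k, levels)
        fit = np.asarray(objective(T, V), dtype=float)
        improved_p = fit > pbest_f
        pbest_x[improved_p] = x[improved_p]
        pbest_f[improved_p] = fit[improved_p]

        iteration += 1
        ci = _best_index(fit, T, V)
        improved = False
        if fit[ci] > gbest_f:
            improved = True
        if fit[ci] > gbest_f or (fit[ci] == gbest_f and _lex_key(T, V, ci) < gbest_tv):
            gbest_f = float(fit[ci])
            gbest_x = x[ci].copy()
            gbest_tv = _lex_key(T, V, ci)
        stall = 0 if improved else stall + 1
        trace.append((iteration, gbest_f))

    return _result(gbest_tv, gbest_f, levels, iteration, trace)


def _de_indices(rng: np.random.Generator, pop: int) -> np.ndarray:
    """Three mutually distinct partner indices per individual (also != self)."""
    own = np.arange(pop)
    rows = np.empty((3, pop), dtype=np.int64)
    for j in range(3):
        rj = rng.integers(0, pop, size=pop)
        while True:
            bad = rj == own
            for prev in rows[:j]:
                bad |= rj == prev
            if pop <= 3:
                # Too few individuals for distinctness; only avoid self.
                bad = (rj == own) & (pop > 1)
            if not bad.any():
                break
            rj[bad] = rng.integers(0, pop, size=int(bad.sum()))
        rows[j] = rj
    return rows


def de_optimize(objective: Objective, k: int, levels: int,
                config: OptimizerConfig | None = None) -> OptimizerResult:
    """DE/rand/1/bin over the same search space and contracts as PSO.

    Selection keeps the better of trial vs target (strictly better replaces,
    so ties preserve the incumbent).  With ``CR = 0`` the crossover mask is
    empty — no forced mutant coordinate — making F = 0 / CR = 0 an exact
    no-op control.
    """
    config = config or OptimizerConfig()
    _check_k_fits(k, levels)
    rng = np.random.default_rng(config.seed)
    dims = 2 * k
    lo, hi = 1.0, float(levels - 2)
    pop = config.population
    F, CR = config.de_mutation_F, config.de_crossover_CR

    x = rng.uniform(lo, hi, size=(pop, dims))
    T, V = repair_batch(x, k, levels)
    fit = np.asarray(objective(T, V), dtype=float)
    gi = _best_index(fit, T, V)
    gbest_f = float(fit[gi])
    gbest_tv = _lex_key(T, V, gi)

    iteration = 1
    stall = 0
    trace = [(iteration, gbest_f)]
    while iteration < config.max_iterations and stall < config.stagnation_patience:
        r1, r2, r3 = _de_indices(rng, pop)
        mutant = x[r1] + F * (x[r2] - x[r3])
        np.clip(mutant, lo, hi, out=mutant)
        mask = rng.random((pop, dims)) < CR
        if CR > 0.0:
            jrand = rng.integers(0, dims, size=pop)
            mask[np.arange(pop), jrand] = True
        trial = np.where(mask, mutant, x)
        Tt, Vt = repair_batch(trial, k, levels)
        tfit = np.asarray(objective(Tt, Vt), dtype=float)
        sel = tfit > fit
        x[sel] = trial[sel]
        fit[sel] = tfit[sel]

        iteration += 1
        ci = _best_index(tfit, Tt, Vt)
        improved = False
        if tfit[ci] > gbest_f:
            improved = True
        if tfit[ci] > gbest_f or (
            tfit[ci] == gbest_f and _lex_key(Tt, Vt, ci) < gbest_tv
        ):
            gbest_f = float(tfit[ci])
            gbest_tv = _lex_key(Tt, Vt, ci)
        stall = 0 if improved else stall + 1
        trace.append((iteration, gbest_f))

    return _result(gbest_tv, gbest_f, levels, iteration, trace)


def exhaustive_search(objective: Objective, k: int, levels: int,
                      cap: int = 10_000_000) -> OptimizerResult:
    """Evaluate every admissible threshold vector; the small-scale oracle.

    Candidates are enumerated in lexicographic order of the concatenated
    ``(t | v)`` vector and compared with strict improvement, so ties resolve
    to the lexicographically smallest optimum.  Refuses instances whose
    candidate count ``C(L - 2, k)**2`` exceeds ``cap``.
    """
    _check_k_fits(k, levels)
    n_half = math.comb(levels - 2, k)
    n_total = n_half * n_half
    if n_total > cap:
        raise ValueError(
            f"exhaustive search refused: {n_total} candidates exceed cap {cap}"
        )
    combos = np.array(list(itertools.combinations(range(1, levels - 1), k)),
                      dtype=np.int64).reshape(n_half, k)
    best_f = -np.inf
    best_tv: tuple = ()
    evaluated = 0
    trace: list[tuple[int, float]] = []
    for t_row in combos:
        T = np.broadcast_to(t_row, (n_half, k))
        fit = np.asarray(objective(T, combos), dtype=float)
        j = int(np.argmax(fit))  # first maximum = lexicographically smallest v
        evaluated += n_half
        if fit[j] > best_f:
            best_f = float(fit[j])
            best_tv = tuple(t_row) + tuple(combos[j])
        trace.append((evaluated, best_f))
    return _result(best_tv, best_f, levels, evaluated, trace)
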