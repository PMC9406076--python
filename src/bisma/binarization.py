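"""Binary form of the hybrid slime mould optimizer (BISMA).

Subset-selection problems are binary, while the slime mould machinery is
continuous.  Each agent therefore keeps a continuous "shadow" position that
evolves under the full continuous update (including the Cauchy and
differential-evolution refinements of the elite), and a bit vector derived
from the shadow through a transfer function:

* S-shaped transfer functions are sigmoids; the bit is redrawn each update,
  ``bit = 1`` iff ``rand < S(x)`` (no memory of the previous bit).
* V-shaped transfer functions are folded sigmoids with ``V(0) = 0``; the
  current bit is complemented with probability ``V(x)``, so a shadow frozen
  at 0 freezes the bits.

Fitness is always measured on the bit vector (lower is better), and a bit
vector submitted for evaluation is never all-zero: the default repair sets
one uniformly chosen bit, the alternative assigns worst (infinite) fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import erf

from .core import (
    ISMAParams,
    OptimizationResult,
    Population,
    Problem,
    VARIANTS,
    _cauchy_vector,
    compute_a,
    compute_b,
    compute_weights,
    de_crossover,
    de_mutation,
    propose_position,
)

__all__ = [
    "TransferFunctionSpec",
    "TRANSFER_FUNCTIONS",
    "get_transfer_function",
    "transfer_value",
    "binary_init",
    "s_shaped_flip",
    "v_shaped_flip",
    "run_bisma",
]


@dataclass(frozen=True)
class TransferFunctionSpec:
    """One of the eight standard S-/V-shaped probability maps."""

    name: str
    family: str  # "S" or "V"
    variant: int
    map: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x):
        return self.map(np.asarray(x, dtype=float))


_SQRT_PI_2 = np.sqrt(np.pi) / 2.0

TRANSFER_FUNCTIONS: dict[str, TransferFunctionSpec] = {
    "S1": TransferFunctionSpec("S1", "S", 1, lambda x: 1.0 / (1.0 + np.exp(-2.0 * x))),
    "S2": TransferFunctionSpec("S2", "S", 2, lambda x: 1.0 / (1.0 + np.exp(-x))),
    "S3": TransferFunctionSpec("S3", "S", 3, lambda x: 1.0 / (1.0 + np.exp(-x / 2.0))),
    "S4": TransferFunctionSpec("S4", "S", 4, lambda x: 1.0 / (1.0 + np.exp(-x / 3.0))),
    "V1": TransferFunctionSpec("V1", "V", 1, lambda x: np.abs(erf(_SQRT_PI_2 * x))),
    "V2": TransferFunctionSpec("V2", "V", 2, lambda x: np.abs(np.tanh(x))),
    "V3": TransferFunctionSpec("V3", "V", 3, lambda x: np.abs(x / np.sqrt(1.0 + x * x))),
    "V4": TransferFunctionSpec(
        "V4", "V", 4, lambda x: np.abs(2.0 / np.pi * np.arctan(np.pi / 2.0 * x))
    ),
}


def get_transfer_function(token: str) -> TransferFunctionSpec:
    try:
        return TRANSFER_FUNCTIONS[token.upper()]
    except KeyError:
        raise KeyError(
            f"unknown transfer function {token!r}; known: {sorted(TRANSFER_FUNCTIONS)}"
        ) from None


def transfer_value(tf: TransferFunctionSpec | str, x) -> np.ndarray | float:
    """Probability map of one transfer function at ``x`` (scalar or vector)."""
    if isinstance(tf, str):
        tf = get_transfer_function(tf)
    out = tf(x)
    return float(out) if np.isscalar(x) else out


def binary_init(d: int, rng: np.random.Generator) -> np.ndarray:
    """Random-threshold bit initialization: bit = 1 iff its draw > 0.5.

    An all-zero outcome is repaired by setting one uniformly chosen bit.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    bits = (rng.random(d) > 0.5).astype(np.int8)
    if not bits.any():
        bits[int(rng.integers(0, d))] = 1
    return bits


def s_shaped_flip(prob: float, rng: np.random.Generator) -> int:
    """S-family bit rule: redraw, bit = 1 with the transfer probability."""
    return int(rng.random() < prob)


def v_shaped_flip(prob: float, current_bit: int, rng: np.random.Generator) -> int:
    """V-family bit rule: complement the current bit with the transfer
    probability, else keep it."""
    return int(1 - current_bit) if rng.random() < prob else int(current_bit)


def _bits_from_shadow(
    shadow: np.ndarray,
    current_bits: np.ndarray,
    tf: TransferFunctionSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    probs = tf(shadow)
    u = rng.random(shadow.shape[0])
    if tf.family == "S":
        return (u < probs).astype(np.int8)
    return np.where(u < probs, 1 - current_bits, current_bits).astype(np.int8)


def _repair(bits: np.ndarray, rng: np.random.Generator, mode: str) -> tuple[np.ndarray, bool]:
    """Enforce the at-least-one-bit contract; returns (bits, evaluable)."""
    if bits.any():
        return bits, True
    if mode == "random-bit":
        bits = bits.copy()
        bits[int(rng.integers(0, bits.shape[0]))] = 1
        return bits, True
    if mode == "penalize":
        return bits, False
    raise ValueError(f"unknown repair mode {mode!r}")


def run_bisma(
    fitness_fn: Callable[[np.ndarray], float],
    d: int,
    tf: TransferFunctionSpec | str = "V4",
    params: ISMAParams | None = None,
    variant: str = "ISMA",
    shadow_bounds: tuple[float, float] = (0.0, 1.0),
    repair: str = "random-bit",
) -> OptimizationResult:
    """Binary subset search with the hybrid slime mould optimizer.

    Parameters
    ----------
    fitness_fn
        Maps a 0/1 vector of length ``d`` (never all-zero) to a scalar;
        lower is better.
    d
        Number of bits (e.g. genes).
    tf
        Transfer function token or spec; ``V4`` by default.
    params
        Continuous optimizer settings; defaults to 20 agents, 50 iterations.
    shadow_bounds
        The box the continuous shadows live in ([0, 1] by default; the
        choice is empirically indifferent because the contraction branch
        drives shadows toward 0 either way).
    repair
        ``"random-bit"`` (set one random bit) or ``"penalize"`` (all-zero
        vectors get infinite fitness without evaluation).

    Returns an :class:`OptimizationResult` whose ``best_bits`` is the best
    bit vector found and ``best_position`` its continuous shadow.
    """
    if isinstance(tf, str):
        tf = get_transfer_function(tf)
    if params is None:
        params = ISMAParams(population_size=20, max_iter=50)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    want_cauchy, want_mc = VARIANTS[variant]
    do_cauchy = want_cauchy and params.use_cauchy
    do_mc = want_mc and params.use_mc

    lo, hi = shadow_bounds
    problem = Problem(
        dimension=d, lower=lo, upper=hi, objective=lambda x: np.nan, name="binary-shadow"
    )
    rng = np.random.default_rng(params.seed)
    max_iter = params.resolve_max_iter()
    n = params.population_size

    def eval_bits(bits: np.ndarray) -> tuple[np.ndarray, float, int]:
        bits, ok = _repair(bits, rng, repair)
        if not ok:
            return bits, float("inf"), 0
        return bits, float(fitness_fn(bits)), 1

    shadows = lo + rng.random((n, d)) * (hi - lo)
    bits = np.stack([binary_init(d, rng) for _ in range(n)])
    fitnesses = np.empty(n)
    n_eval = 0
    for i in range(n):
        bits[i], fitnesses[i], cost = eval_bits(bits[i])
        n_eval += cost
    best = int(np.argmin(fitnesses))
    pop = Population(
        positions=shadows,
        fitnesses=fitnesses,
        best_position=shadows[best].copy(),
        best_fitness=float(fitnesses[best]),
    )
    best_bits = bits[best].copy()

    history: list[tuple[int, int, float]] = []
    for t in range(1, max_iter + 1):
        pop.weights = compute_weights(pop.fitnesses, d, rng)
        a = compute_a(t, max_iter)
        b = compute_b(t, max_iter)
        for i in range(n):
            pop.positions[i] = propose_position(i, pop, problem, params, a, b, rng)
            bits[i] = _bits_from_shadow(pop.positions[i], bits[i], tf, rng)
            bits[i], pop.fitnesses[i], cost = eval_bits(bits[i])
            n_eval += cost
            if pop.fitnesses[i] < pop.best_fitness:
                pop.best_fitness = float(pop.fitnesses[i])
                pop.best_position = pop.positions[i].copy()
                best_bits = bits[i].copy()
        if do_cauchy:
            c = _cauchy_vector(params.cauchy_scale, d, rng)
            cand_shadow = problem.clamp(pop.best_position * (1.0 + c), params.clamp_mode)
            cand_bits = _bits_from_shadow(cand_shadow, best_bits, tf, rng)
            cand_bits, f, cost = eval_bits(cand_bits)
            n_eval += cost
            if f < pop.best_fitness:
                pop.best_fitness = f
                pop.best_position = cand_shadow
                best_bits = cand_bits
        if do_mc:
            best_idx = int(np.argmin(pop.fitnesses))
            candidates = np.array([i for i in range(n) if i != best_idx])
            ia, ib, ic = rng.choice(candidates, size=3, replace=False)
            f_scale = params.de_F if params.de_F is not None else float(rng.random())
            mutant = de_mutation(
                pop.positions[ia], pop.positions[ib], pop.positions[ic], f_scale
            )
            trial = de_crossover(mutant, pop.best_position, params.de_Pc, rng)
            trial = problem.clamp(trial, params.clamp_mode)
            cand_bits = _bits_from_shadow(trial, best_bits, tf, rng)
            cand_bits, f, cost = eval_bits(cand_bits)
            n_eval += cost
            if f < pop.best_fitness:
                pop.best_fitness = f
                pop.best_position = trial
                best_bits = cand_bits
        history.append((t, n_eval, pop.best_fitness))

    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        history=history,
        n_evaluations=n_eval,
        seed=params.seed,
        variant=variant,
        best_bits=best_bits.copy(),
    )
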