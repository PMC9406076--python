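"""Continuous slime mould optimizer (SMA) and its hybrid refinement (ISMA).

The slime mould algorithm is a population-based stochastic minimizer: each
search agent's position is pulled toward the best-known position through a
fitness-derived weight matrix, or contracted toward the origin, with a small
probability of uniform re-seeding inside the search box.  The hybrid variant
adds two greedy refinements of the incumbent best solution every iteration:

* a multiplicative Cauchy mutation, ``x_b * (1 + c)`` with heavy-tailed
  elementwise draws ``c``, giving occasional long jumps out of local basins;
* a differential-evolution step: a mutant ``x_a + F * (x_b - x_c)`` built from
  three random agents is crossed with the incumbent, and the trial replaces
  the incumbent only on strict improvement.

Ablation variants: ``"SMA"`` (no refinement), ``"CSMA"`` (Cauchy only),
``"MCSMA"`` (crossover/mutation only), ``"ISMA"`` (both).

Randomness contract
-------------------
All stochastic operations draw from a single ``numpy.random.Generator`` in a
fixed, documented order so that a run is reproducible from its seed and a
pinned stream can be hand-traced:

* initialization: one ``rng.random((N, D))`` block scaled into the box;
* each iteration, in order:

  1. weights: one ``rng.random((N, D))`` block whose row ``k`` belongs to the
     rank-``k`` agent of the ascending fitness sort;
  2. per agent ``i = 0..N-1``: ``rand = rng.random()``; if ``rand < z`` one
     ``rng.random(D)`` re-seeding block, otherwise ``r = rng.random()``,
     ``A, B = rng.integers(0, N, size=2)``, ``vb = rng.uniform(-a, a, D)``,
     ``vc = rng.uniform(-b, b, D)`` (both drawn regardless of branch);
  3. Cauchy refinement (if enabled): one ``rng.random(D)`` block;
  4. DE refinement (if enabled): ``rng.choice`` of 3 distinct non-best agent
     indices, ``F = rng.random()`` when the F policy is "fresh draw", then
     the crossover draws ``rng.random(D)`` and ``j0 = rng.integers(0, D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "InvalidProblemError",
    "Problem",
    "Population",
    "SMAParams",
    "ISMAParams",
    "OptimizationResult",
    "initialize_population",
    "compute_p",
    "compute_weights",
    "compute_a",
    "compute_b",
    "sma_position_update",
    "cauchy_sample",
    "cauchy_refine_best",
    "de_mutation",
    "de_crossover",
    "mc_refine_best",
    "run_isma",
    "run_sma",
    "VARIANTS",
]

Variant = Literal["SMA", "CSMA", "MCSMA", "ISMA"]

#: variant -> (cauchy refinement enabled, crossover/mutation refinement enabled)
VARIANTS: dict[str, tuple[bool, bool]] = {
    "SMA": (False, False),
    "CSMA": (True, False),
    "MCSMA": (False, True),
    "ISMA": (True, True),
}


class InvalidProblemError(ValueError):
    """Raised for non-finite or inverted search-space bounds."""


@dataclass
class Problem:
    """A box-constrained minimization problem.

    Parameters
    ----------
    dimension
        Number of decision variables ``D``.
    lower, upper
        Bound vectors of length ``D`` (scalars are broadcast).
    objective
        Deterministic map from a length-``D`` vector to a scalar; lower is
        better.
    """

    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    name: str = ""

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise InvalidProblemError("dimension must be >= 1")
        self.lower = np.broadcast_to(
            np.asarray(self.lower, dtype=float), (self.dimension,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, dtype=float), (self.dimension,)
        ).copy()
        if not (np.isfinite(self.lower).all() and np.isfinite(self.upper).all()):
            raise InvalidProblemError("bounds must be finite")
        if not (self.lower < self.upper).all():
            raise InvalidProblemError("lower bound must be < upper bound elementwise")

    def clamp(self, x: np.ndarray, mode: str = "clip") -> np.ndarray:
        """Project ``x`` into the box; ``mode`` is ``"clip"`` or ``"reflect"``."""
        if mode == "clip":
            return np.clip(x, self.lower, self.upper)
        if mode == "reflect":
            span = self.upper - self.lower
            y = np.mod(x - self.lower, 2.0 * span)
            y = np.where(y > span, 2.0 * span - y, y)
            return self.lower + y
        raise ValueError(f"unknown clamp mode {mode!r}")


@dataclass
class SMAParams:
    """Run settings for the plain slime mould optimizer.

    ``z`` is the uniform re-seeding probability (0.03 in the source
    literature).  Exactly one of ``max_iter`` or ``max_evaluations`` governs
    the run length; a function-evaluation budget is converted to
    ``T = floor(budget / (N + 2))`` so that the per-iteration cost of the
    hybrid's two refinement evaluations is accounted for uniformly across
    variants.
    """

    population_size: int = 20
    max_iter: int | None = 50
    max_evaluations: int | None = None
    z: float = 0.03
    seed: int = 0
    clamp_mode: str = "clip"
    # Eq-(1) branch-2 reading: "w-on-a" -> Xb + vb*(W*XA - XB)  (original SMA)
    #                          "w-on-diff" -> Xb + vb*W*(XA - XB) (sensitivity)
    branch2_weighting: str = "w-on-a"

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (DE needs 3 partners)")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("z must lie in [0, 1]")
        if self.max_iter is None and self.max_evaluations is None:
            raise ValueError("one of max_iter / max_evaluations is required")

    def resolve_max_iter(self) -> int:
        if self.max_evaluations is not None:
            t = self.max_evaluations // (self.population_size + 2)
            if t < 1:
                raise ValueError("evaluation budget too small for one iteration")
            return t
        assert self.max_iter is not None
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        return self.max_iter


@dataclass
class ISMAParams(SMAParams):
    """SMA settings plus the hybrid refinement knobs.

    ``de_F = None`` means a fresh uniform [0, 1) scale factor is drawn for
    every mutation; a float pins it.  ``use_cauchy`` / ``use_mc`` gate the
    refinements beneath the variant selection (so the hybrid code path with
    both disabled reproduces plain SMA bit for bit).
    """

    cauchy_scale: float = 1.0
    de_F: float | None = None
    de_Pc: float = 0.5
    use_cauchy: bool = True
    use_mc: bool = True

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy_scale must be positive")
        if not 0.0 <= self.de_Pc <= 1.0:
            raise ValueError("de_Pc must lie in [0, 1]")


@dataclass
class Population:
    """Optimizer state: agent positions/fitnesses plus the elite memory."""

    positions: np.ndarray  # (N, D)
    fitnesses: np.ndarray  # (N,)
    best_position: np.ndarray  # (D,)
    best_fitness: float
    weights: np.ndarray | None = None  # (N, D), refreshed each iteration

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class OptimizationResult:
    """Outcome of a run: incumbent, convergence trace and evaluation count.

    ``history`` rows are ``(iteration, evaluations_so_far, best_fitness)``;
    best fitness is non-increasing because the incumbent is elite.
    """

    best_position: np.ndarray
    best_fitness: float
    history: list[tuple[int, int, float]]
    n_evaluations: int
    seed: int
    variant: str = "ISMA"
    best_bits: np.ndarray | None = None

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.history, columns=["iteration", "evaluations", "best_fitness"]
        )


# ---------------------------------------------------------------------------
# elementary operations


def compute_p(s_i: float, df: float) -> float:
    """Branch-decision probability ``p = tanh(|S_i - DF|)``, in [0, 1)."""
    if not (math.isfinite(s_i) and math.isfinite(df)):
        raise ValueError("fitness values must be finite")
    return math.tanh(abs(s_i - df))


def compute_a(t: int, max_iter: int) -> float:
    """Shrinking half-width ``a = arctanh(1 - t/T)``; iterations count from 1."""
    if not 1 <= t <= max_iter:
        raise ValueError("iteration counter must satisfy 1 <= t <= max_iter")
    return math.atanh(1.0 - t / max_iter)

def compute_b(t: int, max_iter: int) -> float:
    """Shrinking half-width ``b = 1 - t/T`` in [0, 1)."""
    if not 1 <= t <= max_iter:
        raise ValueError("iteration counter must satisfy 1 <= t <= max_iter")
    return 1.0 - t / max_iter


def compute_weights(
    fitnesses: np.ndarray, dimension: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-rank weight matrix ``W`` (N x D).

    Agents are sorted ascending (minimization); the better half gets
    ``1 + r*log10((bF - S)/(bF - wF) + 1)`` and the worse half the ``1 - ...``
    form, with a fresh uniform ``r`` per element.  The log argument's ratio is
    defined as 0 when the spread ``bF - wF`` is zero, so a degenerate
    population gets all-ones weights.  Rows are returned in original agent
    order.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    n = fitnesses.shape[0]
    order = np.argsort(fitnesses, kind="stable")
    s_sorted = fitnesses[order]
    b_f, w_f = s_sorted[0], s_sorted[-1]
    spread = b_f - w_f
    if spread == 0.0:
        ratio = np.zeros(n)
    else:
        ratio = (b_f - s_sorted) / spread
    r = rng.random((n, dimension))
    log_term = np.log10(ratio + 1.0)[:, None]
    half = n // 2  # "condition": ranks 0 .. N//2 - 1
    w_sorted = np.where(np.arange(n)[:, None] < half, 1.0 + r * log_term, 1.0 - r * log_term)
    w = np.empty_like(w_sorted)
    w[order] = w_sorted
    return w


def initialize_population(
    problem: Problem, params: SMAParams, rng: np.random.Generator
) -> Population:
    """Uniform initialization in the box; all agents evaluated, elite set."""
    n, d = params.population_size, problem.dimension
    positions = problem.lower + rng.random((n, d)) * (problem.upper - problem.lower)
    fitnesses = np.array([problem.objective(x) for x in positions], dtype=float)
    best = int(np.argmin(fitnesses))
    return Population(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[best].copy(),
        best_fitness=float(fitnesses[best]),
    )


def propose_position(
    i: int,
    pop: Population,
    problem: Problem,
    params: SMAParams,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One agent's next position under the three-branch update rule.

    Uses the population's current elite as the attractor; does not evaluate.
    """
    d = problem.dimension
    rand = rng.random()
    if rand < params.z:
        return problem.lower + rng.random(d) * (problem.upper - problem.lower)
    r = rng.random()
    idx_a, idx_b = rng.integers(0, pop.size, size=2)
    vb = rng.uniform(-a, a, d)
    vc = rng.uniform(-b, b, d)
    p = compute_p(float(pop.fitnesses[i]), pop.best_fitness)
    assert pop.weights is not None, "weights must be refreshed before the update"
    if r < p:
        x_a, x_b = pop.positions[idx_a], pop.positions[idx_b]
        w_i = pop.weights[i]
        if params.branch2_weighting == "w-on-a":
            step = w_i * x_a - x_b
        elif params.branch2_weighting == "w-on-diff":
            step = w_i * (x_a - x_b)
        else:
            raise ValueError(f"unknown branch2_weighting {params.branch2_weighting!r}")
        new = pop.best_position + vb * step
    else:
        new = vc * pop.positions[i]
    return problem.clamp(new, params.clamp_mode)


def sma_position_update(
    pop: Population,
    problem: Problem,
    params: SMAParams,
    t: int,
    rng: np.random.Generator,
    max_iter: int | None = None,
) -> Population:
    """One full position sweep: propose all agents against the elite
    snapshot, re-evaluate, and update the elite.  Weights must be current."""
    big_t = max_iter if max_iter is not None else params.resolve_max_iter()
    a = compute_a(t, big_t)
    b = compute_b(t, big_t)
    proposals = np.empty_like(pop.positions)
    for i in range(pop.size):
        proposals[i] = propose_position(i, pop, problem, params, a, b, rng)
    pop.positions = proposals
    pop.fitnesses = np.array([problem.objective(x) for x in pop.positions], dtype=float)
    best = int(np.argmin(pop.fitnesses))
    if pop.fitnesses[best] < pop.best_fitness:
        pop.best_fitness = float(pop.fitnesses[best])
        pop.best_position = pop.positions[best].copy()
    return pop


def cauchy_sample(scale: float, rng: np.random.Generator) -> float:
    """One Cauchy(0, scale) draw by CDF inversion: scale*tan(pi*(u - 1/2))."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    u = rng.random()
    return scale * math.tan(math.pi * (u - 0.5))


def _cauchy_vector(scale: float, d: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(d)
    return scale * np.tan(np.pi * (u - 0.5))


def cauchy_refine_best(
    pop: Population, problem: Problem, params: ISMAParams, rng: np.random.Generator
) -> bool:
    """Heavy-tailed elite mutation ``x_b * (1 + c)``; greedy acceptance.

    Returns True if the elite improved.  Always costs one evaluation.
    """
    c = _cauchy_vector(params.cauchy_scale, problem.dimension, rng)
    candidate = problem.clamp(pop.best_position * (1.0 + c), params.clamp_mode)
    f = float(problem.objective(candidate))
    if f < pop.best_fitness:
        pop.best_fitness = f
        pop.best_position = candidate
        return True
    return False


def de_mutation(xa: np.ndarray, xb: np.ndarray, xc: np.ndarray, f: float) -> np.ndarray:
    """Differential mutant ``xa + F*(xb - xc)``."""
    xa, xb, xc = (np.asarray(v, dtype=float) for v in (xa, xb, xc))
    if not (xa.shape == xb.shape == xc.shape):
        raise ValueError("mutation vectors must share a shape")
    return xa + f * (xb - xc)


def de_crossover(
    mutant: np.ndarray, target: np.ndarray, pc: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: take the mutant coordinate where ``rand <= Pc`` or
    at the forced index ``j0``, guaranteeing at least one mutant component."""
    mutant = np.asarray(mutant, dtype=float)
    target = np.asarray(target, dtype=float)
    if mutant.shape != target.shape:
        raise ValueError("mutant/target length mismatch")
    if not 0.0 <= pc <= 1.0:
        raise ValueError("Pc must lie in [0, 1]")
    d = mutant.shape[0]
    take = rng.random(d) <= pc
    j0 = int(rng.integers(0, d))
    take[j0] = True
    return np.where(take, mutant, target)


def mc_refine_best(
    pop: Population, problem: Problem, params: ISMAParams, rng: np.random.Generator
) -> bool:
    """DE mutation + crossover trial against the elite; greedy acceptance."""
    if pop.size < 4:
        raise ValueError("DE refinement needs a population of at least 4")
    best_idx = int(np.argmin(pop.fitnesses))
    candidates = np.array([i for i in range(pop.size) if i != best_idx])
    ia, ib, ic = rng.choice(candidates, size=3, replace=False)
    f = params.de_F if params.de_F is not None else float(rng.random())
    mutant = de_mutation(pop.positions[ia], pop.positions[ib], pop.positions[ic], f)
    trial = de_crossover(mutant, pop.best_position, params.de_Pc, rng)
    trial = problem.clamp(trial, params.clamp_mode)
    fit = float(problem.objective(trial))
    if fit < pop.best_fitness:
        pop.best_fitness = fit
        pop.best_position = trial
        return True
    return False


# ---------------------------------------------------------------------------
# drivers


def run_isma(
    problem: Problem,
    params: ISMAParams | SMAParams,
    variant: str = "ISMA",
) -> OptimizationResult:
    """Run the (hybrid) slime mould optimizer.

    ``variant`` selects the refinement combination (see :data:`VARIANTS`);
    ``ISMAParams.use_cauchy`` / ``use_mc`` can further disable a refinement,
    so ``variant="ISMA"`` with both off is identical to ``variant="SMA"``
    under the same seed.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick one of {sorted(VARIANTS)}")
    want_cauchy, want_mc = VARIANTS[variant]
    if isinstance(params, ISMAParams):
        iparams = params
    else:
        iparams = ISMAParams(**{k: getattr(params, k) for k in (
            "population_size", "max_iter", "max_evaluations", "z", "seed",
            "clamp_mode", "branch2_weighting")})
    do_cauchy = want_cauchy and iparams.use_cauchy
    do_mc = want_mc and iparams.use_mc

    rng = np.random.default_rng(iparams.seed)
    max_iter = iparams.resolve_max_iter()
    pop = initialize_population(problem, iparams, rng)
    n_eval = pop.size
    history: list[tuple[int, int, float]] = []
    for t in range(1, max_iter + 1):
        pop.weights = compute_weights(pop.fitnesses, problem.dimension, rng)
        sma_position_update(pop, problem, iparams, t, rng, max_iter)
        n_eval += pop.size
        if do_cauchy:
            cauchy_refine_best(pop, problem, iparams, rng)
            n_eval += 1
        if do_mc:
            mc_refine_best(pop, problem, iparams, rng)
            n_eval += 1
        history.append((t, n_eval, pop.best_fitness))
    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        history=history,
        n_evaluations=n_eval,
        seed=iparams.seed,
        variant=variant,
    )


def run_sma(problem: Problem, params: SMAParams) -> OptimizationResult:
    """Plain slime mould algorithm (hybrid loop with both refinements off)."""
    return run_isma(problem, params, variant="SMA")
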