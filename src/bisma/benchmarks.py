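"""Classical 23-function continuous benchmark suite.

Seven scalable unimodal functions (sphere, two Schwefel norms, max-norm,
Rosenbrock, step, noisy quartic), six scalable multimodal functions
(Schwefel 2.26, Rastrigin, Ackley, Griewank, two penalized functions) and ten
fixed-dimension multimodal functions (Shekel's foxholes, Kowalik, six-hump
camel, Branin, Goldstein-Price, Hartmann 3/6, Shekel 5/7/10), with their
conventional boxes and D = 30 for the scalable ones.

Fixed-dimension optimum locations were refined numerically to machine
precision and frozen together with their objective values, so the registry is
self-consistent: ``evaluate(name, spec.optimum) == spec.f_star`` to 1e-12.
The noisy quartic's registered optimum refers to its deterministic part (the
uniform-noise term is drawn from an optional generator so that runs remain
reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .core import Problem

__all__ = ["BenchmarkSpec", "evaluate", "list_suite", "get_spec", "make_problem", "SUITE"]

_D = 30  # dimension of the scalable functions


@dataclass(frozen=True)
class BenchmarkSpec:
    """Registry entry: box, modality class, known optimum and its value."""

    name: str
    dimension: int
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    f_star: float
    optimum: tuple[float, ...]
    kind: str  # "unimodal" | "multimodal" | "fixed_dim"
    func: Callable[[np.ndarray], float]
    noisy: bool = False


# ---------------------------------------------------------------------------
# scalable unimodal


def _sphere(x):
    return float(np.sum(x * x))


def _schwefel_2_22(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _schwefel_1_2(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_2_21(x):
    return float(np.max(np.abs(x)))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _step(x):
    return float(np.sum(np.floor(x + 0.5) ** 2))


def _quartic(x):  # deterministic part; noise added by make_objective
    i = np.arange(1, x.size + 1)
    return float(np.sum(i * x**4))


# ---------------------------------------------------------------------------
# scalable multimodal


def _schwefel_2_26(x):
    return float(-np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _rastrigin(x):
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _ackley(x):
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _u(x, a, k, m):
    out = np.zeros_like(x)
    out = np.where(x > a, k * (x - a) ** m, out)
    out = np.where(x < -a, k * (-x - a) ** m, out)
    return out


def _penalized_1(x):
    d = x.size
    y = 1.0 + (x + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * term + np.sum(_u(x, 10.0, 100.0, 4.0)))


def _penalized_2(x):
    term = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * term + np.sum(_u(x, 5.0, 100.0, 4.0)))


# ---------------------------------------------------------------------------
# fixed-dimension multimodal

_FOX_A = np.array(
    [
        list(np.tile([-32.0, -16.0, 0.0, 16.0, 32.0], 5)),
        list(np.repeat([-32.0, -16.0, 0.0, 16.0, 32.0], 5)),
    ]
)


def _foxholes(x):
    denom = np.arange(1, 26) + np.sum((x[:, None] - _FOX_A) ** 6, axis=0)
    return float(1.0 / (1.0 / 500.0 + np.sum(1.0 / denom)))


_KOW_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOW_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _kowalik(x):
    num = x[0] * (_KOW_B**2 + _KOW_B * x[1])
    den = _KOW_B**2 + _KOW_B * x[2] + x[3]
    return float(np.sum((_KOW_A - num / den) ** 2))


def _camel6(x):
    x1, x2 = x
    return float(
        4.0 * x1**2 - 2.1 * x1**4 + x1**6 / 3.0 + x1 * x2 - 4.0 * x2**2 + 4.0 * x2**4
    )


def _branin(x):
    x1, x2 = x
    a, b, c = 1.0, 5.1 / (4.0 * np.pi**2), 5.0 / np.pi
    r, s, t = 6.0, 10.0, 1.0 / (8.0 * np.pi)
    return float(a * (x2 - b * x1**2 + c * x1 - r) ** 2 + s * (1.0 - t) * np.cos(x1) + s)


def _goldstein_price(x):
    x1, x2 = x
    p1 = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1**2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2**2
    )
    p2 = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1**2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2**2
    )
    return float(p1 * p2)


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]])
_H3_P = 1e-4 * np.array(
    [[3689.0, 1170.0, 2673.0], [4699.0, 4387.0, 7470.0], [1091.0, 8732.0, 5547.0], [381.0, 5743.0, 8828.0]]
)


def _hartmann3(x):
    inner = np.sum(_H3_A * (x[None, :] - _H3_P) ** 2, axis=1)
    return float(-np.sum(_H3_ALPHA * np.exp(-inner)))


_H6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_H6_P = 1e-4 * np.array(
    [
        [1312.0, 1696.0, 5569.0, 124.0, 8283.0, 5886.0],
        [2329.0, 4135.0, 8307.0, 3736.0, 1004.0, 9991.0],
        [2348.0, 1451.0, 3522.0, 2883.0, 3047.0, 6650.0],
        [4047.0, 8828.0, 8732.0, 5743.0, 1091.0, 381.0],
    ]
)


def _hartmann6(x):
    inner = np.sum(_H6_A * (x[None, :] - _H6_P) ** 2, axis=1)
    return float(-np.sum(_H3_ALPHA * np.exp(-inner)))


_SHEKEL_A = np.array(
    [
        [4.0, 4.0, 4.0, 4.0],
        [1.0, 1.0, 1.0, 1.0],
        [8.0, 8.0, 8.0, 8.0],
        [6.0, 6.0, 6.0, 6.0],
        [3.0, 7.0, 3.0, 7.0],
        [2.0, 9.0, 2.0, 9.0],
        [5.0, 5.0, 3.0, 3.0],
        [8.0, 1.0, 8.0, 1.0],
        [6.0, 2.0, 6.0, 2.0],
        [7.0, 3.6, 7.0, 3.6],
    ]
)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(m):
    def f(x):
        diff = x[None, :] - _SHEKEL_A[:m]
        return float(-np.sum(1.0 / (np.sum(diff * diff, axis=1) + _SHEKEL_C[:m])))

    return f


# ---------------------------------------------------------------------------
# registry

def _box(lo: float, hi: float, d: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    return tuple([lo] * d), tuple([hi] * d)


def _spec(name, d, lo, hi, f_star, optimum, kind, func, noisy=False):
    if np.isscalar(lo):
        lower, upper = _box(float(lo), float(hi), d)
    else:
        lower, upper = tuple(map(float, lo)), tuple(map(float, hi))
    return BenchmarkSpec(name, d, lower, upper, float(f_star), tuple(map(float, optimum)), kind, func, noisy)


_ZEROS = tuple([0.0] * _D)
_ONES = tuple([1.0] * _D)

# x* of Schwefel 2.26 per coordinate (stationary point of x*sin(sqrt(x))),
# refined numerically; f* = -D * 418.982887272433799...
_SCHWEFEL_XSTAR = 420.96874635760247
_SCHWEFEL_FSTAR = -12569.486618173012  # at D = 30

SUITE: dict[str, BenchmarkSpec] = {}

def _register(spec: BenchmarkSpec) -> None:
    SUITE[spec.name] = spec


_register(_spec("F1", _D, -100, 100, 0.0, _ZEROS, "unimodal", _sphere))
_register(_spec("F2", _D, -10, 10, 0.0, _ZEROS, "unimodal", _schwefel_2_22))
_register(_spec("F3", _D, -100, 100, 0.0, _ZEROS, "unimodal", _schwefel_1_2))
_register(_spec("F4", _D, -100, 100, 0.0, _ZEROS, "unimodal", _schwefel_2_21))
_register(_spec("F5", _D, -30, 30, 0.0, _ONES, "unimodal", _rosenbrock))
_register(_spec("F6", _D, -100, 100, 0.0, _ZEROS, "unimodal", _step))
_register(_spec("F7", _D, -1.28, 1.28, 0.0, _ZEROS, "unimodal", _quartic, noisy=True))
_register(
    _spec(
        "F8",
        _D,
        -500,
        500,
        _SCHWEFEL_FSTAR,
        tuple([_SCHWEFEL_XSTAR] * _D),
        "multimodal",
        _schwefel_2_26,
    )
)
_register(_spec("F9", _D, -5.12, 5.12, 0.0, _ZEROS, "multimodal", _rastrigin))
_register(_spec("F10", _D, -32, 32, 0.0, _ZEROS, "multimodal", _ackley))
_register(_spec("F11", _D, -600, 600, 0.0, _ZEROS, "multimodal", _griewank))
_register(_spec("F12", _D, -50, 50, 0.0, tuple([-1.0] * _D), "multimodal", _penalized_1))
_register(_spec("F13", _D, -50, 50, 0.0, _ONES, "multimodal", _penalized_2))

# fixed-dimension entries are registered at the bottom once their frozen
# optima constants are defined
_FIXED_DEFS = [
    ("F14", 2, -65.536, 65.536, _foxholes),
    ("F15", 4, -5.0, 5.0, _kowalik),
    ("F16", 2, -5.0, 5.0, _camel6),
    ("F17", 2, (-5.0, 0.0), (10.0, 15.0), _branin),
    ("F18", 2, -2.0, 2.0, _goldstein_price),
    ("F19", 3, 0.0, 1.0, _hartmann3),
    ("F20", 6, 0.0, 1.0, _hartmann6),
    ("F21", 4, 0.0, 10.0, _shekel(5)),
    ("F22", 4, 0.0, 10.0, _shekel(7)),
    ("F23", 4, 0.0, 10.0, _shekel(10)),
]

# numerically refined optima: name -> (location, objective value there)
_FIXED_OPTIMA: dict[str, tuple[tuple[float, ...], float]] = {
    "F14": ((-31.978334124672507, -31.978338581891506), 0.9980038377944498),
    "F15": (
        (0.19283345304274813, 0.19083624027597035, 0.12311729907598003, 0.13576599033984466),
        0.0003074859878056051,
    ),
    "F16": ((0.08984201652927098, -0.7126564013807202), -1.0316284534898776),
    "F17": ((3.141592653589793, 2.275), 0.39788735772973816),
    "F18": ((0.0, -1.0), 3.0),
    "F19": (
        (0.11458890903515172, 0.5556488944245587, 0.8525469826803833),
        -3.8627797873326615,
    ),
    "F20": (
        (
            0.20168951209480995,
            0.15001069277685197,
            0.476873971833793,
            0.275332431065528,
            0.3116516179851896,
            0.657300535855056,
        ),
        -3.322368011415515,
    ),
    "F21": (
        (4.000037152376549, 4.000133278657566, 4.000037151057555, 4.000133277090425),
        -10.153199679058229,
    ),
    "F22": (
        (4.00057291614487, 4.000689363677326, 3.999489713727069, 3.9996061594046823),
        -10.40294056681866,
    ),
    "F23": (
        (4.000746533108337, 4.000592934987342, 3.999663397235171, 3.999509802342474),
        -10.536409816692045,
    ),
}

for _name, _d, _lo, _hi, _fn in _FIXED_DEFS:
    _opt, _fstar = _FIXED_OPTIMA[_name]
    _register(_spec(_name, _d, _lo, _hi, _fstar, _opt, "fixed_dim", _fn))


# ---------------------------------------------------------------------------
# public API


def get_spec(name: str) -> BenchmarkSpec:
    try:
        return SUITE[name]
    except KeyError:
        raise KeyError(f"unknown benchmark {name!r}; known: F1..F23") from None


def evaluate(name: str, x, rng: np.random.Generator | None = None) -> float:
    """Evaluate benchmark ``name`` at ``x``.

    For the noisy quartic an ``rng`` adds the conventional uniform [0, 1)
    noise term; without one the deterministic part is returned.
    """
    spec = get_spec(name)
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.dimension,):
        raise ValueError(
            f"{name} expects dimension {spec.dimension}, got shape {x.shape}"
        )
    val = spec.func(x)
    if spec.noisy and rng is not None:
        val += float(rng.random())
    return val


def list_suite(kind: str = "all") -> list[BenchmarkSpec]:
    """Specs of one modality class (``unimodal``/``multimodal``/``fixed_dim``)
    or the whole suite."""
    if kind == "all":
        return list(SUITE.values())
    if kind not in {"unimodal", "multimodal", "fixed_dim"}:
        raise ValueError(f"unknown suite kind {kind!r}")
    return [s for s in SUITE.values() if s.kind == kind]


def make_problem(name: str, rng: np.random.Generator | None = None) -> Problem:
    """Wrap a registry entry as an optimizable :class:`Problem`.

    The noisy quartic binds ``rng`` (seeded by the caller) into its objective
    so that optimizer runs remain reproducible.
    """
    spec = get_spec(name)
    if spec.noisy and rng is not None:
        def objective(x, _f=spec.func, _r=rng):
            return _f(np.asarray(x, dtype=float)) + float(_r.random())
    else:
        objective = lambda x, _f=spec.func: _f(np.asarray(x, dtype=float))  # noqa: E731
    return Problem(
        dimension=spec.dimension,
        lower=np.array(spec.lower),
        upper=np.array(spec.upper),
        objective=objective,
        name=name,
    )


def suite_table():
    """Machine-readable suite listing (name, dimension, bounds, f*)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": s.name,
                "dimension": s.dimension,
                "lower": s.lower[0],
                "upper": s.upper[0],
                "f_star": s.f_star,
                "kind": s.kind,
            }
            for s in SUITE.values()
        ]
    )
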