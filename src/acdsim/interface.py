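"""Deterministic fitness analysis at the hypertumour-cancer interface.

Four cells straddle the interface between a large cancer cluster and a
large hypertumour cluster: Cell 1 (cancer interior), Cell 2 (cancer at the
border), Cell 3 (hypertumour at the border) and Cell 4 (hypertumour
interior).  The CGF is released by the cancer side, so its concentrations
satisfy ``g1 > g2 > g3 > g4 >= 0``.  With F the monotone CGF-to-fitness
transformation and c the production cost,

    w1 = F(g1) - c,   w2 = F(g2) - c,   w3 = F(g3),   w4 = F(g4),

and hypertumours stably invade the cancer cluster iff ``w1 < w3`` and
``w2 < w4``.  A CGF-targeting drug rescales every concentration to ``r*g``
(0 < r < 1); its per-cell fitness change is ``dw_i = F(r*g_i) - F(g_i)``
(the cost cancels).  The relative drug effect

    phi = dw1 - dw3   (or dw2 - dw4)

is negative when the drug promotes hypertumour progression.  For linear F
phi is always negative; nonlinear (e.g. logistic) F admits both signs
depending on where the two clusters sit on the curve.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "FitnessFamily",
    "FitnessFunction",
    "LinearF",
    "LogisticF",
    "PowerF",
    "CustomF",
    "InterfaceScenario",
    "solve_logistic_constants",
    "eval_F",
    "interface_fitness",
    "hypertumour_progresses",
    "drug_deltas",
    "phi",
    "phi_grid",
    "verify_linear_theorem",
    "LinearTheoremReport",
]


class FitnessFamily(enum.Enum):
    LINEAR = "LINEAR"
    LOGISTIC = "LOGISTIC"
    CONVEX = "CONVEX"
    CONCAVE = "CONCAVE"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class FitnessFunction:
    """A monotone CGF-to-fitness transformation F on [0, inf)."""

    family: FitnessFamily

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("concentration must be non-negative")
        out = self._eval(t)
        return float(out) if out.ndim == 0 else out

    def _eval(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def solve_logistic_constants(k1: float) -> tuple[float, float]:
    """Solve the boundary conditions of the three-constant logistic

        F(t) = k0 / (1 + exp(-k1 (t - 1))) + k2

    for (k0, k2) given the steepness k1 (inflection fixed at t = 1): the
    2 x 2 linear system imposes F(0) = 0 and lim_{t->inf} F(t) = k0+k2 = 1.
    For k1 = 5 this yields k0 = 1.0067 and k2 = -0.0067 (4 dp).
    """
    if not k1 > 0:
        raise ValueError(f"steepness k1 must be positive, got {k1}")
    s0 = 1.0 / (1.0 + np.exp(k1))  # logistic factor at t = 0
    a = np.array([[s0, 1.0], [1.0, 1.0]])
    k0, k2 = np.linalg.solve(a, np.array([0.0, 1.0]))
    return float(k0), float(k2)


@dataclass(frozen=True)
class LinearF(FitnessFunction):
    """F(t) = A t + B with A > 0."""

    A: float = 1.0
    B: float = 0.0

    def __init__(self, A: float = 1.0, B: float = 0.0):
        if not A > 0:
            raise ValueError(f"linear slope A must be positive, got {A}")
        object.__setattr__(self, "family", FitnessFamily.LINEAR)
        object.__setattr__(self, "A", float(A))
        object.__setattr__(self, "B", float(B))

    def _eval(self, t):
        return self.A * t + self.B


@dataclass(frozen=True)
class LogisticF(FitnessFunction):
    """F(t) = k0 / (1 + exp(-k1 (t - 1))) + k2."""

    k0: float = 1.0067
    k1: float = 5.0
    k2: float = -0.0067

    def __init__(self, k0: float = 1.0067, k1: float = 5.0, k2: float = -0.0067):
        object.__setattr__(self, "family", FitnessFamily.LOGISTIC)
        object.__setattr__(self, "k0", float(k0))
        object.__setattr__(self, "k1", float(k1))
        object.__setattr__(self, "k2", float(k2))

    @classmethod
    def from_steepness(cls, k1: float = 5.0) -> "LogisticF":
        """Logistic with (k0, k2) solved exactly from the boundary
        conditions F(0)=0 and F(inf)=1."""
        k0, k2 = solve_logistic_constants(k1)
        return cls(k0=k0, k1=k1, k2=k2)

    def _eval(self, t):
        return self.k0 / (1.0 + np.exp(-self.k1 * (t - 1.0))) + self.k2

    @property
    def limit(self) -> float:
        """The t -> infinity limit, k0 + k2."""
        return self.k0 + self.k2


@dataclass(frozen=True)
class PowerF(FitnessFunction):
    """Normalised power family F(t) = min(t / t_max, 1)**p, scaled to [0, 1].

    ``p > 1`` gives a convex, ``0 < p < 1`` a concave transformation on
    [0, t_max]; beyond t_max the benefit saturates at 1.
    """

    p: float = 2.0
    t_max: float = 5.0

    def __init__(self, p: float = 2.0, t_max: float = 5.0):
        if not p > 0:
            raise ValueError(f"power exponent must be positive, got {p}")
        if not t_max > 0:
            raise ValueError(f"t_max must be positive, got {t_max}")
        family = FitnessFamily.CONVEX if p > 1 else FitnessFamily.CONCAVE
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "p", float(p))
        object.__setattr__(self, "t_max", float(t_max))

    def _eval(self, t):
        return np.minimum(t / self.t_max, 1.0) ** self.p


@dataclass(frozen=True)
class CustomF(FitnessFunction):
    """Wrap any monotonically increasing callable as a fitness function."""

    fn: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __init__(self, fn: Callable):
        object.__setattr__(self, "family", FitnessFamily.CUSTOM)
        object.__setattr__(self, "fn", fn)

    def _eval(self, t):
        return np.asarray(self.fn(t), dtype=float)


def eval_F(f: FitnessFunction, t):
    """Evaluate a fitness transformation at concentration(s) t >= 0."""
    return f(t)


@dataclass(frozen=True)
class InterfaceScenario:
    """Inputs of the four-cell interface model."""

    g1: float
    g2: float
    g3: float
    g4: float
    c: float = 0.0
    r: float = 0.5

    def __post_init__(self) -> None:
        if not self.g1 > self.g2 > self.g3 > self.g4 >= 0:
            raise ValueError(
                f"concentrations must satisfy g1 > g2 > g3 > g4 >= 0, got "
                f"({self.g1}, {self.g2}, {self.g3}, {self.g4})"
            )
        if self.c < 0:
            raise ValueError(f"production cost must be >= 0, got {self.c}")
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"drug factor r must be in (0, 1), got {self.r}")

    @property
    def g(self) -> tuple[float, float, float, float]:
        return (self.g1, self.g2, self.g3, self.g4)


def interface_fitness(
    s: InterfaceScenario, f: FitnessFunction
) -> tuple[float, float, float, float]:
    """(w1, w2, w3, w4): cancer cells pay the production cost c,
    hypertumour cells do not."""
    w = [float(f(g)) for g in s.g]
    return (w[0] - s.c, w[1] - s.c, w[2], w[3])


def hypertumour_progresses(w: tuple[float, float, float, float]) -> bool:
    """True iff the border replacements favour the hypertumour side:
    w1 < w3 and w2 < w4."""
    return w[0] < w[2] and w[1] < w[3]


def drug_deltas(
    s: InterfaceScenario, f: FitnessFunction
) -> tuple[float, float, float, float]:
    """Per-cell fitness change of the drug: dw_i = F(r g_i) - F(g_i)."""
    return tuple(float(f(s.r * g) - f(g)) for g in s.g)


def phi(s: InterfaceScenario, f: FitnessFunction, pair: str = "1-3") -> float:
    """Relative drug effect on the cancer cell of a border pair.

    ``pair='1-3'`` returns dw1 - dw3, ``pair='2-4'`` returns dw2 - dw4.
    Negative phi: the drug promotes hypertumour progression.
    """
    d = drug_deltas(s, f)
    if pair == "1-3":
        return d[0] - d[2]
    if pair == "2-4":
        return d[1] - d[3]
    raise ValueError(f"pair must be '1-3' or '2-4', got {pair!r}")


def phi_grid(
    f: FitnessFunction,
    g_values: np.ndarray | None = None,
    ratio_values: np.ndarray | None = None,
    r: float = 0.5,
) -> np.ndarray:
    """phi over a (cancer concentration) x (hypertumour/cancer ratio) grid.

    Entry ``[i, j]`` is ``F(r g_i) - F(g_i) - F(r q_j g_i) + F(q_j g_i)``
    where ``g_i`` is the CGF concentration at the cancer cell and ``q_j`` in
    (0, 1) the hypertumour-to-cancer concentration ratio.  Drug presets
    r = 0.8, 0.5, 0.2 correspond to 20%, 50% and 80% CGF reduction.
    """
    if g_values is None:
        g_values = np.linspace(0.05, 5.0, 101)
    if ratio_values is None:
        ratio_values = np.linspace(0.01, 0.99, 99)
    g_values = np.asarray(g_values, dtype=float)
    ratio_values = np.asarray(ratio_values, dtype=float)
    if np.any((ratio_values <= 0) | (ratio_values >= 1)):
        raise ValueError("ratios must lie strictly in (0, 1)")
    if not 0.0 < r < 1.0:
        raise ValueError(f"drug factor r must be in (0, 1), got {r}")
    g = g_values[:, None]
    gh = g * ratio_values[None, :]
    return (f(r * g) - f(g)) - (f(r * gh) - f(gh))


@dataclass(frozen=True)
class LinearTheoremReport:
    """Outcome of the randomized linear-F check; truthy iff no
    counterexample was found."""

    holds: bool
    trials: int
    counterexample: dict | None = None

    def __bool__(self) -> bool:
        return self.holds


def verify_linear_theorem(
    trials: int = 10_000, rand: np.random.Generator | None = None
) -> LinearTheoremReport:
    """Randomized check that for linear F the drug always favours the
    hypertumour: dw1 < dw3 and dw2 < dw4 for every valid scenario.

    Samples A > 0, any intercept B, ordered positive concentrations and
    r in (0, 1); returns a report carrying the first counterexample, if any.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    rand = rand or np.random.default_rng(0)
    for i in range(trials):
        A = float(rand.uniform(1e-3, 10.0))
        B = float(rand.uniform(-5.0, 5.0))
        g = np.sort(rand.uniform(1e-6, 10.0, size=4))[::-1]
        while len(set(g)) < 4:  # pragma: no cover - ties are measure zero
            g = np.sort(rand.uniform(1e-6, 10.0, size=4))[::-1]
        r = float(rand.uniform(1e-6, 1.0 - 1e-6))
        s = InterfaceScenario(*g, c=float(rand.uniform(0, 2)), r=r)
        d = drug_deltas(s, LinearF(A, B))
        if not (d[0] < d[2] and d[1] < d[3]):
            return LinearTheoremReport(
                holds=False,
                trials=i + 1,
                counterexample={"A": A, "B": B, "g": tuple(g), "r": r},
            )
    return LinearTheoremReport(holds=True, trials=trials)
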