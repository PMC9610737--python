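"""Split-step integrators for the stochastic delayed SVIR system.

Two schemes are provided.  The split-step theta-Milstein (SSTM) scheme is a
direct explicit discretisation with Milstein corrections for the diagonal
multiplicative noise.  The stochastic split-step theta-nonstandard finite
difference (SSSTNSFD) scheme follows Mickens' nonstandard framework: the
step size enters through the denominator function ``v(h) = 1 - exp(-h)``
and each update is a ratio of a nonnegative numerator and a denominator
>= 1, which preserves positivity of the iterates for every step size in
the noise-free case.  Both schemes treat the delayed states with the
split-step theta interpolation ``theta*x[n-m+1] + (1-theta)*x[n-m]`` and
update S, V, I sequentially within a step (Gauss-Seidel style): the fresh
S feeds the V update and both feed the I update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import SVIRParameters

__all__ = [
    "SimulationGrid", "HistorySpec", "NoisePlan", "Trajectory",
    "EnsembleSummary", "SimulationDiverged",
    "denominator_v", "delayed_value",
    "sstm_simulate", "ssstnsfd_simulate", "deterministic_simulate",
    "ensemble_run", "derive_path_seed",
]


class SimulationDiverged(RuntimeError):
    """Raised when a scheme produces a non-finite state.

    Carries the failing ``step`` and the positivity violations recorded up
    to that point, so callers comparing schemes can still report how the
    run failed.
    """

    def __init__(self, method: str, step: int,
                 violations: list[tuple[int, str]]):
        super().__init__(
            f"{method} scheme produced a non-finite state at step {step}")
        self.method = method
        self.step = step
        self.violations = violations


def denominator_v(h: float) -> float:
    """Nonstandard denominator function v(h) = 1 - exp(-h).

    Satisfies v(h) = h + O(h^2) and 0 < v(h) < 1 for every h > 0, which is
    what lets the nonstandard scheme remain stable and positive at step
    sizes where a plain explicit scheme fails.
    """
    if h <= 0.0:
        raise ValueError(f"step size h must be positive, got {h}")
    return -math.expm1(-h)


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid on [0, T] commensurate with both delays.

    ``m1 = tau1/h`` and ``m2 = tau2/h`` must be integers (relative
    tolerance 1e-9): the split-step delay interpolation is defined only on
    grids where the delays are whole numbers of steps.  Non-commensurate
    inputs are an error, never silently rounded.
    """

    T: float
    h: float
    n_steps: int
    m1: int
    m2: int

    @classmethod
    def create(cls, T: float, h: float, tau1: float, tau2: float) -> "SimulationGrid":
        if T <= 0.0 or h <= 0.0:
            raise ValueError(f"T and h must be positive, got T={T}, h={h}")
        n_steps = cls._as_integer(T / h, "T/h")
        m1 = cls._as_integer(tau1 / h, "tau1/h")
        m2 = cls._as_integer(tau2 / h, "tau2/h")
        if m1 < 1 or m2 < 1:
            raise ValueError(
                f"delays must span at least one step: tau1/h={m1}, tau2/h={m2}")
        return cls(T=T, h=h, n_steps=n_steps, m1=m1, m2=m2)

    @classmethod
    def for_params(cls, p: SVIRParameters, T: float, h: float) -> "SimulationGrid":
        return cls.create(T, h, p.tau1, p.tau2)

    @staticmethod
    def _as_integer(ratio: float, label: str) -> int:
        nearest = round(ratio)
        if nearest == 0 or abs(ratio - nearest) > 1e-9 * max(1.0, abs(ratio)):
            raise ValueError(
                f"{label} = {ratio!r} is not an integer; the schemes are "
                "defined only on grids commensurate with the delays")
        return int(nearest)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.h

    @property
    def max_delay_steps(self) -> int:
        return max(self.m1, self.m2)


@dataclass(frozen=True)
class HistorySpec:
    """Initial history on [-max(tau1, tau2), 0].

    ``constant`` mode extends the point initial values (S0, V0, I0)
    backwards in time — the minimal choice when only initial values are
    given.  ``function`` mode accepts a callable t -> (S, V, I) evaluated
    at the (nonpositive) history grid times.  All history values must be
    strictly positive.
    """

    mode: str
    values: tuple[float, float, float] | None = None
    func: Callable[[float], Sequence[float]] | None = None

    @classmethod
    def constant(cls, S0: float, V0: float, I0: float,
                 allow_zero: bool = False) -> "HistorySpec":
        """Constant history.  ``allow_zero`` admits exact zeros for
        boundary studies such as the disease-free axis (I identically 0);
        the well-posedness theory itself assumes strictly positive
        history."""
        low = min(S0, V0, I0)
        if low < 0.0 or (low <= 0.0 and not allow_zero):
            raise ValueError(
                f"history values must be strictly positive, got ({S0}, {V0}, {I0})")
        return cls(mode="constant", values=(S0, V0, I0))

    @classmethod
    def function(cls, func: Callable[[float], Sequence[float]]) -> "HistorySpec":
        return cls(mode="function", func=func)

    def at(self, t: float) -> tuple[float, float, float]:
        if self.mode == "constant":
            assert self.values is not None
            return self.values
        assert self.func is not None
        s, v, i = self.func(t)
        if min(s, v, i) <= 0.0:
            raise ValueError(
                f"history function returned a non-positive value at t={t}: "
                f"({s}, {v}, {i})")
        return float(s), float(v), float(i)


@dataclass(frozen=True)
class NoisePlan:
    """Pre-drawn Brownian increments for one simulated path.

    ``dW`` has shape (n_steps, 3); row n holds (dW1, dW2, dW3) for step n,
    drawn in that fixed order so that both schemes can be driven by
    identical noise for coupled comparisons.  Each increment is
    ``sqrt(h) * xi`` with xi standard normal: a Brownian increment over a
    step of length h has variance h.
    """

    seed: int | None
    dW: np.ndarray

    @classmethod
    def gaussian(cls, seed: int, grid: SimulationGrid) -> "NoisePlan":
        rng = np.random.default_rng(seed)
        dW = math.sqrt(grid.h) * rng.standard_normal((grid.n_steps, 3))
        return cls(seed=seed, dW=dW)

    @classmethod
    def zero(cls, grid: SimulationGrid) -> "NoisePlan":
        return cls(seed=None, dW=np.zeros((grid.n_steps, 3)))


@dataclass
class Trajectory:
    """A single simulated path of (S, V, I) on the grid [0, T].

    ``positivity_violations`` lists every (step, component) at which the
    scheme produced a negative value; states are recorded as computed,
    never clipped, so scheme failures remain observable.
    """

    times: np.ndarray
    S: np.ndarray
    V: np.ndarray
    I: np.ndarray
    method: str
    seed: int | None
    positivity_violations: list[tuple[int, str]] = field(default_factory=list)
    parameters: SVIRParameters | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.S) == len(self.V) == len(self.I) == n):
            raise ValueError("trajectory arrays must share one length")

    @property
    def T(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "S": self.S, "V": self.V, "I": self.I,
            "method": self.method,
            "seed": -1 if self.seed is None else self.seed,
        })

    def to_csv(self, path) -> None:
        # %.17g round-trips doubles exactly, keeping reruns byte-identical.
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def delayed_value(series: np.ndarray, n: int, m: int, theta: float,
                  offset: int = 0) -> float:
    """Split-step theta interpolation of a delayed state.

    Returns ``theta*x[n-m+1] + (1-theta)*x[n-m]`` on a series whose first
    ``offset`` entries hold the pre-zero history (index ``offset + k``
    holds the state at time ``k*h``).  Indices reaching before the stored
    history are an error.
    """
    lo = offset + n - m
    if lo < 0:
        raise IndexError(
            f"delayed index n-m = {n - m} reaches before the stored history")
    return theta * float(series[lo + 1]) + (1.0 - theta) * float(series[lo])


def _alloc(p: SVIRParameters, grid: SimulationGrid, history: HistorySpec):
    """Allocate padded state arrays with the history segment filled in."""
    pad = grid.max_delay_steps
    size = pad + grid.n_steps + 1
    S = np.empty(size)
    V = np.empty(size)
    I = np.empty(size)
    for k in range(pad + 1):
        t = (k - pad) * grid.h
        S[k], V[k], I[k] = history.at(t)
    return S, V, I, pad


def _check_state(method: str, step: int, values: Iterable[float],
                 violations: list[tuple[int, str]]) -> None:
    for value, comp in zip(values, "SVI"):
        if not math.isfinite(value):
            raise SimulationDiverged(method, step, violations)
        if value < 0.0:
            violations.append((step, comp))


def sstm_simulate(p: SVIRParameters, grid: SimulationGrid,
                  history: HistorySpec, noise: NoisePlan) -> Trajectory:
    """Integrate one path with the split-step theta-Milstein scheme.

    Each step updates S, then V (using the fresh S in the vaccination
    inflow), then I (using the fresh S and V inside the incidence
    fractions, with the old I elsewhere).  Each equation carries its own
    Milstein correction ``(sigma^2/2)*X*(dW^2 - h)``; the noise is
    diagonal, so there are no cross terms.  Negative iterates are recorded
    in ``positivity_violations`` and propagated unmodified.
    """
    if noise.dW.shape != (grid.n_steps, 3):
        raise ValueError(
            f"noise plan shape {noise.dW.shape} does not match grid "
            f"({grid.n_steps} steps)")
    S, V, I, pad = _alloc(p, grid, history)
    h = grid.h
    th = p.theta
    kappa1 = p.gamma1 * math.exp(-p.mu * p.tau1)
    kappa2 = p.gamma2 * math.exp(-p.mu * p.tau2)
    dW = noise.dW
    violations: list[tuple[int, str]] = []

    for n in range(grid.n_steps):
        i = pad + n
        s, v, y = S[i], V[i], I[i]
        i_del = th * I[i - grid.m1 + 1] + (1.0 - th) * I[i - grid.m1]
        v_del = th * V[i - grid.m2 + 1] + (1.0 - th) * V[i - grid.m2]
        w1, w2, w3 = dW[n]

        f1 = p.beta1 * s * y / (1.0 + p.lambda1 * s + p.lambda2 * y
                                + p.lambda3 * s * y)
        s_new = (s + (p.mu - (p.mu + p.alpha) * s + kappa1 * i_del - f1) * h
                 + p.sigma1 * s * w1
                 + 0.5 * p.sigma1 ** 2 * s * (w1 * w1 - h))

        f2 = p.beta2 * v * y / (1.0 + p.eta1 * v + p.eta2 * y
                                + p.eta3 * v * y)
        v_new = (v + (p.alpha * s_new - (p.mu + p.gamma2) * v
                      + kappa2 * v_del - f2) * h
                 + p.sigma2 * v * w2
                 + 0.5 * p.sigma2 ** 2 * v * (w2 * w2 - h))

        f1_new = p.beta1 * s_new * y / (1.0 + p.lambda1 * s_new
                                        + p.lambda2 * y
                                        + p.lambda3 * s_new * y)
        f2_new = p.beta2 * v_new * y / (1.0 + p.eta1 * v_new
                                        + p.eta2 * y
                                        + p.eta3 * v_new * y)
        i_new = (y + (f1_new + f2_new - (p.mu + p.gamma1) * y) * h
                 + p.sigma3 * y * w3
                 + 0.5 * p.sigma3 ** 2 * y * (w3 * w3 - h))

        _check_state("sstm", n + 1, (s_new, v_new, i_new), violations)
        S[i + 1], V[i + 1], I[i + 1] = s_new, v_new, i_new

    return Trajectory(times=grid.times, S=S[pad:].copy(), V=V[pad:].copy(),
                      I=I[pad:].copy(), method="sstm", seed=noise.seed,
                      positivity_violations=violations, parameters=p)


def ssstnsfd_simulate(p: SVIRParameters, grid: SimulationGrid,
                      history: HistorySpec, noise: NoisePlan) -> Trajectory:
    """Integrate one path with the split-step theta-nonstandard scheme.

    The implicit loss terms are moved to the denominators and the step
    size enters through ``v(h) = 1 - exp(-h)``, giving the explicit
    Gauss-Seidel updates

        S[n+1] = (S[n] + (mu + return_flow)*v + sigma1*S[n]*dW1)
                 / (1 + (alpha + mu + incidence_rate_per_S)*v)

    and analogously for V and I.  With zero noise every numerator and
    denominator is positive, so positivity holds for arbitrary h.  With
    noise, a large negative increment can push a numerator negative
    (``sigma*dW < -1`` in the I update); such steps are recorded in
    ``positivity_violations`` rather than assumed away.
    """
    if noise.dW.shape != (grid.n_steps, 3):
        raise ValueError(
            f"noise plan shape {noise.dW.shape} does not match grid "
            f"({grid.n_steps} steps)")
    S, V, I, pad = _alloc(p, grid, history)
    v_h = denominator_v(grid.h)
    th = p.theta
    kappa1 = p.gamma1 * math.exp(-p.mu * p.tau1)
    kappa2 = p.gamma2 * math.exp(-p.mu * p.tau2)
    dW = noise.dW
    violations: list[tuple[int, str]] = []

    for n in range(grid.n_steps):
        i = pad + n
        s, v, y = S[i], V[i], I[i]
        i_del = th * I[i - grid.m1 + 1] + (1.0 - th) * I[i - grid.m1]
        v_del = th * V[i - grid.m2 + 1] + (1.0 - th) * V[i - grid.m2]
        w1, w2, w3 = dW[n]

        rate1 = p.beta1 * y / (1.0 + p.lambda1 * s + p.lambda2 * y
                               + p.lambda3 * s * y)
        s_new = ((s + (p.mu + kappa1 * i_del) * v_h + p.sigma1 * s * w1)
                 / (1.0 + (p.alpha + p.mu + rate1) * v_h))

        rate2 = p.beta2 * y / (1.0 + p.eta1 * v + p.eta2 * y
                               + p.eta3 * v * y)
        v_new = ((v + (p.alpha * s_new + kappa2 * v_del) * v_h
                  + p.sigma2 * v * w2)
                 / (1.0 + (p.gamma2 + p.mu + rate2) * v_h))

        gain = (p.beta1 * s_new / (1.0 + p.lambda1 * s_new + p.lambda2 * y
                                   + p.lambda3 * s_new * y)
                + p.beta2 * v_new / (1.0 + p.eta1 * v_new + p.eta2 * y
                                     + p.eta3 * v_new * y))
        i_new = (y * (1.0 + gain * v_h + p.sigma3 * w3)
                 / (1.0 + (p.gamma1 + p.mu) * v_h))

        _check_state("ssstnsfd", n + 1, (s_new, v_new, i_new), violations)
        S[i + 1], V[i + 1], I[i + 1] = s_new, v_new, i_new

    return Trajectory(times=grid.times, S=S[pad:].copy(), V=V[pad:].copy(),
                      I=I[pad:].copy(), method="ssstnsfd", seed=noise.seed,
                      positivity_violations=violations, parameters=p)


_SIMULATORS = {"sstm": sstm_simulate, "ssstnsfd": ssstnsfd_simulate}


def simulate(p: SVIRParameters, grid: SimulationGrid, history: HistorySpec,
             noise: NoisePlan, method: str) -> Trajectory:
    """Dispatch to the named scheme ('sstm' or 'ssstnsfd')."""
    try:
        fn = _SIMULATORS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_SIMULATORS)}"
        ) from None
    return fn(p, grid, history, noise)


def deterministic_simulate(p: SVIRParameters, grid: SimulationGrid,
                           history: HistorySpec, method: str) -> Trajectory:
    """Run the chosen scheme with all noise intensities and increments zero.

    This is the deterministic counterpart used in stochastic-vs-ODE
    overlays: the explicit theta scheme for 'sstm', the deterministic NSFD
    scheme for 'ssstnsfd'.
    """
    traj = simulate(p.noise_free(), grid, history, NoisePlan.zero(grid), method)
    traj.parameters = p
    return traj


def derive_path_seed(base_seed: int, k: int) -> int:
    """Deterministic per-path seed from (base_seed, path index)."""
    ss = np.random.SeedSequence([int(base_seed), int(k)])
    return int(ss.generate_state(1)[0]) % (2 ** 31)


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise ensemble mean and quantiles across paths."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    quantiles: dict[str, np.ndarray]   # component -> (3, n_times): 2.5/50/97.5%
    n_paths: int


def ensemble_run(p: SVIRParameters, grid: SimulationGrid, history: HistorySpec,
                 method: str, n_paths: int, base_seed: int
                 ) -> tuple[list[Trajectory], EnsembleSummary]:
    """Simulate ``n_paths`` independent paths and summarise them pointwise.

    Path k is driven by a seed derived deterministically from
    ``(base_seed, k)``, so ensembles are reproducible and individual paths
    can be re-run in isolation.
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    paths = []
    for k in range(n_paths):
        noise = NoisePlan.gaussian(derive_path_seed(base_seed, k), grid)
        paths.append(simulate(p, grid, history, noise, method))
    stacks = {c: np.stack([getattr(t, c) for t in paths]) for c in "SVI"}
    summary = EnsembleSummary(
        times=grid.times,
        mean={c: a.mean(axis=0) for c, a in stacks.items()},
        quantiles={c: np.quantile(a, [0.025, 0.5, 0.975], axis=0)
                   for c, a in stacks.items()},
        n_paths=n_paths,
    )
    return paths, summary
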