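"""Computable monitors for the extinction, persistence and boundedness theory.

The asymptotic statements of the threshold theory (almost-sure extinction
when R0s < 1, persistence in mean when R0s > 1, the discrete boundedness
envelope of the nonstandard scheme) are rendered here as finite-horizon
observations on simulated trajectories: time averages, the realised decay
rate of ln I against its closed-form bound, the time averages against the
persistence thresholds, and the recursive upper envelope M_n.  Reports
state the horizon they were computed on and never claim convergence.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    SVIRParameters, derived_constants, extinction_rate_bound,
    persistence_thresholds,
)
from .simulate import NoisePlan, SimulationGrid, Trajectory, denominator_v

__all__ = [
    "time_average", "extinction_report", "persistence_report",
    "boundedness_certificate", "boundedness_t_star", "diagnose",
    "ExtinctionReport", "PersistenceReport", "BoundednessCertificate",
    "DiagnosticsReport",
]


def time_average(traj: Trajectory, component: str) -> float:
    """Time average (1/T) * integral of a component over [0, T].

    Trapezoidal quadrature on the trajectory's own grid; exact for
    constant and linear paths.
    """
    if component not in ("S", "V", "I"):
        raise ValueError(f"component must be one of S, V, I, got {component!r}")
    if len(traj.times) < 2:
        raise ValueError("trajectory must cover a positive time span")
    y = getattr(traj, component)
    return float(np.trapezoid(y, traj.times) / traj.T)


@dataclass(frozen=True)
class ExtinctionReport:
    """Realised decay rate of the infection versus its almost-sure bound.

    ``logI_rate`` is ln I(T)/T on this path (−inf when I(T) has hit zero);
    ``extinction_bound`` is the closed-form rate (gamma1+mu+sigma3^2/2)
    (R0s−1), negative exactly when R0s < 1.  The verdict is a
    finite-horizon observation at the stated horizon, not a limit claim.
    """

    logI_rate: float
    extinction_bound: float
    R0s: float
    horizon: float
    extinction_predicted: bool
    verdict: str


def extinction_report(traj: Trajectory, p: SVIRParameters) -> ExtinctionReport:
    d = derived_constants(p)
    bound = extinction_rate_bound(p)
    i_final = float(traj.I[-1])
    rate = math.log(i_final) / traj.T if i_final > 0.0 else -math.inf
    predicted = d.R0s < 1.0
    if predicted:
        verdict = (f"R0s = {d.R0s:.4f} < 1: extinction predicted at rate "
                   f"<= {bound:.4f}; observed ln I(T)/T = {rate:.4f} "
                   f"at T = {traj.T:g}")
    else:
        verdict = (f"R0s = {d.R0s:.4f} >= 1: no extinction predicted; "
                   f"observed ln I(T)/T = {rate:.4f} at T = {traj.T:g}")
    return ExtinctionReport(logI_rate=rate, extinction_bound=bound,
                            R0s=d.R0s, horizon=traj.T,
                            extinction_predicted=predicted, verdict=verdict)


@dataclass(frozen=True)
class PersistenceReport:
    """Time averages of (S, V, I) against the persistence-in-mean thresholds.

    The three threshold statements (<I> >= I*, <S> <= S*, <V> -> V*) are
    asymptotic; the booleans here record whether each held on this finite
    horizon for the mean time averages, as observations only.
    """

    avg_S: float
    avg_V: float
    avg_I: float
    I_star: float
    S_star: float
    V_star: float
    mode: str
    condition_value: float
    R0s: float
    horizon: float
    n_paths: int
    applicable: bool
    observed_I_above_star: bool
    observed_S_below_star: bool
    warning: str | None = None


def persistence_report(trajectories: Trajectory | Sequence[Trajectory],
                       p: SVIRParameters,
                       mode: str = "paper_figures") -> PersistenceReport:
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    avgs = {c: float(np.mean([time_average(t, c) for t in trajectories]))
            for c in "SVI"}
    d = derived_constants(p)
    thr = persistence_thresholds(p, mode)
    warning = None
    if d.R0s <= 1.0:
        warning = (f"R0s = {d.R0s:.4f} <= 1: the persistence thresholds do "
                   "not apply in this regime")
    return PersistenceReport(
        avg_S=avgs["S"], avg_V=avgs["V"], avg_I=avgs["I"],
        I_star=thr.I_star, S_star=thr.S_star, V_star=thr.V_star,
        mode=mode, condition_value=d.condition_value, R0s=d.R0s,
        horizon=trajectories[0].T, n_paths=len(trajectories),
        applicable=thr.applicable,
        observed_I_above_star=avgs["I"] >= thr.I_star,
        observed_S_below_star=avgs["S"] <= thr.S_star,
        warning=warning,
    )


def boundedness_t_star(p: SVIRParameters) -> float:
    """Initial envelope T* = mu/(gamma2*(1-exp(-mu*tau2))+mu) + alpha*mu/c2."""
    d = derived_constants(p)
    return (p.mu / (p.gamma2 * (1.0 - math.exp(-p.mu * p.tau2)) + p.mu)
            + p.alpha * p.mu / d.c2)


@dataclass(frozen=True)
class BoundednessCertificate:
    """Recursive upper envelope M_n for the nonstandard scheme's total mass.

    ``M[n]`` bounds S+V+I at step n+1 under the scheme's boundedness
    recursion M_n = mu*v(h) + (1 + sigma*dW_n)*M_{n-1} with M_{-1} = T*,
    where sigma = max(sigma1..3) and dW_n is the componentwise-max
    increment of step n.  The recursion expands only while
    1 + sigma*dW_n > 0; steps where that factor is nonpositive void the
    certificate and are listed in ``void_steps``.  ``violations`` lists
    steps whose realised total mass exceeded the envelope.
    """

    M: np.ndarray                    # M_0 .. M_{n_steps-1}
    sums: np.ndarray                 # S+V+I at steps 0 .. n_steps
    T_star: float
    M_start: float
    violations: list[int] = field(default_factory=list)
    void_steps: list[int] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations and not self.void_steps


def boundedness_certificate(traj: Trajectory, p: SVIRParameters,
                            grid: SimulationGrid,
                            noise: NoisePlan | None = None,
                            T_star_override: float | None = None,
                            strict: bool = False) -> BoundednessCertificate:
    """Evaluate the boundedness envelope along a nonstandard-scheme path.

    ``noise`` must be the plan that drove the trajectory (zero increments
    are assumed when omitted, which is only correct for deterministic
    runs).  The theorem assumes S0+V0+I0 <= T*; since common initial
    values exceed the default T*, the envelope starts from
    ``max(T*, S0+V0+I0)`` unless ``strict`` is set, in which case the
    hypothesis is enforced and its violation is an error.
    """
    if len(traj.times) != grid.n_steps + 1:
        raise ValueError("trajectory length does not match the grid")
    t_star = boundedness_t_star(p) if T_star_override is None else T_star_override
    sums = traj.S + traj.V + traj.I
    start = float(sums[0])
    if strict:
        if start > t_star:
            raise ValueError(
                f"initial total mass {start:.4f} exceeds T* = {t_star:.4f}; "
                "the boundedness hypothesis fails")
        m_prev = t_star
    else:
        m_prev = max(t_star, start)
    m_start = m_prev

    dW = np.zeros((grid.n_steps, 3)) if noise is None else noise.dW
    sigma = max(p.sigma1, p.sigma2, p.sigma3)
    mu_v = p.mu * denominator_v(grid.h)

    M = np.empty(grid.n_steps)
    violations: list[int] = []
    void_steps: list[int] = []
    for n in range(grid.n_steps):
        factor = 1.0 + sigma * float(np.max(dW[n]))
        if factor <= 0.0:
            void_steps.append(n)
        m_prev = mu_v + factor * m_prev
        M[n] = m_prev
        if sums[n + 1] > M[n]:
            violations.append(n + 1)
    return BoundednessCertificate(M=M, sums=sums, T_star=t_star,
                                  M_start=m_start, violations=violations,
                                  void_steps=void_steps)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Aggregate diagnostics for one run, serialisable to JSON."""

    method: str
    seed: int | None
    horizon: float
    avg_S: float
    avg_V: float
    avg_I: float
    extinction: ExtinctionReport
    persistence: PersistenceReport
    positivity_violation_count: int
    positivity_violations: list[tuple[int, str]]
    boundedness_valid: bool | None = None
    boundedness_violations: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positivity_violations"] = [
            [step, comp] for step, comp in self.positivity_violations]
        return d

    def to_json(self, **kwargs) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"cannot serialise {type(o)}")
        return json.dumps(self.to_dict(), default=default, **kwargs)


def diagnose(traj: Trajectory, p: SVIRParameters,
             grid: SimulationGrid | None = None,
             noise: NoisePlan | None = None,
             mode: str = "paper_figures") -> DiagnosticsReport:
    """Compute the full diagnostics bundle for a single trajectory."""
    ext = extinction_report(traj, p)
    per = persistence_report(traj, p, mode)
    bounded_valid = None
    bounded_violations = None
    if grid is not None and traj.method == "ssstnsfd":
        cert = boundedness_certificate(traj, p, grid, noise)
        bounded_valid = cert.valid
        bounded_violations = len(cert.violations)
    return DiagnosticsReport(
        method=traj.method, seed=traj.seed, horizon=traj.T,
        avg_S=time_average(traj, "S"), avg_V=time_average(traj, "V"),
        avg_I=time_average(traj, "I"),
        extinction=ext, persistence=per,
        positivity_violation_count=len(traj.positivity_violations),
        positivity_violations=list(traj.positivity_violations),
        boundedness_valid=bounded_valid,
        boundedness_violations=bounded_violations,
    )
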