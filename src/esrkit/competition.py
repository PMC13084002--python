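"""Piecewise Lotka-Volterra competition between a stress-prepared wild-type
and a faster-growing stress-sensitive null mutant under periodic severe stress.

The model alternates two phases within each stress cycle of period ``omega``:

* a severe-stress window of duration ``(1 - phi) * omega`` at the start of the
  cycle, during which the wild-type is frozen (``dN_WT/dt = 0``) and the
  mutant dies at rate ``D`` (``dN_Null/dt = -D N_Null``);
* a growth window of duration ``phi * omega`` with logistic competition for a
  shared carrying capacity ``K``:
  ``dN_i/dt = r_i N_i (1 - (N_WT + N_Null) / K)``.

The analytic phase classification works on three dimensionless parameters:
relative wild-type fitness ``alpha = r_WT / r_Null``, time between stresses in
uninhibited mutant doubling times ``beta = omega * phi * r_Null / ln 2``, and
the mutant death fraction per stress event ``m = 1 - exp(-D (1 - phi) omega)``.

Three regimes emerge for ``alpha < 1``:

* State I  (mutant nonviable):   ``m > 1 - e^{-beta ln 2}`` — growth between
  stresses cannot recover the per-event kill.
* State II (wild-type always wins): ``m > 1 - e^{(alpha - 1) beta ln 2}``.
* State III (ratio-dependent): wild-type dominance requires a starting ratio
  ``N_WT / N_Null`` above ``(1 - 1/alpha) beta ln 2 / ln(1 - m) - 1/alpha``.

Note on the simulation oracle: the State III threshold describes the dilute
(exponential-phase) competition. In the saturating ODE the wild-type never
dies, so every stress event frees capacity that it ratchets into; run long
enough, the simulated winner below the State I curve is always the wild-type
regardless of the starting ratio. See docs/methods.md for the full analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

LN2 = math.log(2.0)

#: labels returned by :func:`classify_state`
MUTANT_NONVIABLE = "MUTANT_NONVIABLE"
WT_ALWAYS_WINS = "WT_ALWAYS_WINS"
RATIO_DEPENDENT = "RATIO_DEPENDENT"

#: labels returned by :func:`winner`
WT = "WT"
MUTANT = "MUTANT"
COEXIST_FROZEN = "COEXIST_FROZEN"
MUTANT_EXTINCT = "MUTANT_EXTINCT"


class CompetitionError(ValueError):
    """Invalid parameterization of the competition model."""


@dataclass(frozen=True)
class CompetitionParams:
    """Dimensional parameters of the piecewise competition model.

    Parameters
    ----------
    r_wt, r_null
        Per-unit-time exponential growth rates of the two strains.
    carrying_capacity
        Shared fixed carrying capacity ``K`` (cells).
    stress_period
        Cycle period ``omega`` between stress onsets (time units).
    growth_fraction
        Fraction ``phi`` in (0, 1] of each cycle spent growing; the stress
        window lasts ``(1 - phi) * omega`` at the start of the cycle.
    death_rate
        Mutant death rate ``D`` during the stress window (per unit time).
    """

    r_wt: float
    r_null: float = 1.0
    carrying_capacity: float = 1.0
    stress_period: float = 1.0
    growth_fraction: float = 0.5
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.r_wt < 0 or self.r_null < 0 or self.death_rate < 0:
            raise CompetitionError("rates must be nonnegative")
        if not 0 < self.growth_fraction <= 1:
            raise CompetitionError("growth_fraction must be in (0, 1]")
        if self.carrying_capacity <= 0:
            raise CompetitionError("carrying_capacity must be positive")
        if self.stress_period <= 0:
            raise CompetitionError("stress_period must be positive")

    @property
    def stress_duration(self) -> float:
        return (1.0 - self.growth_fraction) * self.stress_period

    @property
    def growth_duration(self) -> float:
        return self.growth_fraction * self.stress_period


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless reparametrization (alpha, beta, m).

    ``alpha`` is the relative wild-type fitness ``r_WT / r_Null``; ``beta`` the
    time between stresses in uninhibited mutant doubling times; and
    ``death_fraction`` the fraction ``m`` of mutant cells killed per stress
    event.
    """

    alpha: float
    beta: float
    death_fraction: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise CompetitionError("alpha must be positive")
        if self.beta <= 0:
            raise CompetitionError("beta must be positive")
        if not 0 <= self.death_fraction < 1:
            raise CompetitionError("death_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PopulationState:
    t: float
    n_wt: float
    n_null: float

    def __post_init__(self) -> None:
        if self.n_wt < 0 or self.n_null < 0:
            raise CompetitionError("population counts must be nonnegative")


@dataclass
class Trajectory:
    """Sampled solution of :func:`simulate_competition`.

    ``states`` holds solver output samples; ``cycle_log_ratio_changes`` the
    per-cycle change in ``ln(n_wt / n_null)`` (``+inf`` once the mutant count
    underflows to zero).
    """

    states: list[PopulationState] = field(default_factory=list)
    cycle_log_ratio_changes: list[float] = field(default_factory=list)
    carrying_capacity: float = 1.0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def n_wt(self) -> np.ndarray:
        return np.array([s.n_wt for s in self.states])

    @property
    def n_null(self) -> np.ndarray:
        return np.array([s.n_null for s in self.states])


@dataclass(frozen=True)
class PhaseState:
    """Analytic phase classification; ``threshold_ratio`` (critical starting
    ``N_WT / N_Null`` for wild-type dominance) is set only for State III."""

    label: str
    threshold_ratio: float | None = None

    def __post_init__(self) -> None:
        if (self.label == RATIO_DEPENDENT) != (self.threshold_ratio is not None):
            raise CompetitionError(
                "threshold_ratio must be present iff label is RATIO_DEPENDENT"
            )


def reduce_params(p: CompetitionParams) -> ReducedParams:
    """Map dimensional parameters to the (alpha, beta, m) triple.

    ``beta`` normalizes the growth-window duration by the uninhibited mutant
    doubling time ``ln 2 / r_null``; ``m`` is the integrated kill over one
    stress window.
    """
    if p.r_null == 0:
        raise CompetitionError("relative fitness undefined for r_null = 0")
    alpha = p.r_wt / p.r_null
    beta = p.growth_duration * p.r_null / LN2
    m = 1.0 - math.exp(-p.death_rate * p.stress_duration)
    return ReducedParams(alpha=alpha, beta=beta, death_fraction=m)


def expand_params(
    rp: ReducedParams,
    *,
    r_null: float = 1.0,
    carrying_capacity: float = 1.0,
    growth_fraction: float = 0.5,
) -> CompetitionParams:
    """Inverse of :func:`reduce_params` up to the free choices of time scale
    (``r_null``), capacity, and stress/growth split (``growth_fraction``).
    Only the reduced triple matters for the competition outcome."""
    growth_duration = rp.beta * LN2 / r_null
    stress_period = growth_duration / growth_fraction
    stress_duration = stress_period - growth_duration
    if rp.death_fraction > 0 and stress_duration == 0:
        raise CompetitionError("growth_fraction=1 leaves no stress window for killing")
    death_rate = (
        0.0
        if rp.death_fraction == 0
        else -math.log(1.0 - rp.death_fraction) / stress_duration
    )
    return CompetitionParams(
        r_wt=rp.alpha * r_null,
        r_null=r_null,
        carrying_capacity=carrying_capacity,
        stress_period=stress_period,
        growth_fraction=growth_fraction,
        death_rate=death_rate,
    )


def state_one_bound(beta: float) -> float:
    """Death fraction above which the mutant cannot recover between stresses."""
    return 1.0 - math.exp(-beta * LN2)


def state_two_bound(alpha: float, beta: float) -> float:
    """Death fraction above which the wild-type wins at any starting ratio."""
    return 1.0 - math.exp((alpha - 1.0) * beta * LN2)


def threshold_ratio(alpha: float, beta: float, m: float) -> float:
    """State III critical starting ratio ``N_WT / N_Null`` for WT dominance.

    Returns ``+inf`` for ``m = 0`` with ``alpha < 1`` (a slower wild-type can
    never win without killing) and the continuity limit ``-1/alpha`` at
    ``alpha = 1`` (any killing suffices at equal rates).
    """
    if m == 0.0:
        return math.inf if alpha < 1.0 else -1.0 / alpha
    if alpha == 1.0:
        return -1.0
    return ((1.0 - 1.0 / alpha) * beta * LN2) / math.log(1.0 - m) - 1.0 / alpha


def classify_state(rp: ReducedParams) -> PhaseState:
    """Classify (alpha, beta, m) into the three analytic phase states."""
    m = rp.death_fraction
    if m >= 1:
        raise CompetitionError("death_fraction must be < 1")
    if m > state_one_bound(rp.beta):
        return PhaseState(MUTANT_NONVIABLE)
    if m > state_two_bound(rp.alpha, rp.beta):
        return PhaseState(WT_ALWAYS_WINS)
    return PhaseState(
        RATIO_DEPENDENT,
        threshold_ratio=threshold_ratio(rp.alpha, rp.beta, m),
    )


def critical_death_fraction(
    alpha: float, beta: float, start_ratio: float, *, xtol: float = 1e-9
) -> float:
    """Smallest per-event death fraction giving wild-type dominance.

    Solves ``threshold_ratio(m) = start_ratio`` by bracketed bisection on
    ``m in (0, state-I bound)``; the threshold is strictly decreasing in
    ``m``, diverging at 0 and crossing zero at the State II bound, so the
    root is unique when it exists.
    """
    if not 0 < alpha < 1:
        if alpha >= 1:
            # any positive killing favors a wild-type that grows at least as fast
            return 0.0
        raise CompetitionError("alpha must be positive")
    if beta <= 0 or start_ratio <= 0:
        raise CompetitionError("beta and start_ratio must be positive")
    lo = 1e-9
    hi = state_one_bound(beta) - 1e-9

    def f(m: float) -> float:
        return threshold_ratio(alpha, beta, m) - start_ratio

    if f(lo) < 0:
        # even negligible killing already suffices at this starting ratio
        return lo
    if f(hi) > 0:
        raise CompetitionError(
            "wild-type cannot dominate at any sublethal death fraction "
            f"(alpha={alpha}, beta={beta}, start_ratio={start_ratio})"
        )
    return float(bisect(f, lo, hi, xtol=xtol))


def simulate_competition(
    p: CompetitionParams,
    init: PopulationState,
    n_cycles: int,
    *,
    samples_per_phase: int = 12,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the piecewise model for ``n_cycles`` stress cycles.

    Each cycle is integrated phase by phase (the solver never steps across a
    switch): the stress window has the exact solution ``n_wt`` constant and
    ``n_null * exp(-D t)``; the growth window is handled by an adaptive
    stiff-capable solver (LSODA) with rtol ``1e-8`` and atol ``1e-10 * K``.
    """
    if n_cycles < 1:
        raise CompetitionError("n_cycles must be >= 1")
    K = p.carrying_capacity
    atol = 1e-10 * K
    n_wt, n_null = float(init.n_wt), float(init.n_null)
    t = float(init.t)
    traj = Trajectory(carrying_capacity=K)
    traj.states.append(PopulationState(t, n_wt, n_null))

    def _log_ratio(w: float, n: float) -> float:
        if n <= 0.0:
            return math.inf
        if w <= 0.0:
            return -math.inf
        return math.log(w / n)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        w, n = y
        room = 1.0 - (w + n) / K
        return [p.r_wt * w * room, p.r_null * n * room]

    for cycle in range(n_cycles):
        lr0 = _log_ratio(n_wt, n_null)
        # --- stress window: wild-type frozen, mutant exponential decay
        s_dur = p.stress_duration
        if s_dur > 0:
            ts = np.linspace(0.0, s_dur, samples_per_phase + 1)[1:]
            for dt_ in ts:
                traj.states.append(
                    PopulationState(t + dt_, n_wt, n_null * math.exp(-p.death_rate * dt_))
                )
            n_null *= math.exp(-p.death_rate * s_dur)
            t += s_dur
        # --- growth window: logistic competition
        g_dur = p.growth_duration
        if g_dur > 0:
            t_eval = np.linspace(0.0, g_dur, samples_per_phase + 1)[1:]
            sol = solve_ivp(
                rhs,
                (0.0, g_dur),
                [n_wt, n_null],
                method="LSODA",
                rtol=rtol,
                atol=atol,
                t_eval=t_eval,
            )
            if not sol.success:
                raise CompetitionError(
                    f"ODE solver failed in growth phase of cycle {cycle}: {sol.message}"
                )
            for i, dt_ in enumerate(sol.t):
                w = max(sol.y[0, i], 0.0)
                n = max(sol.y[1, i], 0.0)
                traj.states.append(PopulationState(t + dt_, w, n))
            n_wt = max(sol.y[0, -1], 0.0)
            n_null = max(sol.y[1, -1], 0.0)
            t += g_dur
        traj.cycle_log_ratio_changes.append(_log_ratio(n_wt, n_null) - lr0)
    return traj


def winner(
    traj: Trajectory,
    *,
    extinction_floor_frac: float = 1e-9,
    decision_window_frac: float = 0.25,
    tol: float = 1e-6,
) -> str:
    """Decide the competition outcome from a simulated trajectory.

    ``MUTANT_EXTINCT`` if the mutant count ever falls below the extinction
    floor (default ``1e-9 * K``); otherwise the sign of the mean per-cycle
    log-ratio change over the last quarter of cycles decides ``WT`` vs
    ``MUTANT``, with ``COEXIST_FROZEN`` inside tolerance.
    """
    n_cycles = len(traj.cycle_log_ratio_changes)
    if n_cycles < 10:
        raise CompetitionError(f"need >= 10 cycles to call a winner, got {n_cycles}")
    floor = extinction_floor_frac * traj.carrying_capacity
    if np.min(traj.n_null) < floor:
        return MUTANT_EXTINCT
    k = max(1, int(math.ceil(decision_window_frac * n_cycles)))
    late = np.asarray(traj.cycle_log_ratio_changes[-k:], dtype=float)
    mean = float(np.mean(late))
    if abs(mean) <= tol:
        return COEXIST_FROZEN
    return WT if mean > 0 else MUTANT


def simulate_reduced(
    rp: ReducedParams,
    *,
    start_ratio: float = 1.0,
    n_cycles: int = 20,
    total_frac: float = 0.05,
    carrying_capacity: float = 1.0,
    growth_fraction: float = 0.5,
) -> Trajectory:
    """Convenience wrapper: simulate directly from reduced parameters with the
    default dilute inoculum (total population ``0.05 K``) split at
    ``start_ratio`` wild-type : mutant."""
    p = expand_params(
        rp, carrying_capacity=carrying_capacity, growth_fraction=growth_fraction
    )
    total = total_frac * carrying_capacity
    n_null = total / (1.0 + start_ratio)
    init = PopulationState(0.0, total - n_null, n_null)
    return simulate_competition(p, init, n_cycles)


def phase_map(
    alpha: float,
    beta_grid: Sequence[float],
    m_grid: Sequence[float],
    ratios: Sequence[float] = (1.0,),
) -> dict:
    """Evaluate the analytic phase classification on a (beta, m) grid plus,
    for each starting ratio, the dominance contour ``m*(beta)``.

    Returns a dict with ``states`` (len(m_grid) x len(beta_grid) array of
    labels), ``threshold_ratios`` (same shape, NaN outside State III), and
    ``contours`` mapping each ratio to an array of critical death fractions
    over ``beta_grid`` (NaN where the wild-type cannot win sublethally).
    """
    beta_grid = list(beta_grid)
    m_grid = list(m_grid)
    if not beta_grid or not m_grid:
        raise CompetitionError("grids must be nonempty")
    if sorted(beta_grid) != beta_grid or sorted(m_grid) != m_grid:
        raise CompetitionError("grids must be sorted ascending")
    states = np.empty((len(m_grid), len(beta_grid)), dtype=object)
    thresholds = np.full((len(m_grid), len(beta_grid)), np.nan)
    for i, m in enumerate(m_grid):
        for j, beta in enumerate(beta_grid):
            ps = classify_state(ReducedParams(alpha, beta, m))
            states[i, j] = ps.label
            if ps.threshold_ratio is not None:
                thresholds[i, j] = ps.threshold_ratio
    contours = {}
    for ratio in ratios:
        row = np.full(len(beta_grid), np.nan)
        for j, beta in enumerate(beta_grid):
            try:
                row[j] = critical_death_fraction(alpha, beta, ratio)
            except CompetitionError:
                row[j] = np.nan
        contours[ratio] = row
    return {
        "alpha": alpha,
        "beta_grid": np.asarray(beta_grid, dtype=float),
        "m_grid": np.asarray(m_grid, dtype=float),
        "states": states,
        "threshold_ratios": thresholds,
        "contours": contours,
    }
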