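"""Two-species Lotka-Volterra competition model.

Simulation, equilibria, and qualitative outcome classification for the
classical model

    dN1/dt = r1 * N1 * (1 - (N1 + a12 * N2) / K1)
    dN2/dt = r2 * N2 * (1 - (N2 + a21 * N1) / K2)

where state is measured as total biovolume per microcosm (µm³), K is the
single-species steady state (carrying capacity) and a12 is the per-unit
competitive effect of species 2 on species 1.  Neutral coexistence is the
special case a12 = a21 = 1 with equal carrying capacities: the interior
dynamics then conserve the abundance ratio and the community drifts along
the line N1 + N2 = K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LVParams",
    "State",
    "DegenerateEquilibriumError",
    "derivative",
    "simulate",
    "coexistence_equilibrium",
    "classify_outcome",
    "OUTCOMES",
]

#: tolerance for the exact-neutrality test in :func:`classify_outcome`
NEUTRAL_TOL = 1e-9
#: negative excursions below -NEGATIVE_TOL * K are treated as solver failure
NEGATIVE_TOL = 1e-12

OUTCOMES = (
    "stable_coexistence",
    "exclusion_1_wins",
    "exclusion_2_wins",
    "founder_control",
    "neutral",
)


class DegenerateEquilibriumError(ValueError):
    """a12 * a21 = 1: the nullclines are parallel (or coincident).

    There is either no interior equilibrium or a whole line of them, so a
    single coexistence state is undefined.
    """


@dataclass(frozen=True)
class LVParams:
    """Parameters of the two-species competition model.

    r1, r2 : intrinsic growth rates (day⁻¹)
    K1, K2 : carrying capacities (µm³ biovolume per microcosm)
    a12    : effect of species 2 on species 1 (dimensionless)
    a21    : effect of species 1 on species 2 (dimensionless)
    """

    r1: float
    r2: float
    K1: float
    K2: float
    a12: float
    a21: float

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "K1", "K2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("a12", "a21"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class State:
    """Biovolumes (µm³ per microcosm) of the two species."""

    N1: float
    N2: float

    def __post_init__(self) -> None:
        if self.N1 < 0 or self.N2 < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.N1, self.N2], dtype=float)


def derivative(state: State | Sequence[float], params: LVParams) -> tuple[float, float]:
    """Rate of change (dN1/dt, dN2/dt) at ``state``."""
    n1, n2 = (state.N1, state.N2) if isinstance(state, State) else (state[0], state[1])
    d1 = params.r1 * n1 * (1.0 - (n1 + params.a12 * n2) / params.K1)
    d2 = params.r2 * n2 * (1.0 - (n2 + params.a21 * n1) / params.K2)
    return (d1, d2)


def simulate(
    params: LVParams,
    init: State,
    t_grid: Sequence[float],
    dilution_events: Sequence[tuple[float, float]] = (),
    sample_before_events: bool = False,
    rtol: float = 1e-8,
    atol_scale: float = 1e-8,
) -> np.ndarray:
    """Integrate the model, applying instantaneous dilution events.

    Parameters
    ----------
    t_grid
        Strictly increasing output times; the first entry is the initial time.
    dilution_events
        ``(time, factor)`` pairs: at each ``time`` the state is multiplied by
        ``factor`` (e.g. 0.96 for replacing 0.2 mL of a 5 mL microcosm).
        Events at or before the initial time are ignored.
    sample_before_events
        When an event coincides (exact float equality) with an output time,
        record the state just *before* the dilution instead of just after.
        This matches a protocol where the extracted aliquot is what gets
        counted, and fresh medium is only added back afterwards.

    Returns
    -------
    ndarray of shape (len(t_grid), 2); rows are states at ``t_grid`` times.

    Adaptive explicit Runge-Kutta (RK45); logistic-type dynamics are
    non-stiff, so no implicit solver is needed.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    t0, t_end = t_grid[0], t_grid[-1]
    events = sorted((t, f) for t, f in dilution_events if t0 < t <= t_end)
    if any(not 0 < f <= 1 for _, f in events):
        raise ValueError("dilution factors must be in (0, 1]")

    kmin = min(params.K1, params.K2)
    atol = atol_scale * kmin

    def rhs(_t: float, y: np.ndarray) -> tuple[float, float]:
        return derivative(y, params)

    out = np.empty((t_grid.size, 2))
    out[0] = y = init.as_array()
    if t_grid.size == 1:
        return out

    # piecewise integration: solve up to each event time, apply the factor
    breakpoints = [t for t, _ in events] + [t_end]
    factors = [f for _, f in events] + [1.0]
    seg_start = t0
    filled = 1
    for seg_end, factor in zip(breakpoints, factors):
        if seg_end > seg_start:
            inside = t_grid[(t_grid > seg_start) & (t_grid < seg_end)]
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="RK45",
                t_eval=np.concatenate([inside, [seg_end]]),
                rtol=rtol,
                atol=atol,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise RuntimeError(f"integration failed on [{seg_start}, {seg_end}]: {sol.message}")
            ys = sol.y.T
            if np.any(ys < -NEGATIVE_TOL * kmin):
                raise RuntimeError("solution went significantly negative; step-size failure")
            ys = np.clip(ys, 0.0, None)  # zero tiny negative round-off
            out[filled : filled + inside.size] = ys[:-1]
            filled += inside.size
            y = ys[-1]
        take = filled < t_grid.size and t_grid[filled] == seg_end
        if take and sample_before_events:
            out[filled] = y
            filled += 1
        y = y * factor
        if take and not sample_before_events:
            out[filled] = y
            filled += 1
        seg_start = seg_end
    assert filled == t_grid.size
    return out


def coexistence_equilibrium(params: LVParams) -> State | None:
    """Interior equilibrium from the steady-state linear system.

    Solves ``N1 + a12*N2 = K1`` and ``a21*N1 + N2 = K2``; returns the
    solution only if both components are strictly positive, else ``None``.

    Raises
    ------
    DegenerateEquilibriumError
        If ``a12 * a21 = 1`` (parallel nullclines; neutral/degenerate case).
    """
    det = 1.0 - params.a12 * params.a21
    if det == 0.0:
        raise DegenerateEquilibriumError(
            "a12 * a21 = 1: neutral/degenerate case, no unique interior equilibrium"
        )
    n1 = (params.K1 - params.a12 * params.K2) / det
    n2 = (params.K2 - params.a21 * params.K1) / det
    if n1 > 0 and n2 > 0:
        return State(n1, n2)
    return None


def classify_outcome(params: LVParams) -> str:
    """Qualitative outcome from the mutual-invasion criteria.

    Species 2 can invade species 1's monoculture iff ``a21 < K2/K1`` and
    vice versa.  Both invasible → stable coexistence; neither → founder
    control; one-sided → competitive exclusion.  The measure-zero neutral
    point (a12 = a21 = 1 and K1 = K2, within ``NEUTRAL_TOL``) is reported
    separately because its interior dynamics are a line of fixed points.
    """
    if (
        abs(params.a12 - 1.0) < NEUTRAL_TOL
        and abs(params.a21 - 1.0) < NEUTRAL_TOL
        and abs(params.K1 - params.K2) < NEUTRAL_TOL * max(params.K1, params.K2)
    ):
        return "neutral"
    inv1 = params.a12 < params.K1 / params.K2  # species 1 invades species 2's monoculture
    inv2 = params.a21 < params.K2 / params.K1
    if inv1 and inv2:
        return "stable_coexistence"
    if not inv1 and not inv2:
        return "founder_control"
    return "exclusion_1_wins" if inv1 else "exclusion_2_wins"
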