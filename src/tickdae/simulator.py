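"""Method-of-steps integration of the coupled algebraic-delay tick model.

The model couples a delay differential equation for the engorged ticks
E(t) with an algebraic (integral) equation for the feeding ticks F(t):

    dE/dt = -delta E(t) + e^{-S(t)} rho(F(t-T)) eta E(t - tau - T),
    F(t)  = int_0^T e^{-int_{-a}^0 nu(F(t+xi)) dxi} rho(F(t-a)) eta E(t-tau-a) da,

with S(t) = int_{t-T}^t nu(F(s)) ds the running grooming-survival exponent.
On the constraint manifold — reached exactly when the initial history
satisfies the matching condition F(0) = (algebraic right-hand side at 0) —
the algebraic equation may be differentiated, and the trailing distributed
term collapses to nu(F(t)) F(t), giving the equivalent DDE

    dF/dt = rho(F(t)) eta E(t-tau) - e^{-S(t)} rho(F(t-T)) eta E(t-tau-T)
            - nu(F(t)) F(t).

The integrator advances (E, F, S) with classical RK4, treating S as an
auxiliary state with dS/dt = nu(F(t)) - nu(F(t-T)).  The step h is chosen to
divide both T and tau, so every delayed argument the RK4 stages need falls
on a stored grid point or exactly mid-interval; mid-interval values come
from 4-point (cubic) interpolation of the already-computed history, keeping
the scheme 4th order overall.  A residual monitor re-evaluates the algebraic
right-hand side by Simpson quadrature to detect drift off the manifold.

Positivity of solutions from nonnegative matched histories holds for the
exact flow; the integrator enforces it as a runtime invariant (abort
below -1e-9, clamp smaller round-off undershoots).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

from .behaviours import ModelParams, Scenario
from .equilibria import Equilibrium, solve_equilibria, tangency_gap

__all__ = [
    "HistoryFunction",
    "Trajectory",
    "PositivityError",
    "MatchingError",
    "make_history",
    "matching_rhs",
    "step_system",
    "simulate",
    "density_profile",
    "bifurcation_scan",
    "default_step",
]

#: default grid divisor: h = T / 70 (0.1 day for the presets' T = 7)
DEFAULT_STEPS_PER_T = 70
#: relative distance defining convergence to a known equilibrium
CONV_TOL = 1e-4
#: state blow-up threshold -> "diverged"
DIVERGE_AT = 1e12
#: survival integral re-synchronised by full quadrature every this many steps
RESYNC_EVERY = 10_000


class PositivityError(RuntimeError):
    """The integrated state left the nonnegative cone beyond round-off."""


class MatchingError(RuntimeError):
    """The matched-history fixed point did not converge."""


def default_step(params: ModelParams) -> float:
    """h = T/70, which divides T exactly and tau to machine precision
    for the preset delays (tau = 700, T = 7)."""
    return params.T / DEFAULT_STEPS_PER_T


def _check_grid(h: float, params: ModelParams) -> tuple:
    nT = round(params.T / h)
    ntau = round(params.tau / h)
    if nT < 2 or abs(nT * h - params.T) > 1e-9 * params.T:
        raise ValueError(f"step h={h} must divide the feeding duration T={params.T}")
    if abs(ntau * h - params.tau) > 1e-9 * params.tau:
        raise ValueError(f"step h={h} must divide the development delay tau={params.tau}")
    return nT, ntau


@dataclass
class HistoryFunction:
    """Initial data (E, F) on [-tau-T, 0] on a uniform grid of step h.

    ``matching_residual`` is |F(0) - RHS| / max(F(0), 1) where RHS is the
    algebraic right-hand side evaluated on the history by Simpson
    quadrature; the solution stays on the algebraic constraint manifold only
    when this residual vanishes.
    """

    grid: np.ndarray
    E_hist: np.ndarray
    F_hist: np.ndarray
    h: float
    matching_residual: float = math.nan

    def __post_init__(self):
        if np.any(self.E_hist < 0) or np.any(self.F_hist < 0):
            raise ValueError("history values must be nonnegative")


@dataclass
class Trajectory:
    """Integrated solution on t >= 0 plus diagnostics.

    ``Q`` is the derived questing inflow Q(t) = eta E(t - tau).  The
    ``constraint_residual`` series (at times ``residual_t``) monitors the
    algebraic identity; ``terminal_state`` is one of ``converged``
    (``equilibrium`` holds the attractor), ``diverged`` or ``max_time``.
    The private extended arrays include the history segment and are used by
    :func:`density_profile`.
    """

    t: np.ndarray
    E: np.ndarray
    F: np.ndarray
    Q: np.ndarray
    residual_t: np.ndarray
    constraint_residual: np.ndarray
    terminal_state: str
    equilibrium: Optional[Equilibrium]
    h: float
    _t_ext: np.ndarray = field(repr=False, default=None)
    _E_ext: np.ndarray = field(repr=False, default=None)
    _F_ext: np.ndarray = field(repr=False, default=None)
    _params: ModelParams = field(repr=False, default=None)
    _scenario: Scenario = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# history construction and the matching condition
# ---------------------------------------------------------------------------

def matching_rhs(E_hist: np.ndarray, F_hist: np.ndarray, h: float,
                 params: ModelParams, scenario: Scenario) -> float:
    """Algebraic right-hand side at t = 0 evaluated on gridded history.

    int_0^T exp(-int_{-a}^0 nu(F(xi)) dxi) rho(F(-a)) eta E(-tau - a) da by
    composite Simpson quadrature (inner exponent by cumulative Simpson).
    Arrays are ordered along the grid of HistoryFunction, i.e. from
    -tau - T up to 0.
    """
    nT, ntau = _check_grid(h, params)
    F_rev = F_hist[len(F_hist) - nT - 1:][::-1]  # F(-a), a = 0..T
    nu_rev = np.asarray(scenario.nu(F_rev), dtype=float)
    inner = cumulative_simpson(nu_rev, dx=h, initial=0.0)
    rho_rev = np.asarray(scenario.rho(F_rev), dtype=float)
    i0 = len(E_hist) - 1
    E_lag = E_hist[i0 - ntau - nT:i0 - ntau + 1][::-1]  # E(-tau - a), a = 0..T
    integrand = np.exp(-inner) * rho_rev * params.eta * E_lag
    return float(simpson(integrand, dx=h))


def make_history(E0: Union[float, str, Callable[[float], float]],
                 F0: Union[float, str],
                 params: ModelParams, scenario: Scenario,
                 h: Optional[float] = None,
                 f_init: float = 1.0,
                 max_iter: int = 10_000,
                 tol: float = 1e-12) -> HistoryFunction:
    """Constant (or profiled-E) initial data satisfying the matching condition.

    Parameters
    ----------
    E0
        Engorged-tick history level: a nonnegative constant, a callable of
        s on [-tau-T, 0], or the sentinel ``"matched"`` (requires numeric
        F0) which sets the constant level so the matching condition holds
        exactly with F identically F0:
        ``E0 = F0 / (eta rho(F0) Phi(nu(F0), T))``, Phi(s,T)=(1-e^{-sT})/s.
    F0
        Feeding-tick history level, or ``"matched"``: iterate
        f <- rho(f) eta <E around -tau> Phi(nu(f), T) — the algebraic
        right-hand side under constant-F survival — to its fixed point
        (successive relative change below ``tol``).
    """
    if h is None:
        h = default_step(params)
    nT, ntau = _check_grid(h, params)
    n = ntau + nT
    grid = -params.tau - params.T + h * np.arange(n + 1)
    grid[-1] = 0.0

    matched_E = isinstance(E0, str)
    if matched_E:
        if E0 != "matched":
            raise ValueError(f"unrecognised sentinel {E0!r}")
        if isinstance(F0, str):
            raise ValueError("E0='matched' requires a numeric F0")
        f = float(F0)
        if f == 0.0:
            E_hist = np.zeros(n + 1)
        else:
            nu_f = float(scenario.nu(f))
            phi = params.T if nu_f == 0 else (1.0 - math.exp(-nu_f * params.T)) / nu_f
            E_level = f / (params.eta * float(scenario.rho(f)) * phi)
            E_hist = np.full(n + 1, E_level)
        F_hist = np.full(n + 1, f)
    else:
        if callable(E0):
            E_hist = np.asarray([float(E0(s)) for s in grid], dtype=float)
        else:
            E_hist = np.full(n + 1, float(E0))
        if np.any(E_hist < 0):
            raise ValueError("E history must be nonnegative")
        if isinstance(F0, str):
            if F0 != "matched":
                raise ValueError(f"unrecognised sentinel {F0!r}")
            # fixed point of the constant-F-survival right-hand side
            rho_s, nu_s = scenario.rho_s, scenario.nu_s
            a_grid = h * np.arange(nT + 1)
            E_lag = E_hist[n - ntau - nT:n - ntau + 1][::-1]
            f = float(f_init)
            for _ in range(max_iter):
                integrand = np.exp(-float(nu_s(f)) * a_grid) * float(rho_s(f)) \
                    * params.eta * E_lag
                f_new = float(simpson(integrand, dx=h))
                if abs(f_new - f) <= tol * max(abs(f_new), 1e-300):
                    f = f_new
                    break
                f = f_new
            else:
                raise MatchingError(
                    f"matched-F fixed point did not converge in {max_iter} "
                    f"iterations; last residual {abs(f_new - f):.3g}"
                )
            F_hist = np.full(n + 1, f)
        else:
            F_hist = np.full(n + 1, float(F0))

    rhs = matching_rhs(E_hist, F_hist, h, params, scenario)
    residual = abs(F_hist[-1] - rhs) / max(F_hist[-1], 1.0)
    return HistoryFunction(grid, E_hist, F_hist, h, residual)


# ---------------------------------------------------------------------------
# the RK4 method-of-steps core
# ---------------------------------------------------------------------------

# cubic interpolation weights at the half-grid point between the middle
# pair: centred stencil, and one-sided variants used next to a breaking
# point (a grid node where the solution's low-order derivatives jump:
# the initial history joins the solution non-smoothly at t = 0 and the
# kink propagates to t = a*T + b*tau, gaining one derivative of smoothness
# per propagation; a stencil straddling such a node would drop the
# interpolation — and hence the integrator — to second order)
_W_MID = (-1.0 / 16.0, 9.0 / 16.0, 9.0 / 16.0, -1.0 / 16.0)
_W_RIGHT = (0.3125, 0.9375, -0.3125, 0.0625)   # nodes idx .. idx+3
_W_LEFT = (0.0625, -0.3125, 0.9375, 0.3125)    # nodes idx-2 .. idx+1


def breaking_indices(nT: int, ntau: int, n_total: int, max_order: int = 4) -> frozenset:
    """Extended-grid indices of breaking points a*T + b*tau with a+b <= max_order.

    The jump order of the solution's derivatives at a*T + b*tau grows with
    a + b, so only combinations up to the integrator's order matter.
    """
    i0 = ntau + nT
    out = set()
    for a in range(max_order + 1):
        for b in range(max_order + 1 - a):
            idx = i0 + a * nT + b * ntau
            if idx < n_total:
                out.add(idx)
    return frozenset(out)


def _mid(arr, idx, kinks):
    """Value at grid index idx + 1/2 by cubic interpolation of known history.

    Uses the centred 4-point stencil unless a breaking point lies at one of
    its nodes outside the evaluation interval, in which case the one-sided
    stencil on the smooth side is used instead.
    """
    if idx >= 1 and (idx - 1) not in kinks and idx not in kinks \
            and (idx + 1) not in kinks and (idx + 2) not in kinks:
        return (_W_MID[0] * arr[idx - 1] + _W_MID[1] * arr[idx]
                + _W_MID[2] * arr[idx + 1] + _W_MID[3] * arr[idx + 2])
    if idx < 1 or idx in kinks or (idx - 1) in kinks:
        return (_W_RIGHT[0] * arr[idx] + _W_RIGHT[1] * arr[idx + 1]
                + _W_RIGHT[2] * arr[idx + 2] + _W_RIGHT[3] * arr[idx + 3])
    return (_W_LEFT[0] * arr[idx - 2] + _W_LEFT[1] * arr[idx - 1]
            + _W_LEFT[2] * arr[idx] + _W_LEFT[3] * arr[idx + 1])


def step_system(state: tuple, i: int, E: np.ndarray, F: np.ndarray,
                params: ModelParams, scenario: Scenario, h: float,
                nT: int, ntau: int, kinks: frozenset = frozenset()) -> tuple:
    """Advance (E, F, S) one RK4 step from extended-grid index i to i + 1.

    ``E`` and ``F`` are the extended solution arrays (history + computed
    segment, filled up to index i); delayed stage values at half steps are
    cubic-interpolated from them.  Returns the new (E, F, S) triple; raises
    :class:`PositivityError` if a component drops below -1e-9.
    """
    Ei, Fi, Si = state
    eta, delta = params.eta, params.delta
    rho_s, nu_s = scenario.rho_s, scenario.nu_s
    nlag = ntau + nT

    def f(Ev, Fv, Sv, FdT, Etau, EtauT):
        inflow = math.exp(-Sv) * rho_s(FdT) * eta * EtauT
        dE = -delta * Ev + inflow
        dF = rho_s(Fv) * eta * Etau - inflow - nu_s(Fv) * Fv
        dS = nu_s(Fv) - nu_s(FdT)
        return dE, dF, dS

    d0 = (F[i - nT], E[i - ntau], E[i - nlag])
    dm = (_mid(F, i - nT, kinks), _mid(E, i - ntau, kinks),
          _mid(E, i - nlag, kinks))
    d1 = (F[i - nT + 1], E[i - ntau + 1], E[i - nlag + 1])

    k1 = f(Ei, Fi, Si, *d0)
    k2 = f(Ei + 0.5 * h * k1[0], Fi + 0.5 * h * k1[1], Si + 0.5 * h * k1[2], *dm)
    k3 = f(Ei + 0.5 * h * k2[0], Fi + 0.5 * h * k2[1], Si + 0.5 * h * k2[2], *dm)
    k4 = f(Ei + h * k3[0], Fi + h * k3[1], Si + h * k3[2], *d1)

    sixth = h / 6.0
    En = Ei + sixth * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
    Fn = Fi + sixth * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
    Sn = Si + sixth * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
    if En < -1e-9 or Fn < -1e-9:
        raise PositivityError(
            f"positivity violated at step {i}: E={En:.3e}, F={Fn:.3e}"
        )
    return (max(En, 0.0), max(Fn, 0.0), Sn)


def _survival_quad(F_window: np.ndarray, h: float, scenario: Scenario) -> float:
    return float(simpson(np.asarray(scenario.nu(F_window), dtype=float), dx=h))


def simulate(history: HistoryFunction, params: ModelParams, scenario: Scenario,
             t_end: float, h: Optional[float] = None,
             equilibria: Optional[Sequence[Equilibrium]] = None,
             residual_every: int = 50) -> Trajectory:
    """Integrate the coupled system from ``history`` up to ``t_end``.

    Convergence detection: when ``equilibria`` is given (or solvable for the
    scenario), the run stops early once the relative distance
    max(|E - E*|/max(E*,1), |F - F*|/max(F*,1)) to some equilibrium stays
    below 1e-4 for a full life-cycle window (tau + T).  The constraint
    residual is sampled every ``residual_every`` steps.
    """
    if h is None:
        h = history.h
    if abs(h - history.h) > 1e-12 * h:
        raise ValueError("step h must match the history grid")
    nT, ntau = _check_grid(h, params)
    nlag = ntau + nT
    nsteps = int(round(t_end / h))
    if nsteps <= 0:
        raise ValueError("t_end must be positive")

    if equilibria is None:
        try:
            equilibria = solve_equilibria(params, scenario)
        except ValueError:
            equilibria = [Equilibrium(0.0, 0.0, "trivial")]

    n_total = nlag + 1 + nsteps
    E = np.empty(n_total)
    F = np.empty(n_total)
    E[:nlag + 1] = history.E_hist
    F[:nlag + 1] = history.F_hist
    state = (float(E[nlag]), float(F[nlag]),
             _survival_quad(F[:nlag + 1][-(nT + 1):], h, scenario))

    kinks = breaking_indices(nT, ntau, n_total)
    conv_needed = nlag  # sustained window of one life cycle
    conv_run = 0
    conv_eq = None
    terminal = "max_time"
    i_last = nlag + nsteps
    for i in range(nlag, nlag + nsteps):
        state = step_system(state, i, E, F, params, scenario, h, nT, ntau, kinks)
        E[i + 1], F[i + 1] = state[0], state[1]
        if (i + 1 - nlag) % RESYNC_EVERY == 0:
            state = (state[0], state[1],
                     _survival_quad(F[i + 1 - nT:i + 2], h, scenario))
        if state[0] > DIVERGE_AT or state[1] > DIVERGE_AT:
            terminal = "diverged"
            i_last = i + 1
            break
        near = None
        for eq in equilibria:
            d = max(abs(state[0] - eq.E_star) / max(eq.E_star, 1.0),
                    abs(state[1] - eq.F_star) / max(eq.F_star, 1.0))
            if d < CONV_TOL:
                near = eq
                break
        if near is not None and near is conv_eq:
            conv_run += 1
            if conv_run >= conv_needed:
                terminal = "converged"
                i_last = i + 1
                break
        else:
            conv_eq = near
            conv_run = 0 if near is None else 1

    n_out = i_last - nlag
    t = h * np.arange(n_out + 1)
    E_out = E[nlag:i_last + 1].copy()
    F_out = F[nlag:i_last + 1].copy()
    Q_out = params.eta * E[nlag - ntau:i_last - ntau + 1].copy()

    # constraint-residual monitor on a subsampled grid
    res_idx = np.arange(nlag, i_last + 1, residual_every)
    if res_idx[-1] != i_last:
        res_idx = np.append(res_idx, i_last)
    residuals = np.array([
        abs(F[i] - matching_rhs(E[i - nlag:i + 1], F[i - nlag:i + 1], h,
                                params, scenario)) / max(F[i], 1.0)
        for i in res_idx
    ])

    return Trajectory(
        t=t, E=E_out, F=F_out, Q=Q_out,
        residual_t=h * (res_idx - nlag).astype(float),
        constraint_residual=residuals,
        terminal_state=terminal,
        equilibrium=conv_eq if terminal == "converged" else None,
        h=h,
        _t_ext=h * np.arange(n_total) - (params.tau + params.T),
        _E_ext=E[:i_last + 1],
        _F_ext=F[:i_last + 1],
        _params=params,
        _scenario=scenario,
    )


# ---------------------------------------------------------------------------
# feeding-duration density reconstruction
# ---------------------------------------------------------------------------

def density_profile(trajectory: Trajectory, t: float,
                    params: Optional[ModelParams] = None,
                    scenario: Optional[Scenario] = None):
    """Feeding-duration density n(t, .) on [0, T], reconstructed from history.

    n(t, a) = exp(-int_{t-a}^t nu(F)) rho(F(t-a)) Q(t-a) with
    Q(s) = eta E(s - tau).  Returns ``(a_grid, n_values)``; the Simpson
    integral of n over [0, T] reproduces F(t) up to quadrature accuracy, and
    n(t, 0) = rho(F(t)) Q(t) is the attachment boundary flux.
    """
    params = params or trajectory._params
    scenario = scenario or trajectory._scenario
    h = trajectory.h
    nT, ntau = _check_grid(h, params)
    i = round(t / h)
    if abs(i * h - t) > 1e-9 * max(t, 1.0) or i < 0 or i > len(trajectory.t) - 1:
        raise ValueError(f"t={t} outside the trajectory grid [0, {trajectory.t[-1]}]")
    ie = i + ntau + nT  # index on the extended grid
    F_ext, E_ext = trajectory._F_ext, trajectory._E_ext
    a_grid = h * np.arange(nT + 1)
    F_rev = F_ext[ie - nT:ie + 1][::-1]  # F(t - a)
    nu_rev = np.asarray(scenario.nu(F_rev), dtype=float)
    inner = cumulative_simpson(nu_rev, dx=h, initial=0.0)
    rho_rev = np.asarray(scenario.rho(F_rev), dtype=float)
    Q_rev = params.eta * E_ext[ie - ntau - nT:ie - ntau + 1][::-1]  # eta E(t - tau - a)
    return a_grid, np.exp(-inner) * rho_rev * Q_rev


# ---------------------------------------------------------------------------
# one-parameter equilibrium-branch scan
# ---------------------------------------------------------------------------

def bifurcation_scan(params: ModelParams, scenario_tag: str, param_name: str,
                     grid: Sequence[float]):
    """Recompute equilibria and verdicts along a one-parameter grid.

    Returns a pandas DataFrame with one row per (parameter value, branch)
    and, in ``df.attrs["fold"]``, the fold (saddle-node) location found by
    bracketed bisection of the tangency condition between the grid points
    where its sign changes (None if no change).
    """
    import pandas as pd
    from scipy.optimize import brentq

    from .behaviours import make_scenario
    from .stability import classify_reactive, classify_ricker

    classify = {"ricker_linear": classify_ricker,
                "holling3_reactive": classify_reactive}.get(scenario_tag)
    if classify is None:
        raise ValueError(f"bifurcation scan supports ricker_linear and "
                         f"holling3_reactive, not {scenario_tag!r}")

    rows = []
    gaps = []
    for value in grid:
        pv = params.replace(**{param_name: float(value)})
        gaps.append(tangency_gap(pv, make_scenario(scenario_tag, pv)))
        for eq in classify(pv):
            rows.append({param_name: float(value), "branch": eq.branch,
                         "E_star": eq.E_star, "F_star": eq.F_star,
                         "stability": eq.stability, "residual": eq.residual})
    df = pd.DataFrame(rows)

    fold = None
    for a, b, ga, gb in zip(grid, list(grid)[1:], gaps, gaps[1:]):
        if ga * gb < 0:
            def gap_of(v):
                pv = params.replace(**{param_name: float(v)})
                return tangency_gap(pv, make_scenario(scenario_tag, pv))
            fold = brentq(gap_of, a, b, rtol=1e-14)
            break
    df.attrs["fold"] = fold
    df.attrs["param"] = param_name
    return df
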