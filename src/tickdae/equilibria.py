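"""Equilibrium structure of the coupled algebraic-delay tick model.

A nontrivial equilibrium (E*, F*) satisfies the pair

    nu(F*) = (1/T) * ln( eta * rho(F*) / delta ),
    E*     = F* * nu(F*) / ( eta * rho(F*) - delta ),

which requires eta * rho(F*) > delta.  For each named scenario the first
line reduces to a root problem for a unimodal function, so the multiplicity
(0, 1 tangent, or 2 roots per unimodal branch) is decided by comparing the
function's maximum with the right-hand side:

* ``ricker_linear``:  g1(x) = x exp(-(1/c + mu T) x) = delta/(eta p) e^{mu0 T};
* ``holling3_reactive``: first g2(rho) = rho exp(-k T rho) = delta/eta for
  the attachment level rho*, then the Holling-III curve rho(F) = rho* is
  inverted in closed form (a quadratic in F), giving up to four equilibria;
* ``monotone``: the reduced equation is monotone, a unique root iff R0 > 1.

The trivial state (0, 0) always exists; it is locally stable when
delta > rho(0) eta exp(-nu(0) T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy.integrate import quad, simpson
from scipy.optimize import brentq

from .behaviours import ModelParams, Scenario, basic_reproduction_number

__all__ = [
    "Equilibrium",
    "InfeasibleEquilibriumError",
    "E_from_F",
    "equilibrium_residual",
    "solve_ricker",
    "solve_reactive",
    "solve_monotone",
    "solve_equilibria",
    "trivial_stability",
    "critical_case_limit",
    "holling3_inverse",
    "tangency_gap",
]

#: absolute tolerance on g-function residuals at returned roots
G_ATOL = 1e-12
#: relative tolerance on F for root refinement (near machine epsilon so the
#: g-residual check below reaches its floating-point floor)
F_RTOL = 4 * 2.220446049250313e-16
#: relative margin for tangency (double-root) detection
TANGENT_RTOL = 1e-9


class InfeasibleEquilibriumError(ValueError):
    """eta * rho(F*) <= delta: the equilibrium E-line has no positive value."""


@dataclass
class Equilibrium:
    """An (E*, F*) pair with its branch label and stability verdict.

    Branch labels: ``trivial``; ``minus``/``plus`` for the lower/upper root
    of the Ricker equilibrium equation (``critical`` at a tangency);
    ``minus_minus``, ``plus_minus``, ``plus_plus``, ``minus_plus`` for the
    reactive-grooming case, first sign = attachment-level root (rho- / rho+),
    second sign = smaller/larger quadratic inversion root.
    """

    E_star: float
    F_star: float
    branch: str
    stability: str = "undetermined"
    residual: float = 0.0

    @property
    def is_trivial(self) -> bool:
        return self.branch == "trivial"


def E_from_F(F_star: float, params: ModelParams, scenario: Scenario) -> float:
    """E* = F* nu(F*) / (eta rho(F*) - delta), the second equilibrium line."""
    denom = params.eta * float(scenario.rho(F_star)) - params.delta
    if denom <= 0:
        raise InfeasibleEquilibriumError(
            f"eta*rho(F*)={denom + params.delta:.6g} <= delta={params.delta:.6g} "
            f"at F*={F_star:.6g}"
        )
    return F_star * float(scenario.nu(F_star)) / denom


def equilibrium_residual(E_star, F_star, params, scenario) -> float:
    """Max absolute residual of the two equilibrium lines (relative scale)."""
    rho = float(scenario.rho(F_star))
    nu = float(scenario.nu(F_star))
    arg = params.eta * rho / params.delta
    if arg <= 0:
        return math.inf
    r1 = abs(nu - math.log(arg) / params.T) / max(nu, 1.0)
    r2 = abs(E_star - E_from_F(F_star, params, scenario)) / max(E_star, 1.0)
    return max(r1, r2)


def _attach(eq: Equilibrium, params, scenario, tol=1e-10) -> Equilibrium:
    eq.residual = (
        0.0 if eq.is_trivial else equilibrium_residual(eq.E_star, eq.F_star, params, scenario)
    )
    if not eq.is_trivial and eq.residual > tol:
        raise RuntimeError(
            f"equilibrium residual {eq.residual:.3g} above tolerance on branch {eq.branch}"
        )
    return eq


def _trivial() -> Equilibrium:
    return Equilibrium(0.0, 0.0, "trivial")


def _unimodal_roots(g: Callable[[float], float], rhs: float, xmax: float,
                    x_hi: float) -> tuple:
    """Roots of g(x) = rhs for unimodal g rising to g(xmax) then falling.

    Returns (kind, roots): kind in {"none", "tangent", "two"}.  Deterministic
    bracketed Brent on the two monotone segments [eps, xmax], [xmax, x_hi].
    """
    gmax = g(xmax)
    if rhs > gmax * (1.0 + TANGENT_RTOL):
        return "none", ()
    if abs(gmax - rhs) <= TANGENT_RTOL * abs(rhs):
        return "tangent", (xmax,)
    f = lambda x: g(x) - rhs
    eps = xmax * 1e-15
    lo = brentq(f, eps, xmax, xtol=1e-300, rtol=F_RTOL)
    while g(x_hi) > rhs:  # widen until the falling segment crosses rhs
        x_hi *= 2.0
        if x_hi > 1e12:
            raise RuntimeError("failed to bracket the upper equilibrium root")
    hi = brentq(f, xmax, x_hi, xtol=1e-300, rtol=F_RTOL)
    for x in (lo, hi):
        if abs(f(x)) > G_ATOL * max(1.0, abs(rhs)):
            raise RuntimeError(f"g-residual {f(x):.3g} above tolerance at root {x:.6g}")
    return "two", (lo, hi)


# ---------------------------------------------------------------------------
# scenario solvers
# ---------------------------------------------------------------------------

def solve_ricker(params: ModelParams, scenario: Optional[Scenario] = None) -> List[Equilibrium]:
    """Equilibria for Ricker attachment with linear grooming.

    Solves x exp(-(1/c + mu T) x) = delta (eta p)^-1 e^{mu0 T}.  Returns the
    trivial equilibrium plus 0, 1 (``critical``, at a tangency) or 2
    positive equilibria; when two exist the roots bracket (1/c + mu T)^-1.
    """
    from .behaviours import make_scenario

    if scenario is None:
        scenario = make_scenario("ricker_linear", params)
    a = 1.0 / params.c + params.mu * params.T
    rhs = params.delta / (params.eta * params.p) * math.exp(params.mu0 * params.T)
    g = lambda x: x * math.exp(-a * x)
    kind, roots = _unimodal_roots(g, rhs, 1.0 / a, 100.0 * max(params.c, 1.0 / a))
    out = [_trivial()]
    if kind == "tangent":
        out.append(_attach(Equilibrium(E_from_F(roots[0], params, scenario),
                                       roots[0], "critical"), params, scenario))
    elif kind == "two":
        for x, branch in zip(roots, ("minus", "plus")):
            out.append(_attach(Equilibrium(E_from_F(x, params, scenario), x, branch),
                               params, scenario))
    return out


def holling3_inverse(rho_star: float, r: float, j: float) -> tuple:
    """Closed-form inversion of r F/(1 + F^2/j^2) = rho* for F > 0.

    The quadratic (rho*/j^2) F^2 - r F + rho* = 0 gives

        F = ( r/rho* -+ sqrt( (r/rho*)^2 - 4 j^-2 ) ) / (2 j^-2),

    real iff rho* <= r j / 2 (equality: the double root F = j).  Evaluated
    in the cancellation-free equivalent form (larger root by the plus
    branch, smaller via the product of roots F- F+ = j^2), which matters
    when rho* is far below the curve maximum.  Returns (F_minus, F_plus).
    """
    if rho_star <= 0:
        raise ValueError("rho* must be positive")
    b = r / rho_star
    disc = b * b - 4.0 / (j * j)
    if disc < 0:
        if disc > -TANGENT_RTOL * b * b:
            disc = 0.0
        else:
            raise ValueError(f"rho*={rho_star:.6g} exceeds the maximum r j/2 = {r * j / 2:.6g}")
    s = math.sqrt(disc)
    hi = (b + s) * (j * j) / 2.0
    return (j * j) / hi, hi


def solve_reactive(params: ModelParams, scenario: Optional[Scenario] = None) -> List[Equilibrium]:
    """Equilibria for Holling-III attachment with biting-reactive grooming.

    First solves g2(rho) = rho exp(-k T rho) = delta/eta for the attachment
    levels rho-* < (kT)^-1 < rho+* (0, 1 or 2 roots), then inverts
    rho(F) = rho* in closed form for every root with rho* <= r j/2.  With
    four positive equilibria the ordering is
    F-- < F+- < j < F++ < F-+ (first sign: rho branch, second: F root).
    """
    from .behaviours import make_scenario

    if scenario is None:
        scenario = make_scenario("holling3_reactive", params)
    kT = params.k * params.T
    rhs = params.delta / params.eta
    g2 = lambda rho: rho * math.exp(-kT * rho)
    kind, rho_roots = _unimodal_roots(g2, rhs, 1.0 / kT, 100.0 / kT)
    out = [_trivial()]
    if kind == "none":
        return out
    rho_max = params.r * params.j / 2.0
    labels = {0: ("minus_minus", "minus_plus"), 1: ("plus_minus", "plus_plus")}
    if kind == "tangent":
        rho_roots = (rho_roots[0],)
    for i, rho_star in enumerate(rho_roots):
        if rho_star > rho_max * (1.0 + TANGENT_RTOL):
            continue
        lo, hi = holling3_inverse(rho_star, params.r, params.j)
        if hi - lo <= TANGENT_RTOL * params.j:  # discriminant ~ 0: F = j
            out.append(_attach(Equilibrium(E_from_F(params.j, params, scenario),
                                           params.j, "critical"), params, scenario))
            continue
        for F, branch in zip((lo, hi), labels.get(i, ("critical", "critical"))):
            out.append(_attach(Equilibrium(E_from_F(F, params, scenario), F, branch),
                               params, scenario))
    out.sort(key=lambda e: e.F_star)
    return out


def solve_monotone(params: ModelParams, scenario: Optional[Scenario] = None) -> List[Equilibrium]:
    """Equilibria for decreasing attachment p e^{-F/c} with linear grooming.

    The reduced equation mu F + mu0 = (1/T)(ln(eta p/delta) - F/c) is
    strictly monotone, so there is a unique positive equilibrium iff
    R0 = p eta e^{-mu0 T}/delta > 1, found by bracketed root finding.
    """
    from .behaviours import make_scenario

    if scenario is None:
        scenario = make_scenario("monotone", params)
    out = [_trivial()]
    if basic_reproduction_number(params) <= 1.0:
        return out
    T = params.T

    def f(F):
        return float(scenario.nu(F)) - math.log(
            params.eta * float(scenario.rho(F)) / params.delta
        ) / T

    F_hi = params.c
    while f(F_hi) < 0:
        F_hi *= 2.0
        if F_hi > 1e12:
            raise RuntimeError("failed to bracket the monotone equilibrium")
    F_star = brentq(f, 0.0, F_hi, xtol=1e-300, rtol=F_RTOL)
    out.append(_attach(Equilibrium(E_from_F(F_star, params, scenario), F_star, "plus"),
                       params, scenario))
    return out


def solve_equilibria(params: ModelParams, scenario: Scenario) -> List[Equilibrium]:
    """Dispatch to the scenario's solver (constant has none beyond trivial)."""
    if scenario.tag == "ricker_linear":
        return solve_ricker(params, scenario)
    if scenario.tag == "holling3_reactive":
        return solve_reactive(params, scenario)
    if scenario.tag == "monotone":
        return solve_monotone(params, scenario)
    if scenario.tag == "constant":
        # positive equilibria exist only on the measure-zero critical manifold
        return [_trivial()]
    raise ValueError(f"no equilibrium solver for scenario {scenario.tag!r}")


def tangency_gap(params: ModelParams, scenario: Scenario) -> float:
    """Signed distance to the fold: g_max - rhs of the equilibrium equation.

    Positive means the positive-equilibrium pair exists (the unimodal
    maximum clears the right-hand side); the zero crossing is the fold
    (saddle-node) point used by the bifurcation scan.
    """
    if scenario.tag == "ricker_linear":
        a = 1.0 / params.c + params.mu * params.T
        rhs = params.delta / (params.eta * params.p) * math.exp(params.mu0 * params.T)
        return 1.0 / (math.e * a) - rhs
    if scenario.tag == "holling3_reactive":
        kT = params.k * params.T
        return 1.0 / (math.e * kT) - params.delta / params.eta
    raise ValueError(f"tangency condition undefined for scenario {scenario.tag!r}")


# ---------------------------------------------------------------------------
# trivial state and the constant-scenario critical case
# ---------------------------------------------------------------------------

def trivial_stability(params: ModelParams, scenario: Scenario) -> str:
    """Stability of the extinction state (0, 0).

    Compares delta with rho(0) eta e^{-nu(0) T}: ``stable`` when delta is
    larger, ``unstable`` when smaller, ``critical`` at equality.  For the
    Ricker and Holling-III families rho(0) = 0, so extinction is always
    locally stable.
    """
    growth = float(scenario.rho(0.0)) * params.eta * math.exp(-float(scenario.nu(0.0)) * params.T)
    if math.isclose(growth, params.delta, rel_tol=1e-12):
        return "critical"
    return "stable" if params.delta > growth else "unstable"


def critical_case_limit(history_E: Union[Callable[[float], float], Sequence, "np.ndarray"],
                        params: ModelParams) -> float:
    """Asymptotic-constancy limit E_c of the constant scenario at criticality.

    When eta p = delta e^{mu0 T} (R0 = 1) every solution of the engorged-tick
    equation converges to the history-dependent constant

        E_c = ( E(0) + delta * int_{-tau-T}^0 E(s) ds ) / (1 + delta (tau + T)).

    ``history_E`` is either a callable on [-tau-T, 0] (adaptive quadrature)
    or an array of values on a uniform grid over that interval (Simpson).
    """
    crit = params.eta * params.p - params.delta * math.exp(params.mu0 * params.T)
    if abs(crit) > 1e-9 * params.delta * math.exp(params.mu0 * params.T):
        raise ValueError(
            "critical_case_limit requires the critical parameterization "
            "eta p = delta e^{mu0 T}"
        )
    L = params.tau + params.T
    if callable(history_E):
        E0 = float(history_E(0.0))
        integral, _ = quad(history_E, -L, 0.0, limit=200)
    else:
        values = np.asarray(history_E, dtype=float)
        E0 = float(values[-1])
        integral = float(simpson(values, x=np.linspace(-L, 0.0, values.size)))
    return (E0 + params.delta * integral) / (1.0 + params.delta * L)
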