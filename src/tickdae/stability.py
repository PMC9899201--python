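"""Linearized stability of the coupled algebraic-delay tick model.

Linearizing about a nontrivial equilibrium (E*, F*) and inserting an
exponential ansatz yields a 2x2 spectral problem whose entries a_ij(lambda)
mix exponential delay factors with distributed-delay kernels; its
determinant is the characteristic function.  Locating the rightmost zero of
that transcendental function in general is out of reach analytically, so the
classification here follows the small-feeding-duration perturbation: with
T = eps treated as a small parameter (the feeding week against a multi-year
life cycle), the leading eigenvalue coefficient lambda0 solves a scalar
transcendental equation whose sign is decided by closed-form quantities:

* Ricker attachment + linear grooming: sign(lambda0) > 0 exactly on the
  lower branch F0 < c and < 0 on the upper branch F0 > c — bi-stability of
  extinction with the upper equilibrium;
* Holling-III attachment + biting-reactive grooming (k of order 1/eps,
  k0 = k*T): lambda0 solves
  lambda0 + delta - delta e^{-lambda0 tau} + A e^{-lambda0 tau} = 0 with

      A = eta^2 E0 rho'0 e^{-k0 rho0} (1 - k0 rho0)(1 - e^{-k0 rho0})
          / ( k0 (eta E0 rho'0 e^{-k0 rho0} - 1) ),

  and, under the positive-feedback hypotheses (delta > A and
  eta E0 rho'0 < min{e^{k0 rho0}, rho0 k0/(k0 rho0 + e^{-k0 rho0} - 1)}),
  the equilibrium is stable iff A > 0.  Across the four branches the signs
  alternate (-, +, -, +), giving quadri-stability: extinction plus two
  attracting positive states separated by two repelling ones.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np
from scipy.optimize import brentq

from .behaviours import ModelParams, Scenario, make_scenario
from .equilibria import Equilibrium, solve_reactive, solve_ricker, trivial_stability

__all__ = [
    "CharEntries",
    "PerturbationResult",
    "char_entries",
    "char_det",
    "sign_lambda0_ricker",
    "A_value",
    "classify_reactive",
    "classify_ricker",
    "real_axis_roots",
    "contour_root_count",
    "SIGN_TOL",
]

#: |A| or |lambda0| below this -> verdict "undetermined" (numerical boundary)
SIGN_TOL = 1e-9


def _phi(s: complex, T: float) -> complex:
    """(1 - exp(-s T)) / s, with the removable singularity at s = 0."""
    x = s * T
    if abs(x) < 1e-8:
        return T * (1.0 - x / 2.0 + x * x / 6.0)
    return (1.0 - cmath.exp(-x)) / s


def _dphi(s: complex, T: float) -> complex:
    """d/ds of (1 - exp(-s T))/s."""
    if abs(s * T) < 1e-6:
        return -T * T / 2.0 + s * T ** 3 / 3.0
    e = cmath.exp(-s * T)
    return (T * e * s - (1.0 - e)) / (s * s)


@dataclass(frozen=True)
class CharEntries:
    """The four entries a_ij(lambda) of the linearized spectral problem.

    Each is a callable of a complex spectral variable, finite for
    Re(lambda) > -nu(F*); the removable singularities at lambda = 0 (and at
    lambda = -nu(F*) in the distributed kernels) are replaced by their
    limits.
    """

    a11: Callable[[complex], complex]
    a12: Callable[[complex], complex]
    a21: Callable[[complex], complex]
    a22: Callable[[complex], complex]


@dataclass
class PerturbationResult:
    """Output of the small-T eigenvalue expansion at one equilibrium.

    ``lambda0`` is the leading eigenvalue coefficient (1/day); ``A`` the
    composite feedback constant of the reactive-grooming case (None for the
    Ricker case, where the F0-vs-c rule applies directly).  The series
    coefficients (F0, F1, E0, E1, rho0, rho1, nu0, nu1, rho_tilde0) document
    the expansion; ``condition45_holds`` and ``delta_gt_A`` record the
    classification hypotheses, and the verdict is gated on them.
    """

    verdict: str
    lambda0: Optional[float] = None
    A: Optional[float] = None
    F0: float = math.nan
    F1: float = math.nan
    E0: float = math.nan
    E1: float = math.nan
    rho0: float = math.nan
    rho1: float = math.nan
    nu0: float = math.nan
    nu1: float = math.nan
    rho_tilde0: float = math.nan
    condition45_holds: bool = True
    delta_gt_A: bool = True


# ---------------------------------------------------------------------------
# characteristic system
# ---------------------------------------------------------------------------

def char_entries(equilibrium: Equilibrium, params: ModelParams,
                 scenario: Scenario) -> CharEntries:
    """Entries of the characteristic matrix at a nontrivial equilibrium.

    With rho = rho(F*), dr = rho'(F*), nu = nu(F*), dn = nu'(F*) and
    Phi(s) = (1 - e^{-sT})/s:

        a11 = -delta + eta e^{-nu T} rho e^{-lambda (tau+T)}
        a12 = eta e^{-nu T} E* [ dr e^{-lambda T} - rho dn Phi(lambda) ]
        a21 = eta rho e^{-lambda tau} Phi(nu + lambda)
        a22 = eta E* dr Phi(nu+lambda)
              + eta rho E* dn (Phi(nu+lambda) - Phi(nu)) / lambda - 1

    (the a22 form groups the two 1/lambda kernels of the distributed delay
    so the lambda -> 0 limit is the derivative of Phi).
    """
    if equilibrium.is_trivial:
        raise ValueError(
            "the trivial equilibrium has a scalar criterion; use trivial_stability"
        )
    Fs, Es = equilibrium.F_star, equilibrium.E_star
    rho = float(scenario.rho(Fs))
    dr = float(scenario.drho(Fs))
    nu = float(scenario.nu(Fs))
    dn = float(scenario.dnu(Fs))
    eta, delta, T, tau = params.eta, params.delta, params.T, params.tau
    surv = math.exp(-nu * T)

    def a11(lam):
        return -delta + eta * surv * rho * cmath.exp(-lam * (tau + T))

    def a12(lam):
        return eta * surv * Es * (dr * cmath.exp(-lam * T) - rho * dn * _phi(lam, T))

    def a21(lam):
        return eta * rho * cmath.exp(-lam * tau) * _phi(nu + lam, T)

    def a22(lam):
        if abs(lam) < 1e-8:
            kernel = _dphi(nu, T)  # lambda -> 0 limit of the grouped 1/lambda term
        else:
            kernel = (_phi(nu + lam, T) - _phi(nu, T)) / lam
        return eta * Es * dr * _phi(nu + lam, T) + eta * rho * Es * dn * kernel - 1.0

    return CharEntries(a11, a12, a21, a22)


def char_det(lam: complex, entries: CharEntries) -> complex:
    """Characteristic determinant (lambda - a11)(-a22) - (-a12)(-a21).

    Zeros of this function are the characteristic values of the linearized
    coupled system.
    """
    return (lam - entries.a11(lam)) * (-entries.a22(lam)) - entries.a12(lam) * entries.a21(lam)


def real_axis_roots(entries: CharEntries, lo: float, hi: float, n: int = 2001) -> List[float]:
    """Real zeros of the characteristic determinant on [lo, hi].

    Dense sign-change scan followed by Brent refinement.  A diagnostic, not
    a spectral certification: complex roots are invisible here.
    """
    xs = np.linspace(lo, hi, n)
    vals = np.array([char_det(x, entries).real for x in xs])
    roots = []
    for i in range(n - 1):
        if vals[i] == 0.0:
            roots.append(float(xs[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(lambda x: char_det(x, entries).real, xs[i], xs[i + 1]))
    return roots


def contour_root_count(entries: CharEntries, re_range: tuple, im_range: tuple,
                       n: int = 4000) -> int:
    """Argument-principle zero count of char_det over a rectangle.

    Winding number of the determinant image along the rectangle boundary
    (counter-clockwise, n points per side).  The user must choose a
    rectangle whose boundary avoids zeros.
    """
    r0, r1 = re_range
    i0, i1 = im_range
    corners = [complex(r0, i0), complex(r1, i0), complex(r1, i1), complex(r0, i1)]
    pts = []
    for a, b in zip(corners, corners[1:] + corners[:1]):
        pts.extend(a + (b - a) * t for t in np.linspace(0.0, 1.0, n, endpoint=False))
    vals = np.array([char_det(z, entries) for z in pts])
    args = np.angle(vals)
    dtheta = np.diff(np.concatenate([args, args[:1]]))
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    return int(round(dtheta.sum() / (2 * np.pi)))


# ---------------------------------------------------------------------------
# small-T perturbation classifiers
# ---------------------------------------------------------------------------

def _warn_small_T(params):
    frac = params.T / (params.tau + params.T)
    if frac > 0.1:
        warnings.warn(
            f"feeding duration is not small: T/(tau+T) = {frac:.3f} > 0.1; "
            "the perturbation verdict is first-order in T",
            stacklevel=3,
        )


def _solve_scalar_transcendental(f: Callable[[float], float], sign: int) -> float:
    """Root of f with known sign: bracket outward from 0 toward sign*inf."""
    a, b = 0.0, sign * 1e-6
    fa = f(a)
    for _ in range(200):
        if fa * f(b) <= 0:
            lo, hi = (a, b) if a < b else (b, a)
            return brentq(f, lo, hi, rtol=1e-14)
        b *= 2.0
        if abs(b) > 1e6:
            break
    raise RuntimeError("failed to bracket the reduced eigenvalue equation")


def sign_lambda0_ricker(equilibrium: Equilibrium, params: ModelParams) -> PerturbationResult:
    """Leading-order eigenvalue sign for Ricker attachment + linear grooming.

    The reduced equation -(F0/c) lambda0 + delta e^{-lambda0 tau} =
    (F0/c) delta has a positive root iff F0 < c (unstable lower branch) and
    a negative one iff F0 > c (stable upper branch).  Reports lambda0 by
    bracketed root finding together with the first-order series coefficients
    of the equilibrium in T.
    """
    if equilibrium.is_trivial:
        raise ValueError("use trivial_stability for the extinction state")
    _warn_small_T(params)
    F0 = equilibrium.F_star
    c, delta, tau = params.c, params.delta, params.tau
    p, mu, mu0 = params.p, params.mu, params.mu0
    nu0 = mu0 + mu * F0
    rho0 = p * F0 * math.exp(-F0 / c)
    res = PerturbationResult(
        verdict="undetermined",
        F0=F0,
        E0=F0 / delta,  # leading coefficient of T * E(T)
        rho0=rho0,
        rho1=nu0 * rho0,
        nu0=nu0,
        rho_tilde0=p * math.exp(-F0 / c) * (1.0 - F0 / c),
    )
    if abs(F0 - c) < SIGN_TOL * c:
        return res
    res.F1 = nu0 * F0 / (1.0 - F0 / c)
    res.nu1 = mu * res.F1
    res.E1 = nu0 * F0 / delta * (c / (c - F0) - 0.5)
    ratio = F0 / c
    f = lambda lam: -ratio * lam + delta * math.exp(-lam * tau) - ratio * delta
    sign = 1 if F0 < c else -1
    res.lambda0 = _solve_scalar_transcendental(f, sign)
    if abs(res.lambda0) < SIGN_TOL:
        return res
    res.verdict = "unstable" if res.lambda0 > 0 else "stable"
    return res


def A_value(equilibrium: Equilibrium, params: ModelParams) -> PerturbationResult:
    """Feedback constant A and verdict for the biting-reactive grooming case.

    Computes, with k0 = k T, rho0 = rho(F0), rho'0 = rho'(F0) and
    E0 = F0 k0 / (eta (1 - e^{-k0 rho0})):

        A = eta^2 E0 rho'0 e^{-k0 rho0} (1-k0 rho0)(1-e^{-k0 rho0})
            / ( k0 (eta E0 rho'0 e^{-k0 rho0} - 1) ).

    Verdict stable iff A > 0, unstable iff A < 0, gated to
    ``undetermined`` when either hypothesis of the classification (delta > A, or
    eta E0 rho'0 < min{e^{k0 rho0}, rho0 k0/(k0 rho0 + e^{-k0 rho0} - 1)})
    fails or |A| is within tolerance of zero.  lambda0 is the real root of
    lambda0 + delta - (delta - A) e^{-lambda0 tau} = 0.
    """
    if equilibrium.is_trivial:
        raise ValueError("use trivial_stability for the extinction state")
    _warn_small_T(params)
    F0 = equilibrium.F_star
    r, j, eta, delta, tau = params.r, params.j, params.eta, params.delta, params.tau
    k0 = params.k * params.T  # adopted reading of the k = O(1/T) scaling; k1 = 0
    q = (F0 / j) ** 2
    rho0 = r * F0 / (1.0 + q)
    tr0 = r * (1.0 - q) / (1.0 + q) ** 2
    em = math.exp(-k0 * rho0)
    E0 = F0 * k0 / (eta * (1.0 - em))
    A = (eta ** 2 * E0 * tr0 * em * (1.0 - k0 * rho0) * (1.0 - em)) / (
        k0 * (eta * E0 * tr0 * em - 1.0)
    )
    cond45 = eta * E0 * tr0 < min(
        1.0 / em, rho0 * k0 / (k0 * rho0 + em - 1.0)
    )
    res = PerturbationResult(
        verdict="undetermined",
        A=A,
        F0=F0,
        F1=0.0,  # k1 = 0 makes the first-order corrections vanish
        E0=E0,
        E1=0.0,
        rho0=rho0,
        rho1=0.0,
        nu0=params.k * rho0,
        nu1=0.0,
        rho_tilde0=tr0,
        condition45_holds=cond45,
        delta_gt_A=delta > A,
    )
    if not (cond45 and res.delta_gt_A) or abs(A) < SIGN_TOL:
        return res
    f = lambda lam: lam + delta - (delta - A) * math.exp(-lam * tau)
    res.lambda0 = _solve_scalar_transcendental(f, 1 if A < 0 else -1)
    res.verdict = "unstable" if A < 0 else "stable"
    return res


# ---------------------------------------------------------------------------
# whole-system classification
# ---------------------------------------------------------------------------

def classify_reactive(params: ModelParams) -> List[Equilibrium]:
    """All equilibria of the reactive-grooming scenario with verdicts filled.

    With four positive equilibria and the classification hypotheses satisfied the
    census is: trivial stable (rho(0) = 0), F-- unstable, F+- stable,
    F++ unstable, F-+ stable.  With fewer equilibria each existing branch is
    classified through its own A value.
    """
    scenario = make_scenario("holling3_reactive", params)
    eqs = solve_reactive(params, scenario)
    for eq in eqs:
        if eq.is_trivial:
            eq.stability = trivial_stability(params, scenario)
        else:
            eq.stability = A_value(eq, params).verdict
    return eqs


def classify_ricker(params: ModelParams) -> List[Equilibrium]:
    """All equilibria of the Ricker + linear-grooming scenario with verdicts."""
    scenario = make_scenario("ricker_linear", params)
    eqs = solve_ricker(params, scenario)
    for eq in eqs:
        if eq.is_trivial:
            eq.stability = trivial_stability(params, scenario)
        elif eq.branch == "critical":
            eq.stability = "undetermined"
        else:
            eq.stability = sign_lambda0_ricker(eq, params).verdict
    return eqs
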