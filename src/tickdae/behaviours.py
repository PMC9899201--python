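"""Behavioural rate functions and model parameters for the tick-host interface.

The model couples two state variables at the nymphal stage: the engorged
ticks ``E(t)`` on the ground and the feeding ticks ``F(t)`` on hosts.  Two
behavioural functions close the system:

* the attachment (fixation) rate ``rho(F)`` of questing ticks, which may be
  density dependent — cooperative feeding raises it at low feeding loads,
  skin-capacity limits lower it at high loads;
* the grooming (drop-off) rate ``nu(F)`` of the host, which may respond to
  the feeding load directly or to the biting (attachment) intensity.

Four named scenarios are supported, each pairing one ``rho`` family with one
``nu`` family:

========================  =============================  ====================
tag                       rho(F)                         nu(F)
========================  =============================  ====================
``constant``              p                              mu0
``monotone``              p * exp(-F/c)                  mu*F + mu0
``ricker_linear``         p * F * exp(-F/c)              mu*F + mu0
``holling3_reactive``     r*F / (1 + F^2/j^2)            k * rho(F)
========================  =============================  ====================

Rates are per day; F, E, c, j are tick counts; tau and T are days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Union

import numpy as np

__all__ = [
    "ModelParams",
    "Scenario",
    "UnsetParameterError",
    "make_scenario",
    "rho_ricker",
    "rho_holling3",
    "rho_expdecay",
    "nu_linear",
    "nu_reactive",
    "basic_reproduction_number",
    "load_config",
    "SCENARIO_TAGS",
]

SCENARIO_TAGS = ("constant", "monotone", "ricker_linear", "holling3_reactive")

#: Parameter fields that may legitimately be left unset (scenario dependent).
_OPTIONAL_FIELDS = ("eta1", "eta2", "sigma", "p", "c", "mu", "mu0", "k", "r", "j")
_REQUIRED_FIELDS = ("delta", "tau", "T")
_ALL_FIELDS = _REQUIRED_FIELDS + ("eta",) + _OPTIONAL_FIELDS


class UnsetParameterError(AttributeError):
    """Raised when a scenario needs a parameter that was never supplied."""


@dataclass(frozen=True, repr=False)
class ModelParams:
    """All life-cycle rates, delays and behaviour-function parameters.

    Parameters
    ----------
    delta : float
        Exit rate of engorged nymphs (1/day); strictly positive.
    tau : float
        Development delay tau = tau1 + tau2, engorged nymph back to questing
        nymph through the rest of the life cycle (days).
    T : float
        Average feeding duration on the host (days).
    eta : float, optional
        Composite reproduction/survival factor eta = eta2 * sigma * eta1.
        Either supplied directly or derived from ``eta1``, ``eta2``,
        ``sigma``; supplying both is allowed only when consistent.
    eta1, eta2, sigma : float, optional
        Stage survival probabilities (engorged nymph -> egg-laying adult,
        egg -> questing nymph) and egg production rate (eggs/day).
    p : float, optional
        Attachment scale.  For the ``constant`` scenario this is the
        attachment rate itself; for ``monotone``/``ricker_linear`` it is the
        scale (resp. slope at zero) of the attachment function.
    c : float, optional
        Attachment capacity (ticks): the feeding load at which the Ricker
        attachment rate peaks.
    mu, mu0 : float, optional
        Grooming slope (1/(tick*day)) and baseline grooming rate (1/day).
    k : float, optional
        Grooming-per-attachment coefficient (days): nu = k * rho.
    r, j : float, optional
        Holling type-III attack rate (1/(tick*day)) and shape parameter
        (ticks); rho peaks at r*j/2 when F = j.

    Accessing a field that was never supplied raises
    :class:`UnsetParameterError` — scenario/parameter mismatches fail fast.
    """

    delta: float
    tau: float
    T: float
    eta: float = None
    eta1: float = None
    eta2: float = None
    sigma: float = None
    p: float = None
    c: float = None
    mu: float = None
    mu0: float = None
    k: float = None
    r: float = None
    j: float = None

    def __post_init__(self):
        for name in _REQUIRED_FIELDS:
            v = object.__getattribute__(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        comps = [object.__getattribute__(self, n) for n in ("eta1", "eta2", "sigma")]
        eta = object.__getattribute__(self, "eta")
        if all(v is not None for v in comps):
            derived = comps[1] * comps[2] * comps[0]  # eta2 * sigma * eta1
            if eta is None:
                object.__setattr__(self, "eta", derived)
            elif not math.isclose(eta, derived, rel_tol=1e-12):
                raise ValueError(
                    f"eta={eta} inconsistent with eta2*sigma*eta1={derived}"
                )
        if object.__getattribute__(self, "eta") is not None and self.eta <= 0:
            raise ValueError("eta must be strictly positive")
        for name in _OPTIONAL_FIELDS:
            v = object.__getattribute__(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    def __getattribute__(self, name):
        value = object.__getattribute__(self, name)
        if value is None and name in _ALL_FIELDS:
            raise UnsetParameterError(
                f"parameter {name!r} was not supplied for this scenario"
            )
        return value

    def get(self, name, default=None):
        """Return a field without the unset-access check."""
        v = object.__getattribute__(self, name)
        return default if v is None else v

    def replace(self, **changes) -> "ModelParams":
        """A copy with the given fields replaced (used by parameter scans)."""
        kw = {n: object.__getattribute__(self, n) for n in _ALL_FIELDS}
        # recompute eta from components only if eta itself is not overridden
        if any(n in changes for n in ("eta1", "eta2", "sigma")) and "eta" not in changes:
            kw["eta"] = None
        kw.update(changes)
        return ModelParams(**kw)

    def __repr__(self):
        parts = ", ".join(
            f"{n}={object.__getattribute__(self, n)!r}"
            for n in _ALL_FIELDS
            if object.__getattribute__(self, n) is not None
        )
        return f"ModelParams({parts})"


# ---------------------------------------------------------------------------
# attachment / grooming function families
# ---------------------------------------------------------------------------

def _check_nonneg(F):
    if np.any(np.asarray(F) < 0):
        raise ValueError("feeding-tick count F must be nonnegative")


def rho_ricker(F, p, c):
    """Ricker attachment rate rho(F) = p F exp(-F/c).

    Models cooperative feeding (increasing on (0, c)) limited by host-skin
    capacity (decreasing beyond c); the maximum p*c/e is attained at F = c.
    """
    _check_nonneg(F)
    F = np.asarray(F, dtype=float)
    out = p * F * np.exp(-F / c)
    return float(out) if out.ndim == 0 else out


def rho_holling3(F, r, j):
    """Holling type-III attachment rate rho(F) = r F / (1 + F^2/j^2).

    The maximum r*j/2 is attained at F = j.
    """
    _check_nonneg(F)
    F = np.asarray(F, dtype=float)
    out = r * F / (1.0 + (F / j) ** 2)
    return float(out) if out.ndim == 0 else out


def rho_expdecay(F, p, c):
    """Monotone-decreasing attachment rate rho(F) = p exp(-F/c)."""
    _check_nonneg(F)
    F = np.asarray(F, dtype=float)
    out = p * np.exp(-F / c)
    return float(out) if out.ndim == 0 else out


def nu_linear(F, mu, mu0):
    """Density-dependent grooming rate nu(F) = mu F + mu0."""
    _check_nonneg(F)
    F = np.asarray(F, dtype=float)
    out = mu * F + mu0
    return float(out) if out.ndim == 0 else out


def nu_reactive(F, k, rho: Callable[[float], float]):
    """Grooming reactive to biting: nu(F) = k * rho(F)."""
    _check_nonneg(F)
    F = np.asarray(F, dtype=float)
    out = k * np.asarray(rho(F), dtype=float)
    return float(out) if out.ndim == 0 else out


def basic_reproduction_number(params: ModelParams) -> float:
    """Basic reproduction number R0 = p eta exp(-mu0 T) / delta.

    Expected engorged-nymph output per engorged nymph over one life cycle in
    the constant (or, via rho(0) = p, monotone) scenario: reproduction and
    survival through the cycle times the feeding-survival factor
    exp(-mu0 T), divided by the engorged-stage turnover delta.
    """
    return params.p * params.eta * math.exp(-params.mu0 * params.T) / params.delta


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A (rho, nu) family pair with analytic derivatives.

    Derivatives are carried explicitly so the stability module never
    differentiates numerically at an equilibrium.  The ``*_s`` members are
    unvalidated scalar closures for the simulator's inner loop.
    """

    tag: str
    rho: Callable
    drho: Callable
    nu: Callable
    dnu: Callable
    rho_s: Callable[[float], float]
    nu_s: Callable[[float], float]

    def __repr__(self):
        return f"Scenario({self.tag!r})"


def make_scenario(tag: str, params: ModelParams) -> Scenario:
    """Build the Scenario for ``tag``, pulling the fields it requires.

    Raises :class:`UnsetParameterError` at construction if a needed
    parameter is missing, and ``ValueError`` for an unknown tag.
    """
    if tag == "constant":
        p, mu0 = params.p, params.mu0

        def rho(F):
            _check_nonneg(F)
            return p * np.ones_like(np.asarray(F, dtype=float)) if np.ndim(F) else p

        def nu(F):
            _check_nonneg(F)
            return mu0 * np.ones_like(np.asarray(F, dtype=float)) if np.ndim(F) else mu0

        zero = lambda F: np.zeros_like(np.asarray(F, dtype=float)) if np.ndim(F) else 0.0
        return Scenario(tag, rho, zero, nu, zero, lambda F: p, lambda F: mu0)

    if tag == "monotone":
        p, c, mu, mu0 = params.p, params.c, params.mu, params.mu0
        if c <= 0:
            raise ValueError("capacity c must be strictly positive")
        rho = lambda F: rho_expdecay(F, p, c)
        drho = lambda F: -rho_expdecay(F, p, c) / c
        nu = lambda F: nu_linear(F, mu, mu0)
        dnu = lambda F: mu + 0.0 * np.asarray(F, dtype=float)
        return Scenario(
            tag, rho, drho, nu, dnu,
            lambda F: p * math.exp(-F / c),
            lambda F: mu * F + mu0,
        )

    if tag == "ricker_linear":
        p, c, mu, mu0 = params.p, params.c, params.mu, params.mu0
        if c <= 0:
            raise ValueError("capacity c must be strictly positive")
        rho = lambda F: rho_ricker(F, p, c)

        def drho(F):
            _check_nonneg(F)
            F = np.asarray(F, dtype=float)
            out = p * (1.0 - F / c) * np.exp(-F / c)
            return float(out) if out.ndim == 0 else out

        nu = lambda F: nu_linear(F, mu, mu0)
        dnu = lambda F: mu + 0.0 * np.asarray(F, dtype=float)
        return Scenario(
            tag, rho, drho, nu, dnu,
            lambda F: p * F * math.exp(-F / c),
            lambda F: mu * F + mu0,
        )

    if tag == "holling3_reactive":
        r, j, k = params.r, params.j, params.k
        if j <= 0:
            raise ValueError("Holling shape parameter j must be strictly positive")
        rho = lambda F: rho_holling3(F, r, j)

        def drho(F):
            _check_nonneg(F)
            F = np.asarray(F, dtype=float)
            q = (F / j) ** 2
            out = r * (1.0 - q) / (1.0 + q) ** 2
            return float(out) if out.ndim == 0 else out

        nu = lambda F: nu_reactive(F, k, rho)

        def dnu(F):
            out = k * np.asarray(drho(F), dtype=float)
            return float(out) if out.ndim == 0 else out

        jj = j * j

        def rho_s(F):
            return r * F / (1.0 + F * F / jj)

        return Scenario(tag, rho, drho, nu, dnu, rho_s, lambda F: k * rho_s(F))

    raise ValueError(f"unknown scenario tag {tag!r}; expected one of {SCENARIO_TAGS}")


# ---------------------------------------------------------------------------
# key-value configuration files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = set(_ALL_FIELDS) | {"scenario"}


def load_config(path: Union[str, Path]):
    """Parse a ``key = value`` text file into (ModelParams, Scenario).

    Lines starting with ``#`` are comments.  Recognised keys are the
    parameter names of :class:`ModelParams` plus ``scenario``; unknown keys
    are rejected.  Units: days and tick counts.
    """
    values = {}
    tag = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key == "scenario":
            tag = val
        else:
            values[key] = float(val)
    if tag is None:
        raise ValueError(f"{path}: missing required key 'scenario'")
    params = ModelParams(**values)
    return params, make_scenario(tag, params)
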