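"""Single-gene transcription kinetics.

Implements the full mass-action binding scheme for one gene regulated by a
transcription factor (TF), its quasi-steady-state (Michaelis–Menten)
reduction, and thermodynamic state-ensemble (TSE) production-rate laws for
the common cis-regulatory logics: single activator/repressor with
cooperativity, independent OR, competitive OR and multiplicative AND gates.

The binding scheme tracks three state variables: the bound-operator
fraction ``D1`` (with ``D0 + D1 = 1``), the free TF concentration ``X`` and
the transcript concentration ``Y``::

    dD1/dt = k_on (1 - D1) X - k_off D1
    dX/dt  = -dD1/dt
    dY/dt  = k_t D1 - lam Y

No basal transcription is assumed: production requires a bound operator.
All quantities are nondimensional; by convention ``k_t = lam = 1`` scales
transcript levels to a unit maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    IntegrationError,
    InvalidParameterError,
    MissingInputError,
    NoSteadyStateError,
)

__all__ = [
    "BindingKinetics",
    "RegulatorTerm",
    "CisModule",
    "BindingTrajectory",
    "simulate_binding_ode",
    "steady_state_activation",
    "tse_rate",
    "qss_discrepancy",
    "hill_occupancy",
    "hill_repression",
]

_LOGICS = ("single", "or_independent", "or_competitive", "and_product")


def hill_occupancy(c: float, K: float, n: float) -> float:
    """Fractional occupancy (C/K)^n / (1 + (C/K)^n) of a cooperative site."""
    x = (c / K) ** n
    return x / (1.0 + x)


def hill_repression(c: float, K: float, n: float) -> float:
    """Repression factor 1 / (1 + (C/K)^n): unity at C=0, half at C=K."""
    return 1.0 / (1.0 + (c / K) ** n)


@dataclass(frozen=True)
class BindingKinetics:
    """Rate constants of the binding/transcription/decay scheme.

    Parameters
    ----------
    k_on : float
        TF–operator binding rate (per concentration per time).
    k_off : float
        Unbinding rate (per time).
    k_t : float
        Maximal transcription rate from the bound state (per time).
    lam : float
        First-order transcript decay rate (per time).
    """

    k_on: float
    k_off: float
    k_t: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_t", "lam"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {v!r}"
                )

    @property
    def K(self) -> float:
        """Dissociation constant k_off / k_on (binding strength measure)."""
        if self.k_on <= 0:
            raise InvalidParameterError(
                "dissociation constant undefined for k_on = 0"
            )
        return self.k_off / self.k_on


@dataclass(frozen=True)
class RegulatorTerm:
    """One TF input to a cis-regulatory module.

    ``K`` is the dissociation constant (lower = stronger binding), ``n`` the
    Hill coefficient (cooperativity; ``n = 1`` is non-cooperative) and
    ``role`` either ``"activator"`` or ``"repressor"``.
    """

    species: str
    K: float
    n: float = 1.0
    role: str = "activator"

    def __post_init__(self) -> None:
        if not (self.K > 0) or not math.isfinite(self.K):
            raise InvalidParameterError(f"K must be > 0, got {self.K!r}")
        if not (self.n >= 1) or not math.isfinite(self.n):
            raise InvalidParameterError(f"n must be >= 1, got {self.n!r}")
        if self.role not in ("activator", "repressor"):
            raise ConfigurationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class CisModule:
    """Declarative description of one regulatory gate.

    ``logic`` selects how the terms combine:

    - ``single``: exactly one term, classic Hill activation or repression.
    - ``or_independent``: activators on separate sites; the production rate
      is ``k_t`` times the *sum* of occupancies (bounded by ``k_t * #terms``).
    - ``or_competitive``: activators competing for one site;
      ``k_t * S / (1 + S)`` with ``S = sum (C_i/K_i)^n_i``.
    - ``and_product``: product of per-term factors (occupancy for
      activators, repression factor for repressors).
    """

    terms: tuple[RegulatorTerm, ...]
    logic: str = "single"
    k_t: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.logic not in _LOGICS:
            raise ConfigurationError(
                f"unknown logic {self.logic!r}; expected one of {_LOGICS}"
            )
        if self.logic == "single" and len(self.terms) != 1:
            raise ConfigurationError("'single' logic requires exactly 1 term")
        if self.logic in ("or_independent", "or_competitive"):
            if len(self.terms) < 2:
                raise ConfigurationError(f"{self.logic} requires >= 2 terms")
            if any(t.role != "activator" for t in self.terms):
                raise ConfigurationError(f"{self.logic} terms must all be activators")
        if not self.terms:
            raise ConfigurationError("a cis module needs at least one term")
        if not (self.k_t >= 0) or not math.isfinite(self.k_t):
            raise InvalidParameterError(f"k_t must be finite >= 0, got {self.k_t!r}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "logic": self.logic,
            "k_t": self.k_t,
            "terms": [
                {"species": t.species, "K": t.K, "n": t.n, "role": t.role}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CisModule":
        terms = tuple(RegulatorTerm(**t) for t in d["terms"])
        return cls(terms=terms, logic=d.get("logic", "single"),
                   k_t=d.get("k_t", 1.0))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CisModule":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class BindingTrajectory:
    """Sampled solution of the full binding ODE system."""

    times: np.ndarray
    D1: np.ndarray
    X_free: np.ndarray
    Y: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "D1": self.D1, "X_free": self.X_free, "Y": self.Y}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_binding_ode(
    kin: BindingKinetics,
    X_total: float,
    D1_0: float = 0.0,
    Y_0: float = 0.0,
    t_end: float = 50.0,
    n_samples: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> BindingTrajectory:
    """Integrate the full mass-action binding scheme.

    The system conserves total activator: ``X_free(t) + D1(t)`` equals
    ``X_total + D1_0`` along the trajectory (to solver tolerance).  Uses a
    stiff-capable implicit method because binding typically runs orders of
    magnitude faster than transcription.
    """
    if not math.isfinite(X_total) or X_total < 0:
        raise InvalidParameterError(f"X_total must be finite >= 0, got {X_total!r}")
    if not 0.0 <= D1_0 <= 1.0:
        raise InvalidParameterError(f"D1_0 must lie in [0, 1], got {D1_0!r}")
    if not math.isfinite(Y_0) or Y_0 < 0:
        raise InvalidParameterError(f"Y_0 must be finite >= 0, got {Y_0!r}")
    if not t_end > 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end!r}")

    def rhs(t, y):
        D1, X, Y = y
        dD1 = kin.k_on * (1.0 - D1) * X - kin.k_off * D1
        return (dD1, -dD1, kin.k_t * D1 - kin.lam * Y)

    times = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (D1_0, X_total, Y_0),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"binding ODE integration failed: {sol.message}")
    D1, X, Y = sol.y
    return BindingTrajectory(times=times, D1=D1, X_free=X, Y=Y)


def steady_state_activation(kin: BindingKinetics, X: float, K: float) -> float:
    """Stationary transcript level (k_t/lam) * (X/K) / (1 + X/K).

    This is the depletion-free Michaelis–Menten steady state: monotone
    non-decreasing in ``X``, half-maximal at ``X = K`` and saturating at
    ``k_t / lam``.
    """
    if not K > 0:
        raise InvalidParameterError(f"K must be > 0, got {K!r}")
    if kin.lam <= 0:
        raise NoSteadyStateError("no steady state for lam = 0 (transcripts accumulate)")
    if X < 0:
        raise InvalidParameterError(f"X must be >= 0, got {X!r}")
    r = X / K
    return (kin.k_t / kin.lam) * r / (1.0 + r)


def tse_rate(module: CisModule, concentrations: Mapping[str, float]) -> float:
    """Production rate of a cis module under its configured logic.

    Thermodynamic state-ensemble rate law: the rate is ``k_t`` times the
    equilibrium weight of transcriptionally productive operator states.
    """
    conc = {}
    for t in module.terms:
        if t.species not in concentrations:
            raise MissingInputError(t.species)
        c = concentrations[t.species]
        if c < 0 or not math.isfinite(c):
            raise InvalidParameterError(
                f"concentration of {t.species!r} must be finite >= 0, got {c!r}"
            )
        conc[t.species] = c

    kt = module.k_t
    if module.logic == "single":
        t = module.terms[0]
        c = conc[t.species]
        if t.role == "activator":
            return kt * hill_occupancy(c, t.K, t.n)
        return kt * hill_repression(c, t.K, t.n)

    if module.logic == "or_independent":
        return kt * sum(hill_occupancy(conc[t.species], t.K, t.n) for t in module.terms)

    if module.logic == "or_competitive":
        s = sum((conc[t.species] / t.K) ** t.n for t in module.terms)
        return kt * s / (1.0 + s)

    # and_product
    f = 1.0
    for t in module.terms:
        c = conc[t.species]
        if t.role == "activator":
            f *= hill_occupancy(c, t.K, t.n)
        else:
            f *= hill_repression(c, t.K, t.n)
    return kt * f


def _equilibrium_bound_fraction(kin: BindingKinetics, total: float) -> float:
    """Binding-equilibrium D1 with mass conservation X_free = total - D1.

    Solves k_on (1 - D1)(total - D1) = k_off D1, the smaller root of
    D1^2 - (1 + total + K) D1 + total = 0, which lies in [0, min(1, total)].
    """
    K = kin.K
    b = 1.0 + total + K
    disc = b * b - 4.0 * total
    return (b - math.sqrt(disc)) / 2.0


def qss_discrepancy(
    kin: BindingKinetics,
    X_total: float,
    speed_ratio: float,
    t_end: float = 20.0,
    n_samples: int = 400,
) -> float:
    """Max relative deviation between the full binding ODE and its reduction.

    ``speed_ratio`` jointly scales ``(k_on, k_off)`` relative to ``k_t``,
    probing the quasi-steady-state regime.  The reduced model holds the
    bound fraction at its conservation-consistent binding equilibrium and
    integrates only the transcript equation, which has the closed form of a
    saturating exponential.  Returns ``max_t |Y_full - Y_qss| / max Y_qss``
    (0 when both transcripts stay at zero, e.g. ``k_t = 0``).
    """
    if not speed_ratio > 0:
        raise InvalidParameterError(f"speed_ratio must be > 0, got {speed_ratio!r}")
    fast = BindingKinetics(
        k_on=kin.k_on * speed_ratio,
        k_off=kin.k_off * speed_ratio,
        k_t=kin.k_t,
        lam=kin.lam,
    )
    traj = simulate_binding_ode(fast, X_total, 0.0, 0.0, t_end, n_samples)

    d1_eq = _equilibrium_bound_fraction(fast, X_total)
    # dY/dt = k_t d1_eq - lam Y, Y(0) = 0
    if fast.lam > 0:
        y_inf = fast.k_t * d1_eq / fast.lam
        y_qss = y_inf * (1.0 - np.exp(-fast.lam * traj.times))
    else:
        y_qss = fast.k_t * d1_eq * traj.times
    scale = float(np.max(y_qss))
    if scale <= 0.0:
        return float(np.max(np.abs(traj.Y - y_qss)))
    return float(np.max(np.abs(traj.Y - y_qss)) / scale)
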