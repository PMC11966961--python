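"""Morphogen gradient profiles.

Gradients are sigmoid profiles along a 1-D tissue axis: a static profile
``M(x) = 1 / (1 + exp(-k (x - x0)))``, a retracting profile whose
inflection point moves at velocity ``v`` (``x0(t) = x00 + v t``), and a
stable gradient *induced* by a retracting one — a slowly-decaying (here
non-decaying) gene driven at rate ``M' / (1 + M')`` integrates the local
exposure history into a stable long-range profile.

With slope ``k < 0`` the high end of the gradient sits at ``x = 0``, the
orientation used by the default patterning scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InvalidParameterError

__all__ = ["GradientSpec", "Tissue1D", "gradient_value", "induce_stable_gradient"]

_FORMS = ("static_sigmoid", "retracting_sigmoid", "induced_stable")


@dataclass(frozen=True)
class GradientSpec:
    """Sigmoid morphogen profile specification.

    ``k`` is the slope per cell-position unit (sign sets orientation),
    ``x0`` the inflection position (initial position ``x00`` for the
    retracting form) and ``v`` the retraction velocity.
    """

    form: str = "static_sigmoid"
    k: float = -0.1
    x0: float = 50.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ConfigurationError(
                f"unknown gradient form {self.form!r}; expected one of {_FORMS}"
            )
        for name in ("k", "x0", "v"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class Tissue1D:
    """A row of independent cells, by default at integer positions 0..n_cells-1.

    Cells share no state: every spatial operation integrates each cell
    against its local morphogen history only (kinematic, not diffusive), so
    a tissue restricted to any subset of positions reproduces exactly the
    per-cell trajectories of the full tissue (build one with
    :meth:`at_positions`).
    """

    n_cells: int = 100
    _positions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("tissue needs at least 1 cell")
        if self._positions is not None and len(self._positions) != self.n_cells:
            raise ConfigurationError("positions length must equal n_cells")

    @classmethod
    def at_positions(cls, positions) -> "Tissue1D":
        pos = tuple(float(p) for p in positions)
        return cls(n_cells=len(pos), _positions=pos)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is not None:
            return np.asarray(self._positions, dtype=float)
        return np.arange(self.n_cells, dtype=float)


def gradient_value(spec: GradientSpec, x, t: float = 0.0):
    """Morphogen level of a (possibly retracting) sigmoid at position x, time t.

    Values lie in (0, 1) and are monotone in ``x`` with the sign of ``k``.
    """
    x = np.asarray(x, dtype=float)
    if spec.form == "static_sigmoid":
        z = -spec.k * (x - spec.x0)
    elif spec.form == "retracting_sigmoid":
        z = -spec.k * (x - spec.x0 - spec.v * t)
    else:
        raise ConfigurationError(
            "induced_stable gradients are computed by induce_stable_gradient, "
            "not evaluated pointwise"
        )
    out = expit(-z)
    return float(out) if out.ndim == 0 else out


def induce_stable_gradient(
    mprime: GradientSpec,
    tissue: Tissue1D,
    t_end: float,
    n_samples: int = 400,
):
    """Integrate a stable gradient M from a retracting gradient M'.

    Each cell accumulates ``dM/dt = M' / (1 + M')`` with zero decay, so the
    final level records how long the cell was exposed to the retracting
    front: M is non-decreasing in time everywhere and, at ``t_end``,
    monotone along the axis in the direction of longer exposure.

    Returns a :class:`~morphogrn.tissue.SpaceTimeField` whose single
    species ``"M"`` holds the induced gradient and whose ``morphogen``
    channel holds the driving retracting profile.
    """
    from .tissue import SpaceTimeField  # local import to avoid a cycle

    if mprime.form != "retracting_sigmoid":
        raise ConfigurationError("induce_stable_gradient requires a retracting gradient")
    if not t_end > 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end!r}")

    times = np.linspace(0.0, t_end, n_samples)
    x = tissue.positions
    # rate is independent of M, so cumulative quadrature is exact up to
    # the trapezoid error of the sampled drive
    drive = np.stack([gradient_value(mprime, x, t) for t in times])  # (T, C)
    rate = drive / (1.0 + drive)
    dt = np.diff(times)
    increments = 0.5 * (rate[1:] + rate[:-1]) * dt[:, None]
    M = np.vstack([np.zeros(tissue.n_cells), np.cumsum(increments, axis=0)])
    return SpaceTimeField(
        times=times,
        genes=("M",),
        expression=M[:, :, None],
        morphogen={"Mprime": drive},
    )
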