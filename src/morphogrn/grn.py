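"""Single-cell gene regulatory network (GRN) dynamics.

A :class:`GRNModel` is a set of genes, each governed by

    dG/dt = production_scale * [input gain] * prod(Hill factors) - lam * G

where every Hill factor is either an activating occupancy
``(S/theta)^n / (1 + (S/theta)^n)`` or a repression factor
``1 / (1 + (S/theta)^n)`` driven by another gene in the model or by a
declared external input.  The optional input gain ``M / (1 + M)`` couples a
gene to an external morphogen level ``M``.

Production scales and decay rates default to 1 (nondimensional units), so
each gene's level is bounded by ``production_scale / lam``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    IntegrationError,
    InvalidParameterError,
)

__all__ = [
    "HillFactor",
    "GeneRule",
    "GRNModel",
    "GRNTrajectory",
    "AttractorReport",
    "PeakOrder",
    "integrate_grn",
    "classify_attractor",
    "peak_order",
]

EXTERNAL_INPUT = "M"  # reserved name for the external input species


@dataclass(frozen=True)
class HillFactor:
    """One regulatory edge: ``source`` acting on a target gene."""

    source: str
    theta: float
    n: float = 4.0
    role: str = "repressor"

    def __post_init__(self) -> None:
        if not (self.theta > 0) or not math.isfinite(self.theta):
            raise InvalidParameterError(f"theta must be > 0, got {self.theta!r}")
        if not (self.n >= 1):
            raise InvalidParameterError(f"n must be >= 1, got {self.n!r}")
        if self.role not in ("activator", "repressor"):
            raise ConfigurationError(f"unknown role {self.role!r}")

    def value(self, s: float) -> float:
        x = (s / self.theta) ** self.n
        if self.role == "activator":
            return x / (1.0 + x)
        return 1.0 / (1.0 + x)


@dataclass(frozen=True)
class GeneRule:
    """Production law of one gene (product of its factors) plus decay."""

    gene: str
    factors: tuple[HillFactor, ...] = ()
    input_gain: bool = False  # multiply production by M / (1 + M)
    production_scale: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if not (self.production_scale >= 0) or not math.isfinite(self.production_scale):
            raise InvalidParameterError(
                f"production_scale must be finite >= 0, got {self.production_scale!r}"
            )
        if not (self.lam >= 0) or not math.isfinite(self.lam):
            raise InvalidParameterError(f"lam must be finite >= 0, got {self.lam!r}")


@dataclass(frozen=True)
class GRNModel:
    """An ordered collection of gene rules forming a network motif."""

    genes: tuple[GeneRule, ...]
    name: str = "grn"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate gene names in {names}")
        known = set(names) | {EXTERNAL_INPUT}
        for g in self.genes:
            for f in g.factors:
                if f.source not in known:
                    raise ConfigurationError(
                        f"factor source {f.source!r} of gene {g.gene!r} is neither "
                        f"a model gene nor the external input {EXTERNAL_INPUT!r}"
                    )

    @property
    def gene_names(self) -> list[str]:
        return [g.gene for g in self.genes]

    def production(self, levels: Mapping[str, float], external: float = 0.0) -> np.ndarray:
        """Per-gene production rates at the given expression levels."""
        out = np.empty(len(self.genes))
        for i, g in enumerate(self.genes):
            p = g.production_scale
            if g.input_gain:
                p *= external / (1.0 + external)
            for f in g.factors:
                s = external if f.source == EXTERNAL_INPUT else levels[f.source]
                p *= f.value(s)
            out[i] = p
        return out

    def rhs(self, t: float, y: np.ndarray, external: float = 0.0) -> np.ndarray:
        levels = dict(zip(self.gene_names, y))
        prod = self.production(levels, external)
        lam = np.array([g.lam for g in self.genes])
        return prod - lam * y

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "genes": [
                {
                    "gene": g.gene,
                    "input_gain": g.input_gain,
                    "production_scale": g.production_scale,
                    "lam": g.lam,
                    "factors": [
                        {"source": f.source, "theta": f.theta, "n": f.n, "role": f.role}
                        for f in g.factors
                    ],
                }
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GRNModel":
        genes = tuple(
            GeneRule(
                gene=g["gene"],
                factors=tuple(HillFactor(**f) for f in g.get("factors", ())),
                input_gain=g.get("input_gain", False),
                production_scale=g.get("production_scale", 1.0),
                lam=g.get("lam", 1.0),
            )
            for g in d["genes"]
        )
        return cls(genes=genes, name=d.get("name", "grn"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GRNModel":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class GRNTrajectory:
    """Integrated expression time courses, shape (n_times, n_genes)."""

    times: np.ndarray
    values: np.ndarray
    genes: tuple[str, ...]

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.genes))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate_grn(
    model: GRNModel,
    y0: Sequence[float],
    t_end: float,
    n_samples: int = 1000,
    external_input: Optional[float | Callable[[float], float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GRNTrajectory:
    """Integrate a GRN from the given initial expression levels.

    ``external_input`` may be a constant or a function of time; when absent
    it is taken as 0, which silences every gene carrying an input gain.
    """
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (len(model.genes),):
        raise ConfigurationError(
            f"y0 has shape {y0.shape}, expected ({len(model.genes)},)"
        )
    if np.any(y0 < 0):
        raise InvalidParameterError("initial expression levels must be >= 0")
    if not t_end > 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end!r}")

    if external_input is None:
        ext = lambda t: 0.0
    elif callable(external_input):
        ext = external_input
    else:
        const = float(external_input)
        ext = lambda t: const

    def rhs(t, y):
        return model.rhs(t, np.maximum(y, 0.0), ext(t))

    times = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=times, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"GRN integration failed at t={sol.t[-1] if sol.t.size else 0}: {sol.message}"
        )
    values = np.maximum(sol.y.T, 0.0)  # clip solver-level negative round-off
    return GRNTrajectory(times=times, values=values, genes=tuple(model.gene_names))


@dataclass(frozen=True)
class AttractorReport:
    """Classification of a trajectory's long-run behavior."""

    kind: str  # "fixed_point" | "oscillation" | "undecided"
    levels: Optional[dict[str, float]] = None
    period: Optional[dict[str, float]] = None
    amplitude: Optional[dict[str, float]] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "levels": self.levels,
                "period": self.period,
                "amplitude": self.amplitude,
            },
            indent=2,
        )


def classify_attractor(
    traj: GRNTrajectory,
    settle_fraction: float = 0.5,
    amplitude_floor: float = 0.05,
) -> AttractorReport:
    """Classify the post-transient window as fixed point or oscillation.

    The analysis window is the trailing ``settle_fraction`` of the
    trajectory.  A gene is flat when its peak-to-peak variation in the
    window stays below ``amplitude_floor`` times its maximum level (with an
    absolute floor for genes near zero).  If all genes are flat the
    trajectory is a fixed point; otherwise the highest-amplitude gene must
    show at least three peaks, from which the period is estimated as the
    mean inter-peak interval.
    """
    if not 0.0 < settle_fraction <= 1.0:
        raise InvalidParameterError("settle_fraction must lie in (0, 1]")
    i0 = int(len(traj.times) * (1.0 - settle_fraction))
    win = traj.values[i0:]
    t_win = traj.times[i0:]
    if win.shape[0] < 8:
        raise InsufficientDataError("analysis window has too few samples")

    ptp = np.ptp(win, axis=0)
    scale = np.maximum(win.max(axis=0), 1e-9)
    floors = np.maximum(amplitude_floor * scale, 1e-6)
    if np.all(ptp < floors):
        levels = {g: float(win[:, i].mean()) for i, g in enumerate(traj.genes)}
        return AttractorReport(kind="fixed_point", levels=levels)

    lead = int(np.argmax(ptp / scale))
    sig = win[:, lead]
    prom = 0.25 * np.ptp(sig)
    peaks, _ = find_peaks(sig, prominence=prom)
    if len(peaks) < 3:
        raise InsufficientDataError(
            f"only {len(peaks)} peaks in the analysis window; "
            "extend the trajectory to confirm oscillation"
        )
    period = float(np.mean(np.diff(t_win[peaks])))
    periods = {g: period for g in traj.genes}
    amplitudes = {g: float(ptp[i]) for i, g in enumerate(traj.genes)}
    return AttractorReport(kind="oscillation", period=periods, amplitude=amplitudes)


@dataclass(frozen=True)
class PeakOrder:
    """Genes ordered by time of maximum expression."""

    genes: tuple[str, ...]
    times: tuple[float, ...]
    ambiguous: bool = False


def peak_order(traj: GRNTrajectory, tol: Optional[float] = None) -> PeakOrder:
    """Order genes by the time at which each attains its global maximum.

    When two peak times coincide to within ``tol`` (default: one sample
    interval) the result is flagged ambiguous rather than imposing an
    arbitrary order.
    """
    if tol is None:
        tol = float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 0.0
    idx = np.argmax(traj.values, axis=0)
    t_max = traj.times[idx]
    order = np.argsort(t_max, kind="stable")
    sorted_t = t_max[order]
    ambiguous = bool(np.any(np.diff(sorted_t) <= tol)) if len(sorted_t) > 1 else False
    return PeakOrder(
        genes=tuple(traj.genes[i] for i in order),
        times=tuple(float(t) for t in sorted_t),
        ambiguous=ambiguous,
    )
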