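"""1-D tissue patterning simulators.

Every simulator integrates the same single-cell GRN equations in each cell
of a :class:`~morphogrn.gradients.Tissue1D`, driven only by that cell's
local morphogen history — there is no diffusion and no cell-to-cell
coupling, so any apparent expression waves are kinematic (phase) waves.

Families implemented:

- threshold (French Flag) readouts of one or two static gradients,
- the nested feed-forward cross-repression ladder that sharpens a single
  gradient into multiple abutting domains,
- additive two-enhancer stripe formation,
- speed regulation: a morphogen scales the rate at which each cell
  progresses through a de-repression gene cascade,
- enhancer switching: each gene reads a dynamic (sequence-driving) and a
  static (pattern-stabilizing) enhancer, balanced by the morphogen, with
  additive or promoter-competitive integration of the two activities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    IntegrationError,
    InvalidParameterError,
    SizeMismatchError,
)
from .gradients import GradientSpec, Tissue1D, gradient_value

__all__ = [
    "SpaceTimeField",
    "EnhancerSwitchSpec",
    "EnhancerPerturbation",
    "PatternSummary",
    "run_french_flag_thresholds",
    "run_two_gradient_model",
    "run_nested_feedforward",
    "run_additive_stripe_enhancers",
    "run_speed_regulation",
    "run_enhancer_switching",
    "segment_domains",
    "mismatch_score",
    "wave_trajectory",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpaceTimeField:
    """Expression indexed (time, cell, gene) plus named morphogen channels."""

    times: np.ndarray
    genes: tuple[str, ...]
    expression: np.ndarray  # (T, C, G)
    morphogen: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (T, C)

    def __post_init__(self) -> None:
        T, C, G = self.expression.shape
        if len(self.times) != T or len(self.genes) != G:
            raise ConfigurationError("inconsistent field shapes")
        for name, m in self.morphogen.items():
            if m.shape != (T, C):
                raise ConfigurationError(f"morphogen {name!r} has shape {m.shape}")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ConfigurationError(f"gene {gene!r} not in field {self.genes}") from None

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def slice_at(self, t: float) -> np.ndarray:
        """Expression matrix (cell, gene) at the sample closest to t."""
        return self.expression[self.time_index(t)]

    def to_long_dataframe(self):
        import pandas as pd

        T, C, G = self.expression.shape
        tt, cc, gg = np.meshgrid(
            self.times, np.arange(C), np.arange(G), indexing="ij"
        )
        return pd.DataFrame(
            {
                "time": tt.ravel(),
                "cell": cc.ravel().astype(int),
                "gene": np.asarray(self.genes)[gg.ravel()],
                "value": self.expression.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class EnhancerPerturbation:
    """Multiply one gene's enhancer activity by an overactivity factor."""

    gene_index: int  # 1-based, as genes are named G1..GN
    enhancer: str = "dynamic"  # "dynamic" | "static"
    factor: float = 10.0

    def __post_init__(self) -> None:
        if self.enhancer not in ("dynamic", "static"):
            raise ConfigurationError(f"unknown enhancer {self.enhancer!r}")
        if not self.factor > 0:
            raise InvalidParameterError("perturbation factor must be > 0")


@dataclass(frozen=True)
class EnhancerSwitchSpec:
    """Parameters of the two-enhancer (dynamic + static) patterning system.

    ``k_td`` / ``k_ts`` are the maximal rates of the dynamic and static
    enhancers under additive integration; ``k_ed`` / ``k_es`` weight the
    enhancer activities and ``k_t`` caps the promoter rate under
    competitive integration.  Default ``k_t = k_td + k_ts`` makes the two
    integration modes comparable in scale.
    """

    n_genes: int = 5
    theta_s: float = 0.1
    theta_w: float = 1.0
    n: float = 4.0
    lam: float = 1.0
    k_td: float = 1.0
    k_ts: float = 1.0
    k_ed: float = 1.0
    k_es: float = 1.0
    k_t: Optional[float] = None
    integration: str = "additive"  # "additive" | "competitive"
    perturbation: Optional[EnhancerPerturbation] = None

    def __post_init__(self) -> None:
        if self.integration not in ("additive", "competitive"):
            raise ConfigurationError(f"unknown integration {self.integration!r}")
        if self.n_genes < 2:
            raise ConfigurationError("enhancer switching needs at least 2 genes")
        for name in ("theta_s", "theta_w", "lam", "k_td", "k_ts", "k_ed", "k_es"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")
        if self.k_t is None:
            object.__setattr__(self, "k_t", self.k_td + self.k_ts)
        elif not self.k_t > 0:
            raise InvalidParameterError("k_t must be > 0")
        if self.perturbation is not None and not (
            1 <= self.perturbation.gene_index <= self.n_genes
        ):
            raise ConfigurationError("perturbation gene_index out of range")


@dataclass(frozen=True)
class PatternSummary:
    """Per-cell identity and contiguous expression domains at one time."""

    genes: tuple[str, ...]
    identity: np.ndarray  # per-cell gene index, -1 where nothing is expressed
    domains: tuple[tuple[str, int, int], ...]  # (gene, start cell, end cell)
    boundaries: tuple[int, ...]
    t_ref: float

    @property
    def n_cells(self) -> int:
        return len(self.identity)

    def domain_count(self, gene: Optional[str] = None) -> int:
        if gene is None:
            return len(self.domains)
        return sum(1 for d in self.domains if d[0] == gene)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_ref": self.t_ref,
                "genes": list(self.genes),
                "identity": self.identity.tolist(),
                "domains": [list(d) for d in self.domains],
                "boundaries": list(self.boundaries),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# shared integration driver
# ---------------------------------------------------------------------------

def _integrate_field(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,  # (C, G)
    t_end: float,
    n_samples: int,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate C independent G-dimensional cells as one flat system."""
    if not t_end > 0:
        raise InvalidParameterError(f"t_end must be > 0, got {t_end!r}")
    C, G = y0.shape

    def flat_rhs(t, y):
        return rhs(t, np.maximum(y.reshape(C, G), 0.0)).ravel()

    times = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(flat_rhs, (0.0, t_end), y0.ravel(), t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"tissue integration failed at t={t_fail}: {sol.message}")
    expr = np.maximum(sol.y.T.reshape(len(times), C, G), 0.0)
    return times, expr


def _occ(c: np.ndarray, K: float, n: float) -> np.ndarray:
    x = (c / K) ** n
    return x / (1.0 + x)


def _rep(c: np.ndarray, K: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + (c / K) ** n)


def _morphogen_history(spec: GradientSpec, tissue: Tissue1D, times: np.ndarray) -> np.ndarray:
    return np.stack([gradient_value(spec, tissue.positions, t) for t in times])


# ---------------------------------------------------------------------------
# French Flag realizations
# ---------------------------------------------------------------------------

def run_french_flag_thresholds(
    tissue: Tissue1D,
    gradient: GradientSpec,
    K: Sequence[float] = (0.1, 0.5, 0.1, 0.5),
    n: float = 4.0,
    lam: float = 1.0,
    t_end: float = 20.0,
    n_samples: int = 200,
) -> SpaceTimeField:
    """Four genes reading one gradient at distinct thresholds.

    Genes G1/G2 are activated by M (strong/weak: ``K[0] < K[1]``), genes
    G3/G4 repressed by M (strong/weak: ``K[2] < K[3]``).  Each steady-state
    expression boundary sits where M crosses that gene's K.
    """
    import warnings

    if not (K[0] < K[1] and K[2] < K[3]):
        warnings.warn(
            "threshold ordering violated (expected K[0] < K[1], K[2] < K[3]); "
            "running anyway",
            stacklevel=2,
        )
    x = tissue.positions
    M = gradient_value(gradient, x)  # static per cell

    rate = np.stack(
        [
            _occ(M, K[0], n),
            _occ(M, K[1], n),
            _rep(M, K[2], n),
            _rep(M, K[3], n),
        ],
        axis=1,
    )  # (C, 4)

    def rhs(t, y):
        return rate - lam * y

    y0 = np.zeros((tissue.n_cells, 4))
    times, expr = _integrate_field(rhs, y0, t_end, n_samples)
    morph = np.broadcast_to(M, (len(times), tissue.n_cells)).copy()
    return SpaceTimeField(times, ("G1", "G2", "G3", "G4"), expr, {"M": morph})


def run_two_gradient_model(
    tissue: Tissue1D,
    m1: GradientSpec = GradientSpec(form="static_sigmoid", k=-0.2, x0=35.0),
    m2: GradientSpec = GradientSpec(form="static_sigmoid", k=0.2, x0=64.0),
    K_strong: float = 0.1,
    K_weak: float = 0.7,
    n: float = 4.0,
    lam: float = 1.0,
    t_end: float = 20.0,
    n_samples: int = 200,
) -> SpaceTimeField:
    """Two genes bounded by two opposing gradients.

    G1 is strongly repressed by M1 and weakly by M2; G2 mirrors it.  With
    the default mirror-symmetric gradients the two expression domains are
    interior (they reach neither tissue end) and mirror images about the
    tissue center.
    """
    x = tissue.positions
    M1 = gradient_value(m1, x)
    M2 = gradient_value(m2, x)
    rate = np.stack(
        [
            _rep(M1, K_strong, n) * _rep(M2, K_weak, n),
            _rep(M1, K_weak, n) * _rep(M2, K_strong, n),
        ],
        axis=1,
    )

    def rhs(t, y):
        return rate - lam * y

    y0 = np.zeros((tissue.n_cells, 2))
    times, expr = _integrate_field(rhs, y0, t_end, n_samples)
    T = len(times)
    return SpaceTimeField(
        times,
        ("G1", "G2"),
        expr,
        {
            "M1": np.broadcast_to(M1, (T, tissue.n_cells)).copy(),
            "M2": np.broadcast_to(M2, (T, tissue.n_cells)).copy(),
        },
    )


def run_nested_feedforward(
    tissue: Tissue1D,
    gradient: GradientSpec,
    N: int = 5,
    theta_s: float = 0.1,
    theta_w: float = 1.0,
    K_ladder: Optional[Sequence[float]] = None,
    n: float = 4.0,
    lam: float = 1.0,
    t_end: float = 30.0,
    n_samples: int = 300,
) -> SpaceTimeField:
    """Cross-repression ladder refining one gradient into N abutting domains.

    Gene i is activated by M at threshold ``K_ladder[i]`` (ascending), is
    weakly repressed by gene i+1 and strongly repressed by genes i+2..N;
    gene N carries no repression, so its domain spans all cells above its
    activation threshold (the high-M end).
    """
    if N < 3:
        raise ConfigurationError("nested feedforward needs at least 3 genes")
    if K_ladder is None:
        # ascending activation thresholds spread across the gradient range;
        # capped at 0.5 so the top gene saturates at the high-M end
        K_ladder = np.geomspace(0.02, 0.5, N)
    K_ladder = np.asarray(K_ladder, dtype=float)
    if K_ladder.shape != (N,):
        raise ConfigurationError(f"K_ladder must have length {N}")

    x = tissue.positions
    M = gradient_value(gradient, x)
    act = np.stack([_occ(M, K_ladder[i], n) for i in range(N)], axis=1)  # (C, N)

    def rhs(t, y):  # y: (C, N)
        prod = act.copy()
        for i in range(N):
            if i + 1 < N:
                prod[:, i] *= _rep(y[:, i + 1], theta_w, n)
            for j in range(i + 2, N):
                prod[:, i] *= _rep(y[:, j], theta_s, n)
        return prod - lam * y

    y0 = np.zeros((tissue.n_cells, N))
    times, expr = _integrate_field(rhs, y0, t_end, n_samples)
    genes = tuple(f"G{i + 1}" for i in range(N))
    morph = np.broadcast_to(M, (len(times), tissue.n_cells)).copy()
    return SpaceTimeField(times, genes, expr, {"M": morph})


def run_additive_stripe_enhancers(
    tissue: Tissue1D,
    m1: GradientSpec = GradientSpec(form="static_sigmoid", k=-0.25, x0=45.0),
    m2: GradientSpec = GradientSpec(form="static_sigmoid", k=0.25, x0=54.0),
    K_strong: float = 0.1,
    K_weak: float = 0.7,
    n: float = 4.0,
    lam: float = 1.0,
    t_end: float = 20.0,
    n_samples: int = 200,
) -> SpaceTimeField:
    """Two-stripe pattern from the sum of two repressed enhancers.

    Enhancer activity E1 is the product of strong repression by M1 and
    weak repression by M2; E2 mirrors it.  The gene integrates
    ``dG/dt = E1 + E2 - lam G``, yielding one expression domain per
    enhancer — two stripes in total with the default opposing gradients.
    The returned field carries G plus the algebraic enhancer activities.
    """
    x = tissue.positions
    M1 = gradient_value(m1, x)
    M2 = gradient_value(m2, x)
    E1 = _rep(M1, K_strong, n) * _rep(M2, K_weak, n)
    E2 = _rep(M1, K_weak, n) * _rep(M2, K_strong, n)
    total = E1 + E2

    def rhs(t, y):
        return total[:, None] - lam * y

    y0 = np.zeros((tissue.n_cells, 1))
    times, expr_g = _integrate_field(rhs, y0, t_end, n_samples)
    T = len(times)
    expr = np.concatenate(
        [
            expr_g,
            np.broadcast_to(E1[None, :, None], (T, tissue.n_cells, 1)),
            np.broadcast_to(E2[None, :, None], (T, tissue.n_cells, 1)),
        ],
        axis=2,
    )
    return SpaceTimeField(
        times,
        ("G", "E1", "E2"),
        expr,
        {
            "M1": np.broadcast_to(M1, (T, tissue.n_cells)).copy(),
            "M2": np.broadcast_to(M2, (T, tissue.n_cells)).copy(),
        },
    )


# ---------------------------------------------------------------------------
# Speed Regulation realizations
# ---------------------------------------------------------------------------

def _cascade_production(y: np.ndarray, theta_s: float, theta_w: float, n: float) -> np.ndarray:
    """De-repression cascade production terms for every cell at once.

    Gene 1 is strongly repressed by every other gene; gene m > 1 is weakly
    repressed by its predecessor and strongly repressed by the rest.
    """
    C, N = y.shape
    rep_s = 1.0 / (1.0 + (y / theta_s) ** n)  # (C, N)
    rep_w = 1.0 / (1.0 + (y / theta_w) ** n)
    # products of strong repression over all genes, divided out per-target
    prod = np.empty_like(y)
    for m in range(N):
        p = np.ones(C)
        for i in range(N):
            if i == m:
                continue
            if m >= 1 and i == m - 1:
                p *= rep_w[:, i]
            else:
                p *= rep_s[:, i]
        prod[:, m] = p
    return prod


def run_speed_regulation(
    tissue: Tissue1D,
    gradient: GradientSpec,
    N: int = 5,
    theta_s: float = 0.1,
    theta_w: float = 1.0,
    n: float = 4.0,
    lam: float = 1.0,
    t_end: float = 120.0,
    n_samples: int = 300,
    speed_scope: str = "full_rhs",
) -> SpaceTimeField:
    """Morphogen-scaled progression through a de-repression cascade.

    The local speed factor ``s = M / (1 + M)`` multiplies either the whole
    right-hand side (``speed_scope="full_rhs"``: production *and* decay, so
    cells freeze completely at M = 0) or production only
    (``"production_only"``, the rate-law reading).  Cells at higher M run
    the cascade faster, which shows up as kinematic expression waves
    travelling from the high-M toward the low-M end of the tissue.

    Every cell starts with gene 1 at its saturated level ``1 / lam``.
    """
    if N < 3:
        raise ConfigurationError("speed regulation needs at least 3 genes")
    if speed_scope not in ("full_rhs", "production_only"):
        raise ConfigurationError(f"unknown speed_scope {speed_scope!r}")
    x = tissue.positions
    static = gradient.form == "static_sigmoid"
    M0 = gradient_value(gradient, x) if static else None

    def rhs(t, y):  # y: (C, N)
        M = M0 if static else gradient_value(gradient, x, t)
        s = (M / (1.0 + M))[:, None]
        prod = _cascade_production(y, theta_s, theta_w, n)
        if speed_scope == "full_rhs":
            return s * (prod - lam * y)
        return s * prod - lam * y

    y0 = np.zeros((tissue.n_cells, N))
    y0[:, 0] = 1.0 / lam
    times, expr = _integrate_field(rhs, y0, t_end, n_samples)
    morph = (
        np.broadcast_to(M0, (len(times), tissue.n_cells)).copy()
        if static
        else _morphogen_history(gradient, tissue, times)
    )
    genes = tuple(f"G{i + 1}" for i in range(N))
    return SpaceTimeField(times, genes, expr, {"M": morph})


def run_enhancer_switching(
    tissue: Tissue1D,
    gradient: GradientSpec,
    spec: EnhancerSwitchSpec = EnhancerSwitchSpec(),
    t_end: float = 120.0,
    n_samples: int = 300,
) -> SpaceTimeField:
    """Two-enhancer (dynamic + static) realization of speed regulation.

    Each gene j reads a dynamic enhancer ``Ed_j`` (cascade wiring, gated by
    ``M / (1 + M)``) and a static enhancer ``Es_j`` (all-pairs strong
    repression, gated by ``1 / (1 + M)``).  Under additive integration the
    enhancer activities sum (``k_td Ed + k_ts Es``); under competitive
    integration the promoter saturates,
    ``k_t (k_ed Ed + k_es Es) / (1 + k_ed Ed + k_es Es)``, so production is
    bounded by ``k_t`` no matter how overactive an enhancer becomes.
    """
    sp = spec
    N = sp.n_genes
    x = tissue.positions
    static = gradient.form == "static_sigmoid"
    M0 = gradient_value(gradient, x) if static else None

    pert_gene = pert_dyn = None
    factor = 1.0
    if sp.perturbation is not None:
        pert_gene = sp.perturbation.gene_index - 1
        pert_dyn = sp.perturbation.enhancer == "dynamic"
        factor = sp.perturbation.factor

    def enhancer_activities(M: np.ndarray, y: np.ndarray):
        s_dyn = (M / (1.0 + M))[:, None]
        s_sta = (1.0 / (1.0 + M))[:, None]
        Ed = s_dyn * _cascade_production(y, sp.theta_s, sp.theta_w, sp.n)
        rep_s = 1.0 / (1.0 + (y / sp.theta_s) ** sp.n)
        all_rep = np.prod(rep_s, axis=1, keepdims=True)
        Es = s_sta * all_rep / rep_s  # leave-one-out product per gene
        if pert_gene is not None:
            if pert_dyn:
                Ed[:, pert_gene] *= factor
            else:
                Es[:, pert_gene] *= factor
        return Ed, Es

    def rhs(t, y):  # y: (C, N)
        M = M0 if static else gradient_value(gradient, x, t)
        Ed, Es = enhancer_activities(M, y)
        if sp.integration == "additive":
            prod = sp.k_td * Ed + sp.k_ts * Es
        else:
            w = sp.k_ed * Ed + sp.k_es * Es
            prod = sp.k_t * w / (1.0 + w)
        return prod - sp.lam * y

    y0 = np.zeros((tissue.n_cells, N))
    y0[:, 0] = 1.0 / sp.lam
    times, expr = _integrate_field(rhs, y0, t_end, n_samples)
    morph = (
        np.broadcast_to(M0, (len(times), tissue.n_cells)).copy()
        if static
        else _morphogen_history(gradient, tissue, times)
    )
    genes = tuple(f"G{i + 1}" for i in range(N))
    return SpaceTimeField(times, genes, expr, {"M": morph})


# ---------------------------------------------------------------------------
# pattern metrics
# ---------------------------------------------------------------------------

_EXPRESSION_FLOOR = 1e-6


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def segment_domains(
    field: SpaceTimeField,
    t_ref: Optional[float] = None,
    threshold_mode: str = "argmax",
) -> PatternSummary:
    """Summarize the spatial pattern at a reference time.

    ``argmax`` mode assigns each cell the identity of its most expressed
    gene (or -1 where everything is below an expression floor) and reports
    maximal constant-identity runs.  ``half_max`` mode reports, per gene,
    maximal runs of cells above half that gene's spatial maximum.
    """
    if threshold_mode not in ("argmax", "half_max"):
        raise ConfigurationError(f"unknown threshold_mode {threshold_mode!r}")
    if t_ref is None:
        t_ref = float(field.times[-1])
    if not (field.times[0] <= t_ref <= field.times[-1]):
        raise ConfigurationError(
            f"t_ref={t_ref} outside simulated window "
            f"[{field.times[0]}, {field.times[-1]}]"
        )
    snap = field.slice_at(t_ref)  # (C, G)
    C = snap.shape[0]

    identity = np.argmax(snap, axis=1)
    identity[np.max(snap, axis=1) < _EXPRESSION_FLOOR] = -1

    domains: list[tuple[str, int, int]] = []
    if threshold_mode == "argmax":
        boundaries = []
        if np.all(identity == -1):
            return PatternSummary(field.genes, identity, (), (), t_ref)
        start = 0
        for i in range(1, C + 1):
            if i == C or identity[i] != identity[start]:
                if identity[start] >= 0:
                    domains.append((field.genes[identity[start]], start, i - 1))
                if i < C:
                    boundaries.append(i)
                start = i
        return PatternSummary(
            field.genes, identity, tuple(domains), tuple(boundaries), t_ref
        )

    # half_max: per-gene thresholding
    for gi, gene in enumerate(field.genes):
        profile = snap[:, gi]
        peak = profile.max()
        if peak < _EXPRESSION_FLOOR:
            continue
        for start, end in _runs(profile > 0.5 * peak):
            domains.append((gene, start, end))
    edges = set()
    for _, start, end in domains:
        if start > 0:
            edges.add(start)
        if end + 1 < C:
            edges.add(end + 1)
    boundaries = tuple(sorted(edges))
    return PatternSummary(field.genes, identity, tuple(domains), boundaries, t_ref)


def mismatch_score(a: PatternSummary, b: PatternSummary) -> float:
    """Fraction of cells whose identity differs between two summaries."""
    if a.n_cells != b.n_cells:
        raise SizeMismatchError(f"tissue sizes differ: {a.n_cells} vs {b.n_cells}")
    if a.genes != b.genes:
        raise SizeMismatchError(f"gene sets differ: {a.genes} vs {b.genes}")
    return float(np.mean(a.identity != b.identity))


def wave_trajectory(
    field: SpaceTimeField, gene: str, floor_fraction: float = 0.05
) -> np.ndarray:
    """Cell index of the gene's spatial expression maximum over time.

    Times at which the profile is flat, or the gene everywhere below
    ``floor_fraction`` of its global maximum (no meaningful peak yet), are
    flagged NaN.
    """
    gi = field.gene_index(gene)
    profiles = field.expression[:, :, gi]  # (T, C)
    peaks = profiles.max(axis=1)
    # a saturated profile has a plateau of numerically equal maxima; the
    # midpoint of that plateau is the stable reading of "where the max is"
    cells = np.arange(profiles.shape[1], dtype=float)
    pos = np.empty(profiles.shape[0])
    for i in range(profiles.shape[0]):
        at_max = profiles[i] >= peaks[i] * (1.0 - 1e-9) - 1e-15
        pos[i] = cells[at_max].mean()
    floor = max(floor_fraction * profiles.max(), _EXPRESSION_FLOOR)
    undefined = (np.ptp(profiles, axis=1) < _EXPRESSION_FLOOR) | (peaks < floor)
    pos[undefined] = np.nan
    return pos
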