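"""Canonical GRN motif constructors.

Each builder wires a :class:`~morphogrn.grn.GRNModel` whose right-hand
sides realize a classic network motif: mutual-activation and
mutual-repression toggles, the homeostatic negative feedback loop, two
three-gene oscillators (two-activator/one-repressor loop and the
repressilator), the mutually repressing multistable network, the
de-repression genetic cascade, and its cyclic (oscillating) variant.

Developmental motifs (multistable, cascade, chain oscillator) follow
de-repression logic: every gene is constitutively active but strongly
repressed by the others (threshold ``theta_s``), except that each cascade
gene only weakly represses its predecessor (threshold ``theta_w`` >
``theta_s``), which lets activation travel down the chain as successive
genes are de-repressed.
"""

from __future__ import annotations

from typing import Mapping

from .errors import ConfigurationError
from .grn import GeneRule, GRNModel, HillFactor

__all__ = ["build_motif", "MOTIF_KINDS"]

MOTIF_KINDS = (
    "pos_feedback_act",
    "pos_feedback_rep",
    "neg_feedback",
    "act_act_rep_oscillator",
    "repressilator",
    "multistable",
    "cascade",
    "chain_oscillator",
)

# Default thresholds: strong repression an order of magnitude below weak.
THETA_S = 0.1
THETA_W = 1.0
# Oscillator loops need a lower switching threshold to destabilize the
# symmetric fixed point at default Hill steepness.
THETA_OSC = 0.15


def _gene_names(count: int) -> list[str]:
    return [f"G{i + 1}" for i in range(count)]


def build_motif(kind: str, params: Mapping | None = None) -> GRNModel:
    """Construct a named motif.

    Parameters
    ----------
    kind : str
        One of :data:`MOTIF_KINDS`.
    params : mapping, optional
        Overrides: ``n`` (Hill coefficient, default 4), ``lam`` (decay,
        default 1), ``theta`` (two-gene loops and oscillators),
        ``theta_s`` / ``theta_w`` (developmental motifs), ``M`` (gene count
        of the multistable net, default 4), ``N`` (chain length for
        cascade / chain_oscillator, default 5 / 3).
    """
    p = dict(params or {})
    n = float(p.pop("n", 4.0))
    lam = float(p.pop("lam", 1.0))

    if kind == "pos_feedback_act":
        theta = float(p.pop("theta", 0.5))
        _reject_extras(kind, p)
        return GRNModel(
            name=kind,
            genes=(
                GeneRule("X", (HillFactor("Y", theta, n, "activator"),), lam=lam),
                GeneRule("Y", (HillFactor("X", theta, n, "activator"),), lam=lam),
            ),
        )

    if kind == "pos_feedback_rep":
        theta = float(p.pop("theta", 0.5))
        _reject_extras(kind, p)
        return GRNModel(
            name=kind,
            genes=(
                GeneRule("X", (HillFactor("Y", theta, n, "repressor"),), lam=lam),
                GeneRule("Y", (HillFactor("X", theta, n, "repressor"),), lam=lam),
            ),
        )

    if kind == "neg_feedback":
        theta_xy = float(p.pop("theta_xy", 0.5))
        theta_yx = float(p.pop("theta_yx", 0.5))
        _reject_extras(kind, p)
        return GRNModel(
            name=kind,
            genes=(
                GeneRule("X", (HillFactor("Y", theta_xy, n, "repressor"),), lam=lam),
                GeneRule("Y", (HillFactor("X", theta_yx, n, "activator"),), lam=lam),
            ),
        )

    if kind == "act_act_rep_oscillator":
        theta = float(p.pop("theta", THETA_OSC))
        _reject_extras(kind, p)
        return GRNModel(
            name=kind,
            genes=(
                GeneRule("X", (HillFactor("Z", theta, n, "repressor"),), lam=lam),
                GeneRule("Y", (HillFactor("X", theta, n, "activator"),), lam=lam),
                GeneRule("Z", (HillFactor("Y", theta, n, "activator"),), lam=lam),
            ),
        )

    if kind == "repressilator":
        theta = float(p.pop("theta", THETA_OSC))
        _reject_extras(kind, p)
        return GRNModel(
            name=kind,
            genes=(
                GeneRule("X", (HillFactor("Z", theta, n, "repressor"),), lam=lam),
                GeneRule("Y", (HillFactor("X", theta, n, "repressor"),), lam=lam),
                GeneRule("Z", (HillFactor("Y", theta, n, "repressor"),), lam=lam),
            ),
        )

    if kind == "multistable":
        m = int(p.pop("M", 4))
        theta_s = float(p.pop("theta_s", THETA_S))
        _reject_extras(kind, p)
        if m < 2:
            raise ConfigurationError("multistable needs at least 2 genes")
        names = _gene_names(m)
        genes = tuple(
            GeneRule(
                g,
                tuple(
                    HillFactor(other, theta_s, n, "repressor")
                    for other in names
                    if other != g
                ),
                lam=lam,
            )
            for g in names
        )
        return GRNModel(name=kind, genes=genes)

    if kind in ("cascade", "chain_oscillator"):
        default_n_genes = 5 if kind == "cascade" else 3
        n_genes = int(p.pop("N", default_n_genes))
        theta_s = float(p.pop("theta_s", THETA_S))
        theta_w = float(p.pop("theta_w", THETA_W))
        _reject_extras(kind, p)
        minimum = 2 if kind == "cascade" else 3
        if n_genes < minimum:
            raise ConfigurationError(f"{kind} needs at least {minimum} genes")
        names = _gene_names(n_genes)
        genes = []
        for m_idx, g in enumerate(names):
            factors = []
            for i, other in enumerate(names):
                if i == m_idx:
                    continue
                if m_idx == 0:
                    # first gene: strongly repressed by every other gene,
                    # except in the cyclic variant the last gene releases it
                    if kind == "chain_oscillator" and i == n_genes - 1:
                        continue
                    factors.append(HillFactor(other, theta_s, n, "repressor"))
                elif i == m_idx - 1:
                    factors.append(HillFactor(other, theta_w, n, "repressor"))
                else:
                    factors.append(HillFactor(other, theta_s, n, "repressor"))
            genes.append(GeneRule(g, tuple(factors), lam=lam))
        return GRNModel(name=kind, genes=tuple(genes))

    raise ConfigurationError(
        f"unknown motif kind {kind!r}; expected one of {MOTIF_KINDS}"
    )


def _reject_extras(kind: str, leftovers: Mapping) -> None:
    if leftovers:
        raise ConfigurationError(
            f"unknown parameters for motif {kind!r}: {sorted(leftovers)}"
        )
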