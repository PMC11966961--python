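"""Scenario registry and drivers.

Every registered scenario (``sim05`` .. ``sim26``) is an end-to-end
configured run of one library operation — a dose-response curve, a
regulatory-logic surface, a single-cell motif integration, or a 1-D
tissue patterning simulation.  Defaults live in ``data/scenarios.yaml``
(data, not code, so the choices made where the source models leave gaps
are auditable), can be overridden per run, and each run writes CSV/JSON
artifacts plus a manifest with checksums so identical configs and seeds
reproduce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .gradients import GradientSpec, Tissue1D
from .grn import classify_attractor, integrate_grn, peak_order
from .motifs import build_motif
from .tissue import (
    EnhancerPerturbation,
    EnhancerSwitchSpec,
    PatternSummary,
    SpaceTimeField,
    mismatch_score,
    run_additive_stripe_enhancers,
    run_enhancer_switching,
    run_french_flag_thresholds,
    run_nested_feedforward,
    run_speed_regulation,
    run_two_gradient_model,
    segment_domains,
    wave_trajectory,
)
from .transcription import CisModule, RegulatorTerm, tse_rate

__all__ = [
    "Scenario",
    "ScenarioResult",
    "SweepResult",
    "list_scenarios",
    "get_scenario",
    "run_scenario",
    "robustness_sweep",
]

logger = logging.getLogger("morphogrn.scenarios")


@dataclass(frozen=True)
class Scenario:
    """Registry entry: a named, fully-defaulted runnable configuration."""

    id: str
    title: str
    anchor: str
    family: str
    params: dict
    operation: Optional[str] = None
    initial_conditions: Optional[list] = None
    random_ic: Optional[dict] = None
    cascade_ic: bool = False

    def defaults_digest(self) -> str:
        blob = json.dumps(self.params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScenarioResult:
    """In-memory products of one scenario run plus its file manifest."""

    scenario: Scenario
    params: dict
    seed: int
    summary: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    objects: dict[str, Any] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def pattern(self) -> Optional[PatternSummary]:
        return self.objects.get("pattern")

    @property
    def field(self) -> Optional[SpaceTimeField]:
        return self.objects.get("field")


@dataclass(frozen=True)
class SweepResult:
    """Fold-change sweep of one parameter against the fold-1 reference."""

    scenario_id: str
    parameter: str
    folds: tuple[float, ...]
    mismatches: tuple[float, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": self.folds, "mismatch": self.mismatches}
        ).assign(scenario=self.scenario_id, parameter=self.parameter)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: Optional[dict[str, Scenario]] = None


def _load_registry() -> dict[str, Scenario]:
    global _REGISTRY
    if _REGISTRY is None:
        text = (
            importlib.resources.files("morphogrn.data")
            .joinpath("scenarios.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)
        _REGISTRY = {
            sid: Scenario(
                id=sid,
                title=entry["title"],
                anchor=entry["anchor"],
                family=entry["family"],
                params=entry["params"],
                operation=entry.get("operation"),
                initial_conditions=entry.get("initial_conditions"),
                random_ic=entry.get("random_ic"),
                cascade_ic=entry.get("cascade_ic", False),
            )
            for sid, entry in raw.items()
        }
    return _REGISTRY


def get_scenario(scenario_id: str) -> Scenario:
    reg = _load_registry()
    if scenario_id not in reg:
        raise ConfigurationError(
            f"unknown scenario {scenario_id!r}; known: {sorted(reg)}"
        )
    return reg[scenario_id]


def list_scenarios() -> pd.DataFrame:
    """All registered scenarios: id, title, anchor, family and defaults digest."""
    rows = [
        {
            "id": s.id,
            "title": s.title,
            "anchor": s.anchor,
            "family": s.family,
            "operation": s.operation or s.family,
            "defaults_digest": s.defaults_digest(),
        }
        for s in _load_registry().values()
    ]
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def _apply_overrides(params: dict, overrides: Mapping[str, Any]) -> dict:
    """Apply dotted-path overrides, rejecting unknown keys."""
    out = copy.deepcopy(params)
    for key, value in overrides.items():
        node = out
        parts = key.split(".")
        for p in parts[:-1]:
            if not isinstance(node, dict) or p not in node:
                raise ConfigurationError(
                    f"unknown override path {key!r}; valid keys: {_paths(params)}"
                )
            node = node[p]
        leaf = parts[-1]
        if not isinstance(node, dict) or leaf not in node:
            raise ConfigurationError(
                f"unknown override path {key!r}; valid keys: {_paths(params)}"
            )
        node[leaf] = value
    return out


def _paths(params: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in params.items():
        p = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_paths(v, p + "."))
        else:
            out.append(p)
    return sorted(out)


# ---------------------------------------------------------------------------
# family drivers
# ---------------------------------------------------------------------------

def _run_dose_response(p: dict) -> tuple[dict, dict[str, pd.DataFrame], dict]:
    term = RegulatorTerm("X", K=p["K"], n=p["n"], role=p["role"])
    module = CisModule((term,), logic="single", k_t=p["k_t"])
    X = np.linspace(0.0, p["x_max"], int(p["n_points"]))
    y_ss = np.array([tse_rate(module, {"X": x}) for x in X]) / p["lam"]
    slope = np.gradient(y_ss, X)
    summary = {
        "max_level": float(y_ss.max()),
        "max_slope_abs": float(np.max(np.abs(slope))),
        "level_at_K": float(np.interp(p["K"], X, y_ss)),
    }
    return summary, {"curve": pd.DataFrame({"X": X, "Y_ss": y_ss})}, {}


def _run_logic_surface(p: dict) -> tuple[dict, dict[str, pd.DataFrame], dict]:
    terms = (
        RegulatorTerm("A", K=p["K_A"], n=p["n"], role="activator"),
        RegulatorTerm("B", K=p["K_B"], n=p["n"], role="activator"),
    )
    module = CisModule(terms, logic=p["logic"], k_t=p["k_t"])
    grid = np.linspace(0.0, p["c_max"], int(p["n_points"]))
    rows = []
    for a in grid:
        for b in grid:
            rows.append((a, b, tse_rate(module, {"A": a, "B": b})))
    df = pd.DataFrame(rows, columns=["A", "B", "rate"])
    summary = {
        "rate_at_KK": float(tse_rate(module, {"A": p["K_A"], "B": p["K_B"]})),
        "rate_at_high_high": float(
            tse_rate(module, {"A": p["c_max"], "B": p["c_max"]})
        ),
        "rate_at_zero_zero": float(tse_rate(module, {"A": 0.0, "B": 0.0})),
    }
    return summary, {"surface": df}, {}


def _run_motif(scenario: Scenario, p: dict, rng: np.random.Generator):
    kind = p["kind"]
    t_end = p["t_end"]
    motif_params = {
        k: v for k, v in p.items() if k not in ("kind", "t_end")
    }
    model = build_motif(kind, motif_params)
    n_genes = len(model.genes)
    lam = p.get("lam", 1.0)

    if scenario.random_ic is not None:
        ics = [rng.uniform(scenario.random_ic["low"], scenario.random_ic["high"], n_genes)]
    elif scenario.cascade_ic:
        ic = np.zeros(n_genes)
        ic[0] = 1.0 / lam
        ics = [ic]
    else:
        ics = [np.asarray(ic, dtype=float) for ic in scenario.initial_conditions]

    tables, objects = {}, {}
    summary: dict[str, Any] = {"motif": kind, "runs": []}
    for i, ic in enumerate(ics):
        traj = integrate_grn(model, ic, t_end=t_end, n_samples=2000)
        report = classify_attractor(traj)
        run_info: dict[str, Any] = {"ic": list(map(float, ic)), "kind": report.kind}
        if report.kind == "fixed_point":
            run_info["levels"] = report.levels
            # count genes holding more than half the top level (winner call)
            levels = np.array(list(report.levels.values()))
            run_info["n_active"] = int(np.sum(levels > 0.5 * levels.max()))
        else:
            run_info["period"] = report.period[model.gene_names[0]]
        if kind in ("cascade", "chain_oscillator"):
            run_info["peak_order"] = list(peak_order(traj).genes)
        summary["runs"].append(run_info)
        tables[f"trajectory_{i}"] = traj.to_dataframe()
        objects[f"trajectory_{i}"] = traj
        objects[f"attractor_{i}"] = report
    return summary, tables, objects


def _gradient_from(p: Mapping) -> GradientSpec:
    return GradientSpec(**p)


def _run_spatial(scenario: Scenario, p: dict):
    tissue = Tissue1D(int(p["n_cells"]))
    op = scenario.operation
    if op == "french_flag":
        fld = run_french_flag_thresholds(
            tissue, _gradient_from(p["gradient"]), K=p["K"], n=p["n"],
            lam=p["lam"], t_end=p["t_end"],
        )
        pattern = segment_domains(fld, threshold_mode="half_max")
    elif op == "two_gradient":
        fld = run_two_gradient_model(
            tissue, _gradient_from(p["m1"]), _gradient_from(p["m2"]),
            K_strong=p["K_strong"], K_weak=p["K_weak"], n=p["n"],
            lam=p["lam"], t_end=p["t_end"],
        )
        pattern = segment_domains(fld, threshold_mode="half_max")
    elif op == "nested_feedforward":
        fld = run_nested_feedforward(
            tissue, _gradient_from(p["gradient"]), N=int(p["N"]),
            theta_s=p["theta_s"], theta_w=p["theta_w"], n=p["n"],
            lam=p["lam"], t_end=p["t_end"],
        )
        pattern = segment_domains(fld, threshold_mode="argmax")
    elif op == "additive_stripes":
        fld = run_additive_stripe_enhancers(
            tissue, _gradient_from(p["m1"]), _gradient_from(p["m2"]),
            K_strong=p["K_strong"], K_weak=p["K_weak"], n=p["n"],
            lam=p["lam"], t_end=p["t_end"],
        )
        pattern = segment_domains(fld, threshold_mode="half_max")
    elif op == "speed_regulation":
        fld = run_speed_regulation(
            tissue, _gradient_from(p["gradient"]), N=int(p["N"]),
            theta_s=p["theta_s"], theta_w=p["theta_w"], n=p["n"],
            lam=p["lam"], t_end=p["t_end"], speed_scope=p["speed_scope"],
        )
        pattern = segment_domains(fld, threshold_mode="argmax")
    elif op == "enhancer_switching":
        pert = None
        if int(p.get("mut_flag", 0)):
            pert = EnhancerPerturbation(
                gene_index=int(p.get("mut_gene", 3)),
                enhancer="dynamic",
                factor=float(p.get("mut_factor", 10.0)),
            )
        spec = EnhancerSwitchSpec(
            n_genes=int(p["n_genes"]), theta_s=p["theta_s"], theta_w=p["theta_w"],
            n=p["n"], lam=p["lam"], k_td=p["k_td"], k_ts=p["k_ts"],
            k_ed=p.get("k_ed", 1.0), k_es=p.get("k_es", 1.0),
            k_t=p.get("k_t"), integration=p["integration"], perturbation=pert,
        )
        fld = run_enhancer_switching(
            tissue, _gradient_from(p["gradient"]), spec, t_end=p["t_end"]
        )
        pattern = segment_domains(fld, threshold_mode="argmax")
    else:
        raise ConfigurationError(f"unknown spatial operation {op!r}")

    summary = {
        "operation": op,
        "n_cells": tissue.n_cells,
        "t_ref": pattern.t_ref,
        "domains": [list(d) for d in pattern.domains],
        "n_domains": len(pattern.domains),
    }
    gene_domains = {}
    for g in fld.genes:
        gene_domains[g] = pattern.domain_count(g)
    summary["domains_per_gene"] = gene_domains

    tables = {"field": fld.to_long_dataframe()}
    objects = {"field": fld, "pattern": pattern}
    return summary, tables, objects


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def run_scenario(
    scenario_id: str,
    overrides: Optional[Mapping[str, Any]] = None,
    out_dir: Optional[str | Path] = None,
    seed: int = 0,
) -> ScenarioResult:
    """Run one registered scenario and (optionally) write its artifacts.

    ``overrides`` maps dotted parameter paths (e.g. ``"gradient.k"``) to
    replacement values; unknown paths raise :class:`ConfigurationError`
    listing the valid keys.  With ``out_dir`` set, tables are written as
    CSV, the pattern/attractor objects as JSON, and a ``manifest.json``
    recording the resolved config, seed and a sha256 per file.
    """
    scenario = get_scenario(scenario_id)
    params = _apply_overrides(scenario.params, overrides or {})
    rng = np.random.default_rng(seed)
    logger.info("running %s (%s) seed=%d", scenario_id, scenario.title, seed)

    if scenario.family == "dose_response":
        summary, tables, objects = _run_dose_response(params)
    elif scenario.family == "logic_surface":
        summary, tables, objects = _run_logic_surface(params)
    elif scenario.family == "motif":
        summary, tables, objects = _run_motif(scenario, params, rng)
    elif scenario.family == "spatial":
        summary, tables, objects = _run_spatial(scenario, params)
    else:
        raise ConfigurationError(f"unknown scenario family {scenario.family!r}")

    result = ScenarioResult(
        scenario=scenario, params=params, seed=seed, summary=summary,
        tables=tables, objects=objects,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(result: ScenarioResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, df in result.tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        files[path.name] = _sha256(path)
    pattern = result.objects.get("pattern")
    if pattern is not None:
        path = out_dir / "pattern.json"
        path.write_text(pattern.to_json())
        files[path.name] = _sha256(path)
    for name, obj in result.objects.items():
        if name.startswith("attractor_"):
            path = out_dir / f"{name}.json"
            path.write_text(obj.to_json())
            files[path.name] = _sha256(path)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(result.summary, indent=2))
    files[summary_path.name] = _sha256(summary_path)

    manifest = {
        "scenario": result.scenario.id,
        "title": result.scenario.title,
        "seed": result.seed,
        "resolved_params": result.params,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log_path = out_dir / "run.log"
    log_path.write_text(
        f"scenario={result.scenario.id} seed={result.seed}\n"
        f"resolved_params={json.dumps(result.params, sort_keys=True)}\n"
        f"files={sorted(files)}\n"
    )
    result.manifest = manifest


_SWEEPABLE_FAMILIES = ("spatial",)


def robustness_sweep(
    base_scenario: str,
    parameter: str,
    folds: Sequence[float],
    out_dir: Optional[str | Path] = None,
    seed: int = 0,
) -> SweepResult:
    """Fold-change sweep of one numeric parameter of a spatial scenario.

    Each fold multiplies the parameter's default value; the resulting
    pattern is scored against the fold-1 reference with
    :func:`~morphogrn.tissue.mismatch_score`.  Monotone degradation is not
    assumed — the sweep reports whatever the dynamics produce.
    """
    scenario = get_scenario(base_scenario)
    if scenario.family not in _SWEEPABLE_FAMILIES:
        raise ConfigurationError(
            f"scenario {base_scenario!r} ({scenario.family}) does not produce "
            "a spatial pattern; only spatial scenarios are sweepable"
        )
    base_params = scenario.params
    # resolve the parameter's default to validate the path and get the base value
    node = base_params
    for part in parameter.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigurationError(
                f"parameter {parameter!r} not sweepable; valid: {_paths(base_params)}"
            )
        node = node[part]
    if not isinstance(node, (int, float)) or isinstance(node, bool):
        raise ConfigurationError(f"parameter {parameter!r} is not numeric")
    base_value = float(node)

    reference = run_scenario(base_scenario, seed=seed).pattern
    mismatches = []
    for f in folds:
        if f == 1.0:
            mismatches.append(0.0)
            continue
        res = run_scenario(
            base_scenario, overrides={parameter: base_value * f}, seed=seed
        )
        mismatches.append(mismatch_score(reference, res.pattern))

    sweep = SweepResult(
        scenario_id=base_scenario,
        parameter=parameter,
        folds=tuple(float(f) for f in folds),
        mismatches=tuple(mismatches),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sweep.to_dataframe().to_csv(out / "sweep.csv", index=False)
    return sweep
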