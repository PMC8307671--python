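"""Structured run configuration: validation, execution, and file output.

A run config is a YAML (or JSON) document::

    schema_version: 1
    module: edl            # edl | headgroup | vesicle
    task: solve            # module-specific task
    preset: fig8_low_salt  # optional; explicit params override preset values
    params: {...}
    output_prefix: results/run1

Validation happens before any computation, and output files are written
atomically (temp file + rename) only after the computation succeeds, so a
failing run never leaves partial files behind.
"""
from __future__ import annotations

import json
import logging
import os
import tempfile
from typing import Any, Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import edl, headgroup, presets, vesicle
from .models import ElectrolyteModel, HeadgroupModel, PlanarGap

__all__ = ["RunConfig", "run_config", "execute", "load_config"]

log = logging.getLogger("memadh")

_TASKS = {
    "edl": {"solve", "pressure-curve"},
    "headgroup": {"solve"},
    "vesicle": {"minimize", "scan", "transition"},
}


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: Literal[1] = 1
    module: Literal["edl", "headgroup", "vesicle"]
    task: str
    preset: Optional[str] = None
    params: Dict[str, Any] = {}
    output_prefix: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.task not in _TASKS[self.module]:
            raise ValueError(
                f"task '{self.task}' not available for module '{self.module}'"
                f" (choose from {sorted(_TASKS[self.module])})"
            )
        if self.preset is not None:
            p = presets.get_preset(self.preset)
            if p.module != self.module:
                raise ValueError(
                    f"preset '{self.preset}' belongs to module '{p.module}', "
                    f"not '{self.module}'"
                )
        return self

    def resolved_params(self) -> Dict[str, Any]:
        """Preset parameters with explicit params layered on top."""
        base: Dict[str, Any] = {}
        if self.preset is not None:
            base.update(presets.get_preset(self.preset).params)
        base.update(self.params)
        return base


def load_config(path: str) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path!r} does not contain a mapping")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _electrolyte(p: Dict[str, Any]) -> ElectrolyteModel:
    return ElectrolyteModel.from_molar(
        salt_molar=float(p["salt_molar"]),
        temperature=float(p.get("temperature", 298.0)),
        water_molar=float(p.get("water_molar", 55.0)),
        p0_debye=float(p.get("p0_debye", 3.1)),
        refractive_index=float(p.get("refractive_index", 1.33)),
    )


def _edl_solve(p: Dict[str, Any]):
    model = _electrolyte(p)
    gap = PlanarGap.from_nm(float(p["gap_nm"]), float(p["sigma1"]),
                            float(p["sigma2"]))
    prof = edl.solve_planar_edl(gap, model,
                                n_nodes=p.get("n_nodes"))
    pres = edl.osmotic_pressure_profile(prof, model)
    pi_nodes = np.interp(prof.x, prof.x_mid, pres.pointwise)
    table = pd.DataFrame(
        dict(x=prof.x, phi=prof.phi, E=prof.E, eps_r=prof.eps_r,
             n_plus=prof.n_plus, n_minus=prof.n_minus, rho=prof.rho,
             Pi_pointwise=pi_nodes)
    )
    meta = dict(
        converged=bool(prof.converged), residual=float(prof.residual),
        iterations=int(prof.iterations), Pi=pres.Pi, K=pres.K,
        constancy_residual=pres.constancy_residual,
        eps_r_bulk=model.eps_r_bulk, debye_length=model.debye_length,
    )
    return table, meta, prof.converged


def _edl_pressure_curve(p: Dict[str, Any]):
    model = _electrolyte(p)
    table = edl.pressure_distance_curve(
        model, float(p["sigma1"]), float(p["sigma2"]),
        [g * 1e-9 for g in p["gaps_nm"]],
        n_nodes=p.get("n_nodes"),
    )
    ok = bool(table["converged"].all())
    meta = dict(
        converged=ok, eps_r_bulk=model.eps_r_bulk,
        debye_length=model.debye_length, **dict(table.attrs),
    )
    return table, meta, ok


def _headgroup_solve(p: Dict[str, Any]):
    model = _electrolyte(p)
    hg = HeadgroupModel.from_nm(
        float(p["D_nm"]), float(p["alpha"]), float(p["sigma1"]),
        float(p["sigma2"]), float(p["gap_nm"]),
    )
    prof = headgroup.solve_headgroup_edl(
        hg, model, n_nodes=int(p.get("n_nodes", 192001)))
    pres = headgroup.bilayer_wall_pressure(prof, model)
    b = prof.base
    table = pd.DataFrame(
        dict(x=b.x, phi=b.phi, E=b.E, eps_r=b.eps_r, n_plus=b.n_plus,
             n_minus=b.n_minus, rho=b.rho, P=prof.P, rho_zw=prof.rho_zw)
    )
    mean_x, mean_omega = headgroup.headgroup_orientation(prof)
    meta = dict(
        converged=bool(prof.converged), Lambda=prof.Lambda,
        mean_x=mean_x, mean_x_over_D=mean_x / hg.D, mean_omega=mean_omega,
        Pi=pres.Pi, constancy_residual=pres.constancy_residual,
        outer_iterations=prof.outer_iterations,
        normalization_defect=prof.normalization_defect,
    )
    return table, meta, prof.converged


def _contour_table(contour: vesicle.ShapeContour) -> pd.DataFrame:
    return pd.DataFrame(
        dict(s=contour.t * contour.L, r=contour.r, z=contour.z,
             psi=contour.psi, c1=contour.c1, c2=contour.c2)
    )


def _shape_meta(res: vesicle.ShapeResult) -> Dict[str, Any]:
    return dict(
        f=res.f, f_bend=res.f_bend, ac_frac=res.ac_frac,
        shape_class=res.shape_class, class_confidence=res.class_confidence,
        multipliers=res.multipliers, area_residual=res.area_residual,
        volume_residual=res.volume_residual,
        contact_curvature=res.contact_curvature,
        converged=bool(res.converged), message=res.message,
    )


def _vesicle_minimize(p: Dict[str, Any]):
    prob = vesicle.ReducedShapeProblem(
        v=float(p["v"]), c0=float(p.get("c0", 0.0)), w=float(p.get("w", 0.0)))
    res = vesicle.minimize_shape(
        prob, p.get("seed", "prolate"),
        n_modes=int(p.get("n_modes", 40)),
        n_points=int(p.get("n_points", 1200)),
    )
    return _contour_table(res.contour), _shape_meta(res), res.converged


def _vesicle_scan(p: Dict[str, Any]):
    results = vesicle.adhesion_scan(
        float(p["v"]), float(p.get("c0", 0.0)),
        [float(w) for w in p["w_list"]],
        seed=p.get("seed"),
        n_modes=int(p.get("n_modes", 40)),
        n_points=int(p.get("n_points", 1200)),
    )
    table = pd.DataFrame(
        [
            dict(w=r.problem.w, f=r.f, f_bend=r.f_bend, ac_frac=r.ac_frac,
                 shape_class=r.shape_class,
                 contact_curvature=r.contact_curvature,
                 converged=bool(r.converged))
            for r in results
        ]
    )
    ok = bool(table["converged"].all())
    meta = dict(converged=ok, points=[_shape_meta(r) for r in results])
    return table, meta, ok


def _vesicle_transition(p: Dict[str, Any]):
    pair = tuple(p["pair"])
    window = tuple(float(x) for x in p["window"])
    out = vesicle.find_transition(
        float(p.get("c0", 0.0)), float(p.get("w", 0.0)), pair, window,
        n_modes=int(p.get("n_modes", 40)),
        n_points=int(p.get("n_points", 1200)),
    )
    table = pd.DataFrame(
        [dict(v_star=out["v_star"], bracket_lo=out["bracket"][0],
              bracket_hi=out["bracket"][1], f_A=out["f_A"], f_B=out["f_B"])]
    )
    meta = dict(converged=True, v_star=out["v_star"],
                branch_pair=list(pair), f_A=out["f_A"], f_B=out["f_B"])
    return table, meta, True


_DISPATCH = {
    ("edl", "solve"): _edl_solve,
    ("edl", "pressure-curve"): _edl_pressure_curve,
    ("headgroup", "solve"): _headgroup_solve,
    ("vesicle", "minimize"): _vesicle_minimize,
    ("vesicle", "scan"): _vesicle_scan,
    ("vesicle", "transition"): _vesicle_transition,
}


def _atomic_write(path: str, data: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(data)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def execute(cfg: RunConfig) -> Dict[str, Any]:
    """Run the configured computation and (optionally) write its outputs.

    Returns a bundle {table, metadata, converged, files}; the metadata JSON
    always carries the full resolved parameter set for reproducibility.
    """
    params = cfg.resolved_params()
    log.info("running %s/%s with params %s", cfg.module, cfg.task, params)
    table, meta, ok = _DISPATCH[(cfg.module, cfg.task)](params)
    metadata = dict(
        schema_version=cfg.schema_version,
        module=cfg.module,
        task=cfg.task,
        preset=cfg.preset,
        resolved_params=params,
        **meta,
    )
    files: List[str] = []
    if cfg.output_prefix:
        csv_path = cfg.output_prefix + ".csv"
        json_path = cfg.output_prefix + ".json"
        _atomic_write(csv_path, table.to_csv(index=False, float_format="%.12g"))
        _atomic_write(json_path, json.dumps(metadata, indent=2, sort_keys=True,
                                            default=float) + "\n")
        files = [csv_path, json_path]
        log.info("wrote %s", ", ".join(files))
    if not ok:
        log.warning("computation did not fully converge")
    return dict(table=table, metadata=metadata, converged=ok, files=files)


def run_config(config_path: str) -> Dict[str, Any]:
    """Load, validate and execute a config file (validation-first)."""
    cfg = load_config(config_path)
    return execute(cfg)
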