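"""Scenario presets, YAML config round-tripping, and result tables.

The "data" of this analysis is its parameter space: every scenario is a
validated combination of gap geometry, pressure boundary condition, fluid
properties and solver settings.  This module materializes the printed
parameter sets as named presets, reads/writes them as YAML (μm and Pa,
the table-facing units), and writes sweep results with a reproducibility
manifest.
"""

from __future__ import annotations

import difflib
import json
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import yaml

from .geometry import GapGeometry, MicrocrackSpec, build_geometry
from .solver import FluidProperties, PressureBC, SolverSettings
from .sweeps import (
    CRACK_SIZE_VALUES,
    HEIGHT_VALUES,
    LARGE_GROOVE,
    PRESSURE_VALUES,
    SMALL_GROOVE_S34,
    SMALL_GROOVE_TABLE1,
    WIDTH_VALUES,
)

__all__ = [
    "Scenario",
    "ConfigError",
    "paper_presets",
    "read_config",
    "write_config",
    "results_writer",
    "TABLE1_HEIGHT_VALUES",
]

#: printed height row (descending); the height study itself uses
#: HEIGHT_VALUES = (100, 200, 500, 1000) μm
TABLE1_HEIGHT_VALUES = (1000.0, 800.0, 600.0, 400.0, 200.0, 100.0)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    name: str
    geometry: GapGeometry
    bc: PressureBC
    props: FluidProperties = FluidProperties()
    settings: SolverSettings = SolverSettings()
    target_size_um: float = 10.0
    refine_crack_factor: float = 0.25

    def __post_init__(self) -> None:
        build_geometry(self.geometry)
        if self.target_size_um <= 0:
            raise ConfigError("target_size_um must be positive")


def paper_presets() -> dict[str, Scenario]:
    """The 24 printed scenarios: pressure (4), width (6), height (4),
    crack depth (4), crack width (4) and the two small-groove readings.

    The crack-depth value 100 μm with width 50 μm *is* the large groove.
    All share ρ = 1000 kg/m³ and μ = 1 × 10⁻³ Pa·s.
    """
    base2d = GapGeometry(1500.0, 100.0, 100.0, crack=LARGE_GROOVE, dimensionality="planar_2d")
    base3d = GapGeometry(1500.0, 100.0, 100.0, crack=LARGE_GROOVE, dimensionality="full_3d")
    inlet300 = PressureBC(300.0, 0.0)
    out: dict[str, Scenario] = {}
    for dp in PRESSURE_VALUES:
        out[f"pressure_dp{dp:g}"] = Scenario(
            f"pressure_dp{dp:g}", base2d, PressureBC(dp, 0.0))
    for w in WIDTH_VALUES:
        g = GapGeometry(1500.0, w, 100.0, crack=LARGE_GROOVE, dimensionality="full_3d")
        out[f"width_w{w:g}"] = Scenario(f"width_w{w:g}", g, inlet300)
    for h in HEIGHT_VALUES:
        g = GapGeometry(1500.0, 100.0, h, crack=LARGE_GROOVE)
        out[f"height_h{h:g}"] = Scenario(f"height_h{h:g}", g, inlet300)
    for d in CRACK_SIZE_VALUES:
        g = GapGeometry(1500.0, 100.0, 100.0,
                        crack=MicrocrackSpec(depth_um=d, width_um=LARGE_GROOVE.width_um))
        out[f"crack_depth_d{d:g}"] = Scenario(f"crack_depth_d{d:g}", g, inlet300)
    for w in CRACK_SIZE_VALUES:
        g = GapGeometry(1500.0, 100.0, 100.0,
                        crack=MicrocrackSpec(depth_um=LARGE_GROOVE.depth_um, width_um=w))
        out[f"crack_width_w{w:g}"] = Scenario(f"crack_width_w{w:g}", g, inlet300)
    for name, groove in (("small_groove_table1", SMALL_GROOVE_TABLE1),
                         ("small_groove_s34", SMALL_GROOVE_S34)):
        g = GapGeometry(1500.0, 100.0, 100.0, crack=groove)
        out[name] = Scenario(name, g, inlet300)
    assert len(out) == 24
    return out


# ----------------------------------------------------------------------
# YAML config round-trip
# ----------------------------------------------------------------------

_SCHEMA = {
    "name": None,
    "geometry": {"length_um", "width_um", "height_um", "dimensionality", "crack"},
    "crack": {"depth_um", "width_um", "center_x_um", "span", "span_y_um"},
    "bc": {"inlet_pressure_pa", "outlet_pressure_pa", "inlet_type"},
    "fluid": {"density_kg_m3", "dynamic_viscosity_pa_s"},
    "solver": {"model", "newton_tol", "newton_max_iter", "continuation_steps",
               "stabilization", "open_boundary"},
    "mesh": {"target_size_um", "refine_crack_factor"},
}
_TOP_KEYS = {"name", "geometry", "bc", "fluid", "solver", "mesh"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(str(key), allowed, n=1)
            suggest = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suggest}")


def write_config(scenario: Scenario, path: str) -> None:
    g = scenario.geometry
    doc = {
        "name": scenario.name,
        "geometry": {
            "length_um": g.length_um, "width_um": g.width_um,
            "height_um": g.height_um, "dimensionality": g.dimensionality,
            "crack": None if g.crack is None else {
                k: v for k, v in asdict(g.crack).items() if v is not None
            },
        },
        "bc": {"inlet_pressure_pa": scenario.bc.inlet_pressure,
               "outlet_pressure_pa": scenario.bc.outlet_pressure,
               "inlet_type": scenario.bc.inlet_type},
        "fluid": {"density_kg_m3": scenario.props.density,
                  "dynamic_viscosity_pa_s": scenario.props.dynamic_viscosity},
        "solver": asdict(scenario.settings),
        "mesh": {"target_size_um": scenario.target_size_um,
                 "refine_crack_factor": scenario.refine_crack_factor},
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def read_config(path: str) -> Scenario:
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    for section in ("name", "geometry", "bc"):
        if section not in doc:
            raise ConfigError(f"missing required section {section!r}")
    gdoc = doc["geometry"]
    _check_keys(gdoc, _SCHEMA["geometry"], "geometry")
    crack = None
    if gdoc.get("crack") is not None:
        cdoc = gdoc["crack"]
        _check_keys(cdoc, _SCHEMA["crack"], "geometry.crack")
        crack = MicrocrackSpec(**cdoc)
    try:
        geom = GapGeometry(
            length_um=float(gdoc["length_um"]), width_um=float(gdoc["width_um"]),
            height_um=float(gdoc["height_um"]), crack=crack,
            dimensionality=gdoc.get("dimensionality", "planar_2d"),
        )
        geom = build_geometry(geom)
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid geometry: {exc}") from exc
    bdoc = doc["bc"]
    _check_keys(bdoc, _SCHEMA["bc"], "bc")
    bc = PressureBC(float(bdoc["inlet_pressure_pa"]),
                    float(bdoc.get("outlet_pressure_pa", 0.0)),
                    inlet_type=bdoc.get("inlet_type", "static"))
    fdoc = doc.get("fluid", {})
    _check_keys(fdoc, _SCHEMA["fluid"], "fluid")
    props = FluidProperties(
        density=float(fdoc.get("density_kg_m3", 1000.0)),
        dynamic_viscosity=float(fdoc.get("dynamic_viscosity_pa_s", 1e-3)),
    )
    sdoc = doc.get("solver", {})
    _check_keys(sdoc, _SCHEMA["solver"], "solver")
    settings = SolverSettings(**sdoc)
    mdoc = doc.get("mesh", {})
    _check_keys(mdoc, _SCHEMA["mesh"], "mesh")
    return Scenario(
        name=str(doc["name"]), geometry=geom, bc=bc, props=props, settings=settings,
        target_size_um=float(mdoc.get("target_size_um", 10.0)),
        refine_crack_factor=float(mdoc.get("refine_crack_factor", 0.25)),
    )


# ----------------------------------------------------------------------
# Result tables + manifest
# ----------------------------------------------------------------------

def results_writer(results: dict, report: dict | None, output_dir: str) -> list[str]:
    """Write sweep tables, profiles, gradient tables and a manifest.

    ``results`` maps sweep name → SweepResult.  Tables are CSV with
    unit-bearing headers; the manifest records solver settings, mesh sizes
    and per-case Reynolds numbers for reproducibility.
    """
    os.makedirs(output_dir, exist_ok=True)
    written: list[str] = []
    try:
        from importlib.metadata import version as _pkg_version
        _version = _pkg_version("trabflow")
    except Exception:
        _version = "unknown"
    manifest: dict = {
        "software": f"trabflow {_version}",
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "sweeps": {},
    }
    for name, res in results.items():
        tab = res.table.rename(columns={"value": f"{res.config.parameter}"})
        path = os.path.join(output_dir, f"peaks_{name}.csv")
        tab.to_csv(path, index=False)
        written.append(path)
        prof_rows = []
        for prof in res.profiles:
            if prof is None:
                continue
            for x, v in zip(prof.x_um, prof.values):
                prof_rows.append({
                    "parameter": res.config.parameter,
                    "value": prof.metadata.get("value"),
                    "x_um": x, "fss_pa": v,
                })
        if prof_rows:
            import pandas as pd
            ppath = os.path.join(output_dir, f"profiles_{name}.csv")
            pd.DataFrame(prof_rows).to_csv(ppath, index=False)
            written.append(ppath)
        manifest["sweeps"][name] = {
            "parameter": res.config.parameter,
            "values": list(res.config.values),
            "target_size_um": res.config.target_size_um,
            "model": res.config.settings.model,
            "reynolds": [float(r) for r in res.table["reynolds"]],
            "converged": [bool(c) for c in res.table["converged"]],
        }
    if report is not None:
        summary = {}
        for key in ("pressure_fit", "height_fit"):
            if key in report:
                summary[key] = asdict(report[key])
        for key in ("peak_at_h1000_pa", "width_drop_800_to_100_percent",
                    "crack_invariance"):
            if key in report:
                summary[key] = report[key]
        if "gradients" in report:
            summary["gradients"] = {
                k: {kk: vv for kk, vv in v.items() if kk != "field"}
                for k, v in report["gradients"].items()
            }
            import pandas as pd
            for gname, g in report["gradients"].items():
                gf = g["field"]
                gpath = os.path.join(output_dir, f"gradient_{gname}.csv")
                pd.DataFrame({
                    "arc_mm": gf.arc_mm, "fss_pa": gf.fss_pa,
                    "gradient_pa_per_mm": gf.gradient_pa_per_mm,
                    "region": gf.region,
                }).to_csv(gpath, index=False)
                written.append(gpath)
        spath = os.path.join(output_dir, "summary.json")
        with open(spath, "w") as f:
            json.dump(summary, f, indent=2, default=float)
        written.append(spath)
    mpath = os.path.join(output_dir, "manifest.json")
    with open(mpath, "w") as f:
        json.dump(manifest, f, indent=2)
    written.append(mpath)
    return written
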