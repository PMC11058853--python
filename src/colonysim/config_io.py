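"""Run configuration: a sectioned CSV dialect, validation, and file outputs.

A configuration file is plain CSV with a ``section,key,value`` triple per
row.  Sections are ``run`` (steps, seed, output options), ``plate``
(geometry), ``nutrient`` (layer levels, sigmas, flowrate, optional gradient
layout), ``strain:<id>``, ``inoculation:<id>`` and ``event:<id>`` (refeed or
parameter-switch events).  Energetic and nutrient values are abstract units,
lengths are grid cells, times are steps (24 steps per simulated day).  The
first data row carries the schema version.

Example::

    section,key,value
    run,schema_version,1
    run,n_steps,336
    run,seed,1
    plate,shape,circular
    plate,n_rows,200
    plate,n_cols,200
    nutrient,init_top,3.0
    nutrient,init_deep,6.0
    strain:wt,division_distance,1.0
    inoculation:c0,center_x,100
    inoculation:c0,center_y,100
    inoculation:c0,radius,4
    inoculation:c0,n_agents,120
    inoculation:c0,strain,wt
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from .agents import StrainParams
from .engine import MAX_COLONIES, InoculationSpec, ParamSwitchEvent, Simulation, Trajectory
from .environment import (
    DEFAULT_PX_PER_MM2,
    NutrientLayers,
    PlateGeometry,
    RefeedEvent,
    init_gradient_plate,
)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass
class NutrientConfig:
    init_top: float = 3.0
    init_deep: float = 6.0
    sigma_top: float = 1.0
    sigma_deep: float = 1.0
    flowrate: float = 0.5
    layout: str = "uniform"  # or "gradient"
    gradient_fraction: float = 0.2
    gradient_multiplier: float = 1.0
    gradient_pre_steps: int = 0


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (except the seed override)."""

    n_rows: int = 200
    n_cols: int = 200
    shape: str = "circular"
    px_per_mm2: float = DEFAULT_PX_PER_MM2
    nutrient: NutrientConfig = field(default_factory=NutrientConfig)
    strains: dict[str, StrainParams] = field(default_factory=dict)
    inoculations: list[InoculationSpec] = field(default_factory=list)
    events: list = field(default_factory=list)
    n_steps: int = 336
    seed: int = 0
    area_threshold: int = 1
    snapshot_steps: tuple[int, ...] = ()
    visualize: bool = False

    def validate(self) -> None:
        problems = []
        if not self.strains:
            problems.append("at least one strain must be declared")
        if not 1 <= len(self.inoculations) <= MAX_COLONIES:
            problems.append(f"number of inoculations must be in 1..{MAX_COLONIES}")
        for spec in self.inoculations:
            if spec.strain not in self.strains:
                problems.append(
                    f"inoculation:{spec.colony_id} references undeclared strain {spec.strain!r}"
                )
        ids = [s.colony_id for s in self.inoculations]
        if len(set(ids)) != len(ids):
            problems.append("colony ids must be unique")
        if self.n_steps < 0:
            problems.append("run.n_steps must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))

    # -- construction of live objects ----------------------------------

    def geometry(self) -> PlateGeometry:
        return PlateGeometry(self.n_rows, self.n_cols, self.shape, self.px_per_mm2)

    def layers(self) -> NutrientLayers:
        nc = self.nutrient
        geom = self.geometry()
        if nc.layout == "gradient":
            return init_gradient_plate(
                geom,
                nc.init_top,
                nc.init_deep,
                nc.sigma_top,
                nc.sigma_deep,
                nc.flowrate,
                nutrient_fraction_rows=nc.gradient_fraction,
                concentration_multiplier=nc.gradient_multiplier,
                pre_diffusion_steps=nc.gradient_pre_steps,
            )
        return NutrientLayers.uniform(
            geom, nc.init_top, nc.init_deep, nc.sigma_top, nc.sigma_deep, nc.flowrate
        )

    def build(self, seed: int | None = None) -> Simulation:
        self.validate()
        return Simulation(
            self.geometry(),
            self.layers(),
            self.strains,
            self.inoculations,
            events=self.events,
            seed=self.seed if seed is None else seed,
            area_threshold=self.area_threshold,
            snapshot_steps=self.snapshot_steps,
        )

    def run(self, seed: int | None = None, n_steps: int | None = None) -> Simulation:
        sim = self.build(seed)
        sim.run(self.n_steps if n_steps is None else n_steps)
        return sim


# ---------------------------------------------------------------------
# parsing


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


_STRAIN_FIELDS = {f.name for f in dc_fields(StrainParams)}


def parse_config(path: str | Path) -> RunConfig:
    """Read and fully validate a sectioned-CSV configuration file."""
    path = Path(path)
    sections: dict[str, dict[str, object]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and [c.strip().lower() for c in row] == ["section", "key", "value"]:
                continue
            if len(row) < 3:
                raise ConfigError(f"{path}:{lineno}: expected 'section,key,value'")
            section, key, value = row[0].strip(), row[1].strip(), ",".join(row[2:]).strip()
            sections.setdefault(section, {})[key] = _coerce(value)
    return config_from_sections(sections, source=str(path))


def config_from_sections(sections: dict[str, dict], source: str = "<memory>") -> RunConfig:
    cfg = RunConfig()
    run = sections.get("run", {})
    version = run.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"{source}: unsupported schema_version {version}")
    for key in ("n_steps", "seed", "area_threshold"):
        if key in run:
            setattr(cfg, key, int(run[key]))
    if "visualize" in run:
        cfg.visualize = bool(run["visualize"])
    if "snapshot_steps" in run:
        raw = str(run["snapshot_steps"])
        cfg.snapshot_steps = tuple(int(v) for v in raw.split(";") if v != "")

    plate = sections.get("plate", {})
    for key in ("n_rows", "n_cols"):
        if key in plate:
            setattr(cfg, key, int(plate[key]))
    if "shape" in plate:
        cfg.shape = str(plate["shape"])
    if "px_per_mm2" in plate:
        cfg.px_per_mm2 = float(plate["px_per_mm2"])

    nut = sections.get("nutrient", {})
    for key in (
        "init_top",
        "init_deep",
        "sigma_top",
        "sigma_deep",
        "flowrate",
        "gradient_fraction",
        "gradient_multiplier",
    ):
        if key in nut:
            setattr(cfg.nutrient, key, float(nut[key]))
    if "layout" in nut:
        cfg.nutrient.layout = str(nut["layout"])
    if "gradient_pre_steps" in nut:
        cfg.nutrient.gradient_pre_steps = int(nut["gradient_pre_steps"])

    for name, body in sections.items():
        if name.startswith("strain:"):
            sid = name.split(":", 1)[1]
            unknown = set(body) - _STRAIN_FIELDS
            if unknown:
                raise ConfigError(f"{source}: {name}: unknown key(s) {sorted(unknown)}")
            try:
                cfg.strains[sid] = StrainParams(strain_id=sid, **{k: float(v) for k, v in body.items() if k != "strain_id"})
            except ValueError as exc:
                raise ConfigError(f"{source}: {name}: {exc}") from exc
    for name, body in sorted(sections.items()):
        if name.startswith("inoculation:"):
            cid = name.split(":", 1)[1]
            try:
                cfg.inoculations.append(
                    InoculationSpec(
                        center=(float(body["center_x"]), float(body["center_y"])),
                        radius=float(body.get("radius", 0)),
                        n_agents=int(body.get("n_agents", 1)),
                        strain=str(body.get("strain", "wt")),
                        colony_id=cid,
                        at_step=int(body.get("at_step", 0)),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"{source}: {name}: missing mandatory key {exc}") from exc
    for name, body in sorted(sections.items()):
        if name.startswith("event:"):
            kind = str(body.get("kind", "refeed"))
            if kind == "refeed":
                cfg.events.append(
                    RefeedEvent(
                        step=int(body.get("step", 0)),
                        amount=float(body.get("amount", 0.0)),
                        region=str(body.get("region", "all")),
                        layer=str(body.get("layer", "both")),
                    )
                )
            elif kind == "switch":
                updates: dict[str, dict[str, float]] = {}
                for key, value in body.items():
                    if key.startswith("set:"):
                        _, sid, fname = key.split(":", 2)
                        updates.setdefault(sid, {})[fname] = float(value)
                cfg.events.append(
                    ParamSwitchEvent(
                        step=int(body.get("step", 0)),
                        strain_updates=updates,
                        sigma_top=float(body["sigma_top"]) if "sigma_top" in body else None,
                        sigma_deep=float(body["sigma_deep"]) if "sigma_deep" in body else None,
                        flowrate=float(body["flowrate"]) if "flowrate" in body else None,
                    )
                )
            else:
                raise ConfigError(f"{source}: {name}: unknown event kind {kind!r}")
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------
# writing


def config_to_sections(cfg: RunConfig) -> dict[str, dict]:
    sections: dict[str, dict] = {
        "run": {
            "schema_version": SCHEMA_VERSION,
            "n_steps": cfg.n_steps,
            "seed": cfg.seed,
            "area_threshold": cfg.area_threshold,
            "visualize": cfg.visualize,
        },
        "plate": {
            "shape": cfg.shape,
            "n_rows": cfg.n_rows,
            "n_cols": cfg.n_cols,
            "px_per_mm2": cfg.px_per_mm2,
        },
        "nutrient": {
            "layout": cfg.nutrient.layout,
            "init_top": cfg.nutrient.init_top,
            "init_deep": cfg.nutrient.init_deep,
            "sigma_top": cfg.nutrient.sigma_top,
            "sigma_deep": cfg.nutrient.sigma_deep,
            "flowrate": cfg.nutrient.flowrate,
        },
    }
    if cfg.snapshot_steps:
        sections["run"]["snapshot_steps"] = ";".join(str(s) for s in cfg.snapshot_steps)
    if cfg.nutrient.layout == "gradient":
        sections["nutrient"].update(
            gradient_fraction=cfg.nutrient.gradient_fraction,
            gradient_multiplier=cfg.nutrient.gradient_multiplier,
            gradient_pre_steps=cfg.nutrient.gradient_pre_steps,
        )
    for sid, sp in cfg.strains.items():
        sections[f"strain:{sid}"] = {
            f.name: getattr(sp, f.name) for f in dc_fields(StrainParams) if f.name != "strain_id"
        }
    for spec in cfg.inoculations:
        sections[f"inoculation:{spec.colony_id}"] = {
            "center_x": spec.center[0],
            "center_y": spec.center[1],
            "radius": spec.radius,
            "n_agents": spec.n_agents,
            "strain": spec.strain,
            "at_step": spec.at_step,
        }
    for i, event in enumerate(cfg.events):
        name = f"event:e{i}"
        if isinstance(event, RefeedEvent):
            sections[name] = {
                "kind": "refeed",
                "step": event.step,
                "amount": event.amount,
                "region": event.region,
                "layer": event.layer,
            }
        else:
            body: dict = {"kind": "switch", "step": event.step}
            for sid, updates in event.strain_updates.items():
                for fname, value in updates.items():
                    body[f"set:{sid}:{fname}"] = value
            for key in ("sigma_top", "sigma_deep", "flowrate"):
                if getattr(event, key) is not None:
                    body[key] = getattr(event, key)
            sections[name] = body
    return sections


def write_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    sections = config_to_sections(cfg)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["section", "key", "value"])
        for section in sections:
            for key, value in sections[section].items():
                writer.writerow([section, key, value])


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_to_sections(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------
# run outputs


def write_outputs(
    sim: Simulation,
    cfg: RunConfig,
    out_dir: str | Path,
    save_png: bool = False,
) -> dict[str, Path]:
    """Write trajectory.csv, areas.csv, density grids and a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    traj = sim.trajectory.to_frame()
    files["trajectory"] = out_dir / "trajectory.csv"
    traj.to_csv(files["trajectory"], index=False)

    rows = []
    for cid in sim.colony_ids:
        steps, area_px = sim.trajectory.area_series(cid)
        for s, a in zip(steps, area_px):
            rows.append(
                {
                    "step": int(s),
                    "colony_id": cid,
                    "area_px": a,
                    "area_mm2": a / sim.geometry.px_per_mm2,
                }
            )
    import pandas as pd

    files["areas"] = out_dir / "areas.csv"
    pd.DataFrame(rows, columns=["step", "colony_id", "area_px", "area_mm2"]).to_csv(
        files["areas"], index=False
    )

    density = sim.density_grid()
    files["density"] = out_dir / f"density_step{sim.step_count}.csv"
    np.savetxt(files["density"], density, fmt="%g", delimiter=",")
    for step, grid in sorted(sim.snapshots.items()):
        snap_path = out_dir / f"density_step{step}.csv"
        np.savetxt(snap_path, grid, fmt="%g", delimiter=",")
        files[f"density_{step}"] = snap_path
    if save_png:
        files["density_png"] = out_dir / f"density_step{sim.step_count}.png"
        save_density_png(sim, files["density_png"])

    files["config"] = out_dir / "config.csv"
    write_config(cfg, files["config"])
    files["manifest"] = out_dir / "manifest.json"
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": sim.seed,
        "n_steps": sim.step_count,
        "schema_version": SCHEMA_VERSION,
    }
    files["manifest"].write_text(json.dumps(manifest, indent=2))
    return files


def save_density_png(sim: Simulation, path: str | Path) -> None:
    """State-coloured final snapshot: nutrient background, agents on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(sim.layers.top + sim.layers.deep, cmap="YlOrBr", origin="lower")
    pop = sim.population
    from .agents import AgentState

    for state, color, label in (
        (AgentState.ACTIVE, "tab:green", "active"),
        (AgentState.G0, "tab:blue", "G0"),
    ):
        sel = pop.state == state
        if sel.any():
            ax.plot(pop.x[sel], pop.y[sel], ".", ms=0.5, color=color, label=label)
    ax.set_title(f"step {sim.step_count}")
    ax.legend(markerscale=20, loc="upper right")
    fig.savefig(path, dpi=120)
    plt.close(fig)
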