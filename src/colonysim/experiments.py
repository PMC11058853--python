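"""Preset scenarios: one ready-made configuration per studied plate layout.

Each preset returns a complete :class:`~colonysim.config_io.RunConfig` for
one of the studied experimental layouts: one to six colonies sharing a Petri
dish, the 24-droplet OmniTray grid crossing droplet size with founder count,
wet / dry / alternating moisture conditions on a 50 mm agar disc, nutrient
gradient plates, the biweekly-refed giant colony, re-inoculation next to an
aging colony, and the single-cell / droplet colonies used for the
cross-section shapes.

Scale: presets render an 85 mm dish on a 200x200 grid (0.425 mm per cell),
so each preset runs in minutes on one CPU; the per-preset ``px_per_mm2``
reflects that resolution.  The reference conversion of 55.6
px/mm^2 corresponds to a ~7.5x finer grid and can be requested through the
``scale`` argument.

Energetic parameter values are the package's own surrogate set (the model's
abstract units are not tied to physical measurements): a well-fed active
agent gains 0.8 energy units per step net and so divides every 2 steps, the
two-hour division period of well-fed budding yeast at one step per hour.
Wet agar is represented purely by a larger division distance (daughters
slide further on a wetter surface) and faster nutrient diffusion; those
values are the only differences between the wet and dry presets.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .agents import StrainParams
from .config_io import NutrientConfig, RunConfig, write_outputs
from .engine import InoculationSpec, ParamSwitchEvent, Simulation
from .environment import RefeedEvent
from .measurement import AreaSeries, cross_section_profile, radial_growth_rate

#: millimetres represented by one grid cell at the default preset scale
MM_PER_CELL = 85.0 / 200.0

#: surrogate moisture parameter sets: wet agar raises the division distance
#: (daughters slide further on the wetter surface) and the diffusion sigmas;
#: both effects compound, so the modest parameter difference roughly doubles
#: the emergent radial expansion speed
DRY = {"division_distance": 0.8, "sigma_top": 0.6, "sigma_deep": 1.2}
WET = {"division_distance": 0.9, "sigma_top": 0.9, "sigma_deep": 1.8}

#: droplet volumes (ul) used on the 24-droplet grid and their surrogate
#: spread radii in grid cells (radius grows sublinearly with volume, chosen
#: so a 5 ul droplet starts ~2.8x larger in area than a 0.5 ul one)
DROPLET_RADIUS = {0.5: 2.8, 1.0: 3.3, 2.0: 3.8, 3.0: 4.2, 4.0: 4.5, 5.0: 4.7}

#: founder counts per droplet; one agent stands for ~10 cells
FOUNDERS = {1000: 100, 2000: 200, 4000: 400, 8000: 800}


def _base_strain(condition: dict | None = None, strain_id: str = "wt") -> StrainParams:
    # a small G0 uptake (with zero G0 cost) lets quiescent agents charge up
    # and reactivate when nutrient returns — the pathway behind regrowth
    # after refeeding and behind growth resuming when a gradient arrives
    sp = StrainParams(strain_id=strain_id, uptake_rate_g0=0.1)
    if condition:
        sp = sp.replace(division_distance=condition["division_distance"])
    return sp


def _geometry_kw(diameter_mm: float, scale: float = 1.0, shape: str = "circular"):
    n = int(round(diameter_mm / MM_PER_CELL * scale))
    return {
        "n_rows": n,
        "n_cols": n,
        "shape": shape,
        "px_per_mm2": (n / diameter_mm) ** 2,
    }


def _petri_config(condition: dict, n_steps: int, scale: float = 1.0) -> RunConfig:
    cfg = RunConfig(**_geometry_kw(85.0, scale))
    cfg.nutrient = NutrientConfig(
        init_top=3.0,
        init_deep=6.0,
        sigma_top=condition["sigma_top"] * scale,
        sigma_deep=condition["sigma_deep"] * scale,
        flowrate=0.5,
    )
    cfg.strains = {"wt": _base_strain(condition)}
    cfg.n_steps = n_steps
    return cfg


def _ring_positions(n: int, cx: float, cy: float, ring_r: float) -> list[tuple[float, float]]:
    if n == 1:
        return [(cx, cy)]
    return [
        (cx + ring_r * math.cos(2 * math.pi * k / n), cy + ring_r * math.sin(2 * math.pi * k / n))
        for k in range(n)
    ]


def _multi_colony(n_colonies: int, scale: float) -> RunConfig:
    cfg = _petri_config(DRY, n_steps=480, scale=scale)
    c = cfg.n_rows / 2.0
    ring = 0.55 * c
    for i, (x, y) in enumerate(_ring_positions(n_colonies, c, c, ring)):
        cfg.inoculations.append(
            InoculationSpec((x, y), radius=4.0 * scale, n_agents=100, strain="wt", colony_id=f"c{i}")
        )
    return cfg


def _droplet_fig1(kind: str, scale: float) -> RunConfig:
    cfg = _petri_config(DRY, n_steps=240, scale=scale)  # 10 days
    # slow starvation of fully dormant quiescent agents: the crowded droplet
    # interior thins out over days, carving the central crater of the
    # volcano-shaped density profile; single-founder colonies stay conical
    # far longer because their interior quiesces much later
    cfg.strains["wt"] = cfg.strains["wt"].replace(
        uptake_rate_g0=0.0, metabolic_cost_g0=0.003
    )
    c = cfg.n_rows / 2.0
    radius = {"single_cell": 0.0, "droplet_1ul": 3.3, "droplet_3ul": 4.2}[kind]
    n_agents = {"single_cell": 1, "droplet_1ul": 300, "droplet_3ul": 500}[kind]
    cfg.inoculations.append(
        InoculationSpec((c, c), radius=radius * scale, n_agents=n_agents, strain="wt", colony_id="c0")
    )
    return cfg


def _droplet_grid(scale: float) -> RunConfig:
    # OmniTray, 128 x 86 mm; columns sweep droplet volume, rows founder count
    n_cols = int(round(128.0 / MM_PER_CELL * scale))
    n_rows = int(round(86.0 / MM_PER_CELL * scale))
    cfg = RunConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        shape="rectangular",
        px_per_mm2=(n_cols / 128.0) ** 2,
    )
    # moderate nutrient so growth decelerates within the first week, as on
    # densely spotted plates where all spots drain the agar
    cfg.nutrient = NutrientConfig(
        init_top=1.5,
        init_deep=3.0,
        sigma_top=DRY["sigma_top"] * scale,
        sigma_deep=DRY["sigma_deep"] * scale,
        flowrate=0.5,
    )
    cfg.strains = {"wt": _base_strain(DRY)}
    cfg.n_steps = 336
    volumes = sorted(DROPLET_RADIUS)
    counts = sorted(FOUNDERS)
    dx = n_cols / len(volumes)
    dy = n_rows / len(counts)
    for col, vol in enumerate(volumes):
        for row, count in enumerate(counts):
            cfg.inoculations.append(
                InoculationSpec(
                    ((col + 0.5) * dx, (row + 0.5) * dy),
                    radius=DROPLET_RADIUS[vol] * scale,
                    n_agents=FOUNDERS[count],
                    strain="wt",
                    colony_id=f"v{vol:g}_n{count}",
                )
            )
    return cfg


def _wetness(kind: str, scale: float) -> RunConfig:
    first = WET if kind in ("wet", "alternating_wet_dry") else DRY
    second = {
        "wet": WET,
        "dry": DRY,
        "alternating_wet_dry": DRY,
        "alternating_dry_wet": WET,
    }[kind]
    n = int(round(50.0 / MM_PER_CELL * scale))
    cfg = RunConfig(n_rows=n, n_cols=n, shape="circular", px_per_mm2=(n / 50.0) ** 2)
    cfg.nutrient = NutrientConfig(
        init_top=3.0,
        init_deep=6.0,
        sigma_top=first["sigma_top"] * scale,
        sigma_deep=first["sigma_deep"] * scale,
        flowrate=0.5,
    )
    cfg.strains = {"wt": _base_strain(first)}
    c = n / 2.0
    cfg.inoculations.append(
        InoculationSpec((c, c), radius=4.2 * scale, n_agents=100, strain="wt", colony_id="c0")
    )
    cfg.n_steps = 336  # 14 days
    # day-7 media refresh: fresh nutrient enters through the outer ring
    refresh_step = 168
    cfg.events.append(
        RefeedEvent(step=refresh_step, amount=3.0, region=f"ring:{max(2, int(6 * scale))}", layer="both")
    )
    if second is not first:
        cfg.events.append(
            ParamSwitchEvent(
                step=refresh_step,
                strain_updates={"wt": {"division_distance": second["division_distance"]}},
                sigma_top=second["sigma_top"] * scale,
                sigma_deep=second["sigma_deep"] * scale,
            )
        )
    return cfg


#: 4x4 inoculation grid of the gradient plates with the left two columns
#: full and one colony left out of each row in the right half
GRADIENT_OMITTED = {(0, 2), (1, 3), (2, 2), (3, 3)}


def _gradient(kind: str, scale: float) -> RunConfig:
    n_cols = int(round(86.0 / MM_PER_CELL * scale))
    n_rows = int(round(128.0 / MM_PER_CELL * scale))
    n_rows -= n_rows % 5  # the nutrient band is exactly the top fifth of rows
    cfg = RunConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        shape="rectangular",
        px_per_mm2=(n_rows / 128.0) ** 2,
    )
    layout = "uniform" if kind == "gradient_control" else "gradient"
    multiplier = 5.0 if kind == "gradient_5x" else 1.0
    # the deep layer carries the plate-scale transport that lets band
    # nutrient cross the plain-agar region within the 20-day experiment;
    # a slow inter-layer flow keeps it from surfacing (and being consumed)
    # right next to the band
    cfg.nutrient = NutrientConfig(
        init_top=4.0,
        init_deep=8.0,
        sigma_top=DRY["sigma_top"] * scale,
        sigma_deep=14.0 * scale,
        flowrate=0.2,
        layout=layout,
        gradient_fraction=0.2,
        gradient_multiplier=multiplier,
        gradient_pre_steps=0,
    )
    cfg.strains = {"wt": _base_strain(DRY)}
    cfg.n_steps = 480  # 20 days
    # colonies sit in the lower 4/5 of the plate (the nutrient band is the
    # top 1/5); rows of the 4x4 grid are indexed away from the band
    band = 0.2 * n_rows
    usable = n_rows - band
    dy = usable / 4.0
    dx = n_cols / 4.0
    for row in range(4):
        for col in range(4):
            if (row, col) in GRADIENT_OMITTED:
                continue
            cfg.inoculations.append(
                InoculationSpec(
                    ((col + 0.5) * dx, band + (row + 0.5) * dy),
                    radius=4.2 * scale,
                    n_agents=100,
                    strain="wt",
                    colony_id=f"r{row}c{col}",
                )
            )
    return cfg


def _giant_refeed(scale: float) -> RunConfig:
    cfg = RunConfig(**_geometry_kw(135.0, scale))
    cfg.nutrient = NutrientConfig(
        init_top=3.0,
        init_deep=6.0,
        sigma_top=WET["sigma_top"] * scale,
        sigma_deep=WET["sigma_deep"] * scale,
        flowrate=0.5,
    )
    cfg.strains = {"wt": _base_strain(WET)}
    c = cfg.n_rows / 2.0
    cfg.inoculations.append(
        InoculationSpec((c, c), radius=4.2 * scale, n_agents=100, strain="wt", colony_id="c0")
    )
    cfg.n_steps = 1008  # 6 weeks at desk scale
    for step in (336, 672):  # biweekly refeed of the whole dish
        cfg.events.append(RefeedEvent(step=step, amount=3.0, region="all", layer="both"))
    return cfg


def _reinoculation(scale: float) -> RunConfig:
    cfg = _petri_config(DRY, n_steps=864, scale=scale)  # 36 days
    c = cfg.n_rows / 2.0
    cfg.inoculations.append(
        InoculationSpec((c, c), radius=4.2 * scale, n_agents=100, strain="wt", colony_id="old")
    )
    # fresh droplets at day 20: one on the aging colony's edge, one beside it
    edge = 24.0 * scale
    cfg.inoculations.append(
        InoculationSpec(
            (c + edge, c), radius=4.2 * scale, n_agents=100, strain="wt",
            colony_id="on_edge", at_step=480,
        )
    )
    cfg.inoculations.append(
        InoculationSpec(
            (c + 2.2 * edge, c), radius=4.2 * scale, n_agents=100, strain="wt",
            colony_id="beside", at_step=480,
        )
    )
    return cfg


_PRESETS = {
    **{f"multi_colony_{n}": (lambda scale, n=n: _multi_colony(n, scale)) for n in range(1, 7)},
    "single_cell": lambda scale: _droplet_fig1("single_cell", scale),
    "droplet_1ul": lambda scale: _droplet_fig1("droplet_1ul", scale),
    "droplet_3ul": lambda scale: _droplet_fig1("droplet_3ul", scale),
    "droplet_grid_4x6": _droplet_grid,
    "wet": lambda scale: _wetness("wet", scale),
    "dry": lambda scale: _wetness("dry", scale),
    "alternating_wet_dry": lambda scale: _wetness("alternating_wet_dry", scale),
    "alternating_dry_wet": lambda scale: _wetness("alternating_dry_wet", scale),
    "gradient_1x": lambda scale: _gradient("gradient_1x", scale),
    "gradient_5x": lambda scale: _gradient("gradient_5x", scale),
    "gradient_control": lambda scale: _gradient("gradient_control", scale),
    "giant_refeed": _giant_refeed,
    "reinoculation": _reinoculation,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, scale: float = 1.0) -> RunConfig:
    """Build the named scenario configuration.

    ``scale`` multiplies the grid resolution (1.0 = 0.425 mm per cell);
    lengths expressed in grid cells (division distance, sigmas, radii,
    positions) scale with it so the physical scenario is unchanged.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    cfg = factory(scale)
    cfg.validate()
    return cfg


def run_scenario(
    name: str,
    seed: int = 0,
    out_dir: str | Path | None = None,
    scale: float = 1.0,
    n_steps: int | None = None,
) -> tuple[Simulation, dict]:
    """Run a preset and compute its per-scenario report.

    The report holds, per colony, the final area (px and mm^2), the
    first-week radial growth rate in mm/day, and the centre-row density
    profile; with ``out_dir`` set the trajectory, areas, density grid and
    manifest are written there as well.
    """
    cfg = preset(name, scale=scale)
    if n_steps is not None:
        cfg.n_steps = n_steps
    sim = cfg.run(seed=seed)
    report: dict = {"name": name, "seed": seed, "colonies": {}}
    geom = sim.geometry
    for spec in cfg.inoculations:
        cid = spec.colony_id
        steps, area_px = sim.trajectory.area_series(cid)
        series = AreaSeries(cid, steps, area_px, px_per_mm2=geom.px_per_mm2)
        entry = {
            "final_area_px": float(area_px[-1]),
            "final_area_mm2": float(area_px[-1] / geom.px_per_mm2),
        }
        if series.days[-1] >= 2 and np.count_nonzero(series.days <= 7) >= 2:
            entry["rate_week1_mm_per_day"] = radial_growth_rate(series, (0.0, min(7.0, series.days[-1])))
        row = int(spec.center[1])
        entry["profile"] = cross_section_profile(sim.density_grid(cid), row).tolist()
        report["colonies"][cid] = entry
    areas = [c["final_area_px"] for c in report["colonies"].values()]
    report["mean_final_area_px"] = float(np.mean(areas))
    if out_dir is not None:
        out_dir = Path(out_dir)
        files = write_outputs(sim, cfg, out_dir, save_png=cfg.visualize)
        profile_rows = []
        for cid, entry in report["colonies"].items():
            for x, value in enumerate(entry["profile"]):
                profile_rows.append({"colony_id": cid, "x": x, "density": value})
        import pandas as pd

        pd.DataFrame(profile_rows).to_csv(out_dir / "profiles.csv", index=False)
    return sim, report
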