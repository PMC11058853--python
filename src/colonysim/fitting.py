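"""Calibration of simulator parameters to colony-area time series.

The objective is the sum of squared differences between simulated and
reference colony areas in pixels, summed over all colonies and over the
reference time points; simulated step series are sampled at the reference
days (round(day * 24) steps).  Minimisation uses the Nelder-Mead simplex
on log-transformed parameters (all fit-able parameters are strictly
positive, so the unconstrained simplex cannot propose invalid values).
Because a single run is stochastic, each objective evaluation averages the
simulated series over a fixed small set of seeds, giving the simplex a
quasi-deterministic surface.

A synthetic-target generator runs the simulator at known "true" parameters
and adds optional Gaussian pixel noise, which supports parameter-recovery
testing without any experimental tables.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config_io import RunConfig
from .engine import STEPS_PER_DAY

logger = logging.getLogger(__name__)

#: parameters the fitter knows how to apply to a RunConfig
FITTABLE = (
    "division_distance",
    "sigma_top",
    "sigma_deep",
    "flowrate",
    "init_top",
    "init_deep",
    "inoculation_radius",
)

#: objective value substituted when a simulation fails during an evaluation
FAILURE_PENALTY = 1e12


def apply_params(cfg: RunConfig, values: dict[str, float]) -> RunConfig:
    """Return a copy of ``cfg`` with the named free parameters replaced.

    ``division_distance`` applies to every strain and ``inoculation_radius``
    to every inoculation; the remaining names address the nutrient layers.
    """
    cfg = copy.deepcopy(cfg)
    for name, value in values.items():
        if name == "division_distance":
            for sid in cfg.strains:
                cfg.strains[sid] = cfg.strains[sid].replace(division_distance=float(value))
        elif name == "inoculation_radius":
            for spec in cfg.inoculations:
                spec.radius = float(value)
        elif name in ("sigma_top", "sigma_deep", "flowrate", "init_top", "init_deep"):
            setattr(cfg.nutrient, name, float(value))
        else:
            raise ValueError(f"unknown fit parameter {name!r}; choose from {FITTABLE}")
    return cfg


def align(sim_steps: np.ndarray, sim_areas: np.ndarray, ref_days: np.ndarray,
          steps_per_day: int = STEPS_PER_DAY) -> np.ndarray:
    """Sample a per-step area series at the reference days.

    Experimental series are sparse (about one photo per day) while the
    simulation records every step; each reference day t maps to the step
    ``round(t * steps_per_day)``.
    """
    ref_days = np.asarray(ref_days, dtype=float)
    if ref_days.size == 0:
        return np.empty(0)
    wanted = np.rint(ref_days * steps_per_day).astype(int)
    max_step = int(np.max(sim_steps))
    if wanted.max() > max_step:
        raise ValueError(
            f"reference day {ref_days.max():g} needs n_steps >= {int(wanted.max())}, "
            f"simulation only ran {max_step}"
        )
    index = {int(s): i for i, s in enumerate(np.asarray(sim_steps, dtype=int))}
    try:
        rows = [index[int(w)] for w in wanted]
    except KeyError as exc:
        raise ValueError(f"step {exc} missing from the simulated series") from exc
    return np.asarray(sim_areas, dtype=float)[rows]


def objective(sim_areas: np.ndarray, ref_areas: np.ndarray) -> float:
    """Sum of squared differences between matched area samples, in px^2."""
    sim_areas = np.asarray(sim_areas, dtype=float)
    ref_areas = np.asarray(ref_areas, dtype=float)
    if sim_areas.shape != ref_areas.shape:
        raise ValueError("simulated and reference series must have equal length")
    return float(np.sum((sim_areas - ref_areas) ** 2))


@dataclass
class FitProblem:
    """Specification of one calibration run.

    ``reference`` maps colony id -> DataFrame with columns ``day`` and
    ``area_px``; ``free_params`` maps parameter name -> initial value.
    """

    config: RunConfig
    free_params: dict[str, float]
    reference: dict[str, pd.DataFrame]
    n_seeds_per_eval: int = 3
    base_seed: int = 0
    max_evals: int = 200
    xtol_rel: float = 1e-3

    def __post_init__(self) -> None:
        if not self.free_params:
            raise ValueError("at least one free parameter is required")
        unknown = set(self.free_params) - set(FITTABLE)
        if unknown:
            raise ValueError(f"unknown fit parameter(s) {sorted(unknown)}")
        if not self.reference:
            raise ValueError("reference series must be non-empty")
        for name, value in self.free_params.items():
            if value <= 0:
                raise ValueError(f"initial value for {name} must be positive")

    @property
    def eval_seeds(self) -> list[int]:
        return [(self.base_seed + 1000 * i) % (2**31) for i in range(self.n_seeds_per_eval)]

    def required_steps(self) -> int:
        max_day = max(float(df["day"].max()) for df in self.reference.values())
        return int(np.rint(max_day * STEPS_PER_DAY))

    def evaluate(self, values: dict[str, float]) -> float:
        """Seed-averaged objective at one parameter point."""
        cfg = apply_params(self.config, values)
        n_steps = max(self.required_steps(), 1)
        mean_series: dict[str, np.ndarray] = {}
        try:
            for seed in self.eval_seeds:
                sim = cfg.run(seed=seed, n_steps=n_steps)
                for cid in self.reference:
                    steps, areas = sim.trajectory.area_series(cid)
                    sampled = align(steps, areas, self.reference[cid]["day"].to_numpy())
                    mean_series[cid] = mean_series.get(cid, 0.0) + sampled / self.n_seeds_per_eval
        except Exception:
            logger.exception("simulation failed at %s; penalising the point", values)
            return FAILURE_PENALTY
        return sum(
            objective(mean_series[cid], self.reference[cid]["area_px"].to_numpy())
            for cid in self.reference
        )


@dataclass
class FitResult:
    params: dict[str, float]
    objective: float
    n_evals: int
    trace: pd.DataFrame = field(repr=False)
    converged: bool = True


def fit(problem: FitProblem) -> FitResult:
    """Nelder-Mead minimisation of the seed-averaged area objective."""
    names = list(problem.free_params)
    x0 = np.log([problem.free_params[n] for n in names])
    trace_rows: list[dict] = []
    best = [np.inf]

    def wrapped(logx: np.ndarray) -> float:
        values = {n: float(np.exp(v)) for n, v in zip(names, logx)}
        obj = problem.evaluate(values)
        best[0] = min(best[0], obj)
        trace_rows.append({**values, "objective": obj, "running_best": best[0]})
        return obj

    # explicit initial simplex: log-parameters sit near 0, where scipy's
    # default multiplicative perturbation would collapse the simplex
    simplex = np.tile(x0, (len(x0) + 1, 1))
    for k in range(len(x0)):
        simplex[k + 1, k] += 0.25
    res = minimize(
        wrapped,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": problem.max_evals,
            "xatol": problem.xtol_rel,
            "fatol": 1e-8,
            "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    params = {n: float(np.exp(v)) for n, v in zip(names, res.x)}
    return FitResult(
        params=params,
        objective=float(res.fun),
        n_evals=int(res.nfev),
        trace=pd.DataFrame(trace_rows),
        converged=bool(res.success),
    )


def make_synthetic_target(
    cfg: RunConfig,
    true_params: dict[str, float],
    noise_sd_px: float = 0.0,
    seed: int = 0,
    days: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate at known parameters and emit a noisy daily area table.

    Returns ``(reference, truth)`` where ``reference`` has the layout a
    :class:`FitProblem` expects and ``truth`` records the generating
    parameters and seed (the sidecar for recovery tests).
    """
    if noise_sd_px < 0:
        raise ValueError("noise_sd_px must be >= 0")
    target_cfg = apply_params(cfg, true_params)
    n_days = target_cfg.n_steps // STEPS_PER_DAY
    if days is None:
        days = np.arange(1, n_days + 1, dtype=float)
    sim = target_cfg.run(seed=seed)
    noise_rng = np.random.default_rng(seed + 7)
    reference: dict[str, pd.DataFrame] = {}
    for cid in sim.colony_ids:
        steps, areas = sim.trajectory.area_series(cid)
        sampled = align(steps, areas, days)
        noisy = sampled + noise_rng.normal(0.0, noise_sd_px, size=sampled.size)
        reference[cid] = pd.DataFrame({"day": days, "area_px": np.maximum(noisy, 0.0)})
    truth = {"params": dict(true_params), "seed": seed, "noise_sd_px": noise_sd_px}
    return reference, truth


def recovery_problem(param: str, target_seed: int = 11, eval_seed: int = 5):
    """Standard desk-scale parameter-recovery setup.

    Builds a small single-colony plate, generates a noise-free synthetic
    target at a known true value, and returns ``(problem, truth)`` for a 1-D
    fit started 50% above the truth.  For ``sigma_top`` the plate decouples
    the deep layer (flowrate 0) so the colony rim is fed purely by top-layer
    diffusion, which makes the area series strongly sigma-dependent; the
    seed-averaged objective then identifies sigma.  Division distance is
    identifiable in the default two-layer regime.
    """
    from .agents import StrainParams
    from .config_io import NutrientConfig, RunConfig
    from .engine import InoculationSpec

    cfg = RunConfig(n_rows=60, n_cols=60, shape="circular", px_per_mm2=5.54)
    cfg.strains = {"wt": StrainParams("wt", uptake_rate_g0=0.1)}
    cfg.inoculations = [InoculationSpec((30.0, 30.0), 3.0, 50, "wt", "c0")]
    if param == "division_distance":
        cfg.nutrient = NutrientConfig(
            init_top=3, init_deep=6, sigma_top=0.6, sigma_deep=1.2, flowrate=0.5
        )
        cfg.n_steps = 96
        truth, n_seeds = 0.8, 3
    elif param == "sigma_top":
        cfg.nutrient = NutrientConfig(
            init_top=3, init_deep=6, sigma_top=0.6, sigma_deep=0.0, flowrate=0.0
        )
        cfg.n_steps = 168
        truth, n_seeds = 0.6, 5
    else:
        raise ValueError(f"no standard recovery setup for {param!r}")
    reference, _ = make_synthetic_target(cfg, {param: truth}, 0.0, seed=target_seed)
    problem = FitProblem(
        cfg, {param: truth * 1.5}, reference, n_seeds_per_eval=n_seeds, base_seed=eval_seed
    )
    return problem, truth


def read_reference_csv(path, px_per_mm2: float = 55.6) -> dict[str, pd.DataFrame]:
    """Load a reference table (columns: day, colony_id, area_px or area_mm2)."""
    df = pd.read_csv(path)
    if "area_px" not in df.columns:
        if "area_mm2" not in df.columns:
            raise ValueError("reference needs an area_px or area_mm2 column")
        df["area_px"] = df["area_mm2"] * px_per_mm2
    if "colony_id" not in df.columns:
        df["colony_id"] = "c0"
    return {
        str(cid): g[["day", "area_px"]].reset_index(drop=True)
        for cid, g in df.groupby("colony_id")
    }
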