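"""The simulation loop.

One step corresponds to roughly one hour of colony growth and runs, in a
fixed order: (1) scheduled events (refeeds, re-inoculations, parameter
switches), (2) Gaussian diffusion of both nutrient layers, (3) inter-layer
flow, (4) per-cell nutrient allocation and the agent life cycle (uptake,
metabolism, death with nutrient return, division, G0 transitions), and
(5) recording of the trajectory row.  Daughters born in a step first act in
the following step.  All randomness comes from a single seeded generator,
so a run is bit-reproducible from its configuration and seed.

Internally the agent population lives in flat numpy arrays (position,
energy, state, strain, colony); the per-cell pro-rata nutrient allocation
is evaluated with bincounts over the cell index, which is equivalent to
looping over cells in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import AgentState, StrainParams, _sample_positions
from .environment import (
    NutrientLayers,
    PlateGeometry,
    RefeedEvent,
    apply_refeed,
    diffuse_layer,
    interlayer_flow,
)

MAX_COLONIES = 24
STEPS_PER_DAY = 24


@dataclass
class InoculationSpec:
    """A droplet of founder agents.

    ``radius`` (grid cells) is the spread of the inoculating droplet — the
    model's stand-in for droplet volume; 0 places every founder exactly at
    ``center``.  ``at_step`` > 0 schedules a later re-inoculation next to or
    on top of an existing colony.
    """

    center: tuple[float, float]
    radius: float
    n_agents: int
    strain: str = "wt"
    colony_id: str = "c0"
    at_step: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.at_step < 0:
            raise ValueError("at_step must be >= 0")


@dataclass
class ParamSwitchEvent:
    """Replace strain parameters and/or layer sigmas mid-run.

    Used by the alternating wet/dry scenarios, where moving the plate between
    environments changes the division distance and the diffusion speed from a
    given day onward.
    """

    step: int
    strain_updates: dict = field(default_factory=dict)  # strain_id -> {field: value}
    sigma_top: float | None = None
    sigma_deep: float | None = None
    flowrate: float | None = None


class Population:
    """Struct-of-arrays store for the living agents."""

    def __init__(self) -> None:
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.energy = np.empty(0)
        self.state = np.empty(0, dtype=np.int8)
        self.strain = np.empty(0, dtype=np.int16)
        self.colony = np.empty(0, dtype=np.int16)

    def __len__(self) -> int:
        return self.x.shape[0]

    def append(self, x, y, energy, state, strain, colony) -> None:
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, y])
        self.energy = np.concatenate([self.energy, energy])
        self.state = np.concatenate([self.state, np.asarray(state, dtype=np.int8)])
        self.strain = np.concatenate([self.strain, np.asarray(strain, dtype=np.int16)])
        self.colony = np.concatenate([self.colony, np.asarray(colony, dtype=np.int16)])

    def keep(self, mask: np.ndarray) -> None:
        self.x = self.x[mask]
        self.y = self.y[mask]
        self.energy = self.energy[mask]
        self.state = self.state[mask]
        self.strain = self.strain[mask]
        self.colony = self.colony[mask]

    def to_frame(self, strain_ids: list[str], colony_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "colony_id": [colony_ids[c] for c in self.colony],
                "strain": [strain_ids[s] for s in self.strain],
                "x": self.x,
                "y": self.y,
                "energy": self.energy,
                "state": [AgentState(s).name.lower() for s in self.state],
            }
        )


class Trajectory:
    """Per-step record of population, colony areas and nutrient totals."""

    def __init__(self, strain_ids: list[str], colony_ids: list[str]) -> None:
        self.strain_ids = list(strain_ids)
        self.colony_ids = list(colony_ids)
        self.rows: list[dict] = []

    def record(self, step: int, sim: "Simulation") -> None:
        pop = sim.population
        row: dict = {"step": step, "day": step / STEPS_PER_DAY}
        for si, sid in enumerate(self.strain_ids):
            sel = pop.strain == si
            row[f"n_active_{sid}"] = int(((pop.state == AgentState.ACTIVE) & sel).sum())
            row[f"n_g0_{sid}"] = int(((pop.state == AgentState.G0) & sel).sum())
        for ci, cid in enumerate(self.colony_ids):
            row[f"area_px_{cid}"] = sim.colony_area_px(ci)
        row["n_agents"] = len(pop)
        row["nutrient_top"] = float(sim.layers.top.sum())
        row["nutrient_deep"] = float(sim.layers.deep.sum())
        row["agent_energy"] = float(pop.energy.sum())
        row["dissipated"] = sim.dissipated
        row["refed"] = sim.refed
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def area_series(self, colony_id: str) -> tuple[np.ndarray, np.ndarray]:
        df = self.to_frame()
        return df["step"].to_numpy(), df[f"area_px_{colony_id}"].to_numpy(dtype=float)


class Simulation:
    """Full mutable simulation state plus the step loop."""

    def __init__(
        self,
        geometry: PlateGeometry,
        layers: NutrientLayers,
        strains: dict[str, StrainParams],
        inoculations: list[InoculationSpec],
        events: list[RefeedEvent | ParamSwitchEvent] | None = None,
        seed: int = 0,
        area_threshold: int = 1,
        snapshot_steps: tuple[int, ...] = (),
    ) -> None:
        if not 1 <= len(inoculations) <= MAX_COLONIES:
            raise ValueError(f"between 1 and {MAX_COLONIES} inoculations are supported")
        for spec in inoculations:
            if spec.strain not in strains:
                raise ValueError(f"inoculation references unknown strain {spec.strain!r}")
        self.geometry = geometry
        self.layers = layers
        self.strains = dict(strains)
        self.strain_ids = list(strains)
        self.colony_ids = [spec.colony_id for spec in inoculations]
        if len(set(self.colony_ids)) != len(self.colony_ids):
            raise ValueError("colony ids must be unique")
        self.inoculations = list(inoculations)
        self.events = sorted(events or [], key=lambda e: e.step)
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.area_threshold = area_threshold
        self.snapshot_steps = frozenset(snapshot_steps)
        self.snapshots: dict[int, np.ndarray] = {}
        self.population = Population()
        self.step_count = 0
        self.dissipated = 0.0  # cumulative metabolic spend (ledger closure term)
        self.refed = 0.0  # cumulative nutrient added by refeed events
        self.trajectory = Trajectory(self.strain_ids, self.colony_ids)
        self._mask_full = bool(geometry.mask.all())
        for spec in self.inoculations:
            if spec.at_step == 0:
                self._inoculate(spec)
        self.trajectory.record(0, self)

    # -- inoculation ---------------------------------------------------

    def _inoculate(self, spec: InoculationSpec) -> None:
        cx, cy = spec.center
        if not self.geometry.contains(np.array([cx]), np.array([cy]))[0]:
            raise ValueError(f"inoculation centre {spec.center} lies outside the plate")
        n = spec.n_agents
        if spec.radius == 0:
            x = np.full(n, cx)
            y = np.full(n, cy)
        else:
            # uniform over the disc
            r = spec.radius * np.sqrt(self.rng.uniform(0, 1, size=n))
            theta = self.rng.uniform(0, 2 * np.pi, size=n)
            x = cx + r * np.cos(theta)
            y = cy + r * np.sin(theta)
            outside = ~self.geometry.contains(x, y)
            while outside.any():
                k = int(outside.sum())
                r = spec.radius * np.sqrt(self.rng.uniform(0, 1, size=k))
                theta = self.rng.uniform(0, 2 * np.pi, size=k)
                x[outside] = cx + r * np.cos(theta)
                y[outside] = cy + r * np.sin(theta)
                outside = ~self.geometry.contains(x, y)
        params = self.strains[spec.strain]
        si = self.strain_ids.index(spec.strain)
        ci = self.colony_ids.index(spec.colony_id)
        self.population.append(
            x,
            y,
            np.full(n, params.initial_energy),
            np.full(n, AgentState.ACTIVE, dtype=np.int8),
            np.full(n, si, dtype=np.int16),
            np.full(n, ci, dtype=np.int16),
        )

    def inoculate(self, spec: InoculationSpec) -> None:
        """Public hook used by step-0 setup and by re-inoculation events."""
        self._inoculate(spec)

    # -- measurement hooks ---------------------------------------------

    def colony_area_px(self, colony_index: int) -> int:
        """Occupied-cell count for one colony (living agents only)."""
        pop = self.population
        sel = (pop.colony == colony_index) & (pop.state != AgentState.DEAD)
        if not sel.any():
            return 0
        cells = pop.y[sel].astype(np.intp) * self.geometry.n_cols + pop.x[sel].astype(np.intp)
        counts = np.bincount(cells)
        return int((counts >= self.area_threshold).sum())

    def density_grid(self, colony_id: str | None = None, states=("active", "g0")) -> np.ndarray:
        """Living-agent counts per grid cell, optionally for one colony."""
        pop = self.population
        sel = np.ones(len(pop), dtype=bool)
        if colony_id is not None:
            sel &= pop.colony == self.colony_ids.index(colony_id)
        wanted = [AgentState[s.upper()] for s in states]
        sel &= np.isin(pop.state, wanted)
        grid = np.zeros(self.geometry.mask.shape)
        if sel.any():
            cells = pop.y[sel].astype(np.intp) * self.geometry.n_cols + pop.x[sel].astype(np.intp)
            grid = np.bincount(cells, minlength=grid.size).astype(float)[: grid.size]
            grid = grid.reshape(self.geometry.mask.shape)
        return grid

    def energy_ledger(self) -> float:
        """agent energy + nutrient + dissipated − refed; constant over a run."""
        return float(self.population.energy.sum()) + self.layers.total() + self.dissipated - self.refed

    # -- the step ------------------------------------------------------

    def _fire_events(self) -> None:
        due = [e for e in self.events if e.step == self.step_count]
        for event in due:
            if isinstance(event, RefeedEvent):
                self.refed += apply_refeed(self.layers, event, self.geometry)
            elif isinstance(event, ParamSwitchEvent):
                for sid, updates in event.strain_updates.items():
                    self.strains[sid] = self.strains[sid].replace(**updates)
                if event.sigma_top is not None:
                    self.layers.sigma_top = event.sigma_top
                if event.sigma_deep is not None:
                    self.layers.sigma_deep = event.sigma_deep
                if event.flowrate is not None:
                    self.layers.flowrate = event.flowrate
        for spec in self.inoculations:
            if spec.at_step == self.step_count and spec.at_step > 0:
                self._inoculate(spec)

    def _strain_arrays(self) -> dict[str, np.ndarray]:
        cols = {}
        for name in (
            "uptake_rate_active",
            "uptake_rate_g0",
            "metabolic_cost_active",
            "metabolic_cost_g0",
            "division_threshold",
            "g0_threshold",
            "death_threshold",
            "initial_energy",
            "division_distance",
        ):
            cols[name] = np.array([getattr(self.strains[s], name) for s in self.strain_ids])
        return cols

    def step(self) -> None:
        self.step_count += 1
        self._fire_events()

        # transport
        mask = None if self._mask_full else self.geometry.mask
        L = self.layers
        if L.sigma_top > 0:
            L.top = diffuse_layer(L.top, L.sigma_top, mask)
        if L.sigma_deep > 0:
            L.deep = diffuse_layer(L.deep, L.sigma_deep, mask)
        if L.flowrate > 0:
            L.top, L.deep = interlayer_flow(L.top, L.deep, L.init_top, L.init_deep, L.flowrate)

        pop = self.population
        n = len(pop)
        if n:
            P = self._strain_arrays()
            s = pop.strain
            is_g0 = pop.state == AgentState.G0

            # pro-rata allocation per grid cell
            cells = pop.y.astype(np.intp) * self.geometry.n_cols + pop.x.astype(np.intp)
            requests = np.where(is_g0, P["uptake_rate_g0"][s], P["uptake_rate_active"][s])
            flat_top = L.top.ravel()
            demand = np.bincount(cells, weights=requests, minlength=flat_top.size)
            scale = np.ones_like(demand)
            contended = demand > 0
            scale[contended] = np.minimum(1.0, flat_top[contended] / demand[contended])
            amounts = requests * scale[cells]
            taken = np.bincount(cells, weights=amounts, minlength=flat_top.size)
            flat_top -= taken
            np.clip(flat_top, 0.0, None, out=flat_top)

            # energy update and outcome classification
            cost = np.where(is_g0, P["metabolic_cost_g0"][s], P["metabolic_cost_active"][s])
            pop.energy += amounts - cost
            self.dissipated += float(cost.sum())

            dying = pop.energy < P["death_threshold"][s]
            if dying.any():
                returned = np.maximum(pop.energy[dying], 0.0)
                np.add.at(flat_top, cells[dying], returned)
                # energy charged below zero never existed; book it against spend
                self.dissipated += float((pop.energy[dying] - returned).sum())

            dividing = ~dying & (pop.energy >= P["division_threshold"][s])
            if dividing.any():
                e0 = P["initial_energy"][s[dividing]]
                pop.energy[dividing] -= e0
                dx, dy, de, ds, dc = [], [], [], [], []
                for si in np.unique(s[dividing]):
                    msel = dividing & (s == si)
                    mx, my = pop.x[msel], pop.y[msel]
                    nx, ny = _sample_positions(
                        mx, my, P["division_distance"][si], self.rng, self.geometry
                    )
                    dx.append(nx)
                    dy.append(ny)
                    de.append(np.full(nx.size, P["initial_energy"][si]))
                    ds.append(np.full(nx.size, si, dtype=np.int16))
                    dc.append(pop.colony[msel])
                daughters = (
                    np.concatenate(dx),
                    np.concatenate(dy),
                    np.concatenate(de),
                    np.full(sum(a.size for a in dx), AgentState.ACTIVE, dtype=np.int8),
                    np.concatenate(ds),
                    np.concatenate(dc),
                )
            else:
                daughters = None

            # state assignment for survivors
            new_state = np.where(
                pop.energy < P["g0_threshold"][s], AgentState.G0, AgentState.ACTIVE
            ).astype(np.int8)
            new_state[dividing] = AgentState.ACTIVE
            pop.state = new_state
            if dying.any():
                pop.keep(~dying)
            if daughters is not None:
                pop.append(*daughters)  # daughters first act next step

        if self.step_count in self.snapshot_steps:
            self.snapshots[self.step_count] = self.density_grid()
        self.trajectory.record(self.step_count, self)

    def run(self, n_steps: int) -> Trajectory:
        for _ in range(n_steps):
            self.step()
        return self.trajectory
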