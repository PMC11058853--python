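"""Agent state and the per-step life cycle.

An *agent* stands for a small group of yeast cells (plus the matrix around
them), pinned to a point on the plate.  Each step it takes nutrient from the
grid cell it sits on, pays a metabolic cost, and then — in this order —
dies if its energy fell below the death threshold (the remainder returned to
the plate as nutrient), divides if it reached the division threshold
(asymmetric budding: the daughter is seeded with the strain's initial energy
at a fixed distance in a random direction), or falls into / recovers from
the quiescent G0 state depending on whether its energy sits below the G0
threshold.  Agents never move after placement.

Within a grid cell, agents compete for the locally available nutrient; when
demand exceeds supply every request is scaled pro rata, which makes the
outcome independent of agent iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .environment import PlateGeometry

logger = logging.getLogger(__name__)

#: how many fresh directions are tried before a daughter is snapped to the
#: nearest in-plate point
PLACEMENT_RETRIES = 10


class AgentState(IntEnum):
    ACTIVE = 0
    G0 = 1
    DEAD = 2


@dataclass(frozen=True)
class StrainParams:
    """Per-strain energetics and division geometry.

    Energy and nutrient are in the same abstract units; rates and costs are
    per simulation step (~1 h).  Thresholds must satisfy
    ``death_threshold < g0_threshold < division_threshold`` and a newborn's
    ``initial_energy`` must sit below the division threshold.  G0 uptake and
    cost default to zero (a fully dormant quiescent state); scenarios that
    rely on reactivation after refeeding give G0 agents a small uptake rate
    so returning nutrient can push them back over the G0 threshold.
    """

    strain_id: str = "wt"
    uptake_rate_active: float = 1.0
    uptake_rate_g0: float = 0.0
    metabolic_cost_active: float = 0.2
    metabolic_cost_g0: float = 0.0
    division_threshold: float = 2.0
    g0_threshold: float = 0.7
    death_threshold: float = 0.05
    initial_energy: float = 1.0
    division_distance: float = 1.0

    def __post_init__(self) -> None:
        if not (self.death_threshold < self.g0_threshold < self.division_threshold):
            raise ValueError(
                "thresholds must satisfy death < g0 < division; got "
                f"{self.death_threshold} / {self.g0_threshold} / {self.division_threshold}"
            )
        if not (0 <= self.initial_energy < self.division_threshold):
            raise ValueError("initial_energy must lie in [0, division_threshold)")
        if self.division_distance <= 0:
            raise ValueError("division_distance must be positive")
        for name in ("uptake_rate_active", "uptake_rate_g0", "metabolic_cost_active", "metabolic_cost_g0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "StrainParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class Agent:
    """One simulated cell group: continuous position, energy, state, lineage."""

    x: float
    y: float
    energy: float
    state: AgentState = AgentState.ACTIVE
    strain: str = "wt"
    colony_id: str = "c0"


def allocate_uptake(cell_nutrient: float, requests: np.ndarray) -> tuple[np.ndarray, float]:
    """Share one cell's nutrient among the agents sitting on it.

    If the summed requests fit in the available nutrient everyone receives
    their request; otherwise all requests are scaled by the same factor so
    that exactly the available amount is handed out.  Returns the per-agent
    amounts and the nutrient left in the cell.
    """
    requests = np.asarray(requests, dtype=float)
    if cell_nutrient < 0 or (requests < 0).any():
        raise ValueError("nutrient and requests must be non-negative")
    total = requests.sum()
    if total <= cell_nutrient or total == 0:
        amounts = requests.copy()
    else:
        amounts = requests * (cell_nutrient / total)
    return amounts, float(cell_nutrient - amounts.sum())


def agent_update(agent: Agent, uptaken: float, params: StrainParams) -> tuple[str, float]:
    """Advance one agent by one step; returns ``(outcome, energy_returned)``.

    ``outcome`` is one of ``"active"``, ``"g0"``, ``"divide"`` or ``"die"``.
    The energy update (uptake minus the state's metabolic cost) happens
    first; the checks then run death-first so an agent cannot divide in the
    step it starves.  On death the remaining energy — clamped at zero — is
    what flows back to the plate.  On division the caller creates the
    daughter via :func:`place_daughter` and the mother keeps
    ``energy - initial_energy``.
    """
    if agent.state == AgentState.DEAD:
        raise ValueError("cannot update a dead agent")
    if uptaken < 0:
        raise ValueError("uptaken must be non-negative")
    cost = params.metabolic_cost_g0 if agent.state == AgentState.G0 else params.metabolic_cost_active
    agent.energy += uptaken - cost
    if agent.energy < params.death_threshold:
        returned = max(agent.energy, 0.0)
        agent.state = AgentState.DEAD
        return "die", returned
    if agent.energy >= params.division_threshold:
        agent.energy -= params.initial_energy
        agent.state = AgentState.ACTIVE
        return "divide", 0.0
    if agent.energy < params.g0_threshold:
        agent.state = AgentState.G0
        return "g0", 0.0
    agent.state = AgentState.ACTIVE
    return "active", 0.0


def uptake_request(state: AgentState, params: StrainParams) -> float:
    """Nutrient an agent asks for this step, given its metabolic state."""
    return params.uptake_rate_g0 if state == AgentState.G0 else params.uptake_rate_active


def place_daughter(mother: Agent, params: StrainParams, rng: np.random.Generator,
                   geometry: PlateGeometry) -> Agent:
    """Create the daughter produced by a division.

    The daughter sits at Euclidean distance ``division_distance`` from the
    mother in a uniformly random direction, inherits strain and colony
    identity, and starts active with ``initial_energy``.  Directions leading
    outside the plate are re-sampled a bounded number of times, then the
    daughter is snapped to the nearest in-plate point.
    """
    x, y = _sample_positions(
        np.array([mother.x]), np.array([mother.y]), params.division_distance, rng, geometry
    )
    return Agent(
        x=float(x[0]),
        y=float(y[0]),
        energy=params.initial_energy,
        state=AgentState.ACTIVE,
        strain=mother.strain,
        colony_id=mother.colony_id,
    )


def _sample_positions(
    mx: np.ndarray,
    my: np.ndarray,
    distance: float,
    rng: np.random.Generator,
    geometry: PlateGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised daughter placement for many mothers at once."""
    n = mx.shape[0]
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    x = mx + distance * np.cos(theta)
    y = my + distance * np.sin(theta)
    bad = ~geometry.contains(x, y)
    tries = 0
    while bad.any() and tries < PLACEMENT_RETRIES:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(bad.sum()))
        x[bad] = mx[bad] + distance * np.cos(theta)
        y[bad] = my[bad] + distance * np.sin(theta)
        bad = ~geometry.contains(x, y)
        tries += 1
    if bad.any():
        logger.debug("snapping %d daughter(s) to the nearest in-plate point", int(bad.sum()))
        x[bad], y[bad] = _nearest_inside(x[bad], y[bad], geometry)
    return x, y


def _nearest_inside(x: np.ndarray, y: np.ndarray, geometry: PlateGeometry) -> tuple[np.ndarray, np.ndarray]:
    eps = 1e-6
    if geometry.shape == "rectangular":
        return (
            np.clip(x, eps, geometry.n_cols - eps),
            np.clip(y, eps, geometry.n_rows - eps),
        )
    cx, cy = (geometry.n_cols - 1) / 2.0 + 0.5, (geometry.n_rows - 1) / 2.0 + 0.5
    r_max = min(geometry.n_rows, geometry.n_cols) / 2.0 - 1.0
    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    scale = np.where(r > 0, np.minimum(1.0, r_max / np.maximum(r, 1e-12)), 0.0)
    return cx + dx * scale, cy + dy * scale
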