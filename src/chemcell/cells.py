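"""Point-like cell agents: intracellular kinetics, division, death, motion.

Cells carry an intracellular reaction network (SRN), transport and
membrane reactions that couple them to their bulk node, per-species
(max, min) thresholds, and a division fraction rho in (0, 1).  A cell
divides when any species reaches its max threshold; the parent keeps a
fraction rho of every species and the daughter the rest, placed one mesh
spacing away at a uniformly random angle.  A cell dies when any species
falls below its min threshold.  Motion is passive: an overdamped update
under pairwise Hookean springs with rest length cutoff/2, active only
below the cutoff distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import ReactionSystem, SolverFailure, integrate_well_mixed

__all__ = [
    "Cell",
    "CellPopulation",
    "step_intracellular",
    "check_division",
    "divide",
    "check_death",
    "update_positions",
    "apply_cell_rules",
    "population_records",
]


@dataclass
class Cell:
    id: int
    type_name: str
    position: np.ndarray                      # (2,)
    internal_concentrations: dict             # species -> value >= 0
    srn: ReactionSystem | None = None
    transport_reactions: list = field(default_factory=list)
    membrane_reactions: list = field(default_factory=list)   # (outer, inner)
    thresholds: dict = field(default_factory=dict)  # species -> (max, min)
    division_fraction: float = 0.5

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not 0 < self.division_fraction < 1:
            raise ValueError("division fraction must lie in (0, 1)")
        for s, v in self.internal_concentrations.items():
            if v < 0:
                raise ValueError(f"negative concentration for {s!r}")
        for s, (hi, lo) in self.thresholds.items():
            if lo > hi:
                raise ValueError(f"threshold min > max for {s!r}")

    def concentration(self, species: str) -> float:
        return self.internal_concentrations.get(species, 0.0)


@dataclass
class CellPopulation:
    cells: list
    spring_cutoff: float = 1.5
    spring_stiffness: float = 1.0
    mesh_origin: tuple = (0.0, 0.0)
    _next_id: int = None

    def __post_init__(self):
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell ids")
        if self._next_id is None:
            self._next_id = max(ids, default=-1) + 1

    def fresh_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid


def step_intracellular(cell: Cell, dt: float) -> Cell:
    """Advance the cell's SRN one dt (in place) via fixed-step RK4."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cell.srn is None or not cell.srn.reactions:
        return cell
    names = cell.srn.names
    y0 = np.array([cell.concentration(s) for s in names])
    try:
        _, values = integrate_well_mixed(cell.srn, y0, t_end=dt, dt=dt)
    except SolverFailure as err:
        raise SolverFailure(
            f"intracellular solve failed for cell {cell.id}: {err}",
            time=err.time) from err
    for s, v in zip(names, values[-1]):
        cell.internal_concentrations[s] = float(v)
    return cell


def check_division(cell: Cell) -> bool:
    """True iff any species has reached its max threshold."""
    return any(cell.concentration(s) >= hi
               for s, (hi, _lo) in cell.thresholds.items())


def divide(cell: Cell, rng, fresh_id: int, displacement: float = 1.0):
    """Split a cell: parent keeps rho of every species, daughter 1 - rho.

    The daughter inherits type, thresholds and reaction systems, and is
    placed ``displacement`` away at a uniformly random angle.  Totals of
    every intracellular species are conserved exactly.
    """
    rho = cell.division_fraction
    daughter_conc = {}
    for s, v in list(cell.internal_concentrations.items()):
        cell.internal_concentrations[s] = rho * v
        daughter_conc[s] = (1.0 - rho) * v
    theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = displacement * np.array([np.cos(theta), np.sin(theta)])
    daughter = Cell(
        id=fresh_id,
        type_name=cell.type_name,
        position=cell.position + offset,
        internal_concentrations=daughter_conc,
        srn=cell.srn,
        transport_reactions=cell.transport_reactions,
        membrane_reactions=cell.membrane_reactions,
        thresholds=dict(cell.thresholds),
        division_fraction=cell.division_fraction,
    )
    return cell, daughter


def check_death(cell: Cell) -> bool:
    """True iff any species has fallen strictly below its min threshold."""
    return any(cell.concentration(s) < lo
               for s, (_hi, lo) in cell.thresholds.items())


def update_positions(pop: CellPopulation, dt: float, domain_extent=None):
    """Overdamped step under pairwise Hookean springs (unit drag).

    Cells closer than ``spring_cutoff`` interact through a linear spring
    of rest length cutoff/2; forces are equal and opposite, so the net
    population displacement is zero before boundary clamping.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cells = pop.cells
    n = len(cells)
    forces = np.zeros((n, 2))
    k = pop.spring_stiffness
    cutoff = pop.spring_cutoff
    rest = 0.5 * cutoff
    for i in range(n):
        for j in range(i + 1, n):
            d = cells[j].position - cells[i].position
            r = float(np.hypot(*d))
            if r >= cutoff or r == 0.0:
                continue
            u = d / r
            f = k * (r - rest) * u      # r < rest -> push i away from j
            forces[i] += f
            forces[j] -= f
    for cell, f in zip(cells, forces):
        cell.position = cell.position + dt * f
        if domain_extent is not None:
            cell.position[0] = min(max(cell.position[0], 0.0),
                                   domain_extent[0])
            cell.position[1] = min(max(cell.position[1], 0.0),
                                   domain_extent[1])
    return pop


def apply_cell_rules(pop: CellPopulation, mesh, rng, dt: float):
    """Division, death, then position update, in cell-id order."""
    new_cells = []
    for cell in sorted(pop.cells, key=lambda c: c.id):
        if check_division(cell):
            _, daughter = divide(cell, rng, pop.fresh_id(),
                                 displacement=mesh.spacing)
            new_cells.append(daughter)
    pop.cells.extend(new_cells)
    pop.cells = [c for c in pop.cells if not check_death(c)]
    update_positions(pop, dt, domain_extent=mesh.extent)
    return pop


def population_records(pop: CellPopulation, time: float):
    """Flat per-cell rows for trajectory output."""
    rows = []
    for c in pop.cells:
        row = {"time": time, "cell_id": c.id, "type": c.type_name,
               "x": float(c.position[0]), "y": float(c.position[1])}
        row.update({s: float(v)
                    for s, v in c.internal_concentrations.items()})
        rows.append(row)
    return rows
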