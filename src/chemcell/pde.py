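"""Finite-element reaction-diffusion solver on the structured mesh.

Each species u_s obeys  du_s/dt - div(D_s grad u_s) = R_s(u)  with
per-subdomain diffusivities and per-species boundary conditions.  Linear
triangular elements give the stiffness matrix; the mass matrix is lumped
to the nodal volume shares, so reactions act nodally.  Time stepping is
IMEX: reactions advance explicitly (one vectorised RK4 stage over all
nodes), diffusion advances implicitly (backward Euler), i.e. per species

    (M + dt K_s) u^{n+1} = M u* + dt b_s

where u* is the reacted state and b_s collects nonzero-Neumann boundary
sources.  Zero-flux is the natural condition, Dirichlet rows are replaced
by identity rows, and periodic conditions identify opposite-edge nodes.
The factorisation of (M + dt K_s) is cached, so a run costs one sparse LU
per species plus one triangular solve per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .chemistry import SolverFailure

__all__ = [
    "BoundaryConditionSpec",
    "SolverSettings",
    "FieldState",
    "Trajectory",
    "assemble_operators",
    "DiffusionOperators",
    "step",
    "run_simulation",
]

_BC_KINDS = ("neumann_flux", "dirichlet_value", "periodic")


@dataclass
class BoundaryConditionSpec:
    species: str
    kind: str
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in _BC_KINDS:
            raise ValueError(f"unknown boundary-condition kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise ValueError("boundary-condition value must be finite")


@dataclass
class SolverSettings:
    dt: float = 0.01
    t_end: float = 1.0
    sampling_interval: float | None = None
    scheme: str = "imex"

    def __post_init__(self):
        if self.sampling_interval is None:
            self.sampling_interval = self.dt
        if not (0 < self.dt <= self.sampling_interval <= self.t_end):
            raise ValueError(
                "require 0 < dt <= sampling_interval <= t_end, got "
                f"dt={self.dt}, sampling={self.sampling_interval}, "
                f"t_end={self.t_end}")
        if self.scheme not in ("imex", "explicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class FieldState:
    """Concentrations of every bulk species at every node at one time."""

    time: float
    values: np.ndarray        # (n_nodes, n_species)

    def copy(self):
        return FieldState(self.time, self.values.copy())


@dataclass
class Trajectory:
    """Sampled output of a run: bulk fields plus per-sample cell records."""

    times: list = field(default_factory=list)
    fields: list = field(default_factory=list)      # arrays (n_nodes, n_sp)
    cell_records: list = field(default_factory=list)  # list of row dicts
    species: list = field(default_factory=list)
    mesh: object = None

    def slice_values(self, species_idx, y=None):
        """1D slice of one species along x at the row nearest ``y``
        (default: mid-domain).  Returns ``(x, u)``."""
        mesh = self.mesh
        if y is None:
            y = 0.5 * mesh.extent[1]
        j = int(round(y / mesh.spacing))
        j = min(max(j, 0), mesh.ny)
        idx = [mesh.node_index(i, j) for i in range(mesh.nx + 1)]
        x = mesh.node_xy[idx, 0]
        return x, np.array([f[idx, species_idx] for f in self.fields])


def _element_stiffness(xy):
    """Exact P1 stiffness matrix of one triangle (unit diffusivity)."""
    x, y = xy[:, 0], xy[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    # gradients of the barycentric basis are (b_i, c_i) / (2 area)
    area = 0.5 * abs((x[1] - x[0]) * (y[2] - y[0])
                     - (x[2] - x[0]) * (y[1] - y[0]))
    return (np.outer(b, b) + np.outer(c, c)) / (4.0 * area)


class DiffusionOperators:
    """Per-species stiffness matrices plus the shared lumped mass vector."""

    def __init__(self, mesh, stiffness, mass, boundary_sources, dirichlet,
                 periodic_map=None):
        self.mesh = mesh
        self.stiffness = stiffness          # species -> csr matrix
        self.mass = mass                    # (n_nodes,) lumped areas
        self.boundary_sources = boundary_sources  # species -> (n_nodes,) or None
        self.dirichlet = dirichlet          # species -> (nodes, value) or None
        self.periodic_map = periodic_map    # (n_nodes,) master index or None
        self._factors = {}

    def solver(self, species, dt):
        key = (species, dt)
        if key not in self._factors:
            K = self.stiffness[species]
            if self.periodic_map is not None:
                P = self._projector()
                A = P.T @ (sp.diags(self.mass) + dt * K) @ P
                self._factors[key] = ("periodic", splu(A.tocsc()), P)
                return self._factors[key]
            A = (sp.diags(self.mass) + dt * K).tolil()
            dirich = self.dirichlet.get(species)
            if dirich is not None:
                nodes, _ = dirich
                A[nodes, :] = 0.0
                A[nodes, nodes] = 1.0
            self._factors[key] = ("plain", splu(A.tocsc()), None)
        return self._factors[key]

    def _projector(self):
        pm = self.periodic_map
        masters = np.unique(pm)
        col = {m: i for i, m in enumerate(masters)}
        rows = np.arange(pm.size)
        cols = np.array([col[m] for m in pm])
        P = sp.coo_matrix((np.ones(pm.size), (rows, cols)),
                          shape=(pm.size, masters.size)).tocsr()
        return P


def _boundary_edge_lengths(mesh):
    """Per-node half-sum of adjacent boundary-edge lengths."""
    w = np.zeros(mesh.n_nodes)
    h = mesh.spacing
    for idx in np.flatnonzero(mesh.on_boundary):
        x, y = mesh.node_xy[idx]
        width, height = mesh.extent
        n_edges = 0
        # a perimeter node touches 2 boundary edges (corner: one per side)
        on_lr = np.isclose(x, 0) or np.isclose(x, width)
        on_bt = np.isclose(y, 0) or np.isclose(y, height)
        if on_lr:
            n_edges += 2 - (np.isclose(y, 0) + np.isclose(y, height))
        if on_bt:
            n_edges += 2 - (np.isclose(x, 0) + np.isclose(x, width))
        w[idx] = n_edges * h / 2.0
    return w


def _periodic_map(mesh):
    """Map every node to its periodic master (right->left, top->bottom)."""
    pm = np.arange(mesh.n_nodes)
    for j in range(mesh.ny + 1):
        pm[mesh.node_index(mesh.nx, j)] = mesh.node_index(0, j)
    for i in range(mesh.nx + 1):
        pm[mesh.node_index(i, mesh.ny)] = pm[mesh.node_index(i, 0)]
    return pm


def assemble_operators(mesh, domain, species_names, diffusivity=None,
                       boundary_conditions=None):
    """Build per-species stiffness operators and the lumped mass vector.

    ``diffusivity`` maps ``(species, subdomain_name)`` to a coefficient;
    if omitted it is taken from ``domain.diffusivity``.  The element
    coefficient is looked up from the subdomain of the element's
    lowest-index node (for structured grids, the lower-left corner of the
    grid square).  Missing (species, subdomain) pairs raise a
    configuration error naming both.
    """
    diffusivity = domain.diffusivity if diffusivity is None else diffusivity
    bcs = boundary_conditions if boundary_conditions is not None else \
        domain.boundary_conditions
    if mesh.labels is None:
        from .mesh import assign_labels
        assign_labels(mesh, domain)

    n = mesh.n_nodes
    tri = mesh.triangles
    # element subdomain: name of the lowest-index node's label
    elem_sub = [domain.key[mesh.labels[int(t.min())]] for t in tri]

    stiffness = {}
    rows, cols = [], []
    for t in tri:
        rows.append(np.repeat(t, 3))
        cols.append(np.tile(t, 3))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)

    locals_ = np.array([_element_stiffness(mesh.node_xy[t]) for t in tri])

    periodic = any(bc.kind == "periodic" for bc in bcs.values()) if bcs else False
    for s in species_names:
        coeffs = np.empty(len(tri))
        for e, sub in enumerate(elem_sub):
            try:
                coeffs[e] = diffusivity[(s, sub)]
            except KeyError:
                raise KeyError(
                    f"no diffusivity configured for species {s!r} in "
                    f"subdomain {sub!r}") from None
        data = (locals_ * coeffs[:, None, None]).reshape(-1)
        K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        K.eliminate_zeros()
        stiffness[s] = K

    mass = mesh.volume_shares().copy()

    boundary_sources = {}
    dirichlet = {}
    edge_w = None
    for s in species_names:
        bc = bcs.get(s) if bcs else None
        boundary_sources[s] = None
        dirichlet[s] = None
        if bc is None:
            continue
        if bc.kind == "neumann_flux" and bc.value != 0.0:
            if edge_w is None:
                edge_w = _boundary_edge_lengths(mesh)
            boundary_sources[s] = bc.value * edge_w
        elif bc.kind == "dirichlet_value":
            nodes = np.flatnonzero(mesh.on_boundary)
            dirichlet[s] = (nodes, bc.value)

    pm = _periodic_map(mesh) if periodic else None
    return DiffusionOperators(mesh, stiffness, mass, boundary_sources,
                              dirichlet, periodic_map=pm)


def _react_explicit(values, node_systems, dt):
    """Advance nodal reaction ODEs one RK4 step, grouped by subdomain."""
    from .chemistry import rk4_step

    out = values.copy()
    for system, node_idx, col_idx in node_systems:
        sub = values[np.ix_(node_idx, col_idx)]
        sub = rk4_step(system.rates, sub, dt)
        out[np.ix_(node_idx, col_idx)] = sub
    return out


def step(state: FieldState, operators: DiffusionOperators, node_systems,
         settings: SolverSettings) -> FieldState:
    """One IMEX step: explicit nodal reactions, implicit diffusion, BCs.

    ``node_systems`` is a list of ``(ReactionSystem, node_indices,
    species_column_indices)`` triples, one per reaction subdomain (empty
    list for pure diffusion).
    """
    dt = settings.dt
    values = state.values
    if node_systems:
        values = _react_explicit(values, node_systems, dt)

    new = np.empty_like(values)
    mass = operators.mass
    for k, s in enumerate(operators.stiffness):
        rhs = mass * values[:, k]
        src = operators.boundary_sources[s]
        if src is not None:
            rhs = rhs + dt * src
        kind, lu, P = operators.solver(s, dt)
        if kind == "periodic":
            new[:, k] = P @ lu.solve(P.T @ rhs)
        else:
            dirich = operators.dirichlet.get(s)
            if dirich is not None:
                nodes, value = dirich
                rhs = rhs.copy()
                rhs[nodes] = value
            new[:, k] = lu.solve(rhs)
    if not np.all(np.isfinite(new)):
        raise SolverFailure(
            f"non-finite field at t = {state.time + dt:g}",
            time=state.time + dt)
    return FieldState(state.time + dt, new)


def run_simulation(model, progress=False):
    """Run a full model: bulk reaction-diffusion plus optional cell layer.

    ``model`` is a :class:`chemcell.io.ModelSpec`.  Each time step
    executes, in order: (1) intracellular reactions of every cell,
    (2) the bulk IMEX reaction-diffusion step, (3) transport and membrane
    coupling at each cell's bound node, (4) cell rules — division, death,
    then overdamped position update.  Returns a :class:`Trajectory`.
    """
    from . import cells as cells_mod
    from . import coupling as coupling_mod

    mesh = model.mesh
    settings = model.settings
    operators = assemble_operators(mesh, model.domain, model.species_names)
    node_systems = model.node_reaction_systems()

    state = FieldState(0.0, model.initial_field())
    population = model.initial_population()
    rng = np.random.default_rng(model.rng_seed + 1)

    traj = Trajectory(species=list(model.species_names), mesh=mesh)
    stride = max(1, int(round(settings.sampling_interval / settings.dt)))
    n_steps = int(round(settings.t_end / settings.dt))

    def record():
        traj.times.append(state.time)
        traj.fields.append(state.values.copy())
        if population is not None:
            traj.cell_records.append(
                cells_mod.population_records(population, state.time))

    record()
    for step_no in range(1, n_steps + 1):
        try:
            if population is not None:
                for cell in population.cells:
                    cells_mod.step_intracellular(cell, settings.dt)
            state = step(state, operators, node_systems, settings)
            if population is not None:
                bindings = coupling_mod.bind_cells(population, mesh)
                coupling_mod.apply_coupling(
                    bindings, population, state.values,
                    model.species_index, settings.dt)
                cells_mod.apply_cell_rules(population, mesh, rng, settings.dt)
        except SolverFailure as err:
            raise SolverFailure(
                f"simulation failed at step {step_no} "
                f"(t = {step_no * settings.dt:g}): {err}",
                time=step_no * settings.dt) from err
        if step_no % stride == 0 or step_no == n_steps:
            record()
        if progress and step_no % max(1, n_steps // 10) == 0:
            print(f"  t = {state.time:g} / {settings.t_end:g}")
    return traj
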