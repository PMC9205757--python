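"""File-based model interface: parse a model directory into a ModelSpec.

A model directory contains plain-text files (exact dialects below) plus a
``config.txt`` of ``key = value`` lines:

* ``DomainTopology.csv`` — rectangular matrix of subdomain tokens, rows
  listed bottom-to-top;
* ``DomainKey.csv`` — ``token,name`` lines;
* ``DiffusionRates.csv`` — header then ``subdomain,species,value``;
* ``BoundaryConditions.csv`` — header then ``species,bc_type,value`` with
  bc_type in {neumann_flux, dirichlet_value, periodic};
* ``InitialConditions.csv`` — header then ``subdomain,species,value,perturb``;
* ``BulkReactionKey.csv`` — header then ``subdomain,reaction_file``;
* reaction ``.txt`` files in the grammar of :mod:`chemcell.chemistry`.

Cell-coupled models add a cell file root with ``CellLayerTopology.csv``
(grid of numeric ids, 0 = empty, rows bottom-to-top), ``CellLayerKey.csv``
(``id,type``) and one directory per cell type holding
``InitialCellConcentrations.csv`` (``name,value,perturb``),
``SpeciesThreshold.csv`` (``name,max,min``), ``Srn.txt``,
``TransportReactions.txt`` and ``MembraneReactions.txt``.

Config keys (Supp.-table style names): simulation_type
(domain_only | cell_coupled), output_directory, end_time, time_step,
sampling_rate, number_of_pdes, domain_dimensions (``width, height``),
element_dimension (FE spacing h), rng_seed, perturbation_magnitude, the
file-name keys above, and for cell-coupled runs cell_file_root,
cell_mesh_origin (``x, y``), cell_spacing, linear_force_cutoff,
spring_stiffness, division_fraction.

Perturbed initial values (the ``perturb`` flags) add seeded
Uniform(-perturbation_magnitude, +perturbation_magnitude) noise per node
(or per cell species) and are clipped at zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chemistry, mesh as mesh_mod
from .cells import Cell, CellPopulation
from .pde import BoundaryConditionSpec, SolverSettings

__all__ = ["ModelSpec", "ValidationError", "load_model", "write_exemplar",
           "EXEMPLARS"]


class ValidationError(ValueError):
    """Model directory failed validation; lists every problem found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "model validation failed:\n  - " + "\n  - ".join(self.problems))


@dataclass
class CellTypeSpec:
    name: str
    initial_concentrations: dict        # species -> (value, perturb)
    thresholds: dict                    # species -> (max, min)
    srn: chemistry.ReactionSystem | None
    transport_reactions: list
    membrane_reactions: list


@dataclass
class ModelSpec:
    """A fully parsed and validated model directory."""

    mesh: mesh_mod.Mesh
    domain: mesh_mod.DomainField
    species_names: list
    bulk_systems: dict                  # subdomain name -> ReactionSystem|None
    initial_conditions: dict            # (subdomain, species) -> (value, bool)
    settings: SolverSettings
    rng_seed: int = 0
    perturbation_magnitude: float = 1.0
    output_directory: str = "output"
    simulation_type: str = "domain_only"
    cell_types: dict = field(default_factory=dict)
    cell_seeds: list = field(default_factory=list)  # (type_name, x, y)
    cell_params: dict = field(default_factory=dict)

    @property
    def species_index(self):
        return {s: i for i, s in enumerate(self.species_names)}

    def node_reaction_systems(self):
        """(system, node indices, global species columns) per subdomain."""
        out = []
        labels = np.array([self.domain.key[t] for t in self.mesh.labels],
                          dtype=object)
        sidx = self.species_index
        for sub, system in self.bulk_systems.items():
            if system is None or not system.reactions:
                continue
            node_idx = np.flatnonzero(labels == sub)
            col_idx = np.array([sidx[s] for s in system.names])
            out.append((system, node_idx, col_idx))
        return out

    def initial_field(self):
        """Per-node initial concentrations with seeded perturbations."""
        rng = np.random.default_rng(self.rng_seed)
        n = self.mesh.n_nodes
        values = np.zeros((n, len(self.species_names)))
        labels = [self.domain.key[t] for t in self.mesh.labels]
        for k, s in enumerate(self.species_names):
            base = np.zeros(n)
            perturb = np.zeros(n, dtype=bool)
            for i, sub in enumerate(labels):
                value, flag = self.initial_conditions.get((sub, s), (0.0, False))
                base[i] = value
                perturb[i] = flag
            noise = rng.uniform(-self.perturbation_magnitude,
                                self.perturbation_magnitude, size=n)
            values[:, k] = np.clip(base + np.where(perturb, noise, 0.0),
                                   0.0, None)
        return values

    def initial_population(self):
        if self.simulation_type != "cell_coupled":
            return None
        rng = np.random.default_rng(self.rng_seed + 7)
        cells = []
        for i, (type_name, x, y) in enumerate(self.cell_seeds):
            ct = self.cell_types[type_name]
            conc = {}
            for s, (value, flag) in ct.initial_concentrations.items():
                v = value
                if flag:
                    v += rng.uniform(-self.perturbation_magnitude,
                                     self.perturbation_magnitude)
                conc[s] = max(v, 0.0)
            cells.append(Cell(
                id=i, type_name=type_name, position=(x, y),
                internal_concentrations=conc, srn=ct.srn,
                transport_reactions=ct.transport_reactions,
                membrane_reactions=ct.membrane_reactions,
                thresholds=dict(ct.thresholds),
                division_fraction=self.cell_params.get(
                    "division_fraction", 0.5)))
        return CellPopulation(
            cells=cells,
            spring_cutoff=self.cell_params.get("linear_force_cutoff", 1.5),
            spring_stiffness=self.cell_params.get("spring_stiffness", 1.0),
            mesh_origin=self.cell_params.get("cell_mesh_origin", (0.0, 0.0)))


# ---------------------------------------------------------------------------
# parsing


def _read_config(path):
    cfg = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(
                    [f"config line {line!r} is not 'key = value'"])
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.strip()
    return cfg


def _read_csv_rows(path, n_fields, what, problems, header=True):
    rows = []
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for i, row in enumerate(reader):
                if not row or all(not c.strip() for c in row):
                    continue
                if header and i == 0:
                    continue
                if len(row) < n_fields:
                    problems.append(
                        f"{what}: row {i + 1} has {len(row)} fields, "
                        f"expected {n_fields}")
                    continue
                rows.append([c.strip() for c in row])
    except OSError as err:
        problems.append(f"{what}: cannot read {path} ({err})")
    return rows


def _parse_bool(text):
    return text.strip().lower() in ("1", "true", "yes")


def load_model(config_path, overrides=None):
    """Parse ``config.txt`` and the files it references into a ModelSpec.

    ``overrides`` is an optional dict of config keys replacing the file's
    values (used e.g. to shorten end_time for reduced runs).  All
    validation problems are collected and reported together.
    """
    config_path = Path(config_path)
    root = config_path.parent
    cfg = _read_config(config_path)
    if overrides:
        cfg.update({k: str(v) for k, v in overrides.items()})
    problems = []

    def cfg_get(key, default=None, cast=str):
        if key in cfg:
            try:
                return cast(cfg[key])
            except ValueError:
                problems.append(f"config {key} = {cfg[key]!r} is not a "
                                f"valid {cast.__name__}")
                return default
        if default is None:
            problems.append(f"config is missing required key {key!r}")
        return default

    sim_type = cfg_get("simulation_type", "domain_only")
    if sim_type not in ("domain_only", "cell_coupled"):
        problems.append(f"unknown simulation_type {sim_type!r}")

    def path_of(key, default_name):
        p = root / cfg.get(key, default_name)
        if not p.exists():
            problems.append(f"{key}: file not found: {p}")
            return None
        return p

    topo_path = path_of("domain_topology", "DomainTopology.csv")
    key_path = path_of("domain_key", "DomainKey.csv")
    diff_path = path_of("diffusion_rates", "DiffusionRates.csv")
    bc_path = path_of("boundary_conditions", "BoundaryConditions.csv")
    ic_path = path_of("initial_conditions", "InitialConditions.csv")
    rkey_path = path_of("bulk_reaction_key", "BulkReactionKey.csv")

    # geometry
    dims = cfg_get("domain_dimensions", "1, 1")
    try:
        width, height = (float(v) for v in dims.split(","))
    except ValueError:
        problems.append(f"domain_dimensions {dims!r} is not 'width, height'")
        width = height = 1.0
    h = cfg_get("element_dimension", 1.0, float)
    nx, ny = max(1, round(width / h)), max(1, round(height / h))

    label_grid, key = None, {}
    if topo_path:
        grid_rows = _read_csv_rows(topo_path, 1, "domain topology", problems,
                                   header=False)
        if grid_rows:
            widths = {len(r) for r in grid_rows}
            if len(widths) != 1:
                problems.append("domain topology rows have unequal lengths")
            else:
                # file rows top-to-bottom would be the picture convention;
                # this dialect pins bottom-to-top (row 0 at y = 0)
                label_grid = np.array(grid_rows, dtype=object)
    if key_path:
        for row in _read_csv_rows(key_path, 2, "domain key", problems,
                                  header=False):
            key[row[0]] = row[1]

    diffusivity = {}
    species_names = []
    if diff_path:
        for sub, sp, value in _read_csv_rows(diff_path, 3, "diffusion rates",
                                             problems):
            try:
                d = float(value)
            except ValueError:
                problems.append(f"diffusion rate {value!r} for {sp} is not "
                                "numeric")
                continue
            if d < 0:
                problems.append(f"negative diffusivity for species {sp}")
            diffusivity[(sp, sub)] = d
            if sp not in species_names:
                species_names.append(sp)

    n_pdes = cfg_get("number_of_pdes", len(species_names) or 1, int)
    if species_names and n_pdes != len(species_names):
        problems.append(
            f"number_of_pdes = {n_pdes} but {len(species_names)} species "
            f"are configured: {species_names}")

    bcs = {}
    if bc_path:
        for sp, kind, value in _read_csv_rows(bc_path, 3,
                                              "boundary conditions", problems):
            try:
                bcs[sp] = BoundaryConditionSpec(sp, kind, float(value))
            except ValueError as err:
                problems.append(f"boundary condition for {sp}: {err}")

    initial_conditions = {}
    if ic_path:
        for sub, sp, value, perturb in _read_csv_rows(
                ic_path, 4, "initial conditions", problems):
            try:
                initial_conditions[(sub, sp)] = (float(value),
                                                 _parse_bool(perturb))
            except ValueError:
                problems.append(f"initial condition {value!r} for {sp} is "
                                "not numeric")

    bulk_systems = {}
    if rkey_path:
        for sub, fname in _read_csv_rows(rkey_path, 2, "bulk reaction key",
                                         problems):
            rpath = root / fname
            if not rpath.exists():
                problems.append(f"bulk reaction file not found: {rpath}")
                continue
            try:
                reactions = chemistry.parse_reaction_file(rpath,
                                                          context="bulk")
                names = [s for rx in reactions for s in rx.species_names()]
                unknown = [s for s in names if s not in species_names]
                if unknown:
                    problems.append(
                        f"reaction file {fname}: species {sorted(set(unknown))} "
                        "have no diffusion entry")
                    continue
                sys_names = [s for s in species_names
                             if s in dict.fromkeys(names)]
                bulk_systems[sub] = chemistry.ReactionSystem(
                    sys_names, reactions) if reactions else None
            except chemistry.ReactionParseError as err:
                problems.append(f"reaction file {fname}: {err}")

    # cross checks
    if label_grid is not None and key:
        for token in np.unique(label_grid.astype(str)):
            if token not in key:
                problems.append(
                    f"topology label {token!r} missing from the domain key")
        for sub in set(key.values()):
            for sp in species_names:
                if (sp, sub) not in diffusivity:
                    problems.append(
                        f"no diffusivity for species {sp!r} in subdomain "
                        f"{sub!r}")

    settings = None
    try:
        settings = SolverSettings(
            dt=cfg_get("time_step", 0.01, float),
            t_end=cfg_get("end_time", 1.0, float),
            sampling_interval=cfg_get("sampling_rate", None, float)
            if "sampling_rate" in cfg else None)
    except ValueError as err:
        problems.append(str(err))

    cell_types = {}
    cell_seeds = []
    cell_params = {}
    if sim_type == "cell_coupled":
        cell_root = root / cfg.get("cell_file_root", "Cells")
        origin = cfg.get("cell_mesh_origin", "0, 0")
        try:
            ox, oy = (float(v) for v in origin.split(","))
        except ValueError:
            problems.append(f"cell_mesh_origin {origin!r} is not 'x, y'")
            ox = oy = 0.0
        cell_params = {
            "cell_mesh_origin": (ox, oy),
            "linear_force_cutoff": cfg_get("linear_force_cutoff", 1.5, float),
            "spring_stiffness": cfg_get("spring_stiffness", 1.0, float),
            "division_fraction": cfg_get("division_fraction", 0.5, float),
        }
        cell_spacing = cfg_get("cell_spacing", h, float)
        if not cell_root.is_dir():
            problems.append(f"cell_file_root not found: {cell_root}")
        else:
            cell_types, cell_seeds = _load_cell_layer(
                cell_root, cell_spacing, (ox, oy), problems)

    if problems:
        raise ValidationError(problems)

    msh = mesh_mod.build_rectangular_mesh(nx, ny, h)
    domain = mesh_mod.DomainField(
        label_grid=label_grid, key=key, diffusivity=diffusivity,
        reaction_files={}, boundary_conditions=bcs)
    mesh_mod.assign_labels(msh, domain)

    return ModelSpec(
        mesh=msh, domain=domain, species_names=species_names,
        bulk_systems=bulk_systems, initial_conditions=initial_conditions,
        settings=settings,
        rng_seed=cfg_get("rng_seed", 0, int),
        perturbation_magnitude=cfg_get("perturbation_magnitude", 1.0, float),
        output_directory=cfg.get("output_directory", "output"),
        simulation_type=sim_type, cell_types=cell_types,
        cell_seeds=cell_seeds, cell_params=cell_params)


def _load_cell_layer(cell_root, spacing, origin, problems):
    types = {}
    seeds = []
    topo = cell_root / "CellLayerTopology.csv"
    keyf = cell_root / "CellLayerKey.csv"
    key = {}
    if not keyf.exists():
        problems.append(f"missing {keyf}")
    else:
        for row in _read_csv_rows(keyf, 2, "cell layer key", problems,
                                  header=False):
            key[row[0]] = row[1]
    if not topo.exists():
        problems.append(f"missing {topo}")
    else:
        rows = _read_csv_rows(topo, 1, "cell layer topology", problems,
                              header=False)
        for j, row in enumerate(rows):         # rows bottom-to-top
            for i, token in enumerate(row):
                if token == "0" or not token:
                    continue
                if token not in key:
                    problems.append(
                        f"cell layer label {token!r} missing from "
                        "CellLayerKey.csv")
                    continue
                seeds.append((key[token],
                              origin[0] + i * spacing,
                              origin[1] + j * spacing))
    for type_name in dict.fromkeys(key.values()):
        tdir = cell_root / type_name
        if not tdir.is_dir():
            problems.append(f"missing cell type directory {tdir}")
            continue
        types[type_name] = _load_cell_type(tdir, type_name, problems)
    return types, seeds


def _load_cell_type(tdir, name, problems):
    init = {}
    for sp, value, perturb in _read_csv_rows(
            tdir / "InitialCellConcentrations.csv", 3,
            f"{name} initial concentrations", problems):
        try:
            init[sp] = (float(value), _parse_bool(perturb))
        except ValueError:
            problems.append(f"{name}: concentration {value!r} not numeric")
    thresholds = {}
    tfile = tdir / "SpeciesThreshold.csv"
    if tfile.exists():
        for sp, hi, lo in _read_csv_rows(tfile, 3, f"{name} thresholds",
                                         problems):
            try:
                thresholds[sp] = (float(hi), float(lo))
            except ValueError:
                problems.append(f"{name}: threshold {hi!r}/{lo!r} not numeric")

    def parse(fname, context):
        path = tdir / fname
        if not path.exists():
            return []
        try:
            return chemistry.parse_reaction_file(path, context=context)
        except chemistry.ReactionParseError as err:
            problems.append(f"{name}/{fname}: {err}")
            return []

    srn_reactions = parse("Srn.txt", context="cell")
    transport = parse("TransportReactions.txt", context="transport")
    membrane = parse("MembraneReactions.txt", context="membrane")

    srn = None
    if srn_reactions:
        names = list(dict.fromkeys(
            [s for rx in srn_reactions for s in rx.species_names()]
            + list(init)))
        try:
            srn = chemistry.ReactionSystem(names, srn_reactions)
        except ValueError as err:
            problems.append(f"{name}/Srn.txt: {err}")
    return CellTypeSpec(name=name, initial_concentrations=init,
                        thresholds=thresholds, srn=srn,
                        transport_reactions=transport,
                        membrane_reactions=membrane)


# ---------------------------------------------------------------------------
# exemplar model directories


def _write(path, text):
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _write_common(out, *, topology_rows, key_lines, diffusion_rows, bc_rows,
                  ic_rows, reaction_key_rows, config_lines):
    _write(out / "DomainTopology.csv",
           "\n".join(",".join(r) for r in topology_rows) + "\n")
    _write(out / "DomainKey.csv", "\n".join(key_lines) + "\n")
    _write(out / "DiffusionRates.csv",
           "subdomain,species,value\n"
           + "\n".join(",".join(map(str, r)) for r in diffusion_rows) + "\n")
    _write(out / "BoundaryConditions.csv",
           "species,bc_type,value\n"
           + "\n".join(",".join(map(str, r)) for r in bc_rows) + "\n")
    _write(out / "InitialConditions.csv",
           "subdomain,species,value,perturb\n"
           + "\n".join(",".join(map(str, r)) for r in ic_rows) + "\n")
    _write(out / "BulkReactionKey.csv",
           "subdomain,reaction_file\n"
           + "\n".join(",".join(r) for r in reaction_key_rows) + "\n")
    _write(out / "config.txt", "\n".join(config_lines) + "\n")


def _fisher_kpp(out):
    """Logistic invasion front: D = r = kappa = 1, strip seed at x < 1.

    The propagation axis is x (domain 100 x 10); the strip 0 < x < 1 is a
    separate subdomain carrying the nonzero initial condition.
    """
    n_cols = 100
    topology = [["S"] + ["B"] * (n_cols - 1)]
    _write(out / "LogisticReactions.txt",
           "# logistic source r U (1 - U / kappa) with r = kappa = 1\n"
           "MassActionReaction: U -> 2 U ; k = 1.0\n"
           "MassActionReaction: 2 U -> U ; k = 1.0\n")
    _write_common(
        out,
        topology_rows=topology,
        key_lines=["S,Strip", "B,Bulk"],
        diffusion_rows=[("Strip", "U", 1.0), ("Bulk", "U", 1.0)],
        bc_rows=[("U", "neumann_flux", 0.0)],
        ic_rows=[("Strip", "U", 1.0, "false"), ("Bulk", "U", 0.0, "false")],
        reaction_key_rows=[("Strip", "LogisticReactions.txt"),
                           ("Bulk", "LogisticReactions.txt")],
        config_lines=[
            "simulation_type = domain_only",
            "output_directory = output",
            "number_of_pdes = 1",
            "domain_dimensions = 100, 10",
            "element_dimension = 0.5",
            "time_step = 0.01",
            "end_time = 40",
            "sampling_rate = 1.0",
            "rng_seed = 0",
        ])


def _schnakenberg(out, *, k1, k_minus1, k2, k3, d_u, d_v, u0, v0,
                  dt, t_end, sampling):
    _write(out / "SchnakenbergReactions.txt",
           f"ZerothOrderReversibleReaction: <-> U ; "
           f"k_f = {k1}, k_r = {k_minus1}\n"
           f"ZerothOrderReaction: -> V ; k = {k2}\n"
           f"MassActionReaction: 2 U + V -> 3 U ; k = {k3}\n")
    _write_common(
        out,
        topology_rows=[["D"]],
        key_lines=["D,Domain"],
        diffusion_rows=[("Domain", "U", d_u), ("Domain", "V", d_v)],
        bc_rows=[("U", "neumann_flux", 0.0), ("V", "neumann_flux", 0.0)],
        ic_rows=[("Domain", "U", u0, "true"), ("Domain", "V", v0, "true")],
        reaction_key_rows=[("Domain", "SchnakenbergReactions.txt")],
        config_lines=[
            "simulation_type = domain_only",
            "output_directory = output",
            "number_of_pdes = 2",
            "domain_dimensions = 100, 100",
            "element_dimension = 1.0",
            f"time_step = {dt}",
            f"end_time = {t_end}",
            f"sampling_rate = {sampling}",
            "perturbation_magnitude = 1.0",
            "rng_seed = 0",
        ])


def _cooperator_cheater(out):
    """Public-goods exemplar with synthetic defaults.

    The cell metabolic network and the bulk enzyme reactions follow the
    published toy model (all intracellular rate constants 1; the
    enzyme-producing step has k = 0 in the cheater type).  Domain size,
    diffusivities, bulk rates, boundary influx, thresholds and initial
    cell states are synthetic defaults chosen for a compact run; see
    docs/methods.md.
    """
    _write(out / "BulkEnzymeReactions.txt",
           "MassActionReversibleReaction: ES <-> E + S ; k_f = 0.05, k_r = 5\n"
           "MassActionReaction: E -> ; k = 0.01\n")
    _write_common(
        out,
        topology_rows=[["D"]],
        key_lines=["D,Domain"],
        diffusion_rows=[("Domain", "E", 0.01), ("Domain", "S", 1.0),
                        ("Domain", "ES", 0.01), ("Domain", "O2", 1.0)],
        bc_rows=[("E", "neumann_flux", 0.0), ("S", "neumann_flux", 0.1),
                 ("ES", "neumann_flux", 0.0), ("O2", "neumann_flux", 0.1)],
        ic_rows=[("Domain", "E", 0.0, "false"), ("Domain", "S", 0.1, "false"),
                 ("Domain", "ES", 0.0, "false"),
                 ("Domain", "O2", 1.0, "false")],
        reaction_key_rows=[("Domain", "BulkEnzymeReactions.txt")],
        config_lines=[
            "simulation_type = cell_coupled",
            "output_directory = output",
            "number_of_pdes = 4",
            "domain_dimensions = 20, 20",
            "element_dimension = 1.0",
            "time_step = 0.02",
            "end_time = 10000",
            "sampling_rate = 10",
            "rng_seed = 0",
            "cell_file_root = Cells",
            "cell_mesh_origin = 8, 10",
            "cell_spacing = 1.0",
            "linear_force_cutoff = 1.5",
            "spring_stiffness = 1.0",
            "division_fraction = 0.5",
        ])
    cells = out / "Cells"
    _write(cells / "CellLayerTopology.csv", "1,0,0,0,2\n")
    _write(cells / "CellLayerKey.csv", "1,Cooperator\n2,Cheater\n")
    for type_name, k5, e0 in (("Cooperator", 1.0, 0.3), ("Cheater", 0.0, 0.0)):
        tdir = cells / type_name
        _write(tdir / "Srn.txt",
               "MassActionReaction: ES -> E + S ; k = 1\n"
               "MassActionReaction: S + NAD + ADP -> Precursor + NADH + ATP"
               " ; k = 1\n"
               "MassActionReversibleReaction: NADH + ADP + O2 <-> "
               "NAD + H2O + ATP ; k_f = 1, k_r = 1\n"
               "MassActionReaction: Precursor + ATP -> Biomass + ADP ; "
               "k = 1\n"
               f"MassActionReaction: Precursor + ATP -> E + ADP ; k = {k5}\n")
        _write(tdir / "TransportReactions.txt",
               "MassActionTransportReaction: ES -> ES ; k = 5\n"
               "MassActionReversibleTransportReaction: O2 <-> O2 ; "
               "k_f = 1, k_r = 0.1\n"
               "MassActionReversibleTransportReaction: E <-> E ; "
               "k_f = 0.1, k_r = 1\n")
        _write(tdir / "MembraneReactions.txt",
               "# no membrane reactions in this exemplar\n")
        _write(tdir / "InitialCellConcentrations.csv",
               "species,value,perturb\n"
               "NAD,1.0,false\nNADH,0.0,false\nADP,1.0,false\nATP,1.0,false\n"
               f"Biomass,0.5,false\nE,{e0},false\nES,0.0,false\n"
               "S,0.1,false\n"
               "Precursor,0.0,false\nH2O,0.0,false\nO2,1.0,false\n")
        _write(tdir / "SpeciesThreshold.csv",
               "species,max,min\nBiomass,1.0,0.01\n")


EXEMPLARS = {
    "fisher_kpp": _fisher_kpp,
    "schnakenberg_oscillation": lambda out: _schnakenberg(
        out, k1=0.5, k_minus1=2.2, k2=1.5, k3=1.0, d_u=0.5, d_v=0.5,
        u0=0.91, v0=1.67, dt=0.01, t_end=100, sampling=0.5),
    "schnakenberg_pattern": lambda out: _schnakenberg(
        out, k1=0.1, k_minus1=1.0, k2=0.9, k3=1.0, d_u=1, d_v=40,
        u0=1.0, v0=1.0, dt=0.05, t_end=200, sampling=1.0),
    "cooperator_cheater": _cooperator_cheater,
}


def write_exemplar(name, out_dir):
    """Write one of the built-in model directories under ``out_dir``."""
    if name not in EXEMPLARS:
        raise ValueError(
            f"unknown exemplar {name!r}; choose from {sorted(EXEMPLARS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    EXEMPLARS[name](out)
    return out / "config.txt"
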