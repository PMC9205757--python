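"""Structured 2D triangular meshes and labelled domain fields.

The bulk domain is a rectangle discretised into a uniform grid of squares,
each split into two right triangles along the lower-left -> upper-right
diagonal.  Linear (P1) basis functions are used throughout, so all the
geometry the solver needs is the node table, the element connectivity and
the lumped nodal areas ("volume shares").

Conventions (fixed here, documented in docs/methods.md):

* origin at the lower-left corner, node indexing row-major from the origin
  (x fastest);
* the subdomain label grid is stretched to the mesh extent; a node takes
  the label of the closed grid cell containing it, ties resolved toward
  the lower-left cell;
* label-grid rows are listed bottom-to-top (first CSV row is y = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "DomainField",
    "build_rectangular_mesh",
    "assign_labels",
    "nodal_volume_share",
]


@dataclass
class Mesh:
    """Uniform triangulation of a rectangle.

    Attributes
    ----------
    nx, ny : int
        Number of grid squares along x and y.
    spacing : float
        Grid step h; every element has area h^2 / 2.
    node_xy : (n_nodes, 2) float array
        Node positions, row-major from the lower-left origin.
    triangles : (n_elements, 3) int array
        Counter-clockwise node indices.
    on_boundary : (n_nodes,) bool array
    labels : list[str] | None
        Per-node subdomain labels, set by :func:`assign_labels`.
    """

    nx: int
    ny: int
    spacing: float
    node_xy: np.ndarray
    triangles: np.ndarray
    on_boundary: np.ndarray
    labels: list | None = None
    _volume_shares: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_xy.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def extent(self) -> tuple[float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing)

    @property
    def element_area(self) -> float:
        return 0.5 * self.spacing**2

    def node_index(self, i: int, j: int) -> int:
        """Grid coordinates (column i, row j) -> node index."""
        return j * (self.nx + 1) + i

    def volume_shares(self) -> np.ndarray:
        """Lumped nodal areas: one third of incident-element areas.

        They partition the domain: ``sum(shares) == nx * ny * h**2``.
        """
        if self._volume_shares is None:
            shares = np.zeros(self.n_nodes)
            np.add.at(shares, self.triangles.ravel(),
                      self.element_area / 3.0)
            self._volume_shares = shares
        return self._volume_shares

    def nearest_node(self, x: float, y: float) -> int:
        """Index of the mesh node nearest to (x, y); ties -> lowest index."""
        d2 = (self.node_xy[:, 0] - x) ** 2 + (self.node_xy[:, 1] - y) ** 2
        # argmin returns the first (lowest) index among ties
        return int(np.argmin(np.round(d2, 12)))


@dataclass
class DomainField:
    """Subdomain labelling plus per-subdomain physical data.

    label_grid rows run bottom-to-top; ``key`` maps grid tokens to
    subdomain names; ``diffusivity`` maps (species, subdomain name) to a
    non-negative coefficient; ``reaction_files`` maps subdomain name to a
    bulk reaction file (or parsed system); ``boundary_conditions`` maps
    species to a (kind, value) pair.
    """

    label_grid: np.ndarray          # 2D array of str tokens, [row=y][col=x]
    key: dict                       # token -> subdomain name
    diffusivity: dict = field(default_factory=dict)
    reaction_files: dict = field(default_factory=dict)
    boundary_conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        grid = np.asarray(self.label_grid, dtype=object)
        if grid.ndim != 2:
            raise ValueError("label grid must be rectangular (2D)")
        self.label_grid = grid

    def subdomain_names(self) -> list:
        return list(dict.fromkeys(self.key.values()))


def build_rectangular_mesh(nx: int, ny: int, spacing: float) -> Mesh:
    """Triangulate an ``nx`` x ``ny`` grid of squares of side ``spacing``.

    Produces ``(nx+1)(ny+1)`` nodes and ``2 nx ny`` counter-clockwise
    triangles, each grid square split along its lower-left -> upper-right
    diagonal.  Perimeter nodes are flagged as boundary nodes.
    """
    if nx < 1 or ny < 1:
        raise ValueError(f"mesh dimensions must be >= 1, got ({nx}, {ny})")
    if spacing <= 0:
        raise ValueError(f"mesh spacing must be > 0, got {spacing}")

    xs = np.arange(nx + 1) * spacing
    ys = np.arange(ny + 1) * spacing
    X, Y = np.meshgrid(xs, ys)              # row-major: y varies by row
    node_xy = np.column_stack([X.ravel(), Y.ravel()])

    tris = np.empty((2 * nx * ny, 3), dtype=np.int64)
    t = 0
    for j in range(ny):
        for i in range(nx):
            ll = j * (nx + 1) + i
            lr = ll + 1
            ul = ll + (nx + 1)
            ur = ul + 1
            tris[t] = (ll, lr, ur)          # lower-right triangle
            tris[t + 1] = (ll, ur, ul)      # upper-left triangle
            t += 2

    on_boundary = (
        np.isclose(node_xy[:, 0], 0.0)
        | np.isclose(node_xy[:, 0], nx * spacing)
        | np.isclose(node_xy[:, 1], 0.0)
        | np.isclose(node_xy[:, 1], ny * spacing)
    )
    return Mesh(nx=nx, ny=ny, spacing=spacing, node_xy=node_xy,
                triangles=tris, on_boundary=on_boundary)


def assign_labels(mesh: Mesh, domain: DomainField) -> Mesh:
    """Attach a subdomain label to every node from the topology grid.

    The label grid is stretched to the mesh extent.  A node takes the
    label of the grid cell whose closed region contains it; nodes on a
    cell edge resolve toward the lower-left cell.  Labels missing from
    the key are rejected.
    """
    grid = domain.label_grid
    n_rows, n_cols = grid.shape
    width, height = mesh.extent
    cell_w = width / n_cols
    cell_h = height / n_rows

    labels = []
    for x, y in mesh.node_xy:
        # closed-cell membership with lower-left tie break: a node exactly
        # on an internal edge belongs to the cell on its lower/left side
        ci = int(np.ceil(x / cell_w)) - 1 if x > 0 else 0
        rj = int(np.ceil(y / cell_h)) - 1 if y > 0 else 0
        ci = min(max(ci, 0), n_cols - 1)
        rj = min(max(rj, 0), n_rows - 1)
        token = str(grid[rj, ci])
        if token not in domain.key:
            raise KeyError(
                f"topology label {token!r} is not present in the domain key")
        labels.append(token)
    mesh.labels = labels
    return mesh


def nodal_volume_share(mesh: Mesh, node_index: int) -> float:
    """Lumped-mass area of one node (incident element areas / 3)."""
    if not 0 <= node_index < mesh.n_nodes:
        raise IndexError(
            f"node index {node_index} out of range [0, {mesh.n_nodes})")
    return float(mesh.volume_shares()[node_index])
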