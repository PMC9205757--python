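"""Cell-bulk coupling: transport and membrane reactions at bound nodes.

Each cell is bound to its nearest mesh node and interacts with the bulk
only there.  The node's lumped volume share converts between bulk
concentration and amount: cell-side state is amount-like concentration in
a unit cell volume, so a transport rate R moves R*dt of amount, changing
the bulk nodal concentration by -R*dt/share.  Transport reactions (bulk
species on the left, cell species on the right) therefore conserve the
total amount  bulk_conc * share + cell_conc  exactly for balanced
stoichiometries.  Membrane reactions evaluate one shared rate on the
joint (bulk, cell) state and advance the outer equation on bulk species
and the inner equation on cell species; no species crosses the membrane.

Multiple cells bound to one node are applied sequentially in cell-id
order.  Updates that would drive a concentration negative are rescaled to
stop exactly at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CouplingBinding",
    "bind_cells",
    "apply_transport",
    "apply_membrane",
    "apply_coupling",
]


@dataclass
class CouplingBinding:
    cell_id: int
    node_index: int
    volume_share: float


def bind_cells(pop, mesh):
    """Bind every cell to its nearest mesh node (ties -> lowest index)."""
    shares = mesh.volume_shares()
    width, height = mesh.extent
    bindings = []
    for cell in sorted(pop.cells, key=lambda c: c.id):
        x, y = cell.position
        if not (0 <= x <= width and 0 <= y <= height):
            raise ValueError(
                f"cell {cell.id} at ({x:g}, {y:g}) lies outside the domain")
        node = mesh.nearest_node(x, y)
        bindings.append(CouplingBinding(cell.id, node, float(shares[node])))
    return bindings


def _joint_rate(rx, bulk_lookup, cell_lookup, reactant_lookup,
                product_lookup):
    """Rate of one coupling reaction on the joint (bulk, cell) state.

    ``reactant_lookup`` / ``product_lookup`` say which side of the
    membrane each stoichiometric side reads from.  Spectators resolve
    from the cell first, then the bulk.
    """
    def spec_factor():
        out = 1.0
        for s in rx.spectators:
            out *= cell_lookup(s) if cell_lookup(s, None) is not None \
                else bulk_lookup(s)
        return out

    def prod(coeffs, lookup):
        out = 1.0
        for s, nu in coeffs.items():
            out *= lookup(s) ** nu
        return out

    if rx.law == "zeroth_order":
        return rx.parameters["k"]
    if rx.law == "mass_action_irreversible":
        return rx.parameters["k"] * prod(rx.reactants, reactant_lookup) \
            * spec_factor()
    if rx.law == "mass_action_reversible":
        return (rx.parameters["k_f"] * prod(rx.reactants, reactant_lookup)
                - rx.parameters["k_r"] * prod(rx.products, product_lookup)) \
            * spec_factor()
    if rx.law == "michaelis_menten":
        s_name = next(iter(rx.reactants))
        s = reactant_lookup(s_name)
        e = (cell_lookup(rx.spectators[0])
             if rx.spectators and cell_lookup(rx.spectators[0], None)
             is not None else 1.0)
        return rx.parameters["k_cat"] * e * s / (rx.parameters["K_M"] + s)
    raise ValueError(f"coupling does not support custom law {rx.law!r}")


def _limited(deltas, getter):
    """Largest fraction of the proposed update keeping all states >= 0."""
    alpha = 1.0
    for (kind, key), d in deltas.items():
        if d < 0:
            current = getter(kind, key)
            if current + d < 0:
                alpha = min(alpha, current / -d if d != 0 else 1.0)
    return max(alpha, 0.0)


def _apply_deltas(deltas, cell, bulk_row, species_index, alpha):
    for (kind, key), d in deltas.items():
        d *= alpha
        if kind == "cell":
            cell.internal_concentrations[key] = max(
                cell.concentration(key) + d, 0.0)
        else:
            col = species_index[key]
            bulk_row[col] = max(bulk_row[col] + d, 0.0)


def apply_transport(binding, cell, bulk_row, species_index, dt):
    """Advance the cell's transport reactions at its bound node (in place).

    ``bulk_row`` is the node's concentration vector (modified in place);
    ``species_index`` maps bulk species names to columns.
    """
    share = binding.volume_share
    for rx in cell.transport_reactions:
        def bulk_lookup(s, default="raise"):
            if s in species_index:
                return bulk_row[species_index[s]]
            if default == "raise":
                raise KeyError(f"unknown bulk species {s!r}")
            return default

        def cell_lookup(s, default="raise"):
            if s in cell.internal_concentrations:
                return cell.internal_concentrations[s]
            return None if default is None else 0.0

        rate = _joint_rate(rx, bulk_lookup, cell_lookup,
                           reactant_lookup=lambda s: bulk_lookup(s),
                           product_lookup=lambda s: cell_lookup(s))
        if rate == 0.0:
            continue
        deltas = {}
        for s, nu in rx.reactants.items():       # bulk side consumed forward
            deltas[("bulk", s)] = deltas.get(("bulk", s), 0.0) \
                - nu * rate * dt / share
        for s, nu in rx.products.items():        # cell side produced forward
            deltas[("cell", s)] = deltas.get(("cell", s), 0.0) \
                + nu * rate * dt
        alpha = _limited(deltas, lambda kind, key:
                         bulk_row[species_index[key]] if kind == "bulk"
                         else cell.concentration(key))
        _apply_deltas(deltas, cell, bulk_row, species_index, alpha)
    return bulk_row


def apply_membrane(binding, cell, bulk_row, species_index, dt):
    """Advance paired membrane reactions: one rate, two local updates."""
    share = binding.volume_share
    for outer, inner in cell.membrane_reactions:
        def bulk_lookup(s, default="raise"):
            if s in species_index:
                return bulk_row[species_index[s]]
            if default == "raise":
                raise KeyError(f"unknown bulk species {s!r}")
            return default

        def cell_lookup(s, default="raise"):
            if s in cell.internal_concentrations:
                return cell.internal_concentrations[s]
            return None if default is None else 0.0

        def reactant_lookup(s):
            if s in outer.reactants:
                return bulk_lookup(s)
            return cell_lookup(s)

        def product_lookup(s):
            if s in outer.products:
                return bulk_lookup(s)
            return cell_lookup(s)

        joint = type(outer)(
            law=outer.law,
            reactants={**outer.reactants, **inner.reactants},
            products={**outer.products, **inner.products},
            parameters=outer.parameters,
            spectators=outer.spectators,
            reversible=outer.reversible,
            context="membrane",
        )
        rate = _joint_rate(joint, bulk_lookup, cell_lookup,
                           reactant_lookup, product_lookup)
        if rate == 0.0:
            continue
        deltas = {}
        for s, nu in outer.reactants.items():
            deltas[("bulk", s)] = deltas.get(("bulk", s), 0.0) \
                - nu * rate * dt / share
        for s, nu in outer.products.items():
            deltas[("bulk", s)] = deltas.get(("bulk", s), 0.0) \
                + nu * rate * dt / share
        for s, nu in inner.reactants.items():
            deltas[("cell", s)] = deltas.get(("cell", s), 0.0) \
                - nu * rate * dt
        for s, nu in inner.products.items():
            deltas[("cell", s)] = deltas.get(("cell", s), 0.0) \
                + nu * rate * dt
        alpha = _limited(deltas, lambda kind, key:
                         bulk_row[species_index[key]] if kind == "bulk"
                         else cell.concentration(key))
        _apply_deltas(deltas, cell, bulk_row, species_index, alpha)
    return bulk_row


def apply_coupling(bindings, pop, field_values, species_index, dt):
    """Apply transport then membrane coupling for every cell, in id order."""
    by_id = {c.id: c for c in pop.cells}
    for binding in bindings:
        cell = by_id[binding.cell_id]
        row = field_values[binding.node_index]
        apply_transport(binding, cell, row, species_index, dt)
        apply_membrane(binding, cell, row, species_index, dt)
    return field_values
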