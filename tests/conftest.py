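import numpy as np
import pytest

from chemcell import chemistry, mesh as mesh_mod
from chemcell.pde import BoundaryConditionSpec


def make_schnakenberg_system(k1, k_minus1, k2, k3):
    """The two-species production/interconversion/removal network."""
    return chemistry.ReactionSystem(["U", "V"], [
        chemistry.parse_reaction_line(
            f"ZerothOrderReversibleReaction: <-> U ; k_f = {k1}, "
            f"k_r = {k_minus1}"),
        chemistry.parse_reaction_line(f"ZerothOrderReaction: -> V ; k = {k2}"),
        chemistry.parse_reaction_line(
            f"MassActionReaction: 2 U + V -> 3 U ; k = {k3}"),
    ])


@pytest.fixture
def schnakenberg_oscillatory():
    return make_schnakenberg_system(0.5, 2.2, 1.5, 1.0)


@pytest.fixture
def schnakenberg_patterning():
    return make_schnakenberg_system(0.1, 1.0, 0.9, 1.0)


@pytest.fixture
def uniform_domain():
    """Single-subdomain field factory for simple solver tests."""
    def make(species, diffusivity, bcs=None):
        return mesh_mod.DomainField(
            label_grid=np.array([["D"]], dtype=object),
            key={"D": "Domain"},
            diffusivity={(s, "Domain"): d
                         for s, d in zip(species, diffusivity)},
            boundary_conditions=bcs or {
                s: BoundaryConditionSpec(s, "neumann_flux", 0.0)
                for s in species})
    return make
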