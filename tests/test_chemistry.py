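import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemcell import chemistry
from chemcell.chemistry import (ReactionParseError, ReactionSystem,
                                evaluate_rates, integrate_well_mixed,
                                parse_reaction_line, serialize_reaction)
from conftest import make_schnakenberg_system


class TestGrammar:
    def test_mass_action_with_coefficients(self):
        rx = parse_reaction_line("MassActionReaction: 2U + V -> 3U ; k = 1.0")
        assert rx.reactants == {"U": 2, "V": 1}
        assert rx.products == {"U": 3}
        assert rx.parameters == {"k": 1.0}
        assert not rx.reversible

    def test_reversible_zeroth_order_production_removal_pair(self):
        rx = parse_reaction_line(
            "ZerothOrderReversibleReaction: <-> U ; k_f = 0.5, k_r = 2.2")
        assert rx.reactants == {}
        assert rx.products == {"U": 1}
        assert rx.reversible
        system = ReactionSystem(["U"], [rx])
        # production at k_f minus first-order removal at k_r
        assert evaluate_rates(system, [2.0])[0] == \
            pytest.approx(0.5 - 2.2 * 2.0)

    @pytest.mark.parametrize("bad", [
        "MassActionReaction 2U + V -> 3U",          # no delimiters
        "MassActionReaction: 2U + V -> 3U",         # missing ';'
        "MassActionReaction: 2.5 U -> V ; k = 1",   # non-integer coefficient
        "MassActionReaction: U -> V ; k = -1",      # negative parameter
        "NoSuchLaw: U -> V ; k = 1",                # unknown law
        "MassActionReaction: U = V ; k = 1",        # no arrow
    ])
    def test_malformed_lines_rejected(self, bad):
        with pytest.raises(ReactionParseError):
            parse_reaction_line(bad)

    def test_parse_error_reports_line_number(self):
        with pytest.raises(ReactionParseError, match="line 7"):
            parse_reaction_line("MassActionReaction: U -> V", lineno=7)

    def test_membrane_line_splits_into_outer_and_inner(self):
        outer, inner = parse_reaction_line(
            "MassActionCoupledMembrane: -> A | B -> ; k = 2.0",
            context="membrane")
        assert outer.products == {"A": 1} and outer.reactants == {}
        assert inner.reactants == {"B": 1} and inner.products == {}
        assert outer.parameters["k"] == 2.0

    def test_spectators_parsed_from_parameter_list(self):
        rx = parse_reaction_line(
            "MichaelisMentenReaction: S -> P ; k_cat = 2, K_M = 0.5, "
            "spectators = E")
        assert rx.spectators == ["E"]

    def test_grammar_round_trip(self, schnakenberg_oscillatory):
        for rx in schnakenberg_oscillatory.reactions:
            again = parse_reaction_line(serialize_reaction(rx))
            assert again.law == rx.law
            assert again.reactants == rx.reactants
            assert again.products == rx.products
            assert again.parameters == rx.parameters


class TestRates:
    def test_schnakenberg_hand_computed_rates(self, schnakenberg_patterning):
        # k1=0.1, k-1=1.0, k2=0.9, k3=1.0 at (U, V) = (1, 1)
        assert evaluate_rates(schnakenberg_patterning, [1.0, 1.0]) == \
            pytest.approx([0.1, -0.1])

    def test_schnakenberg_steady_state_zeroes_rates(
            self, schnakenberg_patterning):
        assert evaluate_rates(schnakenberg_patterning, [1.0, 0.9]) == \
            pytest.approx([0.0, 0.0], abs=1e-14)

    def test_zero_concentrations_leave_only_zeroth_order_terms(
            self, schnakenberg_oscillatory):
        assert evaluate_rates(schnakenberg_oscillatory, [0.0, 0.0]) == \
            pytest.approx([0.5, 1.5])

    def test_negative_concentration_rejected(self, schnakenberg_oscillatory):
        with pytest.raises(ValueError):
            evaluate_rates(schnakenberg_oscillatory, [-0.1, 1.0])

    def test_michaelis_menten_rate_form(self):
        rx = parse_reaction_line(
            "MichaelisMentenReaction: S -> P ; k_cat = 3.0, K_M = 2.0, "
            "spectators = E")
        system = ReactionSystem(["S", "P", "E"], [rx])
        d = evaluate_rates(system, [4.0, 0.0, 0.5])
        expected = 3.0 * 0.5 * 4.0 / (2.0 + 4.0)
        assert d == pytest.approx([-expected, expected, 0.0])

    def test_reversible_reduces_to_irreversible_when_kr_zero(self):
        fwd = parse_reaction_line("MassActionReaction: A -> B ; k = 0.7")
        rev = parse_reaction_line(
            "MassActionReversibleReaction: A <-> B ; k_f = 0.7, k_r = 0")
        s1 = ReactionSystem(["A", "B"], [fwd])
        s2 = ReactionSystem(["A", "B"], [rev])
        c = [1.3, 2.1]
        assert evaluate_rates(s1, c) == pytest.approx(evaluate_rates(s2, c))

    def test_balanced_stoichiometry_conserves_total(self):
        rx = parse_reaction_line("MassActionReaction: A + B -> 2 C ; k = 1.5")
        system = ReactionSystem(["A", "B", "C"], [rx])
        d = evaluate_rates(system, [0.5, 2.0, 0.1])
        assert d.sum() == pytest.approx(0.0, abs=1e-14)

    def test_vectorised_rates_match_per_node_evaluation(
            self, schnakenberg_patterning):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 2, size=(40, 2))
        batch = schnakenberg_patterning.rates(c)
        rows = np.array([schnakenberg_patterning.rates(row) for row in c])
        np.testing.assert_allclose(batch, rows, atol=1e-14)


def _brute_force_rates(species, reactions, conc):
    """Independent oracle: explicit loops over reactions and species."""
    conc = dict(zip(species, conc))
    deriv = dict.fromkeys(species, 0.0)
    for rx in reactions:
        if rx.law == "zeroth_order":
            rate = rx.parameters["k"]
        elif rx.law == "mass_action_irreversible":
            rate = rx.parameters["k"]
            for s, nu in rx.reactants.items():
                rate *= conc[s] ** nu
        elif rx.law == "mass_action_reversible":
            fwd, rev = rx.parameters["k_f"], rx.parameters["k_r"]
            for s, nu in rx.reactants.items():
                fwd *= conc[s] ** nu
            for s, nu in rx.products.items():
                rev *= conc[s] ** nu
            rate = fwd - rev
        for s in rx.spectators:
            rate *= conc[s]
        for s, nu in rx.reactants.items():
            deriv[s] -= nu * rate
        for s, nu in rx.products.items():
            deriv[s] += nu * rate
    return np.array([deriv[s] for s in species])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_rates_agree_with_brute_force_oracle(data):
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    n_sp = int(rng.integers(1, 6))
    species = [f"X{i}" for i in range(n_sp)]
    reactions = []
    for _ in range(int(rng.integers(1, 7))):
        law = rng.choice(["zeroth_order", "mass_action_irreversible",
                          "mass_action_reversible"])
        sides = []
        for _side in range(2):
            picks = rng.choice(species,
                               size=rng.integers(0, min(3, n_sp + 1)),
                               replace=False)
            sides.append({s: int(rng.integers(1, 3)) for s in picks})
        reactants, products = sides
        if law == "zeroth_order":
            reactants = {}
            params = {"k": float(rng.uniform(0, 2))}
            if not products:
                products = {species[0]: 1}
        elif law == "mass_action_irreversible":
            params = {"k": float(rng.uniform(0, 2))}
            if not reactants and not products:
                reactants = {species[0]: 1}
        else:
            params = {"k_f": float(rng.uniform(0, 2)),
                      "k_r": float(rng.uniform(0, 2))}
            if not reactants and not products:
                reactants = {species[0]: 1}
        reactions.append(chemistry.Reaction(
            law=law, reactants=reactants, products=products,
            parameters=params, reversible=law == "mass_action_reversible"))
    system = ReactionSystem(species, reactions)
    conc = rng.uniform(0, 3, size=n_sp)
    np.testing.assert_allclose(
        system.rates(conc),
        _brute_force_rates(species, reactions, conc), atol=1e-12)


class TestWellMixedIntegration:
    def test_constant_production_grows_linearly(self):
        system = ReactionSystem(
            ["U"], [parse_reaction_line("ZerothOrderReaction: -> U ; k = 1")])
        t, y = integrate_well_mixed(system, [0.0], t_end=1.0, dt=0.01)
        assert y[-1, 0] == pytest.approx(1.0, abs=0.02)

    def test_first_order_decay_matches_exponential(self):
        system = ReactionSystem(
            ["U"], [parse_reaction_line("MassActionReaction: U -> ; k = 1")])
        t, y = integrate_well_mixed(system, [1.0], t_end=2.0, dt=0.01)
        np.testing.assert_allclose(y[:, 0], np.exp(-t), atol=1e-6)

    def test_concentrations_never_negative(self):
        system = ReactionSystem(
            ["U"], [parse_reaction_line("MassActionReaction: U -> ; k = 50")])
        _, y = integrate_well_mixed(system, [1.0], t_end=1.0, dt=0.05)
        assert np.all(y >= 0)

    def test_invalid_stepping_arguments(self, schnakenberg_oscillatory):
        with pytest.raises(ValueError):
            integrate_well_mixed(schnakenberg_oscillatory, [1, 1],
                                 t_end=1.0, dt=0.0)
        with pytest.raises(ValueError):
            integrate_well_mixed(schnakenberg_oscillatory, [1, 1],
                                 t_end=0.001, dt=0.01)

    def test_oscillatory_regime_cycles_around_the_unstable_state(self):
        system = make_schnakenberg_system(0.5, 2.2, 1.5, 1.0)
        t, y = integrate_well_mixed(system, [0.91, 1.67], t_end=60.0,
                                    dt=0.01, sampling_interval=0.1)
        u_late = y[len(t) // 2:, 0]
        assert u_late.max() - u_late.min() > 0.5   # still swinging widely
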