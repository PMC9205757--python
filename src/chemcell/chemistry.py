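"""Chemical species, reactions, the reaction-file grammar and kinetics.

One plain-text line encodes one reaction::

    <rate-law name> : <equation> ; <param> = <value>, <param> = <value>, ...

with ``->`` for irreversible and ``<->`` for reversible equations, integer
stoichiometric coefficients prefixing species tokens, ``+`` separating
terms and an empty side denoting the empty set.  Membrane reactions pair
an outer (bulk-facing) and inner (cell-facing) equation separated by the
membrane delimiter ``|``.  In transport context the left-hand side names
bulk species and the right-hand side cell species.

EBNF (whitespace insignificant)::

    line      = law ":" equation ";" [params]
    equation  = side arrow side | outer "|" inner        (membrane)
    side      = [term {"+" term}]
    term      = [integer] token
    arrow     = "->" | "<->"
    params    = param {"," param}
    param     = name "=" number | "spectators" "=" token {token}

Rate laws (registry-extensible; class-name-like aliases accepted):

* ``zeroth_order``             R = k
* ``mass_action_irreversible`` R = k * prod c_react^nu * prod c_spectator
* ``mass_action_reversible``   R = k_f * prod c_react^nu - k_r * prod c_prod^nu
* ``michaelis_menten``         R = k_cat * E * S / (K_M + S), S the first
  reactant, E the first spectator (or 1 if none)

Spectator species multiply the rate linearly and never appear in the
stoichiometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChemicalSpecies",
    "Reaction",
    "ReactionSystem",
    "ReactionParseError",
    "parse_reaction_line",
    "parse_reaction_file",
    "serialize_reaction",
    "evaluate_rates",
    "integrate_well_mixed",
    "SolverFailure",
    "RATE_LAWS",
    "register_rate_law",
]


class ReactionParseError(ValueError):
    """Malformed reaction line (missing delimiter, bad coefficient ...)."""


class SolverFailure(RuntimeError):
    """ODE/PDE integration produced non-finite values."""

    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


@dataclass
class ChemicalSpecies:
    """A named chemical with optional physical properties.

    ``mass``, ``valence`` and ``gibbs_formation_energy`` are stored and
    exposed but do not modify rates; ``diffusivity`` maps subdomain name
    to an isotropic coefficient.
    """

    name: str
    diffusivity: dict = field(default_factory=dict)
    mass: float | None = None
    valence: int | None = None
    gibbs_formation_energy: float | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("species name must be nonempty")
        for sub, d in self.diffusivity.items():
            if d < 0:
                raise ValueError(
                    f"negative diffusivity for {self.name} in {sub}")


#: law name -> canonical key.  Aliases cover the class-name style used in
#: reaction files (e.g. "MassActionReaction", "ZerothOrderReversibleReaction").
_LAW_ALIASES = {
    "zeroth_order": "zeroth_order",
    "zerothorderreaction": "zeroth_order",
    "zerothordertransportintocell": "zeroth_order",
    "zerothordercoupledmembrane": "zeroth_order",
    "mass_action": "mass_action_irreversible",
    "mass_action_irreversible": "mass_action_irreversible",
    "massactionreaction": "mass_action_irreversible",
    "massactiontransportreaction": "mass_action_irreversible",
    "massactioncoupledmembrane": "mass_action_irreversible",
    "mass_action_reversible": "mass_action_reversible",
    "massactionreversiblereaction": "mass_action_reversible",
    "zerothorderreversiblereaction": "mass_action_reversible",
    "massactionreversibletransportreaction": "mass_action_reversible",
    "michaelis_menten": "michaelis_menten",
    "michaelismentenreaction": "michaelis_menten",
}

_REQUIRED_PARAMS = {
    "zeroth_order": ("k",),
    "mass_action_irreversible": ("k",),
    "mass_action_reversible": ("k_f", "k_r"),
    "michaelis_menten": ("k_cat", "K_M"),
}

RATE_LAWS = dict(_REQUIRED_PARAMS)  # public registry: law -> required params


def register_rate_law(name, required_params, rate_fn):
    """Register a user-defined rate law.

    ``rate_fn(reaction, c_react, c_prod, c_spec) -> rate`` receives, for a
    concentration state, the per-term arrays the built-in laws use.
    """
    key = name.lower()
    _LAW_ALIASES[key] = key
    RATE_LAWS[key] = tuple(required_params)
    _CUSTOM_LAWS[key] = rate_fn


_CUSTOM_LAWS: dict = {}


@dataclass
class Reaction:
    law: str
    reactants: dict            # species -> integer coefficient
    products: dict
    parameters: dict           # name -> float
    spectators: list = field(default_factory=list)
    reversible: bool = False
    context: str = "bulk"      # bulk | cell | transport | membrane-outer/inner

    def __post_init__(self):
        if self.law not in RATE_LAWS:
            raise ReactionParseError(f"unknown rate law {self.law!r}")
        for name, value in self.parameters.items():
            if name != "spectators" and value < 0:
                raise ReactionParseError(
                    f"negative parameter {name} = {value}")
        for p in RATE_LAWS[self.law]:
            if p not in self.parameters:
                raise ReactionParseError(
                    f"law {self.law!r} requires parameter {p!r}")
        if self.law != "zeroth_order" and not (self.reactants
                                               or self.products):
            raise ReactionParseError("reaction has no species on either side")

    def species_names(self):
        seen = dict.fromkeys(self.reactants)
        seen.update(dict.fromkeys(self.products))
        seen.update(dict.fromkeys(self.spectators))
        return list(seen)


_TOKEN_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _parse_side(text: str, lineno=None) -> dict:
    coeffs: dict = {}
    text = text.strip()
    if not text:
        return coeffs
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ReactionParseError(_at(f"empty term in {text!r}", lineno))
        m = re.match(r"^(\d+)?\s*(\S+)$", term)
        if not m:
            raise ReactionParseError(_at(f"cannot parse term {term!r}", lineno))
        coeff = int(m.group(1)) if m.group(1) else 1
        token = m.group(2)
        if not _TOKEN_RE.match(token):
            raise ReactionParseError(
                _at(f"invalid species token {token!r}", lineno))
        coeffs[token] = coeffs.get(token, 0) + coeff
    return coeffs


def _at(msg, lineno):
    return msg if lineno is None else f"line {lineno}: {msg}"


def _parse_params(text: str, lineno=None):
    params: dict = {}
    spectators: list = []
    text = text.strip()
    if not text:
        return params, spectators
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ReactionParseError(
                _at(f"parameter {item!r} is not 'name = value'", lineno))
        name, _, value = item.partition("=")
        name = name.strip()
        value = value.strip()
        if name.lower() in ("spectator", "spectators"):
            spectators.extend(value.split())
            continue
        try:
            params[name] = float(value)
        except ValueError:
            raise ReactionParseError(
                _at(f"non-numeric value {value!r} for parameter {name!r}",
                    lineno)) from None
    return params, spectators


def _parse_equation(eq: str, lineno=None):
    if "<->" in eq:
        lhs, _, rhs = eq.partition("<->")
        reversible = True
    elif "->" in eq:
        lhs, _, rhs = eq.partition("->")
        reversible = False
    else:
        raise ReactionParseError(
            _at(f"equation {eq.strip()!r} has no '->' or '<->'", lineno))
    return _parse_side(lhs, lineno), _parse_side(rhs, lineno), reversible


def _canonical_law(name: str, lineno=None) -> str:
    key = name.strip().lower()
    if key not in _LAW_ALIASES:
        raise ReactionParseError(_at(f"unknown rate law {name.strip()!r}",
                                     lineno))
    return _LAW_ALIASES[key]


def parse_reaction_line(text: str, context: str = "bulk", lineno=None):
    """Parse one reaction line.

    Returns a :class:`Reaction`, or an ``(outer, inner)`` pair in membrane
    context.  ``context`` is one of bulk, cell, transport, membrane.
    """
    if ":" not in text:
        raise ReactionParseError(
            _at(f"missing ':' rate delimiter in {text.strip()!r}", lineno))
    law_name, _, rest = text.partition(":")
    if ";" not in rest:
        raise ReactionParseError(
            _at(f"missing ';' reaction delimiter in {text.strip()!r}", lineno))
    eq_text, _, param_text = rest.partition(";")
    law = _canonical_law(law_name, lineno)
    params, spectators = _parse_params(param_text, lineno)

    if context == "membrane":
        if "|" not in eq_text:
            raise ReactionParseError(
                _at("membrane reaction missing '|' delimiter", lineno))
        outer_eq, _, inner_eq = eq_text.partition("|")
        outer_r, outer_p, rev_o = _parse_equation(outer_eq, lineno)
        inner_r, inner_p, rev_i = _parse_equation(inner_eq, lineno)
        common = dict(law=law, parameters=params, spectators=spectators,
                      reversible=rev_o or rev_i)
        outer = Reaction(reactants=outer_r, products=outer_p,
                         context="membrane-outer", **common)
        inner = Reaction(reactants=inner_r, products=inner_p,
                         context="membrane-inner", **common)
        return outer, inner

    reactants, products, reversible = _parse_equation(eq_text, lineno)
    # the reversible zeroth-order alias is genuinely reversible mass action
    # with an empty reactant side; keep the canonical law consistent
    if law == "mass_action_reversible" and not reversible:
        reversible = True
    return Reaction(law=law, reactants=reactants, products=products,
                    parameters=params, spectators=spectators,
                    reversible=reversible, context=context)


def parse_reaction_file(path, context="bulk"):
    """Parse a reaction file: one reaction per line, '#' comments."""
    reactions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parsed = parse_reaction_line(line, context=context, lineno=lineno)
            reactions.append(parsed)
    return reactions


def serialize_reaction(rx) -> str:
    """Inverse of :func:`parse_reaction_line` (single reactions or pairs)."""
    if isinstance(rx, tuple):          # membrane pair
        outer, inner = rx
        eq = f"{_fmt_side(outer.reactants)} {_arrow(outer)} " \
             f"{_fmt_side(outer.products)} | " \
             f"{_fmt_side(inner.reactants)} {_arrow(inner)} " \
             f"{_fmt_side(inner.products)}"
        rx = outer
    else:
        eq = f"{_fmt_side(rx.reactants)} {_arrow(rx)} {_fmt_side(rx.products)}"
    parts = [f"{k} = {v:g}" for k, v in rx.parameters.items()]
    if rx.spectators:
        parts.append("spectators = " + " ".join(rx.spectators))
    return f"{rx.law}: {eq} ; {', '.join(parts)}"


def _arrow(rx):
    return "<->" if rx.reversible else "->"


def _fmt_side(coeffs):
    return " + ".join(
        (f"{c} {s}" if c != 1 else s) for s, c in coeffs.items())


class ReactionSystem:
    """An ordered species list plus reactions, with vectorised kinetics.

    ``rates`` / :func:`evaluate_rates` accept a concentration array whose
    last axis runs over species (so a whole mesh of nodal states can be
    evaluated at once).
    """

    def __init__(self, species, reactions):
        self.species = [s if isinstance(s, ChemicalSpecies)
                        else ChemicalSpecies(s) for s in species]
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self.index = {n: i for i, n in enumerate(names)}
        self.reactions = list(reactions)
        for rx in self.reactions:
            for name in rx.species_names():
                if name not in self.index:
                    raise ValueError(
                        f"reaction references unknown species {name!r}")
        self._compile()

    @property
    def names(self):
        return [s.name for s in self.species]

    @property
    def n_species(self):
        return len(self.species)

    def _compile(self):
        self._terms = []
        n = self.n_species
        for rx in self.reactions:
            nu = np.zeros(n)
            for s, c in rx.reactants.items():
                nu[self.index[s]] -= c
            for s, c in rx.products.items():
                nu[self.index[s]] += c
            r_idx = np.array([self.index[s] for s in rx.reactants], dtype=int)
            r_pow = np.array(list(rx.reactants.values()), dtype=float)
            p_idx = np.array([self.index[s] for s in rx.products], dtype=int)
            p_pow = np.array(list(rx.products.values()), dtype=float)
            s_idx = np.array([self.index[s] for s in rx.spectators], dtype=int)
            self._terms.append((rx, nu, r_idx, r_pow, p_idx, p_pow, s_idx))

    def _reaction_rate(self, rx, c, r_idx, r_pow, p_idx, p_pow, s_idx):
        spec = np.prod(c[..., s_idx], axis=-1) if s_idx.size else 1.0
        if rx.law == "zeroth_order":
            base = np.broadcast_to(rx.parameters["k"], c.shape[:-1]).copy()
            return base * spec
        if rx.law == "mass_action_irreversible":
            fwd = np.prod(c[..., r_idx] ** r_pow, axis=-1) if r_idx.size else 1.0
            return rx.parameters["k"] * fwd * spec
        if rx.law == "mass_action_reversible":
            fwd = np.prod(c[..., r_idx] ** r_pow, axis=-1) if r_idx.size else 1.0
            rev = np.prod(c[..., p_idx] ** p_pow, axis=-1) if p_idx.size else 1.0
            return (rx.parameters["k_f"] * fwd
                    - rx.parameters["k_r"] * rev) * spec
        if rx.law == "michaelis_menten":
            if not r_idx.size:
                raise ValueError("Michaelis-Menten law needs a substrate")
            s = c[..., r_idx[0]]
            e = c[..., s_idx[0]] if s_idx.size else 1.0
            return rx.parameters["k_cat"] * e * s / (rx.parameters["K_M"] + s)
        fn = _CUSTOM_LAWS[rx.law]
        return fn(rx, c[..., r_idx], c[..., p_idx], c[..., s_idx])

    def rates(self, concentrations):
        """Net concentration derivative, one entry per species.

        ``concentrations`` has species on the last axis; negative values
        are rejected (the integrators guard against them by clipping).
        """
        c = np.asarray(concentrations, dtype=float)
        if c.shape[-1] != self.n_species:
            raise ValueError(
                f"expected {self.n_species} species, got {c.shape[-1]}")
        if np.any(c < 0):
            raise ValueError("negative concentration passed to rate evaluation")
        dcdt = np.zeros_like(c)
        for rx, nu, r_idx, r_pow, p_idx, p_pow, s_idx in self._terms:
            rate = self._reaction_rate(rx, c, r_idx, r_pow, p_idx, p_pow,
                                       s_idx)
            dcdt += np.multiply.outer(rate, nu) if c.ndim > 1 else rate * nu
        return dcdt


def evaluate_rates(system: ReactionSystem, concentrations) -> np.ndarray:
    """Functional alias for :meth:`ReactionSystem.rates`."""
    return system.rates(concentrations)


def rk4_step(f, y, dt):
    """One classical Runge-Kutta step with a non-negativity guard.

    Stage states are clipped at zero before rate evaluation so explicit
    stepping of stiff kinetics never feeds negative concentrations to the
    rate laws; the final state is clipped the same way.
    """
    k1 = f(np.clip(y, 0.0, None))
    k2 = f(np.clip(y + 0.5 * dt * k1, 0.0, None))
    k3 = f(np.clip(y + 0.5 * dt * k2, 0.0, None))
    k4 = f(np.clip(y + dt * k3, 0.0, None))
    return np.clip(y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)


def integrate_well_mixed(system: ReactionSystem, initial, t_end, dt,
                         sampling_interval=None):
    """Integrate the pure (no-diffusion) reaction ODEs with fixed-step RK4.

    Returns ``(times, values)`` where ``values[i]`` is the concentration
    vector at ``times[i]``.  Samples are taken every ``sampling_interval``
    (default: every step).  Raises :class:`SolverFailure` with the failure
    time if the state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < dt:
        raise ValueError("t_end must be at least dt")
    y = np.asarray(initial, dtype=float).copy()
    if y.shape[-1] != system.n_species:
        raise ValueError("initial state has wrong species count")
    n_steps = int(round(t_end / dt))
    stride = 1 if sampling_interval is None else max(
        1, int(round(sampling_interval / dt)))
    times = [0.0]
    values = [y.copy()]
    f = system.rates
    for step in range(1, n_steps + 1):
        y = rk4_step(f, y, dt)
        if not np.all(np.isfinite(y)):
            raise SolverFailure(
                f"non-finite concentrations at t = {step * dt:g}",
                time=step * dt)
        if step % stride == 0 or step == n_steps:
            times.append(step * dt)
            values.append(y.copy())
    return np.array(times), np.array(values)
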