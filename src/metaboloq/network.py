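"""Generalized mass-action reaction networks.

A *generalized* mass-action reaction decouples its kinetic rate law from its
net stoichiometry: the rate is a rate constant times a product of species
amounts (the *rate factors*), while the net change of each species is given
by a separate signed-integer stoichiometry map.  A species may therefore
enter a reaction's kinetics without being consumed or produced by it
(a purely catalytic / regulatory dependency), and vice versa.  Ordinary
mass-action networks are the special case where the factor multiset equals
the reactant multiset.

The module provides the network container, rate and derivative evaluation,
the stoichiometry matrix, exact (rational-arithmetic) conservation-law
detection, and a symbolic rendering of the ODE system, one term per
reaction instance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy

__all__ = [
    "NEGATIVE_STATE_TOL",
    "NetworkError",
    "ValidationError",
    "UnknownIdError",
    "StateDomainError",
    "SpeciesDef",
    "ParameterDef",
    "GeneralizedReaction",
    "ReactionNetwork",
    "SymbolicODE",
    "make_network",
    "reaction_rate",
    "rate_vector",
    "derivative",
    "stoichiometry_matrix",
    "conservation_laws",
    "symbolic_odes",
]

#: States in [NEGATIVE_STATE_TOL, 0) are treated as integrator round-off and
#: clamped to zero before rate evaluation; anything below is a hard error.
NEGATIVE_STATE_TOL = -1e-9


class NetworkError(Exception):
    """Base class for reaction-network errors."""


class ValidationError(NetworkError):
    """A definition violates a structural invariant (e.g. duplicate id)."""


class UnknownIdError(NetworkError):
    """A reaction references a species or parameter that does not exist."""


class StateDomainError(NetworkError):
    """A state vector entry is negative beyond the round-off tolerance."""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: short symbol, human-readable name, initial amount (a.u.)."""

    id: str
    name: str
    initial: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if not math.isfinite(self.initial) or self.initial < 0:
            raise ValidationError(
                f"species {self.id!r}: initial amount must be finite and >= 0, "
                f"got {self.initial}"
            )


@dataclass(frozen=True)
class ParameterDef:
    """A kinetic rate constant (a.u. per time, non-negative)."""

    id: str
    value: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("parameter id must be non-empty")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"parameter {self.id!r}: value must be finite and >= 0, "
                f"got {self.value}"
            )


@dataclass(frozen=True)
class GeneralizedReaction:
    """One reaction: rate = k * prod(amount ** exponent) over the rate factors.

    ``rate_factors`` is the kinetic dependency list (species id, positive
    integer exponent); ``stoichiometry`` maps species id to its signed net
    change.  The two sets of species need not coincide.
    """

    id: str
    rate_constant: str
    rate_factors: tuple[tuple[str, int], ...]
    stoichiometry: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rate_factors", tuple(
            (str(s), int(e)) for s, e in self.rate_factors
        ))
        if not self.rate_factors:
            raise ValidationError(f"reaction {self.id!r}: rate_factors must be non-empty")
        for sp, exp in self.rate_factors:
            if exp < 1:
                raise ValidationError(
                    f"reaction {self.id!r}: exponent for {sp!r} must be a positive "
                    f"integer, got {exp}"
                )
        for sp, change in self.stoichiometry.items():
            if int(change) != change or change == 0:
                raise ValidationError(
                    f"reaction {self.id!r}: stoichiometry for {sp!r} must be a "
                    f"nonzero integer, got {change}"
                )

    def __eq__(self, other):
        if not isinstance(other, GeneralizedReaction):
            return NotImplemented
        return (
            self.id == other.id
            and self.rate_constant == other.rate_constant
            and self.rate_factors == other.rate_factors
            and self.stoichiometry == other.stoichiometry
        )

    __hash__ = None


@dataclass
class ReactionNetwork:
    """Species, parameters and reactions; list orders fix matrix row/column order."""

    species: tuple[SpeciesDef, ...]
    parameters: tuple[ParameterDef, ...]
    reactions: tuple[GeneralizedReaction, ...]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.parameters = tuple(self.parameters)
        self.reactions = tuple(self.reactions)
        self._species_index = {s.id: i for i, s in enumerate(self.species)}
        self._param_value = {p.id: p.value for p in self.parameters}

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, species_id: str) -> int:
        try:
            return self._species_index[species_id]
        except KeyError:
            raise UnknownIdError(f"unknown species id {species_id!r}") from None

    def parameter_value(self, parameter_id: str) -> float:
        try:
            return self._param_value[parameter_id]
        except KeyError:
            raise UnknownIdError(f"unknown parameter id {parameter_id!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    # -- copy-with-changes (used by scenarios and fitting) ------------------
    def with_updates(
        self,
        species_initials: dict[str, float] | None = None,
        parameter_values: dict[str, float] | None = None,
    ) -> "ReactionNetwork":
        """Return a new network with some initial amounts / rate constants replaced.

        The original network is never mutated.  Unknown ids raise
        :class:`UnknownIdError`.
        """
        species_initials = dict(species_initials or {})
        parameter_values = dict(parameter_values or {})
        for sid in species_initials:
            if sid not in self._species_index:
                raise UnknownIdError(f"unknown species id {sid!r}")
        for pid in parameter_values:
            if pid not in self._param_value:
                raise UnknownIdError(f"unknown parameter id {pid!r}")
        new_species = tuple(
            SpeciesDef(s.id, s.name, species_initials.get(s.id, s.initial))
            for s in self.species
        )
        new_params = tuple(
            ParameterDef(p.id, parameter_values.get(p.id, p.value))
            for p in self.parameters
        )
        return ReactionNetwork(new_species, new_params, self.reactions)

    def __eq__(self, other):
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.parameters == other.parameters
            and self.reactions == other.reactions
        )


@dataclass(frozen=True)
class SymbolicODE:
    """dx/dt for one species as a signed sum of reaction-rate terms.

    ``terms`` is a tuple of (sign, reaction id) pairs, ordered by position
    of the reaction in the network, then sign.  A stoichiometric coefficient
    of magnitude m is represented by m repeated terms.
    """

    species_id: str
    terms: tuple[tuple[int, str], ...]

    def render(self, network: "ReactionNetwork | None" = None) -> str:
        """Human-readable equation, expanding rate laws when a network is given."""
        if not self.terms:
            return f"d{self.species_id}/dt = 0"
        by_id = {r.id: r for r in network.reactions} if network is not None else {}
        parts = []
        for sign, rid in self.terms:
            if rid in by_id:
                r = by_id[rid]
                factors = "*".join(
                    sp if e == 1 else f"{sp}**{e}" for sp, e in r.rate_factors
                )
                body = f"{r.rate_constant}*{factors}"
            else:
                body = rid
            parts.append(("+ " if sign > 0 else "- ") + body)
        rhs = " ".join(parts)
        if rhs.startswith("+ "):
            rhs = rhs[2:]
        return f"d{self.species_id}/dt = {rhs}"


def make_network(
    species: list[SpeciesDef],
    parameters: list[ParameterDef],
    reactions: list[GeneralizedReaction],
) -> ReactionNetwork:
    """Validate cross-references and assemble a :class:`ReactionNetwork`.

    Raises
    ------
    ValidationError
        On duplicate species/parameter/reaction ids or an empty network.
    UnknownIdError
        When a reaction references a species or parameter not in the lists.
    """
    if not species:
        raise ValidationError("network needs at least one species")
    if not reactions:
        raise ValidationError("network needs at least one reaction")
    for kind, ids in (
        ("species", [s.id for s in species]),
        ("parameter", [p.id for p in parameters]),
        ("reaction", [r.id for r in reactions]),
    ):
        seen = set()
        for i in ids:
            if i in seen:
                raise ValidationError(f"duplicate {kind} id {i!r}")
            seen.add(i)
    species_ids = {s.id for s in species}
    param_ids = {p.id for p in parameters}
    for r in reactions:
        if r.rate_constant not in param_ids:
            raise UnknownIdError(
                f"reaction {r.id!r} references unknown parameter {r.rate_constant!r}"
            )
        for sp, _ in r.rate_factors:
            if sp not in species_ids:
                raise UnknownIdError(
                    f"reaction {r.id!r} rate law references unknown species {sp!r}"
                )
        for sp in r.stoichiometry:
            if sp not in species_ids:
                raise UnknownIdError(
                    f"reaction {r.id!r} stoichiometry references unknown species {sp!r}"
                )
    return ReactionNetwork(tuple(species), tuple(parameters), tuple(reactions))


def _clean_state(network: ReactionNetwork, state) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValidationError(
            f"state vector has shape {state.shape}, expected ({network.n_species},)"
        )
    low = state.min() if state.size else 0.0
    if low < NEGATIVE_STATE_TOL:
        idx = int(np.argmin(state))
        raise StateDomainError(
            f"state entry {network.species_ids[idx]!r} = {state[idx]} is negative "
            f"beyond tolerance {NEGATIVE_STATE_TOL}"
        )
    return np.clip(state, 0.0, None)


def reaction_rate(
    network: ReactionNetwork,
    reaction: GeneralizedReaction | str,
    state,
    parameters: dict[str, float] | None = None,
) -> float:
    """Flux of one reaction at a state: k * prod(amount ** exponent).

    ``parameters`` optionally overrides rate-constant values without
    rebuilding the network.  Entries of the state in ``[-1e-9, 0)`` are
    clamped to zero (integrator round-off); lower values raise
    :class:`StateDomainError`.
    """
    if isinstance(reaction, str):
        matches = [r for r in network.reactions if r.id == reaction]
        if not matches:
            raise UnknownIdError(f"unknown reaction id {reaction!r}")
        reaction = matches[0]
    state = _clean_state(network, state)
    k = (parameters or {}).get(
        reaction.rate_constant, network.parameter_value(reaction.rate_constant)
    )
    flux = float(k)
    for sp, exp in reaction.rate_factors:
        flux *= state[network.species_index(sp)] ** exp
    return flux


def rate_vector(
    network: ReactionNetwork,
    state,
    parameters: dict[str, float] | None = None,
) -> np.ndarray:
    """All reaction fluxes at a state, in network reaction order."""
    return np.array(
        [reaction_rate(network, r, state, parameters) for r in network.reactions]
    )


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Signed integer matrix S with S[i, j] = net change of species i in reaction j."""
    S = np.zeros((network.n_species, network.n_reactions), dtype=int)
    for j, r in enumerate(network.reactions):
        for sp, change in r.stoichiometry.items():
            S[network.species_index(sp), j] = change
    return S


def derivative(
    network: ReactionNetwork,
    state,
    parameters: dict[str, float] | None = None,
) -> np.ndarray:
    """Time derivative of the state: S @ rate_vector."""
    return stoichiometry_matrix(network) @ rate_vector(network, state, parameters)


def conservation_laws(network: ReactionNetwork) -> list[np.ndarray]:
    """Integer basis of the left null space of the stoichiometry matrix.

    Each returned vector v satisfies v @ S == 0 exactly, so v . state(t) is
    constant along every trajectory (a conserved pool).  Computation is in
    exact rational arithmetic; each basis vector is scaled to the smallest
    integer form with its first nonzero entry positive.  Returns an empty
    list when rank(S) equals the number of species.
    """
    S = sympy.Matrix(stoichiometry_matrix(network).tolist())
    basis = S.T.nullspace()
    out = []
    for v in basis:
        fracs = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q) for x in v]
        lcm = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [int(f * lcm) for f in fracs]
        g = math.gcd(*(abs(i) for i in ints if i != 0))
        ints = [i // g for i in ints]
        first = next((i for i in ints if i != 0), 1)
        if first < 0:
            ints = [-i for i in ints]
        out.append(np.array(ints, dtype=int))
    return out


def symbolic_odes(network: ReactionNetwork) -> list[SymbolicODE]:
    """One signed-term equation per species, reaction instances kept distinct.

    Two reactions with identical rate laws contribute separate terms; they
    are never collapsed into a single term with a numeric coefficient.
    """
    out = []
    for s in network.species:
        terms: list[tuple[int, int, str]] = []
        for j, r in enumerate(network.reactions):
            change = r.stoichiometry.get(s.id, 0)
            if change == 0:
                continue
            sign = 1 if change > 0 else -1
            for _ in range(abs(change)):
                terms.append((j, sign, r.id))
        terms.sort(key=lambda t: (t[0], t[1]))
        out.append(SymbolicODE(s.id, tuple((sign, rid) for _, sign, rid in terms)))
    return out
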