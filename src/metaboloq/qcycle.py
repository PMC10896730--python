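"""The canonical ETFDH-assisted complex III Q-cycle network.

Fourteen state variables track the redox species of a dimeric complex III
(CIII) turning over the Q cycle with help from the electron-transfer
flavoprotein dehydrogenase (ETFDH):

======  =====================  ========================================
symbol  name                   role
======  =====================  ========================================
x1      QH2                    ubiquinol (membrane pool)
x2      Cytc_ox                oxidized cytochrome c
x3      e-                     electron budget (multiplies every rate)
x4      QHdot_CIII_Qo          semiquinone at the CIII Qo site
x5      Cytc_red               reduced cytochrome c (primary observable)
x6      Hplus_P                protons released to the positive side
x7      Q                      ubiquinone (membrane pool)
x8      Hplus_N                protons taken up from the negative side
x9      ETFDH_FADH2            fully reduced ETFDH flavin
x10     ETFDH_FADH             half-reduced ETFDH flavin
x11     ETFDH_FAD              oxidized ETFDH flavin
x12     QHdot_CIII_Qi_1        Qi-site semiquinone after monomer step 1
x13     QHdot_CIII_Qi_2        Qi-site semiquinone after monomer step 2
x14     QHdot_ETFDH            semiquinone bound to ETFDH
======  =====================  ========================================

Seven generalized mass-action reactions drive the system.  r1/r3 are the
two monomer Qo oxidations (identical rate laws, kept as distinct reaction
instances), r2/r4 the two Qi reductions, r5/r6 the ETFDH-assisted
semiquinone reductions and r7 the unassisted (CIII-autonomous) Qi
disproportionation that regenerates QH2.  The ETFDH level is encoded by
the initial amount of x9: 1 for wild type, 0.5 for the heterozygote, 0
for the knockout.

Rate constants k6 and k7 belong to the canonical parameter table but are
referenced by no reaction; they are stored for fidelity and never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import (
    GeneralizedReaction,
    ParameterDef,
    ReactionNetwork,
    SpeciesDef,
    UnknownIdError,
    ValidationError,
    make_network,
)

__all__ = [
    "CANONICAL_SPECIES",
    "CANONICAL_PARAMETERS",
    "SCENARIO_LEVELS",
    "QCycleScenario",
    "build_canonical_network",
    "apply_scenario",
]

#: (id, name, initial amount) for the canonical network, in state order.
CANONICAL_SPECIES: tuple[tuple[str, str, float], ...] = (
    ("x1", "QH2", 0.6),
    ("x2", "Cytc_ox", 1.1),
    ("x3", "e-", 4.6),
    ("x4", "QHdot_CIII_Qo", 0.0),
    ("x5", "Cytc_red", 0.0),
    ("x6", "Hplus_P", 0.0),
    ("x7", "Q", 0.5),
    ("x8", "Hplus_N", 0.5),
    ("x9", "ETFDH_FADH2", 1.0),
    ("x10", "ETFDH_FADH", 0.0),
    ("x11", "ETFDH_FAD", 0.0),
    ("x12", "QHdot_CIII_Qi_1", 0.0),
    ("x13", "QHdot_CIII_Qi_2", 0.0),
    ("x14", "QHdot_ETFDH", 0.0),
)

#: Canonical rate constants; k6 and k7 appear in no rate law.
CANONICAL_PARAMETERS: tuple[tuple[str, float], ...] = (
    ("k1", 5.0),
    ("k2", 5.0),
    ("k3", 5.0),
    ("k4", 5.0),
    ("k5", 20.0),
    ("k6", 21.0),
    ("k7", 21.0),
)

_CANONICAL_REACTIONS: tuple[dict, ...] = (
    dict(id="r1", k="k1", factors=(("x1", 1), ("x2", 1), ("x3", 1)),
         stoich={"x1": -1, "x2": -1, "x3": -1, "x4": 1, "x5": 1, "x6": 1}),
    dict(id="r2", k="k2", factors=(("x3", 1), ("x4", 1), ("x7", 1), ("x8", 1)),
         stoich={"x3": -1, "x4": -1, "x6": 1, "x8": -1, "x12": 1}),
    dict(id="r3", k="k1", factors=(("x1", 1), ("x2", 1), ("x3", 1)),
         stoich={"x1": -1, "x2": -1, "x3": -1, "x4": 1, "x5": 1, "x6": 1}),
    dict(id="r4", k="k2", factors=(("x3", 1), ("x4", 1), ("x7", 1), ("x8", 1)),
         stoich={"x3": -1, "x4": -1, "x6": 1, "x8": -1, "x13": 1}),
    dict(id="r5", k="k3", factors=(("x3", 1), ("x9", 1), ("x12", 1)),
         stoich={"x3": -1, "x8": 1, "x9": -1, "x10": 1, "x12": -1, "x14": 1}),
    dict(id="r6", k="k4", factors=(("x3", 1), ("x10", 1), ("x13", 1), ("x14", 1)),
         stoich={"x1": 1, "x3": -1, "x7": 1, "x8": 1, "x10": -1, "x11": 1,
                 "x13": -1, "x14": -1}),
    dict(id="r7", k="k5", factors=(("x3", 1), ("x12", 1), ("x13", 1)),
         stoich={"x1": 1, "x3": -1, "x7": 1, "x12": -1, "x13": -1}),
)

#: ETFDH levels implied by the genotype labels.
SCENARIO_LEVELS = {"wt": 1.0, "het": 0.5, "ko": 0.0}


def build_canonical_network() -> ReactionNetwork:
    """The 14-species / 7-reaction ETFDH Q-cycle network with printed constants.

    Deterministic and side-effect free; two calls compare equal.  The default
    ETFDH level is the wild type (x9(0) = 1).
    """
    species = [SpeciesDef(i, n, v) for i, n, v in CANONICAL_SPECIES]
    params = [ParameterDef(i, v) for i, v in CANONICAL_PARAMETERS]
    reactions = [
        GeneralizedReaction(d["id"], d["k"], d["factors"], dict(d["stoich"]))
        for d in _CANONICAL_REACTIONS
    ]
    return make_network(species, params, reactions)


@dataclass(frozen=True)
class QCycleScenario:
    """An ETFDH genotype/level plus optional overrides of initials or constants.

    ``overrides`` maps species ids (initial amounts) or parameter ids (rate
    constants) to replacement values; species win on an id clash (none occur
    in the canonical network).
    """

    label: str
    etfdh_level: float
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.etfdh_level < 0:
            raise ValidationError(f"etfdh_level must be >= 0, got {self.etfdh_level}")
        if self.label in SCENARIO_LEVELS and self.etfdh_level != SCENARIO_LEVELS[self.label]:
            raise ValidationError(
                f"label {self.label!r} implies etfdh_level "
                f"{SCENARIO_LEVELS[self.label]}, got {self.etfdh_level}"
            )

    @classmethod
    def from_label(cls, label: str, overrides: dict[str, float] | None = None):
        if label not in SCENARIO_LEVELS:
            raise ValidationError(
                f"unknown scenario label {label!r}; expected one of "
                f"{sorted(SCENARIO_LEVELS)}"
            )
        return cls(label, SCENARIO_LEVELS[label], dict(overrides or {}))

    @classmethod
    def from_level(cls, level: float, overrides: dict[str, float] | None = None):
        for lbl, lvl in SCENARIO_LEVELS.items():
            if level == lvl:
                return cls(lbl, lvl, dict(overrides or {}))
        return cls("custom", level, dict(overrides or {}))

    @classmethod
    def wt(cls):
        return cls.from_label("wt")

    @classmethod
    def het(cls):
        return cls.from_label("het")

    @classmethod
    def ko(cls):
        return cls.from_label("ko")


def apply_scenario(network: ReactionNetwork, scenario: QCycleScenario) -> ReactionNetwork:
    """Copy of the network with x9(0) = etfdh_level and overrides applied.

    The input network is untouched.  Unknown override ids raise
    :class:`UnknownIdError`.
    """
    species_ids = set(network.species_ids)
    if "x9" not in species_ids:
        raise UnknownIdError("network has no species 'x9' to carry the ETFDH level")
    species_over = {"x9": float(scenario.etfdh_level)}
    param_over: dict[str, float] = {}
    param_ids = {p.id for p in network.parameters}
    for key, val in scenario.overrides.items():
        if key in species_ids:
            species_over[key] = float(val)
        elif key in param_ids:
            param_over[key] = float(val)
        else:
            raise UnknownIdError(
                f"override target {key!r} is neither a species nor a parameter"
            )
    return network.with_updates(species_over, param_over)
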