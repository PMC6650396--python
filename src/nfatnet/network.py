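"""Reaction-network domain types.

A :class:`NetworkModel` is a list of species and reactions with typed kinetic
laws (mass action, Michaelis-Menten, Hill), plus annotated feedback links.
Reactions reference kinetic constants *by name*; numeric values live in a
separate :class:`~nfatnet.parameters.ParameterSet`, so a single network can be
simulated under fitted, sampled or perturbed parameterizations.

Conventions
-----------
* concentrations in nM, time in minutes, rate constants in the units implied
  by their prefix (``ka`` nM^-1 min^-1, ``kd``/``kc`` min^-1, ``V``
  nM min^-1, ``Km``/``Ka`` nM, ``kI`` nM^-1, ``kdeg`` min^-1).
* reversible binding is written as two irreversible reactions (forward and
  backward), which keeps every rate expression non-negative.
* the externally driven MHC stimulus enters as a dimensionless multiplier
  ``u(t)`` on reactions flagged ``driven_by_input``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence


class SpeciesRole(str, Enum):
    SIGNALLING = "signalling"
    TRANSCRIPT = "transcript"
    COMPLEX = "complex"
    INPUT = "input"


class LawForm(str, Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    HILL = "hill"


class FeedbackSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


#: the canonical feedback-link labels of the full network, with their signs
#: (direction of net effect on nuclear NFAT).
CANONICAL_LINKS: dict[str, FeedbackSign] = {
    "NFAT/NFAT": FeedbackSign.POSITIVE,
    "pRCAN/CN": FeedbackSign.POSITIVE,
    "RCAN/CN": FeedbackSign.NEGATIVE,
    "Carabin/CN": FeedbackSign.NEGATIVE,
    "Carabin/Ras": FeedbackSign.NEGATIVE,
    "CTLA4/TCR": FeedbackSign.NEGATIVE,
    "CTLA4/PP2A": FeedbackSign.NEGATIVE,
    "TNFa/TAK1": FeedbackSign.POSITIVE,
    "PI3K/Akt": FeedbackSign.POSITIVE,
    "Akt/GSK3": FeedbackSign.POSITIVE,
    "PI3K/Rac1": FeedbackSign.POSITIVE,
}


class NetworkError(ValueError):
    """Raised for structurally invalid models or unknown lookups."""


@dataclass(frozen=True)
class Species:
    name: str
    role: SpeciesRole = SpeciesRole.SIGNALLING
    initial_value: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_value < 0:
            raise NetworkError(f"initial value of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class KineticLaw:
    """A typed rate law referencing parameters by name.

    ``params`` maps a role within the law to a parameter name:

    * mass_action: ``k`` (zeroth order if the reaction has no substrates)
    * michaelis_menten: ``kc`` + ``Km`` (with an enzyme modifier) or
      ``Vmax`` + ``Km``
    * hill: ``Vmax``, ``Km`` and a structural exponent ``n`` (a number, not a
      fitted parameter); optional additive ``basal`` synthesis parameter
    """

    form: LawForm
    params: Mapping[str, str]
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        required = {
            LawForm.MASS_ACTION: {"k"},
            LawForm.MICHAELIS_MENTEN: {"Km"},
            LawForm.HILL: {"Vmax", "Km"},
        }[self.form]
        missing = required - set(self.params)
        if missing:
            raise NetworkError(f"{self.form.value} law missing {sorted(missing)}")
        if self.form is LawForm.MICHAELIS_MENTEN and not (
            "kc" in self.params or "Vmax" in self.params
        ):
            raise NetworkError("michaelis_menten law needs kc (with enzyme) or Vmax")
        if self.hill_n < 1:
            raise NetworkError("hill exponent must be >= 1")


@dataclass(frozen=True)
class Reaction:
    """One reaction with stoichiometry, modifiers and a kinetic law.

    ``rid`` mirrors the source numbering of the full network where one is
    stated; auxiliary reactions use free identifiers.
    """

    rid: str
    law: KineticLaw
    substrates: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    enzyme: str | None = None
    #: transcription-factor style regulator for Hill laws
    regulator: str | None = None
    #: saturating activators: (species, Ka parameter name) -> * S/(Ka+S)
    activators: tuple[tuple[str, str], ...] = ()
    #: hyperbolic enhancers: (species, Ka parameter name) -> * (1 + S/Ka)
    enhancers: tuple[tuple[str, str], ...] = ()
    #: hyperbolic inhibitors: (species, kI parameter name) -> / (1 + kI*I)
    inhibitors: tuple[tuple[str, str], ...] = ()
    driven_by_input: bool = False

    def __post_init__(self) -> None:
        for _, stoich in self.substrates + self.products:
            if int(stoich) != stoich or stoich <= 0:
                raise NetworkError(f"reaction {self.rid}: stoichiometry must be a positive integer")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = list(self.law.params.values())
        names += [p for _, p in self.activators]
        names += [p for _, p in self.enhancers]
        names += [p for _, p in self.inhibitors]
        return tuple(names)

    def species_names(self) -> set[str]:
        names = {s for s, _ in self.substrates} | {s for s, _ in self.products}
        names |= {s for s, _ in self.activators} | {s for s, _ in self.enhancers}
        names |= {s for s, _ in self.inhibitors}
        if self.enzyme:
            names.add(self.enzyme)
        if self.regulator:
            names.add(self.regulator)
        return names


@dataclass(frozen=True)
class FeedbackLink:
    name: str
    sign: FeedbackSign
    controlled_parameters: frozenset[str]

    def __post_init__(self) -> None:
        if not self.controlled_parameters:
            raise NetworkError(f"link {self.name}: controlled_parameters must be non-empty")


@dataclass
class NetworkModel:
    """Species + reactions + feedback annotation; the object every analysis consumes."""

    name: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    feedback_links: tuple[FeedbackLink, ...] = ()
    inputs: tuple[str, ...] = ("MHC",)
    #: moieties conserved by the stoichiometry once synthesis/decay reactions
    #: are disabled; mapping total-name -> member species
    conserved_moieties: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkError("species names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        known = set(names)
        for rxn in self.reactions:
            unknown = rxn.species_names() - known
            if unknown:
                raise NetworkError(f"reaction {rxn.rid} references unknown species {sorted(unknown)}")
        rids = [r.rid for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("reaction ids must be unique")
        seen: set[str] = set()
        for link in self.feedback_links:
            overlap = seen & link.controlled_parameters
            if overlap:
                raise NetworkError(f"link {link.name}: parameters {sorted(overlap)} already controlled")
            seen |= link.controlled_parameters

    # -- lookups ---------------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown species {name!r}") from None

    @property
    def parameter_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for p in rxn.parameter_names:
                seen.setdefault(p)
        return tuple(seen)

    def link(self, name: str) -> FeedbackLink:
        for l in self.feedback_links:
            if l.name == name:
                return l
        raise NetworkError(f"unknown feedback link {name!r}")

    def initial_state(self) -> "np.ndarray":  # noqa: F821 - numpy imported lazily
        import numpy as np

        return np.array([s.initial_value for s in self.species], dtype=float)

    def without_reactions(self, rids: Sequence[str]) -> "NetworkModel":
        """A copy with the given reactions deleted entirely (factor-0 semantics)."""
        drop = set(rids)
        unknown = drop - {r.rid for r in self.reactions}
        if unknown:
            raise NetworkError(f"unknown reaction ids {sorted(unknown)}")
        kept = tuple(r for r in self.reactions if r.rid not in drop)
        kept_params = {p for r in kept for p in r.parameter_names}
        links = tuple(
            l for l in self.feedback_links if l.controlled_parameters & kept_params
        )
        return replace(self, reactions=kept, feedback_links=links)


def evaluate_rate(
    reaction: Reaction,
    state: Mapping[str, float],
    params: Mapping[str, float],
    input_value: float = 1.0,
) -> float:
    """Evaluate one reaction rate (nM min^-1) at a concentration map.

    Mirrors exactly the expression the compiled right-hand side uses; kept as
    a slow reference path for tests and SBML export.
    """

    def conc(name: str) -> float:
        v = state[name]
        if v < 0:
            raise ValueError(f"negative concentration for {name!r}")
        return v

    def par(role: str) -> float:
        pname = reaction.law.params[role]
        try:
            return params[pname]
        except KeyError:
            raise KeyError(f"missing parameter {pname!r} for reaction {reaction.rid}") from None

    law = reaction.law
    if law.form is LawForm.MASS_ACTION:
        rate = par("k")
        for s, stoich in reaction.substrates:
            rate *= conc(s) ** stoich
    elif law.form is LawForm.MICHAELIS_MENTEN:
        (sub, _), = reaction.substrates
        s = conc(sub)
        vmax = par("kc") * conc(reaction.enzyme) if "kc" in law.params else par("Vmax")
        rate = vmax * s / (par("Km") + s)
    else:  # HILL
        s = conc(reaction.regulator)
        n = law.hill_n
        rate = par("Vmax") * s**n / (par("Km") ** n + s**n)
        if "basal" in law.params:
            rate += par("basal")
    for sp, kname in reaction.activators:
        a = conc(sp)
        rate *= a / (params[kname] + a)
    for sp, kname in reaction.enhancers:
        rate *= 1.0 + conc(sp) / params[kname]
    for sp, kname in reaction.inhibitors:
        rate /= 1.0 + params[kname] * conc(sp)
    if reaction.driven_by_input:
        rate *= input_value
    return rate


def apply_link_perturbation(
    model: NetworkModel, link: FeedbackLink | str, factor: float, params=None
):
    """Scale a feedback link's controlled parameters by ``factor``.

    Returns a new :class:`~nfatnet.parameters.ParameterSet` (the model itself
    is untouched: link strength is a property of the parameterization).
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be > 0 (use reduced-model removal for 0)")
    if isinstance(link, str):
        link = model.link(link)
    elif link not in model.feedback_links:
        raise NetworkError(f"link {link.name!r} not part of model {model.name!r}")
    if params is None:
        raise ValueError("a ParameterSet is required")
    return params.scaled({p: factor for p in link.controlled_parameters})
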