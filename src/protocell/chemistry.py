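"""Artificial polymer chemistries: species, reactions, catalysis.

A "chemistry" is one artificial world in the Kauffman sense: molecular
species are ordered strings over a small monomer alphabet, and the only
allowed reactions are catalyzed cleavages (cut a polymer at some position)
and catalyzed condensations (concatenate two polymers, via a transient
catalyst-substrate complex).  Catalysts are drawn at random among species
of length >= 3; no spontaneous or backward reactions exist.

The chemistry also carries the container-facing information: which species
are food (buffered in the external environment), the permeability cutoff
``L_perm`` (species shorter than ``L_perm`` cross the membrane), the
per-species lipid-production coefficients ``k_cont`` and, for finite
diffusion (Fick) mode, the transport coefficients ``diffusion_D``.
"""

from __future__ import annotations

import itertools
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "KineticParams",
    "Chemistry",
    "MIN_CATALYST_LENGTH",
    "enumerate_reactions",
    "assign_catalysis",
    "assign_container_coupling",
    "validate",
]

#: species shorter than this many monomers can never be catalysts
MIN_CATALYST_LENGTH = 3


@dataclass(frozen=True)
class KineticParams:
    """Mass-action rate constants, in simulation units.

    ``k_cleav`` (cleavage) and ``k_assoc`` (complex formation) and
    ``k_cond`` (final condensation) are second-order
    (volume / molecule / time); ``k_diss`` (complex dissociation) is
    first-order (1 / time).
    """

    k_cleav: float = 1.0
    k_assoc: float = 1.0
    k_diss: float = 0.1
    k_cond: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_cleav", "k_assoc", "k_diss", "k_cond"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "k_cleav": self.k_cleav,
            "k_assoc": self.k_assoc,
            "k_diss": self.k_diss,
            "k_cond": self.k_cond,
        }


@dataclass
class Species:
    sequence: str
    is_food: bool = False
    external_concentration: float = 0.0
    k_cont: float = 0.0
    diffusion_D: float = 0.0
    initial_count: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def can_catalyze(self) -> bool:
        return self.length >= MIN_CATALYST_LENGTH

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "is_food": self.is_food,
            "external_concentration": self.external_concentration,
            "k_cont": self.k_cont,
            "diffusion_D": self.diffusion_D,
            "initial_count": self.initial_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Species":
        return cls(
            sequence=d["sequence"],
            is_food=bool(d.get("is_food", False)),
            external_concentration=float(d.get("external_concentration", 0.0)),
            k_cont=float(d.get("k_cont", 0.0)),
            diffusion_D=float(d.get("diffusion_D", 0.0)),
            initial_count=int(d.get("initial_count", 0)),
        )


@dataclass
class Reaction:
    """A catalyzed cleavage or condensation.

    Substrates/products/catalysts are species *sequences* (strings); the
    owning :class:`Chemistry` resolves them.  Condensation proceeds through
    a transient complex between ``substrates[complex_substrate_index]`` and
    the catalyst; for graph/RAF analyses the three elementary steps count
    as a single reaction node.
    """

    kind: str  # "cleavage" | "condensation"
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    cut_position: int | None = None  # cleavage only
    complex_substrate_index: int = 0  # condensation only
    catalysts: frozenset[str] = field(default_factory=frozenset)
    params: KineticParams | None = None  # per-reaction override

    def __post_init__(self) -> None:
        self.substrates = tuple(self.substrates)
        self.products = tuple(self.products)
        self.catalysts = frozenset(self.catalysts)
        if self.kind not in ("cleavage", "condensation"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.kind == "cleavage":
            if len(self.substrates) != 1 or len(self.products) != 2:
                raise ValueError("cleavage needs 1 substrate, 2 products")
        else:
            if len(self.substrates) != 2 or len(self.products) != 1:
                raise ValueError("condensation needs 2 substrates, 1 product")
            if self.complex_substrate_index not in (0, 1):
                raise ValueError("complex_substrate_index must be 0 or 1")

    @property
    def key(self) -> tuple:
        """Identity of the reaction, independent of catalyst assignment."""
        return (self.kind, self.substrates, self.products, self.cut_position)

    def __str__(self) -> str:
        lhs = " + ".join(self.substrates)
        rhs = " + ".join(self.products)
        cats = ",".join(sorted(self.catalysts)) or "-"
        return f"{lhs} -> {rhs} [{cats}]"

    def effective_params(self, defaults: KineticParams) -> KineticParams:
        return self.params if self.params is not None else defaults

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "substrates": list(self.substrates),
            "products": list(self.products),
            "catalysts": sorted(self.catalysts),
        }
        if self.cut_position is not None:
            d["cut_position"] = self.cut_position
        if self.kind == "condensation":
            d["complex_substrate_index"] = self.complex_substrate_index
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        params = KineticParams(**d["params"]) if "params" in d else None
        return cls(
            kind=d["kind"],
            substrates=tuple(d["substrates"]),
            products=tuple(d["products"]),
            cut_position=d.get("cut_position"),
            complex_substrate_index=int(d.get("complex_substrate_index", 0)),
            catalysts=frozenset(d.get("catalysts", ())),
            params=params,
        )


@dataclass
class Chemistry:
    alphabet: tuple[str, ...]
    L_max: int
    L_perm: int
    species: dict[str, Species] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    kinetic_defaults: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)

    # -- convenience views ------------------------------------------------
    @property
    def food(self) -> list[str]:
        return [s.sequence for s in self.species.values() if s.is_food]

    def is_permeable(self, seq: str) -> bool:
        """Species shorter than L_perm cross the membrane."""
        return len(seq) < self.L_perm

    def add_species(self, sp: Species) -> Species:
        existing = self.species.get(sp.sequence)
        if existing is not None:
            return existing
        self.species[sp.sequence] = sp
        return sp

    def ensure_species(self, seq: str) -> Species:
        return self.add_species(Species(seq))

    def catalyzed_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.catalysts]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet),
            "L_max": self.L_max,
            "L_perm": self.L_perm,
            "kinetic_defaults": self.kinetic_defaults.to_dict(),
            "species": [s.to_dict() for s in self.species.values()],
            "reactions": [r.to_dict() for r in self.reactions],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Chemistry":
        chem = cls(
            alphabet=tuple(d["alphabet"]),
            L_max=int(d["L_max"]),
            L_perm=int(d["L_perm"]),
            kinetic_defaults=KineticParams(**d.get("kinetic_defaults", {})),
        )
        for sd in d.get("species", ()):
            chem.add_species(Species.from_dict(sd))
        for rd in d.get("reactions", ()):
            chem.reactions.append(Reaction.from_dict(rd))
        return chem

    @classmethod
    def from_json(cls, source) -> "Chemistry":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "Chemistry":
        return Chemistry.from_dict(self.to_dict())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Chemistry):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# reaction enumeration


def _check_alphabet(seqs, alphabet) -> None:
    allowed = set(alphabet)
    for s in seqs:
        bad = set(s) - allowed
        if bad:
            raise ValueError(
                f"sequence {s!r} contains symbols {sorted(bad)} outside the "
                f"alphabet {list(alphabet)}"
            )


def enumerate_reactions(chem: Chemistry, species_set=None) -> list[Reaction]:
    """Enumerate all allowed reactions among ``species_set``.

    All cleavages at every cut position of every species of length >= 2,
    plus every ordered condensation pair whose product does not exceed
    ``chem.L_max``.  Products not already known are added to the chemistry.
    No catalysts are assigned here.  Order is deterministic (sorted by
    length then lexicographically, cleavages before condensations).
    """
    if species_set is None:
        species_set = list(chem.species)
    species_set = sorted(set(species_set), key=lambda s: (len(s), s))
    if not species_set:
        raise ValueError("species_set must be nonempty")
    _check_alphabet(species_set, chem.alphabet)
    seen = {r.key for r in chem.reactions}
    out: list[Reaction] = []
    for seq in species_set:
        for cut in range(1, len(seq)):
            r = Reaction(
                kind="cleavage",
                substrates=(seq,),
                products=(seq[:cut], seq[cut:]),
                cut_position=cut,
            )
            if r.key not in seen:
                seen.add(r.key)
                out.append(r)
    for a, b in itertools.product(species_set, repeat=2):
        if len(a) + len(b) > chem.L_max:
            continue
        r = Reaction(kind="condensation", substrates=(a, b), products=(a + b,))
        if r.key not in seen:
            seen.add(r.key)
            out.append(r)
    for r in out:
        for seq in (*r.substrates, *r.products):
            chem.ensure_species(seq)
        chem.reactions.append(r)
    return out


# ---------------------------------------------------------------------------
# random assignments


def assign_catalysis(
    chem: Chemistry,
    p: float,
    rng,
    scheme: str = "per_species",
) -> dict[str, list[int]]:
    """Randomly assign catalysts to reactions.

    ``per_species`` (default): each eligible species (length >= 3) is, with
    probability ``p``, made the catalyst of one reaction drawn uniformly at
    random.  ``per_pair``: every (species, reaction) pair is assigned
    independently with probability ``p``.  Returns a map
    species -> list of reaction indices, and updates ``chem.reactions``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(rng)
    eligible = sorted(
        s.sequence for s in chem.species.values() if s.can_catalyze
    )
    assignments: dict[str, list[int]] = {}
    if not eligible:
        if p > 0:
            warnings.warn("no catalyst-eligible species (length >= 3)")
        return assignments
    n_rxn = len(chem.reactions)
    if n_rxn == 0:
        return assignments
    if scheme == "per_species":
        for seq in eligible:
            if rng.random() < p:
                j = int(rng.integers(n_rxn))
                assignments.setdefault(seq, []).append(j)
    elif scheme == "per_pair":
        for seq in eligible:
            hits = np.nonzero(rng.random(n_rxn) < p)[0]
            if hits.size:
                assignments[seq] = [int(j) for j in hits]
    else:
        raise ValueError(f"unknown catalysis scheme {scheme!r}")
    for seq, idxs in assignments.items():
        for j in idxs:
            r = chem.reactions[j]
            r.catalysts = r.catalysts | {seq}
    return assignments


def assign_container_coupling(
    chem: Chemistry,
    p_cont: float,
    k_cont_value: float,
    rng,
) -> list[str]:
    """Couple each non-food species to container growth w.p. ``p_cont``."""
    if not 0 <= p_cont <= 1:
        raise ValueError("p_cont must be in [0, 1]")
    if k_cont_value <= 0:
        raise ValueError("k_cont_value must be positive")
    rng = np.random.default_rng(rng)
    coupled = []
    for seq in sorted(chem.species):
        sp = chem.species[seq]
        if sp.is_food:
            continue
        if rng.random() < p_cont:
            sp.k_cont = k_cont_value
            coupled.append(seq)
    return coupled


# ---------------------------------------------------------------------------
# validation


def validate(chem: Chemistry) -> list[str]:
    """Check every structural invariant; returns a list of violations
    (empty list <=> valid chemistry)."""
    issues: list[str] = []
    allowed = set(chem.alphabet)
    for seq, sp in chem.species.items():
        if seq != sp.sequence:
            issues.append(f"species key {seq!r} != sequence {sp.sequence!r}")
        if len(seq) < 1:
            issues.append("empty species sequence")
        if set(seq) - allowed:
            issues.append(f"species {seq!r} uses symbols outside the alphabet")
        if sp.is_food:
            if not chem.is_permeable(seq):
                issues.append(f"food species {seq!r} is not permeable")
            if sp.external_concentration <= 0:
                issues.append(
                    f"food species {seq!r} has no external concentration"
                )
        if sp.external_concentration < 0:
            issues.append(f"species {seq!r} negative external concentration")
        if sp.k_cont < 0 or sp.diffusion_D < 0:
            issues.append(f"species {seq!r} negative coupling coefficient")
    for i, r in enumerate(chem.reactions):
        label = f"reaction {i} ({r})"
        for seq in (*r.substrates, *r.products, *r.catalysts):
            if seq not in chem.species:
                issues.append(f"{label}: unresolved reference {seq!r}")
        if Counter("".join(r.substrates)) != Counter("".join(r.products)):
            issues.append(f"{label}: monomer mass balance violated")
        if r.kind == "cleavage":
            sub = r.substrates[0]
            if r.products[0] + r.products[1] != sub:
                issues.append(f"{label}: products do not concatenate to substrate")
            if r.cut_position is not None and not (
                1 <= r.cut_position < len(sub)
            ):
                issues.append(f"{label}: cut position out of range")
        else:
            if r.substrates[0] + r.substrates[1] != r.products[0]:
                issues.append(f"{label}: product is not the concatenation")
            if len(r.products[0]) > chem.L_max:
                issues.append(f"{label}: product longer than L_max")
        for c in r.catalysts:
            if len(c) < MIN_CATALYST_LENGTH:
                issues.append(
                    f"{label}: catalyst {c!r} shorter than "
                    f"{MIN_CATALYST_LENGTH} symbols"
                )
    return issues
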