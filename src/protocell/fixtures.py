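"""Reference chemistries and geometries used throughout tests and docs.

Every fixture is generated programmatically — no data files.  The named
fixtures reproduce the qualitative network topologies studied with the
model:

``single_autocatalyst``
    One species (ABA) catalyzing its own condensation from buffered food,
    coupled to the container: the minimal synchronizing protocell.

``fig3_coupled_scc``
    A single irrRAF made of two coupled SCCs: the first SCC (AAB, ABB)
    grows from the food and produces the substrate (BAB) required by the
    second SCC (BABA, BABB), which alone is coupled to the container.
    Includes two inert non-RAF species that undergo death by dilution.

``fig4_two_irrrafs``
    Two reaction-disjoint irrRAFs with different growth rates; only the
    fast one is coupled to the container, so the slow one dilutes away.

``fig9_permeable``
    Two reaction-disjoint, equal-rate irrRAFs drawing on disjoint
    permeable foods, both coupled — the finite-diffusion (Fick) novelty
    scenario: the second cycle is meant to be injected late at low copy
    number.

``random_kauffman``
    A random chemistry in the Kauffman sense: all species up to ``L_max``
    over the alphabet, full reaction enumeration, catalysis assigned with
    probability ``p``.

Sequences are chosen freely (the network topology, not the strings, is
what matters); rate constants and geometry are in simulation units and are
documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .chemistry import (
    Chemistry,
    KineticParams,
    Reaction,
    Species,
    assign_catalysis,
    assign_container_coupling,
    enumerate_reactions,
)
from .container import ContainerGeometry

__all__ = ["make_fixture", "default_geometry", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "single_autocatalyst",
    "fig3_coupled_scc",
    "fig4_two_irrrafs",
    "fig9_permeable",
    "random_kauffman",
)

#: geometry shared by the lineage fixtures: thick-ish membrane so that the
#: finite-size daughter/mother volume ratio (~0.30) is exercised, and a
#: division threshold large enough that lipid-timing noise is small
#: (theta/2 = 10^4 growth events per generation at g = 1).
_LINEAGE_GEOMETRY = dict(delta=2.0, rho=10.0, theta=20000.0, g=1)


def default_geometry(theta: float | None = None, C: float | None = None,
                     **overrides) -> ContainerGeometry:
    params = dict(_LINEAGE_GEOMETRY)
    params.update(overrides)
    if theta is not None:
        params["theta"] = theta
    params.setdefault("C", (C if C is not None else params["theta"] / 2.0))
    if C is not None:
        params["C"] = C
    return ContainerGeometry(**params)


def _base_chem(L_max=4, L_perm=3) -> Chemistry:
    return Chemistry(alphabet=("A", "B"), L_max=L_max, L_perm=L_perm)


def _food(chem: Chemistry, seqs, conc=1.0, D=0.0) -> None:
    for s in seqs:
        chem.add_species(
            Species(s, is_food=True, external_concentration=conc,
                    diffusion_D=D)
        )


def _cond(sub1, sub2, cats, params=None) -> Reaction:
    return Reaction(
        kind="condensation",
        substrates=(sub1, sub2),
        products=(sub1 + sub2,),
        catalysts=frozenset(cats),
        params=params,
    )


def make_fixture(name: str, params: dict | None = None, seed: int = 0):
    """Build a named fixture chemistry.

    Returns (chemistry, geometry).  ``params`` overrides fixture defaults
    (see the individual builders for the accepted keys)."""
    params = dict(params or {})
    builder = _BUILDERS.get(name)
    if builder is None:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        )
    return builder(params, seed)


def _fx_single_autocatalyst(params, seed):
    chem = _base_chem()
    _food(chem, ["A", "B", "AB"])
    k_cont = params.get("k_cont", 0.5)
    chem.add_species(Species("ABA", k_cont=k_cont,
                             initial_count=params.get("n0", 4000)))
    chem.reactions.append(_cond("AB", "A", ["ABA"]))
    geo = default_geometry(
        theta=params.get("theta", 20000.0), delta=1.0, rho=1.0,
    )
    return chem, geo


def _fx_fig3(params, seed):
    chem = _base_chem()
    _food(chem, ["A", "B", "AA", "AB", "BA", "BB"])
    k_cont = params.get("k_cont", 0.27)
    n1 = params.get("n_scc1", 4000)
    n2 = params.get("n_scc2", 4000)
    # SCC 1: AAB <-> ABB mutual catalysis, built from food
    chem.add_species(Species("AAB", initial_count=n1))
    chem.add_species(Species("ABB", initial_count=n1))
    chem.reactions.append(_cond("AA", "B", ["ABB"]))
    chem.reactions.append(_cond("AB", "B", ["AAB"]))
    # bridge: SCC 1 catalyzes production of the substrate for SCC 2
    chem.add_species(Species("BAB", initial_count=params.get("n_bridge", 1500)))
    chem.reactions.append(_cond("BA", "B", ["AAB"]))
    # SCC 2: BABA <-> BABB, consuming BAB; coupled to the container
    chem.add_species(Species("BABA", k_cont=k_cont, initial_count=n2))
    chem.add_species(Species("BABB", k_cont=k_cont, initial_count=n2))
    chem.reactions.append(_cond("BAB", "A", ["BABB"]))
    chem.reactions.append(_cond("BAB", "B", ["BABA"]))
    # inert non-RAF species: neither produced nor consumed
    chem.add_species(Species("AABB", initial_count=params.get("n_inert", 50)))
    chem.add_species(Species("ABBB", initial_count=params.get("n_inert2", 30)))
    return chem, default_geometry()


_SLOW_PARAMS = KineticParams(k_assoc=0.5)


def _fx_fig4(params, seed):
    chem = _base_chem()
    _food(chem, ["A", "B", "AA", "AB", "BA", "BB"])
    k_cont = params.get("k_cont", 0.27)
    nf = params.get("n_fast", 4000)
    ns = params.get("n_slow", 1000)
    # fast irrRAF, coupled
    chem.add_species(Species("AAB", k_cont=k_cont, initial_count=nf))
    chem.add_species(Species("ABB", k_cont=k_cont, initial_count=nf))
    chem.reactions.append(_cond("AA", "B", ["ABB"]))
    chem.reactions.append(_cond("AB", "B", ["AAB"]))
    # slow irrRAF (halved association rate), uncoupled
    slow = KineticParams(k_assoc=params.get("k_assoc_slow", 0.5))
    chem.add_species(Species("BAA", initial_count=ns))
    chem.add_species(Species("BBA", initial_count=ns))
    chem.reactions.append(_cond("BA", "A", ["BBA"], params=slow))
    chem.reactions.append(_cond("BB", "A", ["BAA"], params=slow))
    return chem, default_geometry()


def _fx_fig9(params, seed):
    chem = _base_chem()
    D = params.get("diffusion_D", 0.3)
    _food(chem, ["A", "B", "AA", "AB", "BA", "BB"], D=D)
    k_cont = params.get("k_cont", 0.27)
    n0 = params.get("n_incumbent", 1200)
    # incumbent irrRAF (foods AA, AB, B), coupled
    chem.add_species(Species("AAB", k_cont=k_cont, initial_count=n0))
    chem.add_species(Species("ABB", k_cont=k_cont, initial_count=n0))
    chem.reactions.append(_cond("AA", "B", ["ABB"]))
    chem.reactions.append(_cond("AB", "B", ["AAB"]))
    # latecomer irrRAF, same rate constants, disjoint foods (BA, BB, A),
    # also coupled; starts at zero copies and is injected during a lineage
    chem.add_species(Species("BAA", k_cont=k_cont, initial_count=0))
    chem.add_species(Species("BBA", k_cont=k_cont, initial_count=0))
    chem.reactions.append(_cond("BA", "A", ["BBA"]))
    chem.reactions.append(_cond("BB", "A", ["BAA"]))
    return chem, default_geometry()


def _fx_random_kauffman(params, seed):
    alphabet = tuple(params.get("alphabet", "AB"))
    L_max = params.get("L_max", 4)
    L_perm = params.get("L_perm", 3)
    p = params.get("p", 0.02)
    scheme = params.get("scheme", "per_species")
    chem = Chemistry(alphabet=alphabet, L_max=L_max, L_perm=L_perm)
    seqs = [
        "".join(combo)
        for length in range(1, L_max + 1)
        for combo in _product(alphabet, length)
    ]
    for s in seqs:
        chem.ensure_species(s)
    for s in seqs:
        if len(s) < L_perm:
            sp = chem.species[s]
            sp.is_food = True
            sp.external_concentration = 1.0
    enumerate_reactions(chem)
    rng = np.random.default_rng(seed)
    assign_catalysis(chem, p, rng, scheme=scheme)
    p_cont = params.get("p_cont", 0.0)
    if p_cont > 0:
        assign_container_coupling(
            chem, p_cont, params.get("k_cont", 0.27), rng
        )
    return chem, default_geometry()


def _product(alphabet, length):
    import itertools

    return itertools.product(alphabet, repeat=length)


_BUILDERS = {
    "single_autocatalyst": _fx_single_autocatalyst,
    "fig3_coupled_scc": _fx_fig3,
    "fig4_two_irrrafs": _fx_fig4,
    "fig9_permeable": _fx_fig9,
    "random_kauffman": _fx_random_kauffman,
}
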