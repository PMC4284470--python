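"""Shared fixtures: small chemistries and independent brute-force oracles.

The RAF oracles here are deliberately written as naive set iterations over
explicit subsets, independent of the package's reduction algorithm.
"""

import itertools

import numpy as np
import pytest

from protocell.chemistry import (
    Chemistry,
    Reaction,
    Species,
    enumerate_reactions,
)


@pytest.fixture
def toy_chem():
    """All species of length <= 2 over {A, B}; fully enumerated reactions
    with L_max = 2 (4 cleavages + 4 condensations)."""
    chem = Chemistry(alphabet=("A", "B"), L_max=2, L_perm=3)
    for s in ["A", "B", "AA", "AB", "BA", "BB"]:
        chem.add_species(Species(s, is_food=True, external_concentration=1.0))
    enumerate_reactions(chem)
    return chem


def random_small_chemistry(rng, n_reactions=8, p_cat=0.6, alphabet=("A", "B")):
    """Random chemistry for oracle comparisons: sample reactions from the
    full enumerated universe up to length 4, attach random catalysts drawn
    from the length >= 3 species, pick a random permeable food set."""
    chem = Chemistry(alphabet=alphabet, L_max=4, L_perm=3)
    seqs = [
        "".join(c)
        for length in range(1, 5)
        for c in itertools.product(alphabet, repeat=length)
    ]
    for s in seqs:
        chem.ensure_species(s)
    universe = enumerate_reactions(chem)
    chem.reactions = []
    chosen = rng.choice(len(universe), size=min(n_reactions, len(universe)),
                        replace=False)
    eligible = [s for s in seqs if len(s) >= 3]
    for j in chosen:
        r = universe[j]
        cats = [s for s in eligible if rng.random() < p_cat]
        if not cats:
            cats = [eligible[rng.integers(len(eligible))]]
        chem.reactions.append(
            Reaction(kind=r.kind, substrates=r.substrates, products=r.products,
                     cut_position=r.cut_position, catalysts=frozenset(cats))
        )
    for s in seqs:
        if len(s) < chem.L_perm and rng.random() < 0.5:
            sp = chem.species[s]
            sp.is_food = True
            sp.external_concentration = 1.0
    if not chem.food:
        sp = chem.species["A"]
        sp.is_food = True
        sp.external_concentration = 1.0
    return chem


# ---------------------------------------------------------------------------
# independent oracles


def oracle_closure(food, reactions):
    """Naive iterate-to-fixpoint food closure (catalysis ignored)."""
    w = set(food)
    for _ in range(len(reactions) + 1):
        for r in reactions:
            if set(r.substrates) <= w:
                w |= set(r.products)
    return w


def oracle_is_raf(food, subset):
    """Subset test: all substrates in the closure of the subset itself and
    every reaction catalyzed from within that closure."""
    subset = list(subset)
    if not subset:
        return False
    w = oracle_closure(food, subset)
    return all(
        set(r.substrates) <= w and any(c in w for c in r.catalysts)
        for r in subset
    )


def oracle_max_raf(chem):
    """Union of all RAF subsets, by exhaustive enumeration."""
    food = set(chem.food)
    rxns = chem.catalyzed_reactions()
    union = set()
    for size in range(1, len(rxns) + 1):
        for combo in itertools.combinations(range(len(rxns)), size):
            if oracle_is_raf(food, [rxns[i] for i in combo]):
                union |= set(combo)
    return {rxns[i].key for i in union}


def oracle_minimal_rafs(chem):
    """All minimal RAF subsets, by exhaustive enumeration."""
    food = set(chem.food)
    rxns = chem.catalyzed_reactions()
    rafs = []
    for size in range(1, len(rxns) + 1):
        for combo in itertools.combinations(range(len(rxns)), size):
            if oracle_is_raf(food, [rxns[i] for i in combo]):
                rafs.append(frozenset(combo))
    minimal = [a for a in rafs if not any(b < a for b in rafs)]
    return {frozenset(rxns[i].key for i in m) for m in minimal}


def oracle_sccs(adjacency):
    """Nontrivial SCCs by pairwise reachability (transitive closure)."""
    n = len(adjacency)
    reach = [[False] * n for _ in range(n)]
    for u in range(n):
        for v in adjacency[u]:
            reach[u][v] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    comps = set()
    for u in range(n):
        if reach[u][u]:  # u lies on a cycle (possibly a self-loop)
            comps.add(frozenset(
                v for v in range(n) if reach[u][v] and reach[v][u]
            ))
    return comps
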