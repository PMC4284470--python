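"""Graph views of a chemistry and RAF (reflexively autocatalytic,
food-generated) set detection.

Two complementary representations are used.  The *catalyst-product graph*
has an edge u -> v whenever u catalyzes a reaction producing v; its
nontrivial strongly connected components (SCCs) are candidate collective
replicators.  Whether an SCC can actually sustain growth depends on
substrate availability, which the full bipartite picture captures: a RAF is
a reaction subset in which every reaction is catalyzed by a species
producible from the food by the subset itself, and all substrates are
generated from the food.  The maximal RAF is found by the standard
iterative reduction; irreducible RAFs (irrRAFs) are minimal autocatalytic
cores together with the dependent "tentacle" reactions that collapse when
the core is removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .chemistry import Chemistry, Reaction

__all__ = [
    "RafResult",
    "catalyst_product_graph",
    "find_sccs",
    "food_closure",
    "reduce_to_raf",
    "max_raf",
    "minimal_raf_cores",
    "find_irr_rafs",
    "raf_analysis",
    "classify_species",
    "graph_to_dot",
]


def catalyst_product_graph(chem: Chemistry) -> nx.DiGraph:
    """Directed graph: species u -> species v iff u catalyzes at least one
    reaction having v among its products.  Substrates are not represented."""
    g = nx.DiGraph()
    g.add_nodes_from(chem.species)
    for r in chem.reactions:
        for cat in r.catalysts:
            for prod in r.products:
                g.add_edge(cat, prod)
    return g


def find_sccs(graph: nx.DiGraph) -> list[frozenset]:
    """Nontrivial strongly connected components (size > 1, or a single node
    with a self-loop), in deterministic order."""
    out = []
    for comp in nx.strongly_connected_components(graph):
        if len(comp) > 1 or graph.has_edge(*(2 * list(comp))):
            out.append(frozenset(comp))
    return sorted(out, key=lambda c: sorted(c))


def food_closure(food, reactions) -> frozenset:
    """Least fixed point of food under the reaction subset: repeatedly add
    the products of any reaction all of whose substrates are present.
    Catalysis is *not* required for closure membership."""
    closure = set(food)
    pending = list(reactions)
    changed = True
    while changed:
        changed = False
        remaining = []
        for r in pending:
            if all(s in closure for s in r.substrates):
                new = [p for p in r.products if p not in closure]
                if new:
                    closure.update(new)
                    changed = True
            else:
                remaining.append(r)
        pending = remaining
    return frozenset(closure)


def reduce_to_raf(food, reactions) -> list:
    """Iteratively delete reactions with an unsupported substrate or no
    catalyst inside the closure, until stable.  Returns the (possibly
    empty) maximal RAF within ``reactions``."""
    current = list(reactions)
    while True:
        w = food_closure(food, current)
        kept = [
            r
            for r in current
            if all(s in w for s in r.substrates)
            and any(c in w for c in r.catalysts)
        ]
        if len(kept) == len(current):
            return kept
        current = kept


def max_raf(chem: Chemistry, reactions=None) -> list[Reaction]:
    """Maximal RAF of the chemistry (catalyzed reactions only)."""
    if reactions is None:
        reactions = chem.catalyzed_reactions()
    return reduce_to_raf(frozenset(chem.food), reactions)


def _is_raf(food, subset) -> bool:
    subset = list(subset)
    return bool(subset) and len(reduce_to_raf(food, subset)) == len(subset)


def minimal_raf_cores(
    chem: Chemistry,
    enumeration_cap: int = 4096,
    exact_limit: int = 12,
    rng=None,
    n_random_orders: int = 32,
):
    """Minimal RAF subsets (no proper subset is a RAF) within the max RAF.

    Exact subset enumeration for max RAFs of up to ``exact_limit``
    reactions; above that, randomized deletion orders (deduplicated), which
    may miss cores — the second return value flags completeness.
    """
    import numpy as np

    food = frozenset(chem.food)
    mraf = max_raf(chem)
    if not mraf:
        return [], True
    n = len(mraf)
    if n <= exact_limit and 2**n <= enumeration_cap:
        rafs = []
        for size in range(1, n + 1):
            for combo in itertools.combinations(range(n), size):
                subset = [mraf[i] for i in combo]
                if _is_raf(food, subset):
                    rafs.append(frozenset(combo))
        cores = [
            a for a in rafs if not any(b < a for b in rafs)
        ]
        return [
            [mraf[i] for i in sorted(core)] for core in
            sorted(cores, key=sorted)
        ], True
    # heuristic: randomized greedy deletion to minimality
    rng = np.random.default_rng(rng)
    seen: set[frozenset] = set()
    cores = []
    for _ in range(n_random_orders):
        current = list(mraf)
        progress = True
        while progress:
            progress = False
            for idx in rng.permutation(len(current)):
                trial = current[:idx] + current[idx + 1:]
                reduced = reduce_to_raf(food, trial)
                if reduced:
                    current = reduced
                    progress = True
                    break
        key = frozenset(r.key for r in current)
        if key not in seen:
            seen.add(key)
            cores.append(current)
    return cores, False


def _augment_core(chem: Chemistry, mraf, core) -> list:
    """irrRAF = core plus every max-RAF reaction that collapses when the
    core is removed: maxRAF(R) \\ maxRAF(R \\ core)."""
    food = frozenset(chem.food)
    core_keys = {r.key for r in core}
    rest = [r for r in mraf if r.key not in core_keys]
    surviving = {r.key for r in reduce_to_raf(food, rest)}
    return [r for r in mraf if r.key not in surviving]


def find_irr_rafs(
    chem: Chemistry,
    enumeration_cap: int = 4096,
    rng=None,
) -> tuple[list[list[Reaction]], bool]:
    """Irreducible RAFs: minimal autocatalytic cores augmented with their
    dependent tentacle chains.  Returns (irr_rafs, complete_flag)."""
    mraf = max_raf(chem)
    cores, complete = minimal_raf_cores(
        chem, enumeration_cap=enumeration_cap, rng=rng
    )
    seen: set[frozenset] = set()
    irr = []
    for core in cores:
        aug = _augment_core(chem, mraf, core)
        key = frozenset(r.key for r in aug)
        if key not in seen:
            seen.add(key)
            irr.append(aug)
    return irr, complete


@dataclass
class RafResult:
    """Full RAF analysis of one chemistry."""

    max_raf: list = field(default_factory=list)
    cores: list = field(default_factory=list)
    irr_rafs: list = field(default_factory=list)
    closure: frozenset = frozenset()
    sccs: list = field(default_factory=list)
    complete: bool = True

    def species_of(self, reactions) -> frozenset:
        out = set()
        for r in reactions:
            out.update(r.substrates)
            out.update(r.products)
            out.update(r.catalysts)
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "max_raf": [str(r) for r in self.max_raf],
            "cores": [[str(r) for r in c] for c in self.cores],
            "irr_rafs": [[str(r) for r in c] for c in self.irr_rafs],
            "closure": sorted(self.closure),
            "sccs": [sorted(s) for s in self.sccs],
            "complete": self.complete,
        }


def raf_analysis(chem: Chemistry, enumeration_cap: int = 4096, rng=None) -> RafResult:
    mraf = max_raf(chem)
    cores, complete = minimal_raf_cores(chem, enumeration_cap=enumeration_cap, rng=rng)
    irr, _ = find_irr_rafs(chem, enumeration_cap=enumeration_cap, rng=rng)
    return RafResult(
        max_raf=mraf,
        cores=cores,
        irr_rafs=irr,
        closure=food_closure(frozenset(chem.food), mraf),
        sccs=find_sccs(catalyst_product_graph(chem)),
        complete=complete,
    )


def classify_species(chem: Chemistry, result: RafResult) -> dict[str, str]:
    """Label each species food / RAF-member / non-RAF (used by lineage
    dilution reports; non-RAF species undergo dilution across divisions)."""
    raf_species = result.species_of(result.max_raf)
    labels = {}
    for seq, sp in chem.species.items():
        if sp.is_food:
            labels[seq] = "food"
        elif seq in raf_species:
            labels[seq] = "RAF-member"
        else:
            labels[seq] = "non-RAF"
    return labels


def graph_to_dot(graph: nx.DiGraph, labels: dict | None = None) -> str:
    """Minimal DOT export of the catalyst-product graph."""
    lines = ["digraph catalyst_product {"]
    for n in sorted(graph.nodes):
        attr = f' [label="{n}\\n{labels[n]}"]' if labels and n in labels else ""
        lines.append(f'  "{n}"{attr};')
    for u, v in sorted(graph.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
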