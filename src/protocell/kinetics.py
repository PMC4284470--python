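"""Extended Gillespie dynamics of a chemistry inside a growing protocell.

The reaction network is compiled to flat channel tables
(:class:`ChannelSet`) consumed by the JIT inner loop in
:mod:`protocell._ssa`.  Two transport modes exist:

``instantaneous``
    Permeable species are buffered: their internal concentration is pinned
    to the external one (infinitely fast diffusion), they carry no tracked
    count, and molecules produced of a permeable species vanish into the
    bath.

``fick``
    Permeable species are tracked like everything else; each gets a pair
    of opposing unit-molecule transport channels (influx D_i A [M_i^out],
    efflux D_i A x_i / V_r) whose expected net flux is Fick's law
    dM_i/dt = D_i A ([M_i^out] - [M_i^in]).

Condensation is expanded into complex formation / dissociation / final
condensation with an explicit complex pseudo-species per (substrate,
catalyst) pair; uncatalyzed reactions contribute no channels (no
spontaneous reactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ssa
from .chemistry import Chemistry
from .container import ContainerGeometry, partition_counts

__all__ = [
    "ChannelSet",
    "ProtocellState",
    "Trajectory",
    "build_channels",
    "propensities",
    "ssa_step",
    "simulate_segment",
    "inject_species",
    "divide",
]

_KIND_NAMES = {
    0: "unimolecular",
    1: "bimolecular",
    2: "lipid_growth",
    3: "transport_in",
    4: "transport_out",
}

STATUS_HORIZON = 0
STATUS_DIVISION = 1
STATUS_EVENT_CAP = 2
STATUS_EXHAUSTED = 3  # zero total propensity


def complex_id(substrate: str, catalyst: str) -> str:
    return f"{substrate}:{catalyst}"


@dataclass
class ChannelSet:
    """Compiled channel tables for one chemistry + mode."""

    chem: Chemistry
    mode: str
    names: list[str] = field(default_factory=list)      # species + complexes
    index: dict = field(default_factory=dict)
    buffered: np.ndarray = None
    ext: np.ndarray = None
    k_cont: np.ndarray = None
    is_complex: np.ndarray = None
    kind: np.ndarray = None
    kvec: np.ndarray = None
    r1: np.ndarray = None
    r2: np.ndarray = None
    eff_ptr: np.ndarray = None
    eff_idx: np.ndarray = None
    eff_delta: np.ndarray = None
    labels: list[str] = field(default_factory=list)     # channel descriptions

    @property
    def n_species(self) -> int:
        return len(self.names)

    @property
    def n_channels(self) -> int:
        return len(self.kind)

    def initial_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_species, dtype=np.int64)
        for seq, sp in self.chem.species.items():
            i = self.index[seq]
            if sp.initial_count and not self.buffered[i]:
                counts[i] = sp.initial_count
        return counts

    def partition_mask(self) -> np.ndarray:
        """Species partitioned at division: everything tracked (free
        impermeable species and complexes; in fick mode also permeable
        ones).  Buffered species are re-equilibrated, not partitioned."""
        return ~self.buffered


def build_channels(chem: Chemistry, mode: str = "instantaneous") -> ChannelSet:
    if mode not in ("instantaneous", "fick"):
        raise ValueError(f"unknown mode {mode!r}")
    cs = ChannelSet(chem=chem, mode=mode)

    def add_name(name: str) -> int:
        if name not in cs.index:
            cs.index[name] = len(cs.names)
            cs.names.append(name)
        return cs.index[name]

    for seq in chem.species:
        add_name(seq)
    # complexes: one per (binding substrate, catalyst) pair of each
    # catalyzed condensation
    for r in chem.catalyzed_reactions():
        if r.kind != "condensation":
            continue
        bind = r.substrates[r.complex_substrate_index]
        for cat in sorted(r.catalysts):
            add_name(complex_id(bind, cat))

    n = len(cs.names)
    cs.buffered = np.zeros(n, dtype=np.bool_)
    cs.ext = np.zeros(n, dtype=np.float64)
    cs.k_cont = np.zeros(n, dtype=np.float64)
    cs.is_complex = np.zeros(n, dtype=np.bool_)
    diffusion = np.zeros(n, dtype=np.float64)
    for name, i in cs.index.items():
        sp = chem.species.get(name)
        if sp is None:  # complex pseudo-species: impermeable, inert
            cs.is_complex[i] = True
            continue
        cs.ext[i] = sp.external_concentration
        cs.k_cont[i] = sp.k_cont
        diffusion[i] = sp.diffusion_D
        if chem.is_permeable(name) and mode == "instantaneous":
            cs.buffered[i] = True

    kind, kvec, r1, r2 = [], [], [], []
    eff_lists: list[list[tuple[int, int]]] = []
    labels = []

    def add_channel(k_, kv, a, b, effects, label):
        kind.append(k_)
        kvec.append(kv)
        r1.append(a)
        r2.append(b)
        # drop effects on buffered species (infinite bath) and merge deltas
        merged: dict[int, int] = {}
        for i, d in effects:
            if cs.buffered[i]:
                continue
            merged[i] = merged.get(i, 0) + d
        eff_lists.append([(i, d) for i, d in merged.items() if d != 0])
        labels.append(label)

    defaults = chem.kinetic_defaults
    for r in chem.catalyzed_reactions():
        p = r.effective_params(defaults)
        if r.kind == "cleavage":
            sub = cs.index[r.substrates[0]]
            pr1, pr2 = (cs.index[q] for q in r.products)
            for cat in sorted(r.catalysts):
                ci = cs.index[cat]
                add_channel(
                    1, p.k_cleav, sub, ci,
                    [(sub, -1), (pr1, +1), (pr2, +1)],
                    f"cleave {r.substrates[0]} by {cat}",
                )
        else:
            bind = r.substrates[r.complex_substrate_index]
            other = r.substrates[1 - r.complex_substrate_index]
            bi, oi = cs.index[bind], cs.index[other]
            prod = cs.index[r.products[0]]
            for cat in sorted(r.catalysts):
                ci = cs.index[cat]
                xi = cs.index[complex_id(bind, cat)]
                add_channel(
                    1, p.k_assoc, bi, ci,
                    [(bi, -1), (ci, -1), (xi, +1)],
                    f"assoc {bind}+{cat}",
                )
                add_channel(
                    0, p.k_diss, xi, -1,
                    [(xi, -1), (bi, +1), (ci, +1)],
                    f"diss {bind}:{cat}",
                )
                add_channel(
                    1, p.k_cond, oi, xi,
                    [(oi, -1), (xi, -1), (prod, +1), (ci, +1)],
                    f"cond {bind}:{cat}+{other}->{r.products[0]}",
                )

    # container growth channel (propensity computed from k_cont inside the
    # core; kvec unused)
    add_channel(2, 0.0, -1, -1, [], "lipid_growth")

    if mode == "fick":
        for name, i in cs.index.items():
            if cs.is_complex[i] or not chem.is_permeable(name):
                continue
            D = diffusion[i]
            if D <= 0:
                continue
            add_channel(3, D * cs.ext[i], i, -1, [(i, +1)], f"in {name}")
            add_channel(4, D, i, -1, [(i, -1)], f"out {name}")

    cs.kind = np.asarray(kind, dtype=np.int64)
    cs.kvec = np.asarray(kvec, dtype=np.float64)
    cs.r1 = np.asarray(r1, dtype=np.int64)
    cs.r2 = np.asarray(r2, dtype=np.int64)
    ptr = [0]
    idxs: list[int] = []
    deltas: list[int] = []
    for eff in eff_lists:
        for i, d in eff:
            idxs.append(i)
            deltas.append(d)
        ptr.append(len(idxs))
    cs.eff_ptr = np.asarray(ptr, dtype=np.int64)
    cs.eff_idx = np.asarray(idxs, dtype=np.int64)
    cs.eff_delta = np.asarray(deltas, dtype=np.int64)
    cs.labels = labels
    return cs


@dataclass
class ProtocellState:
    """Discrete protocell state: molecule counts, container, clock."""

    counts: np.ndarray
    geometry: ContainerGeometry
    t: float = 0.0
    generation: int = 0

    def copy(self) -> "ProtocellState":
        return ProtocellState(
            counts=self.counts.copy(),
            geometry=self.geometry.copy(),
            t=self.t,
            generation=self.generation,
        )

    @property
    def volume(self) -> float:
        return self.geometry.volume


@dataclass
class Trajectory:
    t: np.ndarray
    C: np.ndarray
    counts: np.ndarray  # (n_rec, n_species)
    names: list[str]
    status: int = 0
    n_events: int = 0

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=self.names)
        df.insert(0, "t", self.t)
        df["C"] = self.C
        return df


def initial_state(
    cs: ChannelSet,
    geometry: ContainerGeometry,
    counts=None,
) -> ProtocellState:
    c = cs.initial_counts() if counts is None else np.asarray(counts, np.int64).copy()
    if c.shape != (cs.n_species,):
        raise ValueError("counts shape mismatch")
    if (c < 0).any():
        raise ValueError("negative initial counts")
    state = ProtocellState(counts=c, geometry=geometry.copy())
    if cs.mode == "fick":
        _equilibrate_untracked(cs, state, only_zero=True)
    return state


def _equilibrate_untracked(cs: ChannelSet, state: ProtocellState, only_zero=True):
    """In fick mode, start permeable species at their external equilibrium
    count round([out] * V_r) unless explicitly initialized."""
    V = state.geometry.volume
    for name, i in cs.index.items():
        if cs.is_complex[i] or not cs.chem.is_permeable(name):
            continue
        if cs.ext[i] > 0 and (not only_zero or state.counts[i] == 0):
            sp = cs.chem.species[name]
            if sp.initial_count == 0:
                state.counts[i] = int(round(cs.ext[i] * V))


def propensities(cs: ChannelSet, state: ProtocellState) -> np.ndarray:
    """Per-channel propensities at the current state (pure-python mirror of
    the JIT loop; used for inspection and as a unit-test oracle hook)."""
    V = state.geometry.volume
    A = state.geometry.area
    x = state.counts
    out = np.zeros(cs.n_channels)
    for j in range(cs.n_channels):
        kj = cs.kind[j]
        if kj == 0:
            out[j] = cs.kvec[j] * x[cs.r1[j]]
        elif kj == 1:
            i1, i2 = cs.r1[j], cs.r2[j]
            if i1 == i2 and not cs.buffered[i1]:
                out[j] = cs.kvec[j] * x[i1] * (x[i1] - 1) / V if V > 0 else 0.0
            else:
                g1 = cs.ext[i1] * V if cs.buffered[i1] else x[i1]
                g2 = cs.ext[i2] * V if cs.buffered[i2] else x[i2]
                out[j] = cs.kvec[j] * g1 * g2 / V if V > 0 else 0.0
        elif kj == 2:
            out[j] = float(np.dot(cs.k_cont, x)) / state.geometry.g
        elif kj == 3:
            out[j] = cs.kvec[j] * A
        else:
            out[j] = cs.kvec[j] * x[cs.r1[j]] * A / V if V > 0 else 0.0
    return np.maximum(out, 0.0)


def simulate_segment(
    state: ProtocellState,
    cs: ChannelSet,
    seed: int,
    t_end: float = np.inf,
    stop_at_division: bool = True,
    max_events: int = 10_000_000,
    record_every: int = 0,
    max_records: int = 100_000,
) -> tuple[Trajectory, ProtocellState]:
    """Run the SSA until the horizon, the division condition C >= theta,
    or the event cap.  Returns (trajectory, final state); ``state`` is not
    modified.  ``record_every = 0`` records only the endpoints."""
    new = state.copy()
    geo = new.geometry
    kcont_idx = np.nonzero(cs.k_cont > 0)[0].astype(np.int64)
    kcont_val = cs.k_cont[kcont_idx]
    if record_every > 0:
        n_buf = min(max_records, max_events // record_every + 2)
    else:
        n_buf = 2
    rec_t = np.zeros(n_buf)
    rec_C = np.zeros(n_buf)
    rec_counts = np.zeros((n_buf, cs.n_species), dtype=np.int64)
    t_end_eff = t_end if np.isfinite(t_end) else 1e300
    C, t, n_events, n_rec, status = _ssa.ssa_core(
        new.counts,
        float(geo.C), float(new.t),
        cs.kind, cs.kvec, cs.r1, cs.r2,
        cs.eff_ptr, cs.eff_idx, cs.eff_delta,
        cs.buffered, cs.ext,
        kcont_idx, kcont_val, float(geo.g),
        geo.delta, geo.rho,
        float(geo.theta) if stop_at_division else -1.0,
        float(t_end_eff), int(max_events), int(seed) % (2**32),
        int(record_every),
        rec_t, rec_C, rec_counts,
    )
    if status == 4:
        raise RuntimeError("SSA consistency failure: negative count")
    geo.C = C
    new.t = t
    traj = Trajectory(
        t=rec_t[:n_rec].copy(),
        C=rec_C[:n_rec].copy(),
        counts=rec_counts[:n_rec].copy(),
        names=list(cs.names),
        status=int(status),
        n_events=int(n_events),
    )
    return traj, new


def ssa_step(state: ProtocellState, cs: ChannelSet, seed: int) -> ProtocellState:
    """Advance the state by exactly one reaction event (or to infinity if
    no channel can fire)."""
    _, new = simulate_segment(
        state, cs, seed=seed, t_end=np.inf, stop_at_division=False,
        max_events=1,
    )
    return new


def inject_species(
    state: ProtocellState, cs: ChannelSet, species: str, n_copies: int
) -> ProtocellState:
    """Spontaneous appearance of ``n_copies`` molecules of ``species``
    (novelty intake); the state time is unchanged."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if species not in cs.index:
        raise KeyError(f"unknown species {species!r}")
    i = cs.index[species]
    if cs.buffered[i]:
        raise ValueError(f"species {species!r} is buffered; injection is a no-op")
    new = state.copy()
    new.counts[i] += n_copies
    return new


def divide(
    state: ProtocellState,
    cs: ChannelSet,
    rng: np.random.Generator,
    partition_mode: str = "trinomial_with_loss",
    follow: str = "first",
):
    """Split a protocell with C >= theta into two daughters.

    Returns (followed daughter state, sibling counts, lost counts).  Each
    daughter starts with C = theta/2; tracked molecules are partitioned
    independently (trinomial with loss by default, the loss probability
    being 1 - 2 q with q the daughter/mother volume ratio); buffered
    species re-equilibrate through the membrane and are not partitioned.
    """
    geo = state.geometry
    if geo.C < geo.theta:
        raise ValueError("cannot divide: C below the division threshold")
    q = geo.daughter_ratio
    mask = cs.partition_mask()
    d1 = state.counts.copy()
    d2 = np.zeros_like(d1)
    lost = np.zeros_like(d1)
    idx = np.nonzero(mask)[0]
    a, b, c = partition_counts(state.counts[idx], q, rng, mode=partition_mode)
    d1[idx], d2[idx], lost[idx] = a, b, c
    if follow == "first":
        keep, sib = d1, d2
    elif follow == "random":
        keep, sib = (d1, d2) if rng.random() < 0.5 else (d2, d1)
    else:
        raise ValueError(f"unknown follow rule {follow!r}")
    new_geo = ContainerGeometry(
        delta=geo.delta, rho=geo.rho, theta=geo.theta,
        C=geo.theta / 2.0, g=geo.g,
    )
    daughter = ProtocellState(
        counts=keep, geometry=new_geo, t=state.t,
        generation=state.generation + 1,
    )
    if cs.mode == "fick":
        # permeable species already partitioned; nothing buffered to reset
        pass
    return daughter, sib, lost
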