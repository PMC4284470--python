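# Methods

## Model

The package simulates a protocell: a spherical, turgid lipid vesicle whose
aqueous interior hosts a catalytic polymer chemistry, and whose membrane
grows in proportion to the counts of selected internal species until it
divides. The chemistry is of the Kauffman binary-polymer type: species are
ordered strings over a small monomer alphabet; the only reactions are
catalyzed cleavage (cut at a position) and catalyzed condensation
(concatenation, restricted to products no longer than `L_max`).
Condensation proceeds through a transient catalyst-substrate complex
(association, dissociation, final condensation with the second substrate);
cleavage is a single elementary step. Only species of length >= 3 can
catalyze, no spontaneous or backward reactions occur, and catalysts are
assigned at random: each eligible species is, with probability `p`, made
the catalyst of one uniformly drawn reaction (a per-(species, reaction)
pair Bernoulli scheme is available as `scheme="per_pair"`; both appear in
the literature, and the per-pair variant is also what the random-chemistry
emergence scans use because it produces denser catalysis graphs at small
`p`).

### Membrane and transport

The membrane is semipermeable: species shorter than `L_perm` cross it,
longer ones are entrapped (the boundary is read strictly: length exactly
`L_perm` does not permeate). Two transport regimes are implemented.

* **Instantaneous** (the base model): diffusion across the membrane is
  infinitely fast, so permeable species are *buffered* — their internal
  concentration is pinned to the external one, they carry no tracked
  count, and permeable molecules produced inside vanish into the bath.
* **Fick** (finite diffusion): permeable species are tracked discretely
  and each has two opposing unit-molecule channels, influx at rate
  `D_i A [M_i^out]` and efflux at rate `D_i A x_i / V_r`, whose expected
  net flux is Fick's law `dM_i/dt = D_i A ([M_i^out] - [M_i^in])`. The
  jump-process realization keeps the whole simulator a pure Markov jump
  process; a deterministic-flux variant would be an extension hook.

Catalyst-substrate complexes are always impermeable, never catalysts, and
count as a single reaction node in all graph analyses.

### Container geometry

The container size is the lipid count `C`. With membrane thickness `delta`
and lipid density `rho` held constant, the spherical-shell relation
`C = rho (4/3) pi ((r + delta)^3 - r^3)` inverts in closed form to

    r(C) = (delta/2) (sqrt(C / (pi rho delta^3) - 1/3) - 1),
    V_r(C) = (4/3) pi r^3 = O(C^{3/2})  as delta -> 0.

Lipids are produced at rate `sum_i k_i^cont x_i` (first-order in the
coupled catalysts, with an infinite precursor supply; note
`[x_i] V_r = x_i`) and join the membrane instantly. The growth channel can
batch `g` lipids per firing at propensity `sum_i k_i^cont x_i / g`; the
mean dynamics is unchanged and `g = 1` (the default everywhere in the
tests) is the exact one-lipid channel.

Division triggers at `C = theta` (the lipid-count form of the threshold,
matching the daughter-ratio formula, which is parameterized by theta as a
mass). Each daughter receives `C = theta/2`; every tracked molecule is
independently assigned daughter-1/daughter-2/lost with probabilities
`(q, q, 1 - 2q)`, where `q = V_r(theta/2)/V_r(theta)` is the
daughter/mother volume ratio — in the thin-membrane limit `q -> 2^{-3/2}
= 0.3535...`, so about 29.3% ("around 30%") of the internal material is
lost per division. A lossless even split (`binomial_no_loss`) implements
the idealization behind the single-copy loss probability `alpha = 1/2^N`.
Buffered species re-equilibrate through the membrane instead of being
partitioned. Lineages follow one daughter (fixed or random).

### Stochastic dynamics

Dynamics follow the Gillespie direct method extended to a time-varying
volume: bimolecular propensities are `k x_A x_B / V_r` (`k x (x-1) / V_r`
for identical substrates), buffered participants contribute
`[ext] V_r` in place of a count, and all geometry-dependent propensities
are recomputed after every firing. The method stays exact because `V_r`
changes only at discrete (lipid-growth) events. The inner loop is
JIT-compiled (numba) over flat channel tables; everything else (channel
construction, division, lineage logic) is plain numpy.

### RAF analysis

The catalyst-product graph has an edge u -> v when u catalyzes a reaction
producing v; its nontrivial SCCs are candidate collective replicators.
The maximal RAF is computed by the standard reduction: iteratively delete
reactions whose substrates fall outside the food closure or with no
catalyst inside it (catalysis is *not* required for closure membership,
only for reaction retention). Minimal autocatalytic cores are enumerated
exactly by subset checking for max RAFs of up to 12 reactions and by
deduplicated randomized deletion orders above that (flagged incomplete).

Irreducible RAFs are reported as a core together with its dependent
"tentacle" reactions — everything in the max RAF that collapses when the
core is removed, computed as `maxRAF(R) \ maxRAF(R \ core)`. This matches
the working notion of an irrRAF as a self-sustaining unit plus the chains
it roots: for the coupled-SCC fixture the single irrRAF contains both SCCs
and the bridge reaction, while strictly minimal cores are exposed
separately (`RafResult.cores`) and satisfy strict minimality (no proper
subset is a RAF). Nothing beyond max-RAF/irrRAF is implemented (no
uRAF/coRAF variants).

### Population maps

Once a slow irrRAF begins to be lost stochastically at divisions, the
population splits into one-irrRAF (X) and two-irrRAF (Y) protocells with
generation maps

    X' = 2X + alpha Y,               Y' = (2 - alpha) Y          (linear)
    X' = 2X + alpha Y - b_X (X+Y) X, Y' = (2-alpha) Y - b_Y (X+Y) Y

with `alpha = 1/2^N` for N single-copy species under even lossless
partitioning. The printed map uses a single `beta`; the asymmetric
`beta_X != beta_Y` generalization is needed for the coexistence result and
reduces to the printed map when equal. The coexistence scenario assigns
the advantage to the two-irrRAF carriers (`beta_Y < beta_X`: carrying the
losing irrRAF mitigates crowding), which is the reading consistent with
the verbal description; both assignments are runnable. Abundances are
continuous and deterministic; negative outputs are clipped at zero and
flagged.

## Parameters and defaults

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| `k_cleav, k_assoc, k_cond` | second-order rate constants (volume/molecule/time) | 1.0 | exact mass-action constants are free parameters of the model; unit values define the simulation timescale |
| `k_diss` | complex dissociation (1/time) | 0.1 | complexes mostly resolve productively (k_cond [B] >> k_diss at unit food concentration) |
| `delta, rho` | membrane thickness, lipid density | 2.0, 10.0 (lineage fixtures) | gives a finite-membrane daughter ratio q ~ 0.30, away from the thin-membrane idealization |
| `theta` | division threshold (lipids) | 2e4 | theta/2 = 1e4 growth events per generation keeps division-timing noise near 1% |
| `g` | lipid batch per growth firing | 1 | exact channel |
| `L_perm` | permeability cutoff | 3 | food = monomers and dimers; catalysts (length >= 3) are entrapped |
| `k_cont` | lipid production per coupled catalyst | 0.27 (fixtures) | sets division-time pools of order 1e4 molecules so that synchronized division intervals are well resolved |
| `D_i` | Fick transport coefficient | 0.3 (fig9 fixture) | places the incumbent irrRAF in the transport-limited regime while leaving a rare newcomer near equilibrium |

## What the fixtures emulate

The named fixtures are minimal network topologies, not parameter matches
of any published figure: a single autocatalyst (minimal synchronization),
one irrRAF of two coupled SCCs plus inert species (synchronization with
heterogeneous levels and death by dilution), two rate-split irrRAFs with
only the fast one coupled (competition and stochastic extinction), and two
equal-rate irrRAFs on disjoint permeable foods (novelty uptake under
finite diffusion). Sequences are chosen freely; species counts of order
1e3-1e4 and 20-25 generations keep every stochastic check within seconds
to tens of seconds on one CPU. Real figure curves use unstated parameters,
so all figure-level claims are trend/property reproductions under the
fixtures' own documented parameters, never curve matches. What passing
tests show is therefore the phenomenology — synchronization when and only
when a coupled RAF is present, dilution of non-RAF species, dominance of
the fastest coupled irrRAF, latecomer catch-up only under finite
diffusion — not quantitative agreement with any particular wet or
published system.

## Numerical choices and degenerate inputs

* Waiting times use inversion of a single uniform; channel selection a
  second uniform (direct method). Zero total propensity jumps to the
  horizon and is a first-class outcome, as are "no division within the
  per-generation horizon" and event-cap truncation.
* `V_r = 0` (membrane filling the whole sphere) is an admissible boundary
  for the geometry functions; lipid counts below `(4/3) pi rho delta^3`
  raise a domain error. Geometry objects additionally require daughters
  (`theta/2`) to satisfy the bound.
* The closed-form inversion is verified against numeric root bracketing of
  the shell relation to 1e-10 relative error.
* Division uses exact multinomial draws per species; conservation
  (daughter1 + daughter2 + lost = mother) holds exactly.
* Synchronization is declared when every relative change of the division
  interval over the last 5 generations is below 5% (configurable);
  species survival classes use the OLS trend of log(count+1) with a
  +-0.05 per-generation dead band.
* irrRAF augmentation deduplicates by reaction-key sets; heuristic core
  search reports incompleteness rather than silently truncating.

## Known limitations

* No thermodynamics, backward or spontaneous reactions, no energy
  bookkeeping.
* No spatial structure inside the vesicle; division is strictly binary,
  spherical and threshold-triggered (no stochastic thresholds, shape
  dynamics, or membrane rupture).
* Exterior reactions are not simulated (external products are treated as
  instantaneously diluted).
* The population maps are deterministic; no agent-based population
  simulation couples back into the SSA.
* Catalytic activity is structure-independent (uniform `p`), as in the
  base model.
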