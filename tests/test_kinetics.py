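"""SSA channel construction, propensities, and statistical calibration
against Poisson and ODE oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from protocell.chemistry import Chemistry, KineticParams, Reaction, Species
from protocell.container import ContainerGeometry
from protocell.fixtures import make_fixture
from protocell.kinetics import (
    STATUS_DIVISION,
    STATUS_EXHAUSTED,
    STATUS_HORIZON,
    build_channels,
    divide,
    initial_state,
    inject_species,
    propensities,
    simulate_segment,
    ssa_step,
)


def cond(a, b, cats, **kw):
    return Reaction(kind="condensation", substrates=(a, b), products=(a + b,),
                    catalysts=frozenset(cats), **kw)


def cleav(s, cut, cats=()):
    return Reaction(kind="cleavage", substrates=(s,),
                    products=(s[:cut], s[cut:]), cut_position=cut,
                    catalysts=frozenset(cats))


def fixed_geometry(C=50.0, theta=1e9):
    # no coupled species in most tests -> V_r constant during a segment
    return ContainerGeometry(delta=1.0, rho=1.0, theta=theta, C=C)


@pytest.fixture
def linear_chem():
    """Buffered foods AA, BB and buffered catalyst AAA (L_perm = 4) feed a
    tracked product AABB through condensation; a second catalyzed cleavage
    degrades AABB back into the bath.  All channel rates are constant or
    first-order: the exact mean obeys a linear ODE."""
    chem = Chemistry(alphabet=("A", "B"), L_max=4, L_perm=4)
    for s in ("AA", "BB", "AAA"):
        chem.add_species(Species(s, is_food=True, external_concentration=1.0))
    chem.add_species(Species("AABB"))
    chem.reactions.append(cond("AA", "BB", ["AAA"]))
    chem.reactions.append(cleav("AABB", 2, cats=["AAA"]))
    return chem


class TestBuildChannels:
    def test_channel_counting_instantaneous(self):
        chem = Chemistry(alphabet=("A", "B"), L_max=4, L_perm=3)
        for s in ("A", "B", "AB"):
            chem.add_species(Species(s, is_food=True,
                                     external_concentration=1.0))
        chem.add_species(Species("ABA"))
        chem.add_species(Species("ABAB"))
        chem.reactions.append(cond("AB", "A", ["ABA"]))
        chem.reactions.append(cleav("ABAB", 2, cats=["ABA"]))
        cs = build_channels(chem)
        # 3 condensation steps + 1 cleavage + 1 growth
        assert cs.n_channels == 5
        assert "AB:ABA" in cs.index

    def test_fick_mode_adds_two_channels_per_permeable_species(self):
        chem, _ = make_fixture("fig9_permeable")
        inst = build_channels(chem, mode="instantaneous")
        fick = build_channels(chem, mode="fick")
        n_perm = sum(1 for s in chem.species if chem.is_permeable(s))
        assert fick.n_channels == inst.n_channels + 2 * n_perm
        assert not fick.buffered.any()

    def test_uncatalyzed_reactions_make_no_channels(self, toy_chem):
        cs = build_channels(toy_chem)
        assert cs.n_channels == 1  # only the lipid-growth channel
        assert cs.labels == ["lipid_growth"]


class TestPropensities:
    def test_zero_count_zero_propensity(self):
        chem = Chemistry(alphabet=("A", "B"), L_max=4, L_perm=3)
        for s in ("AB", "A"):
            chem.add_species(Species(s, is_food=True,
                                     external_concentration=1.0))
        chem.add_species(Species("ABA"))
        chem.reactions.append(cond("AB", "A", ["ABA"]))
        cs = build_channels(chem)
        st = initial_state(cs, fixed_geometry())
        a = propensities(cs, st)
        assert a[:3].sum() == 0.0  # no catalyst molecules yet

    def test_bimolecular_scales_inversely_with_volume(self):
        chem = Chemistry(alphabet=("A", "B"), L_max=8, L_perm=3)
        chem.add_species(Species("AAB", initial_count=10))
        chem.add_species(Species("ABAB", initial_count=20))
        chem.add_species(Species("ABABAAB"))
        chem.reactions.append(cond("ABAB", "AAB", ["AAB"]))
        cs = build_channels(chem)
        st1 = initial_state(cs, fixed_geometry(C=50.0))
        st2 = initial_state(cs, fixed_geometry(C=50.0))
        # find C with double the volume
        from protocell.container import internal_volume, shell_mass
        v1 = st1.geometry.volume
        from scipy.optimize import brentq
        r2 = (2 * v1 / (4 / 3 * math.pi)) ** (1 / 3)
        st2.geometry.C = shell_mass(r2, 1.0, 1.0)
        a1 = propensities(cs, st1)
        a2 = propensities(cs, st2)
        assoc = cs.labels.index("assoc ABAB+AAB")
        assert a2[assoc] == pytest.approx(a1[assoc] / 2, rel=1e-9)

    def test_buffered_participant_uses_external_concentration(self, linear_chem):
        cs = build_channels(linear_chem)
        st = initial_state(cs, fixed_geometry())
        a = propensities(cs, st)
        assoc = cs.labels.index("assoc AA+AAA")
        # a = k [AA] V [AAA] V / V = k [AA][AAA] V
        assert a[assoc] == pytest.approx(st.geometry.volume, rel=1e-12)

    def test_fick_transport_balances_at_equal_concentration(self):
        chem, geo = make_fixture("fig9_permeable")
        cs = build_channels(chem, mode="fick")
        st = initial_state(cs, geo)
        V, A = st.geometry.volume, st.geometry.area
        i = cs.index["AA"]
        st.counts[i] = int(round(cs.ext[i] * V))
        a = propensities(cs, st)
        jin = cs.labels.index("in AA")
        jout = cs.labels.index("out AA")
        # equal inside/outside concentration -> zero expected net flux
        assert a[jin] == pytest.approx(a[jout], rel=2e-2)


class TestSsaStep:
    def test_no_channels_jumps_to_horizon(self, toy_chem):
        cs = build_channels(toy_chem)
        st = initial_state(cs, fixed_geometry())
        traj, out = simulate_segment(st, cs, seed=0, t_end=5.0,
                                     stop_at_division=False)
        assert traj.status == STATUS_EXHAUSTED
        assert out.t == 5.0
        np.testing.assert_array_equal(out.counts, st.counts)

    def test_single_step_advances_one_event(self, linear_chem):
        cs = build_channels(linear_chem)
        st = initial_state(cs, fixed_geometry())
        out = ssa_step(st, cs, seed=1)
        assert out.t > st.t
        assert np.abs(out.counts - st.counts).sum() == 1  # one complex made

    def test_event_count_is_poisson(self, linear_chem):
        # restrict to the constant-rate association channel by removing the
        # downstream steps
        chem = linear_chem
        chem.reactions = chem.reactions[:1]
        chem.kinetic_defaults = KineticParams(k_diss=0.0, k_cond=0.0)
        cs = build_channels(chem)
        st = initial_state(cs, fixed_geometry())
        lam = propensities(cs, st).sum()
        T = 2.0
        runs = 1000
        counts = []
        for seed in range(runs):
            traj, _ = simulate_segment(st, cs, seed=seed, t_end=T,
                                       stop_at_division=False)
            counts.append(traj.n_events)
        counts = np.asarray(counts)
        mean = lam * T
        assert abs(counts.mean() - mean) < 3 * math.sqrt(mean / runs)
        # waiting times of a constant-rate channel are Exponential(lam)
        traj, _ = simulate_segment(st, cs, seed=99, t_end=200.0,
                                   stop_at_division=False, record_every=1,
                                   max_records=200_000)
        waits = np.diff(traj.t[:-1])  # drop the final horizon point
        stat = kstest(waits, "expon", args=(0, 1 / lam))
        assert stat.pvalue > 0.01

    def test_linear_channel_means_match_ode(self, linear_chem):
        cs = build_channels(linear_chem)
        st = initial_state(cs, fixed_geometry())
        V = st.geometry.volume
        p = linear_chem.kinetic_defaults
        c0 = p.k_assoc * 1.0 * 1.0 * V          # complex formation rate
        kout = p.k_diss + p.k_cond * 1.0        # complex resolution
        kdeg = p.k_cleav * 1.0                  # AABB degradation

        def rhs(t, y):
            cx, prod = y
            return [c0 - kout * cx,
                    p.k_cond * cx - kdeg * prod]

        T = 4.0
        checkpoints = np.linspace(0.4, T, 10)
        sol = solve_ivp(rhs, (0, T), [0.0, 0.0], t_eval=checkpoints,
                        rtol=1e-10, atol=1e-12)
        runs = 600
        ix = cs.index["AA:AAA"]
        ip = cs.index["AABB"]
        acc = np.zeros((2, len(checkpoints)))
        sq = np.zeros((2, len(checkpoints)))
        for seed in range(runs):
            prev = st
            for k, tk in enumerate(checkpoints):
                _, prev = simulate_segment(prev, cs, seed=seed * 101 + k,
                                           t_end=tk, stop_at_division=False)
                vals = (prev.counts[ix], prev.counts[ip])
                acc[:, k] += vals
                sq[:, k] += np.square(vals)
        mean = acc / runs
        sd = np.sqrt(np.maximum(sq / runs - mean**2, 1e-12))
        se = sd / math.sqrt(runs)
        for row, target in zip(mean, sol.y):
            assert np.all(np.abs(row - target) < 3 * np.maximum(se[0], 1e-6)
                          + 3 * se.max())

    def test_identical_seeds_identical_trajectories(self):
        chem, geo = make_fixture("single_autocatalyst")
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        t1, s1 = simulate_segment(st, cs, seed=5, record_every=50)
        t2, s2 = simulate_segment(st, cs, seed=5, record_every=50)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(t1.t, t2.t)
        assert s1.t == s2.t and s1.geometry.C == s2.geometry.C


class TestSegmentsAndGrowth:
    def test_autocatalytic_fixture_reaches_division(self):
        chem, geo = make_fixture("single_autocatalyst")
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        traj, out = simulate_segment(st, cs, seed=3)
        assert traj.status == STATUS_DIVISION
        assert out.geometry.C >= geo.theta

    def test_division_time_matches_ode_prediction(self):
        # deterministic limit: x' = lam x, C' = k_cont x; division when the
        # accumulated lipids reach theta/2
        chem, geo = make_fixture("single_autocatalyst")
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        p = chem.kinetic_defaults
        lam_eff = (p.k_cond / (p.k_cond + p.k_diss)) * p.k_assoc
        k_cont = chem.species["ABA"].k_cont

        def rhs(t, y):
            free, cx, C = y
            return [
                -p.k_assoc * free + (p.k_diss + p.k_cond) * cx
                + p.k_cond * cx,
                p.k_assoc * free - (p.k_diss + p.k_cond) * cx,
                k_cont * free,
            ]

        def hit(t, y):
            return y[2] - geo.theta
        hit.terminal = True
        hit.direction = 1
        sol = solve_ivp(rhs, (0, 100), [4000.0, 0.0, geo.C], events=hit,
                        rtol=1e-10, atol=1e-8)
        t_pred = sol.t_events[0][0]
        times = []
        for seed in range(5):
            traj, out = simulate_segment(st, cs, seed=seed)
            times.append(out.t)
        assert np.mean(times) == pytest.approx(t_pred, rel=0.10)

    def test_growth_channel_mean_is_poisson(self):
        # one coupled species held constant (no reactions): C(t) - C(0)
        # is Poisson(k_cont * x * T)
        chem = Chemistry(alphabet=("A", "B"), L_max=4, L_perm=3)
        chem.add_species(Species("AAB", k_cont=0.2, initial_count=50))
        cs = build_channels(chem)
        geo = ContainerGeometry(delta=1.0, rho=1.0, theta=1e9, C=1000.0)
        T, runs = 5.0, 1000
        lam = 0.2 * 50 * T
        gained = []
        for seed in range(runs):
            st = initial_state(cs, geo)
            _, out = simulate_segment(st, cs, seed=seed, t_end=T,
                                      stop_at_division=False)
            gained.append(out.geometry.C - 1000.0)
        gained = np.asarray(gained)
        assert abs(gained.mean() - lam) < 3 * math.sqrt(lam / runs)

    def test_no_coupled_species_container_constant(self, linear_chem):
        cs = build_channels(linear_chem)
        st = initial_state(cs, fixed_geometry())
        traj, out = simulate_segment(st, cs, seed=0, t_end=1.0,
                                     stop_at_division=False)
        assert out.geometry.C == st.geometry.C
        assert traj.status == STATUS_HORIZON

    def test_monomer_mass_conserved_in_closed_system(self):
        # fick mode with zero diffusion = closed vesicle: the total monomer
        # inventory (weighting each species by its length) is invariant
        chem, geo = make_fixture("fig3_coupled_scc")
        for sp in chem.species.values():
            sp.diffusion_D = 0.0
            if sp.is_food:
                sp.initial_count = 2000
        cs = build_channels(chem, mode="fick")
        st = initial_state(cs, geo)
        weights = np.array([len(n.replace(":", "")) for n in cs.names])
        traj, out = simulate_segment(st, cs, seed=2, t_end=0.5,
                                     stop_at_division=False,
                                     record_every=100)
        masses = traj.counts @ weights
        assert np.all(masses == masses[0])


class TestInjectAndDivide:
    def test_inject_adds_copies(self):
        chem, geo = make_fixture("fig9_permeable")
        cs = build_channels(chem, mode="fick")
        st = initial_state(cs, geo)
        out = inject_species(st, cs, "BAA", 5)
        assert out.counts[cs.index["BAA"]] == 5
        assert st.counts[cs.index["BAA"]] == 0

    def test_inject_unknown_species_raises(self):
        chem, geo = make_fixture("single_autocatalyst")
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        with pytest.raises(KeyError):
            inject_species(st, cs, "BBBB", 1)
        with pytest.raises(ValueError):
            inject_species(st, cs, "ABA", 0)

    def test_divide_requires_threshold(self):
        chem, geo = make_fixture("single_autocatalyst")
        cs = build_channels(chem)
        st = initial_state(cs, geo)  # C = theta/2
        with pytest.raises(ValueError, match="threshold"):
            divide(st, cs, np.random.default_rng(0))

    def test_divide_conserves_every_species(self):
        chem, geo = make_fixture("fig3_coupled_scc")
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        st.geometry.C = geo.theta
        rng = np.random.default_rng(0)
        daughter, sib, lost = divide(st, cs, rng)
        np.testing.assert_array_equal(
            daughter.counts + sib + lost, st.counts
        )
        assert daughter.geometry.C == geo.theta / 2
        assert daughter.generation == st.generation + 1

    def test_divide_empty_mother_gives_empty_daughters(self):
        chem, geo = make_fixture("single_autocatalyst")
        chem.species["ABA"].initial_count = 0
        cs = build_channels(chem)
        st = initial_state(cs, geo)
        st.geometry.C = geo.theta
        daughter, sib, lost = divide(st, cs, np.random.default_rng(0))
        assert daughter.counts.sum() == 0 and sib.sum() == 0
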