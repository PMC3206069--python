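"""Coalescent simulator: closed forms, oracle equivalence, invariants."""

import numpy as np
import pytest
from scipy import stats as sps

import msprime

from divabc import coalescent as C
from divabc.demography import LocusSpec, ParameterVector, compile_epochs
from divabc.popgen import summarize_matrix


def msprime_demography(p: ParameterVector) -> "msprime.Demography":
    """Translate a parameter vector into an msprime demography (oracle)."""
    gen = p.gen_years
    dem = msprime.Demography()
    scen, mode = p.model[:2], p.model[2]
    Tsp = p.T_split / gen
    if mode == "C":
        dem.add_population(name="A", initial_size=p.N_hal)
        dem.add_population(name="B", initial_size=p.N_lyr)
    elif mode == "E":
        Tg = Tsp / 2
        dem.add_population(name="A", initial_size=p.N_hal,
                           growth_rate=np.log(p.N_hal / (p.N_anc / 2)) / Tg)
        dem.add_population(name="B", initial_size=p.N_lyr,
                           growth_rate=np.log(p.N_lyr / (p.N_anc / 2)) / Tg)
    else:
        Tb = p.T_b / gen
        dem.add_population(
            name="A", initial_size=p.N_hal,
            growth_rate=np.log(1.0 / p.bottleneck_f) / Tb)
        dem.add_population(name="B", initial_size=p.N_lyr)
    dem.add_population(name="anc", initial_size=p.N_anc)
    mab = p.M_AB / (4 * p.N_hal)
    mba = p.M_BA / (4 * p.N_hal)
    if scen == "CM":
        dem.set_migration_rate(source="A", dest="B", rate=mab)
        dem.set_migration_rate(source="B", dest="A", rate=mba)
    elif scen == "AM":
        Ti = p.T_iso / gen
        dem.add_migration_rate_change(time=Ti, source="A", dest="B",
                                      rate=mab)
        dem.add_migration_rate_change(time=Ti, source="B", dest="A",
                                      rate=mba)
    elif scen == "SC":
        Tsc = p.T_SC / gen
        dem.set_migration_rate(source="A", dest="B", rate=mab)
        dem.set_migration_rate(source="B", dest="A", rate=mba)
        dem.add_migration_rate_change(time=Tsc, source="A", dest="B",
                                      rate=0)
        dem.add_migration_rate_change(time=Tsc, source="B", dest="A",
                                      rate=0)
    if mode == "E":
        dem.add_population_parameters_change(
            time=Tsp / 2, population="A", initial_size=p.N_anc / 2,
            growth_rate=0)
        dem.add_population_parameters_change(
            time=Tsp / 2, population="B", initial_size=p.N_anc / 2,
            growth_rate=0)
    if mode == "B":
        dem.add_population_parameters_change(
            time=p.T_b / gen, population="A", initial_size=p.N_hal,
            growth_rate=0)
    dem.add_population_split(time=Tsp, derived=["A", "B"], ancestral="anc")
    dem.sort_events()
    return dem


def _panmictic(N=10_000, theta=5.0, n=(5, 5), L=1, rho_over_theta=0.0):
    mu = theta / (4 * N * L)
    p = ParameterVector("SIC", N, N, N, 0.0)
    spec = LocusSpec("l", n[0], n[1], L, mu, rho_over_theta)
    return compile_epochs(p), spec


class TestClosedForms:
    """Single-deme reductions against neutral coalescent expectations."""

    def test_expected_S_and_pi(self, workspace):
        theta, n = 5.0, 10
        ep, spec = _panmictic(theta=theta, n=(5, 5))
        reps = 5000
        S = np.empty(reps)
        piL = np.empty(reps)
        for r in range(reps):
            ns, *_ = C._run_kernel(ep, spec, 10_000 + r, workspace)
            S[r] = ns
            d = workspace.dA[:ns] + workspace.dB[:ns]
            piL[r] = (2.0 * d * (n - d) / (n * (n - 1))).sum()
        a1 = sum(1 / i for i in range(1, n))
        assert S.mean() == pytest.approx(theta * a1, rel=0.05)
        assert piL.mean() == pytest.approx(theta, rel=0.05)

    def test_tmrca_pair_is_standard_exponential(self, workspace):
        # n=2, one deme: TMRCA (in 4N units) ~ Exp(mean 1/2)
        ep, spec = _panmictic(theta=0.0, n=(2, 2))
        spec = LocusSpec("l", 2, 2, 1, 0.0)
        # use 2+2 but merge both demes at t=0; take t_end as the grand
        # TMRCA of 4 lineages instead: compare with the sum of
        # exponentials via simulation would be indirect -- use a true
        # pair by making one species carry the only lineages
        reps = 4000
        t = np.empty(reps)
        p = ParameterVector("SIC", 10_000, 10_000, 10_000, 0.0)
        ep = compile_epochs(p)
        spec = LocusSpec("l", 2, 2, 1, 0.0)
        for r in range(reps):
            t[r] = C._run_kernel(ep, spec, 50_000 + r, workspace)[2]
        # TMRCA of 4 lineages: mean = (1/2)*(1 - 1/4)*2 = 0.75 in 4N units
        assert t.mean() == pytest.approx(0.75, rel=0.05)

    def test_mu_zero_gives_no_sites(self, workspace):
        ep, spec = _panmictic(theta=0.0)
        spec = LocusSpec("l", 5, 5, 100, 0.0)
        for r in range(20):
            ns, *_ = C._run_kernel(ep, spec, r, workspace)
            assert ns == 0


class TestOracleEquivalence:
    """Distributional agreement with msprime on matched scenarios."""

    SCENARIOS = [
        ParameterVector("SIC", 50_000, 80_000, 200_000, 600_000),
        ParameterVector("CMC", 60_000, 40_000, 150_000, 1_000_000,
                        M_AB=5, M_BA=2),
        ParameterVector("AMC", 50_000, 50_000, 300_000, 1_200_000,
                        M_AB=8, M_BA=8, T_iso=400_000),
        ParameterVector("SCC", 50_000, 50_000, 300_000, 1_200_000,
                        M_AB=8, M_BA=8, T_SC=300_000),
        ParameterVector("SIE", 90_000, 90_000, 400_000, 800_000),
    ]

    @pytest.mark.parametrize("p", SCENARIOS, ids=lambda p: p.model)
    def test_site_count_distribution_matches(self, p, workspace):
        reps = 1200
        mu, L = 5e-8, 100
        spec = LocusSpec("l", 8, 8, L, mu, rho_over_theta=1.0)
        ep = compile_epochs(p)
        mine = np.empty(reps)
        for r in range(reps):
            mine[r], *_ = C._run_kernel(ep, spec, 3000 + r, workspace)
        dem = msprime_demography(p)
        other = np.empty(reps)
        anc = msprime.sim_ancestry(
            samples={"A": 4, "B": 4}, demography=dem,
            recombination_rate=mu, sequence_length=L,
            discrete_genome=False, num_replicates=reps, random_seed=11)
        for i, ts in enumerate(anc):
            mts = msprime.sim_mutations(ts, rate=mu, discrete_genome=False,
                                        random_seed=30_000 + i)
            other[i] = mts.num_sites
        assert sps.ks_2samp(mine, other).pvalue > 0.01


class TestSimulatorInvariants:
    def test_deterministic_under_seed(self, workspace):
        p = ParameterVector("CMC", 60_000, 40_000, 150_000, 1_000_000,
                            M_AB=5, M_BA=2)
        spec = LocusSpec("l", 6, 6, 200, 2e-8)
        ep = compile_epochs(p)
        a = C.simulate_locus(ep, spec, 42, workspace)
        b = C.simulate_locus(ep, spec, 42, workspace)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.bits, b.bits)
        c = C.simulate_locus(ep, spec, 43, workspace)
        assert (len(c.positions) != len(a.positions)
                or not np.array_equal(c.positions, a.positions))

    def test_haplotype_matrix_consistent_with_counts(self, workspace):
        p = ParameterVector("SIC", 80_000, 80_000, 300_000, 500_000)
        spec = LocusSpec("l", 7, 9, 150, 5e-8)
        sim = C.simulate_locus(compile_epochs(p), spec, 7, workspace)
        H = C.haplotype_matrix(sim)
        assert H.shape == (16, sim.n_sites)
        np.testing.assert_array_equal(H[:7].sum(axis=0), sim.dA)
        np.testing.assert_array_equal(H[7:].sum(axis=0), sim.dB)

    def test_ms_block_format(self, workspace):
        p = ParameterVector("SIC", 80_000, 80_000, 300_000, 500_000)
        spec = LocusSpec("l", 3, 3, 50, 5e-8)
        sim = C.simulate_locus(compile_epochs(p), spec, 3, workspace)
        block = C.ms_block(sim)
        lines = block.strip().split("\n")
        assert lines[0] == "//"
        assert lines[1] == f"segsites: {sim.n_sites}"
        if sim.n_sites:
            assert lines[2].startswith("positions:")
            assert len(lines) == 3 + 6
            assert set("".join(lines[3:])) <= {"0", "1"}

    def test_deep_split_completes_lineage_sorting(self, workspace):
        # ancient split: no shared polymorphism, plenty of fixed
        # differences
        p = ParameterVector("SIC", 20_000, 20_000, 20_000, 50_000_000)
        spec = LocusSpec("l", 6, 6, 200, 1e-8)
        ep = compile_epochs(p)
        ss_total, sf_total = 0, 0
        for r in range(300):
            ns, *_ = C._run_kernel(ep, spec, r, workspace)
            v = C.locus_stats_vector(
                (workspace.dA[:ns], workspace.dB[:ns]), 6, 6, 200)
            ss_total += v[8]
            sf_total += v[9]
        assert ss_total == 0
        assert sf_total > 300  # >1 fixed difference per replicate

    def test_migration_reduces_fst_monotonically(self, workspace):
        means = []
        loci = [LocusSpec(f"l{j}", 8, 8, 150, 3e-8) for j in range(4)]
        for M in (0.0, 2.0, 10.0):
            model = "SIC" if M == 0 else "CMC"
            p = ParameterVector(model, 50_000, 50_000, 200_000, 1_500_000,
                                M_AB=M, M_BA=M)
            f = []
            for r in range(400):
                per_locus, _ = C.simulate_dataset(p, loci, 900 + r,
                                                  workspace)
                v, _ = summarize_matrix(per_locus[:, :12])
                f.append(v[14])  # fst_mean
            means.append(np.mean(f))
        assert means[0] > means[1] > means[2]

    def test_panmictic_pool_gives_fst_near_zero(self, workspace):
        # the two "species" drawn from one panmictic population
        ep, spec = _panmictic(theta=5.0, n=(8, 8), L=100)
        spec = LocusSpec("l", 8, 8, 100, 5.0 / (4 * 10_000 * 100))
        f = []
        for r in range(2000):
            ns, *_ = C._run_kernel(ep, spec, 600 + r, workspace)
            v = C.locus_stats_vector(
                (workspace.dA[:ns], workspace.dB[:ns]), 8, 8, 100)
            if np.isfinite(v[7]):
                f.append(v[7])
        assert abs(np.mean(f)) < 0.02

    def test_tajima_d_near_zero_under_neutrality(self, workspace):
        ep, spec = _panmictic(theta=5.0, n=(10, 10), L=100)
        spec = LocusSpec("l", 10, 10, 100, 5.0 / (4 * 10_000 * 100))
        d = []
        for r in range(5000):
            ns, *_ = C._run_kernel(ep, spec, 100_000 + r, workspace)
            v = C.locus_stats_vector(
                (workspace.dA[:ns], workspace.dB[:ns]), 10, 10, 100)
            # pooled-sample D via the 20-lineage counts
            if np.isfinite(v[4]):
                d.append(v[4])
        assert abs(np.mean(d)) < 0.05

    def test_dataset_reproducible_and_finite(self, workspace):
        p = ParameterVector("SCB", 150_000, 150_000, 500_000, 1_600_000,
                            M_AB=10, M_BA=10, T_SC=800_000, T_b=400_000,
                            bottleneck_f=0.2)
        loci = [LocusSpec(f"l{j}", 10, 12, 300, 7e-9) for j in range(5)]
        v1 = C.dataset_summary(p, loci, 123, workspace)
        v2 = C.dataset_summary(p, loci, 123, workspace)
        np.testing.assert_array_equal(v1, v2)
        assert np.all(np.isfinite(v1))
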