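import numpy as np
import pytest
from scipy import stats

from hetsis import (
    Network,
    RecoveryRates,
    exact_qs_oracle,
    homogeneous_rates,
    quasistationary_run,
)
from hetsis.rates import SpreadingScheme
from hetsis.sim import EpidemicState, gillespie_step, moments_from_histogram

from conftest import complete, hetero_rates, ring, star

UNIFORM1 = SpreadingScheme("uniform", 1.0)


def replicate_qs(net, rates, scheme, n_rep, seed0, **qs):
    rhos, chis = [], []
    for r in range(n_rep):
        est = quasistationary_run(net, rates, scheme, seed=seed0 + r, **qs)
        rhos.append(est.rho)
        chis.append(est.chi)
    return np.array(rhos), np.array(chis)


class TestGillespieStep:
    def test_single_clock_waiting_time_is_exponential(self):
        # node 0 is isolated and infected with delta = 1: the only event is
        # its recovery after an Exp(1) time
        net = Network.from_edges(3, [(1, 2)])
        rates = homogeneous_rates(3, 1.0)
        rng = np.random.default_rng(0)
        state = EpidemicState(infected={0})
        dts = [gillespie_step(state, net, rates, UNIFORM1, rng).time for _ in range(10_000)]
        assert abs(np.mean(dts) - 1.0) < 3 / np.sqrt(10_000)
        assert all(
            gillespie_step(state, net, rates, UNIFORM1, rng).n_infected == 0
            for _ in range(20)
        )

    def test_dyad_events_split_evenly(self, dyad):
        # infected node with delta = 1 and one susceptible neighbor at
        # lambda = 1: recovery and transmission each have probability 1/2
        rates = homogeneous_rates(2, 1.0)
        rng = np.random.default_rng(1)
        n_trials = 4000
        n_infections = sum(
            gillespie_step(EpidemicState(infected={0}), dyad, rates, UNIFORM1, rng).n_infected
            == 2
            for _ in range(n_trials)
        )
        sd = np.sqrt(n_trials * 0.25)
        assert abs(n_infections - n_trials / 2) < 3 * sd

    def test_fully_infected_network_recovers_proportionally_to_delta(self):
        net = complete(3)
        rates = RecoveryRates(np.array([1.0, 2.0, 7.0]))
        rng = np.random.default_rng(2)
        n_trials = 5000
        counts = np.zeros(3)
        for _ in range(n_trials):
            new = gillespie_step(EpidemicState(infected={0, 1, 2}), net, rates, UNIFORM1, rng)
            (recovered,) = {0, 1, 2} - new.infected
            counts[recovered] += 1
        expected = np.array([1, 2, 7]) / 10 * n_trials
        sds = np.sqrt(expected * (1 - np.array([1, 2, 7]) / 10))
        assert np.all(np.abs(counts - expected) < 3.5 * sds)

    def test_interevent_times_exponential_with_total_rate(self, ring4):
        # frozen configuration {0, 1}: total rate = sum of recoveries plus
        # lambda per (infected, susceptible-neighbor) pair
        rates = RecoveryRates(np.array([0.5, 1.5, 1.0, 2.0]))
        lam = 0.8
        scheme = SpreadingScheme("uniform", lam)
        total = 0.5 + 1.5 + 2 * lam  # nodes 0,1 infected; edges 1-2 and 0-3 active
        rng = np.random.default_rng(3)
        state = EpidemicState(infected={0, 1})
        dts = [gillespie_step(state, ring4, rates, scheme, rng).time for _ in range(10_000)]
        ks = stats.kstest(dts, stats.expon(scale=1 / total).cdf)
        assert ks.pvalue > 0.01

    def test_absorbing_state_rejected(self, ring4):
        with pytest.raises(ValueError):
            gillespie_step(EpidemicState(infected=set()), ring4,
                           homogeneous_rates(4, 1.0), UNIFORM1, np.random.default_rng(0))


class TestHistogramMoments:
    def test_degenerate_histogram_has_zero_chi(self):
        hist = np.zeros(10)
        hist[4] = 1.0
        _, _, chi = moments_from_histogram(hist)
        assert chi == 0.0

    def test_two_point_histogram_arithmetic(self):
        # P(2) = P(4) = 1/2: <n> = 3, <n^2> = 10, chi = 1/3
        hist = np.zeros(6)
        hist[2] = hist[4] = 0.5
        m1, m2, chi = moments_from_histogram(hist)
        assert (m1, m2) == (3.0, 10.0)
        assert chi == pytest.approx(1 / 3)


class TestExactOracle:
    def test_single_node_point_mass(self):
        net = Network.from_edges(1, [])
        est = exact_qs_oracle(net, homogeneous_rates(1, 2.0), UNIFORM1)
        assert est.rho == 1.0
        assert est.chi == 0.0

    def test_vertex_transitive_symmetry(self):
        # homogeneous rates on a ring: QS marginals identical across nodes
        net = ring(5)
        est = exact_qs_oracle(net, homogeneous_rates(5, 1.0),
                              SpreadingScheme("uniform", 0.9))
        pi = est.meta["state_probs"]
        marginals = np.zeros(5)
        for s in range(1, 2**5):
            for i in range(5):
                if (s >> i) & 1:
                    marginals[i] += pi[s - 1]
        assert np.allclose(marginals, marginals[0], atol=1e-10)

    def test_size_cap_enforced(self):
        net = ring(13)
        with pytest.raises(ValueError):
            exact_qs_oracle(net, homogeneous_rates(13, 1.0), UNIFORM1)


class TestQuasistationaryRun:
    def test_vanishing_lambda_concentrates_on_one_infected(self, ring4):
        est = quasistationary_run(
            ring4, homogeneous_rates(4, 1.0), SpreadingScheme("uniform", 1e-4),
            relax_time=3000, avg_time=10000, sample_interval=0.5, seed=0,
            p_store_update=0.2, n_store=50,
        )
        assert est.qs_histogram[1] > 0.99
        assert est.rho == pytest.approx(0.25, rel=0.01)
        assert est.chi < 0.05

    @pytest.mark.parametrize(
        "maker,scheme_kind,lam,rate_seed",
        [
            ("dyad", "uniform", 1.0, None),        # homogeneous baseline
            ("ring4", "uniform", 1.2, 10),         # heterogeneous rates
            ("path5", "uniform", 1.5, 11),
            ("star5", "contact_process", 3.0, 12),
            ("complete6", "contact_process", 2.5, 13),
            ("complete6", "uniform", 0.8, 14),
        ],
    )
    def test_simulator_matches_exact_oracle(self, maker, scheme_kind, lam, rate_seed,
                                            dyad, ring4, path5, star5):
        net = {"dyad": dyad, "ring4": ring4, "path5": path5, "star5": star5,
               "complete6": complete(6)}[maker]
        n = net.n_nodes
        rates = (homogeneous_rates(n, 1.0) if rate_seed is None
                 else hetero_rates(n, rate_seed))
        scheme = SpreadingScheme(scheme_kind, lam)
        oracle = exact_qs_oracle(net, rates, scheme)
        # short windows need a faster-refreshing store than the production
        # default, else restarts over-sample the initial configuration; too
        # fast an update rate feeds the recent trajectory back into the
        # restarts, so p is kept moderate
        rhos, chis = replicate_qs(
            net, rates, scheme, n_rep=8, seed0=100 * (rate_seed or 1),
            relax_time=500, avg_time=12000, sample_interval=0.5,
            p_store_update=0.2, n_store=50,
        )
        sem_rho = rhos.std(ddof=1) / np.sqrt(len(rhos))
        sem_chi = chis.std(ddof=1) / np.sqrt(len(chis))
        assert abs(rhos.mean() - oracle.rho) < 3 * sem_rho + 1e-3
        assert abs(chis.mean() - oracle.chi) < 3 * sem_chi + 1e-3

    def test_rate_rescaling_leaves_qs_law_invariant(self, ring4):
        # multiplying all rates by c and dividing all time windows by c is a
        # pure change of time units: identical random stream, identical law
        # c is a power of two so every scaled float is exact and the two
        # runs consume an identical random stream
        rates = hetero_rates(4, 21)
        c = 4.0
        base = dict(n_store=50, sample_interval=0.5, seed=5)
        a = quasistationary_run(
            ring4, rates, SpreadingScheme("uniform", 1.1),
            relax_time=200, avg_time=4000, p_store_update=0.01, **base,
        )
        b = quasistationary_run(
            ring4, RecoveryRates(rates.delta * c), SpreadingScheme("uniform", 1.1 * c),
            relax_time=200 / c, avg_time=4000 / c, p_store_update=0.01 * c,
            n_store=50, sample_interval=0.5 / c, seed=5,
        )
        assert np.allclose(a.qs_histogram, b.qs_histogram)
        assert a.rho == pytest.approx(b.rho)
        assert a.chi == pytest.approx(b.chi)

    def test_observable_ranges(self):
        net = ring(30)
        est = quasistationary_run(
            net, homogeneous_rates(30, 1.0), SpreadingScheme("uniform", 0.8),
            relax_time=100, avg_time=2000, seed=2,
        )
        assert 0 < est.rho <= 1
        assert est.chi >= 0
        assert est.qs_histogram[0] == 0
        assert est.qs_histogram.sum() == pytest.approx(1.0)

    def test_short_averaging_window_warns(self, ring4):
        with pytest.warns(UserWarning, match="samples"):
            quasistationary_run(
                ring4, homogeneous_rates(4, 1.0), SpreadingScheme("uniform", 1.0),
                relax_time=10, avg_time=50, seed=0,
            )
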