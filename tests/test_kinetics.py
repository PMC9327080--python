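"""Population extraction, net hop counting, sequential-model fits, bootstrap."""

import numpy as np
import pytest
import scipy.linalg

from sehop import kinetics as K
from sehop import synth
from sehop.propagator import Ensemble, Trajectory


def toy_ensemble(series_list, t=None, hops=None, labels=("S0", "S1", "S2", "T1", "T2", "T3")):
    if t is None:
        t = np.arange(series_list[0].size, dtype=float)
    trajs = [
        Trajectory(t=t, active_spinfree=np.asarray(s, int),
                   hops=(hops or {}).get(i, []))
        for i, s in enumerate(series_list)
    ]
    return Ensemble(trajectories=trajs, t=t, n_states_spinfree=len(labels),
                    state_labels=labels)


class TestPopulations:
    def test_single_trajectory_constant_state(self):
        ens = toy_ensemble([np.full(11, 2)])
        pops = K.spinfree_populations(ens)
        assert np.all(pops.P[:, 2] == 1.0)
        assert np.allclose(pops.P.sum(axis=1), 1.0)

    def test_t0_populations_equal_initial_split(self):
        ens = synth.gen_kinetic_ensemble(n_traj=200, t_max=10.0, seed=3)
        pops = K.spinfree_populations(ens)
        split = pops.P[0, pops.labels.index("S2")]
        n2 = sum(tr.active_spinfree[0] == 2 for tr in ens.trajectories)
        assert split == pytest.approx(n2 / 200)

    def test_markov_ensemble_matches_matrix_exponential(self):
        taus = {("S2", "S1"): 50.0, ("S1", "T"): 80.0, ("S2", "T"): 200.0}
        n = 2000
        ens = synth.gen_kinetic_ensemble(taus=taus, n_traj=n, dt=2.0,
                                         t_max=400.0, seed=11)
        pops = K.spinfree_populations(ens)
        agg = pops.aggregate({"S2": ("S2",), "S1": ("S1",), "T": ("T1", "T2", "T3")})
        Kmat = K.rate_matrix(list(taus), list(taus.values()), ["S2", "S1", "T"])
        p2 = agg.P[0, 0]
        init = np.array([p2, 1 - p2, 0.0])
        for i in [50, 100, 200]:
            ref = scipy.linalg.expm(Kmat * agg.t[i]) @ init
            se = np.sqrt(np.maximum(ref * (1 - ref), 1e-12) / n)
            assert np.all(np.abs(agg.P[i] - ref) <= 3 * se + 1e-9)

    def test_inconsistent_grid_raises(self):
        tr = Trajectory(t=np.arange(5.0), active_spinfree=np.zeros(5, int))
        ens = Ensemble(trajectories=[tr], t=np.arange(7.0), n_states_spinfree=6)
        with pytest.raises(K.KineticsError):
            K.spinfree_populations(ens)


class TestNetHops:
    def test_back_and_forth_cancellation(self):
        hops = {0: [(1.0, 2, 1, True), (2.0, 1, 2, True), (3.0, 2, 1, True)]}
        ens = toy_ensemble([np.array([2, 1, 2, 1, 1])], hops=hops)
        mat = K.net_hops(ens)
        assert mat[2, 1] == 1 and mat[1, 2] == -1

    def test_empty_logs_zero_matrix(self):
        ens = toy_ensemble([np.full(5, 2)])
        assert np.all(K.net_hops(ens) == 0)

    def test_random_sequences_match_bruteforce_tally(self, rng):
        hops = {}
        expect = np.zeros((6, 6))
        series = []
        for i in range(20):
            log = []
            state = 2
            s = [state]
            for step in range(30):
                if rng.random() < 0.2:
                    new = int(rng.integers(0, 6))
                    if new != state:
                        log.append((float(step), state, new, True))
                        expect[state, new] += 1
                        state = new
                s.append(state)
            hops[i] = log
            series.append(np.array(s))
        ens = toy_ensemble(series, hops=hops)
        assert np.array_equal(K.net_hops(ens), expect - expect.T)


class TestKineticFit:
    def test_noiseless_three_channel_recovery(self):
        taus = {("S2", "S1"): 257.0, ("S1", "T"): 282.0, ("S2", "T"): 1236.0}
        labels = ["S2", "S1", "T"]
        t = np.linspace(0, 1000, 501)
        P = K.solve_compartments(list(taus), list(taus.values()),
                                 [0.85, 0.15, 0.0], t, labels)
        pops = K.PopulationSeries(t=t, P=P, labels=tuple(labels))
        fit = K.fit_kinetic_model(pops, topology=tuple(taus))
        for pair, true in taus.items():
            assert fit.tau[pair] == pytest.approx(true, rel=1e-3)

    def test_single_compartment_decay_exact(self):
        t = np.linspace(0, 500, 200)
        P = np.column_stack([np.exp(-t / 123.0), 1 - np.exp(-t / 123.0)])
        pops = K.PopulationSeries(t=t, P=P, labels=("S", "T"))
        fit = K.fit_kinetic_model(pops, topology=(("S", "T"),))
        assert fit.tau[("S", "T")] == pytest.approx(123.0, rel=1e-6)

    def test_fit_invariant_under_grid_refinement(self):
        taus = {("S2", "S1"): 100.0, ("S1", "T"): 150.0, ("S2", "T"): 400.0}
        for n in (200, 800):
            t = np.linspace(0, 800, n)
            P = K.solve_compartments(list(taus), list(taus.values()),
                                     [0.9, 0.1, 0.0], t, ["S2", "S1", "T"])
            pops = K.PopulationSeries(t=t, P=P, labels=("S2", "S1", "T"))
            fit = K.fit_kinetic_model(pops, topology=tuple(taus))
            for pair, true in taus.items():
                assert fit.tau[pair] == pytest.approx(true, rel=1e-3)

    def test_triplet_closure_of_fitted_model(self):
        taus = {("S2", "S1"): 257.0, ("S1", "T"): 282.0, ("S2", "T"): 1236.0}
        t = np.linspace(0, 1000, 101)
        P = K.solve_compartments(list(taus), list(taus.values()),
                                 [0.85, 0.15, 0.0], t, ["S2", "S1", "T"])
        assert np.allclose(P[:, 2], 1.0 - P[:, 0] - P[:, 1], atol=1e-10)

    def test_empty_source_compartment_raises(self):
        t = np.linspace(0, 100, 50)
        P = np.column_stack([np.zeros_like(t), np.exp(-t / 50), 1 - np.exp(-t / 50)])
        pops = K.PopulationSeries(t=t, P=P, labels=("S2", "S1", "T"))
        with pytest.raises(K.KineticsError):
            K.fit_kinetic_model(pops, topology=(("S2", "S1"), ("S1", "T")))


class TestBootstrap:
    def test_identical_trajectories_zero_error(self):
        t = np.arange(0.0, 200.0, 2.0)
        s = (t > 60).astype(int) * 3 + (t <= 60).astype(int) * 2
        # all trajectories identical: resampling cannot change the fit
        ens = toy_ensemble([s.copy() for _ in range(20)], t=t)
        errs = K.bootstrap_errors(ens, topology=(("S2", "T"),), n_boot=20, seed=1)
        assert errs[("S2", "T")] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        ens = synth.gen_kinetic_ensemble(n_traj=40, dt=4.0, t_max=600.0, seed=5)
        e1 = K.bootstrap_errors(ens, n_boot=12, seed=9)
        e2 = K.bootstrap_errors(ens, n_boot=12, seed=9)
        assert e1 == e2

    def test_error_scales_with_ensemble_size(self):
        """Doubling the ensemble shrinks the bootstrap SE by about sqrt(2)."""
        taus = {("S2", "S1"): 100.0, ("S1", "T"): 150.0, ("S2", "T"): 500.0}
        ratios = []
        for rep in range(6):
            small = synth.gen_kinetic_ensemble(taus=taus, n_traj=60, dt=4.0,
                                               t_max=800.0, seed=100 + rep)
            big = synth.gen_kinetic_ensemble(taus=taus, n_traj=240, dt=4.0,
                                             t_max=800.0, seed=200 + rep)
            es = K.bootstrap_errors(small, n_boot=40, seed=rep)
            eb = K.bootstrap_errors(big, n_boot=40, seed=rep)
            ratios.append(es[("S2", "S1")] / eb[("S2", "S1")])
        # 4x trajectories -> expect ratio ~2
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.35)


class TestTripletFraction:
    def test_matches_closed_form_evaluation(self):
        taus = {("S2", "S1"): 257.0, ("S1", "T"): 282.0, ("S2", "T"): 1236.0}
        frac = K.triplet_fraction(taus, {"S2": 0.85, "S1": 0.15}, 1000.0)
        k2 = 1 / 257.0 + 1 / 1236.0
        k1 = 1 / 282.0
        s2 = 0.85 * np.exp(-k2 * 1000)
        s1 = (0.15 * np.exp(-k1 * 1000)
              + 0.85 * (1 / 257.0) / (k1 - k2)
              * (np.exp(-k2 * 1000) - np.exp(-k1 * 1000)))
        assert frac == pytest.approx(1 - s1 - s2, abs=1e-10)
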