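"""Vibronic-model backend: diagonalization, SOC scalar, Wigner sampling."""

import numpy as np
import pytest

from sehop import model as M
from sehop.constants import KB_EV

from .conftest import make_random_model


class TestEvaluate:
    def test_uncoupled_origin_returns_vertical_energies(self, default_model):
        m = default_model
        m0 = M.VibronicModel(omega=m.omega, epsilon=m.epsilon,
                             kappa=m.kappa, lam=np.zeros_like(m.lam),
                             soc_cart=m.soc_cart)
        res = M.evaluate(m0, np.zeros(m.n_modes))
        assert np.allclose(res.energies_spinfree, m.epsilon, atol=1e-14)

    def test_default_model_origin_matches_vertical_excitation_table(self, default_model):
        # ADC(2) vertical energies of the 6SeGua-like chromophore
        res = M.evaluate(default_model, np.zeros(3))
        assert res.energies_spinfree[1] == pytest.approx(2.76)
        assert res.energies_spinfree[2] == pytest.approx(3.61)
        assert res.energies_spinfree[3] == pytest.approx(2.55)
        assert res.energies_spinfree[4] == pytest.approx(2.63)

    def test_energies_match_bruteforce_diagonalization(self, rng):
        m = make_random_model(rng, n_modes=2, n_singlets=2)
        for _ in range(100):
            q = rng.normal(0, 1.5, 2)
            res = M.evaluate(m, q)
            ref = np.linalg.eigvalsh(m.diabatic_potential(q))
            assert np.allclose(res.energies_spinfree, ref, atol=1e-12)

    def test_gradients_match_finite_differences(self, default_model):
        q0 = np.array([0.3, -0.4, 0.25])
        res = M.evaluate(default_model, q0)
        h = 1e-4
        for j in range(3):
            dq = np.zeros(3)
            dq[j] = h
            num = (
                M.evaluate(default_model, q0 + dq).energies_spinfree
                - M.evaluate(default_model, q0 - dq).energies_spinfree
            ) / (2 * h)
            assert np.allclose(num, res.gradients[:, j], atol=1e-6)

    def test_degenerate_diabats_give_unitary_invariant_energies(self):
        # two degenerate coupled states: energies must not depend on the
        # unitary frame chosen for the degenerate pair
        lam = np.zeros((3, 3, 1))
        lam[1, 2, 0] = lam[2, 1, 0] = 0.08
        m = M.VibronicModel(omega=[0.1], epsilon=[0.0, 2.0, 2.0],
                            kappa=[[0.0], [0.05], [-0.05]], lam=lam,
                            soc_cart=np.zeros((3, 0, 3)), n_singlets=3,
                            n_triplets=0)
        q = np.array([0.7])
        v = m.diabatic_potential(q)
        theta = 0.37
        R = np.eye(3)
        R[1:, 1:] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        e1 = np.linalg.eigvalsh(v)
        e2 = np.linalg.eigvalsh(R.T @ v @ R)
        assert np.allclose(e1, e2, atol=1e-12)

    def test_dimension_mismatch_raises(self, default_model):
        with pytest.raises(ValueError):
            M.evaluate(default_model, np.zeros(2))

    def test_non_hermitian_model_rejected(self):
        lam = np.zeros((2, 2, 1))
        lam[0, 1, 0] = 0.1  # asymmetric on purpose
        with pytest.raises(M.ModelConfigurationError):
            M.VibronicModel(omega=[0.1], epsilon=[0.0, 1.0], kappa=np.zeros((2, 1)),
                            lam=lam, soc_cart=np.zeros((2, 0, 3)),
                            n_singlets=2, n_triplets=0)

    def test_spin_hamiltonian_is_hermitian(self, default_model):
        h = default_model.full_spin_hamiltonian(np.array([0.2, -0.1, 0.4]))
        assert np.allclose(h, h.conj().T)

    def test_soc_vanishes_between_singlets_and_within_sublevels(self, default_model):
        h = default_model.soc_spin_matrix()
        ns = default_model.n_singlets
        assert np.allclose(h[:ns, :ns], 0.0)
        sf = default_model.spinfree_of_component()
        for t in range(ns, default_model.n_states):
            cols = np.nonzero(sf == t)[0]
            assert np.allclose(h[np.ix_(cols, cols)], 0.0)


class TestEffectiveSOC:
    @pytest.mark.parametrize(
        "elements,expected",
        [
            (np.zeros((3, 3)), 0.0),
            ([3.0, 4.0, 0.0], 5.0),
            (np.ones(9), 3.0),
            ([], 0.0),
        ],
    )
    def test_root_sum_square(self, elements, expected):
        assert M.effective_soc(elements) == pytest.approx(expected)

    def test_invariant_under_global_phase(self, rng):
        el = rng.normal(0, 1, 9) + 1j * rng.normal(0, 1, 9)
        phase = np.exp(1j * 1.234)
        assert M.effective_soc(el * phase) == pytest.approx(M.effective_soc(el))


class TestWignerSampling:
    def test_zero_temperature_variance(self, default_model):
        pts = M.sample_wigner(default_model, 10000, seed=2)
        q = np.stack([p.q for p in pts])
        p = np.stack([p.p for p in pts])
        se = 0.5 * np.sqrt(2.0 / 10000)
        assert np.all(np.abs(q.var(axis=0) - 0.5) < 3 * se)
        assert np.all(np.abs(p.var(axis=0) - 0.5) < 3 * se)

    def test_thermal_variance_ratio(self, default_model):
        T = 300.0
        n = 20000
        cold = M.sample_wigner(default_model, n, temperature=0.0, seed=3)
        hot = M.sample_wigner(default_model, n, temperature=T, seed=3)
        qc = np.stack([p.q for p in cold]).var(axis=0)
        qh = np.stack([p.q for p in hot]).var(axis=0)
        expected = 1.0 / np.tanh(default_model.omega / (2 * KB_EV * T))
        assert np.allclose(qh / qc, expected, rtol=0.06)

    def test_deterministic_under_seed(self, default_model):
        a = M.sample_wigner(default_model, 5, seed=9)
        b = M.sample_wigner(default_model, 5, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.q, y.q) and np.array_equal(x.p, y.p)

    def test_nonpositive_frequency_rejected(self, default_model):
        m = default_model
        with pytest.raises(M.ModelConfigurationError):
            bad = M.VibronicModel(omega=[-0.1], epsilon=[0.0, 1.0],
                                  kappa=np.zeros((2, 1)), lam=np.zeros((2, 2, 1)),
                                  soc_cart=np.zeros((2, 0, 3)), n_singlets=2,
                                  n_triplets=0)
            M.sample_wigner(bad, 10)


class TestConfigIO:
    def test_yaml_roundtrip(self, default_model, tmp_path):
        path = tmp_path / "model.yaml"
        M.save_model(default_model, path)
        m2 = M.load_model(path)
        assert np.allclose(m2.epsilon, default_model.epsilon)
        assert np.allclose(m2.soc_cart, default_model.soc_cart)
        res1 = M.evaluate(default_model, np.array([0.1, 0.2, 0.3]))
        res2 = M.evaluate(m2, np.array([0.1, 0.2, 0.3]))
        assert np.allclose(res1.energies_spinfree, res2.energies_spinfree)

    def test_unknown_unit_rejected(self, default_model, tmp_path):
        d = M.model_to_dict(default_model)
        d["units"]["energy"] = "furlongs"
        with pytest.raises(M.ModelConfigurationError):
            M.model_from_dict(d)
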