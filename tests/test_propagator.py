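"""Surface-hopping propagator: conservation laws, decoherence, hop mechanics."""

import numpy as np
import pytest

from sehop import model as M
from sehop.constants import EV_PER_HARTREE, HBAR_EV_FS
from sehop.model import PhaseSpacePoint, VibronicModel
from sehop.propagator import (
    apply_decoherence,
    diagonal_state_index,
    propagate,
    propagate_ensemble,
    rescale_after_hop,
)


@pytest.fixture(scope="module")
def ic():
    return PhaseSpacePoint(q=np.array([0.5, -0.3, 0.2]), p=np.array([0.4, 0.1, -0.2]))


def strip_couplings(m, soc=True, lam=True, kappa=False):
    return VibronicModel(
        omega=m.omega, epsilon=m.epsilon,
        kappa=np.zeros_like(m.kappa) if kappa else m.kappa,
        lam=np.zeros_like(m.lam) if lam else m.lam,
        soc_cart=np.zeros_like(m.soc_cart) if soc else m.soc_cart,
        mu0=m.mu0, mu_ee=m.mu_ee,
    )


class TestAdiabaticLimits:
    def test_zero_couplings_no_hops_and_energy_conserved(self, default_model, ic):
        m0 = strip_couplings(default_model, kappa=True)
        idx = diagonal_state_index(m0, ic.q, 2)
        tr = propagate(ic, m0, initial_state=idx, t_max=1000.0, seed=3)
        assert tr.hops == []
        assert np.all(tr.active == idx)
        etot = tr.ekin + tr.epot
        assert etot.max() - etot.min() < 1e-3  # eV over 1 ps

    def test_zero_soc_conserves_spin(self, default_model, ic):
        m0 = strip_couplings(default_model, soc=True, lam=False)
        idx = diagonal_state_index(m0, ic.q, 2)  # start in S2
        tr = propagate(ic, m0, initial_state=idx, t_max=300.0, seed=4)
        # active state never acquires triplet character
        assert set(np.unique(tr.active_spinfree)) <= {0, 1, 2}

    def test_electronic_norm_conserved(self, default_model, ic):
        idx = diagonal_state_index(default_model, ic.q, 2)
        tr = propagate(ic, default_model, initial_state=idx, t_max=100.0, seed=5)
        assert np.allclose(tr.populations.sum(axis=1), 1.0, atol=1e-8)

    def test_spinfree_populations_sum_to_one(self, default_model, ic):
        idx = diagonal_state_index(default_model, ic.q, 2)
        tr = propagate(ic, default_model, initial_state=idx, t_max=50.0, seed=6)
        assert np.all((tr.active_spinfree >= 0)
                      & (tr.active_spinfree < default_model.n_states))

    def test_deterministic_under_seed(self, default_model, ic):
        idx = diagonal_state_index(default_model, ic.q, 2)
        t1 = propagate(ic, default_model, initial_state=idx, t_max=60.0, seed=7)
        t2 = propagate(ic, default_model, initial_state=idx, t_max=60.0, seed=7)
        assert np.array_equal(t1.active, t2.active)
        assert np.array_equal(t1.q, t2.q)

    def test_halving_electronic_substep_converged(self, default_model, ic):
        idx = diagonal_state_index(default_model, ic.q, 2)
        a = propagate(ic, default_model, initial_state=idx, t_max=50.0,
                      dt_el=0.02, seed=8)
        b = propagate(ic, default_model, initial_state=idx, t_max=50.0,
                      dt_el=0.01, seed=8)
        assert np.max(np.abs(a.populations[-1] - b.populations[-1])) < 1e-3


class TestDecoherence:
    def test_pure_active_state_is_fixed_point(self):
        c = np.array([0.0, 1.0, 0.0], dtype=complex)
        out = apply_decoherence(c, active=1, ekin=0.5, energies=[0.0, 1.0, 2.0])
        assert np.allclose(out, c)

    def test_norm_restored_exactly(self, rng):
        c = rng.normal(0, 1, 4) + 1j * rng.normal(0, 1, 4)
        c = c / np.linalg.norm(c)
        out = apply_decoherence(c, active=2, ekin=0.3,
                                energies=[0.0, 1.0, 2.0, 3.0], dt=0.5)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_two_state_damping_closed_form(self):
        # |dE| = 1 eV, ekin = 1 hartree, dt = 0.5 fs
        ekin = 1.0 * EV_PER_HARTREE
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        out = apply_decoherence(c, active=1, ekin=ekin, energies=[0.0, 1.0],
                                C=0.1, dt=0.5)
        tau = HBAR_EV_FS / 1.0 * (1.0 + 0.1 * EV_PER_HARTREE / ekin)
        expected = np.sqrt(0.5) * np.exp(-0.5 / tau)
        assert abs(out[0]) == pytest.approx(expected, abs=1e-12)

    def test_zero_kinetic_energy_stays_finite(self):
        c = np.array([0.6, 0.8], dtype=complex)
        out = apply_decoherence(c, active=1, ekin=0.0, energies=[0.0, 1.0])
        assert np.all(np.isfinite(out))


class TestHopRescaling:
    def test_isoenergetic_hop_keeps_momenta(self):
        p = np.array([1.0, -2.0])
        p2, ok = rescale_after_hop(p, 1.0, 1.0, 0.5)
        assert ok and np.allclose(p2, p)

    def test_frustrated_upward_hop_rejected(self):
        p = np.array([0.5])
        p2, ok = rescale_after_hop(p, 1.0, 2.0, ekin=0.3)
        assert not ok and np.allclose(p2, p)

    def test_downward_hop_energy_balance(self):
        # 0.5 eV downward from ekin 0.5 eV -> new ekin exactly 1.0 eV
        omega = np.array([0.1])
        p = np.array([np.sqrt(2 * 0.5 / omega[0])])
        p2, ok = rescale_after_hop(p, 1.0, 0.5, ekin=0.5)
        assert ok
        assert 0.5 * omega[0] * p2[0] ** 2 == pytest.approx(1.0, abs=1e-12)


class TestLandauZener:
    def test_hop_fraction_matches_landau_zener(self):
        """1D two-state avoided crossing: surface-hopping transfer fractions
        agree with the analytic Landau-Zener probability (evaluated with the
        velocity at the crossing) within 3 binomial standard errors at 1e4
        trajectories per incident momentum."""
        k, c, off, omega = 0.1, 0.025, 0.3, 0.1
        m = VibronicModel(
            omega=[omega], epsilon=[0.0, off], kappa=[[0.0], [-k]],
            lam=np.zeros((2, 2, 1)), soc_cart=np.zeros((2, 0, 3)),
            n_singlets=2, n_triplets=0, eta=np.array([[0.0, c], [c, 0.0]]),
            harmonic_baseline=False,
        )
        B = 10000
        for p0 in (1.5, 2.0, 2.8, 3.6, 4.5):
            p_cross = np.sqrt(p0**2 + 2 * c / omega)
            v = omega * p_cross / HBAR_EV_FS
            t_need = (off / k + 12.0) / (omega * p0 / HBAR_EV_FS)
            res = propagate_ensemble(
                m, np.full((B, 1), -6.0), np.full((B, 1), p0),
                np.zeros(B, dtype=int), dt_nuc=0.25, dt_el=0.05,
                t_max=t_need, seed=1, record=False, decoherence_c=None,
            )
            frac = (res["active_final"] == 1).mean()
            p_lz = np.exp(-2 * np.pi * c**2 / (HBAR_EV_FS * v * k))
            se = np.sqrt(p_lz * (1 - p_lz) / B)
            assert abs(frac - p_lz) <= 3 * se, (p0, frac, p_lz)


class TestValidation:
    def test_invalid_initial_state_rejected(self, default_model, ic):
        with pytest.raises(ValueError):
            propagate(ic, default_model, initial_state=99, t_max=1.0, seed=0)

    def test_dt_el_must_divide_dt_nuc(self, default_model, ic):
        with pytest.raises(ValueError):
            propagate(ic, default_model, initial_state=0, dt_nuc=0.5,
                      dt_el=0.3, t_max=1.0, seed=0)
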