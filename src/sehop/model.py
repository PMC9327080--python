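"""Linear vibronic coupling (LVC) model with spin–orbit coupling.

This module provides the surrogate electronic-structure backend used by the
dynamics and observable pipeline: a diabatic potential matrix linear in
dimensionless mass–frequency-scaled normal-mode displacements, covering three
singlet and three triplet spin-free states of a 6-selenoguanine-like
chromophore.  The individual M_S sublevels of each triplet are carried
explicitly, so the full spin basis has ``n_singlets + 3 * n_triplets``
components (12 for the default model).

The diabatic Hamiltonian is

    V_nm(q) = delta_nm * (V0(q) + eps_n + sum_j kappa_nj q_j)
              + (1 - delta_nm) * sum_j lam_nmj q_j            (same multiplicity)

with harmonic baseline ``V0(q) = sum_j omega_j q_j^2 / 2``.  Spin–orbit
coupling enters as geometry-independent complex matrix elements between
singlets and triplet M_S sublevels, assembled from Cartesian components
(H_x, H_y, H_z) through the standard spherical-component relations, which
preserve the effective-SOC norm ``sum_MS |<S|H|T,MS>|^2 = |H_x|^2 + |H_y|^2 + |H_z|^2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import EV_PER_CM1, EV_PER_HARTREE, HBAR_EV_FS, KB_EV

STATE_LABELS = ("S0", "S1", "S2", "T1", "T2", "T3")


class ModelConfigurationError(ValueError):
    """Raised for inconsistent or non-Hermitian model definitions."""


@dataclass
class VibronicModel:
    """LVC-style diabatic model for coupled singlet/triplet manifolds.

    Parameters
    ----------
    omega : (n_modes,) mode frequencies in eV.
    epsilon : (n_states,) vertical energies of the spin-free diabatic states
        at the origin, in eV; ordered singlets first, then triplets.
    kappa : (n_states, n_modes) intra-state linear gradients in eV.
    lam : (n_states, n_states, n_modes) linear diabatic couplings in eV;
        symmetric in the first two indices and nonzero only within one
        spin multiplicity.
    soc_cart : (n_singlets, n_triplets, 3) complex Cartesian spin–orbit
        components (x, y, z) in eV.
    mu0 : (n_states, 3) transition dipoles from the ground state (a.u.).
    mu_ee : (n_states, n_states, 3) excited-to-excited transition dipoles
        (a.u.), used for excited-state absorption.
    n_singlets, n_triplets : manifold sizes (spin-free states).
    harmonic_baseline : include V0(q); switch off for scattering-type
        (free-particle) test models.
    hole_site_weights, particle_site_weights : optional (n_states, n_sites)
        per-diabatic-configuration site weights of the transition density,
        consumed by the charge-transfer analysis.
    """

    omega: np.ndarray
    epsilon: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    soc_cart: np.ndarray
    n_singlets: int = 3
    n_triplets: int = 3
    mu0: np.ndarray | None = None
    mu_ee: np.ndarray | None = None
    masses: np.ndarray | None = None
    eta: np.ndarray | None = None  # constant diabatic couplings (same multiplicity)
    harmonic_baseline: bool = True
    hole_site_weights: np.ndarray | None = None
    particle_site_weights: np.ndarray | None = None
    site_labels: tuple = ()

    def __post_init__(self):
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.soc_cart = np.asarray(self.soc_cart, dtype=complex)
        ns, nm = self.n_states, self.n_modes
        if self.epsilon.shape != (ns,):
            raise ModelConfigurationError(
                f"epsilon must have length n_singlets+n_triplets={ns}"
            )
        if self.kappa.shape != (ns, nm):
            raise ModelConfigurationError("kappa must be (n_states, n_modes)")
        if self.lam.shape != (ns, ns, nm):
            raise ModelConfigurationError("lam must be (n_states, n_states, n_modes)")
        if not np.allclose(self.lam, np.swapaxes(self.lam, 0, 1)):
            raise ModelConfigurationError("lam must be symmetric (Hermitian model)")
        sing = slice(0, self.n_singlets)
        trip = slice(self.n_singlets, ns)
        if np.any(self.lam[sing, trip, :] != 0.0):
            raise ModelConfigurationError(
                "lam couples states of different multiplicity; use soc_cart instead"
            )
        if self.soc_cart.shape != (self.n_singlets, self.n_triplets, 3):
            raise ModelConfigurationError("soc_cart must be (n_singlets, n_triplets, 3)")
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)
            if self.eta.shape != (ns, ns) or not np.allclose(self.eta, self.eta.T):
                raise ModelConfigurationError("eta must be symmetric (n_states, n_states)")
            if np.any(self.eta[sing, trip] != 0.0):
                raise ModelConfigurationError("eta couples different multiplicities")
            if np.any(np.diag(self.eta) != 0.0):
                raise ModelConfigurationError("eta must be purely off-diagonal")
        if self.masses is None:
            self.masses = np.ones(nm)
        if np.argmin(self.epsilon[: self.n_singlets]) != 0 or np.any(
            self.epsilon[0] >= self.epsilon[1:]
        ):
            raise ModelConfigurationError("ground state must be strictly lowest at origin")

    # -- sizes -------------------------------------------------------------
    @property
    def n_modes(self) -> int:
        return self.omega.size

    @property
    def n_states(self) -> int:
        return self.n_singlets + self.n_triplets

    @property
    def n_spin(self) -> int:
        """Number of spin components (triplet M_S sublevels counted)."""
        return self.n_singlets + 3 * self.n_triplets

    # -- Hamiltonian assembly ---------------------------------------------
    def diabatic_potential(self, q: np.ndarray) -> np.ndarray:
        """Spin-free diabatic potential matrix V(q), shape (..., n_states, n_states)."""
        q = np.asarray(q, dtype=float)
        if q.shape[-1] != self.n_modes:
            raise ValueError(
                f"q has {q.shape[-1]} modes, model expects {self.n_modes}"
            )
        v0 = 0.0
        if self.harmonic_baseline:
            v0 = 0.5 * np.sum(self.omega * q**2, axis=-1)
        diag = self.epsilon + q @ self.kappa.T  # (..., n_states)
        v = np.einsum("nmj,...j->...nm", self.lam, q)
        if self.eta is not None:
            v = v + self.eta
        idx = np.arange(self.n_states)
        v[..., idx, idx] = diag + v0[..., None] if self.harmonic_baseline else diag
        return v

    def diabatic_gradient_matrices(self) -> np.ndarray:
        """Constant part of dV/dq_j, shape (n_modes, n_states, n_states).

        The harmonic-baseline contribution ``omega_j q_j`` (diagonal in state
        space) is geometry dependent and added separately by callers.
        """
        g = np.transpose(self.lam, (2, 0, 1)).copy()
        idx = np.arange(self.n_states)
        g[:, idx, idx] = self.kappa.T
        return g

    def soc_spin_matrix(self) -> np.ndarray:
        """SOC block in the diabatic spin basis, shape (n_spin, n_spin), Hermitian.

        Spin basis ordering: singlets, then for each triplet the M_S = -1, 0, +1
        sublevels.  Couplings are built from Cartesian components via

            <S|H|T,+1> = -(H_x + i H_y)/sqrt(2)
            <S|H|T, 0> =  H_z
            <S|H|T,-1> =  (H_x - i H_y)/sqrt(2)
        """
        n = self.n_spin
        h = np.zeros((n, n), dtype=complex)
        for s in range(self.n_singlets):
            for t in range(self.n_triplets):
                hx, hy, hz = self.soc_cart[s, t]
                base = self.n_singlets + 3 * t
                h[s, base + 0] = (hx - 1j * hy) / np.sqrt(2.0)  # M_S = -1
                h[s, base + 1] = hz                             # M_S = 0
                h[s, base + 2] = -(hx + 1j * hy) / np.sqrt(2.0)  # M_S = +1
        return h + h.conj().T

    def spin_expand(self, mat_spinfree: np.ndarray) -> np.ndarray:
        """Expand an (..., n_states, n_states) spin-free matrix to the spin basis.

        Each triplet spin-free state is replicated over its three sublevels;
        off-diagonal elements couple only equal M_S.
        """
        idx = self.spinfree_of_component()
        ms = self.ms_of_component()
        out = mat_spinfree[..., idx[:, None], idx[None, :]].copy()
        out[..., ms[:, None] != ms[None, :]] = 0.0
        return out

    def spinfree_of_component(self) -> np.ndarray:
        """Spin-free state index of each spin-basis component."""
        return np.array(
            list(range(self.n_singlets))
            + [self.n_singlets + t for t in range(self.n_triplets) for _ in range(3)]
        )

    def ms_of_component(self) -> np.ndarray:
        """M_S quantum number of each spin-basis component (0 for singlets)."""
        return np.array(
            [0] * self.n_singlets + [m for _ in range(self.n_triplets) for m in (-1, 0, 1)]
        )

    def full_spin_hamiltonian(self, q: np.ndarray) -> np.ndarray:
        """Total diabatic Hamiltonian in the spin basis: V(q) expanded + SOC."""
        return self.spin_expand(self.diabatic_potential(q)) + self.soc_spin_matrix()


@dataclass
class ElectronicStructureResult:
    """Spin-free adiabatic quantities at a single geometry.

    energies_spinfree are sorted ascending within each multiplicity block;
    ``eigvecs`` holds the diabatic-to-adiabatic rotation per multiplicity
    block (block diagonal over singlets/triplets), and ``soc_matrix`` the
    full spin-basis coupling block rotated into this spin-free adiabatic
    basis.  ``overlap_prev`` is the overlap of the current spin-free
    eigenvectors with those of a previous geometry (identity when no
    reference is given).
    """

    energies_spinfree: np.ndarray
    gradients: np.ndarray
    eigvecs: np.ndarray
    soc_matrix: np.ndarray
    dipoles: np.ndarray | None
    overlap_prev: np.ndarray


@dataclass
class PhaseSpacePoint:
    """A sampled nuclear phase-space point in dimensionless coordinates."""

    q: np.ndarray
    p: np.ndarray
    seed_id: int = 0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.p))):
            raise ValueError("phase-space point has non-finite entries")
        if self.q.shape != self.p.shape:
            raise ValueError("q and p dimensions differ")


def _align_eigvecs(vecs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign/phase by maximal diagonal overlap with ``ref``."""
    ov = ref.conj().T @ vecs
    phases = np.diag(ov)
    signs = np.where(np.abs(phases) > 0, np.sign(phases.real + (phases.real == 0)), 1.0)
    return vecs * signs


def evaluate(
    model: VibronicModel,
    q: np.ndarray,
    prev: ElectronicStructureResult | None = None,
) -> ElectronicStructureResult:
    """Diagonalize the spin-free diabatic blocks at geometry ``q``.

    Returns adiabatic energies (ascending within each multiplicity),
    analytic Hellmann–Feynman gradients, the SOC matrix rotated into the
    spin-free adiabatic basis, and the overlap with ``prev`` when given.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_modes,):
        raise ValueError(f"q must have shape ({model.n_modes},)")
    v = model.diabatic_potential(q)
    ns, nt = model.n_singlets, model.n_triplets
    blocks = [(0, ns), (ns, ns + nt)]
    energies = np.empty(model.n_states)
    vecs = np.zeros((model.n_states, model.n_states))
    for lo, hi in blocks:
        e, u = np.linalg.eigh(v[lo:hi, lo:hi])
        energies[lo:hi] = e
        vecs[lo:hi, lo:hi] = u
    if prev is not None:
        vecs_aligned = np.zeros_like(vecs)
        for lo, hi in blocks:
            vecs_aligned[lo:hi, lo:hi] = _align_eigvecs(
                vecs[lo:hi, lo:hi], prev.eigvecs[lo:hi, lo:hi]
            )
        vecs = vecs_aligned
        overlap = prev.eigvecs.T @ vecs
    else:
        overlap = np.eye(model.n_states)

    # Hellmann–Feynman: dE_n/dq_j = <n| dV/dq_j |n>  (+ harmonic baseline)
    gmats = model.diabatic_gradient_matrices()
    grads = np.einsum("in,jik,kn->nj", vecs, gmats, vecs)
    if model.harmonic_baseline:
        grads = grads + model.omega * q

    # rotate SOC into the spin-free adiabatic basis
    u_spin = model.spin_expand(vecs[None])[0]
    soc_ad = u_spin.conj().T @ model.soc_spin_matrix() @ u_spin

    dip = None
    if model.mu0 is not None:
        dip = np.einsum("in,id->nd", vecs, np.asarray(model.mu0, dtype=float))
    return ElectronicStructureResult(
        energies_spinfree=energies,
        gradients=grads,
        eigvecs=vecs,
        soc_matrix=soc_ad,
        dipoles=dip,
        overlap_prev=overlap,
    )


def effective_soc(elements) -> float:
    """Effective spin–orbit coupling: root of the summed squared magnitudes
    of all Cartesian components over all triplet M_S sublevels.

    ``elements`` may be any array-like (or mapping of values) of complex SOC
    matrix elements; the result has the units of the inputs.  Empty input
    gives 0.  The scalar is invariant under a global phase rotation.
    """
    if isinstance(elements, dict):
        elements = list(elements.values())
    arr = np.asarray(elements, dtype=complex).ravel()
    if arr.size == 0:
        return 0.0
    return float(np.sqrt(np.sum(np.abs(arr) ** 2)))


def sample_wigner(
    model: VibronicModel,
    n: int,
    temperature: float = 0.0,
    seed: int = 0,
) -> list[PhaseSpacePoint]:
    """Sample the (thermal) harmonic Wigner distribution of the ground state.

    In mass–frequency-scaled units the T = 0 Wigner function of each mode is
    a Gaussian with Var(q) = Var(p) = 1/2; at finite temperature both
    variances scale by coth(hbar*omega / 2 k_B T).  Deterministic under a
    fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if np.any(model.omega <= 0):
        raise ModelConfigurationError("Wigner sampling requires positive frequencies")
    factor = np.ones(model.n_modes)
    if temperature > 0:
        x = model.omega / (2.0 * KB_EV * temperature)
        factor = 1.0 / np.tanh(x)
    sigma = np.sqrt(0.5 * factor)
    rng = np.random.default_rng(seed)
    qs = rng.normal(0.0, 1.0, size=(n, model.n_modes)) * sigma
    ps = rng.normal(0.0, 1.0, size=(n, model.n_modes)) * sigma
    return [PhaseSpacePoint(q=qs[i], p=ps[i], seed_id=i) for i in range(n)]


# ----------------------------------------------------------------------------
# default model and config I/O
# ----------------------------------------------------------------------------

_UNIT_TO_EV = {"ev": 1.0, "cm-1": EV_PER_CM1, "cm^-1": EV_PER_CM1, "au": EV_PER_HARTREE,
               "hartree": EV_PER_HARTREE}


def default_model() -> VibronicModel:
    """Three-mode, six-state model emulating 6-selenoguanine photophysics.

    Vertical energies follow the ADC(2) column of the chromophore's gas-phase
    excitation table (S1 2.76, S2 3.61, T1 2.55, T2 2.63 eV; T3 placed at
    3.10 eV just below S2 so that the triplet density near the bright state
    matches the dynamics setup).  One tuning mode stands in for the C=Se
    stretch; two further modes carry the interstate couplings that open the
    S2/S1 internal-conversion funnel and modulate singlet–triplet crossings.
    SOC magnitudes are El-Sayed-rule-patterned inputs: ~120 cm^-1 between
    states of different orbital character (S1–T1, S2–T2), ~15 cm^-1 otherwise.
    """
    n_modes = 3
    omega = np.array([0.12, 0.08, 0.18])  # eV; C=Se stretch analogue + 2 coupling modes
    epsilon = np.array([0.0, 2.76, 3.61, 2.55, 2.63, 3.10])
    kappa = np.zeros((6, n_modes))
    # excited states displaced along the tuning mode (C=Se stretch analogue);
    # opposite S1/S2 gradients put the S2/S1 crossing seam within reach of the
    # Franck-Condon wavepacket, and the triplet gradients interleave the
    # singlet-triplet seams along the same coordinate
    kappa[1, 0] = +0.10   # S1 (n_Se pi*)
    kappa[2, 0] = -0.20   # S2 (pi pi*), strongest C=Se elongation
    kappa[3, 0] = -0.18   # T1 (pi pi*)
    kappa[4, 0] = -0.05   # T2 (n pi*)
    kappa[5, 0] = -0.15
    lam = np.zeros((6, 6, n_modes))

    def _set_lam(a, b, j, val):
        lam[a, b, j] = lam[b, a, j] = val

    _set_lam(1, 2, 1, 0.15)   # S1/S2 coupling mode -> conical intersection
    _set_lam(0, 1, 2, 0.02)
    _set_lam(3, 4, 1, 0.08)   # T1/T2 coupling
    _set_lam(4, 5, 2, 0.05)
    soc = np.zeros((3, 3, 3), dtype=complex)
    strong = 120.0 * EV_PER_CM1 / np.sqrt(3.0)
    weak = 15.0 * EV_PER_CM1 / np.sqrt(3.0)
    # indices: (singlet, triplet): S1=(1), S2=(2) -> soc rows 1,2; T1..T3 cols 0..2
    soc[1, 0] = strong * np.array([1.0, 1.0j, 1.0])   # S1-T1 (El-Sayed allowed)
    soc[2, 1] = strong * np.array([1.0, -1.0j, 1.0])  # S2-T2 (El-Sayed allowed)
    soc[1, 1] = weak * np.array([1.0, 0.0, 1.0j])
    soc[2, 0] = weak * np.array([1.0j, 1.0, 0.0])
    soc[1, 2] = weak * np.array([0.0, 1.0, 1.0])
    soc[2, 2] = weak * np.array([1.0, 1.0, 0.0])
    mu0 = np.zeros((6, 3))
    mu0[1] = [0.05, 0.0, 0.02]   # S0->S1 nearly dark
    mu0[2] = [1.20, 0.3, 0.0]    # S0->S2 bright (pi pi*)
    mu_ee = np.zeros((6, 6, 3))

    def _set_mu(a, b, vec):
        mu_ee[a, b] = vec
        mu_ee[b, a] = vec

    _set_mu(1, 2, [0.4, 0.0, 0.0])
    _set_mu(3, 4, [0.5, 0.1, 0.0])
    _set_mu(3, 5, [0.3, 0.0, 0.2])
    _set_mu(4, 5, [0.2, 0.2, 0.0])
    # transition-density site weights on (Se, Re) fragments per diabatic state
    hole = np.zeros((6, 2))
    part = np.zeros((6, 2))
    hole[1] = [1.0, 0.0]   # n_Se -> pi*: hole on Se
    part[1] = [0.1, 0.9]
    hole[2] = [0.75, 0.25]  # pi_Se -> pi*
    part[2] = [0.2, 0.8]
    hole[3] = [0.75, 0.25]
    part[3] = [0.2, 0.8]
    hole[4] = [1.0, 0.0]
    part[4] = [0.1, 0.9]
    hole[5] = [0.5, 0.5]
    part[5] = [0.3, 0.7]
    return VibronicModel(
        omega=omega,
        epsilon=epsilon,
        kappa=kappa,
        lam=lam,
        soc_cart=soc,
        mu0=mu0,
        mu_ee=mu_ee,
        hole_site_weights=hole,
        particle_site_weights=part,
        site_labels=("Se", "Re"),
    )


def model_to_dict(model: VibronicModel) -> dict:
    d = {
        "n_modes": int(model.n_modes),
        "n_singlets": int(model.n_singlets),
        "n_triplets": int(model.n_triplets),
        "units": {"energy": "eV", "dipole": "au"},
        "omega": model.omega.tolist(),
        "epsilon": model.epsilon.tolist(),
        "kappa": model.kappa.tolist(),
        "lambda": model.lam.tolist(),
        "soc_real": model.soc_cart.real.tolist(),
        "soc_imag": model.soc_cart.imag.tolist(),
        "masses": model.masses.tolist(),
        "harmonic_baseline": bool(model.harmonic_baseline),
    }
    if model.mu0 is not None:
        d["mu0"] = np.asarray(model.mu0).tolist()
    if model.mu_ee is not None:
        d["mu_ee"] = np.asarray(model.mu_ee).tolist()
    if model.hole_site_weights is not None:
        d["hole_site_weights"] = np.asarray(model.hole_site_weights).tolist()
        d["particle_site_weights"] = np.asarray(model.particle_site_weights).tolist()
        d["site_labels"] = list(model.site_labels)
    return d


def model_from_dict(d: dict) -> VibronicModel:
    unit = str(d.get("units", {}).get("energy", "eV")).lower()
    if unit not in _UNIT_TO_EV:
        raise ModelConfigurationError(f"unknown energy unit {unit!r}")
    scale = _UNIT_TO_EV[unit]
    soc = np.asarray(d["soc_real"], dtype=float) + 1j * np.asarray(
        d.get("soc_imag", np.zeros_like(np.asarray(d["soc_real"], dtype=float))),
        dtype=float,
    )
    kwargs = {}
    for key in ("mu0", "mu_ee", "hole_site_weights", "particle_site_weights"):
        if key in d:
            kwargs[key] = np.asarray(d[key], dtype=float)
    if "site_labels" in d:
        kwargs["site_labels"] = tuple(d["site_labels"])
    return VibronicModel(
        omega=np.asarray(d["omega"], dtype=float) * scale,
        epsilon=np.asarray(d["epsilon"], dtype=float) * scale,
        kappa=np.asarray(d["kappa"], dtype=float) * scale,
        lam=np.asarray(d["lambda"], dtype=float) * scale,
        soc_cart=soc * scale,
        n_singlets=int(d.get("n_singlets", 3)),
        n_triplets=int(d.get("n_triplets", 3)),
        masses=np.asarray(d["masses"], dtype=float) if "masses" in d else None,
        harmonic_baseline=bool(d.get("harmonic_baseline", True)),
        **kwargs,
    )


def save_model(model: VibronicModel, path) -> None:
    path = str(path)
    d = model_to_dict(model)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=1)
        else:
            yaml.safe_dump(d, fh)


def load_model(path) -> VibronicModel:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return model_from_dict(d)
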