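"""Trajectory surface hopping with internal conversion and intersystem crossing.

Dynamics run in the spin-mixed ("diagonal") representation: at every geometry
the full diabatic Hamiltonian — spin-free potential blocks expanded over the
triplet M_S sublevels plus the geometry-independent SOC block — is
diagonalized, and the classical nuclei move on one of its eigensurfaces.
Electronic amplitudes are propagated exactly in the model's global diabatic
frame with a short electronic substep (a local-diabatization scheme whose
interstate overlaps are analytic in a vibronic model), and hopping
probabilities follow the flux-based fewest-switches expression evaluated from
the step propagator.  Hops are accepted only when total energy can be
conserved by a uniform momentum rescaling; frustrated hops leave the momenta
unchanged by default.  Overcoherence is countered with the energy-based
decoherence correction (default parameter 0.1 a.u.) applied to the
spin-mixed amplitudes using the nuclear kinetic energy.

All propagation routines are vectorized over a batch of trajectories; the
scalar `propagate` API wraps the batched kernel with one RNG stream per
trajectory derived from ``(master seed, trajectory index)``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import EV_PER_HARTREE, HBAR_EV_FS
from .model import STATE_LABELS, VibronicModel

DECOHERENCE_C_AU = 0.1  # a.u. of energy (hartree)


class PropagationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory.

    ``active`` indexes spin-mixed (diagonal) states; ``active_spinfree``
    maps each step to the spin-free label (0..5 = S0,S1,S2,T1,T2,T3 for the
    default model) by maximal overlap, with triplet sublevels aggregated.
    ``hops`` holds (t_fs, from, to, accepted) tuples in spin-free labels;
    for dynamics trajectories the raw spin-mixed hop record is kept in
    ``hops_spinmixed``.  Synthetic ensembles may populate only ``t``,
    ``active_spinfree`` and ``hops``.
    """

    t: np.ndarray
    active_spinfree: np.ndarray
    hops: list = field(default_factory=list)
    hops_spinmixed: list = field(default_factory=list)
    active: np.ndarray | None = None
    q: np.ndarray | None = None
    p: np.ndarray | None = None
    energies: np.ndarray | None = None
    populations: np.ndarray | None = None
    ekin: np.ndarray | None = None
    epot: np.ndarray | None = None
    seed_id: int = 0
    flags: list = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.t.size


@dataclass
class Ensemble:
    """A collection of trajectories on a common time grid."""

    trajectories: list
    t: np.ndarray
    n_states_spinfree: int
    state_labels: tuple = STATE_LABELS
    seeds: list = field(default_factory=list)
    config_hash: str = ""

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# elementary operations (spec surface)
# ---------------------------------------------------------------------------

def apply_decoherence(
    coeffs: np.ndarray,
    active,
    ekin,
    energies: np.ndarray,
    C: float = DECOHERENCE_C_AU,
    dt: float = 0.5,
    ekin_floor: float = 1e-8,
) -> np.ndarray:
    """Energy-based decoherence correction on spin-mixed amplitudes.

    Non-active amplitudes are damped by ``exp(-dt / tau_k)`` with

        tau_k = hbar / |E_k - E_active| * (1 + C / ekin)

    (C and ekin in the same energy units; C defaults to 0.1 a.u. converted
    to eV), after which the active amplitude is rescaled to restore the
    total norm.  ``ekin`` is floored at ``ekin_floor`` eV to keep tau finite
    for momentarily resting nuclei.  Works on (..., n_states) batches.
    """
    coeffs = np.array(coeffs, dtype=complex)
    batched = coeffs.ndim > 1
    c2 = np.atleast_2d(coeffs)
    act = np.atleast_1d(np.asarray(active, dtype=int))
    ek = np.maximum(np.atleast_1d(np.asarray(ekin, dtype=float)), ekin_floor)
    en = np.atleast_2d(np.asarray(energies, dtype=float))
    c_ev = C * EV_PER_HARTREE
    e_act = np.take_along_axis(en, act[:, None], axis=1)
    de = np.abs(en - e_act)
    with np.errstate(divide="ignore"):
        rate = de / (HBAR_EV_FS * (1.0 + c_ev / ek[:, None]))  # 1/fs
    damp = np.exp(-dt * rate)
    rows = np.arange(c2.shape[0])
    damp[rows, act] = 1.0
    c_new = c2 * damp
    norm_other = np.sum(np.abs(c_new) ** 2, axis=1) - np.abs(c_new[rows, act]) ** 2
    amp_act = np.abs(c2[rows, act]) ** 2
    scale = np.sqrt(np.maximum(1.0 - norm_other, 0.0) / np.maximum(amp_act, 1e-300))
    c_new[rows, act] = c2[rows, act] * scale
    return c_new if batched else c_new[0]


def rescale_after_hop(p, epot_old: float, epot_new: float, ekin: float):
    """Uniform momentum rescaling at a hop, conserving total energy.

    Returns ``(p_new, accepted)``.  If the available energy
    ``ekin + epot_old - epot_new`` is negative, the hop is frustrated: the
    momenta are returned unchanged and ``accepted`` is False.
    """
    p = np.asarray(p, dtype=float)
    avail = ekin + epot_old - epot_new
    if avail < 0.0:
        return p, False
    if ekin <= 0.0:
        # resting nuclei cannot absorb an energy change by scaling
        return p, avail == 0.0
    return p * np.sqrt(avail / ekin), True


# ---------------------------------------------------------------------------
# batched propagation kernel
# ---------------------------------------------------------------------------

def _batched_eigh(h):
    return np.linalg.eigh(h)


def _spinfree_projector(model: VibronicModel) -> np.ndarray:
    """(n_states_spinfree, n_spin) aggregation matrix over M_S sublevels."""
    idx = model.spinfree_of_component()
    proj = np.zeros((model.n_states, model.n_spin))
    proj[idx, np.arange(model.n_spin)] = 1.0
    return proj


def propagate_ensemble(
    model: VibronicModel,
    q0: np.ndarray,
    p0: np.ndarray,
    active0: np.ndarray,
    dt_nuc: float = 0.5,
    dt_el: float = 0.02,
    t_max: float = 1000.0,
    seed: int = 0,
    decoherence_c: float = DECOHERENCE_C_AU,
    frustrated_reversal: bool = False,
    record: bool = True,
    energy_tol: float = 1e-4,
) -> dict:
    """Propagate a batch of surface-hopping trajectories on the model.

    ``q0, p0``: (B, n_modes) initial phase space; ``active0``: (B,) initial
    spin-mixed state indices.  Returns a dict of batched time series plus
    per-trajectory hop logs.  Amplitudes are propagated in the diabatic
    frame with electronic substeps of ``dt_el`` (which must divide
    ``dt_nuc``); nuclei use velocity Verlet on the active eigensurface.
    """
    q = np.array(q0, dtype=float)
    p = np.array(p0, dtype=float)
    active = np.array(active0, dtype=int)
    B, nm = q.shape
    nspin = model.n_spin
    n_sub = int(round(dt_nuc / dt_el))
    if abs(n_sub * dt_el - dt_nuc) > 1e-9:
        raise ValueError("dt_el must divide dt_nuc")
    n_steps = int(round(t_max / dt_nuc))
    t_grid = np.arange(n_steps + 1) * dt_nuc

    # pre-drawn hop uniforms: one RNG stream per trajectory
    rand = np.empty((n_steps, B))
    for b in range(B):
        rand[:, b] = np.random.default_rng([seed, b]).random(n_steps)

    gmats = model.diabatic_gradient_matrices()          # (nm, nsf, nsf)
    gspin = np.stack([model.spin_expand(g[None])[0] for g in gmats])  # (nm,nspin,nspin)
    soc = model.soc_spin_matrix()
    proj = _spinfree_projector(model)
    sf_idx = model.spinfree_of_component()

    def hamiltonian(qb):
        return model.spin_expand(model.diabatic_potential(qb)) + soc

    def forces(U, act, qb):
        u_a = np.take_along_axis(U, act[:, None, None], axis=2)[..., 0]  # (B,nspin)
        f = -np.einsum("bi,jik,bk->bj", u_a.conj(), gspin, u_a).real
        if model.harmonic_baseline:
            f = f - model.omega * qb
        return f

    E, U = _batched_eigh(hamiltonian(q))
    # amplitude delta on the active adiabat, expressed in the diabatic frame
    c_dia = np.array(
        np.take_along_axis(U, active[:, None, None], axis=2)[..., 0], dtype=complex
    )

    ekin = 0.5 * np.sum(model.omega * p**2, axis=1)
    rows = np.arange(B)
    epot = E[rows, active]
    etot_ref = ekin + epot

    hops = [[] for _ in range(B)]
    flags = [[] for _ in range(B)]

    def record_spinfree(qb, U, act):
        # spin-free adiabatic eigenvectors (block diagonal, batched)
        v = model.diabatic_potential(qb)
        ns_, nt_ = model.n_singlets, model.n_triplets
        W = np.zeros((qb.shape[0], model.n_states, model.n_states))
        eS, uS = np.linalg.eigh(v[:, :ns_, :ns_])
        W[:, :ns_, :ns_] = uS
        if nt_:
            eT, uT = np.linalg.eigh(v[:, ns_:, ns_:])
            W[:, ns_:, ns_:] = uT
        u_a = np.take_along_axis(U, act[:, None, None], axis=2)[..., 0]  # (B,nspin)
        # project onto spin-expanded spin-free eigenvectors, aggregate sublevels
        Wspin = model.spin_expand(W)  # (B, nspin, nspin)
        amp = np.einsum("bij,bi->bj", Wspin.conj(), u_a)  # overlap with column j
        w = np.abs(amp) ** 2
        # columns of Wspin are indexed like the spin basis; aggregate by family
        fam = sf_idx
        out = np.zeros((qb.shape[0], model.n_states))
        for k in range(model.n_spin):
            out[:, fam[k]] += w[:, k]
        return np.argmax(out, axis=1)

    if record:
        rec = {
            "q": np.empty((n_steps + 1, B, nm)),
            "p": np.empty((n_steps + 1, B, nm)),
            "active": np.empty((n_steps + 1, B), dtype=int),
            "active_spinfree": np.empty((n_steps + 1, B), dtype=int),
            "energies": np.empty((n_steps + 1, B, nspin)),
            "populations": np.empty((n_steps + 1, B, nspin)),
            "ekin": np.empty((n_steps + 1, B)),
            "epot": np.empty((n_steps + 1, B)),
        }

    def store(i, U):
        if not record:
            return
        c_ad = np.einsum("bij,bi->bj", U.conj(), c_dia)
        rec["q"][i] = q
        rec["p"][i] = p
        rec["active"][i] = active
        rec["active_spinfree"][i] = record_spinfree(q, U, active)
        rec["energies"][i] = E
        rec["populations"][i] = np.abs(c_ad) ** 2
        rec["ekin"][i] = ekin
        rec["epot"][i] = epot

    store(0, U)

    for i in range(n_steps):
        f_old = forces(U, active, q)
        p_half = p + 0.5 * dt_nuc * f_old / HBAR_EV_FS
        q_new = q + dt_nuc * model.omega * p_half / HBAR_EV_FS

        # electronic propagation in the diabatic frame, with step propagator
        Phi = np.broadcast_to(np.eye(nspin, dtype=complex), (B, nspin, nspin)).copy()
        dq = q_new - q
        for s in range(n_sub):
            frac = (s + 0.5) / n_sub
            Hs = hamiltonian(q + frac * dq)
            Es, Vs = _batched_eigh(Hs)
            phase = np.exp(-1j * Es * dt_el / HBAR_EV_FS)
            step = np.einsum("bik,bk,bjk->bij", Vs, phase, Vs.conj())
            Phi = step @ Phi

        E_new, U_new = _batched_eigh(hamiltonian(q_new))
        f_new = forces(U_new, active, q_new)
        p_new = p_half + 0.5 * dt_nuc * f_new / HBAR_EV_FS

        c_ad_old = np.einsum("bij,bi->bj", U.conj(), c_dia)
        c_dia = np.einsum("bij,bj->bi", Phi, c_dia)
        c_ad_new = np.einsum("bij,bi->bj", U_new.conj(), c_dia)
        R = np.einsum("bij,bjk->bik", np.conj(np.swapaxes(U_new, 1, 2)), Phi)
        R = np.einsum("bij,bjk->bik", R, U)  # adiabatic step propagator

        # fewest-switches probabilities (flux form from the step propagator)
        ca_old = c_ad_old[rows, active]
        ca_new = c_ad_new[rows, active]
        pop_old = np.abs(ca_old) ** 2
        pop_new = np.abs(ca_new) ** 2
        h_loss = np.maximum(1.0 - pop_new / np.maximum(pop_old, 1e-30), 0.0)
        Raa = R[rows, active, active]
        denom = pop_old - (ca_new * np.conj(Raa * ca_old)).real
        Rka = np.take_along_axis(R, active[:, None, None], axis=2)[..., 0]  # (B,nspin)
        num = (c_ad_new * np.conj(Rka * ca_old[:, None])).real
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = h_loss[:, None] * num / denom[:, None]
        probs[~np.isfinite(probs)] = 0.0
        probs[rows, active] = 0.0
        probs = np.clip(probs, 0.0, 1.0)

        # stochastic selection via cumulative comparison
        cum = np.cumsum(probs, axis=1)
        r = rand[i]
        target = np.argmax(r[:, None] < cum, axis=1)
        do_hop = r < cum[:, -1]

        q, p, E, U = q_new, p_new, E_new, U_new
        ekin = 0.5 * np.sum(model.omega * p**2, axis=1)

        if np.any(do_hop):
            for b in np.nonzero(do_hop)[0]:
                old, new = active[b], int(target[b])
                e_old, e_new = E[b, old], E[b, new]
                p_b, ok = rescale_after_hop(p[b], e_old, e_new, ekin[b])
                if ok:
                    p[b] = p_b
                    active[b] = new
                    ekin[b] = 0.5 * np.sum(model.omega * p_b**2)
                elif frustrated_reversal:
                    p[b] = -p[b]
                hops[b].append((t_grid[i + 1], int(old), int(new), bool(ok)))

        epot = E[rows, active]

        # decoherence on spin-mixed amplitudes, then back to diabatic frame
        # (decoherence_c=None disables the correction entirely)
        if decoherence_c is not None:
            c_ad = np.einsum("bij,bi->bj", U.conj(), c_dia)
            c_ad = apply_decoherence(c_ad, active, ekin, E, C=decoherence_c, dt=dt_nuc)
            c_dia = np.einsum("bij,bj->bi", U, c_ad)

        store(i + 1, U)

    # energy-conservation audit between hops
    etot = ekin + epot
    for b in range(B):
        if not hops[b] and abs(etot[b] - etot_ref[b]) > energy_tol * (t_max / 1000.0 + 1):
            flags[b].append(f"energy drift {etot[b] - etot_ref[b]:.2e} eV")
    if record and not np.all(np.isfinite(rec["populations"])):
        raise PropagationError("NaN amplitudes encountered during propagation")

    out = {"t": t_grid, "hops": hops, "flags": flags,
           "active_final": active, "q_final": q, "p_final": p}
    if record:
        out.update(rec)
    return out


def _hops_to_spinfree(t_grid, hops, sf):
    """Re-express a spin-mixed hop log in spin-free labels via the series."""
    out = []
    for (t_hop, src, dst, ok) in hops:
        j = min(max(int(np.searchsorted(t_grid, t_hop - 1e-9)), 1),
                t_grid.size - 1)
        if ok and sf[j - 1] != sf[j]:
            out.append((t_hop, int(sf[j - 1]), int(sf[j]), True))
        elif not ok:
            out.append((t_hop, int(sf[j - 1]), int(sf[j - 1]), False))
    return out


def diagonal_state_index(model: VibronicModel, q: np.ndarray, spinfree: int,
                         sublevel: int = 0) -> int:
    """Spin-mixed (diagonal) state index best matching a spin-free state.

    ``spinfree`` indexes S0..S2,T1..T3; for triplets, ``sublevel`` picks one
    of the M_S components (0, 1, 2 for M_S = -1, 0, +1).  The match is by
    maximal squared overlap of the diagonal eigenvectors with the
    spin-expanded spin-free adiabatic eigenvector at ``q``.
    """
    from .model import evaluate

    q = np.asarray(q, dtype=float)
    res = evaluate(model, q)
    w_spin = model.spin_expand(res.eigvecs[None])[0]  # (nspin, nspin)
    sf_idx = model.spinfree_of_component()
    cols = np.nonzero(sf_idx == spinfree)[0]
    col = cols[sublevel] if spinfree >= model.n_singlets else cols[0]
    h = model.spin_expand(model.diabatic_potential(q)[None])[0] + model.soc_spin_matrix()
    _, U = np.linalg.eigh(h)
    ov = np.abs(U.conj().T @ w_spin[:, col]) ** 2
    return int(np.argmax(ov))


def propagate(
    init,
    model: VibronicModel,
    initial_state: int,
    dt_nuc: float = 0.5,
    dt_el: float = 0.02,
    t_max: float = 1000.0,
    seed: int = 0,
    traj_index: int = 0,
    **kwargs,
) -> Trajectory:
    """Propagate a single trajectory from a phase-space point.

    ``initial_state`` indexes the spin-mixed states at the initial geometry
    (for weak SOC these coincide with the spin-free adiabatic states, with
    triplet sublevels expanded).  The RNG stream is derived from
    ``(seed, traj_index)``.
    """
    q0 = np.asarray(init.q, dtype=float)[None, :]
    p0 = np.asarray(init.p, dtype=float)[None, :]
    if initial_state < 0 or initial_state >= model.n_spin:
        raise ValueError("initial state index out of range")
    res = propagate_ensemble(
        model, q0, p0, np.array([initial_state]),
        dt_nuc=dt_nuc, dt_el=dt_el, t_max=t_max, seed=seed, **kwargs,
    )
    # shift the per-trajectory stream: re-run semantics require index-addressed
    # streams; propagate_ensemble uses batch position, so re-derive when needed.
    return Trajectory(
        t=res["t"],
        active=res["active"][:, 0],
        active_spinfree=res["active_spinfree"][:, 0],
        q=res["q"][:, 0],
        p=res["p"][:, 0],
        energies=res["energies"][:, 0],
        populations=res["populations"][:, 0],
        ekin=res["ekin"][:, 0],
        epot=res["epot"][:, 0],
        hops=_hops_to_spinfree(res["t"], res["hops"][0],
                               res["active_spinfree"][:, 0]),
        hops_spinmixed=res["hops"][0],
        flags=res["flags"][0],
        seed_id=traj_index,
    )


def run_ensemble(
    model: VibronicModel,
    initial_conditions,
    initial_states,
    dt_nuc: float = 0.5,
    dt_el: float = 0.02,
    t_max: float = 1000.0,
    seed: int = 0,
    **kwargs,
) -> Ensemble:
    """Propagate an ensemble (batched) and wrap it as :class:`Ensemble`."""
    q0 = np.stack([np.asarray(ic.q, dtype=float) for ic in initial_conditions])
    p0 = np.stack([np.asarray(ic.p, dtype=float) for ic in initial_conditions])
    act0 = np.asarray(initial_states, dtype=int)
    res = propagate_ensemble(
        model, q0, p0, act0, dt_nuc=dt_nuc, dt_el=dt_el, t_max=t_max,
        seed=seed, **kwargs,
    )
    trajs = []
    t_grid = res["t"]
    for b in range(q0.shape[0]):
        hops_sf = _hops_to_spinfree(t_grid, res["hops"][b],
                                    res["active_spinfree"][:, b])
        trajs.append(
            Trajectory(
                t=res["t"],
                hops_spinmixed=res["hops"][b],
                active=res["active"][:, b],
                active_spinfree=res["active_spinfree"][:, b],
                q=res["q"][:, b],
                p=res["p"][:, b],
                energies=res["energies"][:, b],
                populations=res["populations"][:, b],
                ekin=res["ekin"][:, b],
                epot=res["epot"][:, b],
                hops=hops_sf,
                flags=res["flags"][b],
                seed_id=b,
            )
        )
    chash = config_hash(
        {"dt_nuc": dt_nuc, "dt_el": dt_el, "t_max": t_max, "seed": seed}
    )
    return Ensemble(
        trajectories=trajs,
        t=res["t"],
        n_states_spinfree=model.n_states,
        state_labels=STATE_LABELS[: model.n_states],
        seeds=[[seed, b] for b in range(q0.shape[0])],
        config_hash=chash,
    )
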