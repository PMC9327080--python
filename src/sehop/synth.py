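"""Synthetic ensembles with known ground truth for every analysis stage.

Each generator emulates one data product of the photorelaxation study —
sequential population kinetics, rising transient-absorption band integrals,
first-solvation-shell depletion, electron/hole fragment curves, relaxing
bond series, and excitation line lists — and records its generating
parameters in a ``meta`` dict so that recovery tests read ground truth from
metadata, never from file names.  Noise models per generator: binomial
(trajectory counts, via the stochastic jump sampling itself), Gaussian
(signals at a stated signal-to-noise ratio), Poisson-like counting
(pair-distance histograms, via finite particle numbers).  All generators
are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charge_transfer import EHPopulations
from .kinetics import DEFAULT_TOPOLOGY
from .model import STATE_LABELS
from .propagator import Ensemble, Trajectory, config_hash
from .spectra import SpectrumLine

# study conditions: Table-2-patterned defaults
DEFAULT_TAUS_FS = {("S2", "S1"): 257.0, ("S1", "T"): 282.0, ("S2", "T"): 1236.0}
GLOBAL_TAU_FS = 452.0
BAND_TAUS_FS = {"low": 131.0, "high": 191.0}
SOLVENT_TAU_FS = 129.0
HOLE_TAU_FS = 14.0
HOLE_SATURATION = 0.8
ELECTRON_TAUS_FS = (9.0, 240.0)
INITIAL_SPLIT = {"S2": 0.85, "S1": 0.15}
N_TRAJ = 99


def gen_kinetic_ensemble(
    taus: dict | None = None,
    n_traj: int = N_TRAJ,
    dt: float = 0.5,
    t_max: float = 1000.0,
    initial_split: dict | None = None,
    seed: int = 0,
    labels: tuple | None = None,
) -> Ensemble:
    """Continuous-time Markov-jump ensemble on an irreversible network.

    ``taus`` maps (source, destination) compartment labels to time constants
    in fs (default: the three-channel S2 -> S1 -> T scheme with the direct
    S2 -> T branch).  Waiting times are exponential; hops are logged and the
    state series discretized to the output grid.  Trajectory-count noise is
    binomial by construction.
    """
    taus = dict(taus or DEFAULT_TAUS_FS)
    initial_split = dict(initial_split or INITIAL_SPLIT)
    comp_labels = []
    for (src, dst) in taus:
        for s in (src, dst):
            if s not in comp_labels:
                comp_labels.append(s)
    if labels is None:
        labels = STATE_LABELS if all(
            c in STATE_LABELS or c == "T" for c in comp_labels
        ) else tuple(comp_labels)

    def state_index(comp):
        if comp in labels:
            return labels.index(comp)
        if comp == "T" and "T1" in labels:
            return labels.index("T1")  # triplet sink recorded as T1
        raise ValueError(f"compartment {comp} not representable in labels {labels}")

    t_grid = np.arange(int(round(t_max / dt)) + 1) * dt
    out_rates = {c: [] for c in comp_labels}
    for (src, dst), tau in taus.items():
        out_rates[src].append((dst, 1.0 / tau))
    init_labels = list(initial_split)
    init_probs = np.array([initial_split[k] for k in init_labels], dtype=float)
    init_probs = init_probs / init_probs.sum()

    trajectories = []
    for b in range(n_traj):
        rng = np.random.default_rng([seed, b])
        comp = init_labels[rng.choice(len(init_labels), p=init_probs)]
        t_now = 0.0
        series = np.empty(t_grid.size, dtype=int)
        filled = 0
        hops = []
        while True:
            channels = out_rates.get(comp, [])
            total = sum(k for _, k in channels)
            t_next = t_now + rng.exponential(1.0 / total) if total > 0 else np.inf
            n_fill = np.searchsorted(t_grid, min(t_next, t_max), side="right")
            series[filled:n_fill] = state_index(comp)
            filled = n_fill
            if t_next > t_max or filled >= t_grid.size:
                series[filled:] = state_index(comp)
                break
            ks = np.array([k for _, k in channels])
            dst = channels[rng.choice(len(channels), p=ks / ks.sum())][0]
            hops.append((t_next, state_index(comp), state_index(dst), True))
            comp = dst
            t_now = t_next
        trajectories.append(
            Trajectory(t=t_grid, active_spinfree=series, hops=hops, seed_id=b)
        )
    meta = {"taus": {f"{s}->{d}": v for (s, d), v in taus.items()},
            "initial_split": initial_split, "seed": seed, "n_traj": n_traj}
    ens = Ensemble(
        trajectories=trajectories, t=t_grid, n_states_spinfree=len(labels),
        state_labels=tuple(labels), seeds=[[seed, b] for b in range(n_traj)],
        config_hash=config_hash(meta),
    )
    ens.meta = meta
    return ens


@dataclass
class SolventEnsemble:
    """Synthetic solute–solvent distance series.

    ``distances``: (n_times, n_traj, n_water) Se–H distances in Å.  Shell
    waters start in the hydrogen-bonded first shell near 2.5 Å and relocate
    to the second shell near 4 Å after an exponential waiting time with the
    prescribed constant; bulk waters are uniform in volume.  The total pair
    count is conserved over time.
    """

    t: np.ndarray
    distances: np.ndarray
    meta: dict = field(default_factory=dict)


def gen_solvent_trajectories(
    tau_shell: float = SOLVENT_TAU_FS,
    n_water: int = 40,
    n_traj: int = 500,
    n_shell: int = 4,
    dt: float = 10.0,
    t_max: float = 1000.0,
    r_shell: float = 2.5,
    r_second: float = 4.0,
    r_max: float = 8.0,
    jitter: float = 0.12,
    seed: int = 0,
) -> SolventEnsemble:
    """First-solvation-shell depletion dynamics with conserved pair count."""
    if tau_shell <= 0:
        raise ValueError("tau_shell must be positive")
    t = np.arange(int(round(t_max / dt)) + 1) * dt
    rng = np.random.default_rng(seed)
    nt = t.size
    d = np.empty((nt, n_traj, n_water))
    # bulk: uniform in volume between the shell region and the droplet edge
    n_bulk = n_water - n_shell
    u = rng.random((n_traj, n_bulk))
    r_lo = r_shell + 0.5
    r_bulk = (r_lo**3 + u * (r_max**3 - r_lo**3)) ** (1.0 / 3.0)
    d[:, :, n_shell:] = r_bulk[None, :, :] + rng.normal(
        0.0, 0.5 * jitter, size=(nt, n_traj, n_bulk)
    )
    # shell waters: exponential departure to the second shell
    if np.isfinite(tau_shell):
        t_dep = rng.exponential(tau_shell, size=(n_traj, n_shell))
    else:
        t_dep = np.full((n_traj, n_shell), np.inf)
    base = np.where(
        t[:, None, None] < t_dep[None, :, :], r_shell, r_second
    )
    d[:, :, :n_shell] = base + rng.normal(0.0, jitter, size=(nt, n_traj, n_shell))
    meta = {"tau_shell": tau_shell, "n_water": n_water, "n_traj": n_traj,
            "n_shell": n_shell, "r_shell": r_shell, "r_second": r_second,
            "r_max": r_max, "seed": seed}
    return SolventEnsemble(t=t, distances=d, meta=meta)


def gen_eh_curves(
    tau_hole: float = HOLE_TAU_FS,
    hole_start: float = 0.5,
    hole_saturation: float = HOLE_SATURATION,
    electron_taus=ELECTRON_TAUS_FS,
    electron_coeffs=(0.25, 0.18, -0.08),  # offset c, a_fast, a_slow on Se
    snr: float = 20.0,
    n_curves: int = N_TRAJ,
    dt: float = 1.0,
    t_max: float = 1000.0,
    seed: int = 0,
) -> EHPopulations:
    """Ensemble-averaged electron/hole fragment curves with Gaussian noise.

    Hole on the Se fragment: ``h0 + (sat - h0)(1 - exp(-t/tau_hole))``;
    electron on Se: ``c + a1 exp(-t/tau1) + a2 exp(-t/tau2)`` (fast loss to
    the Re fragment, partial slow return).  Per-curve Gaussian noise with
    standard deviation (saturation amplitude)/snr; averaging over
    ``n_curves`` reduces it by sqrt(n).
    """
    t = np.arange(int(round(t_max / dt)) + 1) * dt
    rng = np.random.default_rng(seed)
    hole_true = hole_start + (hole_saturation - hole_start) * (
        1.0 - np.exp(-t / tau_hole)
    )
    c, a1, a2 = electron_coeffs
    tau1, tau2 = electron_taus
    el_true = c + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    amp_h = abs(hole_saturation - hole_start)
    amp_e = abs(a1) + abs(a2)
    noise_h = (amp_h / snr) if snr and np.isfinite(snr) else 0.0
    noise_e = (amp_e / snr) if snr and np.isfinite(snr) else 0.0
    hole_curves = hole_true[None, :] + rng.normal(0, noise_h, (n_curves, t.size))
    el_curves = el_true[None, :] + rng.normal(0, noise_e, (n_curves, t.size))
    hole_se = hole_curves.mean(axis=0)
    el_se = el_curves.mean(axis=0)
    hole = np.column_stack([hole_se, 1.0 - hole_se])
    electron = np.column_stack([el_se, 1.0 - el_se])
    meta = {"tau_hole": tau_hole, "hole_start": hole_start,
            "hole_saturation": hole_saturation,
            "electron_taus": list(electron_taus),
            "electron_coeffs": list(electron_coeffs),
            "snr": snr, "n_curves": n_curves, "seed": seed}
    return EHPopulations(t=t, hole=hole, electron=electron,
                         fragment_names=("Se", "Re"), meta=meta)


def gen_band_signals(
    taus: dict | None = None,
    amplitudes: dict | None = None,
    snr: float = 20.0,
    dt: float = 4.0,
    t_max: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Unconvoluted band-integral time series rising as A (1 - exp(-t/tau)).

    Gaussian noise with sigma = A/snr per sample.  Ground truth is stored
    in ``df.attrs['meta']``.
    """
    taus = dict(taus or BAND_TAUS_FS)
    amplitudes = dict(amplitudes or {name: 1.0 for name in taus})
    t = np.arange(int(round(t_max / dt)) + 1) * dt
    rng = np.random.default_rng(seed)
    out = {"t_fs": t}
    for name, tau in taus.items():
        a = amplitudes[name]
        y = a * (1.0 - np.exp(-t / tau))
        if snr and np.isfinite(snr):
            y = y + rng.normal(0.0, a / snr, size=t.size)
        out[name] = y
    df = pd.DataFrame(out)
    df.attrs["meta"] = {"taus": taus, "amplitudes": amplitudes,
                        "snr": snr, "seed": seed}
    return df


def gen_geometry_series(
    offset: float = 1.95,
    amplitudes=(-0.13, 0.0),
    taus=(14.0, 123.0),
    snr: float = 50.0,
    dt: float = 1.0,
    t_max: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Relaxing bond/angle series: ``offset + sum_i a_i exp(-t/tau_i)``.

    Defaults caricature the C=Se stretch: 1.82 Å at t = 0 relaxing toward
    ~1.95 Å with the nuclear-relaxation constants.
    """
    t = np.arange(int(round(t_max / dt)) + 1) * dt
    rng = np.random.default_rng(seed)
    y = np.full(t.size, offset)
    for a, tau in zip(amplitudes, taus):
        y = y + a * np.exp(-t / tau)
    amp = sum(abs(a) for a in amplitudes)
    if snr and np.isfinite(snr) and amp > 0:
        y = y + rng.normal(0.0, amp / snr, size=t.size)
    df = pd.DataFrame({"t_fs": t, "value": y})
    df.attrs["meta"] = {"offset": offset, "amplitudes": list(amplitudes),
                        "taus": list(taus), "snr": snr, "seed": seed}
    return df


def gen_line_list(
    band_centers=(3.59,),
    widths=(0.12,),
    f_scales=(0.4,),
    n_points: int = 100,
    f_jitter: float = 0.25,
    seed: int = 0,
) -> list:
    """Excitation line list with Gaussian-distributed energies per band.

    Each of ``n_points`` sampling points contributes one line per band:
    energy ~ N(center, width), oscillator strength = f_scale * (1 + jitter)
    clipped at zero.  Broadening such a list reproduces bands peaking at
    the prescribed centers.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for pid in range(n_points):
        for k, (c, w, fs) in enumerate(zip(band_centers, widths, f_scales)):
            e = rng.normal(c, w)
            while e <= 0.05:
                e = rng.normal(c, w)
            f = max(fs * (1.0 + rng.normal(0.0, f_jitter)), 0.0)
            lines.append(
                SpectrumLine(energy=float(e), osc_strength=float(f),
                             from_state="S0", to_state=f"S{k + 1}", point_id=pid)
            )
    return lines
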