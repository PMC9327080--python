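"""Population kinetics: extraction, sequential-model fitting, bootstrap errors.

Spin-free adiabatic populations are the fraction of trajectories whose active
spin-mixed state maps to each spin-free state (triplet M_S sublevels
aggregated).  Time constants come from fitting the solution of an
irreversible first-order compartment network — by default the sequential
scheme S2 -> S1, S1 -> T, S2 -> T with the triplet manifold as one sink —
jointly to all compartment curves by unweighted least squares.  A global
two-compartment variant (S -> T on the summed singlet/triplet populations)
yields the effective intersystem-crossing constant.  Uncertainties are
bootstrap standard errors over trajectory resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import scipy.linalg

DEFAULT_TOPOLOGY = (("S2", "S1"), ("S1", "T"), ("S2", "T"))
GLOBAL_TOPOLOGY = (("S", "T"),)


class KineticsError(ValueError):
    pass


@dataclass
class PopulationSeries:
    """Fractional populations on a common time grid; rows sum to one."""

    t: np.ndarray
    P: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.t.size, len(self.labels)):
            raise KineticsError("P must be (n_times, n_labels)")

    def aggregate(self, groups: dict) -> "PopulationSeries":
        """Sum labelled columns into named groups, e.g. {"S": ("S1","S2"), ...}."""
        cols = []
        for name, members in groups.items():
            idx = [self.labels.index(m) for m in members if m in self.labels]
            cols.append(self.P[:, idx].sum(axis=1))
        return PopulationSeries(
            t=self.t, P=np.column_stack(cols), labels=tuple(groups)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, columns=list(self.labels))
        df.insert(0, "t_fs", self.t)
        return df


@dataclass
class KineticFit:
    """Fitted compartment network: per-transition time constants in fs."""

    topology: tuple
    tau: dict
    tau_err: dict = field(default_factory=dict)
    n_boot: int = 0
    initial: np.ndarray | None = None
    labels: tuple = ()
    residual_rms: float = float("nan")


# ---------------------------------------------------------------------------
# population extraction
# ---------------------------------------------------------------------------

def spinfree_populations(ensemble) -> PopulationSeries:
    """Fraction of trajectories in each spin-free state at each time."""
    trajs = list(ensemble.trajectories)
    if not trajs:
        raise KineticsError("empty ensemble")
    t = np.asarray(ensemble.t, dtype=float)
    n_states = ensemble.n_states_spinfree
    counts = np.zeros((t.size, n_states))
    for tr in trajs:
        s = np.asarray(tr.active_spinfree, dtype=int)
        if s.size != t.size:
            raise KineticsError("trajectory grid inconsistent with ensemble grid")
        counts[np.arange(t.size), s] += 1.0
    return PopulationSeries(
        t=t, P=counts / len(trajs), labels=tuple(ensemble.state_labels)
    )


def net_hops(ensemble, accepted_only: bool = True) -> np.ndarray:
    """Antisymmetric net transfer-count matrix among spin-free states.

    Entry (A, B) is count(A->B) - count(B->A), tallied from the
    per-trajectory hop logs (already expressed in spin-free labels by both
    the propagator and the synthetic generators).
    """
    n = ensemble.n_states_spinfree
    mat = np.zeros((n, n))
    for tr in ensemble.trajectories:
        for (t_hop, src, dst, ok) in tr.hops:
            if (accepted_only and not ok) or src == dst:
                continue
            mat[src, dst] += 1.0
    return mat - mat.T


# ---------------------------------------------------------------------------
# compartment ODE and fitting
# ---------------------------------------------------------------------------

def rate_matrix(topology, taus, labels) -> np.ndarray:
    """First-order rate matrix K with dP/dt = K P for the given transitions."""
    n = len(labels)
    K = np.zeros((n, n))
    for (src, dst), tau in zip(topology, taus):
        i, j = labels.index(src), labels.index(dst)
        k = 1.0 / tau
        K[i, i] -= k
        K[j, i] += k
    return K


def solve_compartments(topology, taus, initial, t, labels) -> np.ndarray:
    """Populations P(t) of the linear network, shape (n_times, n_compartments)."""
    K = rate_matrix(topology, taus, labels)
    t = np.asarray(t, dtype=float)
    w, V = np.linalg.eig(K)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < 1e10:
        c = np.linalg.solve(V, np.asarray(initial, dtype=float))
        P = np.real(np.einsum("ik,tk,k->ti", V, np.exp(np.outer(t, w)), c))
    else:  # defective K (e.g. exactly equal rates): fall back to expm
        P = np.stack(
            [scipy.linalg.expm(K * ti) @ np.asarray(initial, dtype=float) for ti in t]
        )
    return P


def _topology_labels(topology) -> tuple:
    labels = []
    for src, dst in topology:
        for s in (src, dst):
            if s not in labels:
                labels.append(s)
    return tuple(labels)


def fit_kinetic_model(
    pops: PopulationSeries,
    topology=DEFAULT_TOPOLOGY,
    tau_guess: dict | None = None,
) -> KineticFit:
    """Joint unweighted least-squares fit of the compartment network.

    The initial fractions are fixed at the data's t = 0 values; all
    compartment curves enter the residual simultaneously (they share one
    normalization).  Raises if a source compartment never carries
    population (non-identifiable channel).
    """
    labels = _topology_labels(topology)
    missing = [l for l in labels if l not in pops.labels]
    if missing:
        raise KineticsError(f"population series lacks compartments {missing}")
    cols = [pops.labels.index(l) for l in labels]
    data = pops.P[:, cols]
    t = pops.t - pops.t[0]
    initial = data[0]
    for src, _ in topology:
        if data[:, labels.index(src)].max() <= 0:
            raise KineticsError(
                f"source compartment {src} carries no population; channel not identifiable"
            )
    params = lmfit.Parameters()
    names = [f"tau_{src}_{dst}" for src, dst in topology]
    t_span = max(t[-1], 1.0)
    for (src, dst), name in zip(topology, names):
        guess = (tau_guess or {}).get((src, dst), t_span / 3.0)
        params.add(name, value=guess, min=1e-3, max=1e7)

    def residual(p):
        taus = [p[name].value for name in names]
        model = solve_compartments(topology, taus, initial, t, list(labels))
        return (model - data).ravel()

    out = lmfit.minimize(residual, params, method="leastsq")
    tau = {
        (src, dst): float(out.params[name].value)
        for (src, dst), name in zip(topology, names)
    }
    return KineticFit(
        topology=tuple(topology),
        tau=tau,
        initial=initial,
        labels=labels,
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
    )


def fit_global_isc(pops: PopulationSeries) -> KineticFit:
    """Two-compartment S -> T fit on summed singlet and triplet populations."""
    singlets = [l for l in pops.labels if l.startswith("S") and l != "S0"]
    triplets = [l for l in pops.labels if l.startswith("T")]
    agg = pops.aggregate({"S": singlets, "T": triplets})
    return fit_kinetic_model(agg, topology=GLOBAL_TOPOLOGY)


def bootstrap_errors(
    ensemble,
    topology=DEFAULT_TOPOLOGY,
    n_boot: int = 200,
    seed: int = 0,
    compartments: dict | None = None,
) -> dict:
    """Bootstrap standard errors of the fitted time constants.

    Trajectories are resampled with replacement ``n_boot`` times and the
    network refitted per resample; failed fits are skipped (warned when more
    than 5% fail).  ``compartments`` optionally maps spin-free labels into
    the fit compartments (default: S1, S2 kept, triplets merged into T).
    """
    if n_boot < 2:
        raise KineticsError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    trajs = list(ensemble.trajectories)
    n = len(trajs)
    results = {pair: [] for pair in topology}
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = _Resample(ensemble, [trajs[i] for i in idx])
        try:
            pops = spinfree_populations(sub)
            pops = _default_compartments(pops, compartments)
            fit = fit_kinetic_model(pops, topology=topology)
        except (KineticsError, ValueError):
            skipped += 1
            continue
        for pair in topology:
            results[pair].append(fit.tau[pair])
    if skipped > 0.05 * n_boot:
        warnings.warn(f"{skipped}/{n_boot} bootstrap resamples failed and were skipped")
    return {pair: float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            for pair, vals in results.items()}


def _default_compartments(pops: PopulationSeries, compartments: dict | None):
    if compartments is None:
        have_T = all(l in pops.labels for l in ("T1", "T2", "T3"))
        if have_T:
            compartments = {
                "S2": ("S2",), "S1": ("S1",), "T": ("T1", "T2", "T3"),
            }
        else:
            return pops
    return pops.aggregate(compartments)


class _Resample:
    def __init__(self, parent, trajectories):
        self.trajectories = trajectories
        self.t = parent.t
        self.n_states_spinfree = parent.n_states_spinfree
        self.state_labels = parent.state_labels


def triplet_fraction(taus: dict, initial: dict, t: float) -> float:
    """Deterministic triplet fraction of the three-channel sequential model.

    ``taus`` maps ("S2","S1"), ("S1","T"), ("S2","T") to time constants in
    fs; ``initial`` gives the t = 0 fractions of S2 and S1.
    """
    topology = DEFAULT_TOPOLOGY
    labels = ["S2", "S1", "T"]
    init = np.array([initial.get("S2", 0.0), initial.get("S1", 0.0), 0.0])
    init[2] = max(1.0 - init[0] - init[1], 0.0)
    P = solve_compartments(
        topology, [taus[pair] for pair in topology], init, np.array([t]), labels
    )
    return float(P[0, labels.index("T")])
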