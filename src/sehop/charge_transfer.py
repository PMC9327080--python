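"""Fragment-resolved electron/hole populations and their time constants.

The transition-density analysis is carried at the level of per-configuration
site weights: each diabatic configuration of the model declares where its
hole and its excited electron sit (e.g. on the selenium atom "Se" versus the
remainder of the molecule "Re"), and the adiabatic character at a geometry
is the amplitude-squared-weighted mixture of those configurations.  Fragment
populations are sums of site weights over fragment membership; the
ensemble-averaged curves are fitted mono- (hole) or biexponentially
(electron) with an offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import fit_exponentials


@dataclass(frozen=True)
class FragmentScheme:
    """Named, disjoint, jointly exhaustive groups of site indices."""

    fragments: dict  # name -> tuple of site indices
    n_sites: int

    def __post_init__(self):
        seen = []
        for sites in self.fragments.values():
            seen.extend(sites)
        if sorted(seen) != list(range(self.n_sites)):
            raise ValueError("fragments must be disjoint and cover all sites")

    @property
    def names(self):
        return tuple(self.fragments)


DEFAULT_SCHEME = FragmentScheme(fragments={"Se": (0,), "Re": (1,)}, n_sites=2)


@dataclass
class EHPopulations:
    """Per-fragment hole and electron fractions over time; rows sum to one."""

    t: np.ndarray
    hole: np.ndarray      # (n_times, n_fragments)
    electron: np.ndarray  # (n_times, n_fragments)
    fragment_names: tuple
    meta: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_fs": self.t})
        for j, name in enumerate(self.fragment_names):
            df[f"hole_{name}"] = self.hole[:, j]
        for j, name in enumerate(self.fragment_names):
            df[f"e_{name}"] = self.electron[:, j]
        return df


def _normalize(weights: np.ndarray) -> np.ndarray:
    s = weights.sum(axis=-1, keepdims=True)
    if np.any(np.abs(s - 1.0) > 1e-9):
        warnings.warn("site weights not normalized; renormalizing")
    return weights / np.where(s > 0, s, 1.0)


def fragment_populations(hole_sites, electron_sites, scheme: FragmentScheme = DEFAULT_SCHEME):
    """Aggregate site-resolved hole/electron weights into fragment fractions.

    ``hole_sites`` and ``electron_sites`` are (..., n_sites) arrays of
    transition-density weights (renormalized with a warning if needed).
    Returns two (..., n_fragments) arrays; invariant under any permutation
    of sites within one fragment.
    """
    h = _normalize(np.asarray(hole_sites, dtype=float))
    e = _normalize(np.asarray(electron_sites, dtype=float))
    out_h = np.stack([h[..., list(s)].sum(axis=-1) for s in scheme.fragments.values()], axis=-1)
    out_e = np.stack([e[..., list(s)].sum(axis=-1) for s in scheme.fragments.values()], axis=-1)
    return out_h, out_e


def mixture_site_weights(amplitudes, hole_site_weights, particle_site_weights):
    """Site weights of an adiabatic state from its diabatic amplitudes.

    ``amplitudes``: (..., n_configs) complex mixture coefficients;
    ``*_site_weights``: (n_configs, n_sites) per-configuration weights.
    """
    w = np.abs(np.asarray(amplitudes)) ** 2
    w = w / np.maximum(w.sum(axis=-1, keepdims=True), 1e-300)
    return w @ np.asarray(hole_site_weights, float), w @ np.asarray(particle_site_weights, float)


def ensemble_eh_populations(ensemble, model, scheme: FragmentScheme = DEFAULT_SCHEME) -> EHPopulations:
    """Ensemble-averaged fragment populations along dynamics trajectories.

    At each output step the active spin-free adiabatic state's diabatic
    composition is evaluated from the stored geometry, converted to site
    weights through the model's per-configuration hole/particle tables, and
    aggregated over fragments.  Ground-state snapshots carry no exciton and
    are excluded from the average (one hole and one electron are conserved
    per excited snapshot).
    """
    if model.hole_site_weights is None:
        raise ValueError("model declares no transition-density site weights")
    t = np.asarray(ensemble.t, float)
    nfrag = len(scheme.fragments)
    hole_sum = np.zeros((t.size, nfrag))
    el_sum = np.zeros((t.size, nfrag))
    count = np.zeros(t.size)
    ns = model.n_singlets
    for tr in ensemble.trajectories:
        if tr.q is None:
            raise ValueError("trajectory lacks geometries")
        v = model.diabatic_potential(tr.q)  # (n_t, nsf, nsf)
        eS, uS = np.linalg.eigh(v[:, :ns, :ns])
        eT, uT = np.linalg.eigh(v[:, ns:, ns:])
        act = np.asarray(tr.active_spinfree, int)
        excited = act > 0
        amps = np.zeros((t.size, model.n_states))
        sel_s = excited & (act < ns)
        sel_t = act >= ns
        if np.any(sel_s):
            amps[np.ix_(sel_s.nonzero()[0], range(ns))] = np.transpose(
                uS[sel_s, :, :], (0, 2, 1)
            )[np.arange(sel_s.sum()), act[sel_s], :]
        if np.any(sel_t):
            amps[np.ix_(sel_t.nonzero()[0], range(ns, model.n_states))] = np.transpose(
                uT[sel_t, :, :], (0, 2, 1)
            )[np.arange(sel_t.sum()), act[sel_t] - ns, :]
        # the closed-shell ground configuration carries no electron-hole
        # pair; its admixture is excluded and the mixture renormalized
        amps_x = amps[excited].copy()
        amps_x[:, 0] = 0.0
        hs, es = mixture_site_weights(
            amps_x, model.hole_site_weights, model.particle_site_weights
        )
        fh, fe = fragment_populations(hs, es, scheme)
        hole_sum[excited] += fh
        el_sum[excited] += fe
        count += excited
    good = count > 0
    hole = np.full((t.size, nfrag), np.nan)
    el = np.full((t.size, nfrag), np.nan)
    hole[good] = hole_sum[good] / count[good, None]
    el[good] = el_sum[good] / count[good, None]
    return EHPopulations(t=t, hole=hole, electron=el,
                         fragment_names=scheme.names)


def eh_time_constants(
    eh: EHPopulations,
    fragment: str = "Se",
    hole_components: int = 1,
    electron_components: int = 2,
) -> dict:
    """Exponential time constants of the fragment's hole and electron curves.

    The hole curve is fitted monoexponentially with offset; the electron
    curve biexponentially (both configurable).  Flat curves return a
    zero-amplitude diagnostic instead of constants.
    """
    j = eh.fragment_names.index(fragment)
    good = np.isfinite(eh.hole[:, j])
    t = eh.t[good]
    out = {}
    for name, y, ncomp in (
        ("hole", eh.hole[good, j], hole_components),
        ("electron", eh.electron[good, j], electron_components),
    ):
        fit = fit_exponentials(t, y, n_components=ncomp)
        out[name] = fit
    return out
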