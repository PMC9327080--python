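"""Geometric and solvent observables.

Radial distribution functions use a finite-droplet convention (no periodic
box): pair distances are histogrammed with 0.3 Å bins, normalized by the
spherical shell volume and by a bulk density estimated from a stated
reference shell, so that a uniform-density cloud gives g(r) = 1.  The
time-resolved difference map and its 2.5 Å slice quantify first-solvation-
shell depletion after excitation; slices, bond-length series and fragment
curves are fitted with mono/biexponentials.  LIIC paths interpolate
internal coordinates (bonds, angles, dihedrals) linearly between two
endpoint structures, rebuild Cartesians by iterative least squares, and
report the barrier on a followed electronic state, which is an upper bound
to the true reaction barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_BIN_A = 0.3
DEFAULT_SLICE_A = 2.5


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFProfile:
    r_bins: np.ndarray        # bin edges, Å
    g: np.ndarray             # one value per bin
    n_frames: int
    rho_bulk: float = 0.0     # estimated bulk pair density (Å^-3)
    counts: np.ndarray | None = None

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_bins[:-1] + self.r_bins[1:])


def _shell_volumes(edges: np.ndarray) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)


def rdf_from_distances(
    distances,
    bin_width: float = DEFAULT_BIN_A,
    r_max: float | None = None,
    n_frames: int | None = None,
    reference_shell: tuple | None = None,
) -> RDFProfile:
    """g(r) from a flat collection of pair distances over ``n_frames`` frames.

    The bulk density is estimated from the counts in ``reference_shell``
    (default: the outer 60–90% of the radial range), which makes g -> 1
    in homogeneous regions of a finite droplet.
    """
    d = np.concatenate([np.ravel(x) for x in np.atleast_1d(distances)]) \
        if isinstance(distances, (list, tuple)) else np.ravel(distances)
    if n_frames is None:
        n_frames = 1
    if r_max is None:
        r_max = float(d.max()) + bin_width
    if d.size and r_max < d.max():
        warnings.warn("r_max below the largest pair distance; tail discarded")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    vols = _shell_volumes(edges)
    if reference_shell is None:
        reference_shell = (0.6 * r_max, 0.9 * r_max)
    lo, hi = reference_shell
    ref = (edges[:-1] >= lo) & (edges[1:] <= hi)
    if not np.any(ref):
        ref = slice(len(vols) // 2, None)
    rho = counts[ref].sum() / (vols[ref].sum() * n_frames)
    if rho <= 0:
        # sparse input (no bulk pairs): normalize to the whole-range density
        warnings.warn("empty bulk reference shell; normalizing to full-range density")
        rho = counts.sum() / (vols.sum() * n_frames)
    if rho <= 0:
        raise StructureError("no pair distances; cannot normalize g(r)")
    g = counts / (vols * rho * n_frames)
    return RDFProfile(r_bins=edges, g=g, n_frames=n_frames, rho_bulk=rho,
                      counts=counts)


def rdf(
    frames,
    pair_spec,
    bin_width: float = DEFAULT_BIN_A,
    r_max: float | None = None,
    reference_shell: tuple | None = None,
) -> RDFProfile:
    """g(r) between two atom selections over multi-frame coordinates.

    ``frames``: iterable of (n_atoms, 3) arrays; ``pair_spec``: pair of
    index sequences (group A, group B).
    """
    idx_a, idx_b = (np.asarray(s, dtype=int) for s in pair_spec)
    if idx_a.size == 0 or idx_b.size == 0:
        raise StructureError("pair selections must be non-empty")
    dists = []
    n_frames = 0
    for xyz in frames:
        xyz = np.asarray(xyz, dtype=float)
        diff = xyz[idx_a][:, None, :] - xyz[idx_b][None, :, :]
        d = np.linalg.norm(diff, axis=-1).ravel()
        dists.append(d[d > 1e-9])
        n_frames += 1
    if n_frames == 0:
        raise StructureError("need at least one frame")
    return rdf_from_distances(
        np.concatenate(dists), bin_width=bin_width, r_max=r_max,
        n_frames=n_frames, reference_shell=reference_shell,
    )


def time_resolved_rdf(
    distances_t,
    bin_width: float = DEFAULT_BIN_A,
    r_max: float | None = None,
    reference_shell: tuple | None = None,
) -> tuple:
    """Per-time g(r): ``distances_t`` is (n_times, ...) pair distances.

    Returns (edges, G) with G shape (n_times, n_bins).  All times share one
    binning and one bulk-density estimate per time slice.
    """
    profiles = [
        rdf_from_distances(np.ravel(dd), bin_width=bin_width, r_max=r_max,
                           n_frames=1, reference_shell=reference_shell)
        for dd in distances_t
    ]
    edges = profiles[0].r_bins
    for p in profiles[1:]:
        if p.r_bins.size != edges.size or not np.allclose(p.r_bins, edges):
            raise StructureError("time slices produced inconsistent binning")
    return edges, np.stack([p.g for p in profiles])


def rdf_difference_map(g_excited_t: np.ndarray, ground: RDFProfile) -> np.ndarray:
    """Delta g(r, t) = g_excited(r, t) - g_ground(r); shapes must share bins."""
    g_excited_t = np.asarray(g_excited_t, dtype=float)
    if g_excited_t.shape[1] != ground.g.size:
        raise StructureError("bin mismatch between excited map and ground profile")
    return g_excited_t - ground.g[None, :]


def rdf_slice_fit(
    diff_map: np.ndarray,
    t: np.ndarray,
    edges: np.ndarray,
    r_slice: float = DEFAULT_SLICE_A,
):
    """Monoexponential fit of the difference-map slice nearest ``r_slice``.

    The slice amplitude relaxes as ``c + A exp(-t/tau)``; returns
    ``(tau_fs, details)``.  A non-decaying slice produces a warning and a
    zero-amplitude diagnostic.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not (edges[0] <= r_slice <= edges[-1]):
        raise StructureError("slice radius outside the binned range")
    j = int(np.argmin(np.abs(centers - r_slice)))
    y = np.asarray(diff_map, dtype=float)[:, j]
    fit = fit_exponentials(np.asarray(t, float), y, n_components=1)
    if fit["status"] != "ok":
        warnings.warn("RDF slice is flat; no relaxation constant extracted")
        return float("nan"), fit
    return fit["tau"][0], fit


# ---------------------------------------------------------------------------
# exponential fitting (shared by slices, bonds, fragment curves)
# ---------------------------------------------------------------------------

def fit_exponentials(t, y, n_components: int = 1, n_starts: int = 4):
    """Least-squares mono/biexponential fit with offset.

    Model: ``y = c + sum_i A_i exp(-t/tau_i)``.  Multi-start initial guesses
    guard against local minima; returned time constants are sorted
    ascending.  Returns a dict with keys tau, amplitudes, offset, status,
    redchi.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size <= 3 * (2 * n_components + 1) // 2:
        raise StructureError("series too short for the requested model")
    span = y.max() - y.min()
    if span <= 1e-13 * max(1.0, np.abs(y).max()):
        return {"status": "zero-amplitude", "tau": [], "amplitudes": [],
                "offset": float(y.mean()), "redchi": 0.0}
    t0 = t - t[0]
    t_span = max(t0[-1], 1e-6)
    best = None
    starts = np.geomspace(t_span / 50.0, t_span / 2.0, n_starts)
    for tau_start in starts:
        params = lmfit.Parameters()
        params.add("c", value=float(y[-1]))
        if n_components == 1:
            params.add("tau1", value=tau_start, min=1e-4, max=1e8)
            params.add("a1", value=float(y[0] - y[-1]))
        else:
            params.add("tau1", value=tau_start / 4.0, min=1e-4, max=1e8)
            params.add("tau2", value=tau_start * 4.0, min=1e-4, max=1e8)
            params.add("a1", value=float((y[0] - y[-1]) / 2.0))
            params.add("a2", value=float((y[0] - y[-1]) / 2.0))

        def residual(p):
            model = np.full_like(t0, p["c"].value)
            for i in range(1, n_components + 1):
                model = model + p[f"a{i}"].value * np.exp(-t0 / p[f"tau{i}"].value)
            return model - y

        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return {"status": "failed", "tau": [], "amplitudes": [],
                "offset": float("nan"), "redchi": float("nan")}
    taus = [best.params[f"tau{i}"].value for i in range(1, n_components + 1)]
    amps = [best.params[f"a{i}"].value for i in range(1, n_components + 1)]
    order = np.argsort(taus)
    return {
        "status": "ok",
        "tau": [float(taus[i]) for i in order],
        "amplitudes": [float(amps[i]) for i in order],
        "offset": float(best.params["c"].value),
        "redchi": float(best.redchi),
    }


# ---------------------------------------------------------------------------
# pyramidalization
# ---------------------------------------------------------------------------

def pyramidalization(geometry, atoms=(0, 1, 2, 3), definition: str = "bond-plane"):
    """Signed pyramidalization angle p_{a,b,c,d} in degrees.

    ``atoms = (apex, central, sub1, sub2)``: the angle between the bond from
    the central atom to the apex atom and the plane spanned at the central
    atom by its two remaining substituents.  Signed by the orientation of
    the substituent-plane normal, in (-90, 90]; a planar arrangement gives
    0 and a mirror image flips the sign.  ``definition="improper"`` instead
    returns the improper dihedral apex–central–sub1–sub2.
    """
    xyz = np.asarray(geometry, dtype=float)
    a, b, c, d = atoms
    if len({a, b, c, d}) != 4:
        raise ValueError("pyramidalization needs four distinct atoms")
    va = xyz[a] - xyz[b]
    v1 = xyz[c] - xyz[b]
    v2 = xyz[d] - xyz[b]
    if definition == "improper":
        return dihedral_angle(xyz[a], xyz[b], xyz[c], xyz[d])
    n = np.cross(v1, v2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise StructureError("substituent atoms are collinear; plane undefined")
    s = np.dot(n / nn, va / np.linalg.norm(va))
    return float(np.degrees(np.arcsin(np.clip(s, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# internal coordinates and LIIC paths
# ---------------------------------------------------------------------------

def bond_length(p1, p2):
    return float(np.linalg.norm(np.asarray(p2) - np.asarray(p1)))


def bend_angle(p1, p2, p3):
    v1 = np.asarray(p1) - np.asarray(p2)
    v2 = np.asarray(p3) - np.asarray(p2)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(p1, p2, p3, p4):
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


_COORD_FUNCS = {"bond": bond_length, "angle": bend_angle, "dihedral": dihedral_angle}


def evaluate_internals(xyz, internal_spec) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    vals = []
    for item in internal_spec:
        kind, *idx = item
        vals.append(_COORD_FUNCS[kind](*(xyz[i] for i in idx)))
    return np.array(vals)


def _interp_internals(vA, vB, internal_spec, frac):
    """Linear interpolation; dihedrals go the short way around the circle."""
    out = np.empty_like(vA)
    for k, item in enumerate(internal_spec):
        if item[0] == "dihedral":
            dd = (vB[k] - vA[k] + 180.0) % 360.0 - 180.0
            out[k] = vA[k] + frac * dd
        else:
            out[k] = vA[k] + frac * (vB[k] - vA[k])
    return out


@dataclass
class LIICPath:
    frames: np.ndarray            # (n_points, n_atoms, 3) or (n_points, n_dof)
    energies: np.ndarray | None   # (n_points, n_states)
    barrier: float = 0.0
    followed_state: int = 0
    internals: np.ndarray | None = None
    internal_spec: list = field(default_factory=list)


def liic(
    geomA,
    geomB,
    n_points: int = 10,
    internal_spec=None,
    provider=None,
    followed_state: int = 0,
    tol: float = 1e-10,
) -> LIICPath:
    """Linear interpolation in internal coordinates between two structures.

    With ``internal_spec`` (list of ("bond", i, j) / ("angle", i, j, k) /
    ("dihedral", i, j, k, l)) each frame's Cartesians are rebuilt by
    iterative least squares so that its internals match the interpolated
    values to ``tol``; without a spec the interpolation is linear in the
    raw coordinates (Cartesian or model-mode space).  ``provider`` maps a
    geometry to per-state energies; the barrier on the followed state is
    ``max(E) - E[0]`` and is an upper bound to the true reaction barrier.
    """
    A = np.asarray(geomA, dtype=float)
    B = np.asarray(geomB, dtype=float)
    if A.shape != B.shape:
        raise StructureError("endpoint geometries must have identical shape")
    fracs = np.linspace(0.0, 1.0, n_points)
    internals = None
    if internal_spec:
        vA = evaluate_internals(A, internal_spec)
        vB = evaluate_internals(B, internal_spec)
        frames = [A]
        internals = [vA]
        guess = A.copy()
        for frac in fracs[1:-1]:
            # previous frame is the warm start for the next back-conversion
            target = _interp_internals(vA, vB, internal_spec, frac)

            def resid(x, tgt=target):
                cur = evaluate_internals(x.reshape(A.shape), internal_spec)
                d = cur - tgt
                for k, item in enumerate(internal_spec):
                    if item[0] == "dihedral":
                        d[k] = (d[k] + 180.0) % 360.0 - 180.0
                return d

            sol = least_squares(resid, guess.ravel(), xtol=tol, ftol=tol, gtol=tol)
            if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
                raise StructureError(
                    f"back-conversion failed at frame with fraction {frac:.3f}"
                )
            guess = sol.x.reshape(A.shape)
            frames.append(guess)
            internals.append(evaluate_internals(guess, internal_spec))
        frames.append(B)
        internals.append(vB)
        frames = np.stack(frames)
        internals = np.stack(internals)
    else:
        frames = A[None] + fracs.reshape([-1] + [1] * A.ndim) * (B - A)[None]
    energies = None
    barrier = 0.0
    if provider is not None:
        energies = np.stack([np.atleast_1d(provider(f)) for f in frames])
        e_path = energies[:, followed_state]
        barrier = float(max(e_path.max() - e_path[0], 0.0))
    return LIICPath(
        frames=frames, energies=energies, barrier=barrier,
        followed_state=followed_state, internals=internals,
        internal_spec=list(internal_spec or []),
    )
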