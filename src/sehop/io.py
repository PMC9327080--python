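"""Shared format readers/writers: multi-frame XYZ, ensemble tables, manifests.

Geometry series use the multi-frame XYZ convention via MDAnalysis; tabular
data are CSV/TSV with 12-significant-digit floats; manifests are JSON with
the configuration hash and seeds needed to regenerate an output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .propagator import Ensemble, Trajectory

FLOAT_FMT = "%.12g"


def write_xyz(frames, path, symbols=None, comments=None) -> None:
    """Write (n_frames, n_atoms, 3) coordinates (Å) as multi-frame XYZ."""
    import MDAnalysis as mda

    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if symbols is None:
        symbols = ["X"] * n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", symbols)
    u.add_TopologyAttr("elements", symbols)
    with mda.Writer(str(path), n_atoms) as w:
        for i, xyz in enumerate(frames):
            u.atoms.positions = xyz
            w.write(u.atoms)


def read_xyz(path):
    """Read a multi-frame XYZ file; returns (frames, symbols)."""
    import MDAnalysis as mda

    u = mda.Universe(str(path), format="XYZ")
    frames = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    symbols = list(u.atoms.names)
    return frames, symbols


# ---------------------------------------------------------------------------
# ensemble (state-series) tables
# ---------------------------------------------------------------------------

def ensemble_to_frame(ensemble: Ensemble) -> pd.DataFrame:
    """Long-format (traj, t_fs, state) table of the spin-free state series."""
    rows = []
    for b, tr in enumerate(ensemble.trajectories):
        rows.append(
            pd.DataFrame(
                {"traj": b, "t_fs": ensemble.t,
                 "state": np.asarray(tr.active_spinfree, int)}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_ensemble(ensemble: Ensemble, path) -> None:
    ensemble_to_frame(ensemble).to_csv(path, index=False, float_format=FLOAT_FMT)
    hops = []
    for b, tr in enumerate(ensemble.trajectories):
        for (t_hop, src, dst, ok) in tr.hops:
            hops.append((b, t_hop, src, dst, int(ok)))
    hop_path = Path(str(path)).with_suffix(".hops.csv")
    pd.DataFrame(hops, columns=["traj", "t_fs", "src", "dst", "accepted"]).to_csv(
        hop_path, index=False, float_format=FLOAT_FMT
    )


def read_ensemble(path, state_labels) -> Ensemble:
    df = pd.read_csv(path)
    t = np.sort(df["t_fs"].unique())
    trajs = []
    hop_path = Path(str(path)).with_suffix(".hops.csv")
    hops_df = pd.read_csv(hop_path) if hop_path.exists() else None
    for b, sub in df.groupby("traj"):
        sub = sub.sort_values("t_fs")
        hops = []
        if hops_df is not None:
            for r in hops_df[hops_df["traj"] == b].itertuples():
                hops.append((float(r.t_fs), int(r.src), int(r.dst), bool(r.accepted)))
        trajs.append(
            Trajectory(t=t, active_spinfree=sub["state"].to_numpy(int),
                       hops=hops, seed_id=int(b))
        )
    return Ensemble(
        trajectories=trajs, t=t, n_states_spinfree=len(state_labels),
        state_labels=tuple(state_labels),
    )


def write_manifest(path, stage: str, config: dict, outputs: list, seeds=None) -> None:
    from . import __version__
    from .propagator import config_hash

    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seeds": seeds if seeds is not None else config.get("seed"),
        "outputs": [str(o) for o in outputs],
        "version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
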