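"""Absorption-spectrum construction and stochastic initial-state selection.

The ground-state absorption spectrum is a sum over Gaussians centered at the
vertical excitation energies of an excitation line list, with heights
proportional to the oscillator strengths and a fixed full width at half
maximum (0.25 eV by default).  Initial excited states for the nonadiabatic
dynamics are drawn stochastically inside a pump window (3.45–3.59 eV by
default): the line with the highest oscillator strength is accepted with
probability one and every other in-window line independently with
probability f / f_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_FWHM_EV = 0.25
DEFAULT_WINDOW_EV = (3.45, 3.59)


@dataclass(frozen=True)
class SpectrumLine:
    """One vertical excitation: energy (eV), oscillator strength, state labels."""

    energy: float
    osc_strength: float
    from_state: str = "S0"
    to_state: str = "S1"
    point_id: int = 0

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError("line energy must be positive")
        if self.osc_strength < 0:
            raise ValueError("oscillator strength must be non-negative")


@dataclass
class SpectralGrid:
    """1D broadened spectrum on a strictly increasing energy grid."""

    axis: np.ndarray
    intensity: np.ndarray
    fwhm: float

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("energy grid must be strictly increasing")


class EmptyLineListError(ValueError):
    pass


def broaden_spectrum(
    lines,
    fwhm: float = DEFAULT_FWHM_EV,
    grid: np.ndarray | None = None,
    points_per_fwhm: int = 25,
) -> SpectralGrid:
    """Sum-over-Gaussians broadening of an excitation line list.

    Each line contributes ``f * exp(-(E - E0)^2 / 2 sigma^2)`` with
    ``sigma = fwhm / (2 sqrt(2 ln 2))``.  The default grid covers
    [min(E) - 3 sigma, max(E) + 3 sigma].
    """
    lines = list(lines)
    if not lines:
        raise EmptyLineListError("cannot broaden an empty line list")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    e0 = np.array([l.energy for l in lines])
    f = np.array([l.osc_strength for l in lines])
    sigma = fwhm * FWHM_TO_SIGMA
    if grid is None:
        lo, hi = e0.min() - 3 * sigma, e0.max() + 3 * sigma
        n = max(int(np.ceil((hi - lo) / fwhm * points_per_fwhm)), 10)
        grid = np.linspace(lo, hi, n)
    grid = np.asarray(grid, dtype=float)
    inten = np.sum(
        f[:, None] * np.exp(-((grid[None, :] - e0[:, None]) ** 2) / (2 * sigma**2)),
        axis=0,
    )
    return SpectralGrid(axis=grid, intensity=inten, fwhm=fwhm)


def selection_probabilities(lines, window=DEFAULT_WINDOW_EV) -> np.ndarray:
    """Acceptance probability per line: f / f_max inside the (inclusive)
    window, 0 outside.  Probabilities are not renormalized after the window
    truncation; the rule is applied as stated."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window lower bound must be below upper bound")
    e = np.array([l.energy for l in lines])
    f = np.array([l.osc_strength for l in lines])
    inside = (e >= lo) & (e <= hi)
    if not np.any(inside) or f[inside].max() <= 0:
        return np.zeros(len(lines))
    fmax = f[inside].max()
    return np.where(inside, f / fmax, 0.0)


def select_initial_states(
    lines,
    window=DEFAULT_WINDOW_EV,
    seed: int = 0,
    subsample: int | None = None,
    subsample_seed: int | None = None,
):
    """Stochastic initial-condition selection inside the pump window.

    Each in-window line is accepted independently with probability
    ``f / f_max`` (Bernoulli); the maximum-f line is therefore always
    selected.  Returns a list of ``(point_id, to_state)`` tuples.  An
    optional uniform subsample (own seed) mirrors the reduction of a
    selected pool to a fixed trajectory count.
    """
    lines = list(lines)
    probs = selection_probabilities(lines, window=window)
    if probs.max(initial=0.0) == 0.0:
        warnings.warn("no line inside the selection window; empty selection")
        return []
    rng = np.random.default_rng(seed)
    u = rng.random(len(lines))
    chosen = [
        (l.point_id, l.to_state) for l, pi, ui in zip(lines, probs, u) if ui < pi
    ]
    if subsample is not None and subsample < len(chosen):
        rng2 = np.random.default_rng(
            subsample_seed if subsample_seed is not None else seed + 1
        )
        keep = rng2.choice(len(chosen), size=subsample, replace=False)
        chosen = [chosen[k] for k in sorted(keep)]
    return chosen


# ---------------------------------------------------------------------------
# I/O: tab-separated line lists, two-column CSV spectra
# ---------------------------------------------------------------------------

def lines_to_frame(lines) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "point_id": [l.point_id for l in lines],
            "from_state": [l.from_state for l in lines],
            "to_state": [l.to_state for l in lines],
            "energy_eV": [l.energy for l in lines],
            "f": [l.osc_strength for l in lines],
        }
    )


def write_line_list(lines, path) -> None:
    lines_to_frame(lines).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_line_list(path):
    df = pd.read_csv(path, sep="\t")
    return [
        SpectrumLine(
            energy=float(r.energy_eV),
            osc_strength=float(r.f),
            from_state=str(r.from_state),
            to_state=str(r.to_state),
            point_id=int(r.point_id),
        )
        for r in df.itertuples()
    ]


def write_spectrum(grid: SpectralGrid, path) -> None:
    pd.DataFrame({"energy_eV": grid.axis, "intensity": grid.intensity}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_spectrum(path) -> SpectralGrid:
    df = pd.read_csv(path)
    axis = df["energy_eV"].to_numpy()
    de = np.diff(axis)
    fwhm = float(de.mean() * 25) if de.size else 0.25
    return SpectralGrid(axis=axis, intensity=df["intensity"].to_numpy(), fwhm=fwhm)
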