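"""Ground-state absorption spectrum and stochastic initial-state selection.

Samples the harmonic Wigner distribution of the vibronic model's ground
state (500 points, standing in for ground-state QM/MM snapshots), computes
vertical S0 -> Sn excitation lines with oscillator strengths at each point,
broadens them with 0.25 eV FWHM Gaussians, and stochastically selects
initial excited states inside the 3.45-3.59 eV pump window with
probability f / f_max.  Writes the line list, the spectrum and the
selected initial conditions under results/.
"""

from pathlib import Path

import numpy as np

from sehop import model as M
from sehop import spectra as S

OUT = Path(__file__).resolve().parent.parent / "results"
N_POINTS = 500
SEED = 2026


def main():
    OUT.mkdir(exist_ok=True)
    model = M.default_model()
    points = M.sample_wigner(model, N_POINTS, seed=SEED)
    lines = []
    for pt in points:
        res = M.evaluate(model, pt.q)
        for n in range(1, model.n_singlets):
            de = res.energies_spinfree[n] - res.energies_spinfree[0]
            f = (2.0 / 3.0) * de * float(np.sum(res.dipoles[n] ** 2))
            lines.append(S.SpectrumLine(energy=de, osc_strength=f,
                                        from_state="S0", to_state=f"S{n}",
                                        point_id=pt.seed_id))
    S.write_line_list(lines, OUT / "absorption_lines.tsv")
    grid = S.broaden_spectrum(lines, fwhm=0.25)
    S.write_spectrum(grid, OUT / "absorption_spectrum.csv")
    peak = grid.axis[np.argmax(grid.intensity)]
    print(f"absorption band peaks at {peak:.2f} eV "
          f"({1239.84 / peak:.0f} nm) from {len(lines)} lines")

    window = (3.45, 3.59)
    selected = S.select_initial_states(lines, window=window, seed=SEED + 1)
    per_state = {}
    for pid, to_state in selected:
        per_state[to_state] = per_state.get(to_state, 0) + 1
    print(f"selected {len(selected)} initial conditions in "
          f"{window[0]}-{window[1]} eV: {per_state}")
    with open(OUT / "initial_conditions.csv", "w") as fh:
        fh.write("point_id,to_state\n")
        for pid, st in selected:
            fh.write(f"{pid},{st}\n")


if __name__ == "__main__":
    main()
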