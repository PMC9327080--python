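"""Physical constants and unit conversions.

Internal unit convention: energies in eV, times in fs, distances in Å.
Nuclear coordinates are dimensionless mass–frequency-scaled normal-mode
displacements, in which the ground-state harmonic potential is
``sum_j omega_j * q_j**2 / 2`` and the kinetic energy ``sum_j omega_j * p_j**2 / 2``.
"""

# hbar in eV*fs
HBAR_EV_FS = 0.6582119569509066

# energy conversions
EV_PER_CM1 = 1.23984193e-4
EV_PER_HARTREE = 27.211386245988
EV_PER_NM_PRODUCT = 1239.84193  # E[eV] * lambda[nm]

# Boltzmann constant in eV/K
KB_EV = 8.617333262e-5

# bohr radius in Å
BOHR_ANGSTROM = 0.529177210903

# atomic mass unit in electron masses (for Cartesian embedding helpers)
AMU_TO_ME = 1822.888486209


def cm1_to_ev(x):
    return x * EV_PER_CM1


def ev_to_cm1(x):
    return x / EV_PER_CM1


def hartree_to_ev(x):
    return x * EV_PER_HARTREE


def ev_to_hartree(x):
    return x / EV_PER_HARTREE


def ev_to_nm(e_ev):
    return EV_PER_NM_PRODUCT / e_ev


def nm_to_ev(lam_nm):
    return EV_PER_NM_PRODUCT / lam_nm
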