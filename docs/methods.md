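# Methods

This note documents the models, numerical choices and limitations of the
package in one place.  Energies are in eV, times in fs, distances in Å;
nuclear coordinates are dimensionless mass–frequency-scaled normal modes,
in which the ground-state potential is Σ ω_j q_j²/2 and the kinetic energy
Σ ω_j p_j²/2.

## Vibronic model

The electronic-structure backend is a linear vibronic coupling model: a
diabatic potential matrix linear in the mode displacements around a
harmonic reference, diagonal energies ε_n + Σ κ_nj q_j, off-diagonal
couplings Σ λ_nmj q_j (plus optional constant couplings η_nm for
scattering-type setups), restricted to one spin multiplicity per block.
Spin–orbit coupling is geometry independent and resolved into Cartesian
components per singlet–triplet pair; the spin Hamiltonian over the
triplet M_S sublevels uses the standard spherical relations
⟨S|T,±1⟩ = ∓(H_x ± iH_y)/√2, ⟨S|T,0⟩ = H_z, which preserve the
root-sum-square effective SOC.  The summation convention of the effective
SOC (over Cartesian components and sublevels) is the standard one; it is
stated here because the source expression could not be rendered from the
extracted text.

The default model has 3 modes and 6 spin-free states:

- ω = (0.12, 0.08, 0.18) eV: one C=Se-stretch-like tuning mode, two
  coupling modes.  Mode frequencies are in the mid-IR range typical of
  double-bond stretches and ring deformations.
- ε = (0, 2.76, 3.61, 2.55, 2.63, 3.10) eV; the first five follow the
  ADC(2) vertical excitations of 6SeGua, T3 is placed just below S2 to
  give the triplet density of states the dynamics needs.
- κ chosen so that the S2/S1 crossing seam and the singlet–triplet seams
  are reachable from the Franck–Condon region (opposite S1/S2 gradients
  along the tuning mode).  These are design inputs of the surrogate, not
  fitted quantities; the published time constants are *not* targeted by
  the model dynamics.
- SOC magnitudes follow the El-Sayed pattern: 120 cm⁻¹ for S1–T1 and
  S2–T2 (different orbital character), 15 cm⁻¹ otherwise.  They are
  config parameters, not literature values.

Spin-free adiabatic states are obtained per multiplicity block; gradients
are analytic (Hellmann–Feynman), degenerate sorting is by energy with
maximal-overlap sign alignment against the previous geometry.

Wigner sampling of the harmonic ground state gives Var(q) = Var(p) = 1/2
per mode at T = 0, scaled by coth(ħω/2kT) at finite temperature.

## Surface hopping

Hopping runs in the spin-mixed (diagonal) basis of the full 12×12
Hamiltonian (spin-free potential expanded over sublevels + SOC).  The
electronic amplitudes are propagated in the model's global diabatic frame
— exact up to the substep discretization, the natural limit of local
diabatization when overlaps are analytic — with the Hamiltonian
interpolated linearly across each nuclear step and exponentiated per
0.02 fs substep via eigendecomposition.  Hop probabilities use the
flux (Granucci–Persico) form built from the accumulated step propagator
transformed to the adiabatic basis; this form is invariant to the
arbitrary eigenvector phases.  All kernels are vectorized over a batch of
trajectories; the per-trajectory RNG stream is derived from
(master seed, trajectory index), so results are independent of batch
composition.

Choices worth stating:

- **Velocity rescaling** at hops is uniform along the momenta; no
  nonadiabatic coupling vectors exist in this representation.  A hop is
  frustrated when the kinetic energy cannot cover the potential-energy
  jump; frustrated hops leave momenta unchanged (a reversal switch
  exists: `frustrated_reversal=True`).  A hop from exactly zero kinetic
  energy is accepted only if isoenergetic.
- **Decoherence**: energy-based correction with C = 0.1 a.u. applied to
  the spin-mixed amplitudes each nuclear step, using the total nuclear
  kinetic energy (in the reduced-mode model all kinetic energy is solute
  kinetic energy).  The kinetic energy is floored at 1e-8 eV so the
  decoherence time stays finite for momentarily resting nuclei.  The
  correction can be disabled (`decoherence_c=None`); the Landau–Zener
  scattering validation runs without it, because a single-passage
  comparison probes exactly the coherence the correction is designed to
  suppress in multi-crossing dynamics.
- **Landau–Zener check**: the analytic probability
  exp(−2π c²/(ħ v |Δκ|)) is evaluated with the velocity *at the
  crossing* (energy conservation on the incoming adiabat), and incident
  momenta are restricted to the fast-passage regime where the asymptotic
  formula is itself valid.  The residual method-vs-formula bias measured
  at 10⁴ trajectories per momentum is ≈ +0.3% absolute, well inside the
  3-binomial-SE band of the test.
- Spin-free state assignment of the active spin-mixed state is by maximal
  squared overlap with the spin-expanded spin-free eigenvectors, sublevels
  aggregated.  Total-energy drift between hops is audited
  (< 1e-4 eV/ps-scale tolerance) and flagged, not silently accepted.

## Kinetics

Populations are trajectory fractions per spin-free state.  Time constants
come from fitting the closed-form solution of an irreversible first-order
network jointly to all compartment curves (unweighted least squares via
lmfit; eigendecomposition of the rate matrix, expm fallback for defective
cases).  Initial fractions are fixed at the data's t = 0 values.

The default three-channel topology is S2 → S1, S1 → T, S2 → T.  For
*recovery at n = 99*, the triplet manifold is resolved into T1 (fed by
S1) and T2,3 (fed by the direct channel): with a single merged sink the
slow direct channel is practically unidentifiable at this ensemble size
(fits diverge in a quarter of replicates), while the resolved sinks — the
same resolution the published fit reports — make it well conditioned.
Replicate-aggregated constants are harmonic means over replicates
(inverse of the averaged fitted rate): τ̂ = 1/k̂ is heavy-tailed when k̂
is noisy, so averaging rates rather than time constants is the stable
estimator.  Bootstrap errors resample trajectories with replacement and
refit; failed resamples are skipped and counted.

## Transient absorption

ESA lines connect the active state to same-multiplicity states, with
f = (2/3)ΔE|μ|² from the rotated excited-to-excited dipoles.  The display
TAS is a trajectory-averaged sum of separable 2D Gaussians (0.25 eV ×
200 fs FWHM); rise-constant fits always use the *unconvoluted* band
integrals, as temporal convolution would bias τ upward by the IRF width.
Ground-state bleach is subtracted as scale · Φ((t − t0)/σ_IRF) · A_g(E)
with Φ the normal CDF (an erf step); the functional form of the temporal
step is an assumption and is configurable.  The bleach scale defaults to
the excited-trajectory fraction times the unit-area-normalized ground
spectrum and is exposed as a parameter.  The default model's six states
give ESA gaps below 3.25 eV only; the high-energy band requires the
enlarged probe-state space (15 singlets / 13 triplets in the source
setup), so high-band fits are exercised on synthetic signals.

## Solvent structure

g(r) uses 0.3 Å bins and a finite-droplet normalization: bulk density is
estimated from a reference shell (default the outer 60–90% of the radial
range), so a uniform cloud gives g = 1 without periodic boundaries.  For
sparse inputs with an empty reference shell the normalization falls back
to the whole-range density (warned).  The time-resolved difference map
subtracts the ground-state profile bin by bin; the 2.5 Å slice is fitted
as c + A e^(−t/τ).

## Charge transfer

The one-electron transition density is represented by per-configuration
hole/particle site weights declared in the model (Se site vs rest); the
adiabatic character is the amplitude-squared mixture with the closed-shell
ground configuration excluded (it carries no electron–hole pair).
Fragment fractions are site-weight sums; hole curves are fitted mono-,
electron curves biexponentially, both with an offset term (offsets are
reported).

## Geometry and LIIC

Pyramidalization p_{a,b,c,d} is the signed angle between the bond b→a and
the plane spanned at b by c and d, in (−90°, 90°]; an improper-dihedral
alternative is available (`definition="improper"`) since the source does
not fix the formula.  LIIC interpolates bonds/angles/dihedrals linearly
(dihedrals along the shorter arc) and rebuilds Cartesians by iterative
least squares from the previous frame (tolerance 1e-10); without an
internal-coordinate list the interpolation is linear in the raw
coordinates.  The barrier is max(E_path) − E(frame 0) on the followed
state — an upper bound to the true barrier by construction.

## Synthetic generators

Each generator emulates one data product with declared noise: Markov-jump
ensembles (binomial trajectory-count noise by construction; waiting times
exponential; 85/15 S2/S1 initial split, 99 trajectories, 1 ps defaults),
band integrals and fragment curves (Gaussian noise at a stated SNR,
default 20), solvent distances (4 first-shell waters near 2.5 Å with
exponential departure to 4 Å, 36 bulk waters uniform in volume, Gaussian
jitter).  Ground truth travels in a `meta` dict, never in file names.
What the generators do *not* emulate: anharmonicity, explicit water
structure beyond the two-shell caricature, correlated noise between
observables, and any geometry dependence of the SOC.  Recovery tests
therefore demonstrate the correctness and calibration of the estimators,
not the accuracy of the underlying quantum chemistry.

## Problem sizes and tolerances

Recovery protocols use the study's ensemble sizes (99 trajectories, 500
solvent trajectories, 50 seeds for signal fits) with replicate counts
chosen so the aggregated estimate's sampling error is a few percent:
120 replicates for the three-channel fit, 50 for the global
two-compartment fit and the signal fits, 20 for the solvent slice.  Jump
ensembles for fitting are discretized at 4 fs (the fit is grid-invariant
on noiseless input; 4 fs keeps 251 points over 1 ps).  Noiseless-fit
tests assert recovery at 0.1–2%; noisy recoveries at 5–15% depending on
the stated SNR.  The deterministic triplet fraction at 1 ps from the
three-channel model with the published constants and the 85/15 split
evaluates to 93.1%.

## Known limitations

- The propagator's gradients and couplings are exact for the model; no
  conclusions about ab initio surfaces follow from its validation.
- Hopping in the diagonal basis with uniform rescaling is one defensible
  SHARC-style variant; direction-resolved rescaling is not implemented.
- The merged-sink kinetic topology remains the default for exploratory
  fits but is poorly identified for slow direct channels at small n; use
  resolved sinks (as the recovery protocols do) for quantitative work.
- The droplet g(r) normalization depends on the reference-shell choice
  for strongly inhomogeneous clouds; the reference shell is a parameter
  and is recorded with the profile.
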