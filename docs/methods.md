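# Methods

This note records the models implemented in `mpasl`, their assumptions, the
numerical choices behind them, and what the synthetic-data studies do and do
not demonstrate.

## Signal model

A multi-phase PCASL acquisition samples the labelling response at RF phase
offsets θ (here always in degrees at the API surface).  The per-voxel model
is the modified Fermi line shape

    f(θ) = Ms − ΔM · b(|θ − ϕ|),   b(d) = 2 / (1 + exp((d − α)/β)) − 1,

where `|θ − ϕ|` is always the wrapped circular distance in [0°, 180°].
`b` is +1 deep inside the inversion notch (signal `Ms − ΔM`, maximal
labelling) and −1 far outside (control, `Ms + ΔM`), so the label–control
span is `2ΔM`.  Following the convention that the fitted `ΔM` map is used
directly as a label−control difference image, the CBF calibration divides
by `2·α_inv` (see below) and no extra factor of 2 is applied to `ΔM`
itself.  Line-shape constants default to (α, β) = (54°, 13°) for human 3T
and (70°, 19°) for rat 9.4T pulse trains.

## Inference

`fit_multiphase` is a MAP estimator with independent Gaussian priors and a
Laplace (curvature) approximation for posterior variances:

* **Priors.** "Low-precision" means prior sd 10⁶ in native units
  (effectively flat); "high-precision" means prior sd 10⁻⁶ (the parameter
  is effectively a constant).  Fixing the phase — the heart of the
  multi-stage correction — is expressed as a high-precision prior centred
  on the supplied value, and the phase prior distance is computed on the
  circle.
* **Optimiser.** Damped (Levenberg-style) Gauss–Newton with analytic
  Jacobians, run from a deterministic data-driven initialisation:
  `Ms ← series mean`, `ΔM ← (max − min)/2`, `ϕ ← θ at the series minimum`.
  Convergence when the relative change of all parameters falls below 10⁻⁶,
  with a 100-iteration cap; series hitting the cap are flagged, not
  discarded.  All series in a batch (a whole volume, or 10⁵ Monte-Carlo
  replicates) are iterated together with vectorised 3×3 solves.
* **Positivity.** `ΔM` is projected onto its physical domain `ΔM ≥ 0` at
  each step.  At very low amplitude-to-noise ratios this projection itself
  contributes a positive bias to the fixed-phase estimator; at the
  operating points of interest (amplitude-to-noise ≳ 1) the fixed-phase
  fit is essentially unbiased.
* **Noise.** The additive noise sd is estimated from the residuals over
  all samples (phases × repeats) with a degrees-of-freedom correction
  `n − p`, `p` being the number of effectively free parameters.  The
  SNR proxy reported per voxel is `M̂s / σ̂`.
* **Bias behaviour.** With all three parameters free the estimator
  overestimates `ΔM` at finite SNR — a local optimiser started from the
  data-driven phase guess partially locks onto noise, and the bias grows
  as SNR falls (≈7% at SNR 63 / ΔM 2.1% of Ms; ≈22% at SNR 40 / 2%;
  hundreds of percent in the noise-dominated regime SNR 10 / 1%).  Fixing
  the phase at a high-SNR regional estimate removes almost all of it.
  The exact magnitude of the free-fit bias in the deeply noise-dominated
  regime is estimator-specific: any fixed-phase *linear* refit is exactly
  unbiased there, and no estimator without strongly informative priors can
  produce a small, precisely reproducible bias value at amplitude-to-noise
  0.1 (the per-realisation spread of the amplitude estimate is ~5× the true
  amplitude).  The simulation tables therefore report the Monte-Carlo
  standard error alongside each mean, and both signed (bias) and absolute
  errors.

The velocity-dependent lookup model is fitted with the phase pinned:
candidate velocities are profiled on a dense grid spanning the table
(step 0.25 cm/s), the amplitude and offset are solved in closed form per
candidate, and the arg-min is polished with a parabolic step.  Estimates
never leave the tabulated velocity range (no extrapolation).

## Supervoxel phase clustering

The off-resonance phase is treated as a unit vector (cos ϕ, sin ϕ), so all
distances are circular.  The phase map is first canonicalised by rotating
its global circular mean to zero, which makes the partition exactly
invariant to a constant phase shift.  The stages are:

1. Gaussian pre-smoothing of the two channels (σ = 0.8 voxels, default);
2. 3D SLIC supervoxels on the smoothed channels (compactness 0.1,
   ~96 supervoxels by default);
3. k-means (K = 4, one class per feeding artery) on supervoxel
   circular-mean phases, followed by a few ICM sweeps on the supervoxel
   adjacency graph — a supervoxel disagreeing with all its neighbours at
   these SNRs is almost always noise;
4. a voxel-level refinement: mean-field updates of a von Mises + uniform
   outlier mixture over the *raw* per-voxel phase vectors with a Potts
   spatial prior (26-neighbourhood, weight 1.5), then a few hard sweeps
   with the data term damped.  The raw vectors matter here: the smoothed
   field blurs territory boundaries by ~2 voxels, whereas the Potts term
   supplies the noise averaging without displacing the boundary.  When the
   voxel-wise fit supplies Laplace phase variances they weight the data
   term (clipped to the equivalent of 8°–90° sd); voxels whose fitted
   phase is pure noise are absorbed by the outlier component
   (prior weight 0.3).

Classes are renumbered by ascending canonical mean phase, so the labelling
is deterministic given the seed.  The number of classes is an anatomical
prior (4 feeding arteries), not a data-driven choice; classes are not
constrained to be spatially connected, the Potts term only encourages
coherence.

## Bloch simulation of inversion profiles

PCASL inversion is flow-driven: a spin moving at laminar speed v through
the labelling plane sees a train of Hanning pulses whose phase advances by
Δψ = θ − ϕ per interval, plus gradient-induced precession.  The propagator
uses the hard-pulse approximation properly understood: each shaped pulse is
discretised into hard sub-pulses (instantaneous rotations, Hanning-weighted
flips summing to the nominal flip angle), interleaved with exact free
precession in the piecewise-constant gradient (labelling gradient during
the pulse window; the refocusing value implied by the interval-mean
gradient for the remainder).  Numerical choices:

* sub-pulse count adapts so intra-pulse precession stays ≤ 0.25 rad per
  sub-pulse (8–128 sub-pulses);
* a pulse is skipped entirely once the intra-pulse dephasing
  γ·G_label·|z|·τ exceeds 16π — far beyond the pulse bandwidth the RF has
  no effect; the threshold is deliberately generous so that aliased
  labelling planes (spacing 2π/(γ·G_mean·Δt)) remain inside the simulated
  zone.  Halving/doubling these settings changes rat profiles by < 10⁻³;
* the spin path covers the RF-active zone with a small margin, with a 2 cm
  minimum (±2 cm for the rat train; ~±32 cm for the human train, whose
  mean gradient of 0.06 mT/m makes the active zone very long);
* transverse decay with T2 = 200 ms for arterial blood; T1 neglected;
* propagation stops at the path end or when Mz has settled (< 10⁻⁴ change
  over 10 pulses), checked only downstream of the plane.

The test suite holds the propagator to within 0.02 Mz of an independent
brute-force integrator (10 µs steps aligned to pulse boundaries, rotation
about the instantaneous effective field, no culling); observed agreement is
~10⁻³.  Laminar flow is modelled as Poiseuille: centreline speed twice the
mean, six equal-width annuli at mid-annulus speeds weighted by annular area
((2k−1)/36).  Lookup tables hold 200 phase offsets over ±π per tabulated
mean speed (5, 10, 20, 30, 40, 50, 60 cm/s by default), serialised as
versioned JSON; evaluation is bilinear (wrapped phase × velocity), exact at
the nodes.  The tabulated Mz is mapped into the signal model as
`g = −Mz`, so full inversion aligns with the Fermi bracket's +1.

The simulated human-parameter profile at 30 cm/s is well described by a
modified Fermi shape (best-fit RMS residual < 5% of the profile amplitude),
with a narrower notch than (α, β) = (54°, 13°); those constants were
calibrated on a different pulse train, and the lookup model exists
precisely because the Fermi shape is only an approximation.  Cardiac
pulsatility and multi-artery/off-isocentre geometry are not modelled.

## Pipeline and calibration

`run_multistage` executes the five stages on a 4D volume (phase-major or
repeat-major ordering declared in the config; repeats enter the likelihood
directly).  In velocity mode the final refit swaps the Fermi model for the
lookup model; by default velocity is estimated per cluster (where SNR
permits it) and held fixed voxel-wise, with a voxel-wise option.  CBF
calibration is the standard single-PLD PCASL formula

    CBF = 6000 λ ΔM exp(PLD/T1b) / (2 α_inv T1b M0_blood (1 − exp(−τ/T1b)))

in mL/100g/min, clamped at zero; `M0_blood` is supplied by the user (a
full CSF reference-region chain is out of scope).  The high-variability
mask flags voxels whose series deviates more than 10% from its mean.

## Synthetic data

The generator emulates the structure of an MP-PCASL acquisition at the
simulation conditions used throughout: Ms = 1000, 8 equally spaced phases,
white Gaussian noise of sd Ms/SNR (SNR defined against the static tissue
magnitude), amplitudes 1–32% of Ms, quadrant or Voronoi territory
geometries with per-territory phases (and optionally velocities, via a
lookup table), on a default 32×32×10 grid — a downscaled preclinical
matrix chosen to keep whole-volume tests fast.  Every voxel's generating
parameters are stored as ground-truth maps and round-trip through the
NIfTI/JSON writers.  What passing tests show is therefore statistical
correctness of the estimators under the stated noise model; they do not
exercise motion, physiological noise, partial-volume effects, transit
delays or coil-sensitivity structure, all of which real data have and the
generator deliberately omits.

## Simulation studies and problem sizes

* Bias tables: 10,000 replicates per (SNR, ΔM/Ms, phase-mode) cell by
  default (20,000–50,000 in the reproduction script, where the wide
  per-replicate spread at low SNR makes the larger counts worthwhile);
  cells are seeded independently from the master seed, so tables are
  reproducible cell by cell.
* Phase-mismatch underestimation: the default ("lineshape") convention is
  the closed-form relative loss of the line shape itself,
  `1 − b(δ)/b(0)`, whose 5%/10% thresholds are 13.4°/21.4° (rat shape) and
  12.6°/19.1° (human shape); a "refit" mode instead refits amplitude and
  offset to sampled 8-phase data with the phase fixed off-truth, which
  re-absorbs part of the loss into the offset and yields larger
  thresholds.  Thresholds are found by bisection to 0.05°.
* Velocity-error study: true velocities uniform over the interior of the
  tabulated range ([10.5, 54.5] cm/s), amplitude 2.1% of Ms (the
  preclinical operating point), phase fixed at truth, matched velocity
  draws across SNR levels for paired comparisons.  RMS errors at these
  SNRs sit near the uninformative limit of the bounded velocity range —
  which is the point: voxel-level SNR does not support velocity
  estimation, regional averaging does.

## Known limitations

* The free-fit bias magnitude in deeply noise-dominated regimes depends on
  optimiser details (initialisation, damping, projection); only its sign,
  monotone decrease with SNR, and removal by phase-fixing are robust
  properties.
* The clustering refinement assumes territory-scale spatial coherence of
  the phase; pathologies producing fine-grained phase structure would
  violate it.
* Velocity estimates are confined to the lookup range and pile up at its
  edges when the data are uninformative, which inflates RMS errors near
  the bounds.
* Calibration accepts user-supplied constants; no attempt is made to
  estimate M0 from a reference region.
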