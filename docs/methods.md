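# Methods

## The physical model

EEG analysis traditionally invokes the quasi-static approximation: all time
derivatives are dropped from Maxwell's equations and the potential obeys a
static Poisson equation driven by assumed dipole sources.  This package
implements the alternative: keep the displacement current.  Charge
continuity with D = εE and J = σ·E then yields, for the potential
φ (E = −∇φ),

    ∂t ∇²φ = −∇·(Σ·∇φ),        Σ = σᵢⱼ/ε   (units 1/s)

a *wave* equation whose coefficient is the scaled conductivity tensor.
Linear analysis with φ ~ exp[i(k·x − Ωt)] gives the complex dispersion
relation

    γ ≡ Im Ω = (kᵀΣk)/|k|²        (damping)
    ω ≡ Re Ω = −(∂ᵢΣᵢⱼ kⱼ)/|k|²   (oscillation)

Two features matter.  First, ω ∝ 1/|k| — the opposite of an EM wave — so
long waves oscillate fastest and can span the whole head.  Second, with
measured gray/white-matter values (σ ≈ 2.75–2.77×10⁻² S/m,
ε ≈ 2.76–4.07×10⁷ ε₀) the bulk damping rate γ = σ/(εε₀) is 75–115 s⁻¹:
bulk waves die within tens of milliseconds.  Waves survive only in thin
boundary layers where the conductivity falls across the fiber direction.
There the leading-order equations split into a damped oscillator along the
fibers, (∂t + a∂²z + b∂z)φ∥ = 0, and an *undamped* wave equation
transverse to them, (∂t∂²y + b∂y)φ⊥ = 0 — weakly evanescent transverse
cortical waves.  `wetcow_dynamics.boundary_layer_spectrum` carries both
branches; a and b are treated as free constants of the 1D layer model
because their magnitudes depend on an unmodeled conductivity profile.

## Sign conventions

The package uses the ansatz exp[i(k·x − Ωt)] with Ω = ω + iγ packaged so
that γ > 0 means decay for the volumetric dispersion relation
(`dispersion_relation`), i.e. the temporal factor is e^(−iωt) e^(−γt).
For the 1D boundary-layer branches the spectrum is reported raw from the
ansatz (amplitude ∝ exp(Im[Ω]t)); decay therefore corresponds to
Im[Ω] < 0, e.g. a < 0 in the parallel branch.  Only magnitudes of ω and γ
are physically fixed; tests compare magnitudes.

## Property fields

`tissue_model` assigns σ and ε_rel per tissue label and builds Σ.
Defaults: gray/white matter use the measured averages quoted above; scalp
(σ = 0.43 S/m), skull (0.01), and CSF (1.79) use literature-typical
conductivities with a common ε_rel = 10⁷ placeholder — no measured
permittivities exist for them at these frequencies, so they are config
entries, not constants.  Background is vacuum-like with a σ = 10⁻⁶ S/m
floor and the same ε_rel placeholder, keeping its scaled conductivity
(~10⁻² s⁻¹) inert rather than stiff (σ/ε₀ with ε_rel = 1 would be ~10⁵ s⁻¹
and dominate every time-step bound while meaning nothing physically).

Scalar maps are Gaussian-smoothed (default width: one voxel) *before*
tensor assembly because pseudo-spectral differentiation of discontinuous
coefficients rings.  Anisotropy is optional: with user-supplied fiber
directions, labels with anisotropy_ratio < 1 get the transversely
isotropic tensor v vᵀ Σ∥ + (I − v vᵀ) Σ⊥ with Σ⊥/Σ∥ the ratio and the
trace matched to the isotropic construction (so switching anisotropy on
does not change the mean damping rate).

## Forward simulation

`simulate_wave_field` integrates u = ∇²φ with u̇ = −∇·(Σ∇φ): spatial
derivatives are spectral on the periodic grid, φ is recovered from u by
spectral Laplacian inversion at every stage, and time stepping is classic
RK4 with fixed dt.  The k = 0 mode of u is projected out (gauge: φ is
defined up to a constant).  Σ is apodized with a 3-voxel cosine taper at
the box edges so the FFT's periodic wrap-around cannot couple opposite
faces of the head.

Stability: the stiffest modes are purely damped at rates up to max Σ
(~2×10⁴ s⁻¹ in CSF with the default placeholders).  The integrator
enforces dt·max Σ ≤ 2.5, just inside the RK4 real-axis stability boundary
(≈2.785).  Strongly damped modes are then stable though not accurately
tracked — they are slaved to their quasi-static balance within a few
steps, which is the correct physics — while the dynamics of interest
(≲ tens of Hz) are resolved with ~10³ steps per cycle.  A much more
conservative guard would make the driven 48³ studies an order of magnitude
slower for no accuracy gain in the recorded band.

`forward_sim.synthesize_study` adds oscillatory Gaussian-splat forcings to
u̇ (default FWHM 3 voxels).  This drive is fixture machinery: some source
term is needed to produce a nontrivial recording, and no claim is made
that it models physiological generators (the model's internal nonlinear
source term is out of scope).  Electrodes are placed by farthest-point
sampling on the outer scalp surface and sampled by trilinear
interpolation; the default reference is the average reference.

## The inverse solver

In the frequency domain the wave equation becomes L̂φω = R̂φω + 𝓕ω with
L̂ = ∇² and

    R̂ = (σ̄ + iωε)/(σ̄² + ω²ε²) · [ iω(∂ᵢε)∂ᵢ − (∂ᵢΣᵢⱼ)∂ⱼ − (Σᵢⱼ − σ̄δᵢⱼ)∂ᵢ∂ⱼ ]

where here Σ = σᵢⱼ/ε₀ (1/s), ε is the relative-permittivity field,
σ̄ = TrΣ/3, and ω is angular.  With these units σ̄ and ωε are commensurate
(~10⁹ s⁻¹ at alpha frequencies for brain tissue), which is the regime in
which the displacement current matters; dropping the ε factors from the
prefactor while keeping the ∂ε term would inflate that term by ~10⁷ and
the iteration would always diverge.  The three bracketed terms are sourced
by permittivity gradients (WM/GM interface), conductivity gradients
(GM/CSF boundary), and anisotropy; for isotropic fields the third term
vanishes voxelwise and is skipped.  The internal source term 𝓕ω is not
modeled.

`reconstruct_band` couples the data to the solver as follows, per retained
DFT bin (rectangular window, 2/N scaling, DC always excluded):

1. each channel's complex coefficient is splatted as a Gaussian (FWHM
   `seed_splat_fwhm`, default 3 voxels) at its electrode voxel into a
   source volume s, and φ⁽⁰⁾ = L̂⁻¹s;
2. the iteration φ⁽ᵏ⁾ = L̂⁻¹R̂φ⁽ᵏ⁻¹⁾ is accumulated, φ̃ = Σₖ φ⁽ᵏ⁾, for up
   to K steps (default 10) with an early stop when the accumulant's
   relative change drops below tol (default 10⁻⁶) and a hard error if it
   grows 10⁶-fold (the spectral radius of L̂⁻¹R̂ is not guaranteed below 1
   for strong gradients);
3. a single complex scalar α is fit by least squares to the measured
   coefficients at the electrode positions, and αφ̃ is returned.

The coupling mechanism (splat + final scalar fit) is one defensible
reading of an underdetermined design space; per-iteration residuals are
logged so its behavior is inspectable.  Because the final amplitude is
fixed entirely by the sensor fit, the reconstruction is invariant to any
global rescaling of the property nondimensionalization.

### What the inverse can and cannot do on the phantom

The forward–inverse recovery study (deep 10 Hz source, 64 electrodes,
noiseless) is the hardest test in the suite and the package reports it
honestly: with the default property placeholders the CSF shell's scaled
conductivity (~2×10⁴ s⁻¹) is far above ω, so the shell behaves as a
near-grounded conductor.  The deep source's field is confined inside it
(verified against the grounded-shell Green's function): the ground-truth
band-power map is essentially the source blob (dynamic range ~10³–10⁴
over brain voxels) and the scalp sees ~10⁻³ of the interior amplitude.  A
reconstruction whose sources live at the electrodes and at tissue-gradient
shells is smooth in the deep interior and cannot co-locate such a
concentrated target; measured r ≈ 0 and peak error ≈ 9 voxels.  Depth
localization does emerge when the recording retains its monopole moment
(unreferenced synthetic data: peak within ~5 voxels, r ≈ 0.4), but an
absolute scalp potential is not measurable EEG, so the package keeps the
average reference and reports the failure rather than engineering around
it.  On superficial cortical sources, where scalp data genuinely
constrain the field, the same pipeline recovers the band-power pattern
well (r ≈ 0.7 on the 32³ study) and degrades gracefully with noise
(r at 10 dB SNR ≥ 0.99× the noiseless r).

## Mode decomposition

`efd_modes` implements a deliberately simplified entropy-based
decomposition: the coupling between masked voxels is their absolute
temporal Pearson correlation (nonnegativity is required for a
path-entropy weight), its eigendecomposition supplies orthonormal spatial
modes, and the squared leading eigenvector — or, under degeneracy, the
basis-invariant diagonal of the leading eigenprojector — gives the
equilibrium distribution μ*, normalized to sum 1.  Mode time courses are
τₖ = ψ⁽ᵏ⁾ᵀX on demeaned courses; the mode-k power map is (ψ⁽ᵏ⁾)²·var τₖ.
The displayed summed map weights modes by their coupling eigenvalues (a
weight rule has to be chosen; eigenvalues rank coherence); the
unit-weighted sum over a complete basis equals the masked data variance
exactly and is what the energy-conservation test checks.  The full
field-theoretic construction this simplifies is not restated here and no
equivalence is claimed.  Masks larger than `max_voxels` (default 2000) are
subsampled deterministically: one seeded draw per contiguous stratum of
the C-ordered mask, which keeps spatial coverage.

Comparison statistics follow the conventions used for volumetric
activation maps: Pearson correlation restricted to voxels where both maps
exceed an activation threshold (default 0.1), slice-wise correlation
profiles, per-region mean power over an atlas, and Fisher's z = arctanh r.

## Wave-loop detection

`detect_wave_loops` computes per-voxel instantaneous phase from the
temporal Hilbert transform, takes the wrap-safe in-plane phase gradient,
and integrates streamlines (midpoint rule, 0.5-voxel steps, step cap 10×
the plane perimeter) from a seed lattice.  A streamline returning within
`closure_tol` voxels of its start is a loop; loops are deduplicated by
centroid distance, keeping the tightest.  The plane is treated as bounded
— streamlines terminate at its edge — so traveling plane waves produce no
spurious torus-wrapping loops.

## Synthetic data: what it does and does not emulate

The phantom is five nested ellipsoidal shells with an optional sinusoidal
perturbation of the gray/white interface standing in for cortical folding.
It reproduces the *structure* that drives the model — nested conductivity
and permittivity contrasts, a folded interface with strong gradients — but
not realistic cortical geometry, electrode caps, physiological artifacts,
or tissue anisotropy maps (isotropy is the default; the study regime this
mirrors used no diffusion data).  Passing tests on the phantom therefore
demonstrate internal consistency of the operators and solvers and the
physics of the idealized head, not clinical performance.

## Numerical choices and problem sizes

- Dispersion–simulator cross-check: 128² 2D grid, sinusoidal conductivity
  profile measured at its locally linear zero crossing; fitted (ω, γ)
  agree with the closed form to <1% (5% tolerance asserted).
- Boundary-layer checks: 256-point 1D spectral integrations; transverse
  energy drift <10⁻⁹ per period, parallel decay exact to RK4 order.
- Forward studies: 48³ (acceptance) and 32³ (unit) phantoms at 2 mm,
  0.6 s at 250/125 Hz sampling, dt ≈ 10⁻⁴ s set by the CSF damping rate.
  These sizes keep the full suite at a few minutes on one core while
  leaving every rate and contrast at its physical value.
- Degenerate inputs: k = 0 is rejected in all dispersion evaluations; the
  DC bin is excluded from every band; constant voxel time courses are
  dropped from coupling matrices with a warning; empty atlas regions are
  flagged with NaN means rather than silently omitted.

## Known limitations

- The operator iteration is a plain Neumann series; no preconditioning or
  relaxation is attempted, and convergence is only guarded, not ensured.
- The data coupling is one point in a large design space and is the
  limiting factor for deep-source recovery (see above).
- EDF reading covers continuous single-session recordings only and
  delegates to mne; BIDS layouts are out of scope.
- Electrode registration is affine (NIfTI world coordinates); nonlinear
  template registration is out of scope.
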