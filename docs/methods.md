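# Methods

## Problem and model

Cardiac-driven exchange of blood and CSF deforms the brain and modulates its
perfusion. Both effects change the electric impedance measured between scalp
electrodes by a tiny amount (~1e-4 of the base value), which a naive
difference of two full field solutions cannot resolve reliably. `impedyn`
computes these changes perturbatively from a *single* base solve.

The base problem is electro-quasistatic: at ~1 MHz the head is much smaller
than the wavelength, so the potential obeys `div(eps_c grad phi) = 0` with
`eps_c = eps0 eps_r - j sigma/omega` (e^{+j omega t} convention; the sign is
fixed so that a passive medium gives `Y = G + j omega C` with non-negative
G and C). Dirichlet values are applied on electrode voxel sets, zero-flux
Neumann everywhere else; air is excluded from the domain (its permittivity
is negligible against tissue values). The admittance follows from the total
charge enclosing one electrode, `Y = j omega Q / V0`, reported as
parallel-equivalent `C = Im Y/omega` and `R = 1/Re Y`.

## Charge-change perturbation

A moving tissue interface (region 1 -> region 2, unit normal n pointing into
region 2) behaves, to first order in the displacement d, like a charge
bi-layer at the original interface. A reciprocity argument collapses the
perturbed problem onto base-solution quantities only:

    V0 dQ_geom = - sum_faces [ (eps2^2/eps1 - eps2) En+^2
                               + (eps2 - eps1) Et.Et ] (d.n) A
    V0 dQ_diel = d_eps1 * sum_faces phi(r1) dphi/dn|-  A

and the combined case is their superposition. Complex products are
**unconjugated**: the derivation multiplies base and perturbed phasor
fields, not a field with its conjugate, and only the unconjugated form
yields a genuinely complex dQ — hence both dC and dR. (A conjugated variant
is available behind a flag for comparison; the complex-valued slab oracle
validates the unconjugated choice.) The per-face geometry kernel divided by
V0 is the sensitivity map S(r): the functional derivative of dQ with
respect to locally swept interface volume, stored *including* the 1/V0
factor so that integrating S against d.n dS reproduces dQ exactly.

dR is linearised as `-Re(dY)/Re(Y)^2`; the difference to re-inverting Y+dY
is second order, below the method's error floor.

Gauge subtlety: the dielectric-change formula uses phi itself, so for an
*open* interface terminating on an electrode (the 1D/coaxial benchmarks) the
charge layer at the electrode junction must not be dropped. The benchmarks
therefore ground the electrode adjacent to region 1 and measure the charge
at the driven electrode; for a closed interface (the brain case) the
formula is gauge-invariant as written.

## Perfusion model

Blood volume changes dv_total perturb the parenchyma permittivity through
the Lichtenecker power-law mixture, linearised at fractional volume
f = dv_total/V_tissue << 1:

    d_eps1 = eps_tissue * f * ln(eps_blood/eps_tissue)

Maxwell-Garnett/Clausius-Mossotti, Rayleigh and Bruggeman rules are
implemented to quantify model-choice sensitivity; at f <= 1e-3 the spread
across rules is a few percent of d_eps1. The Monro-Kellie closure ties the
perfusion drive to the deformation data: dv_total(t) = -dVCSF(t), the
negative of the CSF volume change computed from the brain-surface sweep.
Principal branches are used for complex log/power; tissue permittivities at
1 MHz lie in the right half-plane, so no branch crossing occurs (asserted).

## Verification benchmarks

Four geometries with closed-form or semi-analytic solutions provide a
direct-difference oracle (dQ = Q* - Q from two independent solutions):

* **slab** — two dielectric layers in series between plate electrodes;
* **concentric cylinder** — dielectric disc in a circular boundary carrying
  a Fourier Dirichlet potential (default V0 cos theta), solved per harmonic;
  an optional inner electrode gives the logarithmic coaxial limit;
* **offset cylinder** — the disc translated off-center, solved by a Moebius
  map onto the concentric problem (2D interface conditions are conformally
  invariant; this closed form is what image-charge series sum to). Radius
  growth combined with a rigid drift exercises displacements not aligned
  with the interface normal. Near-contact configurations work up to the
  point where the mapped harmonic series stops converging (checked, with a
  reported truncation bound);
* **concentric spheres** — the 3D analogue via Legendre series. The default
  radius ratio is 0.8, a thin-outer-shell regime of a brain surface inside
  the skull; Taylor analysis of the closed form shows a ratio of 0.5 would
  make the intrinsic second-order remainder of *any* first-order method
  exceed the 6% target at 10% perturbations (~8.7%), while 0.8 gives ~5%.

The measured functional in the 2D/3D benchmarks is the potential-weighted
boundary charge `(1/V0) * integral V sigma ds`, which equals the electrode
charge for two-level boundary data and is exactly the quantity the
reciprocity identity controls for smooth Dirichlet data.

Error sweeps perturb the interface position and the region-1 permittivity
by up to 10% (single kinds swept with both signs; the combined kind along
the equal-fractional-amplitude diagonal — a full tensor grid contains
near-cancellation points where dQ_direct -> 0 and the relative error of any
first-order method diverges). With the default specs the maxima are ~6.7%
(slab), ~2.4% (cylinder), ~2.3% (offset), ~6.0% (sphere).

## Voxel solver

7-point finite differences with harmonic face averaging of eps_c; electrode
values are imposed at the faces of pinned background voxels (half-distance
single-sided coefficients), so planar electrodes are represented exactly.
Direct sparse factorisation up to ~2e5 unknowns; Jacobi-preconditioned CG
for larger real (lossless) systems and BiCGSTAB for larger complex ones.
Default tolerance 1e-10 relative residual: perturbation targets are ~1e-4
of the base quantity, so oracle solves need several extra digits. Charge is
integrated with the same face conductances as the stencil, making the
discrete flux exactly conservative (shell independence to solver residual).

Interface fields are sampled from the voxel potential by trilinear
interpolation at centroid offsets of h and 2h per side (h = half voxel)
with two-point one-sided stencils. Half-voxel central sampling is *not*
used: the interpolation cell straddling the material interface smears the
kink in phi, and both one-sided slopes would collapse onto the cell-average
slope.

Grid-convergence notes: for the slab, refinement by factors of 3 (9, 27, 81
cells) keeps the interface at a fixed mid-voxel offset, so the voxelisation
error is exactly proportional to h and the log-log fit is clean (R^2 ~ 1).
Curved boundaries (disc, sphere) carry staircase error; agreement with the
analytic charge is ~0.6% at 256^2 (2D) and ~5% at 48^3 (3D), decreasing
monotonically under refinement.

## Deformation pipeline

Displacement-encoded (DENSE-like) inputs: 20 cardiac phases, two opposite
gradient polarities. Processing: (1) polarity subtraction (pos - neg)/2
cancels the shared background error exactly; (2) masking to GM/WM
(probability maps; GM+WM wins over CSF at threshold 0.5) eroded by 3 voxels
(6-connectivity) to stay clear of CSF-adjacent voxels; (3) k-nearest-
neighbour smoothing, k = 150, uniform mean per phase and component over
physical-distance neighbourhoods; (4) extrapolation onto triangulated
surfaces by nearest-neighbour lookup or by an unstructured least-squares
Fourier fit ("FFT") with SVD regularisation (relative cutoff 1e-3) that
assumes nothing outside the domain. The Fourier basis is the tensor of
1/cos/sin up to 4 harmonics per axis on the mask bounding box padded by
25% (config-exposed; ~729 functions is what a scattered SVD fit supports —
larger bases are rank-deficient on realistic masks and add cost cubically).
Reconstructions with surface motion >> 100 um (default cap 300 um) are
rejected. Features per phase: dVCSF = -sum (d.n) A (normals out of the
brain: expansion expels CSF), TS = area-weighted mean displacement, RS =
area-weighted least-squares infinitesimal rigid rotation about the area
centroid. For inference, signed anatomical projections are used (cranio-
caudal TS_z, nodding RS_x) — magnitudes fold the sign and needlessly
nonlinearise the signal-feature relation.

Method characterisation on synthetic fields: NN extrapolation is exact for
fields that are locally uniform across the mask gap (plateau envelopes,
rigid shifts) and biased low for fields growing with radius; the Fourier
fit is near-exact for band-limited fields but under-extrapolates thin-shell
fields. The recovery studies therefore use NN; the Fourier path is
validated on smooth fields (interpolation to 1e-8, 40%-masked
reconstruction to <5%).

## Synthetic phantom and cohort

The phantom is a four-layer ellipsoidal head (brain 70, CSF 76, skull 82,
scalp 88 mm nominal radii; common aspect 1.10/1.00/0.84 — a sphere is a
degenerate special case for which rotation sweeps no volume and would be
invisible in every signal) with a tri-axial ellipsoidal ventricle and
representative 1 MHz tissue properties. Three 16 mm electrode pairs
(front-back, top-front diagonal-back, left-top) are deliberately not all
opposed: an opposed pair is blind to rigid translation and rotation by
symmetry, and the configurations are meant to carry complementary feature
information.

Ground-truth motion per subject: radial pulsation, ventricular pulsation
(amplitude and waveform tied to the cortical one — both are driven by the
same cerebral blood volume change), rigid translation, a nodding rotation
about a craniocervical pivot below the brain (adding a rotation-locked
uniform shift, the mechanism that makes rotation measurable), and a
divergence-free vortex nuisance buried mid-parenchyma. Radial and
rotational terms carry plateau envelopes over each surface's neighbourhood:
brain-surface amplitudes do not grow linearly into the parenchyma, and the
plateau makes the surface features well-defined independently of where the
validity mask ends. Amplitudes: 30 um radial, 15 um translation, 40 um
rotational (tangential), 8 um ventricular, 3 um vortex — sub-100 um
surface motion, consistent with the >>100 um rejection rule. Waveforms are
two-harmonic cardiac-like shapes; subjects differ in amplitudes (+-35%),
phase lags (+-0.08 cycle for TS and RS, producing hysteretic
signal-feature loops), waveform shape and direction jitter (+-0.08).
Polarity pairs add a shared smooth background field (50 um scale) and
independent 10 um voxel noise. The deformation grid (64^3, 3.125 mm) is
independent of the EM grid (48^3).

What the generator does **not** emulate: anatomical detail beyond four
layers, heterogeneous perfusion, MR acquisition physics, registration
error between the anatomical model and the deformation data, and
electrode-skin contact effects. Passing tests therefore demonstrate the
correctness and internal consistency of the method chain, not its accuracy
on real heads.

## Inference protocol

Per subject, the 6 signal curves (3 configurations x dC, dR, referenced to
the third cardiac snapshot) and 3 feature curves are z-scored per series
across the cohort, concatenated and decomposed by PCA (n_subjects - 1
components). Components are projected to the measurement and feature
sub-spaces and renormalised; ridge regression (penalty by leave-one-out
cross-validation over a log grid) maps measurement-subspace coordinates to
feature-subspace coordinates. Prediction quality uses the normalised
mismatch |x - x'| / sqrt(|x| |x'|) (geometric-mean normalisation, the
symmetric reading of the deviation metric; plain |x| normalisation is
config-switchable). Baselines: deviation from the cohort-mean curve, and
mean deviation from the other subjects. Shapiro-Wilk justifies the
one-sided paired Wilcoxon tests.

Power, measured over six cohort seeds with the frozen conditions:
predictions beat inter-subject variability at p < 1% for every seed, and
beat the subject-averaged baseline at p < 5% for five of six; one seed
draws a subject whose TS and RS lags nearly coincide (temporal collinearity
of rotation and translation) and is marginal there — the expected sampling
variability of an eight-subject study.

## Uncertainty budget

Sensitivity coefficients s (dB/dB, central difference over +-20% property
scalings of the peak-to-peak dC/dR) combine with log-normal input
uncertainties (10% standard deviation = 20 log10(1.1) dB) and the
grid-convergence numerical term by root sum of squares. The numerical term
is the dB deviation of the finest-grid value from the power-law
extrapolation q(h) = q* + C h^p fitted on >= 3 resolutions (R^2 of the
log-log error fit is reported).

## Numerical choices and limitations

* Harmonic truncation: 64 cylinder/sphere harmonics by default; the offset
  map checks the decay of the transported boundary series and raises before
  returning an unconverged answer (near-contact needs higher order).
* Degenerate inputs raise: empty masks, rank-collapsed Fourier bases,
  non-physiological displacement magnitudes, shells enclosing both
  electrodes, left-half-plane permittivities.
* Ties at voxelised interfaces assign the voxel to region 1.
* The first-order formulas degrade when the displacement is comparable to a
  local geometric gap (near-contact: error roughly doubles when the shift
  exceeds the gap width).
* Second-order perturbation terms and interface topology changes are out of
  scope; dR linearisation assumes Re Y is not tiny.
* Problem sizes (48^3 EM grid, 64^3 deformation grid, 20k Fourier fit
  samples) are the package defaults chosen to keep the full synthetic study
  at workstation scale; all are config-exposed.
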