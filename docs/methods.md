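# Methods

This note documents the models implemented in `mphsim`, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do not
emulate.

## Physical model

The temperature field in the tumor-in-muscle phantom obeys transient Fourier
conduction with two volumetric sources,

    rho c_p dT/dt = div(k grad T) + s(t) (Q_MNP + Q_eddy),

where `s(t)` ∈ {0, 1} is the AMF duty-cycle indicator. There is deliberately
no perfusion (Pennes) term and no thermal-damage model: the workflow targets
the cadaver/phantom verification setting in which perfusion is absent by
design, so that the nanoparticle heating is isolated. Predictions for live
tissue will overestimate temperature rise accordingly.

**Nanoparticle source (Q_MNP).** The tracer image, after co-registration and
calibration, gives W/m³ per voxel directly. The underlying assumptions are
(i) the tracer signal is linear in local iron concentration, (ii) the
specific loss power is independent of concentration and aggregation state,
and (iii) particles do not migrate during heating.

**Eddy-current source (Q_eddy).** At hyperthermia frequencies
(f ≈ 341 kHz) and tissue conductivity σ = 0.23 S/m, the electromagnetic skin
depth √(2/(ω μ σ)) ≈ 1.8 m is three orders of magnitude larger than the
phantom, so the applied axial field is undisturbed and the induced Joule
heating admits the closed magnetoquasistatic form

    Q_eddy(r) = sigma (omega mu0 mu_r H0)^2 r^2 / 8     [W/m^3],

with `r` the distance from the coil axis and `H0` the *peak* amplitude (the
factor 1/8 contains the phasor time-average; RMS inputs are rejected at the
interface). A full vector-potential (Maxwell frequency-domain) solve is out
of scope; at the default drive (12 kA/m, 341.25 kHz) the closed form gives
~7.5e2 W/m³ at r = 5 mm — four orders below typical nanoparticle sources
(~1e7 W/m³) — so the reduction is inconsequential for the temperatures while
still being modelled. The coil axis defaults to z through the source
centroid, since lateral placement inside the coil is otherwise unspecified.

**Boundary and initial conditions.** Exposed solid/air faces carry a
convective (Robin) condition q = h (T − T∞), default h = 20 W/(m²·K),
T∞ = 37 °C. The five non-top faces of the muscle cuboid carry a uniform
Dirichlet temperature interpolated in time from a measured (or synthetic)
core-temperature trace; passing a constant is supported, and passing no
trace makes those faces adiabatic, which the closed-form verification
problems use. Initial temperature is a scalar or a full field.

## Discretization

Finite-volume on the structured voxel grid; unknowns are the solid (muscle ∪
tumor) voxels. Face conductances use the harmonic mean of the two adjacent
conductivities, which is exact for a piecewise-constant k interface; the
Dirichlet ghost sits half a voxel outside the boundary face. Time stepping
is backward Euler — unconditionally stable on stiff fine-voxel lattices and
an M-matrix at every step, so the scheme inherits a discrete maximum
principle (field min never drops below min(initial, boundary)) and, on
insulated runs, conserves energy to solver precision; both are asserted in
the test suite. Accuracy is first order in time, second order in space away
from staircase boundaries; a dt-halving Richardson check and a
grid-refinement check on the heated-sphere oracle are in the suite. The
default dt = 1 s matches the 1 s thermometry cadence of the emulated
experiments.

Linear systems are solved by sparse LU for up to 6e4 unknowns and by
Jacobi-preconditioned conjugate gradients (rtol 1e-12, warm-started from the
previous step) beyond that. A run stops early when the tumor volumetric
*maximum* exceeds the schedule's cutoff (default 51 °C); the maximum is the
conservative reading of a cutoff specified only as "the tumor" temperature,
and the statistic is configurable.

## Registration

Fiducial correspondence is by row order in the landmark CSVs — the markers
are user-identified, never auto-matched. The default motion model is
*similarity* (rotation + translation + isotropic scale, closed-form
Umeyama/SVD): three fiducials, the typical bench setup, cannot determine a
12-dof affine, and whether the reference tooling includes shear is unknown,
so the model is a flag rather than a fixed behavior. The affine branch is a
plain least-squares solve requiring ≥4 non-coplanar points. Resampling pulls
target-voxel centers through the inverse transform (nearest or trilinear);
unmapped voxels get a configurable fill (default 0 GV = no tracer).
Coordinates are mm on LPS axes with voxel-center indexing; the solver is SI
internally, mm appears only at the I/O boundary.

## Calibration

The serial-dilution regression is fixed as GV = intercept + slope·Q with the
slope in GV per (W·m⁻³) (numerically ~1.1e-5 for the emulated tracer/scanner
combination) and Q = SLP·c, 1 mg/mL = 1000 g/m³. Replicate maxima are
averaged per concentration before the fit (Type-A treatment); 95 % CIs come
from the t-distribution with n−2 dof. The inverse map clamps at zero: GV at
or below the zero-power intercept carries no heating. Saturating/nonlinear
detector response is a known limitation and is not modelled.

The SLP estimator fits the lumped calorimetry model with absorbed power P
and loss coefficient L free (L ≥ 0 via log-parameterization), using the
exact piecewise-exponential solution between samples with schedule edges
handled exactly. The global (P, L) fit gives the point estimate
SLP = P/m_Fe; P is then refit per ON pulse at the global L and the spread of
per-pulse SLPs is the reported uncertainty. A fitted P ≤ 0 is flagged, not
silently returned. The estimator is invariant to a common offset of ambient
and trace temperatures (only T − T∞ enters).

## Phantom assembly

Both the tumor label field and the nanoparticle source live on one
structured voxel grid — the source data are natively voxels, and a single
grid makes the conduction solver self-contained; smoothed-surface FEM
meshing is out of scope. The tumor is centered laterally on the muscle
cuboid's top face (no lateral placement rule exists in the emulated
protocol) and embedded so that the requested volume fraction (default 1/3,
the subcutaneous configuration) lies below the top plane; the integer-layer
scan guarantees the realized fraction is within one voxel layer. An
`extra_depth_voxels` option buries the tumor fully for deep-seated or
verification geometries. Source power falling into air after placement is
clipped and reported, so total power is conserved up to the explicit
`clipped_power`. The manual tracer lower threshold is a per-case config
parameter; `signal_capture_fraction` reports the fraction of in-tumor signal
a candidate bound captures, mimicking the "majority of signal encompassed"
criterion. In the pipeline the source is additionally restricted to a
dilated tumor ROI (default 3 mm margin) so that bright fiducial markers far
from the tumor cannot masquerade as tissue heating. Default material
properties (muscle: ρ 1090, c_p 3421, k 0.49; tumor: ρ 1045, c_p 3760,
k 0.51; both σ 0.23 S/m, µ_r 1, ε_r 2000) ship as package data and are
overridable per case.

## Dosimetry

CEM43 uses the Sapareto–Dewey convention R = 0.5 at/above the breakpoint and
0.25 below, breakpoint 43 °C; the ~42.5 °C human-cell breakpoint is exposed
as a parameter since the metric's constants are conventions, not measured
here. Dose arithmetic is exact rational scaling — no rounding to one decimal
(reference tables round; e.g. a 144 mm³ tumor at 2 from 50 mg Fe/mL is
5.76 µL, which a rounded table may print as 5.6).

## Synthetic fixtures

The generator emulates: an ellipsoidal tumor partially embedded in muscle,
Gaussian (or uniform-ball) nanoparticle deposits of declared total iron
mass, point-like fiducials rendered in both modalities, a known ground-truth
similarity transform between tracer and anatomical frames, additive Gaussian
image noise, serial-dilution calibration tables, duty-cycled calorimetry
traces from the lumped model, and a smooth core-temperature trace regulated
to ±0.1 °C around 37 °C. Tracer point-spread is a Gaussian blur folded
analytically into the deposit width (σ_eff² = σ_blob² + σ_psf², default PSF
1 mm), which keeps integrated mass exact and deposits spanning several
voxels. Defaults represent the emulated study: ~176 mm³ tumor, 2 mg Fe/mL
dose (0.35 mg Fe), SLP 496 W/g, calibration line 1031 + 1.10e-5·Q, GV noise
σ = 5, three fiducials, 1 mL water calorimetry sample (C = 4.18 J/K) with
1 mg Fe at 60 s ON/60 s OFF; the calorimeter loss coefficient is not
specified by any protocol we emulate, so the fixture declares L = 5e-3 W/K
(cooling time constant ≈ 14 min, typical of a passively insulated bench
calorimeter).

Not emulated: scanner physics (MPI system matrices, point-spread anisotropy,
detector saturation), CT Hounsfield calibration, particle migration, and
perfused live tissue. Passing tests therefore demonstrate correctness of the
*processing and physics chain* under known ground truth, not fidelity of any
particular scanner.

## Verification problems and problem sizes

The suite verifies the solver against closed forms: an insulated homogeneous
block heating at exactly Q/(ρc_p); the uniformly heated sphere, whose
surface rise is q_v R²/(3k) (checked at 0.5 mm resolution on a 64³ grid to
within 5 %, and coarser in the unit tests); and the eddy closed form to
1e-9. The full-pipeline check buries a uniform spherical deposit deep in a
48 mm muscle block and compares the steady tumor-mean against the
infinite-medium sphere solution evaluated voxel-by-voxel; the finite
Dirichlet box depresses the result by ~R/R_box, which the 10 % tolerance
absorbs at this geometry. Pipeline-level tests run on 1 mm grids with
schedules of a few minutes; these sizes are verification choices — the
physics and code paths are identical at finer resolution, only runtimes
grow.

## Known limitations

- Staircase voxel boundaries limit spatial accuracy near curved interfaces;
  no surface smoothing or cut-cell treatment.
- The eddy closed form assumes an axially uniform applied field; real coil
  end effects are not modelled (and are negligible at the default drive).
- The calibration model is strictly linear; detector saturation at high
  concentration is outside the model.
- Uniform Dirichlet side temperature from a single core trace ignores
  spatial gradients along the body.
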