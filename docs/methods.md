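# Methods

## Problem and coordinate conventions

A rotating-gantry linac carries two imaging chains: the treatment (MV) beam
with its portal imager, and an orthogonally mounted kilovoltage (kV) chain.
Implanted gold-seed fiducials visible on both give a stereoscopic view of
target motion during arc delivery.  The patient frame is right-handed with
origin at isocenter: `x` = left–right, `y` = anterior–posterior (toward the
gantry-zero source), `z` = superior–inferior (the rotation axis).  Gantry
angles are in degrees, increasing clockwise viewed from the foot of the
couch; the kV chain trails the MV chain by 90°.  The sign of this convention
is a declared configuration choice (`angle_convention` in the geometry
block): both chains are used consistently, so all derived quantities are
independent of the sign choice.  Reporting axes are anatomical:
(vertical, lateral, longitudinal) = (AP, LR, SI) = patient (y, x, z).

Default geometry: source–axis distance 1000 mm, isocenter–detector distance
500 mm (so source–detector distance 1500 mm and isocenter magnification
1.5), detector pixel pitch 0.392 mm (MV) and 0.388 mm (kV).

## Triangulation

In the system frame of a chain at angle θ (obtained by rotating patient
coordinates with `r(θ)`, rotation about `z`), the source sits at
`[0, SAD, 0]` and a detector point at `[i, −IDD, k]`.  A point
`u = r(θ)·X_p` on the source ray through `(i, k)` satisfies

    SID·u_x + i·u_y = i·SAD
    SID·u_z + k·u_y = k·SAD

Two chains give four linear equations in the three unknowns of `X_p`; the
overdetermined system is solved by unweighted ordinary least squares
(`numpy.linalg.lstsq`), and the maximum reprojection distance over both
chains is reported as a residual.  For consistent observations the identity
`triangulate(project(·)) = id` holds to < 1e-6 mm (tested over 1000 random
points); against an independent coarse-to-fine 3-D grid search minimising
summed squared reprojection error, the solution agrees to within one
0.01 mm grid step.  Chains separated by less than 5° (mod 180°) are
rejected as ill-conditioned rather than returning an unstable solution.

## Synthetic phantom study

The generator emulates a phantom accuracy experiment: three cylindrical
fiducials (3 mm × 1.2 mm) whose centre of mass lies exactly at isocenter
(offsets ≤ 10 mm, mimicking an arc planned "centred on the fiducials"),
ellipsoidal background clutter in and out of the isocenter plane standing
in for vertebral anatomy, a single 360° arc at 1 rpm (6°/s) with 177
control points, kV frames at 11 Hz and MV frames at 9.5 Hz (frame counts
`floor(rate × duration)`).

**Rendering.**  Images use a line-integral convention (fiducials bright).
Each cylinder is splatted analytically: pixel intensity proportional to the
chord length `2√(r² − d²)` at distance `d` from the projected axis, with
the radius magnified at the fiducial's depth, followed by a Gaussian
detector blur (0.8 px).  The same renderer builds the reference templates,
so template and simulated image agree on sub-pixel fiducial position to
< 0.1 px.  Monte-Carlo transport, scatter, detector lag and CT-number
attenuation are deliberately not modelled.

**Motion.**
*Prostate-like drift*: a seeded band-limited random walk per axis
(cumulative Gaussian noise, Gaussian-smoothed, σ = 10 control points),
rescaled so the maximum excursion per axis equals (1.9, 1.8, 4.9) mm in
(vertical, lateral, longitudinal) exactly; defined at the 177 control
points and linearly interpolated in time (continuous couch motion).  A
measured trace can be substituted via CSV.
*Respiration*: `A·sin(πt/T)^{2n}` with period T = 4 s, peak-to-peak
amplitudes (5, 2, 10) mm and dwell exponent n = 2, which keeps the target
in the end-exhale half of its range for ≈ 64 % of each cycle.  Delivery
starts at end-exhale — the position the phantom is set up and matched in —
so the tracker latches at the first frame, as in a couch-programmed
experiment.  The exponent is a configuration knob.
*Static*: optionally a constant setup-error offset (default zero).

**Artifacts.**  MV frames receive multiplicative horizontal band artifacts
(groups of ~4 rows scaled by factors uniform in [0.6, 1.0] at random
spacings) inside the irradiated region, and additive Gaussian noise
everywhere.  The default noise level (σ = 80 on a 1000-level open field
against fiducial contrast 400) puts the fiducial contrast-to-noise ratio
near 5, typical of portal imaging at treatment energies; it was calibrated
once so that the static-scenario tracking error lands in the
sub-0.3 mm regime reported for physical phantom studies of this kind.  The
simulator models image noise only — couch/gantry mechanical reproducibility
and real detector physics are absent — so absolute accuracy numbers from
the synthetic study are expected to sit below measured ones, and passing
tests demonstrate correct mechanism rather than clinical accuracy.

**Apertures.**  The default MLC aperture is a fiducial-enclosing rectangle
with a 15 mm beam's-eye-view margin around the *planned* positions (the
aperture follows the plan, not the target); `open` and `closed` modes
support occlusion experiments.

## MV band removal

Irradiated pixels are identified by Otsu's criterion on the intensity
histogram (a percentile fallback is exposed).  Each row with at least 5
irradiated pixels is scaled by `I_ave,max / I_ave,r`; gains are clamped at
5× so near-empty rows cannot amplify noise into artifacts.  Non-irradiated
pixels are untouched and the operation is idempotent.  Fiducial pixels are
included in the row means (they are a negligible fraction of a row).

## Short-arc tomosynthesis

`frames_for_arc` rounds `arc·rate/speed` to the nearest odd integer ≥ 3
(3 frames at 2°, 7 at 4.4°, 11 at 7°).  Reconstruction backprojects each
frame onto the isocentric plane perpendicular to the central ray of the
central angle: every output pixel corresponds to a 3-D plane point, which
is projected through each frame's own geometry and sampled bilinearly
(nearest-neighbour optional); samples are averaged with per-pixel
normalisation by the number of contributing frames.  Output pixels are at
isocenter scale (detector pitch / magnification), which makes the
single-frame reconstruction the identity on the matched grid and lets
SA-DTS images be registered against detector-scale templates directly.
Frames are weighted uniformly.  The reconstruction plane depth is a
configuration override; volumetric multi-plane DTS and filtered variants
are out of scope.

## Templates and registration

Reference templates are rendered analytically from the 3-D fiducial models
at one-degree gantry increments (lazily, with caching, in the pipeline).
Each fiducial's ROI is its cylinder grown by a 1 mm margin in 3-D (radius
and half-length) and then projected, guaranteeing the ROI contains the
rendered footprint; the registration cost is evaluated over ROI pixels
only, and the template background is zero — the advantage of fiducial-only
templates over full DRRs.  A position-of-the-day adjustment re-renders the
set from 3-D fiducial positions observed in a setup image pair.

Registration minimises `1 − ZNCC` over 2-D translation.  The cost is
evaluated on a 2 mm grid laid symmetrically over the search region
(10×10 mm about the planned position for the first frame, 5×5 mm about the
previous match subsequently); Nelder–Mead simplex minimisation
(shift tolerance 0.01 mm, ≤ 200 iterations) starts from the five
lowest-cost grid points and, independently, from the planned position, each
arm confined to the search region about its own anchor — the planned-arm
restart is what lets tracking recover after the target leaves the local
region.  The lowest final cost wins; ties break toward the smallest
displacement from the start.  Matched-filter output is gated by a
peak-to-sidelobe figure of merit: correlation magnitude at the match
divided by the standard deviation of the correlation sampled on a 0.5 mm
lattice over a 5–8 mm annulus around it.  The annulus starts at 5 mm
because the projected three-fiducial pattern (≈ 4.5 mm long footprints)
keeps a correlated shoulder out to ~4 mm; sampling that shoulder would
inflate the sidelobe deviation and compress the separation between good
and spurious matches.  The acceptance threshold defaults to 4 + 1 = 5.0,
calibrated on the shipped fixture family: across angles and noise levels,
well-visualised fiducials score ≥ 5.4 while pure-noise surfaces score
≤ 4.8.  Fully blocked fiducials produce a zero-variance patch and are
flagged as failures outright.  The joint three-fiducial pattern is matched
rigidly (translation only); partially blocked fiducials then bias the
pattern's centre of mass, and a config-gated option drops zero-variance
ROIs from the cost for that case.

## Pairing, 3-D recovery, statistics

Each kV frame pairs with the MV frame minimising the circular deviation of
`θ_MV − θ_kV` from 90° (ties toward the earlier MV frame); the residual
offset is bounded by half the MV angular spacing (≤ 0.32° at 1 rpm and
9.5 Hz) and is absorbed exactly because each frame's own angle enters the
triangulation.  The measured detector point per chain is the template's
planned centre-of-mass projection plus the registered shift; triangulation
followed by subtraction of the planned 3-D centre of mass yields the
displacement, reported on anatomical axes.  If either chain fails its
confidence gate the sample becomes a 2-D kV-only record (in-plane shift at
isocenter scale), excluded from 3-D statistics but counted in the failure
rate.  Summaries report per-axis mean, standard deviation and maximum of
(measured − planned), plus the three-axis mean SD used when accuracy is
quoted as one number.

## Problem sizes and seeds

The shipped test-suite and acceptance runs use shortened deliveries
(1–8 s segments of the 60 s arc, 11–88 pairs) on 256² detectors, chosen as
the smallest sizes at which every mechanism under test is resolved;
stochastic checks fix their seeds and, where they assert orderings (e.g.
respiratory accuracy of single-frame vs 2° vs 7° SA-DTS), average over two
seeds.  All randomness flows from per-run seeds through
`numpy.random.SeedSequence` spawning, and identical (config, seed) pairs
reproduce byte-identical trace CSVs.

## Known limitations

- The 2° gantry-angle mis-assignment error for the default fiducial set is
  0.02–0.04 mm at most gantry angles with a worst case of ≈ 0.05 mm; it
  scales with the fiducial offsets from isocenter (here up to 10 mm).
- Rotations and deformations are outside the 2-D search space
  (translation-only registration), matching the centre-of-mass output
  convention.
- The band-artifact model is phenomenological (uniform row gains); real
  readout physics is not reproduced.
- The FOM threshold calibration is specific to this renderer's contrast and
  clutter family; real images require re-calibration through the exposed
  configuration value.
- Real-time performance engineering (sub-second processing) is a non-goal;
  the implementation favours clarity and testability.
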