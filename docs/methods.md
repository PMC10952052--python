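# Methods

`exobench` implements a desk-scale benchmarking pipeline for passive
back-support exoskeletons and exosuits ("exos"): from optical marker
trajectories and surface EMG to per-device assistive moment–angle curves,
hysteresis, MVC-normalized muscle-effort metrics, and condition-comparison
statistics.  Because real participant recordings of this kind are not freely
redistributable, the package ships a first-class synthetic-study generator;
every processing stage is validated against the generator's ground truth.

## Trunk and device kinematics

The trunk is modeled as a single rigid segment pivoting at the sacrum point.
Trunk inclination θ is the angle between the vector from the sacrum point
(midpoint of the left/right posterior sacroiliac markers) to the acromion
midpoint and the vertical lab axis (Z-up, meters, sagittal plane X–Z;
flexion increases θ).  Midpoints are used on both ends for symmetry; the
marker-label bindings are configurable so real exports with other marker
sets can be mapped on.

The reported angle is computed directly from the marker geometry.  A
zero-lag second-order Butterworth low-pass at 2 Hz (applied
forward–backward) smooths the angle *only* for differentiation; the velocity
is then a central difference.  This keeps the angle channel bit-faithful to
the markers (noise-free synthetic trials are recovered to < 1e-6 deg) while
giving a usable velocity for segmentation.

Dynamic trials are segmented into flexion and extension by the sign of the
trunk angular velocity with a ±2 deg/s dead band and a 0.25 s minimum
segment duration; shorter runs are merged into the longer neighboring run
and dead-band frames attach to the preceding segment.  Both thresholds are
configurable.  The first lifting cycle is the first flexion segment and the
first subsequent extension segment.  A movement mask (|velocity| > 5 deg/s
on trunk inclination, standing in for a hip-flexion velocity gate) restricts
iEMG integration to the moving portion of a trial.

## Device models

*Soft exosuits* are characterized by per-branch (loading/unloading)
polynomial force–elongation fits (N vs mm).  Band elongation is the change
in straight-line distance between the two markers at either end of the band
relative to the first frame (assumed neutral standing; the reference frame
is configurable).  Band curvature is neglected.  Bilateral bands are
evaluated per side on their own elongation and their forces summed; the
moment about the sacrum uses a constant sagittal moment arm (default
0.10 m), so soft moments are exactly linear in the moment arm.

*Rigid exoskeletons* are characterized by per-branch polynomial torque–angle
fits (Nm vs the exo angle α between the trunk link B1, clavicle marker →
exo hip joint, and the leg link B2, hip joint → thigh pad).  The device
torque is resolved into a trunk force at the chest-pad marker with magnitude
M_exo/|B1|, directed perpendicular to B1 within the B1–B2 plane and
extension-assisting; the sagittal assistive moment about the sacrum is the
sagittal component of r × F with r from the sacrum point to the chest pad.
This force-resolution rule is a declared convention (recorded in output
metadata) — bench-test rigs resolve the interface force differently in
detail — and alternative resolutions can be swapped in.  Negative evaluated
forces/torques clamp to zero: a passive element cannot push the trunk into
flexion.  Inputs outside a fit's valid range are clipped to the range
endpoint with a warning.

Hysteresis per lift cycle is the difference between the loading (flexion,
i.e. lowering) and unloading (extension) branch areas of the moment–angle
curve, ∫M dθ with θ in radians, integrated sample-wise along the trial
frames (equivalent to time-domain ∫M·θ̇ dt, trapezoidal).  Time-domain
integration avoids re-gridding branches whose θ is not strictly monotone.
The loss percentage is referenced to the loading (lowering) area.

The four device parameter files shipped under `exobench/devices/` are
**synthetic fixture parameterizations** at plausible scale (rigid torque
curves peaking in the tens of Nm, soft bands delivering a few Nm about the
sacrum, unloading branches at 66–75% of loading); they are not manufacturer
data.

## EMG processing

Band-pass 30–300 Hz, full-wave rectification, 6 Hz low-pass to the linear
envelope, normalization to MVC.  "Fourth-order zero-lag Butterworth" is
implemented as a second-order design applied forward–backward (net
fourth-order magnitude response, zero phase); the per-pass order is
configurable for the alternative reading (fourth-order design, doubled by
`filtfilt`).  No 50 Hz notch is applied by default — 50 Hz lies inside the
analysis band — but an optional notch flag exists for mains-contaminated
recordings.

The MVC reference per channel is the maximum, over the (two) calibration
trials, of a 0.5 s moving average of the processed envelope — more robust to
isolated spikes than the raw envelope maximum, at the price of a small
upward bias (a max statistic over a fluctuating window mean); tests bound
this bias at 10%.  Normalized envelopes may exceed 100 %MVC (submaximal MVC
is flagged when sustained).  Static trials are summarized by the RMS of the
normalized envelope over the hold window (detected as the longest quasi-still
near-peak interval); Dynamic trials by the trapezoidal time-integral of the
envelope over movement-mask-true samples (mask upsampled from 128 Hz to the
EMG timebase by nearest neighbor), in %MVC·s.

## Synthetic data generator

The generator emulates the measurement campaign the pipeline targets: 128 Hz
markers (C7, T10, clavicle, both acromions, anterior/posterior sacroiliac,
plus device markers), 2048 Hz EMG from six bilateral trunk muscles, four
lifting tasks under five conditions (four devices + no-device control), a
12.6 kg handled load, and Borg-6–20 / VAS-0–10 questionnaire scores.

- θ follows a raised-cosine (C¹) profile: ramp-and-hold for Static tasks
  (40°/60°, 5 s holds), metronome-paced flexion–extension cycles at 30 bpm
  (one beat per phase, 2 s each) for Dynamic tasks.  Stoop peaks at 85°,
  Asymmetric at 70° with a 30° yaw sinusoid, Squat at 15° with a 0.25 m
  vertical pelvis excursion instead of trunk flexion.
- Marker noise is i.i.d. Gaussian, σ = 0.5 mm per axis (typical optical
  capture noise; no published value exists for this protocol) — configurable
  and disabled for recovery tests.
- EMG channels are amplitude-modulated band-limited (30–300 Hz) Gaussian
  carriers: activation a(t) = baseline + g_ch·gain·max(0, M_grav −
  s·M_exo)/M_ref, with M_grav the single-segment gravitational trunk+load
  moment, M_ref its value at 90° with load, s ∈ [0,1] the assist share, and
  g_ch a per-muscle responsiveness (back extensors 0.9–1.0, obliques 0.3,
  abdominals 0.1).  Defaults: baseline 2 %MVC, gain 0.6, MVC scale 1 mV.
  This is a statistical stand-in for the muscle response the analysis
  assumes, not a motor-unit model; it carries no fatigue, crosstalk,
  electrode artifacts, or left–right asymmetry, so passing tests demonstrate
  pipeline correctness, not field validity on real recordings.
- Ground truth per trial (true θ, band elongation, device moment evaluated
  along the noise-free trajectory, phase labels) is written as a JSON
  sidecar.  Phase labels use a 5 deg/s dead band, matching the movement-mask
  default so the labeled moving portion is consistent with the analysis gate.
- The full study writes one directory per (subject, condition, task) with
  markers (TSV, mm), EMG (CSV, volts), and the sidecar, plus per-subject MVC
  recordings and score tables.  The Squat task is omitted for the Paexo-like
  device, whose hip hinge does not allow the squat degree of freedom.
  Identical (config, master seed) reproduce the directory byte-for-byte;
  per-trial seeds derive from the master seed through `SeedSequence` keys.
- Problem sizes: the default study runs 10 subjects × 5 conditions ×
  5 tasks with one set of two repetitions per Dynamic trial and 3 s MVC
  trials — a deliberately desk-scale rendition of the five-sets-of-two
  field protocol; set `n_repetitions` (and per-task specs) for more.

## Statistics

Shapiro–Wilk screens normality; device conditions are compared with the
tie-corrected Kruskal–Wallis test followed by Dunn's test with Bonferroni
correction (the standard companion post hoc; swappable), computed from
pooled ranks with tie correction.  The global discomfort scale uses one-way
ANOVA with Tukey HSD; a binary covariate (sex) uses the Mann–Whitney U
(exact for small tie-free samples, normal approximation with tie correction
otherwise; U reported for the first sample).  EMG metrics are described by
median and interquartile range, subjective scores by means.  Left/right
muscles are reported separately for the Asymmetric task and averaged per
subject for Squat/Stoop.  Omnibus tests and Tukey HSD are delegated to
scipy; Dunn's test is implemented here and cross-checked in the tests
against an independent loop-based evaluation of the formula.  A calibration
utility (`kruskal_type1_rate`, also exposed as `exobench simulate-power`)
verifies the type-I error rate sits near α under the null.

## Numerical choices and degenerate inputs

- Marker gaps up to 10 consecutive frames are linearly interpolated; longer
  gaps (or gaps touching the ends) raise an error naming marker and span.
- Zero-length trunk or device link vectors raise; collinear B1/B2 (α = 0)
  fall back to the sagittal-plane normal so the zero-torque standing pose is
  well-defined.
- Constant-angle trials yield an empty segmentation with a warning and no
  lift cycle.
- All filters refuse signals shorter than ~3× their warm-up length.
- Frames are 0-based, time starts at 0, segments are half-open [start, end).

## Known limitations

The generator's single-segment trunk cannot exhibit lumbar curvature, so
soft-band elongations are the geometric elongation of a straight chord
(tens of mm in deep stoop) rather than the smaller strap-level elongations
measured on real devices; the fixture stiffnesses are scaled accordingly.
The EMG model's activation–moment linearity makes effort ratios identifiable
by construction; real recordings would add crosstalk and amplitude
nonstationarity.  Lumbosacral net moments and compressive forces are out of
scope, as is fitting torque–angle curves from bench tests.  C3D files are
not read in this build; captures must be exported to the TSV dialect.
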