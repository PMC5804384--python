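# Methods

## Measurement model

A joint-position observation is five image-space landmarks in
millimetres — T (articular tubercle), P (porus acusticus externus), G
(glenoid fossa apex), C (condyle center), D (posterior band of the
disc) — plus two direction vectors: the Frankfort-horizontal trace
`fh_dir` and `superior_dir`, the image direction pointing superior
(default (0, 1), i.e. y increases superior; DICOM-style y-down data must
be converted before ingestion).

**Fossa frame.**  `x_hat = normalize(P − T)` (posterior positive),
`y_hat` its perpendicular with positive dot product against
`superior_dir`, origin G.  The "tangent" from T to P is the straight
line through the two supplied points; identifying the tangency points on
the anatomy is the annotator's task.  Frame coordinates of any point are
inner products against these axes, so the construction is exactly
invariant under rigid motion of the whole scene and affine in the point.

**Disc–condyle angle.**  Reference ray u = the superior perpendicular of
`fh_dir`; measured ray v = D − C.  The returned value is the angle from
u to v in (−180°, 180°], with the sign chosen so that positive means D
lies on the *anterior* side, where anterior is the T←P direction.
Because the sign is derived from the landmarks rather than from image
handedness, the angle (and all frame coordinates) are unchanged when a
scene is mirrored left↔right.  For this reason left-side images are
*not* flipped at ingestion; the `side` flag is metadata.  This is a
deliberate simplification over canonicalizing by reflection: the
measurement operations are intrinsically mirror-invariant, which the
test suite verifies directly.

**Sign conventions** (not derivable from any single published table;
fixed jointly by the coordinate tables and their verbal reading): frame
x positive = posterior, y positive = superior, angle positive =
anterior.  Display rounding is 0.1° for angles, 0.01 mm for coordinates
and movements, 0.1 % for percentages; all computation is double
precision.

**Frankfort direction.**  The FH plane cannot be recovered from the five
landmarks, so `fh_dir` is an explicit per-image input.  When absent it
defaults to the T→P tangent direction, optionally tilted by
`fh_offset_deg` (default 0°) — an explicit, logged assumption rather
than a guess.

**Degenerate inputs.**  T≈P (separation ≤ 1e-6 mm) and C≈D raise
dedicated errors; so does a `superior_dir` parallel to the tangent
(orientation undecidable).  Angles of exactly −180° are mapped to +180°.

## Classification

Normal disc position is the closed band [−15°, +15°]; strictly above is
anterior displacement, strictly below posterior displacement.  The band
is closed because displacement is defined by "greater than 15°", so the
boundary itself is normal.  Recapture is defined only for joints whose
baseline (position 1) is anteriorly displaced; asking about any other
baseline raises a not-applicable error.  Cohort recapture rates are the
per-joint indicator mean, with the percentage rounded to one decimal.
DDwoR (displacement without reduction) is carried as a diagnosis label;
its angles flow through the same classifier, but no reduction-dynamics
logic exists for it.

## Kinematics

Movements are componentwise frame-coordinate differences `to − from`,
split into named anatomical directions (negative Δx → anterior, negative
Δy → inferior).  Group means are arithmetic means of per-joint vectors;
by linearity they equal the displacement between group-mean coordinates,
which is why feeding published group means through the operation
reproduces published movement magnitudes exactly.  Joints missing either
position are excluded pairwise.  The posture summary reports D2 − D1
(vertical opening change; D1–D3 are inter-incisor distances in the three
bite registrations) and overjet_p1 − overjet_p3 (protrusion change of
the stabilization posture, ≈ 0 by design).

## Statistics

* Descriptives: mean and n−1 SD (SD undefined for n = 1).
* One-way ANOVA: classic between/within decomposition; p from the F
  distribution.  Fisher's LSD pairwise p uses
  t = (mᵢ − mⱼ)/√(MSw(1/nᵢ + 1/nⱼ)) on the within df, which for two
  groups reduces exactly to the pooled t-test (F = t²).  Zero within-
  variance with unequal means is reported as p = 0 and flagged.
* t-tests: Student's, two-sided, pooled variance when unpaired (scipy);
  zero-variance cases are flagged rather than silently NaN.
* ICC: single-measure Shrout–Fleiss coefficients from the two-way mean
  squares.  Default model is ICC(2,1) — two-way random effects, absolute
  agreement — the standard choice for inter-observer reliability of
  continuous measurements; ICC(1,1) and ICC(3,1) are selectable.  The
  implementation is ~20 lines of mean-squares algebra and is cross-
  checked in the tests against an independent reference implementation.
* Across-position comparisons default to the one-way ANOVA even though
  positions are within-joint, mirroring conventional reporting in this
  literature; a paired option exists (`run_study(..., paired=True)`).
  No multiplicity correction is applied beyond LSD.  All tests are
  two-sided at α = 0.05 by convention of the report renderer.

## Synthetic cohort generator

The generator emulates a clinical cohort — defaults 10 normal, 60 DDwR,
4 DDwoR joints, three bite positions — whose derived measurements
reproduce the published group statistics this package models.

**What is drawn.**  Per joint and position: condyle frame coordinates
from independent per-axis normals (published mean/SD per group and
position); the disc–condyle angle; the disc radius ‖D−C‖ from
N(4.8, 0.5) mm (4.8 mm is the norm of the displaced group's baseline
mean disc–condyle offset).  Patient metadata: D1 ~ N(14.2, 2.0) mm,
opening increment ~ N(2.7, 0.8) truncated at 0 (so D2 = D1 + increment,
D3 = D2 by protocol), overjets ~ N(3.1, 1.1) and N(3.0, 1.2) clipped at
0, drawn independently.

**Angle-first generation.**  Angles are drawn directly and D is placed
at the drawn angle and radius around C.  For DDwR joints in treated
positions the angle is a two-component mixture: with probability
`recapture_prob` (defaults 58/60 for position 2, 20/60 for position 3) a
normal truncated to the ±15° band, otherwise truncated above it.  A
plain normal calibrated to the treated-position moments (−10.5 ± 17.1°)
would put ~37 % of mass outside the band, irreconcilable with 2/60
observed failures; the mixture matches the recapture fractions exactly
in expectation while keeping the component shapes.  Two documented
consequences: the realized treated-position angle mean/SD deviate from
the nominal parameters (truncation pulls the position-2 mean from −10.5°
to ≈ −2°), and disc *coordinate* distributions match the published
coordinate table only approximately.  Baseline (position 1) DDwR angles
are drawn untruncated from N(53.4, 16.7), so ≈ 1 % of simulated
baselines fall inside the band; `run_study` therefore restricts
recapture rates to joints with displaced baselines and reports the
excluded count.

**Scene embedding.**  T, P, G are placed at anatomical offsets with
0.5 mm placement jitter; C and D are synthesized *through the frame
axes*, the whole scene gets a random rigid motion (±10°, ±10 mm by
default) and left-side joints are mirrored.  Measuring any generated
scene through the geometry module recovers the drawn values to < 1e-9
(the round-trip test that pins generator and measurement to the same
conventions).  `fh_dir` is generated parallel to the T–P tangent plus
`fh_tilt_deg` (default 0°), as no tangent-vs-FH relationship is
published.

**Seeding.**  One global seed expands into independent substreams for
latent clinical draws, scene nuisance and metadata, so changing scene
settings or adding rater noise never perturbs latent values; cohorts are
byte-identical across runs with the same config.

**Deliberate simplifications.**  Condyle axes are drawn independently
(no coordinate covariances are published); positions are independent
within a joint by default (`position_corr`, default 0, adds a shared
joint-level effect to condyle coordinates — the true within-joint
correlation is unknown); DDwoR angle SDs default to the DDwR baseline SD
and DDwoR condyle parameters reuse the DDwR values (neither is
published); each joint gets its own synthetic patient (no bilateral
structure, which no computed statistic uses).

**Rater noise.**  `add_rater_noise` perturbs every landmark point with
isotropic Gaussian noise, emulating a replicate annotation session for
ICC analysis; zero noise reproduces the cohort exactly and yields
ICC = 1.

**What passing tests do and do not show.**  The generator validates the
pipeline's internal consistency (round-trip fidelity, invariances,
calibration recovery) and the statistics' correctness.  It does not
establish performance on real MRI: real annotations have structured,
anatomy-dependent error, real FH traces are not parallel to the fossa
tangent, real cohorts have within-joint and within-patient correlation,
and real disc shapes make the D landmark itself uncertain.

## Validation problem sizes

Calibration tests use 200 replicate cohorts of the default 74 joints;
the acceptance script uses 500 replicates for recapture fractions and
200 for the baseline angle mean (replicate-averaged, compared within
Monte-Carlo standard error).  Large-sample recovery checks use 2 000 –
10 000 joints.  These sizes put Monte-Carlo error well below the effects
being checked while keeping the full suite under a minute.

## Known limitations

2D single-slice geometry only (no medial/lateral displacement, condylar
rotation or fossa morphometrics); no automatic landmark detection; no
DICOM ingestion (coordinates must already be in mm with a known superior
direction); the ±15° band is the only diagnostic criterion implemented;
ANOVA/LSD inherits the usual caveats of unpaired analysis of
within-joint positions — the paired option is provided for sensitivity
analysis.
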