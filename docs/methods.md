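# Methods

## Coordinate systems and calibration

Four rigid frames are involved: the B-mode image plane `p`, the probe-
mounted sensor `r`, the electromagnetic transmitter `t`, and the user's
reconstruction frame `c`; a pixel reaches world coordinates through
`cTp = cTt · tTr · rTp`. Poses carry translations in millimetres and
intrinsic Z-Y-X Euler angles (azimuth, elevation, roll) in degrees —
the convention common to electromagnetic trackers; it is recorded in
every stream's metadata so files are self-describing, and conversions go
through `scipy.spatial.transform.Rotation`. `cTt` defaults to the
identity (reconstruction frame = transmitter frame) and is configurable.

Cross-wire calibration estimates `rTp` and the wire location `w`
simultaneously: with `x_i` the wire pixel of observation `i` in
probe-frame mm, the residuals `tTr_i · rTp · x_i − w` are minimised by
Levenberg–Marquardt over 9 parameters, initialised at the identity
transform and the centroid of the tracker-transformed pixels. Because the
wire pixel always has `z = 0` in the image plane, only the first two
rotation columns are directly observed; parametrising the rotation by
Euler angles keeps the estimate a proper rotation, and the solution is
unique once the observations span ≥ 3 distinct orientations (enforced;
fewer raises a degenerate-geometry error, as do < 8 observations). On
noise-free synthetic observations the inversion is exact to machine
precision; at the tracker's documented accuracy (0.5 mm, 0.1°) and 50
observations the translation error is typically a few tenths of a
millimetre.

## Narrow-band rendering

The coronal image is generated directly from the raw frames; no 3D voxel
volume is ever built. Per frame, a layer of thickness 5.6 mm (the
clinical default; configurable) is selected:

* **nonplanar** — rows whose image depth `v · spacing_y` lies in
  `[depth, depth + thickness)`; since the probe face stays in skin
  contact, this band follows the skin surface (a developable surface)
  and tracks anatomy that undulates in depth;
* **planar** — pixels whose world depth coordinate lies in the same
  half-open slab, the conventional fixed-depth reslice.

Selected pixels are deposited into a regular grid (rows = longitudinal
axis at `spacing_y` = 0.5 mm by default, the operator's choice; columns =
lateral axis defaulting to the transducer pixel spacing, 0.1 mm). Bin
assignment is `floor((coord − origin)/spacing)` with half-open bins, so a
point exactly on an upper boundary belongs to the next bin. Each bin
displays the mean of its hits (pixel-nearest-neighbour filling); points
outside the grid are dropped and counted.

Hole filling assigns each empty bin the mean of the nonempty bins in its
immediate neighbourhood. The neighbourhood wording in the field is
ambiguous ("nearest two-by-two" has no centre); the default here is the
8-connected 3×3 ring, with 4-connected available. The pass is single and
reads only original emptiness flags — no cascading — so the result is
order-independent, and it acts on a display copy only; the sum/count
accumulators are never modified. Contrast is a linear stretch mapping the
1st–99th percentile range of nonempty pixels to [0, 255] (robust to
speckle outliers; percentiles configurable; a constant image maps to
mid-grey 128, empty pixels render black).

## Incremental imaging

A session is prepared from two recorded boundary poses (caudal to L5,
cranial to T1): their probe footprints, expanded by an operator offset on
every face, define the cubic scan range that sizes the grid. During
streaming, each batch's in-layer pixels are deposited, and only `C_new` —
their bounding bin box padded by one bin so border hole filling sees its
neighbours — is re-averaged and hole-filled; the contrast stretch is
recomputed over the whole image, since it is a display-only global
operation. Imaging stops when a frame pose reaches the upper boundary
(boundary inclusive); finalisation re-runs hole filling globally and
writes the 8-bit BMP.

The headline engineering property is exact batch/stream equivalence:
accumulator sums are float64, but inputs are 8-bit integers, so every
partial sum is an exactly-representable integer and float addition is
effectively associative — the final accumulators are bit-identical for
any batching, and the finalised image matches a single-shot render
pixel for pixel. Frames arriving out of scan order are accepted (the
accumulators are order-invariant) with a warning, since an upward sweep
is the expected use. Per-batch timing is logged and reported as an
incremental frame rate; it is informational and hardware-dependent.

## The spine phantom and scan simulator

The phantom emulates exactly what the rendering method needs to be
tested against, not ultrasound physics. World axes: x lateral, y depth,
z longitudinal over a spine of length L (default 300 mm — a desk-scale
sweep giving 750 frames at the default 25 frames/s and 10 mm/s, ~1 cm/s).
A spinous-process ridge of radius ~4 mm (gently modulated per vertebra)
runs along a parametric centerline; its lateral deviation encodes the
scoliotic curve with closed-form SPA:

* `straight` (SPA 0), `c` half-sine bump (SPA = 2·atan(Aπ/L)), `s` full
  sine (double curve), `piecewise` two straight segments (exact angle by
  construction). `target_spa` solves the amplitude in closed form.

The skin surface undulates sinusoidally in depth (default amplitude 8 mm,
exceeding the 5.6 mm layer) to mimic the sagittal kyphosis/lordosis
profile, and the bone sits a fixed 20 mm below the skin, so a skin-
following sweep sees it at constant image depth — the premise that makes
nonplanar reslicing outperform a fixed-depth planar slab. Frames show a
bright specular arc (0.6 mm half-thickness, intensity 235) at the bone
surface, an exponential acoustic shadow beneath it (0.5 /mm attenuation
of the 120-intensity soft-tissue background), and additive Gaussian
speckle (σ = 10, clipped to [0, 255]). Real speckle is Rayleigh-like and
multiplicative; the additive model was chosen because the rendering under
test is intensity-agnostic, and the noise model is pluggable. The
simulated trajectory keeps the probe on the skin and the spine centred
laterally, as an operator would; sensor poses are emitted as
`tTr = tTp · rTp⁻¹` so a calibrated replay recovers the probe placement
exactly. All randomness is an explicit seeded generator; identical
(config, seed) gives bit-identical streams.

What passing tests on this phantom do **not** show: robustness to
refraction, attenuation through thick soft tissue (high-BMI subjects),
rib shadows, probe pressure deformation, or tracker drift — none of which
the simulator models.

## Automatic SPA measurement

Clinically the SPA lines are drawn by an observer; the automatic
extractor exists so the pipeline can be tested closed-loop, and is a
testing surrogate, not a model of observer behaviour. Per image row the
dark trough is located as a darkness-weighted centroid (weights are the
squared excess darkness over half the row's maximum darkness, relative to
the row median), giving sub-pixel centres robust to the flat-bottomed
shadow; rows lacking 8 grey levels of trough contrast are skipped. The
centreline is smoothed (15-row moving average by default; not a clinical
parameter), tangent angles come from local linear fits (±8 rows), and
lines are placed at the tangent-angle extrema — two lines for a single
curve, three alternating extrema for a double curve, with one angle per
adjacent pair. Angles are unsigned acute angles from the atan2 form of
the direction-vector formula (numerically exact near 0° and 90°).
End-to-end, phantoms with true SPAs of 5–40° (the clinical range) are
recovered within a fraction of a degree under default conditions.

## Statistics

Repeatability uses the intraclass correlation in its ICC(2,1) form —
two-way random effects, absolute agreement, single measures — computed
via `pingouin.intraclass_corr` (form configurable). Currier reliability
bands are applied as ≥ 0.80 "very reliable", 0.60–0.79 "moderately
reliable", < 0.60 "questionably reliable"; the published band edges
overlap at 0.60, resolved here by treating the moderate band as the
half-open [0.60, 0.80). Zero between-subject variance raises an
undefined-ICC error. Method agreement uses the through-origin regression
`slope = Σxy/Σx²`; its R² is computed against the uncentered total sum of
squares (the natural choice for a no-intercept model), with the centered
R², Pearson r and the ordinary least-squares fit with intercept reported
alongside for comparison.

## Numerical choices and limitations

* Half-open intervals everywhere (layer bands, bins); 0-based row-major
  indices; mm for all world coordinates; degrees at interfaces, radians
  internally.
* Rigid-transform invariants (orthonormality, det +1, last row) are
  validated at 1e-8–1e-9 — implementation contracts, not physical
  tolerances.
* Percentile definition: linear interpolation between order statistics
  (the numpy default); the display rounding is `rint` then clip.
* A mid-scan layer-depth change is supported by replaying with a new
  `LayerSpec` over subsequent batches; previously rendered bins keep
  their old-depth content (the ambiguity is inherent to incremental
  depth changes and is left to the operator).
* Problem sizes in the test-suite and acceptance runs (200–300 mm
  sweeps, 500–820 mm for milestone checks) are desk-scale choices; the
  method itself is size-agnostic.
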