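# Methods

## The model

The expiratory limb of a flow-volume loop is summarized by three
landmarks: **A**, the point of peak expiratory flow (PEF); **B**, the
curve point after 75% of the expiratory vital capacity has been exhaled
(the FEF75 locus — roughly where flow becomes dominated by the small
airways); and **C**, the end of the limb on the volume axis at
(FVC, 0).  B is linearly interpolated between the bracketing samples;
A resolves ties at the maximum to the first sample; C is the last
sample.  A curve whose peak lies at or beyond 75% of FVC has no A–B
segment and is rejected as degenerate.

Flow is regressed on volume by ordinary least squares separately over
the A–B span `[v_A, v_B]` and the B–C span `[v_B, v_C]` (B belongs to
both).  Writing θ = arctan(−slope/aspect) for the signed descent
inclination of a fitted line, the indices are

- **∠ABC** = 180° − (θ_AB − θ_BC), folded into (0, 180] when the tail
  is steeper than the A–B descent.  This equals the interior angle at
  B between the ray B→A along the A–B line and the ray B→C along the
  B–C line (the test suite checks it against an independent
  direction-vector atan2(cross, dot) oracle to 1e-9 degrees).
- **∠BCX** = arctan(|slope_BC|/aspect) ∈ [0°, 90°).
- **log(BC/A-x)** = log10(|slope_BC| / PEF).  The slope magnitude makes
  the ratio positive; a zero tail slope raises an undefined-ratio error
  rather than returning −∞.  Base 10 is the default; the quantity under
  a different base is a constant multiple, so orderings and cutoff
  logic are unaffected.

**The aspect parameter.** Angles are not invariant to how many L/s are
plotted per L of volume.  All angle operations take `aspect` (L/s per
L, default 1), i.e. by default angles are computed in value space with
1 L ≡ 1 L/s.  Passing the panel's pixel aspect instead reproduces
display-space angles.  Under a fixed aspect, affine axis re-scalings
preserve the ordering of ∠ABC across curves, which is what cutoff
classification needs.

## Digitization

Pages are grayscale rasters (PNG/TIFF/JPEG; vector reports should be
rasterized upstream, nominally at 200 dpi).  Three stages:

1. **Panel localization.**  A 64-bit average hash is computed for every
   template-sized window (8×8 block grid, block mean ≥ grid mean → 1;
   a constant raster therefore hashes to all ones).  The window with
   minimum Hamming distance to the locator-glyph hash wins, ties going
   to the first window in row-major scan order; distances above the
   acceptance threshold (default 4 bits) raise panel-not-found.  The
   panel bounds are the winning window expanded by configured margins
   (defaults sized to the bundled synthetic layout).  The search is
   vectorized with an integral image, so whole-page scans are cheap.
2. **Axis calibration.**  The axis origin is the intersection of the
   row with the longest horizontal dark run and the column with the
   longest vertical dark run inside the panel.  The digit glyph ("2")
   is searched below the x axis and left of the y axis; each template
   carries an anchor→tick offset, and all accepted matches plus the
   origin (value 0) enter a least-squares affine fit per axis.  A
   failed axis names itself in the error.  Round-trip
   value→pixel→value error is self-checked to < 0.5 × scale.
3. **Tracing.**  For each pixel column right of the origin, ink runs at
   or above the axis row are curve candidates; the topmost run is
   taken (when in- and expiratory limbs overlap, the expiratory limb
   lies above), runs that never rise above the axis line are treated
   as axis stroke, and the run centroid over above-axis rows maps
   through the calibration to (volume, flow).  This keeps flat tails
   that merge optically into the axis traceable out to C while
   terminating the trace on axis-only columns.  The output is trimmed
   to the span of non-negative flow; fewer than 10 traceable columns
   raise trace-failed.

Flow resolution is one pixel row, so tail flows below ~1 px read as
~1 px; at the default synthetic layout (50 px per L/s) that is
0.02 L/s and the traced end of the limb satisfies the curve
invariant |flow_final| ≤ 0.05 L/s.  Layouts plotting fewer than
~20 px per L/s will not meet that invariant for flat tails.

## Synthetic fixtures

`piecewise_linear` limbs rise straight from (0, 0) to (v_peak, PEF)
and then descend along two exact segments with requested inclinations
θ_AB and θ_BC (measured under aspect 1), B pinned at 0.75 × FVC and C
at (FVC, 0).  Pinning B and C makes PEF a *derived* quantity,
PEF = tan(θ_BC)·0.25·FVC + tan(θ_AB)·(0.75·FVC − v_peak); a supplied
PEF that contradicts it raises invalid-spec.  Ground truth is closed
form: ∠ABC = 180° − (θ_AB − θ_BC), ∠BCX = θ_BC.  `smooth_power` limbs
decay as PEF·((FVC−v)/(FVC−v_peak))^γ; their ground truth comes from
running the index code on a dense noise-free sampling (oracle by
construction).  Optional Gaussian flow noise is seeded, clipped at 0
and excluded from the endpoints so curve invariants hold.

The renderer draws axes (1 px), integer ticks, the digit "2" at value
2 on each axis, the "F/V ex" locator label — all from a bundled 5×7
bitmap font — and the limb as a vertically-stroked band inked per
pixel column over the rows the curve crosses, widened by half the
stroke.  That band construction keeps the column-wise ink centroid on
the true curve to within quantization, which is the property the
tracer's accuracy contract is measured against.  The default layout is
an 800×600 page with the panel in the upper right, 60 px per L and
50 px per L/s.  Rendering is fully deterministic: same spec and seed,
byte-identical page.

The cohort simulator draws per-subject target ∠ABC values from two
Gaussians — flattening 144.8 ± 8.5°, non-flattening 163.8 ± 14.1° —
with a fixed A–B inclination (default 60°), converts each target to
θ_BC = ∠ABC − (180° − θ_AB), generates the limb and records the
indices the index code actually computes.  The targets are truncated
to the geometrically feasible interval (180° − θ_AB + 0.5°, 180°]:
∠ABC > 180° cannot exist, so the upper tail of the non-flattening
Gaussian is necessarily cut and the realized non-flattening group mean
sits near 160.5° with SD near 11.5° (the truncated-normal moments),
not at the nominal 163.8 ± 14.1.  The derived mean − 1·SD cutoff lands
within ~1° of 149.7°.  Tests assert against the truncated-moment
oracle, not the nominal moments.

What the simulator does *not* emulate: multi-effort overlays, cough
artifacts, obstructive (FEV1/FVC < 0.7) loop shapes, device-specific
noise spectra, anti-aliased or colored rendering, and scanned-page
skew.  Passing end-to-end tests therefore demonstrate correctness of
the geometry, calibration arithmetic and tracing logic on clean
report-like pages, not robustness to degraded clinical scans.

## Cohort statistics

`summarize_cohort` uses the sample SD (n−1).  The flattening cutoff is
mean − k·SD of an expert-labelled non-flattening group (k = 1 ≈ the
Gaussian 15th percentile); classification is strictly `value <
cutoff`, so a value exactly at the cutoff is non-flattening.  The
lower limit of normal is reported both parametrically
(mean − 1.6449·SD, the Gaussian 5th percentile) and as the
linearly-interpolated empirical percentile.

Fleiss' kappa is computed from the subjects × categories count table:
κ = (P̄ − P̄e)/(1 − P̄e) with P_i = (Σ_j n_ij² − n)/(n(n−1)) and
P̄e = Σ_j p_j².  The default 95% CI is κ ± 1.96·SE with the
large-sample SE
√(2/(N n(n−1))) · √((Σp_jq_j)² − Σp_jq_j(q_j − p_j)) / Σp_jq_j; a
seeded subject-resampling percentile bootstrap is available
(`bootstrap=N`).  If every rating falls in one category, P̄e = 1 and κ
is returned as 1.0 with a degenerate [κ, κ] interval and a flag.
Missing ratings are rejected, not imputed.  The unpaired equal-variance
t-test is a thin wrapper (scipy) with an explicit degenerate-variance
error when both groups have zero within-group variance and unequal
means.

## Batch pipeline

`run_batch` processes inputs independently in sorted path order,
mapping every failure to a status token (`panel-not-found`,
`trace-failed`, `degenerate-curve`, …) in a JSON manifest that also
records the tool version and a config digest; one bad input never
aborts the batch, and the CLI exits 0 on total success, 3 on partial
failure, mirroring how a reading room would triage a stack of reports.
The FEV1/FVC > 0.7 inclusion filter is applied only when a sidecar
metadata CSV supplies the ratio; the tool does not OCR it from the
page.  "Adequate quality" is operationalized as: trace succeeded with
≥ 10 columns and the curve invariants hold — anything else is flagged
for a human.

## Numerical choices and edge cases

- Hash tie rule: block mean ≥ grid mean → bit 1 (constant window ⇒ all
  ones); fixed so that matches are bit-reproducible.
- Glyph match ties: first window in row-major scan order; overlapping
  matches are suppressed within one template size.
- Curve container invariants: ≥ 10 samples, volume strictly
  increasing, flow ≥ −0.05 L/s, final flow within 0.05 L/s of zero.
- Angle fold: 180° − (θ_AB − θ_BC) values above 180° (tail steeper
  than descent) are reflected to 360° − x, keeping the interior angle.
- Problem sizes: the end-to-end fidelity checks use 20 rendered pages
  and the statistical-recovery checks a 500 + 500 cohort, enough for
  sampling error well inside the asserted tolerances.

## Known limitations

- Raster input only; vector PDF path extraction is out of scope.
- One locator label per layout; reports lacking it are not handled.
- Single-effort tracings; the topmost-band rule resolves loop overlap
  near the origin but not overlaid repeat efforts.
- No reference equations (age/height/sex) for the indices; cutoffs are
  cohort-derived.
- Kappa CIs assume complete panels with a constant rater count.
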