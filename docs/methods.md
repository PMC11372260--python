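# Methods

## Delineation model

The package implements fixed-threshold TMTV delineation: a voxel is
candidate tumor iff SUV ≥ 4.0, candidates are grouped into 3-D connected
components, and the automated preselection keeps components of volume
≥ 3 cm³. Both comparisons are inclusive ("at least 4", "at least 3"). The
SUV is assumed body-weight normalised — the standard convention when a
fixed SUV-4.0 cutoff is quoted; no other normalisation is offered.
Volume is voxel count × voxel volume, with no partial-volume weighting or
mesh correction: the simplest convention consistent with a threshold rule
on a voxel grid, and the one that makes phantom ground truth exact.

Connectivity defaults to 26 (faces + edges + corners). The original
benchmark software does not state its adjacency; 26 is the common default
in SUV-threshold MTV tools and merges diagonal bridges the way readers
perceive single lesions. 6 and 18 are available everywhere connectivity
appears. Components touching the image border are kept.

## Workflow semantics

The four-stage protocol is driven by a serialisable session:

- **Stages 1–2 (remove_click):** a click deletes the *whole* component
  containing the clicked voxel. Whole-component semantics were chosen
  because partial removal by click is underdetermined; the stage-3 edit
  mask is the escape hatch when physiologic uptake is fused with tumor.
  Clicks use world-mm coordinates (voxel indices with an explicit flag)
  and require exact containment — no snapping — because silently grabbing
  a neighbouring structure is worse than an error.
- **Stage 3 (edit_mask):** arbitrary voxel erasure followed by relabeling
  (a cut component splits). The ≥ 3 cm³ filter applies **only** at
  preselection; fragments a reader deliberately keeps survive at any size.
- **Stage 4 (add_seed):** the full connected SUV ≥ 4 region under the seed
  is added with no volume threshold, using the preselection connectivity.
  Overlap with the existing segmentation merges (idempotent union), since
  additions model "missed" uptake and union is the only non-destructive
  semantics.
- Failure handling is lenient by default (log and continue), strict on
  request; replay is deterministic — there is no hidden state.

## Agreement harness

- Reference value per case: median of the 3–4 reader TMTVs (mean of the
  middle pair for even counts).
- Concordance: pass iff |Δ| < 10 cm³ or |Δ|/reference < 10%. Strict `<`
  is used and stated in every report; the source material mixes "within"
  and "less than", and boundary-equal cases are practically nonexistent at
  float precision. The relative arm is normalised by the reference
  (median), not the pair mean.
- ICC: ICC(2,1) — two-way random effects, absolute agreement, single
  rater — because readers are a random sample of an expert population and
  absolute agreement is the claim being validated. Computed via
  `pingouin.intraclass_corr`; rows with missing readers are dropped
  (case-wise deletion). A panel with zero total variance is defined as
  ICC 1 with a warning rather than 0/0.
- Discrepancy flagging: a case is flagged when any reader deviates from
  the median by more than 25% (relative) or more than 45 cm³ (absolute).
  The 45 cm³ default is chosen so that all eight published adjudicated
  cases — including the ~50–100 cm³ non-spleen ones — are captured; both
  thresholds are configurable because the original nomination rule is not
  stated.

## Phantom generator

Organs are analytic spheres, ellipsoids, boxes and capsules painted in
`paint_order` (higher wins); a voxel belongs to an organ iff the shape
contains the voxel *center*. No antialiasing: truth volumes are
integer-voxel exact, which is what makes zero-error recovery a meaningful
test. Truth masks and per-organ voxel counts are recorded before
degradation. A liver is always present as reference tissue so the
spleen-to-liver ratio (the > 1.5× rule for diffuse splenic uptake) is well
defined.

Scanner physics is emulated post hoc: Gaussian PSF blur with
σ = FWHM/2.355 per axis, then additive Gaussian noise in SUV space clamped
at zero, fully determined by a seed. Gaussian SUV noise approximates
post-reconstruction PET noise; Poisson projection noise and reconstruction
itself are out of scope, as are anthropomorphic (XCAT-style) anatomies.

The default grid is 128 × 128 × 160 at 4 mm isotropic — a realistic
whole-body PET sampling that keeps a full scenario rasterization and
workflow replay at a few seconds. The scenario library covers the uptake
patterns the benchmark was curated to span: multifocal nodal disease;
physiologic-only interaction; reactive spleen + marrow removed at stage 2;
diffuse splenic uptake at 1.6× liver both with marrow changes (removed)
and without (retained as disease, mirroring the reader instruction);
a node fused to the kidney requiring a stage-3 edit; myocardial uptake
fused to a mediastinal lesion; sub-3 cm³ lesions added at stage 4; focal
bone disease; and a bulky ~1,900 cm³ case, so suite TMTV4 values span
~9–1,900 cm³. Expected stage TMTVs are derived purely from rasterizer
voxel counts by per-scenario organ bookkeeping, independent of the
segmentation code. Scenario SUVs: physiologic organs use typical values
(brain 10, bladder 12, myocardium 6, kidneys 8), lesions 6–12, liver
2.5–3.0, background 1.0 (soft tissue); diffuse-spleen cases use liver 3.0
and spleen 4.8, i.e. a ratio of exactly 1.6.

What passing clean-mode tests shows — and does not show: exact recovery
demonstrates the threshold/labeling/interaction bookkeeping is correct,
not that the method segments real reconstructed images well; real data
adds PSF, noise, respiratory motion and heterogeneous uptake the phantom
only caricatures. The degraded-mode property (a 100 cm³ SUV-10 lesion
under 6 mm FWHM and 0.2 SUV noise recovered within ±15%, measured ~5%
worst case over 20 seeds) is a desk-scale illustration of why a fixed
SUV-4 threshold is robust to reconstruction differences, not a clinical
validation.

## Numerical choices

- SUV stored float32, labels uint16; negative input SUV clamped to 0 with
  a warning (reconstruction noise); non-finite input is an error.
- Volumes are loaded into a fixed RAS+ frame; grid equality checks use a
  1e-3 mm tolerance to absorb float32 header round-trip.
- Components are labeled in decreasing volume order (ties by scan order)
  for stable reporting; filtering preserves survivor identity.
- World→index mapping rounds to the nearest voxel center and rejects
  out-of-grid points.
- Human-readable reports round TMTV to 0.1 cm³; machine outputs keep full
  precision.
- Exact-recovery tests compare at 1e-9 cm³ (13 orders of magnitude below
  one voxel) to allow float summation-order noise while still asserting
  zero voxel error.

## Test and simulation sizes

Oracle-equivalence checks use 100 random 10³ masks against a BFS flood
fill and voxel-loop thresholding; monotonicity fuzzing uses 50 random
40³-voxel phantoms with random sessions; ICC calibration uses 4-reader
panels of 5,000 cases, averaging 10 panels per variance ratio
(ρ ∈ {0.5, 0.9, 0.99}) so the Monte-Carlo error of the mean (~0.002) sits
well inside the 0.01 acceptance band; robustness uses 20 noise seeds on a
64³ grid. These sizes keep the whole suite at a few minutes on one core.

## Known limitations

- No DICOM ingestion or vendor-tag SUV derivation; NIfTI-1 (plus optional
  JSON sidecar metadata) is the only supported format.
- The clinical judgement of what is physiologic/reactive lives in session
  scripts; the package never classifies uptake automatically.
- Baseline-scan setting only: a fixed SUV-4 threshold is not expected to
  work for interim or end-of-treatment response scans with faint residual
  uptake.
- The harness validates implementations against references; it does not
  assess clinical segmentation quality or prognostic value.
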