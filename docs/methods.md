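# Methods

This note documents the models, parameter choices and numerical decisions
behind `hsiwound`, and what the synthetic-phantom tests do and do not show
about real bedside data.

## Reflectance calibration

Raw snapshot-mosaic counts are converted to relative reflectance by
flat-field normalisation, `R = f (raw − dark) / (white − dark)`, with
`f = 0.98` the stated reflectance of the calibration board, imaged at the
70 cm working distance. The white reference may be a full frame or a
single spectrum broadcast spatially. Whether the camera performs dark-
current subtraction internally is unknown, so the dark frame is an
optional input that defaults to zero rather than a guess.

Calibrated values are clipped to [0, 1.10] instead of erroring above 1:
bedside scenes are lit uncontrollably and specular glints routinely push a
few pixels past the white reference. Any `(white − dark) ≤ 0` entry is a
hard error reporting the bad-pixel count, since it means the reference
frame cannot normalise that pixel at all.

The 16 band centres (465–630 nm) are bundled as a named constant. The
mosaic tile order of the sensor is proprietary; the demosaicer fixes
row-major 4×4 offsets mapped to the sorted wavelength list, and
already-demosaiced cubes (ENVI or multi-band TIFF) are the primary input
path. Coordinates are 0-based row-major with half-open ROIs throughout.

## Segmentation

k-means is implemented from scratch (it is the core of the measurement
method, not a dependency): Lloyd iterations from k-means++ starts, best of
`restarts` runs by within-cluster sum of squares, stopping when the
largest centroid shift drops below `tol` (1e−6) or at `max_iter` (300).
All randomness flows from one integer seed; the same cube and seed give
the same mask, bit for bit. An emptied cluster is re-seeded at the point
farthest from its current centroid rather than silently dropping k. The
final iteration re-assigns labels and sets every centroid to the exact
mean of its members, so the fitted model satisfies the mean property to
machine precision and the recorded inertia trace is non-increasing.

Defaults: k = 2 (wound vs healthy skin — the ROI has already removed
non-skin content), 10 restarts, Euclidean distance on raw reflectance.
An optional per-pixel mean normalisation (off by default) makes the
partition invariant to global illumination scaling. All 16 bands are used.

With 10 restarts on tiny unstructured instances (n ≤ 10 random spectra),
Lloyd attains the exhaustive-enumeration global optimum in roughly 94% of
instances — indistinguishable from scikit-learn's KMeans with `n_init=10`
on the same instances, i.e. a property of the algorithm, not of this
implementation. The global-optimality check in the acceptance suite
therefore runs at 20 restarts, where the attainment rate is 96–100%
across seed bases; the pipeline default stays at 10, which is ample for
real two-class scenes.

**Wound labelling.** The study distinguishes wound from healthy skin but
states no labelling rule, so one had to be chosen: the wound cluster is
the centroid minimising mean R(534–586 nm) / mean R(600–630 nm). Erythema
and granulation absorb in the oxy-hemoglobin bands; skin reflectance rises
monotonically over this range. A `darkest` fallback (minimum overall mean)
is provided for scenes where the dip contrast fails (e.g. necrotic
eschar). The rule used is recorded in the output provenance.

## Area

* `machine_lw`: axis-aligned bounding-box area of the **raw** wound mask.
  No rotated-rectangle fitting — the convention mirrors a ruler laid along
  image axes.
* `machine_morph`: the mask is opened with a radius-1 cross (diamond)
  structuring element, reduced to its largest 4-connected component (ties
  broken by smallest top-left bounding-box corner), hole-filled, and
  counted: pixels × pitch². The chain is the minimal standard one for a
  single-wound scene: opening removes sensor speckle, the largest
  component drops disconnected false positives, hole filling restores
  specular dropouts inside the wound bed.

The two measurements deliberately use different masks (raw vs cleaned);
in the bundled case table the morphology column exceeds the LW column in
some cases, which is only possible if the study did likewise. A cross-
element opening shaves the four corner pixels of any solid rectangle —
an accepted, documented artefact of the element shape (≤ 4 px per
measurement).

An empty mask is an error at every stage (with the stage recorded), never
area 0: all study cases had visible wounds, so emptiness means the
segmentation failed and silence would hide it. Pixel pitch is a config
input derived from the imaging geometry or a fiducial of known size
(e.g. a 1 cm² grid in frame); there is no automatic ruler detection.

## Agreement statistics

* Pearson r from centred sums (exactly 1.0 for identical inputs, which
  scipy's normalized-vector formulation narrowly misses); Spearman ρ as
  Pearson on midranks.
* ICC: both single-measure forms are reported rather than guessing the
  study's choice — one-way random ICC(1,1) and two-way absolute-agreement
  ICC(A,1), from the standard ANOVA mean squares (verified against
  pingouin). For replicated designs, `icc_mixed` estimates
  σ²_subject/(σ²_subject+σ²_residual) by ANOVA method of moments with the
  unbalanced-design n₀ coefficient, truncating a negative between-subject
  component at zero. Truncation makes the null-case estimator positively
  biased (≈ +0.06 at 20 subjects × 3 replicates); tests account for this.
* Cohen's κ on categories, with identity/linear/quadratic agreement
  weights and the Fleiss–Cohen–Everitt large-sample variance for 95% CIs
  (point estimates verified against scikit-learn). κ on continuous areas
  requires binning, and the bin scheme is part of the statistic: the
  default is five pooled-quantile bins over the union of the two compared
  columns, recorded in every report. The study's own binning is not
  recoverable from the publication, so printed κ and ICC point values are
  not reproduction targets; the rank correlations, which need no binning,
  are.
* Reports print to 2 decimals; JSON output keeps full precision.

**A reporting discrepancy in the source table.** On the bundled 30-case
table, nurse-LW vs machine-LW gives ρ = 0.8251, which prints as 0.83,
while the study reports 0.82 (and reports r for the same pair as 0.82 in
text but 0.80 in its table). The printed table contains two exact ties
(14.60 cm² twice; 0.73 cm² twice); recomputing ρ with those ties broken —
as unrounded source data would break them — yields 0.822–0.827 depending
on order. The package reports its computed value and flags the
discrepancy, taking no side. The other four printed ρ values (0.44, 0.70,
and 0.92, 0.97 after outlier removal) reproduce exactly at two decimals,
as does the qualitative claim that removing the seven flagged cases
raises every pairwise correlation.

## Synthetic phantoms

The generator emulates what the analysis needs from a bedside scene, not
skin biophysics:

* **Spectra**: skin is piecewise-linear through fixed anchors (0.35 at
  465 nm rising to 0.60 at 630 nm); wound subtracts a raised-cosine dip of
  depth 0.25 centred at 560 nm with 95 nm half-width (zero at the 465 nm
  anchor, floored at 0.05). The constants are documented choices for
  separability with a hemoglobin-like motif, not fits to optical data.
* **Geometry**: a digital disk (default radius 20 px at 0.05 cm/px,
  ≈ π cm²) or a single connected blob from thresholded smoothed noise, in
  a 96×96 raster. The truth mask is the discrete pixel set, so the true
  area (count × pitch²) is exact whatever the shape.
* **Nuisance structure**: an optional erythema halo ring (spectra blend
  linearly from wound to skin across the ring), a multiplicative planar
  illumination gradient (default max ±10%) in a seeded random direction,
  and additive Gaussian reflectance noise (default σ = 0.01).
* **Nurse simulation**: the LW product over the bounding box of the truth
  mask — plus the halo ring when `include_halo` is set, since manual
  measurements integrate the reddened margin into "wound" — with optional
  seeded uniform ruler jitter per dimension. With an 8–10 px halo the
  nurse/machine-planimetry ratio averages ≈ 1.7, reproducing the
  mechanism (though not calibrated to the magnitude) of the known ~44%
  manual overestimation.

What passing phantom tests shows: the pipeline recovers known areas
(median planimetric error < 5% at σ = 0.01, in practice ≈ 0%), LW
dominates planimetry structurally, the halo mechanism inflates manual
readings, and everything is seed-deterministic. What it does not show:
performance under real tissue spectra, mixed pathologies (slough,
eschar), shadows, curved anatomy or camera PSF — no claim about clinical
accuracy follows from synthetic recovery.

## Problem sizes

Defaults keep every check cheap and exhaustive where exhaustiveness is the
point: optimality over 100 instances of n ≤ 10 (2ⁿ enumerations each),
area recovery over 50 phantom seeds, ICC recovery over 200 simulated
replicate studies, κ null over 1000 draws. The full suite plus acceptance
script completes in well under a minute on one CPU.

## Known limitations

Single wound per scene (multi-wound scenes reduce to the largest
component); no depth or volume; no automatic ROI or pixel-pitch
detection; the wound-labelling rule presumes vascularised wound tissue;
the study's κ/ICC point values and triplicate mixed-model ICCs are not
reproducible from published information and are validated by construction
(simulation with known truth) instead.
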