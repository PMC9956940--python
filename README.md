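# hsiwound

Hyperspectral measurement of pressure-injury wound area, for wound-care
research and nursing-informatics groups who want a standardized, operator-
independent alternative to the bedside ruler.

## The problem

Pressure injuries (PIs) are staged and tracked by wound size. At the
bedside, a nurse measures maximal length and width with a plastic ruler and
records the product — the **length × width (LW) rule**. Because wounds are
irregular and surrounded by erythema (red but intact skin), the LW rule
systematically overestimates the true wound surface, by ~44% in published
comparisons, and the overestimate varies between observers.

A 16-band snapshot-mosaic hyperspectral camera (465–630 nm) records a
reflectance spectrum at every pixel. Wound tissue — granulation and
erythema — absorbs strongly in the oxy-hemoglobin bands around 534–586 nm,
while healthy skin reflectance keeps rising toward the red end. That
spectral contrast lets an unsupervised algorithm separate wound from skin
without training data.

## The method

For a scene cube `raw` with white-reference frame `white` (board
reflectance f = 0.98) and optional dark frame:

1. **Calibration** — per pixel and band,
   `R = f · (raw − dark) / (white − dark)`, clipped to [0, 1.10].
2. **Framing** — a user-supplied region of interest removes bed sheets,
   clothing and other non-skin content.
3. **Segmentation** — from-scratch k-means (Lloyd iterations, k-means++
   seeding, 10 restarts, seeded and fully deterministic) partitions the
   pixel spectra, k = 2 by default. The *wound* cluster is the one whose
   centroid minimizes mean R(534–586 nm) / mean R(600–630 nm) — the
   hemoglobin-dip rule.
4. **Area** — two conventions, both in cm² from the pixel pitch p (cm/px):
   * `machine_lw` — bounding-box area of the wound mask,
     (Δrow·p)·(Δcol·p), mirroring the nurse's ruler;
   * `machine_morph` — planimetry after morphological clean-up
     (cross-element opening → largest 4-connected component → hole fill),
     pixel count · p².
5. **Agreement** — Pearson r, Spearman ρ (midranks), single-measure ICC
   (one-way ICC(1,1) and absolute-agreement ICC(A,1)), and Cohen's κ
   (unweighted and quadratic-weighted, on pooled-quintile area bins) with
   large-sample 95% CIs, plus a variance-components ICC for replicated
   measurements.

The package bundles the study's 30-case table (NPUAP stage, nurse-LW,
machine-LW and machine-morphology areas, and the seven cases flagged as
outliers for inconsistent wound localisation) and a synthetic phantom
generator that produces 16-band scenes with exactly known wound area, an
optional erythema halo, illumination gradients and sensor noise — so the
whole pipeline is testable without any image download.

## Worked example

Generate a disk phantom (radius 20 px at 0.05 cm/px — a wound of
3.16 cm²) and measure it:

```sh
$ hsiwound simulate --preset disk --seed 7 --out demo/
wrote phantom (true area 3.1600 cm^2) to demo

$ hsiwound measure --raw demo/phantom.hdr --white white.hdr \
      --seed 7 --out demo_out/
{
  "machine_lw_cm2": 4.0,
  "machine_morph_cm2": 3.16,
  ...
}
```

The morphology planimetry recovers the true 3.16 cm² exactly at this noise
level; the LW bounding box reads 4.0 cm² (2.05 cm × ~1.95 cm), showing the
built-in overestimate of the ruler convention even before any halo is
included.

Recompute the full agreement grid on the bundled 30-case table:

```sh
$ hsiwound reproduce-table4
```

prints, among others (two decimals):

| comparison                        | n  | r    | ρ    |
|-----------------------------------|----|------|------|
| nurse-LW vs machine-LW            | 30 | 0.80 | 0.83 |
| nurse-LW vs machine-morph         | 30 | 0.44 | 0.44 |
| machine-LW vs machine-morph       | 30 | 0.69 | 0.70 |
| nurse-LW vs machine-morph, no outliers   | 23 | 0.88 | 0.92 |
| machine-LW vs machine-morph, no outliers | 23 | 0.97 | 0.97 |

Dropping the seven flagged outlier cases raises every correlation —
the machine and the nurse disagree mostly where they disagreed about
*where* the wound is, not how big it is. (See `docs/methods.md` for a
note on the nurse-vs-machine-LW ρ, which the study reported as 0.82.)

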