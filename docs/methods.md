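# Methods

## The virtual microscope

The simulator renders 16-bit camera frames from a procedural
ground-truth *transmittance* field `T(x, y) ∈ [0, 1]` sampled at a fixed
base resolution (4 nm per sample by default, the native pixel scale of
the real instrument class being modelled). A frame at stage position
`(cx, cy)` with pixel size `p` nm/px is

    pixel = clip(round(T̃ · G · S + D + ε), 0, 65535)

where `T̃` is the (optionally defocus-blurred) truth resampled
bilinearly onto the camera grid, `G` the illumination gain surface, `S`
the full-scale signal (40 000 DN at transmittance 1), `D` the dark
offset plus per-pixel fixed-pattern field, and `ε` Poisson shot noise on
the signal (conversion gain 2 DN/e⁻) plus Gaussian read noise
(25 DN sd). With the beam off only `D + ε_read` remains. Outside the
aperture the tape is opaque (`T = 0`), which is what the centroid
finder's bright/dark binary search exploits.

Specific modelling choices:

* **Sections.** Tissue is an elliptical patch of band-passed Gaussian
  texture (default feature band 30–200 nm, emulating membrane-scale
  contrast in a 40 nm section) with darker somata and bright,
  low-texture vessel voids punched out of the tissue mask. A weak
  band-passed "support-film grain" (3% amplitude) covers the substrate:
  without it NCC matching on tissue-free regions would lock onto the
  sensor's fixed-pattern noise, and with it the matcher behaves the way
  it does on real substrate, succeeding away from tissue.
* **Illumination.** `G` is a normalized radial dome
  `(1−f) + f·exp(−r²/2σ²)` (mean exactly 1, strictly positive), centred
  at the frame centre plus a beam shift plus clock-driven drift. This is
  the phenomenon the brightfield correction removes and the beam
  centering loop repositions.
* **Defocus.** Blur sigma is `k·|f − f_opt(x, y)|` rendered pixels,
  with `f_opt` a linear plane (value at origin plus gradient per µm) per
  section — the "sample height gradient" that motivates satellite focus
  points. `k` defaults to 0.8 px per lens unit; focus tests use `k = 2`
  so that sub-unit focus errors are resolvable at the coarse test pixel
  size.
* **Stage.** Per-move isotropic Gaussian error truncated at 4 sd
  (the printed overlap margin constrains only the worst case, not the
  law), plus a Gaussian settle-time draw that advances a simulated
  millisecond clock. The clock replaces wall time everywhere, making
  throughput bookkeeping exactly reproducible.
* **Barcodes.** The optical tape frames carry a Manchester-coded 16-bit
  strip (3-module start/stop bars, one even-parity bit). This is a
  documented synthetic encoding standing in for the real optical
  barcode; the decoder is run-length based and tolerant of ~10% additive
  noise.
* **Determinism.** Generators are pure functions of (seed, parameters);
  the scope owns a single `numpy` Generator, so identical seeds and call
  sequences give bit-identical frames, metadata and reports.

## Correction and calibration

The flat-field ratio `(image − dark)/(bright − dark)` is computed in
float and mapped to 8 bpp with a configurable gain (default 180, i.e.
full transmittance ≈ 70% of the 8-bit range; the conversion itself is
the only thing fixed by the source design). Brightfield "scaling" is
normalization to unit mean, which makes the ratio a relative
transmittance; the stored brightfield is the unit-mean shape rescaled to
the scene's DN level so the ratio stays near [0, 1]. A correction set is
invalid wherever `bright − dark ≤ 0` and is rejected before any tile is
written.

Pixel calibration measures the NCC displacement of a centred 3×3
template grid (128 px squares, quarter-frame spacing) under ±step moves
per axis; each template is used under whichever sign keeps its content
in view, and a (template, sign) pair whose expected position leaves the
frame is skipped rather than matched spuriously. `nm/px =
1000·step/mean(|displacement|)` per axis, with the vector scatter
reported, never dropped. Steps should satisfy
`step ≤ (fov/2 − template)` so the centre column stays measurable, and
be large relative to the stage error (which enters the measurement
directly). Beam rotation is the angle of the measured stage-equivalent
displacement for a commanded +x move, normalized to (−180°, 180°].

Beam centering iterates measure-and-correct on the intensity-weighted
centroid of an open-beam frame (the dome centroid is attenuated by the
flat background, so a gain of 1.8 with up to 4 iterations converges
without oscillating) and fails if the offset is not reduced below 2% of
the frame.

## Focus

The score masks the centred log-magnitude spectrum to integer radii
r ∈ [6, min(1600, r_max)] — the stated low/high cut-offs read as radial
bins of the shifted spectrum, the one well-defined interpretation of the
constants — bins it into 720 angular cells by nearest assignment
(empty cells ignored), averages per radius and sums. The image mean is
subtracted before the DFT: mathematically this only changes the
(already excluded) DC bin, but it makes the additive-offset invariance
*bit-exact* for integer images, which the property suite asserts.

Autofocus scans the range at step range/12, rejects flat curves
(max−min < 5% of max ⇒ "no peak", the vessel-void signature) and
boundary maxima, then golden-sections the winning bracket to 1% of the
range, averaging 2 frames per evaluation to keep shot noise from
steering the comparisons. Montage focus is the mean of accepted points:
the ROI centroid plus up to 4 satellites at the centroid-to-corner
midpoints.

## QC

Templates are square, one third of the overlap-strip width, placed at
1/4, 1/2, 3/4 along the shared edge and *flush against the edge*: flush
placement keeps template content inside the neighbour for displacements
up to the full strip width, which mid-strip placement does not. The
search region is the neighbour's strip of twice the overlap. Degenerate
(zero-variance) templates count as unmatched, never raise. Sub-pixel
positions come from a parabolic fit around the NCC peak. Sign
convention: positive = found beyond the expected position (blue in the
rendered offset maps).

Default criteria (all config-exposed; the source design states that the
thresholds exist but not their values): NCC ≥ 0.5, ≥ 2 matched templates
per edge, vector sd ≤ 2 px, offset ≤ 10% of the overlap width, dark-tile
mean < 10/255, intensity band [10, 245], flagged-tile budget 5%,
montage-failure budget 3 per run.

## Problem sizes and what the tests show

Tests and the acceptance script run the whole loop at desk scale: truth
sampling coarsened to 16 nm, apertures of tens of µm, frames of
128–512 px, 3×3 to 8×8 montages. These sizes were chosen as the
package's own study conditions; the geometry and the statistics under
test are size-independent, and the production frame sizes (3840/5408)
appear in the pure-arithmetic checks, which do not render pixels. One
consequence of the coarse pixel scale is that the stage-error-to-
QC-threshold ratio must be preserved explicitly: scaled scenarios use a
0.01 µm per-move sd (≈ 0.6 px at 16 nm/px against a 3.3 px offset
threshold), the same ratio a 0.05 µm stage achieves against the ~50 px
threshold at production scale.

The synthetic tape reproduces the *mechanisms* real data exercises —
illumination gradients, defocus blur, stage scatter, voids, empty
apertures, beam-off tiles — but not the full texture statistics of
stained tissue, optical tape photography, or real barcode optics.
Passing tests therefore demonstrate the correctness of the algorithms
and the closed loop against known ground truth, not performance figures
on real microscopes; the printed production numbers that depend on
hardware (net frame rates, petabyte totals, stitching residuals) are
out of scope, and the reported throughput arithmetic is reproduced as
arithmetic.

## Known limitations

* Montage planning covers the axis-aligned bounding box of a rotated
  ROI; tile-level rotation handling is left to stitching.
* The brightfield walk integrates a finite number of discrete positions
  (default 6 per frame) rather than continuous motion, so a faint
  texture residue survives at very low frame counts.
* The databases are local JSON-lines files with last-write-wins
  semantics — the cloud/database infrastructure of a production
  deployment is an operational concern, not an algorithm.
* Detection power is quantified for row-level faults (offset, dark,
  defocus). A single dark tile among 64 is below the 5% flagged-tile
  budget by design; catching isolated single-tile faults requires
  tightening `max_flagged_tiles_frac`.
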