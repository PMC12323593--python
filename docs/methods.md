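# Methods

This note documents the models, default parameters and numerical choices
behind `flaps_phenotyper`, and what the synthetic validation does and does
not establish about real data.

## Imaging model and cell classification

A field of view (FOV) is a stack of pre-registered channel rasters acquired
at one stage position: a DAPI nucleic-acid counterstain, the FLAPS substrate
channel at several exposure times, and optional FISH and autofluorescence
(Auto) channels. The instrument acquires all channels through one
multi-filter module without moving the sample, so no registration is
computed. Pixel coordinates are 0-based row-major; all object masks are
boolean rasters of the FOV shape (stored internally as sorted flat indices).

**Segmentation.** Each channel is thresholded at
`median + k_mad · 1.4826 · MAD` of the raster (`robust_background`, default
`k_mad = 5`; Otsu offered as an alternative), labeled into 8-connected
components, and size-filtered to `[0.05, 20] µm²` (defaults). The background
estimate for the signal-to-background ratio (SBR = mean object intensity /
median non-object intensity) is the median outside all above-threshold
pixels. The robust location/scale are taken on a 1-in-3 strided subsample of
the raster for speed; on ~10⁵ pixels the induced error is far below a count.
Touching cells are not split (no watershed): the simulator never places
overlapping cells, and the classification rule is cell-centric, so splitting
errors would first appear on dense real samples — a stated limitation.

**Multi-exposure consolidation.** The FLAPS channel is acquired at 10, 35
and 140 ms so both dim and bright staining land inside the camera's dynamic
range. An object is *saturated* when ≥ 1% of its pixels reach ≥ 98% of the
camera maximum. Detections at different exposures whose centroids fall
within 0.5 µm, or whose masks intersect, are one physical object; the
retained representative is the longest unsaturated exposure, falling back to
the shortest exposure when all are clipped. Both saturation thresholds are
package choices — the instrument protocol motivates multiple exposures but
prescribes no merge rule.

**Classification.** A cell is a DAPI object. It is FLAPS-positive when the
single best-overlapping FLAPS object covers ≥ 30% of the DAPI mask *and*
that object's SBR is ≥ 1 (both thresholds inclusive, reading "minimum"
literally). The overlap denominator is the DAPI mask (configurable
convention; the cited image-analysis protocol does not name a denominator).
FISH and Auto positivity use the same overlap rule. The truth table is
exhaustive and mutually exclusive: Auto ∧ FLAPS → cyanobacterium (pigment
autofluorescence bleeds into the substrate channel and would otherwise
masquerade as selfish uptake); FLAPS ∧ FISH → probe-identified FLAPS cell;
FLAPS alone → FLAPS cell; otherwise unstained. FLAPS objects that overlap no
DAPI object above threshold are background particles (substrate adhering to
particulate organic matter) and enter no cell count. An optional crosstalk
correction subtracts `c ×` the exposure-scaled FISH raster from each FLAPS
raster before segmentation (default `c = 0`), countering red-to-green
bleed-through from FISH fluorophores.

**Quantification.** `total_cells` counts all DAPI objects including
cyanobacteria; the selfish fraction is `n_flaps_pos / (total −
n_cyanobacteria)` — cyanobacteria are excluded from numerator and
denominator. Uncertainty on the pooled fraction is a Wilson 95% interval
(chosen for its behaviour at small counts and fractions near 0; the
experimental protocol reports replicate spread without naming an interval).
Cell concentration is `mean cells per FOV × (filter area / FOV area) /
volume filtered`. Timecourses carry a *dilution flag* per interval: a
falling selfish fraction coinciding with rising cell numbers signals
fluorescence dilution by division (daughter cells splitting the substrate)
rather than a genuine loss of selfish activity.

## Synthetic fields of view

The generator renders what the classification rules assume, with one truth
record per object:

- Cells are filled ellipses (default 1.6 × 0.8 µm at 0.1 µm/px, random
  orientation quantized to 24 bins for cached geometry), placed by rejection
  sampling so that rendered extents never touch — every object stays its own
  connected component. Failure to place after 300 tries raises a placement
  error rather than silently overlapping cells.
- Selfish cells carry one of the two staining patterns seen by
  super-resolution imaging: a periplasmic **halo** band spanning 1 px
  outside to 2 px inside the cell outline, or **polar caps** at one or both
  ends (cut at 15% of the semi-major axis). Both geometries overlap the DAPI
  ellipse well above the 30% threshold, as a diffraction-limited periplasmic
  ring does in a real widefield image; a ring drawn strictly outside the
  cell would have zero pixel overlap and could never satisfy a
  co-localization criterion.
- Counts derived from fractions (selfish, autofluorescent, FISH-positive,
  halo/polar split) use round-half-away-from-zero applied once, so truth
  counts are deterministic; identities follow placement order, which is
  spatially unbiased because positions are i.i.d.
- Autofluorescent (cyanobacteria-like) cells deposit in DAPI, FLAPS and
  Auto. FISH positives are drawn among selfish cells (the probe is chosen to
  target the selfish clade of interest). Background particles are disks of
  radius 3–5 px in the FLAPS channel only.
- FLAPS deposits are rates (default 40 counts/ms; particles 10 counts/ms)
  scaled linearly by exposure and clipped at the camera maximum (default
  12-bit, 4095), so default-brightness cells saturate at 140 ms and exercise
  the merge rule. DAPI/FISH/Auto levels are amplitudes at their fixed
  exposures (1500/1200/1000 counts). A per-object log-normal brightness
  factor (log-sd 0.3) models staining variability. Background is flat
  (100 counts) plus optional Gaussian read noise; "moderate" noise in the
  validation experiments is sd 8 counts, i.e. deposits sit tens to hundreds
  of robust sd above threshold, as well-stained cells do. FISH→FLAPS
  crosstalk adds `c ×` the FISH emission rate into each FLAPS exposure.

What passing on synthetic fields does **not** show: performance under
non-uniform illumination, focus drift, touching or dividing cells, irregular
particle morphologies, or staining intensities near the detection limit.
The synthetic experiment validates the *logic* of the workflow (counting,
co-localization, exclusion rules, exposure merging, statistics), not the
segmentation's robustness on difficult real images.

## Chromatograms and hydrolysis rates

Gel permeation chromatography maps molecular weight to elution volume;
`log10(MW)` is fitted as a least-squares line in elution volume from ≥ 2
standards (a positive slope warns — larger molecules eluting later is
physically suspect for size exclusion — but does not abort). Chromatogram
signal is integrated per descending MW class with the trapezoid rule on the
native elution grid (no resampling, for determinism) and normalized to
fractions; signal outside the outermost bounds is ignored. Class boundaries
are experiment-specific config inputs (defaults 10⁶/3·10⁴/3·10³/300/30 Da
with a 100 kDa parent).

The rate over `(t_a, t_b)` is the unweighted monomer-equivalent product
gain: `Σ_i max(0, f_i(t_b) − f_i(t_a)) · C / Δt` over classes below the
parent, `C` defaulting to 3500 nmol monomer L⁻¹ (the standard 3.5 µM
monomer-equivalent addition — about 21 µmol C L⁻¹ for a hexose polymer, a
deliberately low carbon amendment). A per-class weight vector is accepted
for users who apply a cut-count weighting from the original GPC rate
formalism; it is not applied by default. When a killed-control series is
supplied, the control's class-wise drift over the interval is subtracted
from the live endpoint fractions (clipped at zero and renormalized) before
computing gains, so abiotic MW drift cancels. Rates are clipped at zero.
Intervals are reported both between consecutive timepoints and against t0,
covering both conventions for "the rate detected in the 48 h sample". Rates
are invariant to uniform rescaling of the raw fluorescence, since only
normalized fractions enter.

The simulated timecourse builds each chromatogram as a mass-weighted sum of
Gaussian peaks normalized to unit grid integral, so total signal is
conserved exactly and a transfer fraction *f* over Δt must be recovered as
`f · C / Δt` up to class-binning error (< 1% with default peak width 0.3 mL
against ≥ 2.5 mL between peak centres and class boundaries).

## Flow cytometry

Events below the instrument's electric threshold (FSC-H < 17 000) are
discarded. The FL1-H gate is the nearest-rank 0.999 quantile of a negative
control — either the unamended community or a fixed-and-inactivated sample
with FLAPS added (the operation is agnostic to which) — among events passing
the scatter threshold; at least 100 surviving control events are required.
The quantile is a documented package default: the experimental protocol
draws a threshold line without a formula. Sample events are positive when
FL1-H strictly exceeds the gate, so a control gated against its own
threshold yields ≈ 0.1% positives by construction — a useful self-check.
Positive fractions carry Wilson 95% intervals. No doublet gating is
performed (pulse-area columns are not part of the input contract).

The event simulator draws FL1-H from a two-component log-normal mixture
(negative median 100, positive median 5000, log-sd 0.5 each — separated far
beyond the control's 0.999 quantile) with scatter independent of the
positive flag (FSC-H median 50 000, log-sd 0.4, so ~0.3% of events fall
under the electric threshold). The planted positive count is exact by
deterministic rounding.

## Validation experiment sizes

The acceptance suite uses 20 noise-free 100-cell fields for exact-recovery
checks; 100 replicate "incubations" of 45 FOV × 100 cells (288 × 288 px) at
noise sd 8 for selfish-fraction recovery with planted fraction 0.16; 100
seeds of 10 000 events for cytometry recovery with planted fraction 0.30;
and single-interval chromatogram series for rate recovery. The
reporting script (`scripts/acceptance.py`) runs the same experiments at 30
incubation replicates. FOV raster sizes only set how many cells fit per
field; per-cell statistics are unaffected.

## Known limitations

- One FISH probe per FOV; multi-probe multiplexing is out of scope.
- FISH-induced FLAPS signal loss (roughly half the positives can wash out
  during hybridization) is not corrected for — no correction model is
  established — so probe-identified selfish counts are lower bounds.
- No optical PSF, 3-D stacks, flat-field correction or proprietary
  microscope formats; FCS support covers list-mode FCS 3.0/3.1 with uniform
  parameter width, plus a delimited fallback.
- Hydrolysis rates ignore column-spreading and peak-deconvolution effects;
  classes are treated as independent bins.
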