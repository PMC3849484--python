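# Methods

## Color model

Stain classes are axis-aligned boxes in RGB space with inclusive per-channel
bounds, applied directly to the 8-bit image — no HSV conversion and no color
deconvolution. The shipped defaults split DAB brown into three intensity
bands and add the hematoxylin-blue negative class:

| class          | R         | G         | B         |
|----------------|-----------|-----------|-----------|
| darkest brown  | 40–120    | 20–90     | 0–70      |
| mid brown      | 121–170   | 80–130    | 40–100    |
| light brown    | 171–215   | 120–170   | 70–135    |
| negative blue  | 60–160    | 70–170    | 130–230   |
| wide positive  | hull of the three browns (40–215, 20–170, 0–135) |
| bg1            | = wide positive |
| bg2            | 171–230   | 120–185   | 70–150    |

These defaults are calibrated to the synthetic generator's palette; real
material requires recalibration via the YAML configuration. Ranges may
overlap; the pipeline keeps its per-step maps disjoint by sentinel masking,
not by assuming disjoint boxes.

Pixels excluded from a pass (negative nuclei, previously selected objects)
are recolored with a sentinel (default pure green, (0,255,0)) validated at
configuration load to lie outside every positive box. Masking at the pixel
level rather than the object level is deliberate: at step 1 the light
positive objects are not yet segmented, so "mask negative and light-positive
objects" can only be realized as color-range masking.

## Morphometry

Objects are 8-connected components, labeled in raster-scan order. The
perimeter is the length of the closed Moore-neighbor boundary walk of the
component (orthogonal steps 1, diagonal steps √2; holes do not contribute;
one-pixel-wide protrusions are walked on both sides). Roundness is
`perimeter²/(4π·area)`, clamped below at 1; a single pixel is 1 by
convention. This estimator is implemented in-package and pinned by tests on
exact shapes (a 1×50 strip has walk length 98; a digital disc of radius 20
lands at roundness ≈ 1.05) because library perimeter estimators use
different weightings and would silently shift every roundness band.

Default morphological gates (px², dimensionless):

* maps 1–3: area 80–5000, roundness 1–3.0;
* final pass: area 80–1200, roundness 1–1.6 — only small, nearly circular
  objects survive;
* wide macro: area ≥ 80 with no upper gates. The legacy macro trusts color
  alone and relies on area-quotient splitting for arbitrarily large nucleus
  clusters; per-step morphological gating is precisely what the multistep
  procedure adds. This choice also reproduces the legacy macro's documented
  failure on background-laden images, where diffuse deposits are selected
  and counted as positive area.

Hole filling and border-object exclusion are off by default and exposed as
configuration flags.

## Background discrimination and routing

With `selected` the union of maps 1–3:

* `area1 = |bg1 \ selected|` — non-selected pixels in the primary positive
  hull;
* `area2 = |bg2 \ (selected ∪ bg1)|` — non-selected pixels in the lighter
  extension band only. Excluding the bg1 support makes the two measurements
  disjoint, so `area2 == 0` is a meaningful "no diffuse stain beyond the
  positive palette" test even when brown nuclei are present.

Class NONE iff `area2 == 0`; otherwise LOW when `area2/area1 <` the
threshold (default 0.2) and HIGH when the ratio reaches it or `area1 == 0`.
The tie at the threshold goes to HIGH — the conservative direction, since
the full macro filters hardest. Normalizing area2 by area1 makes the cut
scale-free in the deposit amount and sensitive to its palette instead.

Routing: NONE → wide macro (maps 1–3 discarded, one wide segmentation);
LOW → restrictive macro (union of maps 1–3); HIGH → full macro. In the full
macro the light-color pass is run as the *final* step under the strict
final band, replacing the permissive map-3 gate: the light band is where
nuclei and diffuse deposits collide, and the strict area/roundness band is
what separates small round nuclei from amorphous background fragments. A
light pass under both the permissive and the strict gate would be
redundant — every object passing the strict band passes the permissive
one — so the full macro's per-step maps are MAP1, MAP2 and FINAL.

## Counting

An object is a cluster iff its area exceeds `cluster_factor` (default 1.5)
times the mean single-nucleus area; a cluster contributes
`round(area/mean_area)` nuclei with a floor of 2, a singleton contributes 1.
Rounding is half-away-from-zero to avoid banker's-rounding drift. The mean
nucleus area is, by default ("auto"), the per-image median area of objects
with roundness ≤ 1.3 (near-round objects are almost surely single nuclei),
falling back to 450 px² when no such object exists; a fixed value can be
configured. Images are grouped as low complexity (≤ 100 estimated positive
nuclei, the conventional cutoff) or high complexity (> 100).

## Synthetic scenes

The generator emulates exactly what the procedure consumes, not histology:

* **Canvas** — white-ish tissue base (244,242,239) with ±6 per-pixel jitter;
  default 696×520 px (half the nominal 1392×1040 capture) for speed, full
  size by argument.
* **Nuclei** — flat-shaded ellipses, hard-edged (no anti-aliasing: blended
  rim colors would stray into the bg2 band and break the clean-scene
  contract). Semi-axes derive from a base radius r ~ U(10.5, 13.5) px and
  aspect ratio U(1.0, 1.25), keeping all semi-axes in [8, 16] px and
  single-nucleus areas in ≈ [346, 572] px², below 1.5× the median — so the
  cluster rule cannot misread a large single nucleus. Positives split
  40/40/20% across the dark/mid/light bands; each nucleus samples a base
  color ≥ 6 counts inside its class box and adds ±6 per-pixel jitter, making
  palette containment exact by construction. A configurable fraction of
  positives is laid out as chains of 2–4 touching ellipses (each member
  counted in ground truth); all other nuclei keep a ≥ 3 px rim.
* **Background deposits** — connected blobs built from random walks of
  overlapping discs, Gaussian-smoothed (σ = 3) and re-thresholded, covering
  ≈ 3% (low) or ≈ 12% (high) of the canvas with per-blob areas ≥ 8000 px²
  (low) / ≥ 14000 px² (high). Deposit pixels sample light-brown colors: a
  fraction f_ext falls in the bg2-only extension zone (f_ext = 0.08 low,
  0.5 high; faint deposits hug the positive palette, heavy deposits wash out
  beyond it), the rest inside the light positive band. The per-blob area
  floors guarantee that the in-band connected core of every blob exceeds the
  5000 px² map gate, so deposits are rejected by morphology rather than by
  luck; this palette split also makes area2 strictly monotone in the level
  and the ratio cut separate LOW from HIGH.

What the generator does **not** model: optics (blur, vignetting, chromatic
noise), chromatin texture, stain gradients within a nucleus, overlapping
nuclei beyond touching chains, tissue architecture. Passing tests therefore
demonstrate the procedure's internal correctness and its discrimination
logic under controlled palettes — not performance on real slides, whose
color boxes must be recalibrated.

## Numerical choices and degenerate inputs

* Inclusive bounds on both ends of every color box.
* Labels and object ordering are raster-scan deterministic; the whole
  pipeline is a pure function of (image, configuration), and the generator
  is bit-reproducible from its seed (PCG64).
* `area1 == 0` with `area2 > 0` classifies HIGH (the ratio is undefined);
  ratio exactly at the threshold classifies HIGH.
* Zero-pixel images, dimension mismatches, lo > hi bounds, sentinel inside a
  positive box, non-positive mean nucleus area: all rejected with
  `ValueError` at the boundary.
* Packing is rejection-sampled with bounded retries; impossible requests
  (too many nuclei for the canvas) raise rather than degrade.

## Validation problem sizes

The shipped tests and the acceptance script use 696×520 scenes with 20–100
nuclei for routing and count-recovery checks (50 and 20 seeds per condition
respectively), and 30 full-size 1392×1040 scenes with 120–250 positive
nuclei for the macro comparison — the package's chosen balance between
statistical resolution and a test suite that runs in minutes.

## Known limitations

* RGB boxes cannot separate stains that overlap in RGB; color deconvolution
  is out of scope by design.
* Counting splits clusters by area only; chains with heavy mutual overlap
  undercount, and no per-nucleus coordinates are produced.
* The full macro discards light-band objects failing the strict band, so
  genuinely large or elongated light-positive clusters on heavy-background
  images are traded away against background rejection.
* Agreement statistics use absolute differences for the cumulative curve
  (the magnitude of disagreement is what the ≥ d threshold means) and report
  no confidence intervals on the limits of agreement.
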