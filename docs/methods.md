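# Methods

This note documents the models, numerical choices and known limitations of
`g4afm`. Units are nanometres throughout; the raster convention is row-major
with the origin top-left and pixel centres at integer indices.

## Synthetic topographs

### Backbone geometry

Filament backbones are discrete 2-D worm-like chains: steps of fixed length
`step_nm` (default 0.25 nm) whose heading performs a Gaussian random walk
with per-step variance `step / lp`. This gives the standard 2-D tangent
correlation `⟨t(s)·t(0)⟩ = exp(−s / 2lp)` and the closed form

    ⟨R²⟩ = 4 lp L [1 − (2 lp / L)(1 − e^(−L / 2lp))],

which the test suite checks against a 500-replicate ensemble. Persistence
lengths: 250 nm for the stiff G4 filaments (they appear gently curved at
100–200 nm contour), 18–25 nm for the coiled thin chains. These are
generator realism choices, not measured values.

### Ridge rendering

A structure is rendered by sweeping a cross-section along its backbone and
max-composing with the existing surface (AFM reports the topmost surface, so
overlap is max, never sum). The cross-section is a flat top of width
`apparent_width / 2` with Gaussian shoulders chosen so the full width at
half maximum equals `apparent_width`. A pure Gaussian fall-off is available
(`profile="gaussian"`) but is not the default: these assemblies are solid
objects whose imaged edges are tip-limited and steep, and a Gaussian ridge
spreads so many pixels over intermediate heights that the pixel-height
histogram of a mixed field loses the clean bimodality the real system shows.

Each swept patch is narrow along the local tangent (σ = 1 nm, with samples
every 0.1 nm of arc). The axial footprint matters: a radially symmetric
deposit with σ comparable to the bump period smears the axial modulation
(troughs fill in, the apex mean rises ~0.05 nm) — the sweep keeps the crest
equal to the prescribed apex profile to better than 1%.

Axial modulation is `baseline + a·sin(2πs/P + φ)` by default, or a
"stacked-unit" mode (piecewise-constant offsets over unit lengths drawn
N(P, 0.2P), uniform offsets matched to the same RMS) emulating bulky
irregular repeats. The helper `amplitude_for_rms` inverts RMS = a/√2,
corrected for the 3-sample rolling-average gain at the expected digitised
sample spacing (see *Arc-length convention* below).

Beaded chains are a thin ridge at the inter-bead baseline (0.2 nm) plus
isotropic Gaussian beads (height 2 nm, FWHM 4 nm) at arc spacings drawn
N(11, 4) truncated positive. On a finite chain the last interval is dropped
when it overshoots the contour, which biases retained spacings slightly low
(about −0.1 nm at 100–200 nm contours); the tests compare against an
independent simulation of the same renewal process rather than the nominal
mean.

### Instrument artifacts

Applied in physical order: spherical-cap tip dilation (grayscale dilation
with structuring function `√(r²−|v|²) − r`; extensive, apex-preserving,
identity at r = 0), then per-row offsets (N(0, 0.1 nm)), an optional global
plane, and i.i.d. pixel noise (N(0, 0.05 nm)). The noise and row-offset
scales are engineering choices — small relative to the 0.9 nm chains that
must remain resolvable. The default tip radius is 1 nm, the nominal value
for high-resolution liquid-cell probes; a 2 nm cap would partially fill the
troughs of a 5.4 nm repeat (dilation raises slope points by ≈ r·h′²/2) and
distort the modulation the scenes exist to carry. Everything is reproducible
bit-for-bit from the scene seed.

### Scene presets (the studied populations)

Per-structure parameters are drawn from the reported between-molecule
distributions, so population recoveries can be judged against honest
sampling error:

| preset | structures | apex height (nm) | repeat (nm) | roughness target (nm) |
|---|---|---|---|---|
| `g4_scene` | 33 G4 | N(3.4, 0.2) | 5.4 | N(0.21, 0.07) |
| `post_cycling_scene` | 15 G4 | N(2.6, 0.1) | 5.1 | N(0.07, 0.02) |
| `mixed_scene` | 16 G4 + 32 chains | N(2.5, 0.1) / N(0.9, 0.1) | 5.1 / – | N(0.07, 0.02) / smooth |
| `ionic_exchange_scene` | 33 chains + 10 G4, paired | N(0.9, 0.1) / N(2.6, 0.1) | – / 5.1 | – |

Pixel size is 0.5 nm (2 px/nm); fields are 512×512 px and structures are
placed by rejection sampling without mutual overlap (the analysis chain does
not disentangle crossings). In paired mode the "after" field removes a
configured fraction of G4s, fragments the rest (retention fraction 0.5 in
1–3 pieces), and re-renders thin chains as beaded chains.

## The measurement chain

### Flattening

Order of operations: (1) per-row median over all pixels (a row carrying a
large offset would otherwise sit bodily above the background quantile and
escape the mask), (2) coarse order-1 plane fit and background mask = pixels
at or below the 0.7 height quantile, (3) per-row *median* of background
pixels (medians resist residual foreground), (4) least-squares polynomial
surface (order 1 or 2) on background pixels, re-zeroed on the background
median. Degenerate inputs: a constant image at zero is all background; a
constant tall plateau has no identifiable substrate and fails; rows with
fewer than 3 background pixels get interpolated offsets and a warning.
Round-trip (artifacts → flatten) leaves background residual RMS below twice
the noise σ.

### Grain detection and tracing

Grains are 8-connected components above an absolute height threshold
(default 0.4 nm ≈ 8 noise σ; 0.1 nm for beaded-chain fields, below the
0.2 nm inter-bead baseline), with components under `min_size_px` (default
20 px ≈ a 10 nm contour) removed and border-touching components flagged and
excluded from statistics. Detection and skeletonisation run on a 1-px
Gaussian-filtered copy of the image; without it, noise makes the outline of
low structures ragged and the skeleton zigzags, inflating beaded-chain arc
lengths by ~25%. Heights are always measured on the unfiltered image.

Skeletons (topology-preserving thinning) are ordered by reducing the
8-connected pixel graph to its minimum spanning tree — this drops the
redundant √2 diagonal of every junction 3-clique and cuts genuine loops at
one deterministic edge — then taking the weighted tree diameter between
endpoints (lexicographic tie-break). Side branches are pruned and counted.

### Height profiles

At each backbone pixel the profile height is the **mean across the
3-px-wide dilated cross-section** perpendicular to the local tangent
(tangents estimated over ±3 samples; single-step tangents staircase).
The dilation exists to tolerate ±1 px skeleton-off-crest error; since
structure tops are plateau-like at this resolution the lane mean tracks the
apex without bias, whereas a max over three noisy lanes would add
+0.85 σ_noise (~0.04 nm) to every height. The series is then smoothed by a
centred 3-sample rolling mean, window truncated (never padded) at the ends.
Profiles are trimmed at each end by the grain's estimated half-width
(area / trace length / 2): the skeleton of a thresholded ridge overshoots
the ridge tip by about that much, and those samples ride down the end slope.

### Arc-length convention and its bias

Arc positions and contour lengths use Freeman steps — 1 or √2 pixels per
move, scaled to nm. This convention is fixed deliberately (it is what
pixel-path tracing reports), but it is *biased*: an 8-connected path cannot
be shorter than the digital straight line, which is `cosθ + (√2−1) sinθ`
times the true length — +5.5% averaged over orientations, +8.2% worst case
at 22.5°. Everything derived from arc positions inherits it: peak–peak
separations, bead spacings and contour lengths read ~5–7% high. The
expected digitised sample spacing, `(4/π)·ln(1+√2) ≈ 1.122` pixels of true
arc, is the same geometry and is used when converting roughness targets to
modulation amplitudes. The recovery suite asserts 3-standard-error
agreement regardless, so the periodicity and bead-spacing checks fail by
design at roughly the size of this bias — a deliberate red flag rather than
a silently widened tolerance.

### Statistics

Peaks are selected by topographic prominence (scipy definition; default
floor 0.15 nm ≈ 3 noise σ, 0.5 nm for beads which stand 1.8 nm above their
baseline). Separation histograms (1 nm bins over 0–20 nm) are fitted with a
single Gaussian by unweighted least squares — mirroring how such plotted
distributions are usually fitted — with a maximum-likelihood alternative;
the reported standard error of the fitted mean is floored at sd/√n, since a
near-perfect histogram fit can report an unrealistically small covariance.
RMS roughness is √mean((h−h̄)²) per profile; population summaries are
mean ± SD across structures with N stated.

### Height classification

The pixel-height histogram (0.1 nm bins) uses a mask built from the grain
labels dilated by 1 px then eroded by 4 px. The net 3-px trim matches the
width of the tip-broadened edge band; edge-slope pixels report tip geometry
rather than structure height, and a 1-px trim leaves enough of them to drag
the fitted component means several percent low. A sum of two Gaussians is
least-squares fitted (initial means from the two most prominent modes;
components sorted by mean, so initialisation order cannot flip labels).
Fits are flagged degenerate when the means are closer than a bin or than
the narrower component's width, when a component is narrower than a bin, or
when one amplitude is <10% of the other. Structures are labelled by the
nearest component mean of their mean apex height, "ambiguous" within one SD
of both.

### Paired-field comparison

Registration maximises the exact per-shift Pearson correlation (FFT
cross-sums) over integer shifts; sub-pixel precision is pointless at
0.5 nm/px. Matching is greedy nearest-centroid within 20 nm after offset
correction; leftover after-structures within tolerance of a before-polyline
group as its fragments. Retained length fraction = Σ after contour / before
contour, clipped to [0, 1.05] with a warning above 1.

## What the synthetic scenes do and do not show

Passing recoveries demonstrate that the chain from raw pixels to population
statistics is unbiased (or has known, quantified bias) *under the generator's
assumptions*: isolated non-crossing structures, flat-topped cross-sections,
stationary Gaussian noise, linear background, a spherical tip. Real images
add crossing filaments, scars, nonlinear scanner bow, tip asymmetry and
contamination, none of which are modelled; results on real data depend on
those being handled upstream or being rare. The interpretation constants
(0.34 nm quartet stacking, 0.676 nm/nt single-stranded rise) are literature
geometry, exposed as parameters.

## Benchmark sizes

The recovery benchmark uses the preset populations exactly (33 + 15
filaments, 48 mixed structures, 33 paired chains across 512-px fields);
one full run takes ~20 s on a single CPU, and each quantity is reported
with its n and a 3-standard-error pass flag.
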