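# g4afm

Morphometry of self-assembled G-quadruplex (G4) filaments and thin RNA-like
chains in liquid-cell AFM topographs, with a seeded synthetic topograph
generator so the whole measurement chain can be validated without instrument
data.

## The problem

Guanosine monophosphate (GMP) self-assembles on mica into long filamentous
G-quadruplexes — stacks of hydrogen-bonded G-quartets (axial spacing
3.4 Å) chelating K⁺ — and, after hot wet/dry cycling, into thin coiled
RNA-like chains. Characterising these assemblies from AFM height maps is a
chain of image-analysis steps, each of which can bias the final numbers:

1. **flatten** — remove per-scan-line offsets and substrate tilt so heights
   are nm above the mica background;
2. **trace** — threshold structures into grains, thin each to a one-pixel
   skeleton, and order it into a backbone polyline;
3. **profile** — read the apex height along each backbone (3-px-wide dilated
   cross-section, 3-sample rolling mean);
4. **profile_stats** — prominence peaks and peak–peak separations (axial
   periodicity, Gaussian-fitted), RMS roughness, mean trace height, contour
   length;
5. **height_classes** — the masked pixel-height histogram of a mixed field
   is bimodal; a two-Gaussian fit separates thin chains (~0.9 nm) from G4
   filaments (~2.5 nm) and labels each structure;
6. **compare** — before/after ionic-exchange images of the same field:
   cross-correlation registration, structure matching,
   persistence/fragmentation statistics, and bead morphometry of contracted
   chains (beads ~2 nm high, ~11 nm apart);
7. **interpret** — convert geometry to structure: axial repeat → stacked
   G-quartets (`n = round(d / 0.34 nm)`), contour length → single-stranded
   nucleotide count (rise 0.676 nm/nt), surface coverage → effective
   solution molarity.

The package is aimed at scanning-probe/biophysics researchers who want these
steps as tested, composable functions rather than GUI operations.

## The synthetic generator

`g4afm.synth` / `g4afm.scenes` render seeded scenes with per-structure
ground truth: worm-like-chain backbones (2-D tangent correlation
`exp(-s/2lp)`, closed-form ⟨R²⟩ available for validation), swept flat-top
cross-sections, axial sinusoidal or stacked-unit modulation, beaded chains,
and the instrument's artifacts — row offsets, plane tilt, pixel noise and
spherical-cap tip dilation. Scene presets encode the studied populations
(e.g. G4 apex heights 3.4 ± 0.2 nm with a 5.4 nm axial repeat; thin chains
0.9 nm high and 50–100 nm long; beads spaced 11 ± 4 nm). Paired mode
re-renders the same field after a simulated K⁺→Ni²⁺ exchange.

## Worked example

```python
import numpy as np
from g4afm import quartet_count, pooled_separation_fit
from g4afm.scenes import g4_scene, generate_scene
from g4afm.pipeline import analyze_fields

fields = generate_scene(g4_scene(), seed=1)        # 33 filaments, 7 images
analyses = analyze_fields([f.topo for f in fields])
fit, seps = pooled_separation_fit(analyses)
heights = [s.mean_height_nm for a in analyses for s in a.stats]
print(f"n = {len(heights)} structures")
print(f"mean trace height = {np.mean(heights):.2f} +/- {np.std(heights, ddof=1):.2f} nm")
print(f"axial repeat = {fit.mean:.2f} +/- {fit.sd:.2f} nm (n = {len(seps)} separations)")
print(f"stacked quartets = {quartet_count(fit.mean, fit.sd).n_quartets}")
```

prints

```
n = 33 structures
mean trace height = 3.51 +/- 0.23 nm
axial repeat = 5.76 +/- 0.43 nm (n = 836 separations)
stacked quartets = 17
```

i.e. the pipeline recovers the generated 3.4 nm apex population and the
5.4 nm bump period — the repeat reads ~6% high because arc length along an
8-connected pixel path (steps of 1 or √2 pixels) systematically overstates
the true curve length; see `docs/methods.md`.

A CLI mirrors the stages: `g4afm synth|flatten|trace|stats|classes|interpret|compare|run|benchmark`.

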