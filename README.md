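# fiberweave

Quantification of layered skin architecture from histology sections and
second-harmonic-generation (SHG) microscopy stacks, built around the
kind of question raised by muscular-hydrostat skin (an elephant trunk,
a tongue, an octopus arm): how does a tissue combine a thick protective
keratin armor with the flexibility and strength of its collagen
network?

The package implements four measurements plus the synthetic phantoms
that make every one of them verifiable against exact ground truth:

1. **Layer-thickness morphometry.** A labeled section (background /
   stratum corneum SC / viable epidermis VE / dermis D) is cut into
   one-pixel-wide strips along the outward skin normal; a layer's
   thickness in a strip is its pixel count × pixel size, and sites are
   summarized as mean ± sd per layer.
2. **SHG intensity contrast.** Stacks are preprocessed (clip to the
   (0, 4000) display range, per-slice Gaussian blur σ = 0.5 px,
   rolling-ball background subtraction with radius 40 px defined as
   grayscale opening by a spherical cap), then mean intensity is taken
   over ten 200 × 250 μm ROIs placed ≥ 150 px from the boundary, and
   dorsal vs ventral samples are compared by fold change and t test.
3. **Fiber orientation.** Fibers are traced by a multiscale Hessian
   ridge filter (top 6% most salient pixels kept, skeletonized, and
   re-joined across junctions by angular continuity); each fiber gets
   the angle θ ∈ [0°, 180°) of its total-least-squares line, measured
   from the outward normal. *Perpendicular* fibers have θ ∈ 0 ± 5° ∪
   180 ∓ 5°, *parallel* fibers θ ∈ 90 ± 5°, and a site is *bimodal*
   when both windows hold ≥ 20% of fibers.
4. **Fiber-crossing ("entanglement") density.** A crossing is a contact
   between two distinct fibers within the sum of their radii at a local
   in-plane angle ≥ 15°, declustered so each geometric intersection
   counts once; density is crossings per μm³ of a half-open
   200 × 200 px × 100 μm ROI box.

The phantom generator (`fiberweave.phantom`) renders layered masks with
sinusoidal boundary undulation and fibrous stacks of 10 μm-thick tubes
whose angles come from a (perpendicular, parallel, diffuse) mixture,
with plantable crossings, a 2× or 6× intensity pairing, generator PSF
blur and 12-bit detector noise — and returns the exact truth next to
every image.

## Worked example

`examples/04_fiber_orientation.py` renders 200 fibers from a
25/25/50 mixture, traces them back from the image and classifies them:

```
true fibers: 200, traced fibers: 200
perpendicular (0±5°/180∓5°): truth 24.0% → traced 24.0%
parallel      (90±5°):       truth 26.5% → traced 26.0%
bimodal (both ≥ 20%): truth True → traced True
```

The traced percentages recover the generator's truth to within a
point or two; the bimodal call (≥ 20% in both windows) is the signature
of a tissue that resists load both along and across the skin normal.
The other examples cover thickness profiling, preprocessing, the
planted 2× intensity pair (measured fold 1.901, Welch p = 1.65e-07),
planted-crossing recovery (20 planted → 20 exact / 18 from the noisy
image), and the end-to-end pipeline.

A thin CLI mirrors the library: `fiberweave synth|thickness|preprocess|
intensity|orient|entangle|report|run` (see `fiberweave --help`).

## Layout

- `src/fiberweave/` — library: `phantom`, `morphometry`, `preprocess`,
  `intensity`, `orientation`, `entanglement`, `stats_report`, `io`,
  `config`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameters, numerical choices, limits
- `tests/` — unit, property and acceptance tests
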