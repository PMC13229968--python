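# Methods

## Architecture model

A plant is a list of shoots in depth-first order. Each shoot records its
parent shoot, the 0-based phytomer index where it attaches, its branching
order (primary = 0, capped at 3), a leaf-composition type (1 unifoliate,
3 trifoliate) and base pitch/yaw/roll. Each phytomer holds one internode
(length, radius, pitch, phyllotactic angle), one petiole (length, radius,
pitch, curvature, plus leaflet scale when trifoliate) and its leaves. Cowpea
morphology fixes the leaf counts: the unifoliate node carries a **pair** of
leaves on one petiole slot (two code-3 leaf tokens), trifoliate nodes carry
exactly three leaflets (codes 3, 4, 5). Angles are stored in degrees
everywhere, lengths in metres; radians appear only inside geometry.

Roots and reproductive organs are out of scope: only vegetative shoot
systems are modelled.

### XML dialect

Root `plant_architecture` (attribute `age`), then `base_position`,
`base_rotation`, then `shoot` elements (`id`, `parent_shoot`, `parent_node`,
`type`, `order`, base angles) containing `phytomer` → `internode` /
`petiole` / `leaf` elements with named float attributes. Floats are written
with 6 significant digits and fixed attribute order, so canonical documents
round-trip byte-identically (`write(read(doc)) == doc`). `read(write(A))`
is exact for values with ≤ 6 significant digits — everything the quantizer
or dataset writer produces — and accurate to a relative 1e-5 otherwise.
This is a self-contained dialect: it is not intended to be byte-compatible
with any external simulator's schema.

## Tokenization

Vocabulary layout (228 IDs): organ tokens 0–23 (ID = 6·order + code),
parameter tokens 24–222, specials 223–227 (SOS, EOS, META open/close, PAD —
assignment order is this package's convention). The 199-value parameter
grid is the deduplicated sorted union of

* constants {0, −10, 10, 90, 1, 3} (frequent angles plus the two shoot-type
  labels);
* the angle grid −40° … 360° in 2.5° steps (161 points);
* 10-point linear grids on [0.1, 1], [0.01, 0.1], [0.001, 0.01] and
  [0.0001, 0.001] m (37 distinct values after endpoint overlap).

Quantization maps a value to the nearest grid point with ties broken toward
the smaller value (deterministic; a relative tolerance of 1e-9 absorbs
floating-point noise in tie detection). The error is at most half the local
grid gap — ≤ 1.25° on the angle grid. Petiole curvature, whose natural
range (−200 … −50) lies outside the grid, registers an invertible prescale
of 1/10; all other parameters use identity. The same mechanism is available
for any out-of-range custom parameter.

Per-organ parameter schemas (count and order): shoot → type, base pitch,
yaw, roll; internode → length, radius, pitch, phyllotactic angle; petiole →
length, radius, pitch, curvature (+ leaflet scale when trifoliate); leaf →
scale, pitch, yaw, roll. Plant-level parameters travel as a 4-token header
(base pitch, yaw, roll, age) after the `<META>` block, which itself carries
width, height and vegetation fraction on the shared grid. Because the three
ID ranges are disjoint, the grammar is self-delimiting: the decoder reads
parameters greedily after each organ token, infers unifoliate vs trifoliate
phytomers from the petiole's parameter count, and rebuilds shoot nesting
from block position alone (a child shoot's block follows the phytomer it
attaches to). Decode errors carry the offending token index.

`detokenize ∘ tokenize` is the identity up to quantization; on quantized
plants it is exact, hence the second round-trip is token-identical. Base
position is not tokenized and decodes to the origin.

## Procedural generator

Every organ parameter is sampled from the cowpea parameter table
(constant / uniform / normal per parameter and context): e.g. phyllotactic
angle ~ U(145°, 215°), trifoliate petiole length ~ U(0.06, 0.08) m,
trifoliate leaf pitch ~ N(45°, 20°), leaf roll ≡ −15°. The table is a
plain list of `ParameterSpec` and can be replaced wholesale.

Growth dynamics are internal to any particular simulator and are therefore
exposed as explicit, documented configuration with these defaults:

| constant | default | meaning |
|---|---|---|
| `phyllochron_days` | 3.0 | days between successive phytomers at an apex |
| `lateral_bud_break_prob` | 0.02 | per-node per-day Bernoulli branching probability (one lateral per node, orders ≤ 3) |
| `internode_growth_rate` | 0.25 /day | first-order elongation rate |
| `internode_length_max` | 0.05 m | elongation asymptote (initial length 0.002 m) |
| `max_phytomers_per_shoot` | 20 | apex production cap |

The bud-break probability was set, once, so that day-39 plants reach the
scale of a mature vegetative cowpea: over 100 seeds the generator produces
41–464 leaves (mean ≈ 187), up to ~37 shoots and ~155 phytomers at day 39.
Internodes are the only organs that change after creation
(L(a) = L_max + (L₀ − L_max)·e^(−r·a)); petiole and leaf dimensions are
sampled at mature values, which keeps every stored sampled value on its
specified distribution — the property the distribution-recovery check
relies on. The day-0 plant is one unifoliate phytomer; all later phytomers
and all lateral shoots are trifoliate.

Each plant owns an independent `numpy` Generator seeded with
`seed_base + seed`; draws are consumed in a fixed order (plant base
rotation, then per day: apex phytomer initiation shoot-by-shoot in creation
order, then bud-break trials node-by-node), so the day-d architecture is an
exact prefix of day d+1 and results are platform-independent. Snapshots
canonicalize the shoots list to depth-first order (children after their
attachment phytomer), matching the token layout, and `generate_dataset`
stores the grid-quantized architecture so each XML file is exactly the
decode of its paired token line.

### What the synthetic population does and does not emulate

The generator reproduces the *parameter distributions* and the qualitative
growth pattern (daily phytomer production, stochastic lateral branching,
internode elongation) of a vegetative cowpea population. It does not
emulate environmental response, organ-level growth plasticity, curvature
dynamics, self-shading feedbacks, or any photorealistic appearance. Tests
passing on this population therefore demonstrate correctness of the codec,
geometry and metrics machinery under realistic architectural statistics —
not fidelity of any particular biological growth law.

## Geometry and traits

Right-handed frames, z up. A (pitch, yaw, roll) triple composes as
Rz(yaw)·Ry(pitch)·Rx(roll) — yaw outermost, so a base-yaw change is exactly
a rigid rotation about the vertical axis; heights, areas and inclination
histograms are invariant under it to numerical precision. The phyllotactic
angle accumulates azimuth along each shoot; internode pitch tilts segments
from the shoot axis without compounding (so a constant 20° pitch does not
curl a long shoot onto itself). Petiole curvature is rendered as a circular
arc in the petiole's pitch plane, discretized in 5 segments, with leaves
attached to the arc-end frame at structural azimuth offsets (unifoliate
pair {0°, 180°}; trifoliate terminal 0°, laterals ±120° with the lateral
leaflets scaled by leaflet_scale).

A leaf is a square lamina of side scale·√A₀ with unit prototype area
A₀ = 1 m², so area = scale² exactly; the lamina normal is the leaf frame's
z axis. Plant height is the maximum z over all organ points minus the base
z. Leaf inclination is the angle between the lamina normal and vertical,
folded to [0°, 90°], binned by default into 10 bins of 9° (bin edges at
multiples of 9° keep the conventional 18°/36°/45°/63°/90° boundaries on the
grid). Inclination is measured normal-vs-vertical; users wanting
lamina-vs-horizontal should take the complement. The vegetation fraction
rasterizes the leaf quads orthographically onto a 256×256 top-view grid
over a square window (default 2 m) centred on the plant base, giving a
quantization of about one cell layer (≈ 1/256 of the window) per polygon
edge.

## Metrics

* **Accuracy / weighted F1** (teacher-forcing, aligned corpora): per-ID
  one-vs-rest confusion counts; weighted F1 is Σ nₖ·F1ₖ / Σ nₖ with nₖ the
  reference support. IDs absent from both sequences contribute nothing.
* **BLEU-4**: corpus-level clipped n-gram precisions for n = 1…4, geometric
  mean, times brevity penalty min(1, e^(1 − Σl_ref/Σl_gen)); no smoothing —
  a zero n-gram precision yields 0. Reported ×100.
* **ROUGE-L**: LCS by dynamic programming. The default orientation takes
  recall = LCS/len(gen) and precision = LCS/len(ref) with β = P/R, which
  algebraically reduces the F-score to LCS/len(ref); `standard=True` gives
  the conventional β²-weighted definition with R/P in the usual roles. Both
  equal 1.0 exactly on identical sequences. Scores are averaged over pairs.
* **Wasserstein distance**: p = 1 through the integrated-CDF formulation;
  general p ≥ 1 by exact piecewise integration of the quantile difference.
  The *normalized* distance divides by the reference sample's range, with a
  zero-range (constant) reference defined to give 0 when the raw distance
  is ~0 and +inf otherwise.
* **Regression metrics**: standard R², RMSE, and MAPE in percent with
  zero-valued truths excluded (their count is reported).

## Numerical and design notes

* Quantization tie-breaking, the 6-significant-digit float format, and the
  fixed RNG draw order are all deterministic and documented above; no
  wall-clock or locale dependence anywhere.
* Degenerate inputs: empty plants cannot be tokenized; leafless geometries
  have no inclination distribution (error) and vegetation fraction 0;
  constant reference distributions short-circuit the normalized WD; MAPE
  excludes zero truths.
* Problem sizes in the test suite (1,000 plants for codec round-trips,
  4,000 for distribution recovery, 10⁵ quantization draws, 100 plants for
  rotation invariance) were chosen as the smallest populations at which the
  checked statistics are stable.

## Known limitations

* Growth-rule constants are calibrated stand-ins, not measurements; only
  their emergent organ-count scale was matched to a mature vegetative
  cowpea.
* The XML dialect is self-contained; interoperating with an external
  simulator's schema would need a mapping layer.
* Petiole curvature units are ambiguous in the source material (degrees vs
  1/m); the dialect stores the raw signed number and the geometry treats it
  as a total arc bend in degrees.
* Leaf laminae are square prototypes; absolute areas are exact by
  construction (area = scale²) but shapes are not species-accurate.
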