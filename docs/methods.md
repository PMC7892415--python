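# Methods

This note documents the models implemented in `evocamo`, their defaults,
and the design decisions taken where the problem was genuinely open.  It
states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Pattern genomes (`evocamo.genome`)

A target's pattern is a program: a finite expression tree evaluated over the
75 × 100 px pixel grid (origin top-left, x rightward, y downward, pixel
centers at half-integers).  Terminals produce base fields — constant
luminance, x/y coordinate gradients, texture lookups from a small greyscale
library, and seeded lattice value-noise.  Internal operators combine or warp
children: add, subtract, normalized multiply, min, max, full-wave rectify
about mid-grey, threshold, sine-warp (a parameterized grating whose phase
can be spatially modulated by the child), coordinate rotation and scaling,
and a three-argument blend.  This set spans the phenotype classes the study
system explores: uniform fields, gratings of any orientation/period/phase,
and texture-derived mottling.  The exact original operator set is not
published; this one is a documented, configurable stand-in.

Evaluation runs entirely in float64; non-finite values map to greys and the
result is clamped to [0, 255] and quantized to 8 bits only at the final
render, so intermediate arithmetic never accumulates quantization error.
Rendering is pure: genome + texture library determine the image bit-for-bit.

**Mutation** (defaults: rate 0.05 per node, max depth 8): each node
independently mutates with the configured probability, choosing uniformly
among (i) Gaussian parameter jitter with sd 10 % of the parameter range,
(ii) operator swap of equal arity with redrawn parameters, and (iii)
replacement by a random subtree of depth ≤ 3.  Trees exceeding the depth cap
afterwards are truncated back to terminals.  Rate 0 is the identity on the
rendered phenotype.  These mutation details are likewise unpublished in the
original system and are exposed as configuration.

## 2. The evolutionary game (`evocamo.engine`)

Protocol defaults follow the exhibit game: 128 bugs per generation, three
speed classes (600/450/300 px s⁻¹), 5 plays per bug, 5 s timeout, 4
replicates, 40-generation analysis window.  Fitness is the arithmetic mean
of a bug's capture times; trials that hit the timeout enter the mean at the
timeout value, because censored trials cannot be removed from an online
evolutionary score (this cap-at-timeout choice is configurable).  Selection
is truncation with overlapping replacement: the fitness-top half survives
unchanged (elitism — survivors' phenotypes reappear bit-identically) and
contributes one mutated copy each.  Ties in the fitness ranking break on
genome id (ascending), making every run reproducible from the master seed.

**Null model.** The control run keeps the identical machinery but replaces
the player with genome-blind lognormal capture times.  Supplied moments are
*bug-level* (mean and sd of 5-play average fitness); the per-trial variance
is the bug-level variance multiplied by the number of plays, and the
lognormal is moment-matched on the seconds scale (σ² = ln(1 + (sd/mean)²),
μ = ln mean − σ²/2).  Note the 5 s cap slightly shrinks realized moments
relative to the requested ones (the default mean 1.2 s / sd 0.4 s loses
≈ 6 % of the bug-level sd to the cap); the parameterization itself is exact
and is what the tests verify.  The empirical per-population moments of the
original game are unpublished, so the defaults (1.2 s, 0.4 s) are arbitrary
and user-suppliable.

**Trend testing.** Population-mean metric series from this engine are
strongly autocorrelated by construction: survivors persist, so under a
genome-blind player the series is close to a random walk.  An OLS t-test of
the slope on generation is therefore anticonservative (spurious-trend
problem).  The package reports the OLS slope but assesses significance with
a one-sample t-test on the first differences of the series
(`selection.generation_trend`), which directly tests for systematic
per-generation drift and keeps its nominal size for a driftless random
walk.

## 3. Synthetic players and backgrounds (`evocamo.player`)

The original data come from museum visitors; this package replaces them
with two documented capture-time models so the full pipeline runs with no
behavioural data.

*Backgrounds* are seeded mean-127 greyscale textures in three families
(smoothed noise, thresholded patches, oriented quasi-grass), emulating the
normalization of the original 40 photographic backgrounds.  Default texture
contrast (sd 30) keeps clipping negligible so the mean-127 normalization
holds to ±0.5.

*Conspicuousness* of a target against a background is scored as
`w₁·CV + w₂·|meanₜ − mean_b|/255 + w₃·(mean Gabor-bank energy / 127)` with
default weights (1, 1, 1): three dimensionless O(1) terms covering internal
contrast, mean-luminance mismatch, and patterning.  A uniform mid-grey
target on a mean-127 background scores exactly 0.

*Perceptual model*: median capture time `t0(speed) + k·max(0, s_max − s)`
with defaults t0 = 1.4/1.1/0.8 s (fast/medium/slow), k = 2 s, s_max = 1,
multiplicative lognormal noise (sd 0.35 on the log scale), capped at the
timeout.  The expected time is monotone non-increasing in conspicuousness —
the only structure the downstream analyses require — and fast targets take
longer at equal conspicuousness.  Defaults were chosen to land fitness
means and spreads in a plausible 1–4 s range with headroom below the 5 s
cap; they are a synthetic stand-in and are not fitted to human data.

What the generator deliberately does *not* emulate: participant identity,
learning and fatigue across the 20-trial session, pursuit dynamics of a
finger (capture time is modelled directly rather than via a simulated
touch), and background-specific crypsis (the conspicuousness score uses the
background's mean, not its local texture).  Passing tests therefore show
that the *pipeline* recovers selection that is present in the generating
model; they do not validate the perceptual model against human behaviour.

## 4. Pattern metrics (`evocamo.metrics`)

Luminance statistics use the population sd; CV contrast is sd/mean (an
all-black target is flagged degenerate with CV 0).  The Gabor bank covers
orientations {vertical, horizontal, two diagonals} × σ ∈ {2, 4, 8, 16} px,
where "vertical stripes" means intensity varies along x.  The kernel is
even (cosine-phase) with wavelength λ = 2σ, aspect ratio 1, support
truncated at 3σ, mean-subtracted to force exactly zero response on uniform
fields, and L1-normalized so responses live on the luminance scale.
Convolution uses reflect padding, chosen so the target's own border does
not leak spurious energy into the edge metrics.  "Energy" is the sd of the
convolved values over the target; edge energies restrict the sd to a
σ-wide strip flush with each edge, with the kernel oriented orthogonally to
that edge.  The five-metric preset (`PRESET5`) is {sd luminance, vertical,
horizontal, pooled-diagonal, right-edge} at σ = 4 px; which σ the original
five metrics used, and whether the diagonals were pooled, is unpublished,
so both choices are explicit here and configurable.

## 5. Selection analysis (`evocamo.selection`)

β is computed cross-sectionally per (replicate, speed, generation) stratum:
traits are z-scored within the stratum, fitness is divided by its stratum
mean (so mean w = 1), and β is the coefficient vector of the joint
least-squares regression of w on all traits — gradients, not univariate
differentials.  Zero-variance traits (inevitable once populations converge
to uniform grey) are dropped with a flag; rank-deficient designs drop the
last-listed collinear trait first; strata too small for the regression are
skipped, never imputed.  Replicate averaging and quadratic-in-generation
summaries reproduce the trajectory view of selection pressure.  Metric
pre-selection regresses log fitness (greedy forward AIC); β itself uses raw
relative fitness, as the Lande–Arnold framework defines it — the original
analysis does not state which scale it standardized on, so both dials are
exposed.  The original mixed-model/cumulative-link machinery is replaced by
this stratified computation with replicate averaging, a documented
simplification.

## 6. Motion model (`evocamo.motion`)

Movies composite the rendered target onto a background with bilinear
sub-pixel placement; the trajectory runs straight up for the first half of
the displacement steps and then turns 15° to the right, with the whole path
centred in the frame.  The veridical direction is the circular mean of the
two segment headings (90° and 75° → 82.5°).  Angles are degrees
counterclockwise from +x, wrapped to [0, 360); bias is the absolute wrapped
difference in [0, 180].

Each pixel hosts two opponent Reichardt pairs (along x and along y):
R(x) = D(x)·I(x+Δ) − I(x)·D(x+Δ), with neighbour spacing Δ = 2 px and D a
first-order recursive low-pass with τ = 33 ms at 60 frames s⁻¹.  Frames are
contrast-normalized and mean-subtracted; the low-pass state is initialized
to the first frame, so a static movie yields an exactly zero field (the
opponent symmetry is exact, not approximate).  The x/y opponent outputs
form the per-pixel motion vector (θ, r).  Per-movie statistics pool all
frame pairs and pixels, discard zero vectors (r < 10⁻⁹, floating-point
guard), and report coherence (mean resultant length), energy (mean r), and
bias.  The generation-0 experiment fits `fitness ~ coherence × bias` and
`fitness ~ energy` by OLS, optionally filtering bugs whose circular-mean
difference exceeds 6°.

The original model's exact parameters (spacing, delay constant, frame rate,
movie geometry) are unpublished; the defaults above are conventional for
correlation-type EMD simulations and are all surfaced in configuration.  At
the "fast" speed (10 px/frame at 60 fps) the detector operates far above
its velocity optimum (Δ/τ ≈ 60 px s⁻¹), so direction estimates for
broadband patterns are noisy — which is why the acceptance checks rely on
parameter-robust properties (direction recovery for matched gratings,
energy monotonicity, the energy–fitness sign) rather than parameter-matched
values.

## 7. Problem sizes and reproducibility

Default problem sizes are chosen to make every analysis rerunnable on a
laptop core: evolutionary checks use single populations of 128 bugs over
20–40 generations; motion experiments use 128 generation-0 bugs with
16-frame movies on 320 × 160 backgrounds; Monte-Carlo checks use 10⁴ draws
or 100 replicate fits.  One master seed deterministically spawns per-module
substreams (CRC-stable, order-independent), so a configuration snapshot
plus seed reproduces any pipeline output bit-for-bit.

## Known limitations

- The perceptual player is a construction, not a fit: effect sizes (fitness
  gains, gradient magnitudes) are properties of its parameters and should
  not be compared numerically to behavioural data.
- Genome-blind control runs show a small negative drift tendency in
  contrast metrics (mutation toward random subtrees mildly regresses
  extreme phenotypes); the drift test is sized for this regime, but
  long-horizon null runs are not variance-stationary.
- Capture-time capping truncates the lognormal tail, so realized moments
  sit slightly below requested moments at high sd/mean ratios.
- The EMD array is single-scale; no photoreceptor front-end, spatial
  pyramid, or contrast adaptation is modelled.
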