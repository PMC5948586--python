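# Methods

## Problem and scope

`nightgrape` detects green grape clusters in night-time RGB images taken
under stable artificial (LED) illumination and computes a picking point on
the stem above the cluster. Under warm-white LED light the red channel of
green grapes occupies a high, narrow band (roughly 160–215 of 255) while
foliage and ground remain mostly below 150; the whole pipeline exploits
this single separability. Daytime images, stereo depth, occluded stems and
robot control are out of scope.

The pipeline stages, in execution order:

1. **Standardization** — resample to 300×450 px (bilinear, Gaussian
   anti-alias prefilter on downsampling) and extract the R plane.
2. **Presence gate** — count pixels with R strictly greater than 140 (`a`)
   against all pixels (`b`); proceed only if `a/b > 7.75 %`. A failed gate
   is the "cessation" outcome: no cluster is centered under the light.
3. **Value rotation** — `r₁ = r + 35` if `r + 35 ≤ 255`, else
   `r₁ = r + 35 − 255`. This moves the fruit band to the top of the scale
   and wraps over-bright highlights to the bottom. Note the printed map is
   *not* mod-256: 220 → 255 but 221 → 1, and both 0 and 255 land on 35, so
   the map is injective only on 0…254. We implement the two branches
   literally.
4. **Segmentation** — improved two-region Chan–Vese level set, run
   coarse-to-fine (50×75 then 300×450).
5. **Cleanup** — keep the largest 8-connected region, fill holes
   (4-connected background flood), then open/close with disk radius 3.
   A final largest-region pass restores the ≤1-component guarantee that
   opening can break. Radius 3 removes speckle and thin appendages (the
   stem) without eroding berries at this working resolution.
6. **Picking point** — axis-aligned bounding box of the fruit and its
   centroid; the region of interest is the box's x-range above its top
   edge; the rotated R channel inside the ROI is binarized at 175 (the
   gate's ">140" criterion carried through the +35 rotation), skeletonized,
   and fed to a probabilistic Hough transform (threshold 10 votes, minimum
   length 15 px, maximum gap 3 px at 300×450). Segments more than 15° off
   vertical are discarded; the most vertical survivor (ties: longer, then
   topmost midpoint) is the stem, and its midpoint, rounded to the nearest
   pixel, is the picking point. The Hough sampler is randomized; we fix its
   internal seed so identical inputs give byte-identical results.

## The level-set model

The energy is the two-region piecewise-constant functional

    E = μ·L(C) + ν·S_o + λ_o Σ_in (I − c_o)² + λ_b Σ_out (I − c_b)²,

with c_o, c_b the means of the φ>0 / φ≤0 regions (recomputed every
iteration), L(C) a discrete contour length (4-neighbor sign changes × h)
and S_o the φ>0 area. Instead of a signed distance function, φ is
initialized as a two-valued step: ρ_u on rows y ≥ y₀, ρ_d above
(ρ_u·ρ_d < 0, default ±1, y₀ = H/2), and is never re-initialized. The
explicit update is

    φⁿ⁺¹ = φⁿ + Δt · δ_ε(φⁿ) · V,

where δ_ε(z) = ε/(π(z²+ε²)) and V is the gradient-flow velocity
μκ(φ) − ν − λ_o(I−c_o)² + λ_b(I−c_b)², with κ the curvature of the level
lines. The rows adjacent to the initialization boundary receive an extra
constant kick ∓(u/h)·sign(ρ_u−ρ_d) (rows j₀ and j₀−1) that starts the flat
interface moving; u = 0 makes all rows identical.

### Numerical choices

* **Unit intensity scale.** The velocity is evaluated with I/255 and the
  weights divided by 255², so V is O(1) and the explicit step is stable at
  Δt = 5 without CFL trouble from the fidelity terms.
* **Bounded φ.** Without re-initialization φ grows wherever the force is
  consistent, δ_ε collapses, and corrections needed after the region means
  move become impossibly slow. Each step therefore clips |φ| at the
  initialization magnitude max(|ρ_u|,|ρ_d|) (never pulling in values
  already beyond it, so a vanishing update is an exact no-op). This keeps
  every pixel responsive; the field stays a step function, which is all
  the sign partition needs.
* **Two-phase continuation.** From the step initialization the two region
  means start nearly equal, so the constant area force −ν would drain the
  still-undifferentiated interface uniformly into the empty region. Phase
  one therefore runs with ν = 0 until the partition settles; the field is
  then oriented (see below) and phase two switches ν on. The area penalty
  is what detaches foliage: leaf pixels sit between the two modes and fit
  the background mean only a little worse than the fruit mean, so a small
  constant penalty tips them out while berries, far from the background
  mean, stay. Default ν = 0.08·255² ejects structures whose fidelity
  advantage is below 0.08 on the unit scale (foliage at rotated values
  ≲ 185) and keeps the fruit band (≥ 195 rotated).
* **Orientation.** The model is symmetric in its two regions, so which one
  converges to φ>0 depends on the initial means. The mask convention is
  fruit = {φ > 0}; with `orient_bright` (default) the sign of φ is flipped
  when the φ>0 region comes out darker, both before the area phase (the
  penalty must shrink the fruit side, not the background) and at the end.
  Disabling it restores the exact two-region sign symmetry.
* **Stopping.** Iteration stops when the fraction of pixels whose sign of
  φ changed in a step stays below 10⁻⁴ for 60 consecutive steps, after a
  50-step burn-in: from the flat initialization the first sign flips take
  ~15 steps, and the slow drainage phase shows flip-free plateaus up to
  ~50 steps long. Caps: 800 iterations per phase at the coarse stage, 80
  at the refinement stage.
* **Degenerate inputs.** A zero-contrast channel yields an all-false mask
  flagged degenerate; an empty region's mean is defined as 0 and flagged.
  Non-finite φ raises a divergence error carrying the iteration index.
* **Curvature** uses central differences (one-sided at edges) with the
  denominator regularized by 10⁻⁸; μ defaults to 0.01·255², enough to
  smooth single-pixel chatter without letting curvature noise dominate
  the O(1) fidelity forces.
* **u (boundary kick)** defaults to 0.05. On the unit velocity scale a
  kick of 1 would permanently override the image force on the two
  boundary rows and leave a one-pixel stripe artifact in every converged
  mask; 0.05 keeps all three row-cases of the update distinct (they are
  tested) while remaining a perturbation.

### Coarse-to-fine

The rotated channel is downsampled 6× (bilinear) to 50×75, segmented to
convergence, the coarse mask is block-upsampled (nearest-neighbor) back to
300×450, φ is rebuilt from it as a ±|ρ| step (no boundary-row kick — there
is no single boundary row anymore), and a short full-resolution refinement
finishes the contour. On noise-free scenes the refined mask agrees with a
direct full-resolution solve to well under 2 % of pixels while using a
fraction of the full-resolution iterations; that saving is the entire
point of the pyramid.

## Synthetic scenes

No field images are available, so a seeded generator renders scenes that
reproduce the statistics the pipeline relies on: berry R drawn uniformly
in [160, 215]; smooth mottled background at mean 60 (σ 15); leaf-like
ellipses at mean 110 (σ 15), shaded ~35 % darker toward the rim (a flat
blob would cross a brightness threshold as one block, which real leaves do
not); G and B rendered 30–60 / 60–100 below R. The cluster is a packed
cone (shoulder width 2.7·spread, height 2.9·spread, tapering to 0.35),
filled row-by-row with overlapping elongated-oval berries so the union is
a single connected region, as in a real cluster where berries press
against each other; `berry_count` (default 40, which fills the default
cone) trims or pads the packing. A bright bar (R ≈ 175, width 2–4 px,
length 30–60 px) rises from the top of the cluster's bounding box at a
configurable angle off vertical — its true segment is the picking ground
truth. Four conditions mirror the field situations: cluster near the
light center, near the center but at the frame edge (both "present"),
dim cluster far off-center (illumination 0.55–0.7), and no cluster.
Depth is emulated by an illumination falloff
`1 − s·(0.5 + 0.5·(d/d_max)²)` (global plus radial); there is no
quantitative distance-vs-brightness law to calibrate against, so the
model is a stand-in for the qualitative darkening with distance.

What the generator does **not** model: specular highlight spots, motion
blur, berry-level shading, occlusions and real foliage texture. Passing
tests on these scenes therefore validate the pipeline's geometry,
arithmetic and convergence behavior — not its accuracy on field images.

## Evaluation metrics

Per image: PCA = 100·tp/(tp+fn) (fruit pixels recovered over all true
fruit pixels) and PFA = 100·fp/(tp+fp) (false fruit pixels over all
predicted fruit pixels; defined as 0, flagged, when nothing is predicted).
Batches are binned: PCA >90 / 70–90 / <70 and PFA <5 / 5–15 / >15 percent,
with inclusive boundaries at 90 (top bin) and 5 (best bin). Pixel-level
confusion tables are also reported row-normalized (each true class by its
own total) — note the background row's false rate fp/(fp+tn) is a
different quantity from PFA. A picking point succeeds when its horizontal
distance to the true stem, evaluated at the point's row (clamped to the
segment span), is at most 5 px, boundary inclusive; error bins are exact /
1–5 / >5 px, and a run that produced no point counts in the last bin.

## Problem sizes used in tests and in `scripts/acceptance.py`

Gate separability: 400 scenes (100 per condition). Segmentation recovery:
8 noise-free scenes (mean IoU), 3 pyramid-vs-direct pairs. Picking
recovery: 200 noise-free scenes with stem angles uniform in (−12°, +12°).
Depth degradation: 6 falloff levels × 12 paired scenes (same seeds per
level, so accuracy can only move through the illumination change). Energy
descent: 20 noisy two-region fixtures at 60×60.

## Known limitations

* Two-region model: multiple clusters are segmented together and only the
  largest is kept; touching clusters are not split.
* Foliage brighter than ~145 (original scale) is intrinsically inside the
  fruit band's basin and will be segmented as fruit; any intensity-only
  two-region model shares this failure mode with highlights and dimming.
* The stem detector assumes a near-vertical bright stem above the fruit;
  a stem hidden behind leaves (the excluded field situation) yields
  `no_line`, not a guess.
* Wall-clock performance is not a target; the implementation is plain
  vectorized NumPy.
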