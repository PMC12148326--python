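# Methods

`migflow` measures how *disciplined* a migrating cell cohort is from
time-lapse microscopy: whether essentially all apparent motion along the
anterior–posterior axis points one way (posterior, +x), or splits in both
directions. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot establish.

## Pipeline model

1. **Grayscale + stabilization.** Multi-channel stacks are reduced with
   BT.709 luminance weights (0.2125, 0.7154, 0.0721). Stabilization is
   translation-only, per frame against a reference frame (default frame 0).
   Because the dominant content of these movies is the *moving* cohort, a
   naive whole-frame correlation locks onto the cells and subtracts the very
   signal being measured. The stabilizer therefore masks bright moving
   objects (pixels above median + 3 scaled MADs of the frame) and anchors on
   the static tissue: the integer offset comes from masked normalized
   cross-correlation, the subpixel remainder from a global gradient
   least-squares fit over the static pixels (two Gauss–Newton steps). When
   no bright foreground exists the mask covers the whole frame and the
   procedure reduces to ordinary translation registration; a plain
   upsampled phase-correlation path (`suppress_foreground=False`) is also
   available. Registered frames are resampled bilinearly with constant-0
   fill; offsets are reported as content displacement (dx, dy) relative to
   the reference. Landmark-based affine warping (per-frame linear
   least-squares fit, bilinear resampling) is available when paired landmark
   lists are supplied; it is never invoked automatically.

2. **Sparse flow.** For each consecutive frame pair, the optical-flow
   constraint Ix·vx + Iy·vy + It = 0 is solved by windowed least squares at
   every pixel (gradient sums via uniform filters), iterated coarse-to-fine
   over a Gaussian pyramid with warping. Two numerical details matter:
   the warp uses cubic interpolation, and the flow field is smoothed with a
   small Gaussian (σ = 1.5 px) after each Gauss–Newton step — without
   these, per-pixel increments chase interpolation bias and window-scale
   oscillations and the iteration diverges for shifts of a few pixels.
   Because coarse pyramid levels can leak the cohort's motion into static
   regions that the short-correlation background texture cannot pull back,
   a zero-initialized single-scale estimate is computed in parallel and,
   per pixel, whichever hypothesis warps frame B onto frame A with the
   smaller windowed residual is kept. The result is sampled at grid-cell
   centres (default spacing 4 px, window 9 px — windows small enough to
   resolve individual cells, see below).

   *Validity.* A cell is texture-valid when the smallest eigenvalue of its
   gradient normal matrix exceeds 1e-2·window² (rejecting rank-deficient,
   textureless windows). The pipeline additionally applies a
   motion-significance gate: the fitted flow must reduce the windowed warp
   residual relative to the zero-flow hypothesis by at least a factor
   `min_significance` (default 1, i.e. halve it). This ratio is
   self-calibrating — it needs no noise model and is ≈ 0 for static
   windows regardless of texture strength — and implements the principle
   that only windows whose temporal change is *explained by motion* carry
   direction information.

3. **Dense smoothing.** Valid sparse vectors are projected, with a ridge
   penalty (default 1e-3), onto an orthonormal basis of 2D vector fields.
   With a training corpus, `fit_basis` learns the basis by PCA of
   vectorized flow fields (mean removed, top-K right singular vectors).
   Without one — the default — the basis is analytic: per-component 2D
   polynomials of degree ≤ 2, QR-orthonormalized over the grid (K = 12).
   If fewer valid cells than K exist (a static, noise-free stack), the
   reconstruction falls back to the basis mean field rather than failing.

4. **Direction statistics.** Per frame pair, each voting grid cell is
   binarized on sign(vx); vx = 0 is excluded. Votes pass a magnitude
   filter (‖v‖ strictly above the per-field 0.2-quantile of valid norms).
   Counts pool across frame pairs into p̂ = #left/(#left+#right) and the
   binary entropy H(p̂) in bits (base-2 logarithm, so max H = 1 at
   p̂ = 0.5). κ = Q0.9{‖v‖} (linear-interpolation quantile convention) is
   reported per frame; the pooled 1D variance share Varx/(Varx+Vary)
   (sample variances, ddof = 1) is computed on κ-normalized,
   magnitude-filtered vectors so frames of different overall flow scale
   pool comparably. The share is NaN ("undefined") when the total variance
   is zero.

   Two estimator refinements, both default-on in the pipeline and exposed
   as flags, address known sampling biases of grid votes:

   - *Mass weighting* (`mass_weighting`): each cell's vote is weighted by
     the foreground fluorescence (above-median intensity summed over the
     window). Plain per-window counts weight by *area*, so a tight cluster
     of co-moving cells is undercounted relative to dispersed cells;
     weighting by fluorescence mass makes p̂ an approximately per-cell
     quantity.
   - *Persistence gating* (`persistence_gate`): a vote counts only if the
     same grid cell shows the same sign in the previous or next frame
     pair. Migrating cells move persistently over the 5-min frame
     interval; single-pair sign flips are overwhelmingly transient
     artifacts of crossing or merging cells.

   By default the statistics are computed on the *sparse validated*
   vectors rather than the dense smoothed field: the low-order analytic
   basis spatially averages opposing local motions, so a dense-field
   binarization cannot resolve intermediate mixtures (it collapses a 90/10
   split toward 100/0). `stats_source="dense"` switches this for users
   supplying a rich learned basis.

5. **Track metrics.** From per-cell trajectories: leading-edge distances
   posterior = max(0, max_i xᵢ − origin) and anterior = max(0, origin −
   min_i xᵢ) (an intensity-threshold variant on max-projections serves
   stacks without tracks); velocity v = d/t in µm/min; straightness d/D
   (net displacement over path length; NaN for a static track); rose
   histograms of step or net-displacement angles, bins centred so that 0°
   (posterior) is a bin centre, angles computed as atan2(−Δy, Δx) because
   image y points down. Default 16 bins, per-track mode.

## Synthetic data

The simulator emulates a pupal tracheal-progenitor movie: `n_cells`
(default 100) bright spots start clustered around the junction
(`origin_x`; x-spread SD 25 µm — the progenitor group spans on the order
of 100 µm — and the middle of the field in y) and move with persistent
per-cell direction: sign +1 (posterior) with probability `q`, drawn once
at t = 0. Per 5-min step, Δx = s·max(0, N(speed_mean, speed_sd²))·Δt +
drift_x and Δy = N(0, transverse_sd²) + drift_y; speeds are truncated at
zero so noise never reverses a cell — reversals exist only through q.
Defaults: speed 0.7 ± 0.2 µm/min (order-of-magnitude choice: the cohort
crosses ~85 µm in 2 h), transverse jitter 1 µm/step, 25 frames at 5 min,
384 × 128 px at 1 µm/px. The field boundary is absorbing (cells stop at a
2-px margin) so simulator output is always renderable.

Rendering sums an isotropic Gaussian blob per cell (σ = 2 px ≈ an 8-µm
cell; per-cell brightness lognormal with CV 0.3, as real fluorescence
varies and identical blobs would make nearest-neighbour correspondence
ambiguous), a *static background texture* (smooth random field, SD 100,
correlation 2 px, shifted together with the cells by the stage drift),
a constant offset, and i.i.d. Gaussian sensor noise (SD 10), clipped to
16 bits. The static texture stands in for autofluorescent tissue: without
any static anchor, stabilization of a scene whose only content moves
coherently is ill-posed. Setting `texture_amplitude=0` recovers a
blobs-plus-noise-only model. Ground-truth per-cell signs are exported
(`signs.csv`) so recovery tests compare against the realized truth rather
than re-inferring it.

What the simulator does *not* model: mitosis/apoptosis, cell–cell
collisions or volume exclusion, chemoattractant fields, 3D geometry,
photobleaching, and non-translational stage motion. Passing recovery
tests therefore show that the statistics recover a known direction
mixture under realistic noise, drift and clustering — not that they are
robust to deformation, division or signalling-driven coordination.

## Parameter recovery and its limits

Across 20 replicate movies per q ∈ {0.5, 0.7, 0.9, 1.0} run through the
full pipeline, the folded estimate min(p̂, 1−p̂) tracks the realized folded
sign fraction with |bias| ≲ 0.03 and the mean entropy is strictly
decreasing in |q − 0.5| (≈ 0.98 at q = 0.5 versus ≈ 0.00 at q = 1 at the
study conditions above). The residual bias is a mild majority
amplification: windows containing cells of both directions resolve toward
the local majority or are vetoed as ambiguous, so the minority is slightly
undercounted. The acceptance test accordingly checks the mean recovery
error against three Monte-Carlo standard deviations of the per-replicate
error; a mean-standard-error band is not attainable by *any* image-based
estimator here, because the folding bias at q = 0.5 and the ≥0 support of
p̂ at q = 1 exceed an SE that shrinks with replicate count.

## Other numerical choices

- Quantiles use numpy's linear-interpolation convention (Q0.9 of
  {1,…,10} = 9.1); stated because conventions differ at small n.
- Entropy uses log base 2, fixed by the requirement H(0.5) = 1;
  0·log 0 := 0.
- Coordinates are 0-based pixels, x = column (posterior = +x), y = row
  (down). Flow vectors are px/frame; track coordinates µm.
- Grid cells whose window could touch registration border fill are
  invalidated (margin = ⌈max offset⌉ + window/2 + 1).
- The run manifest stores a SHA-256 of the analysis configuration
  (excluding the output directory) plus the package version and seed;
  identical inputs and config reproduce byte-identical summary JSON.

## Known limitations

- p̂ is an image-based quantity: with heavy cell overlap it is
  fluorescence-mass-weighted, not exactly cell-count-weighted.
- The analytic polynomial basis is deliberately low-order; dense fields
  are for visualization and variance smoothing, not for resolving
  fine-grained direction mixtures.
- Stabilization handles translation only; rotational or deformable drift
  requires supplying landmark pairs for the affine stage.
- The entropy statistic says nothing about speed: a slow and a fast
  disciplined cohort both score H ≈ 0. Combine with the velocity and
  leading-edge outputs for a complete picture.
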