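# Methods

## Model

The network is a predictive-coding hierarchy of `n_layers` identical
modules. Layer `l` holds:

* **Representation** `R_l` — a convolutional LSTM (3×3 kernels, standard
  gates without peepholes, forget-gate bias initialised to 1) whose input
  at each time step is the concatenation of the layer's own error from
  the previous step, its previous hidden state, and the nearest-neighbour
  2× upsampling of the representation above. Updates sweep top-down.
* **Prediction** `Â_l` — a 3×3 convolution of `R_l`. At layer 0 it
  passes through a saturating rectifier, `clip(x, 0, pixel_max)`, so the
  frame forecast stays inside the pixel range; upper layers use ReLU.
* **Target** `A_l` — the incoming frame at layer 0; at layer `l+1`, a
  max-pooled (2×2) ReLU convolution of the error below.
* **Error** `E_l = concat(relu(A_l − Â_l), relu(Â_l − A_l))` — the only
  bottom-up signal, nonnegative by construction, with `2·stack_sizes[l]`
  channels.

The default configuration is four layers with channel stacks 3/48/96/192
on 120×160 RGB input; the spatial extent of layer `l` is the input extent
divided by `2^l`, which requires the input to be divisible by
`2^(n_layers−1)`.

**Training.** Frames are consumed sequentially in batches of 20. The
forecast emitted at the final step of a batch (made before that frame is
shown) is scored by mean-squared error against the frame, and one Adam
step (lr 1e-3, β₁ 0.9, β₂ 0.999) is taken. The loss is the layer-0
reconstruction error only, not a weighted sum of all layer errors;
gradients are truncated at batch boundaries while the hidden state
carries across consecutive batches and resets at each pass through the
stream (a video boundary). Weight initialisation is He-scaled Gaussian,
deterministic in the seed; everything downstream of a fixed seed is
bit-reproducible.

**Closed-loop probing.** A probe is exactly one batch (20 frames). After
stepping through frames T1..T20, the next forecast is P1; the step that
produces P1 receives P1 itself as its layer-0 target (the closed loop),
so the following forecast P2 is conditioned on T1..T20 plus P1, and
likewise P3. Rollouts start from zeroed `R`/`C`/`E` state and run in
inference mode (no graph construction).

The network, including its reverse-mode autodiff core, is implemented in
numpy inside the package; convolutions use an im2col formulation.

## Stimuli and the synthetic corpus

* **Propellers**: three tapered blades on a light background, rendered
  with 4× supersampled anti-aliasing; blade angle at frame `t` is
  `t·ω` with `ω = rpm·2π/(60·fps)` signed clockwise-positive in y-down
  screen coordinates (15 rpm at 30 fps → 0.0524 rad/frame). A
  `blade_asymmetry` parameter skews the blade outline along the rotation
  direction (default 0: symmetric). `mirror` flips frames horizontally,
  which exactly negates the apparent rotation.
* **Snake rings**: an annulus divided into `4·elements_per_ring` sectors
  cycling through blue → black → yellow → white along increasing polar
  angle (handedness reverses the cycle); two concentric bands are
  staggered by half a repeating unit. The negative control keeps the
  identical geometry and colours but reverses the cycle in every other
  repeating unit, so the local circular colour order cancels and no
  consistent direction survives — per-colour pixel counts agree with the
  illusion layout to within rasterisation error. The four-ring layout
  tiles a 2×2 grid with alternating handedness, each ring confined to a
  40×30 px quadrant of the 160×120 frame. The chosen control
  construction is a stand-in for the published control artwork, which is
  specified only graphically.
* **Ego-motion corpus**: clips of fixed length viewing a multi-octave
  smooth random RGB texture through a moving window — translations
  (0.5–3 px/frame with slight camera roll), in-plane rotations
  (0.02–0.12 rad/frame, both signs), and rotating textured discs over a
  static background. This emulates the statistics that matter for the
  probes (smooth textures under rigid image motion, including rotary
  motion) and deliberately omits much of real first-person video:
  objects, depth parallax, occlusion, lighting changes, saccade-like
  cuts. Passing the direction-recovery test therefore shows that the
  architecture extracts and extrapolates rigid motion from unsupervised
  exposure — not that it reproduces results obtained on natural video.

## Motion readout

Features are local maxima of the Shi-Tomasi minimum-eigenvalue corner
response, thresholded at `quality_level` (default 0.3) of the global
maximum, spaced at least `min_distance` apart (default 10 px), at most
`max_features` (default 100). A border band (default `min_distance`
pixels) is excluded: predicted frames carry convolution-padding artifacts
at the frame edge, and tracking windows there lack support — without
this exclusion a single border vector can dominate a probe's mean.

Displacements are estimated per point by iterative Lucas-Kanade: the 2×2
windowed gradient normal equations (window 50 → normalised to 51 px,
Sobel gradients) solved against the warped second frame, 30 iterations
or a 0.01 px step, over a 3-level Gaussian pyramid. Points with a
near-singular gradient matrix or that leave the frame are flagged
untrackable. Known rigid shifts ≤ 5 px are recovered to well under
0.5 px on smooth textures. Under rigid *rotation* the windowed estimate
averages a spatially varying field, which biases the implied angular
velocity upward near the centre; this motivates both the minimum-radius
exclusion below and the use of smaller windows when frames are small
(the CPU preset uses window 21 on 48×48 frames, and a relaxed corner
threshold of 0.15 because closed-loop predictions are blurrier than
input frames at that scale).

Angular velocity per vector is `ω = (r_x v_y − r_y v_x)/|r|²` about the
rotation centre (clockwise positive, y-down); vectors with `|r| < 5 px`
are excluded as numerically unstable. The centre is estimated from the
probe video itself — Otsu-thresholded summed absolute frame differences,
intensity-weighted centroid — for moving stimuli (accurate to < 2 px on
rendered propellers); static ring stimuli use the geometric ring centre,
and a static propeller (no motion to threshold) falls back to its known
geometric centre. A `coord_scale` maps analysis coordinates back to the
original stimulus frame; ω itself is scale-invariant.

Per-pair means are aggregated over the checkpoints inside an analysis
window (mean ± SE of per-checkpoint means; the full-scale protocol
averages the 400K–1000K window, n = 7). Group comparisons are one-tailed
unpaired t-tests; `test="auto"` uses the pooled-variance (Student) form
for equal group sizes with variance ratio ≤ 4 and Welch's otherwise, and
`absolute=True` compares magnitudes. The one-sided alternative follows
the expected sign of the stimulus (or larger-magnitude for absolute
comparisons). No multiple-testing correction is applied.

## Scaled-down direction-recovery experiment

The full-scale protocol (four layers, ~530K natural frames, checkpoints
to 1000K) needs GPU-scale resources, so the packaged experiment
(`predflow.experiments`) is a reduced instance of the same design chosen
to run in minutes on one CPU: two layers with stacks 3/16 on 48×48
frames, a 4000-frame synthetic corpus cycled to 20K training frames
(1000 updates), checkpoints every 2000 frames, and the last five
checkpoints (12K–20K) as the analysis window. Probes are 15-rpm cw/ccw
and 0-rpm propellers rendered at 48×48. The readout is qualitative by
design: the sign of the mean P1/P2 angular velocity must match each
probe's direction, and the static probe's magnitude must fall below
both. Whether the static snake-illusion images also elicit directional
flow at this scale is recorded as an observational output of the full
pipeline, not asserted.

## Numerical and design notes

* Pixel values are [0, 1] floats (8-bit inputs divided by 255);
  `pixel_max = 1` caps the layer-0 forecast.
* Checkpoints are single-file archives embedding weights, config,
  frames-seen and seed; reloading reproduces rollouts bit-identically.
* Activation dumps write each representation channel min-max normalised
  to 8-bit grayscale PNG under `layer_<l>/channel_<c>.png`; a uniform
  channel maps to zero.
* Frame I/O is serial JPEG/PNG stills in lexicographic order (the
  canonical on-disk form); no video-container codec is required.
* Degenerate inputs raise typed errors rather than returning silently:
  static videos in centre estimation (`NoMotionError`), fully excluded
  or untracked vector sets (`NoUsableVectorsError`), zero-variance
  identical groups in the t-test.

## Known limitations

* The surrogate corpus contains no natural-scene statistics; absolute
  flow magnitudes and significance levels at toy scale are not
  comparable to full-scale results, only signs and orderings.
* Windowed Lucas-Kanade underestimates nothing but *averages* rotating
  fields; implied ω carries a window-size-dependent bias (measured ~3%
  at window 21, ~10% at window 51 for ω = 0.05) that the minimum-radius
  exclusion only partly removes.
* The conv-LSTM gate formulation, upsampling kernel and loss placement
  follow the common conventions noted above; where the protocol's
  description is silent these are fixed choices, not fitted ones.
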