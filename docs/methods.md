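# Methods

## The measurement and its model

Constriction-based deformability cytometry drives cells through channels
narrower than the cell diameter and reads mechanics from the entry and
transit kinetics. `cdcyto` analyzes such videos in five stages: detection
(background subtraction), tracking (Kalman prediction + Hungarian assignment
on IoU), event logging against per-constriction focal regions, morphometric
segmentation, and rheological inversion.

The mechanical core treats the cell as a homogeneous power-law viscoelastic
body. With projected area A (µm²) and a constriction of width W, define

- deformation rate `ε_e = 1 − c2/√A` with `c2 = R_e·√π`;
- creep time `t_creep = c1 · ε_e^(1/β)` with `c1 = (E/ΔP̄)^(1/β)·t0`.

Assumptions: the cell is incompressible over the short entry (so the 2-D
projected area is conserved); the mean pressure drop ΔP̄ across a
constriction is constant within a run; the power-law exponent β is shared
within a cell population while c1 varies per cell. Under these assumptions
c1 is a size-independent stiffness index and `E = ΔP̄ · c1^β`.

### The c2 convention

`c2` defaults to 17.7245 µm, i.e. the *full* 10 µm constriction width times
√π. The half-width convention (5·√π ≈ 8.86 µm) is also supported via
`StiffnessModelParams(c2=...)`; the default follows the convention that is
consistent with the 547.1357–1034.096 µm² optimal size range used throughout
(with c2 = 17.7245 µm, ε_e > 0 requires A > 314.16 µm², which that range
satisfies). Callers working with smaller cells should switch conventions or
their records will be excluded as non-deforming.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| constriction W×H×L | 10 × 30 × 60 | µm | chip design |
| lead channel width | 25 | µm | separates cells upstream |
| layout | 4 groups × 9 | — | parallel throughput; 1 group ≈ one 10× field of view |
| pixel size | 0.65 (chip), 1.0 (benchmarks) | µm/px | benchmark value keeps frames small with cells ≥ 13 px radius |
| fps | 988 | 1/s | acquisition rate of the reference camera |
| creep window half-length | 12.95 | µm | mean measured cell radius-scale (mean of 12.75 and 13.15 µm line diameters); window = entrance ± half-length |
| c2 | 17.7245 | µm | see above |
| ΔP̄ | 162.82 | Pa | fluidic simulation of the chip at 50 µL/min |
| β grid | 0.1 … 0.5 | — | physiological range for cells |
| t0 | 1 | s | power-law timescale, fixed |
| entrance/exit region offsets | 18 / 10 | µm | entrance box sits upstream of the creep window so pre-entry area frames show the undeformed cell |
| region half-extents | 4 (flow) × 12.5 (transverse) | µm | one box per lane, no overlap between lanes |
| tracker iou_min / max_age / n_init | 0.3 / 5 / 2 | — | inter-frame motion at 988 fps is ≪ one cell diameter, so IoU gating is loose |
| detector min area | 50 | px | smallest default cell is ≈ 547 px at 1 µm/px; shards are far below |
| dilation radius | 2 | px | boundary closing without merging lanes |

## The synthetic-data generator

The simulator is the package's study-condition definition and test oracle.

**Populations.** Two log-normal c1 populations ("stiff" median 0.48 s,
"soft" median 0.12 s, geometric SD 1.25, β = 0.5), mirroring the ~4× c1
ratio between a low- and high-metastatic-potential pair of breast-cancer
lines. Absolute c1 medians are scaled so creep events span tens of frames at
988 fps (tens of ms); group-level stiffness ratios and orderings, not
absolute seconds, are the quantities the benchmarks assert. Areas are
uniform on 547.1357–1034.096 µm² — the optimal size range for this chip —
which guarantees ε_e > 0 under the default c2.

**Kinematics.** Piecewise per cell: constant approach speed (600 µm/s) to
the creep-window start; inside the window the position fraction follows
`s(t) = (t/t_creep)^β`, a decelerating power-law displacement that traverses
the window in exactly the forward-model t_creep; constant transit speed
(1000 µm/s) from window end past the exit region. Speeds are an order of
magnitude below the real chip's flow so that events are resolvable over many
frames; they are config-exposed (`KinematicsParams`).

**Shapes and rendering.** Outside the constriction a cell is a disk of its
nominal area; inside, an ellipse with the transverse axis clamped to the
constriction width and the longitudinal axis preserving projected area
(H = 4A/(πW)). The renderer morphs linearly between the two across the creep
window and back over one cell diameter past the exit — a cell deforms
gradually, and the smooth morph also means the bounding box never jumps
between frames. Frames are 8-bit: uniform background (180), darker cells
(contrast −60), Gaussian PSF blur (σ = 1 px), additive Gaussian sensor noise
(σ = 2). One cell per lane at a time, enforced by a headway; frame 0 is kept
cell-free as a clean background reference, and the video ends with one
event's worth of background so temporal-median backgrounds stay
uncontaminated (every pixel is background in > 50% of frames).

**What it does not emulate.** No channel walls or optics beyond Gaussian
blur; no cell–cell interactions, rotation, or sub-cellular texture; no flow
coupling between lanes; no fouling debris other than the stalled-cell
occluder used by QC scenarios; shape relaxation on exit is geometric, not
viscoelastic. Passing benchmarks therefore demonstrate the correctness of
the *pipeline computations* (detection geometry, identity maintenance,
event timing, model inversion) under controlled imaging conditions — not
robustness to real-microscope artifacts such as illumination drift, focus
variation, or debris.

## Numerical and design choices

- **Coordinates**: pixels, origin top-left, x along flow, 0-based indexing;
  px↔µm conversions stay floating-point, with rounding (half away from zero)
  only at a final integer conversion.
- **Background model**: per-pixel median of ≤ 200 uniformly sampled frames
  (config: first-frame or mean). The detection threshold is a *global* Otsu
  on the pooled absolute-difference histogram of a frame sample — a
  per-frame Otsu would split the noise histogram on empty frames. The signed
  difference is smoothed (σ = 1 px) before thresholding so noise at the
  blurred cell boundary cannot shatter the contour; smoothing is symmetric,
  so the half-contrast boundary and hence the measured area stay unbiased.
- **Detector as labeler**: the same classical detections are exported as
  normalized center-box text annotations (one file per frame) to bootstrap a
  neural detector's training set; any plug-in returning the same `Detection`
  contract can replace the classical detector at run time.
- **Tracking**: constant-velocity Kalman filter on (cx, cy, w, h, vx, vy);
  association maximizes total IoU (Hungarian); tentative tracks die on their
  first miss, confirmed tracks survive `max_age` misses and are then frozen
  — cells flow one way, so there is no re-identification. Appearance
  similarity (patch histogram cosine) can be blended in but defaults to off.
- **Event timing**: passage time = (last frame in exit region − first frame
  in entrance region)/fps; creep time = first frame with centroid ≥ window
  end minus first frame with centroid ≥ window start, over fps. Before
  crossing detection the centroid trajectory is de-jittered with a 3-sample
  running median (exact, hence unbiased, on monotone motion): near the
  window end a stiff cell advances ~0.1 px/frame, so sub-pixel centroid
  noise would otherwise shift the detected crossing by several frames.
  Sub-frame linear interpolation is available but off by default (one
  timestamp per frame). Cells starting inside the window or never reaching
  its end are censored with a reason code, not guessed.
- **Morphometrics**: H/W are the side lengths of the minimum-area *rotated*
  rectangle (rotating calipers over the convex hull of pixel corners, so an
  axis-aligned a×b rectangle measures exactly a×b); H ≥ W is enforced and
  the deformation index is (H−W)/(H+W). A_cell is the median morphometric
  area over the 3 frames before the entrance event (undeformed cell);
  area-in-constriction is the median over frames with the centroid inside
  the constriction span — median because partial-occlusion frames are
  outliers. The centroid-inside rule (rather than whole-cell-inside) is
  deliberate: at the default size range the deformed cell length
  (70–132 µm) exceeds the 60 µm constriction, so a literal fully-inside rule
  would never be satisfied; `require_fully_inside=True` restores it.
- **Group fit**: t = c1·x with x = ε_e^(1/β) has no intercept, so c1 has the
  closed form Σxt/Σx². r² is reported against SS_tot about the mean of t
  (no-intercept r² conventions differ; this one is comparable across β
  candidates). β is selected by maximizing r² over the grid, ties broken
  toward the larger (more fluid) β.
- **Optimal size range**: per cell type, OLS of per-cell E on A; the A
  interval where the fitted line stays within mean(E) ± SD(E), clipped to
  the observed A range; the final range is the intersection across types,
  with an explicit empty result. Zero-variance E degenerates to the whole
  observed range.
- **Statistics**: groupwise two-tailed Student's t (equal variance) and
  Mann–Whitney U with the standard star convention; no multiplicity
  correction by default (Holm available via a flag).
- **Fouling QC**: a constriction is fouled when a tracked object stays
  within its span for ≥ 3 s worth of frames (config); a recording is
  discarded iff *more than 3* constrictions in one group are fouled (exactly
  3 keeps). The pipeline's QC pass detects against the first frame rather
  than the temporal median, because an object that sits still for most of
  the video is absorbed into the median background and would be invisible.

## Benchmark sizes

Chosen once as the package's study conditions: parameter recovery uses
n = 300 cells, 5% multiplicative noise, 20 replicates per β; the end-to-end
video benchmark uses 50 cells in 9 lanes at 1 µm/px (~1900 frames, ~15 s on
one CPU); mixture stratification uses 4000 cells per mixture at exact
ratios — sized by a power analysis so the closest adjacent pair of the
six-group median series (9:1 vs 4:1, whose medians sit at the 44.4% and
37.5% quantiles of the stiff c1 distribution, ~4% apart at geometric SD
1.25) is separated by ≈ 5 standard errors, making the strict-ordering
assertion stable across seeds.

## Known limitations

- The classical detector assumes a static background and dark-ish cells on
  a brighter plate; strong illumination drift needs a rolling background
  (not implemented).
- Segmentation is threshold-based; touching cells in one lane would merge
  (the chip design and headway make this rare by construction).
- c1 units are t0-scaled seconds; comparing c1 across frame rates or
  pressure settings requires identical ΔP̄ and β.
- The tracker never re-identifies after loss; a cell occluded longer than
  `max_age` frames returns as a new identity (and a censored record).
- Neural detector/segmenter backends are interface hooks
  (`detect_frames`-compatible callables, `segmenter=` in `measure_cells`);
  no trained weights ship with the package.
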