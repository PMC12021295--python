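# Methods

## Coordinate and unit conventions

`x` is the column index, `y` the row index, 0-based, pixel centers at
integer coordinates.  Track files store pixel/frame units; physical
quantities derive on demand from `pixel_size_nm` and `frame_interval_s`,
and analytics that need physical units raise `MissingMetadataError` rather
than assuming defaults.  Headings use `θ = atan2(−Δrow, Δcol)` so that "up"
in a displayed image is 90°; tissue axes (apical, leading edge) are supplied
by the user per movie.

## Preprocessing

Background at frame *i* is the per-pixel mean over the `m`-frame window
centered on *i* (truncated at the sequence ends; median available via
`background_stat`), subtracted and clipped at zero.  The window is centered
rather than causal for a symmetric estimate; default `m = 20` frames.
CLAHE (clip 0.01, tile 32 px) follows, after min–max normalization so the
mapping is invariant to global affine intensity changes.  Optional
registration estimates one translation per frame by maximizing the mutual
information of a 32-bin joint histogram against the previous registered
frame — integer grid search over ±5 px with parabolic subpixel refinement —
and applies cumulative shifts by interpolation.  Translation-only is
deliberate: the drift being corrected is a slow rigid movement of the whole
tissue in the field of view.

## Detection

The multiscale spot-enhancing filter iterates over an increasing σ ladder
(default {1.0, 1.5, 2.5, 4.0} px).  Iteration *k* convolves the masked frame
with a scale-normalized (×σ²), sign-flipped Laplacian-of-Gaussian, so bright
blobs of any scale produce comparable positive peaks, then updates the mask
by thresholding at `T_k = μ_k + c·ς_k` (default `c = 0.8`), where μ_k and
ς_k are the mean and standard deviation of the *whole* response image — a
flat response (degenerate input) yields an empty mask.  The first iteration
uses the all-ones mask.  Whether the original filter masks before or after
the first convolution is ambiguous in the literature; masking with
`b(σ⁰) ≡ 1` was chosen.

Candidates are 3×3 local maxima of the final response inside the final
mask; peaks closer than `min_peak_sep_px` (default 3) merge keeping the
higher response.  Each candidate yields a 16×16 ROI from the **raw** frame
(the classifier is trained on raw patches; preprocessing only sharpens
candidate finding); candidates within half an ROI of a border are rejected
because both the classifier and the centroid need complete windows.

The patch classifier is a small CNN — conv 3×3×16 → ReLU → conv 3×3×32 →
ReLU → max-pool 2×2 → FC 64 → ReLU → FC 2 → softmax — trained with
cross-entropy and RMSprop on per-patch standardized inputs, with ×6
rotation/flip augmentation.  It is written in plain numpy (float32): at this
size (~150k parameters) that is fast enough, exactly reproducible under a
seed, and dependency-free.  Candidates with spot probability below `p_min`
(default 0.5) are dropped.

Accepted candidates are refined by iterative center-of-mass: the window of
radius `refine_radius_px` (default 4) around the current estimate has its
minimum subtracted, the estimate moves to the intensity centroid, and the
loop stops below a 0.01 px step or after `refine_iters` (default 20).
On noiseless rendered spots this reaches < 0.1 px mean absolute error;
at SNR 4, ~0.5 px.

## Linking

Tracklets form frame-sequentially: Hungarian assignment (via
`scipy.optimize.linear_sum_assignment` on a padded matrix, so every entity
may stay unmatched at the gate price) matches open tracklet ends to new
detections with gate `max_link_dist_px` (default 5).  Unmatched detections
open tracklets; tracklets missing more than `max_missed_frames` (default 2)
close; a length cap (default 10) keeps tracklets short and reliable.

Tracklet pairs that are close in space and time (end-to-start distance ≤
`pair_gate_px` = 15, frame gap ≤ `pair_gate_frames` = 5) receive a
connectivity score from a discrete Bayesian network with the binary
connectivity variable CS and six evidence nodes, each discretized to three
ordinal states (cut points in the config): intensity ratio of the terminal
ROI means {<1.3, <2, ≥2}; heading difference of the terminal segments
{<45°, <120°, ≥120°}; speed ratio {<1.5, <3, ≥3}; end-to-start distance as
a fraction of the gate {<⅓, <⅔, ≥⅔}; frame gap {≤1, ≤3, >3}; and a sequence
state derived from its two parents, order and overlap (in order without
overlap / overlapping / reversed).  The published description of the network
gives its node groups but not its tables or wiring, so the network here is a
clean, fully user-editable design: CS is the parent of each evidence node,
whose conditional tables are chosen so that every favorable state multiplies
the posterior odds of CS=True; inference is exact enumeration (the
implementation prunes barren nodes, so unobserved evidence is simply left
out).  Terminal segment velocity is averaged over up to three steps, a
heading is treated as uninformative when either terminal step is below a
1 px/frame localization-noise floor, and the speed ratio uses the same
additive floor — otherwise near-stationary (paused) particles would present
meaningless random headings and unstable ratios and good joins would be
rejected.

Assembly is a predecessor→successor Hungarian assignment with cost
`1 − P_c` and gate `1 − score_min` (default 0.5); each tracklet takes at
most one predecessor and one successor, and joins must strictly advance
time, so chains are acyclic, concatenation preserves strictly increasing
frames, and no detection is created or lost.  For large instances the same
gated assignment is solved sparsely (square doubling with per-entity dummy
edges, `scipy.sparse.csgraph.min_weight_full_bipartite_matching`), which is
exactly equivalent to the dense form.  Multi-pass linking re-runs scoring
and assembly on the current track set with per-pass overrides (typically a
growing distance gate); the pass at which each join occurred is recorded.
Track filtering by minimum point count and minimum net physical length
(700 nm and 1,000 nm are the conventional cutoffs for vesicle work)
removes the short spurious tracks that false detections produce.

## Trajectory measures

For detections p_1..p_N with pixel size s and frame interval t:
d_total = Σ‖p_{i+1} − p_i‖; d_net = ‖p_N − p_1‖; d_max = max_i ‖p_i − p_1‖;
t_traj = (last_frame − first_frame)·t — gap frames count toward elapsed
time, otherwise speeds would be overestimated across missed detections;
v = d_total/t_traj and v_line = d_net/t_traj.  The "maximum distance" is
measured from the first point; the variant over all point pairs is exposed
as `max_distance_pairwise` since both conventions circulate.  Normalized
brightness is the mean over detections of (mean ROI intensity)/b_max with
b_max the brightest pixel of the sequence.

Moving segments come from a rolling-window MSD exponent: within each
5-point window the MSD over lags 1–3 is fit log-log; points with exponent ≥
1.4 are "moving" (ballistic motion has exponent 2, confined/paused 0–1).
Tracks shorter than the window are flagged unsegmentable.  The maximum
curvilinear speed uses a sliding window of `speed_window_s` (default 1 s)
fully inside a moving segment; if no segment is long enough the value is
flagged undefined rather than silently extrapolated.

Quadrant classification measures the angular distance from the net heading
to the apical (or leading) axis: ≤45° axial, ≥135° anti-axial, otherwise
lateral; the tie at exactly 45° goes to the axial class.  Polar histograms
use 36 bins of 10°, include only tracks with net displacement ≥ 1 µm
(in-plane 2D distance — the movies are single planes), and report raw
counts, counts per minute of movie duration, and per-bin net-distance sums.
Axis displacement is the signed projection of the net vector on the axis
unit vector.  Per-frame Pearson correlation between two channels is
anchored at a reference time point (first frame by default, last optionally)
and normalized by the maximum change K so the peak is 1.

## Evaluation

Track pairing minimizes the gated distance
`d(θ_g, θ_e) = Σ_frames∈union min(‖p_g − p_e‖, ε)` (ε charged where either
track lacks a point; default ε = 5 px) via assignment, with unpaired
ground-truth tracks charged their empty-match penalty `n_points·ε`; pairs
with no point ever inside ε dissolve.  Then α = 1 − D(gt,est)/D(gt,∅);
β = (D(gt,∅) − D(gt,est))/(D(gt,∅) + D(spurious,∅)); JSC = TP/(TP+FN+FP)
over points; JSC_θ = paired/(paired + unpaired gt + spurious); RMSE over
matched point pairs; γ counts a ground-truth track as detected when its
pair matches ≥ `gamma_min_cover` (default 0.5) of its points.  The exact
aggregation conventions of the original benchmark tool are not published in
detail; these operational definitions are the contract here, and ε and the
γ cover fraction are explicit parameters reported with every result.  Only
pairs overlapping in time with centroids within 50 px are scored, for
tractability.

## Synthetic data

The generator emulates the standard tracker-evaluation scenario — moving
sub-resolution spots at low/middle/high density (10/50/100 particles per
512×512 frame, scaled by area) and Poisson SNR ∈ {1, 2, 4, 7} — plus the
nuisance structure of real secretory-pathway movies: a constant diffuse
background (default 30 counts) and bright immobile Golgi-like blobs
(2D Gaussians, σ ∈ [3, 6] px, 3–10× the spot amplitude).  Spots are
isotropic Gaussians (σ = 1.3 px) of peak amplitude A above background b
with `A = (snr² + snr√(snr² + 4b))/2`, the shot-noise SNR at the peak;
the exact SNR convention of the original benchmark is not published, so
this definition is the stated emulation target, verified to 2% on the
noiseless render.  Per-pixel Poisson noise leaves the expected image equal
to the noiseless image.  Motion models: directed (constant velocity),
Brownian (step sd 0.5 px), and switching — directed runs with geometric
dwells (mean 10 frames moving, 5 paused, new random heading per run), which
produces the moving-segment structure the analytics measure.  Particles
reflect off a 16 px interior margin so spots stay in the usable field of
view (border candidates are rejected by design).  Defaults: 100 frames,
512×512, low density, SNR 7, 10 distractors, 100 nm pixels at 4.5 fps.

Classifier training patches are pooled from three independent realizations
of the scenario, as a user would annotate ROIs across several movies;
positives are jittered ±1 px around true spots, negatives come from
background (snapped to the local noise maximum — the detector only ever
asks about local maxima, so off-peak background patches would understate
the negative class), distractor interiors, and distractor edges.

What the generator does **not** emulate: photobleaching, camera gain/EM
noise, focus drift, out-of-focus halos, anisotropic PSFs, particle
merge/split events, and motion heterogeneity beyond the three models.
Passing the synthetic benchmark therefore demonstrates the algorithmic
chain (enhancement → candidate pruning → localization → two-step linking →
metrics) under controlled noise, not performance on any particular
microscope's data; on real movies the classifier should be retrained on
annotated ROIs from that system.

## Problem sizes and reproducibility

The standard benchmark used by the test suite and `scripts/acceptance.py`
is one 100-frame 512×512 movie per SNR at low density (10 particles, ~1,000
ground-truth points), with the classifier trained on 200+200 patches for 30
epochs — large enough for stable metrics, small enough to run on a laptop
CPU in minutes.  Every random choice (movie, weight initialization, batch
shuffling, patch sampling) flows from explicit integer seeds; identical
seeds give byte-identical outputs, and thread count never affects results.

## Known limitations

* The Bayesian-network tables are a designed prior, not learned from data;
  they are exposed in the config for tuning or replacement.
* Tracklet chaining is greedy-optimal per pass (one Hungarian pass over
  pairwise scores), not a global multi-hypothesis optimization; heavily
  crossing trajectories at high density can swap identities.
* γ, α at SNR ≤ 2 degrade sharply — by design the benchmark keeps the
  detector honest rather than tuning the scenario to flatter it.
* Merge/split events and 3D stacks are out of scope.
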