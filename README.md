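# spotlink

Single-particle tracking for noisy fluorescence time-lapse movies — built for
the hard case where small, fast, dim vesicles must be followed against much
brighter static organelles (e.g. post-Golgi carriers moving between Golgi
ministacks in epithelial cells).

## What it does

**Detection.** Each frame is enhanced (sliding-window background subtraction,
CLAHE) and passed through a multiscale spot-enhancing filter: a ladder of
scale-normalized Laplacian-of-Gaussian filters applied sequentially,

    f_k = LoG(σ_k) ∗ (b_{k−1} · g),    T_k = μ_k + c·ς_k,

where the binary mask `b_k = f_k > T_k` carries candidate regions from scale
to scale.  Local maxima of the final response form a candidate pool, which a
lightweight CNN patch classifier (two conv layers, max-pool, two FC layers,
softmax; trained on a few hundred 16×16 ROIs) prunes to actual particles.
Accepted candidates are localized to subpixel precision by iterative
center-of-mass refinement.

**Linking.** Detections are first joined into short, reliable tracklets by
frame-to-frame Hungarian assignment on Euclidean distance.  A discrete
Bayesian network then scores every pair of tracklets that is close in space
and time, combining intensity similarity *I*, orientation and speed
similarity *O_r*, *S_p*, temporal order/overlap *O_d*, *O_v*, and frame gap
*G* into a connectivity posterior

    P_c = P(CS = True | I, O_r, S_p, O_d, O_v, G),

and a second Hungarian pass chains tracklets into trajectories (optionally
multi-pass: a tight distance gate for slow particles, then a wide one for
fast ones).

**Analytics.** Per track: total/net/maximum distance, trajectory time, net
orientation, normalized brightness, curvilinear and straight-line speed,
MSD-based moving-segment detection, sliding-window maximum segment speed,
quadrant classification against a tissue axis (apical/lateral/basal or
leading/perpendicular/trailing), 10° polar histograms normalized to tracks
per minute, axis-projected net displacement, and per-frame Pearson
correlation between two channels.

**Evaluation.** Tracking performance against ground truth via the standard
measures α, β (β ≤ α; β penalizes spurious tracks), point- and track-level
Jaccard coefficients JSC and JSC_θ, RMSE of matched points, and γ — the
fraction of ground-truth tracks recovered.

**Synthetic data.** A movie generator renders moving Gaussian spots at a
requested Poisson SNR (`snr = A/√(A+b)` at the spot peak) over three density
presets, plus bright immobile Golgi-like distractor blobs, with exact
ground-truth tracks — so every stage is testable without external data.

## Worked example

```bash
spotlink simulate --out demo/                 # movie.tif + ground_truth.json
spotlink train    --out demo/model.json      # CNN on 200+200 synthetic ROIs
spotlink track    --model demo/model.json --in demo/movie.tif \
                  --out demo/tracks.json --pixel-size-nm 100 --frame-interval-s 0.22
spotlink evaluate --gt demo/ground_truth.json --est demo/tracks.json \
                  --out demo/report.json
```

The evaluate step prints (seed 0 defaults; 100-frame 512×512 movie, 10
particles, SNR 7):

```json
{
 "alpha": 0.8749,
 "beta": 0.5899,
 "gamma": 0.9,
 "jsc": 0.6278,
 "jsc_theta": 0.2041,
 "n_paired": 10,
 "n_spurious": 39,
 "rmse_px": 0.3429
}
```

meaning: paired tracks cover ~87% of the ground-truth point mass (α), 9 of
10 true trajectories are recovered (γ = 0.9), and matched points are
localized to ~0.34 px; the 39 spurious short tracks from residual false
detections depress β and JSC_θ.  Filtering those away the way vesicle data
is normally curated — `--min-net-len-nm 700` on the `track` call — leaves 10
tracks with JSC_θ = 0.82 and β = 0.75, at the price of also dropping short
true fragments (γ = 0.8, α = 0.78).  Per-track measures export with
`spotlink analyze --tracks demo/tracks.json --out measures.csv`.

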