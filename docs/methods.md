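# Methods

This note documents the models, numerical choices and limitations of the
package: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Acquisition model and image formation

A frame is one cycle of the single-transmit/multi-receive scheme: each of
the 32 transducers fires in turn while all 32 record, giving a
`32 × 32 × S` tensor at 50 MHz over a 110 µs listening window, so
`S = round(50e6 × 110e-6) = 5500` samples per line at 12-bit resolution.
The bracelet is built as two parallel rings of 16 elements (one per holder),
so each raw frame splits into two independent `16 × 16 × S` ring frames;
the two cross-ring blocks are discarded. The raw channel ordering is not
dictated by the ring geometry, so ring membership is configurable through a
`channel_map` container attribute; the default interleaves (even global
channel → ring 0, odd → ring 1), matching the one-holder-two-transducers
construction.

Per line the chain is:

1. **Trim** the first 800 samples (hardware dead zone, static artifacts and
   reverberation inside the silicone coupling layer). Time-gain
   compensation is assumed already applied in hardware upstream; the
   package applies no software TGC.
2. **Band-pass** 0.4–1.6 MHz around the 1 MHz transducers with a 4th-order
   Butterworth applied zero-phase. Numerically this is done in the
   frequency domain as the squared-magnitude response |H(f)|² — the
   transfer function of forward-backward filtering — fused with the
   analytic-signal mask into a single FFT pass per line.
3. **Envelope**: magnitude of the analytic signal. Lines are reflectively
   padded by 500 samples on each edge (an order of magnitude wider than the
   ~50-sample pulse) so edge transients never reach the retained window.
4. **Log compression** to dB relative to full scale `2^(12−1) = 2048`, so
   sensitivity cutoffs are absolute and hardware-comparable. A zero
   envelope is clamped at `eps × full scale` before the log, mapping silent
   input to a finite floor (≈ −313 dB) far below any cutoff.
5. **Axial decimation** by 10 via strided subsampling: the post-Hilbert
   envelope is smooth at this scale, so no additional anti-alias filter is
   applied; the decimator is a separable, swappable step. The trimmed
   4700-sample line becomes P = 470 axial pixels.

The 16 receive lines of transmission *k* stack into one `16 × 470` image;
the 16 images tile a two-rows-of-eight mosaic with the axial axis vertical
(`2 × 470 = 940` rows, `8 × 16 = 128` columns) — the only orientation
consistent with both the tile shape and the overall mosaic shape. Before
the regressor, a sensitivity cutoff clamps values below −50 dB
(multi-receive) or −40 dB (single-receive baseline, which keeps only the
pulse-echo diagonal `x[k, k, :]`), `[cutoff, 0]` dB maps linearly to
`[0, 255]`, the mosaic is resized to `128 × 128` (bilinear, anti-aliased —
the common default for CNN inputs), divided by 255, and z-scored with
training-population statistics. The `/255` scaling is a fixed affine map
rather than a per-image min-max so that the z-score statistics remain
meaningful across images; a per-image variant can be composed from
`pixelize` by callers who want it.

## Raw-signal augmentation

Six train-time policies act on raw lines before any filtering, so the
induced shifts are physically plausible and the band-pass smooths blanking
edges naturally: channel rotation by n∈[1,15] (equals a physical bracelet
rotation — verified exactly against the simulator), blanking of 1–8 shots,
blanking of 1–8 receive channels, blanking of 1–4 random axial portions of
50–500 samples, and axial shifts up to ±200 samples with zero-filled
vacated regions (echoes move with depth; nothing wraps). Whether rotation
accompanies the five-policy draw is not dictated by the acquisition model;
here it is an independent coin with probability 0.5 (configurable),
followed by exactly one category drawn uniformly from the five policies
plus "none". Portion count/length distributions are uniform over the
ranges above and configurable. Evaluation paths never augment.

## Marker model and inverse kinematics

Ten passive markers are used: radial/ulnar styloids (wrist), medial/lateral
epicondyles (elbow), third metacarpal head and third proximal-phalanx head
(hand), and an upper-arm cluster UA1–4 that is parsed but unused by the IK
(in the source protocol it only donates trajectories during manual gap
repair). Gaps shorter than 20 samples are filled per coordinate by a cubic
spline through up to 4 valid samples on each side; longer or boundary gaps
stay masked.

Angles come from three planes:

- hand plane {RSTY, USTY, MC3_HEAD};
- non-rotating forearm plane {RSTY, mid(RSTY,USTY), mid(MEPI,LEPI)} — it
  contains the forearm long axis and the radial styloid, so it co-rotates
  with the radius under pronation;
- elbow-anchored forearm plane {MEPI, LEPI, mid(RSTY,USTY)} — pronation-
  invariant.

Each plane yields a right-handed frame (x = long axis, z = plane normal,
y = z × x). Flexion–extension and radial–ulnar deviation are the intrinsic
Y–Z′ decomposition of the hand frame relative to the non-rotating forearm
frame: flexion about the radial–ulnar axis first, deviation about the
rotated palm normal second. Because the reference plane follows the radius,
pronation cancels exactly in this relative rotation. Pronation–supination
is the twist of the hand frame about the forearm long axis relative to the
elbow-anchored frame — the first angle of an intrinsic X–Y′–Z″
decomposition, which reduces to the hand/elbow plane dihedral at zero
flexion and deviation but remains well-posed away from it. Hand open–close
is the elevation of the MC3→PP3 segment out of the palm plane (a
two-marker "plane" is only well-posed as a segment-versus-plane angle).
Flexion, ulnar deviation, pronation and closing are positive; the neutral
pose defines all zeros. The decomposition is a documented, swappable
convention: published wrist models differ in Euler sequence, and the exact
sequence used with Plug-in-Gait-style marker sets is not uniquely
determined by the plane definitions alone.

All constructions use markers only, so angles are invariant to global rigid
motion (tested to 1e-6°) and to uniform skeleton scaling. The synthetic
forward chain (`synthesis.marker_positions`) composes the same frames in
the same order, so forward→inverse recovers commanded angles to numerical
precision; the 0.5° acceptance bound is dominated by the 200 Hz resampling
of trajectories, not the geometry. Gimbal degeneracy appears only at ±90°
flexion, outside the tested ±60° envelope.

Angles are normalized per session to activations
`a = (θ − θmin)/(θmax − θmin)`, clipped to [0, 1]; RMSE is reported in
degrees after denormalizing with the same session ROM, so
`rmse_deg = rmse_act × (θmax − θmin)` per DoF. A `2·a − 1` utility maps
activations to the [−1, 1] range VR control stacks expect. Ultrasound
frames pair with the nearest-in-time mocap sample from a shared start
trigger; at 200 Hz the pairing error is ≤ 2.5 ms, and frames beyond the
mocap extent are dropped with a warning.

## Synthetic data generator

The generator exists so every stage is testable without hardware. Each ring
channel k sees M = 3 acoustic interfaces at depths
`d[k, m] = d0[k, m] + Σ_d W[k, m, d] · a_d` (mm): baseline profiles d0 vary
smoothly around 16–36 mm, and the mixing weights W (1.5–3 mm per unit
activation, smooth over channels) move interfaces linearly with the four
activations. A transmission i received on j contributes, per interface, a
1 MHz Gaussian burst (σ = 0.6 µs) at the bistatic delay
`τ = (d[i,m] + d[j,m]) / c` with c = 1540 m/s, with amplitude set by
reflectivity, 0.02 dB/mm residual attenuation (most attenuation is assumed
compensated by hardware TGC) and a 1.5 dB-per-channel-step directivity
penalty (inward-pointing elements couple weakly across the ring). Gaussian
noise (σ = 20 at a ~1200 signal scale, ≥ 20 dB SNR) is added and lines are
quantized to signed 12 bits. Delays are measured from the start of the
retained window, mirroring hardware that discards the dead zone.

Participants differ in baseline morphology (d0, reflectivity — drawn from a
morphology seed) but share the activation response W (a fixed physiology
seed): this is the structural assumption that makes a neutral-pose
reference informative on unseen users, and mirrors the premise that muscle
mechanics generalize while anatomy does not. Bracelet position perturbs d0
smoothly; bracelet rotation rotates the channel indexing of d0/W and of the
tissue-anchored noise field, which makes physical rotation *exactly* equal
to the channel-rotation augmentation under a shared seed — the equality is
an index-arithmetic validation, not a tautology, because signal and noise
both travel through the rotated tables. Frames arrive at 11.8 Hz with
Gaussian rate jitter (σ = 0.5/2.355 Hz, i.e. 0.5 Hz FWHM), timestamps
jittered accordingly; every recording starts with a 2.5 s neutral lead so
the referencing path always finds frames inside its 2 s window.

What the generator does **not** emulate: speckle texture and coherent
scattering, refraction and multipath, nonlinear muscle-to-depth coupling,
marker soft-tissue artifact, or occlusion-driven marker gaps. Passing tests
therefore demonstrate that the pipeline is internally consistent and that
the regression task is solvable when its structural assumptions hold — not
that the specific R² levels transfer to human forearms.

## Splits, referencing, metrics

SameSet splits every recording chronologically at `floor(0.7 · n_frames)`
(boundary frame goes to test; the rule is deterministic). Functional trains
on the wrist video set and tests on functional movements; Position,
Rotation and Session are leave-one-level-out over their factorial columns
(3, 4, 2 folds); Participant holds out configured participant lists.
Missing design cells raise an error naming the absent combinations. The
"first 2 seconds" neutral window uses frame timestamps, not counts, because
the frame rate jitters. In train mode the reference frame is drawn
uniformly per example from that window; in inference mode a single fixed
neutral frame per session is used. R² is the out-of-sample coefficient of
determination (1 − SSres/SStot, ≤ 1, 0 = mean predictor), undefined and
masked when truth variance is zero; Pearson CC likewise requires variance
in both streams. Medians are reported across recordings because a few
strongly negative R² outliers dominate means.

## Regressor and training contract

The backbone is a compact 5-stage CNN (stride-2 3×3 convolutions,
16–32–64–64–64 channels) whose 4×4×64 output flattens to a 1024-dim
feature, preserving the 1024→100→4 regression head shape used at full
scale; the backbone is pluggable behind `build_model`. Training uses AdamW
(β = (0.9, 0.99), decoupled weight decay 1e-3 on matrices only) with an
RMSE loss. The learning rate ramps geometrically from 1 % of peak to peak
over the first 2 epochs (a literal exponential from zero never leaves
zero; the geometric ramp keeps both endpoints exact) and then decays
linearly to 1 % of peak at the final epoch. Best-epoch selection uses a
held-out 10 % of the training frames scored by validation loss. Everything
is float32 numpy and deterministic under fixed seeds: weights, batch
order, validation carve-out and reference draws reproduce bit-identically,
and training histories hash-compare equal across runs on one machine.

Desk-scale study configuration: the studies in `amodehmi.study` train from
random initialization (no pretraining is available or wanted at this
scale), so they use a 3e-3 peak learning rate, batch 32, 10 epochs on
~2000 samples (four 40 s recordings at 11.8 Hz), 3 model seeds, and report
the median. The `ModelConfig` default of 1e-4 (3e-5 multi-source) is the
full-scale contract and is kept as the default for users replicating that
setting. The unseen-morphology study trains on six synthetic participants
and tests on three fresh phantoms, comparing median held-out R² (over test
recordings, DoFs and model seeds) of a 2-channel (reference + target)
model against a 1-channel model at equal capacity, seeds and schedule.
During training the reference channel is redrawn every epoch from the
source recording's neutral window — the same contract as full scale, where
each example pairs with a random neutral frame — so the model must learn
the reference-relative mapping rather than memorize one reference image.
This is a directional comparison by design: with few morphologies and
desk-scale training both absolute scores stay modest, and the claim
defended is only that referencing does not hurt and typically helps.

## Numerical details and degenerate inputs

- Zero-length or over-trimmed lines, non-32×32 raw frames, invalid design
  labels, duplicate recording ids, unknown marker names and missing
  container attributes raise typed errors naming the offending field.
- Collinear plane points (tolerance 1e-8 relative) mask the frame with a
  warning instead of propagating NaNs.
- Echo delays beyond the listening window are dropped silently; simulated
  depths clamp at 1 mm.
- Blank-portion draws clip at the line end; a zero-portion draw is the
  identity.
- RMSE loss at exactly zero returns a zero gradient (the √ is not
  differentiable there).
- `compute_norm_stats` refuses empty collections and zero variance.

## Known limitations

- The echo model is linear in activations by construction; the regressor's
  high recovery R² on synthetic data says nothing about nonlinear human
  muscle mechanics.
- The single-receive baseline shares the multi-receive normalization
  machinery but has no dedicated end-to-end study at desk scale.
- Only the wrist/hand 4-DoF chain is modeled; elbow and shoulder are out of
  scope, as are beamformed B-mode reconstruction and acoustic
  interferometry.
- The CNN is intentionally small; absolute performance numbers are not
  comparable to large pretrained backbones and are used only for
  parameter-recovery and ablation-direction claims.
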