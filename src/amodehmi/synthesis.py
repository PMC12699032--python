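"""Synthetic paired data: multi-receive echo frames + marker trajectories.

The generator stands in for the bracelet hardware and the optical capture
volume so that every downstream stage (imaging, augmentation, kinematics,
splits, regression) can be exercised with known ground truth.

Echo model
----------
A phantom forearm presents each ring channel ``k`` with a small number of
acoustic interfaces at depths ``d[k, m] = d0[k, m] + sum_d W[k, m, d] * act_d``
(mm): depths vary linearly with the 4 joint activations through smooth
per-channel mixing weights.  For a transmission by channel ``i`` received on
channel ``j``, each interface contributes a 1 MHz Gaussian-windowed burst at
the bistatic delay ``tau = (d[i, m] + d[j, m]) / c``, with amplitude set by
interface reflectivity, round-trip attenuation, and a directivity penalty
growing with ring distance between transmitter and receiver (transducers
point inward, so widely separated pairs couple weakly).  Gaussian noise is
added and the line is quantized to the hardware's 12-bit signed range.
Delays are expressed relative to the retained window (the trimmed samples
model the dead zone + coupling reverberation the hardware discards).

Marker model
------------
A forearm-hand kinematic chain places the ten markers from the commanded
4-DoF joint states; it is the exact forward counterpart of
:func:`amodehmi.kinematics.compute_joint_angles`, so the inverse kinematics
round trip recovers the commanded angles to numerical precision.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .io_core import (
    MARKER_NAMES,
    AcquisitionConfig,
    CircleFrame,
    MarkerTrajectory,
    Recording,
    RecordingMeta,
)
from .kinematics import SessionROM

#: Nominal per-session range of motion (degrees) used by the generator.
DEFAULT_ROM = {
    "flexion_extension": (-60.0, 60.0),
    "radial_ulnar": (-30.0, 30.0),
    "pronation_supination": (-80.0, 80.0),
    "hand_open_close": (-30.0, 60.0),
}

#: Neutral frame with x = forearm long axis (+Y), z = palm normal (+Z).
_E0 = np.array([[0.0, -1.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0]])
_X, _Y, _Z = np.eye(3)


@dataclass(frozen=True)
class Phantom:
    """A synthetic forearm cross-section seen by one 16-channel ring."""

    ring_radius: float = 40.0                      # mm
    interface_base_depths: np.ndarray = None       # [16, M] mm
    mixing_weights: np.ndarray = None              # [16, M, 4] mm per unit activation
    reflectivity: np.ndarray = None                # [M] in (0, 1]
    attenuation: float = 0.02                      # dB/mm (residual after hardware TGC)
    directivity_decay: float = 1.5                 # dB per channel-index separation
    speed_of_sound: float = 1540.0                 # m/s
    pulse_freq: float = 1.0e6                      # Hz
    pulse_sigma: float = 0.6e-6                    # s, Gaussian envelope width
    noise_std: float = 20.0                        # amplitude units (full scale 2048)
    amplitude_scale: float = 1200.0                # peak amplitude of a unit reflector
    morphology_seed: int = 0

    def __post_init__(self) -> None:
        if self.interface_base_depths is None or self.mixing_weights is None:
            raise ValueError("use default_phantom() to build a phantom")
        d0 = np.asarray(self.interface_base_depths)
        if (d0 <= 0).any() or (d0 >= 2 * self.ring_radius).any():
            raise ValueError("interface depths must be positive and inside the ring")
        r = np.asarray(self.reflectivity)
        if (r <= 0).any() or (r > 1).any():
            raise ValueError("reflectivity must be in (0, 1]")
        if self.speed_of_sound <= 0:
            raise ValueError("speed of sound must be positive")


#: Seed of the shared activation-to-depth response; participants differ in
#: baseline morphology (d0, reflectivity) but share physiology (W), which is
#: what makes a neutral-pose reference informative on unseen morphologies.
PHYSIOLOGY_SEED = 1540


def default_phantom(
    morphology_seed: int = 0,
    n_interfaces: int = 3,
    noise_std: float = 20.0,
    position: int = 1,
    physiology_seed: int = PHYSIOLOGY_SEED,
) -> Phantom:
    """Draw a phantom morphology: smooth per-channel depth profiles and
    smooth activation-to-depth mixing weights.

    Distinct ``morphology_seed`` values emulate distinct participants
    (different baseline depth profiles); the mixing weights ``W`` come from
    ``physiology_seed`` and are shared across participants.  ``position``
    perturbs the depth profiles smoothly, emulating sliding the bracelet
    along the forearm.
    """
    rng = np.random.default_rng(morphology_seed)
    prng = np.random.default_rng(physiology_seed)
    k = np.arange(16)
    base = np.linspace(16.0, 36.0, n_interfaces)  # mm, superficial -> deep
    d0 = np.empty((16, n_interfaces))
    W = np.empty((16, n_interfaces, 4))
    for m in range(n_interfaces):
        amp = rng.uniform(1.0, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        d0[:, m] = base[m] + amp * np.sin(2 * np.pi * k / 16 + phase) \
            + rng.uniform(-2.0, 2.0)
        for d in range(4):
            w_amp = prng.uniform(1.5, 3.0) * prng.choice([-1.0, 1.0])
            w_phase = prng.uniform(0, 2 * np.pi)
            W[:, m, d] = w_amp * np.sin(2 * np.pi * k / 16 + w_phase)
    refl = rng.uniform(0.4, 1.0, size=n_interfaces)
    if position != 1:
        # bracelet translation: a smooth, position-dependent morphology change
        prng = np.random.default_rng((morphology_seed, 7919, position))
        shift = prng.uniform(1.0, 2.0) * np.sin(2 * np.pi * k / 16 + prng.uniform(0, 2 * np.pi))
        d0 = d0 + (position - 1) * shift[:, None]
    return Phantom(
        interface_base_depths=d0,
        mixing_weights=W,
        reflectivity=refl,
        noise_std=noise_std,
        morphology_seed=morphology_seed,
    )


@dataclass(frozen=True)
class Protocol:
    """Recording protocol: a neutral lead followed by guided movements."""

    video_set: str = "wrist"          # "wrist": one DoF at a time; "functional": combined
    duration_s: float = 40.0          # movement duration after the neutral lead
    frame_rate: float = 11.8          # Hz, mean ultrasound frame rate
    frame_rate_jitter: float = 0.5 / 2.355  # Hz (FWHM 0.5)
    neutral_lead_s: float = 2.5       # rest period at the start of every recording

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.neutral_lead_s < 0:
            raise ValueError("durations must be positive")


# ---------------------------------------------------------------------------
# Echo simulation


def _ring_distance(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    d = np.abs(i - j)
    return np.minimum(d, 16 - d)


def simulate_frame(
    phantom: Phantom,
    activation: np.ndarray,
    rng: np.random.Generator,
    config: AcquisitionConfig | None = None,
    timestamp: float = 0.0,
    channel_rotation: int = 0,
) -> CircleFrame:
    """Simulate one 16x16xS multi-receive ring frame at a joint state.

    ``channel_rotation`` physically rotates the bracelet by that many
    channels: channel ``i`` then faces the tissue sector previously under
    channel ``i + n``, and the additive noise field is anchored to the tissue
    so that a physical rotation equals the channel-rotation augmentation
    exactly under a shared generator state.
    """
    config = config or AcquisitionConfig()
    act = np.asarray(activation, dtype=np.float64)
    if act.shape != (4,) or (act < 0).any() or (act > 1).any():
        raise ValueError("activation must be 4 values in [0, 1]")
    S = config.samples_per_line
    fs = config.sampling_rate
    n = int(channel_rotation) % 16

    d0 = np.roll(phantom.interface_base_depths, -n, axis=0)
    W = np.roll(phantom.mixing_weights, -n, axis=0)
    depths = np.maximum(d0 + W @ act, 1.0)                    # [16, M] mm
    path = depths[:, None, :] + depths[None, :, :]            # [16, 16, M] mm
    tau = path * 1e-3 / phantom.speed_of_sound                # s
    centers = tau * fs + config.trim_samples                  # fractional sample index

    ii, jj = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    decay_db = phantom.attenuation * path + \
        phantom.directivity_decay * _ring_distance(ii, jj)[..., None]
    amps = phantom.reflectivity[None, None, :] * 10.0 ** (-decay_db / 20.0) \
        * phantom.amplitude_scale

    half = int(np.ceil(4 * phantom.pulse_sigma * fs))
    offsets = np.arange(-half, half + 1)
    n0 = np.floor(centers).astype(np.int64)
    idx = n0[..., None] + offsets                             # [16,16,M,Wn]
    t_rel = (idx - centers[..., None]) / fs
    burst = amps[..., None] * np.exp(-0.5 * (t_rel / phantom.pulse_sigma) ** 2) \
        * np.cos(2 * np.pi * phantom.pulse_freq * t_rel)

    lines = np.zeros((16, 16, S), dtype=np.float32)
    valid = (idx >= 0) & (idx < S)                            # out-of-window echoes dropped
    flat_line = (ii[..., None, None] * 16 + jj[..., None, None]) * S + idx
    np.add.at(lines.ravel(), flat_line[valid], burst[valid].astype(np.float32))

    if phantom.noise_std > 0:
        noise = rng.standard_normal((16, 16, S), dtype=np.float32)
        noise *= phantom.noise_std
        if n:
            noise = np.roll(np.roll(noise, -n, axis=0), -n, axis=1)
        lines += noise

    full = np.float32(config.full_scale)
    quantized = np.clip(np.rint(lines), -full, full - 1).astype(np.int16)
    return CircleFrame(quantized, ring_id=0, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Forward kinematics -> markers


@dataclass(frozen=True)
class Skeleton:
    """Segment geometry (mm) of the synthetic forearm-hand chain."""

    forearm_length: float = 250.0
    elbow_half_width: float = 30.0
    styloid_half_width: float = 25.0
    hand_length: float = 80.0
    phalanx_length: float = 40.0
    upper_arm_offset: float = 120.0

    def __post_init__(self) -> None:
        for name in ("forearm_length", "elbow_half_width", "styloid_half_width",
                     "hand_length", "phalanx_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (degenerate skeleton)")


def marker_positions(
    theta_deg: np.ndarray,
    skeleton: Skeleton | None = None,
    rigid: "tuple[np.ndarray, np.ndarray] | None" = None,
) -> np.ndarray:
    """Place the 10 markers for one joint state (FE, RUD, PS, OC in degrees).

    ``rigid`` optionally applies a global (R, t) to every marker; joint
    angles are invariant to it.  Returns [10 x 3] in canonical marker order.
    """
    sk = skeleton or Skeleton()
    fe, rud, ps, oc = np.radians(np.asarray(theta_deg, dtype=np.float64))

    r_hand_local = Rotation.from_euler("XYZ", [ps, fe, rud]).as_matrix()
    f_h = _E0 @ r_hand_local
    r_ps_global = _E0 @ Rotation.from_euler("X", ps).as_matrix() @ _E0.T

    emid = np.zeros(3)
    wmid = emid + sk.forearm_length * _Y
    sty_dir = r_ps_global @ _X                      # styloid axis follows the radius
    pos = {
        "MEPI": emid - sk.elbow_half_width * _X,
        "LEPI": emid + sk.elbow_half_width * _X,
        "RSTY": wmid + sk.styloid_half_width * sty_dir,
        "USTY": wmid - sk.styloid_half_width * sty_dir,
    }
    pos["MC3_HEAD"] = wmid + sk.hand_length * f_h[:, 0]
    phal_dir = f_h @ np.array([np.cos(oc), 0.0, -np.sin(oc)])
    pos["PP3_HEAD"] = pos["MC3_HEAD"] + sk.phalanx_length * phal_dir
    ua0 = emid - sk.upper_arm_offset * _Y
    for q, (dx, dz) in enumerate([(-25, 20), (25, 20), (25, -20), (-25, -20)]):
        pos[f"UA{q + 1}"] = ua0 + dx * _X + dz * _Z

    out = np.stack([pos[name] for name in MARKER_NAMES])
    if rigid is not None:
        R, t = rigid
        out = out @ np.asarray(R).T + np.asarray(t)
    return out


def synthesize_markers(
    times: np.ndarray,
    theta_deg: np.ndarray,
    skeleton: Skeleton | None = None,
    rate: float = 200.0,
    rigid: "tuple[np.ndarray, np.ndarray] | None" = None,
) -> MarkerTrajectory:
    """Marker trajectory at ``rate`` Hz from a joint-angle time series.

    ``theta_deg`` is [T x 4] sampled at ``times`` (s); it is linearly
    resampled onto the uniform mocap grid covering the same span.
    """
    times = np.asarray(times, dtype=np.float64)
    theta_deg = np.atleast_2d(np.asarray(theta_deg, dtype=np.float64))
    grid = np.arange(0.0, times[-1] + 0.5 / rate, 1.0 / rate)
    theta_grid = np.column_stack(
        [np.interp(grid, times, theta_deg[:, d]) for d in range(4)]
    )
    positions = np.stack([marker_positions(th, skeleton, rigid) for th in theta_grid])
    mask = np.zeros(positions.shape[:2], dtype=bool)
    return MarkerTrajectory(positions=positions, missing_mask=mask, rate=rate, times=grid)


# ---------------------------------------------------------------------------
# Protocol trajectories and full recordings


def _neutral_activation(rom: SessionROM) -> np.ndarray:
    return -rom.mins / (rom.maxs - rom.mins)


def protocol_activations(
    protocol: Protocol, rng: np.random.Generator, rate: float = 200.0,
    rom: SessionROM | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth activation trajectory [T x 4] on the mocap grid.

    The wrist set sweeps one DoF at a time to an extreme and back (raised
    cosine bumps); the functional set superposes slow sinusoids on all four
    DoFs.  Both start from the neutral pose during the lead-in.
    """
    rom = rom or SessionROM(DEFAULT_ROM)
    total = protocol.neutral_lead_s + protocol.duration_s
    t = np.arange(0.0, total, 1.0 / rate)
    act0 = _neutral_activation(rom)
    act = np.tile(act0, (len(t), 1))
    t_move = t - protocol.neutral_lead_s
    if protocol.video_set == "wrist":
        seg_len = 3.0
        n_seg = int(np.ceil(protocol.duration_s / seg_len))
        for s in range(n_seg):
            dof = s % 4
            target = float(rng.choice([0.0, 1.0]))
            tau = (t_move - s * seg_len) / seg_len
            bump = np.where((tau >= 0) & (tau < 1),
                            0.5 * (1 - np.cos(2 * np.pi * np.clip(tau, 0, 1))), 0.0)
            act[:, dof] += (target - act0[dof]) * bump
    else:
        for dof in range(4):
            for f in rng.uniform(0.08, 0.35, size=3):
                a = rng.uniform(0.1, 0.25)
                phase = rng.uniform(0, 2 * np.pi)
                wave = a * np.sin(2 * np.pi * f * t_move + phase)
                wave -= wave[t_move <= 0].mean() if (t_move <= 0).any() else 0.0
                act[:, dof] += np.where(t_move >= 0, wave, 0.0)
    return t, np.clip(act, 0.0, 1.0)


def frame_times(protocol: Protocol, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered ultrasound frame timestamps starting at t = 0."""
    ts = [0.0]
    while True:
        rate = max(rng.normal(protocol.frame_rate, protocol.frame_rate_jitter), 1.0)
        nxt = ts[-1] + 1.0 / rate
        if nxt > duration:
            break
        ts.append(nxt)
    return np.array(ts)


def generate_recording(
    phantom: Phantom,
    protocol: Protocol,
    meta: RecordingMeta,
    rng: np.random.Generator,
    config: AcquisitionConfig | None = None,
    skeleton: Skeleton | None = None,
    frame_sink=None,
) -> tuple[Recording, np.ndarray]:
    """One synthetic recording: frames + markers + per-frame activations.

    ``meta.rotation`` is applied as a physical bracelet rotation (90 degrees
    = 4 of the 16 ring channels); ``meta.position`` perturbs the phantom's
    depth profiles smoothly.  Returns the Recording (markers attached, ROM
    filled in) and the ground-truth activation [n_frames x 4] aligned to the
    frame timestamps.

    A raw recording is large (~2.8 MB per frame); passing ``frame_sink``
    streams each frame to the callable instead of accumulating it, and the
    returned Recording carries no frames.
    """
    config = config or AcquisitionConfig()
    rom = SessionROM(meta.rom or DEFAULT_ROM)
    if meta.position != 1:
        phantom = default_phantom(
            morphology_seed=phantom.morphology_seed,
            n_interfaces=phantom.interface_base_depths.shape[1],
            noise_std=phantom.noise_std,
            position=meta.position,
        )
    channel_rotation = (meta.rotation // 90) * 4  # 90 deg = 4 of 16 channels

    t200, act200 = protocol_activations(protocol, rng, rom=rom)
    theta200 = act200 * (rom.maxs - rom.mins) + rom.mins
    markers = synthesize_markers(t200, theta200, skeleton)

    ts = frame_times(protocol, t200[-1], rng)
    frames = []
    frame_act = np.empty((len(ts), 4))
    for fi, t in enumerate(ts):
        a = np.array([np.interp(t, t200, act200[:, d]) for d in range(4)])
        frame_act[fi] = a
        frame = simulate_frame(phantom, a, rng, config, timestamp=float(t),
                               channel_rotation=channel_rotation)
        if frame_sink is not None:
            frame_sink(frame)
        else:
            frames.append(frame)
    meta = replace(meta, rom=dict(rom.limits))
    rec = Recording(meta=meta, frames=frames, markers=markers)
    return rec, frame_act


def generate_design(
    participant_id: str,
    metas: "list[RecordingMeta]",
    seed: int = 0,
    protocol_kwargs: dict | None = None,
    noise_std: float = 20.0,
) -> "list[tuple[Recording, np.ndarray]]":
    """Generate recordings for a list of design cells of one participant.

    The participant's morphology is drawn from a seed derived from
    ``participant_id`` and ``seed``; sessions add a small re-donning
    perturbation through the per-recording noise stream.
    """
    out = []
    pid_seed = zlib.crc32(f"morph:{participant_id}:{seed}".encode()) % (2**31)
    for i, meta in enumerate(metas):
        phantom = default_phantom(morphology_seed=pid_seed, noise_std=noise_std,
                                  position=meta.position)
        rng = np.random.default_rng((seed, i, meta.session))
        protocol = Protocol(video_set=meta.video_set, **(protocol_kwargs or {}))
        out.append(generate_recording(phantom, protocol, meta, rng))
    return out
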