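"""Raw-signal augmentation policies for multi-receive ring frames.

All policies act on the raw A-mode lines *before* filtering and image
formation, so the induced domain shifts are physically plausible: rotating
channels emulates a physical bracelet rotation, blanking emulates coupling
loss on shots or receivers, and axial shifts emulate depth changes.  Blanked
samples are set to 0 on the raw amplitudes; the band-pass stage then smooths
the edges naturally.

Per training example, channel rotation is an independent coin flip, after
which exactly one of {blank_shots, blank_channels, blank_portions,
shift_left, shift_right, none} is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import CircleFrame

POLICIES = ("blank_shots", "blank_channels", "blank_portions", "shift_left", "shift_right", "none")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range: tuple[int, int] = (1, 15)
    blank_shots_range: tuple[int, int] = (1, 8)
    blank_channels_range: tuple[int, int] = (1, 8)
    shift_max: int = 200
    portion_count_range: tuple[int, int] = (1, 4)
    portion_len_range: tuple[int, int] = (50, 500)
    policy_probs: tuple[float, ...] = (1 / 6,) * 6
    rotation_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.policy_probs) != len(POLICIES):
            raise ValueError(f"policy_probs must have {len(POLICIES)} entries")
        if abs(sum(self.policy_probs) - 1.0) > 1e-9:
            raise ValueError("policy_probs must sum to 1")
        if not 0 <= self.rotation_prob <= 1:
            raise ValueError("rotation_prob must be in [0, 1]")
        for name in ("rotation_range", "blank_shots_range", "blank_channels_range",
                     "portion_count_range", "portion_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-negative interval")
        if not 1 <= self.rotation_range[0] <= self.rotation_range[1] <= 15:
            raise ValueError("rotation_range must lie in [1, 15]")


def _copy(frame: CircleFrame, amps: np.ndarray) -> CircleFrame:
    return CircleFrame(amps, ring_id=frame.ring_id, timestamp=frame.timestamp)


def rotate_channels(frame: CircleFrame, n: int) -> CircleFrame:
    """Rotate all channels (and corresponding receive events) clockwise by n.

    ``out[i, j] = in[(i + n) % 16, (j + n) % 16]``; a cyclic group action on
    both the transmit and receive axes simultaneously.
    """
    if not 0 <= n < 16:
        raise ValueError(f"rotation n must be in [0, 16), got {n}")
    idx = (np.arange(16) + n) % 16
    return _copy(frame, frame.amplitudes[np.ix_(idx, idx)].copy())


def blank_shots(frame: CircleFrame, which: "set[int] | list[int]") -> CircleFrame:
    """Zero entire transmission events (and their 16 receive lines)."""
    which = sorted(set(int(i) for i in which))
    if not 1 <= len(which) <= 8:
        raise ValueError(f"must blank between 1 and 8 shots, got {len(which)}")
    if any(i < 0 or i >= 16 for i in which):
        raise ValueError(f"shot indices must be in [0, 16), got {which}")
    out = frame.amplitudes.copy()
    out[which, :, :] = 0
    return _copy(frame, out)


def blank_channels(frame: CircleFrame, which: "set[int] | list[int]") -> CircleFrame:
    """Zero receiver channels across all transmit events."""
    which = sorted(set(int(i) for i in which))
    if not 1 <= len(which) <= 8:
        raise ValueError(f"must blank between 1 and 8 channels, got {len(which)}")
    if any(i < 0 or i >= 16 for i in which):
        raise ValueError(f"channel indices must be in [0, 16), got {which}")
    out = frame.amplitudes.copy()
    out[:, which, :] = 0
    return _copy(frame, out)


def blank_portions(
    frame: CircleFrame,
    portions: "list[tuple[int, int]] | None" = None,
    rng: np.random.Generator | None = None,
    config: AugmentConfig | None = None,
) -> CircleFrame:
    """Zero contiguous axial sample ranges across all (tx, rx) lines.

    Either pass explicit ``portions`` as half-open (start, stop) sample
    intervals, or let the policy draw them: count uniform in
    ``portion_count_range``, length uniform in ``portion_len_range``, start
    uniform over the line.  Portions running past the line end are clipped.
    """
    S = frame.amplitudes.shape[-1]
    if portions is None:
        if rng is None:
            raise ValueError("either portions or rng must be given")
        config = config or AugmentConfig()
        m = int(rng.integers(config.portion_count_range[0], config.portion_count_range[1] + 1))
        portions = []
        for _ in range(m):
            length = int(rng.integers(config.portion_len_range[0], config.portion_len_range[1] + 1))
            start = int(rng.integers(0, max(S - 1, 1)))
            portions.append((start, start + length))
    out = frame.amplitudes.copy()
    for start, stop in portions:
        if start < 0:
            raise ValueError("portion start must be >= 0")
        out[:, :, start:min(stop, S)] = 0
    return _copy(frame, out)


def shift_axial(frame: CircleFrame, delta: int, shift_max: int = 200) -> CircleFrame:
    """Shift every line by ``delta`` samples (positive = deeper / right).

    Vacated samples are zero-filled (no wrap): a physical depth change moves
    echoes, it does not re-inject them at the other end.
    """
    if abs(delta) > shift_max:
        raise ValueError(f"|delta| must be <= {shift_max}, got {delta}")
    amps = frame.amplitudes
    out = np.zeros_like(amps)
    if delta == 0:
        out[:] = amps
    elif delta > 0:
        out[..., delta:] = amps[..., :-delta]
    else:
        out[..., :delta] = amps[..., -delta:]
    return _copy(frame, out)


def apply_policy(
    frame: CircleFrame,
    config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    return_policy: bool = False,
):
    """Draw and apply one augmentation for a training example.

    First an independent coin decides channel rotation (n uniform in
    ``rotation_range``), then exactly one of the five blank/shift policies
    (or none) is drawn from ``policy_probs``.  Fully reproducible given the
    generator state.  With ``return_policy`` the drawn category name is
    returned alongside the frame.
    """
    config = config or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    out = frame
    if rng.random() < config.rotation_prob:
        n = int(rng.integers(config.rotation_range[0], config.rotation_range[1] + 1))
        out = rotate_channels(out, n)

    policy = POLICIES[int(rng.choice(len(POLICIES), p=config.policy_probs))]
    if policy == "blank_shots":
        k = int(rng.integers(config.blank_shots_range[0], config.blank_shots_range[1] + 1))
        out = blank_shots(out, rng.choice(16, size=k, replace=False))
    elif policy == "blank_channels":
        k = int(rng.integers(config.blank_channels_range[0], config.blank_channels_range[1] + 1))
        out = blank_channels(out, rng.choice(16, size=k, replace=False))
    elif policy == "blank_portions":
        out = blank_portions(out, rng=rng, config=config)
    elif policy == "shift_left":
        out = shift_axial(out, -int(rng.integers(1, config.shift_max + 1)), config.shift_max)
    elif policy == "shift_right":
        out = shift_axial(out, int(rng.integers(1, config.shift_max + 1)), config.shift_max)
    elif out is frame:  # "none" and no rotation: still return a copy
        out = _copy(frame, frame.amplitudes.copy())
    return (out, policy) if return_policy else out
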