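"""Domain types and container I/O for multi-receive A-mode recordings.

The acquisition hardware fires each of the 32 single-element transducers in
turn while every transducer listens, producing one raw frame of shape
``32 tx x 32 rx x S`` per acquisition cycle.  The bracelet holds the 32
elements as two parallel rings of 16, so each raw frame is split into two
independent 16x16 ring frames (the cross-ring blocks are discarded).

Recordings are stored in a simple HDF5 layout (group ``/us`` with ``frames``
and ``timestamps``) together with per-session range-of-motion metadata, and
marker trajectories travel as plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

SPEC_VERSION = 1

#: Canonical marker order: wrist styloids, elbow epicondyles, hand, upper-arm cluster.
MARKER_NAMES = (
    "RSTY", "USTY", "MEPI", "LEPI", "MC3_HEAD", "PP3_HEAD",
    "UA1", "UA2", "UA3", "UA4",
)

VALID_SESSIONS = (1, 2)
VALID_POSITIONS = (1, 2, 3)
VALID_ROTATIONS = (0, 90, 180, 270)
VALID_VIDEO_SETS = ("wrist", "functional")
DOF_NAMES = ("flexion_extension", "radial_ulnar", "pronation_supination", "hand_open_close")


class FormatError(ValueError):
    """A container or CSV does not match the expected layout."""


class IntegrityError(ValueError):
    """Dataset-level consistency violation (e.g. duplicate recording ids)."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Static description of the acquisition chain.

    Defaults mirror the hardware: 50 MHz sampling over a 110 us listening
    window (5500 samples per line), the first 800 samples discarded (static
    artifacts and coupling-layer reverberation), a 0.4-1.6 MHz pass band
    around the 1 MHz transducers, axial decimation by 10 and 12-bit samples.
    """

    sampling_rate: float = 5.0e7
    window: float = 110e-6
    n_transducers_per_ring: int = 16
    n_rings: int = 2
    trim_samples: int = 800
    band: tuple[float, float] = (0.4e6, 1.6e6)
    decimation: int = 10
    cutoff_db: float = -50.0
    single_receive_cutoff_db: float = -40.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.trim_samples >= self.samples_per_line:
            raise ValueError(
                f"trim_samples={self.trim_samples} must be < samples per line "
                f"{self.samples_per_line}"
            )
        lo, hi = self.band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(f"band {self.band} must satisfy 0 < lo < hi < Nyquist")
        if (self.samples_per_line - self.trim_samples) % self.decimation:
            raise ValueError("decimation must divide the trimmed line length")

    @property
    def samples_per_line(self) -> int:
        """S — number of samples recorded per A-mode line."""
        return round(self.sampling_rate * self.window)

    @property
    def axial_pixels(self) -> int:
        """P — axial pixels after trim and decimation (470 under defaults)."""
        return (self.samples_per_line - self.trim_samples) // self.decimation

    @property
    def full_scale(self) -> float:
        """Reference amplitude for dB compression (signed full scale)."""
        return float(2 ** (self.bit_depth - 1))


@dataclass
class RawFrame:
    """One 32x32xS multi-receive acquisition cycle."""

    amplitudes: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes)
        if a.ndim != 3 or a.shape[0] != 32 or a.shape[1] != 32:
            raise ValueError(f"raw frame must be 32x32xS, got {a.shape}")
        self.amplitudes = a


@dataclass
class CircleFrame:
    """One ring's 16x16xS multi-receive frame."""

    amplitudes: np.ndarray
    ring_id: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes)
        if a.ndim != 3 or a.shape[0] != 16 or a.shape[1] != 16:
            raise ValueError(f"circle frame must be 16x16xS, got {a.shape}")
        if self.ring_id not in (0, 1):
            raise ValueError("ring_id must be 0 or 1")
        self.amplitudes = a


@dataclass(frozen=True)
class RecordingMeta:
    """Identity of one recording inside the factorial collection design."""

    participant_id: str
    session: int
    position: int
    rotation: int
    video_set: str
    rom: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session not in VALID_SESSIONS:
            raise ValueError(f"session must be one of {VALID_SESSIONS}")
        if self.position not in VALID_POSITIONS:
            raise ValueError(f"position must be one of {VALID_POSITIONS}")
        if self.rotation not in VALID_ROTATIONS:
            raise ValueError(f"rotation must be one of {VALID_ROTATIONS}")
        if self.video_set not in VALID_VIDEO_SETS:
            raise ValueError(f"video_set must be one of {VALID_VIDEO_SETS}")
        for dof, (lo, hi) in self.rom.items():
            if not hi > lo:
                raise ValueError(f"ROM for {dof} must have max > min, got ({lo}, {hi})")

    @property
    def recording_id(self) -> str:
        return (
            f"{self.participant_id}_s{self.session}_p{self.position}"
            f"_r{self.rotation}_{self.video_set}"
        )


@dataclass
class Recording:
    """An ordered frame sequence with its metadata and (optional) markers."""

    meta: RecordingMeta
    frames: list[CircleFrame]
    markers: "MarkerTrajectory | None" = None

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=np.float64)


@dataclass
class MarkerTrajectory:
    """10 named markers at 200 Hz; missing samples carried as a mask, never zeros."""

    positions: np.ndarray              # [T, 10, 3] mm
    missing_mask: np.ndarray           # [T, 10] True where missing
    rate: float = 200.0
    marker_names: tuple[str, ...] = MARKER_NAMES
    times: np.ndarray | None = None    # [T] seconds; defaults to arange/rate

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        T, M, D = self.positions.shape
        if (M, D) != (len(self.marker_names), 3):
            raise ValueError(f"positions must be [T x {len(self.marker_names)} x 3]")
        if self.missing_mask.shape != (T, M):
            raise ValueError("missing_mask must be [T x M]")
        if not np.isfinite(self.positions[~self.missing_mask]).all():
            raise ValueError("positions must be finite where not masked")
        if self.times is None:
            self.times = np.arange(T) / self.rate
        else:
            self.times = np.asarray(self.times, dtype=np.float64)

    def index_of(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError as exc:
            raise FormatError(f"unknown marker name {name!r}") from exc


@dataclass
class DatasetIndex:
    """One row per recording container; a full single-participant design has 48 rows."""

    rows: pd.DataFrame

    COLUMNS = (
        "recording_id", "participant_id", "session", "position",
        "rotation", "video_set", "n_frames", "path",
    )

    def __post_init__(self) -> None:
        if self.rows.empty:
            self.rows = pd.DataFrame(columns=list(self.COLUMNS))
        dup = self.rows["recording_id"].duplicated()
        if dup.any():
            raise IntegrityError(
                f"duplicate recording ids: {sorted(self.rows['recording_id'][dup])}"
            )

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Ring splitting


def ring_channel_map(n_channels: int = 32) -> np.ndarray:
    """Default ring membership of the 32 raw channels.

    Each 3D-printed holder carries one transducer of each ring, and holders
    fire in order, so consecutive global channels alternate rings: even
    global index -> ring 0, odd -> ring 1.  Containers may override this with
    an explicit ``channel_map`` attribute.
    """
    return np.arange(n_channels) % 2


def split_circles(
    frame: RawFrame, channel_map: np.ndarray | None = None
) -> tuple[CircleFrame, CircleFrame]:
    """Split a 32x32xS raw frame into the two 16x16xS ring frames.

    The two cross-ring 16x16 blocks (ring-0 transmit heard on ring-1
    receivers and vice versa) are discarded.
    """
    amps = frame.amplitudes
    cmap = ring_channel_map(amps.shape[0]) if channel_map is None else np.asarray(channel_map)
    if cmap.shape != (amps.shape[0],):
        raise ValueError("channel_map must have one entry per raw channel")
    out = []
    for ring in (0, 1):
        idx = np.flatnonzero(cmap == ring)
        if idx.size != 16:
            raise ValueError(f"channel_map must assign 16 channels to ring {ring}")
        sub = amps[np.ix_(idx, idx)]
        out.append(CircleFrame(sub, ring_id=ring, timestamp=frame.timestamp))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Recording container I/O (HDF5)


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a Recording to its HDF5 container. Round trip is bit-exact."""
    path = Path(path)
    frames = np.stack([f.amplitudes for f in recording.frames])
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.int16)
    ring_ids = {f.ring_id for f in recording.frames}
    if len(ring_ids) != 1:
        raise ValueError("a recording holds frames from exactly one ring")
    with h5py.File(path, "w") as h5:
        g = h5.create_group("us")
        g.create_dataset("frames", data=frames, chunks=(1,) + frames.shape[1:])
        g.create_dataset("timestamps", data=recording.timestamps)
        m = recording.meta
        g.attrs["participant_id"] = m.participant_id
        g.attrs["session"] = m.session
        g.attrs["position"] = m.position
        g.attrs["rotation_deg"] = m.rotation
        g.attrs["video_set"] = m.video_set
        g.attrs["ring_id"] = ring_ids.pop()
        g.attrs["channel_map"] = ring_channel_map()
        g.attrs["spec_version"] = SPEC_VERSION
        rom = h5.create_group("rom")
        for dof, (lo, hi) in m.rom.items():
            rom.create_dataset(dof, data=np.array([lo, hi], dtype=np.float64))
    return path


_REQUIRED_ATTRS = ("participant_id", "session", "position", "rotation_deg", "video_set")


def read_recording(path: str | Path) -> Recording:
    """Read a Recording container written by :func:`write_recording`."""
    with h5py.File(path, "r") as h5:
        if "us" not in h5:
            raise FormatError(f"{path}: missing group '/us'")
        g = h5["us"]
        version = g.attrs.get("spec_version")
        if version != SPEC_VERSION:
            raise FormatError(
                f"{path}: container spec_version {version!r} != supported {SPEC_VERSION}"
            )
        for attr in _REQUIRED_ATTRS:
            if attr not in g.attrs:
                raise FormatError(f"{path}: missing required attribute {attr!r}")
        rom = {}
        if "rom" in h5:
            for dof, ds in h5["rom"].items():
                lo, hi = np.asarray(ds)
                rom[dof] = (float(lo), float(hi))
        meta = RecordingMeta(
            participant_id=str(g.attrs["participant_id"]),
            session=int(g.attrs["session"]),
            position=int(g.attrs["position"]),
            rotation=int(g.attrs["rotation_deg"]),
            video_set=str(g.attrs["video_set"]),
            rom=rom,
        )
        frames_arr = np.asarray(g["frames"])
        ts = np.asarray(g["timestamps"])
        ring_id = int(g.attrs.get("ring_id", 0))
        frames = [
            CircleFrame(frames_arr[i], ring_id=ring_id, timestamp=float(ts[i]))
            for i in range(frames_arr.shape[0])
        ]
    return Recording(meta=meta, frames=frames)


def build_dataset_index(paths: Sequence[str | Path]) -> DatasetIndex:
    """Index a collection of recording containers (one row each)."""
    rows = []
    for p in paths:
        p = Path(p)
        with h5py.File(p, "r") as h5:
            if "us" not in h5:
                raise FormatError(f"{p}: missing group '/us'")
            g = h5["us"]
            for attr in _REQUIRED_ATTRS:
                if attr not in g.attrs:
                    raise FormatError(f"{p}: missing required attribute {attr!r}")
            meta = RecordingMeta(
                participant_id=str(g.attrs["participant_id"]),
                session=int(g.attrs["session"]),
                position=int(g.attrs["position"]),
                rotation=int(g.attrs["rotation_deg"]),
                video_set=str(g.attrs["video_set"]),
            )
            rows.append(
                dict(
                    recording_id=meta.recording_id,
                    participant_id=meta.participant_id,
                    session=meta.session,
                    position=meta.position,
                    rotation=meta.rotation,
                    video_set=meta.video_set,
                    n_frames=int(g["frames"].shape[0]),
                    path=str(p),
                )
            )
    df = pd.DataFrame(rows, columns=list(DatasetIndex.COLUMNS))
    return DatasetIndex(rows=df)


# ---------------------------------------------------------------------------
# Marker CSV I/O


def read_markers(path: str | Path, rate: float = 200.0) -> MarkerTrajectory:
    """Read a marker CSV (``time_s,RSTY_x,RSTY_y,RSTY_z,...`` in mm).

    Empty cells become masked entries.  Columns may arrive in any order; they
    are re-ordered to the canonical marker order.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    seen = {c.rsplit("_", 1)[0] for c in df.columns if c != "time_s"}
    unknown = seen - set(MARKER_NAMES)
    if unknown:
        raise FormatError(f"{path}: unknown marker name(s) {sorted(unknown)}")
    T = len(df)
    positions = np.full((T, len(MARKER_NAMES), 3), np.nan)
    for mi, name in enumerate(MARKER_NAMES):
        for di, ax in enumerate("xyz"):
            col = f"{name}_{ax}"
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
            positions[:, mi, di] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    missing = np.isnan(positions).any(axis=2)
    positions[missing] = 0.0  # placeholder under the mask
    return MarkerTrajectory(
        positions=positions,
        missing_mask=missing,
        rate=rate,
        times=df["time_s"].to_numpy(dtype=np.float64),
    )


def write_markers(traj: MarkerTrajectory, path: str | Path) -> Path:
    """Write a marker trajectory as CSV; masked cells become empty cells."""
    path = Path(path)
    data: dict[str, np.ndarray] = {"time_s": traj.times}
    for mi, name in enumerate(traj.marker_names):
        for di, ax in enumerate("xyz"):
            col = traj.positions[:, mi, di].astype(object)
            col[traj.missing_mask[:, mi]] = None
            data[f"{name}_{ax}"] = col
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def full_design(participant_id: str) -> list[RecordingMeta]:
    """The 48-cell factorial design (4 rotations x 3 positions x 2 sets x 2 sessions)."""
    metas = []
    for session in VALID_SESSIONS:
        for position in VALID_POSITIONS:
            for rotation in VALID_ROTATIONS:
                for video_set in VALID_VIDEO_SETS:
                    metas.append(
                        RecordingMeta(
                            participant_id=participant_id,
                            session=session,
                            position=position,
                            rotation=rotation,
                            video_set=video_set,
                        )
                    )
    assert len(metas) == 48
    return metas
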