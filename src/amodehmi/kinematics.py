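"""Marker gap-filling, plane-based wrist inverse kinematics, ROM
normalization, and ultrasound/mocap time alignment.

Four degrees of freedom are computed from the ten reflective markers:

* **flexion-extension (FE)** and **radial-ulnar deviation (RUD)** — relative
  orientation of the hand plane (radial styloid, ulnar styloid, third
  metacarpal head) with respect to the *non-rotating* forearm plane (radial
  styloid, styloid midpoint, epicondyle midpoint).  Because the styloids
  follow forearm pronation, this reference plane co-rotates with the radius
  and the decomposition is insensitive to pronation by construction.
* **pronation-supination (PS)** — the twist of the hand frame about the
  forearm long axis relative to the elbow-anchored forearm plane (medial
  epicondyle, lateral epicondyle, styloid midpoint), whose orientation does
  not follow the radius.
* **hand open-close (OC)** — the elevation of the proximal-phalanx segment
  (MC3_HEAD -> PP3_HEAD) out of the palm plane.

Sign conventions: flexion, ulnar deviation, pronation and hand closing are
positive; the neutral pose defines all zeros.  All angles are reported in
degrees.  The four upper-arm cluster markers are parsed but unused (in the
source protocol they only serve as manual gap-fill donors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .io_core import DOF_NAMES, MarkerTrajectory

#: Markers required by the inverse kinematics (upper-arm cluster excluded).
IK_MARKERS = ("RSTY", "USTY", "MEPI", "LEPI", "MC3_HEAD", "PP3_HEAD")

_COLLINEAR_TOL = 1e-8


@dataclass
class JointState:
    """Angles (deg) for the 4 DoFs, optionally with ROM-normalized activations."""

    theta: np.ndarray                 # [4] degrees, DOF_NAMES order
    activation: np.ndarray | None = None
    time: float = 0.0


@dataclass(frozen=True)
class SessionROM:
    """Per-DoF (theta_min, theta_max) in degrees, measured per session."""

    limits: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for dof in DOF_NAMES:
            if dof not in self.limits:
                raise ValueError(f"ROM missing DoF {dof!r}")
            lo, hi = self.limits[dof]
            if not hi > lo:
                raise ValueError(f"ROM for {dof} must have max > min")

    @property
    def mins(self) -> np.ndarray:
        return np.array([self.limits[d][0] for d in DOF_NAMES])

    @property
    def maxs(self) -> np.ndarray:
        return np.array([self.limits[d][1] for d in DOF_NAMES])


@dataclass(frozen=True)
class PlaneDef:
    """A named plane through three points, each a marker or a marker-pair midpoint."""

    name: str
    points: tuple[tuple[str, ...], ...]  # each entry: 1 marker or 2 (midpoint)

    def resolve(self, pos: dict[str, np.ndarray]) -> np.ndarray:
        pts = []
        for spec in self.points:
            p = np.mean([pos[m] for m in spec], axis=0)
            pts.append(p)
        return np.stack(pts)


HAND_PLANE = PlaneDef("hand", (("RSTY",), ("USTY",), ("MC3_HEAD",)))
FOREARM_PLANE_NONROTATING = PlaneDef(
    "forearm_nonrotating", (("RSTY",), ("RSTY", "USTY"), ("MEPI", "LEPI"))
)
FOREARM_PLANE_ELBOW = PlaneDef("forearm_elbow", (("MEPI",), ("LEPI",), ("RSTY", "USTY")))


# ---------------------------------------------------------------------------
# Gap filling


def fill_gaps(traj: MarkerTrajectory, max_gap: int = 20, n_support: int = 4) -> MarkerTrajectory:
    """Fill marker gaps shorter than ``max_gap`` samples with a cubic spline.

    Each gap is interpolated per coordinate from up to ``n_support`` valid
    samples on each side.  Gaps of ``max_gap`` samples or more, and gaps
    touching the sequence boundary (extrapolation), are left masked.
    """
    positions = traj.positions.copy()
    mask = traj.missing_mask.copy()
    T = positions.shape[0]
    for mi in range(positions.shape[1]):
        miss = mask[:, mi]
        if not miss.any():
            continue
        # enumerate contiguous gap runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], miss.astype(int), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= max_gap:
                continue
            if start == 0 or stop == T:
                continue  # boundary gap: cannot interpolate
            left = np.flatnonzero(~miss[:start])[-n_support:]
            right = stop + np.flatnonzero(~miss[stop:])[:n_support]
            if len(left) == 0 or len(right) == 0:
                continue
            support = np.concatenate([left, right])
            t_sup = traj.times[support]
            t_gap = traj.times[start:stop]
            for di in range(3):
                spline = CubicSpline(t_sup, positions[support, mi, di])
                positions[start:stop, mi, di] = spline(t_gap)
            mask[start:stop, mi] = False
    return MarkerTrajectory(
        positions=positions, missing_mask=mask, rate=traj.rate,
        marker_names=traj.marker_names, times=traj.times,
    )


# ---------------------------------------------------------------------------
# Frames from planes


def _frame_from_axis_pair(long_axis: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    """Right-handed frame with x = long axis and z = plane normal.

    ``lateral`` is any in-plane vector pointing to the radial/lateral side;
    z = unit(lateral x long), y = z x x.  Columns are the axes.
    """
    x = long_axis / np.linalg.norm(long_axis)
    zraw = np.cross(lateral, x)
    nz = np.linalg.norm(zraw)
    if nz < _COLLINEAR_TOL * np.linalg.norm(lateral):
        raise ValueError("plane points are collinear")
    z = zraw / nz
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def _marker_dict(traj: MarkerTrajectory, t: int) -> dict[str, np.ndarray]:
    return {name: traj.positions[t, traj.index_of(name)] for name in IK_MARKERS}


def _pose_angles(pos: dict[str, np.ndarray]) -> np.ndarray:
    """The four DoF angles (deg) for one marker snapshot."""
    wmid = 0.5 * (pos["RSTY"] + pos["USTY"])
    emid = 0.5 * (pos["MEPI"] + pos["LEPI"])
    long_axis = wmid - emid

    # elbow-anchored forearm frame: lateral = MEPI -> LEPI
    f_el = _frame_from_axis_pair(long_axis, pos["LEPI"] - pos["MEPI"])
    # non-rotating forearm frame: lateral = wrist midpoint -> RSTY (follows the radius)
    f_nr = _frame_from_axis_pair(long_axis, pos["RSTY"] - wmid)
    # hand frame: x = wrist midpoint -> MC3 head, lateral = styloid axis
    f_h = _frame_from_axis_pair(pos["MC3_HEAD"] - wmid, pos["RSTY"] - pos["USTY"])

    # FE/RUD: hand relative to the pronation-following forearm frame, flexion
    # about the radial-ulnar axis (local y) first, deviation about the palm
    # normal (rotated local z) second -> intrinsic Y-Z' extraction.
    r_wrist = f_nr.T @ f_h
    fe, rud, _ = Rotation.from_matrix(r_wrist).as_euler("YZX", degrees=True)

    # PS: twist about the forearm long axis (local x) of the hand frame
    # relative to the elbow-anchored frame (intrinsic X-Y'-Z'' extraction);
    # equals the hand/elbow plane dihedral when FE = RUD = 0.
    r_el = f_el.T @ f_h
    ps = Rotation.from_matrix(r_el).as_euler("XYZ", degrees=True)[0]

    # OC: elevation of the proximal phalanx out of the palm plane (positive
    # towards the palm side = closing).
    seg = pos["PP3_HEAD"] - pos["MC3_HEAD"]
    seg = seg / np.linalg.norm(seg)
    palm_normal = f_h[:, 2]
    oc = np.degrees(np.arcsin(np.clip(-seg @ palm_normal, -1.0, 1.0)))

    return np.array([fe, rud, ps, oc])


def compute_joint_angles(traj: MarkerTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame joint angles from a marker trajectory.

    Returns ``(theta, valid)`` where ``theta`` is [T x 4] degrees in
    :data:`~amodehmi.io_core.DOF_NAMES` order and ``valid`` marks frames
    where every required marker was present and the planes well-posed.
    """
    T = traj.positions.shape[0]
    theta = np.full((T, 4), np.nan)
    valid = np.zeros(T, dtype=bool)
    ik_idx = [traj.index_of(m) for m in IK_MARKERS]
    frame_ok = ~traj.missing_mask[:, ik_idx].any(axis=1)
    for t in np.flatnonzero(frame_ok):
        try:
            theta[t] = _pose_angles(_marker_dict(traj, t))
        except ValueError:
            warnings.warn(f"degenerate marker geometry at frame {t}; output masked")
            continue
        valid[t] = True
    return theta, valid


# ---------------------------------------------------------------------------
# ROM normalization


def normalize_rom(theta: np.ndarray, rom: SessionROM) -> np.ndarray:
    """Map angles (deg) to activations ``(theta - min) / (max - min)``, clipped to [0, 1]."""
    theta = np.asarray(theta, dtype=np.float64)
    act = (theta - rom.mins) / (rom.maxs - rom.mins)
    return np.clip(act, 0.0, 1.0)


def denormalize_rom(activation: np.ndarray, rom: SessionROM) -> np.ndarray:
    """Inverse of :func:`normalize_rom` on the interior of the ROM."""
    activation = np.asarray(activation, dtype=np.float64)
    return activation * (rom.maxs - rom.mins) + rom.mins


def activation_to_vr(activation: np.ndarray) -> np.ndarray:
    """Map [0, 1] activations to the [-1, 1] range used by VR control targets."""
    return 2.0 * np.asarray(activation) - 1.0


# ---------------------------------------------------------------------------
# Stream alignment


def align_streams(
    us_timestamps: np.ndarray,
    mocap_rate: float = 200.0,
    t0: float = 0.0,
    mocap_n: int | None = None,
) -> np.ndarray:
    """Pair each ultrasound frame with the nearest-in-time mocap sample.

    Both streams share a hardware start trigger at ``t0``.  Returns, per US
    frame, the mocap sample index, or -1 for frames beyond the mocap extent
    (those are dropped with a warning).  The pairing error is at most half a
    mocap period (2.5 ms at 200 Hz).
    """
    us_timestamps = np.asarray(us_timestamps, dtype=np.float64)
    idx = np.round((us_timestamps - t0) * mocap_rate).astype(int)
    idx[idx < 0] = -1
    if mocap_n is not None:
        over = idx >= mocap_n
        if over.any():
            warnings.warn(f"dropping {int(over.sum())} US frame(s) beyond the mocap extent")
        idx[over] = -1
    return idx
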