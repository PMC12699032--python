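"""Cross-validation splits, neutral-pose referencing, and evaluation metrics.

Six cross-validation groups probe increasingly severe domain shifts:

* ``SameSet`` — within every recording, the first 70% of frames train and
  the last 30% test (the only group that splits individual recordings);
* ``Functional`` — train on the wrist video set, test on the functional set;
* ``Position`` — leave one of the three bracelet positions out (3 folds);
* ``Rotation`` — leave one of the four bracelet rotations out (4 folds);
* ``Session`` — leave one of the two sessions out (2 folds);
* ``Participant`` — leave one or more participants out (config-driven).

Metrics are computed per recording and per DoF: out-of-sample R², RMSE in
degrees (after ROM denormalization of both streams), and Pearson CC; medians
are reported across recordings because a few strongly negative R² outliers
dominate a mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .imaging import NormalizedSample
from .io_core import DOF_NAMES, DatasetIndex
from .kinematics import SessionROM, denormalize_rom

GROUPS = ("SameSet", "Functional", "Position", "Rotation", "Session", "Participant")

TRAIN_FRACTION = 0.7  # SameSet chronological boundary


@dataclass(frozen=True)
class FrameRange:
    """A contiguous chronological frame range of one recording."""

    recording_id: str
    start: int
    stop: int


@dataclass
class Fold:
    train: list
    test: list


@dataclass
class SplitSpec:
    group: str
    folds: list[Fold]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


class DesignError(ValueError):
    """The index is missing design cells required by the requested group."""


def _require_levels(index: DatasetIndex, column: str, levels) -> None:
    present = set(index.rows[column].unique())
    missing = [lv for lv in levels if lv not in present]
    if missing:
        raise DesignError(f"index is missing {column} level(s) {missing}")


def make_splits(
    index: DatasetIndex,
    group: str,
    held_out_participants: "list[list[str]] | None" = None,
) -> SplitSpec:
    """Build the fold structure for one cross-validation group.

    All folds partition recordings except ``SameSet`` (frame-level) and
    ``Functional``/``Participant`` (coverage asymmetric by design).  For
    ``Participant``, pass the held-out participant list per fold.
    """
    rows = index.rows
    if group == "SameSet":
        folds = [Fold(train=[], test=[])]
        for _, r in rows.iterrows():
            boundary = int(np.floor(TRAIN_FRACTION * r.n_frames))
            folds[0].train.append(FrameRange(r.recording_id, 0, boundary))
            folds[0].test.append(FrameRange(r.recording_id, boundary, int(r.n_frames)))
        return SplitSpec(group=group, folds=folds)

    if group == "Functional":
        _require_levels(index, "video_set", ("wrist", "functional"))
        train = list(rows.loc[rows.video_set == "wrist", "recording_id"])
        test = list(rows.loc[rows.video_set == "functional", "recording_id"])
        return SplitSpec(group=group, folds=[Fold(train=train, test=test)])

    leave_one_out = {"Position": ("position", (1, 2, 3)),
                     "Rotation": ("rotation", (0, 90, 180, 270)),
                     "Session": ("session", (1, 2))}
    if group in leave_one_out:
        column, levels = leave_one_out[group]
        _require_levels(index, column, levels)
        folds = []
        for held in levels:
            train = list(rows.loc[rows[column] != held, "recording_id"])
            test = list(rows.loc[rows[column] == held, "recording_id"])
            folds.append(Fold(train=train, test=test))
        return SplitSpec(group=group, folds=folds)

    if group == "Participant":
        if not held_out_participants:
            raise ValueError("Participant group needs held_out_participants per fold")
        all_p = set(rows.participant_id.unique())
        folds = []
        for held in held_out_participants:
            missing = set(held) - all_p
            if missing:
                raise DesignError(f"index is missing participant(s) {sorted(missing)}")
            train = list(rows.loc[~rows.participant_id.isin(held), "recording_id"])
            test = list(rows.loc[rows.participant_id.isin(held), "recording_id"])
            folds.append(Fold(train=train, test=test))
        return SplitSpec(group=group, folds=folds)

    raise ValueError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# Neutral referencing

NEUTRAL_WINDOW_S = 2.0  # every recording starts with >= 2 s of rest


class NoNeutralFrameError(RuntimeError):
    pass


def pick_reference_index(
    timestamps: np.ndarray,
    mode: str = "train",
    rng: np.random.Generator | None = None,
) -> int:
    """Index of the neutral reference frame for one recording.

    Train mode draws uniformly among frames inside the first 2 s of the
    recording (the rest period before the first movement); inference mode
    uses the first frame, standing in for the single neutral frame captured
    once per session.
    """
    timestamps = np.asarray(timestamps)
    candidates = np.flatnonzero(timestamps < NEUTRAL_WINDOW_S)
    if candidates.size == 0:
        raise NoNeutralFrameError(
            "no frame inside the first 2 s; capture a neutral frame before use"
        )
    if mode == "inference":
        return int(candidates[0])
    if mode != "train":
        raise ValueError("mode must be 'train' or 'inference'")
    if rng is None:
        raise ValueError("train mode requires an rng")
    return int(rng.choice(candidates))


def pair_with_reference(
    target: NormalizedSample, reference: NormalizedSample
) -> NormalizedSample:
    """Stack reference (channel 0) and target (channel 1) into one sample.

    Both must come through the identical imaging pipeline (same stats).
    """
    if target.stats_id != reference.stats_id:
        raise ValueError("reference and target must share normalization stats")
    return NormalizedSample(
        tensor=np.concatenate([reference.tensor, target.tensor], axis=0),
        stats_id=target.stats_id,
    )


# ---------------------------------------------------------------------------
# Metrics


def r_squared(truth: np.ndarray, pred: np.ndarray) -> float:
    """Out-of-sample coefficient of determination (range -inf..1; 0 = mean
    predictor)."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    ss_res = float(np.sum((truth - pred) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def score_recording(
    pred_act: np.ndarray,
    truth_act: np.ndarray,
    rom: SessionROM,
    recording_id: str = "",
) -> pd.DataFrame:
    """Per-DoF metrics for one recording.

    ``pred_act`` and ``truth_act`` are [N x 4] ROM-normalized activations;
    RMSE is computed in degrees after denormalizing both streams with the
    session ROM.  DoFs with zero truth variance get NaN R²/CC with a warning.
    """
    pred_act = np.atleast_2d(np.asarray(pred_act, dtype=np.float64))
    truth_act = np.atleast_2d(np.asarray(truth_act, dtype=np.float64))
    if pred_act.shape != truth_act.shape or pred_act.shape[0] < 2:
        raise ValueError("pred and truth must share shape [N>=2 x 4]")
    pred_deg = denormalize_rom(pred_act, rom)
    truth_deg = denormalize_rom(truth_act, rom)
    rows = []
    for d, dof in enumerate(DOF_NAMES):
        rmse = float(np.sqrt(np.mean((pred_deg[:, d] - truth_deg[:, d]) ** 2)))
        if np.var(truth_act[:, d]) == 0.0:
            import warnings

            warnings.warn(f"zero truth variance for {dof}; R2/CC undefined")
            r2 = cc = np.nan
        else:
            r2 = r_squared(truth_act[:, d], pred_act[:, d])
            if (pred_act[:, d] == pred_act[0, d]).all():
                cc = np.nan  # constant prediction: correlation undefined
            else:
                cc = float(pearsonr(truth_act[:, d], pred_act[:, d]).statistic)
        rows.append(dict(recording_id=recording_id, dof=dof, r2=r2,
                         rmse_deg=rmse, cc=cc))
    return pd.DataFrame(rows)


def compare_models(metric_a, metric_b, paired: bool = True) -> dict:
    """Thin wrapper over the standard two-model significance tests.

    Paired per-recording metrics use the Wilcoxon signed-rank test; unpaired
    collections use Mann-Whitney U.  Two-sided p-value; no re-derivation.
    """
    from scipy.stats import mannwhitneyu, wilcoxon

    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs equal-length metrics")
        stat, p = wilcoxon(a, b)
        test = "wilcoxon"
    else:
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitneyu"
    return {"test": test, "statistic": float(stat), "p_value": float(p)}


def summarize(reports: "list[pd.DataFrame] | pd.DataFrame") -> pd.DataFrame:
    """Median of each metric per DoF across recordings."""
    if isinstance(reports, list):
        if not reports:
            raise ValueError("no reports to summarize")
        reports = pd.concat(reports, ignore_index=True)
    if reports.empty:
        raise ValueError("no reports to summarize")
    return reports.groupby("dof", sort=False)[["r2", "rmse_deg", "cc"]].median()
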