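"""End-to-end desk-scale studies on synthetic data.

These workflows wire the full stack together — phantom simulation, envelope
imaging, chronological SameSet splitting, neutral referencing, CNN training
and per-recording scoring — at sizes that run on a single CPU in minutes.
They back both the test suite and ``scripts/acceptance.py``.

Desk-scale training configuration: the compact CNN trains from random
initialization (no pretraining), so the study runs use a 3e-3 peak learning
rate over 10 epochs; the schedule shape (2-epoch ramp, linear decay to 1% of
peak) matches the full-scale contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import (
    TRAIN_FRACTION,
    pick_reference_index,
    score_recording,
    summarize,
)
from .imaging import (
    AcquisitionConfig,
    assemble_mosaic,
    compute_norm_stats,
    form_multireceive_images,
    prepare_image,
    preprocess_lines,
)
from .io_core import DOF_NAMES, Recording, RecordingMeta
from .kinematics import SessionROM
from .regressor import ModelConfig, build_model, predict, train
from .synthesis import DEFAULT_ROM, Protocol, default_phantom, generate_recording

DESK_LR = 3e-3
DESK_EPOCHS = 10


@dataclass
class PreparedRecording:
    """A recording reduced to pre-z-score [0, 1] images + frame activations.

    Raw frames are streamed through the imaging chain and discarded, so a
    prepared recording is ~40x smaller than its raw counterpart.
    """

    meta: RecordingMeta
    timestamps: np.ndarray   # [n_frames] seconds
    images: np.ndarray       # [n_frames x 128 x 128], pixel value / 255
    activations: np.ndarray  # [n_frames x 4]

    @property
    def n_frames(self) -> int:
        return len(self.images)


def frame_image(frame, config: AcquisitionConfig, dtype=np.float32) -> np.ndarray:
    """One frame's multi-receive image on the [0, 1] scale."""
    env = preprocess_lines(frame, config, dtype=dtype)
    mosaic = assemble_mosaic(form_multireceive_images(env))
    return (prepare_image(mosaic, cutoff_db=config.cutoff_db) / 255.0).astype(np.float32)


def recording_images(rec: Recording, config: AcquisitionConfig | None = None) -> np.ndarray:
    """Multi-receive image stack for every frame, scaled to [0, 1]."""
    config = config or AcquisitionConfig()
    return np.stack([frame_image(f, config) for f in rec.frames])


def prepare_participant(
    participant_id: str,
    seed: int,
    n_recordings: int = 4,
    duration_s: float = 40.0,
    noise_std: float = 20.0,
    config: AcquisitionConfig | None = None,
) -> list[PreparedRecording]:
    """Simulate + preprocess one participant's recordings (position 1,
    rotation 0, alternating wrist/functional video sets)."""
    config = config or AcquisitionConfig()
    phantom = default_phantom(morphology_seed=seed, noise_std=noise_std)
    out = []
    for i in range(n_recordings):
        video_set = "wrist" if i % 2 == 0 else "functional"
        meta = RecordingMeta(
            participant_id=participant_id, session=1, position=1, rotation=0,
            video_set=video_set, rom=dict(DEFAULT_ROM),
        )
        rng = np.random.default_rng((seed, 104729 + i))
        images: list[np.ndarray] = []
        timestamps: list[float] = []

        def sink(frame):
            images.append(frame_image(frame, config))
            timestamps.append(frame.timestamp)

        rec, act = generate_recording(
            phantom, Protocol(video_set=video_set, duration_s=duration_s), meta, rng,
            config=config, frame_sink=sink,
        )
        out.append(PreparedRecording(rec.meta, np.asarray(timestamps),
                                     np.stack(images), act))
    return out


def _sameset_boundaries(prep: list[PreparedRecording]) -> list[int]:
    return [int(np.floor(TRAIN_FRACTION * p.n_frames)) for p in prep]


def _assemble(
    prep: list[PreparedRecording],
    stats,
    referenced: bool,
    rng: np.random.Generator | None,
    frame_sel: "list[np.ndarray]",
    mode: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score and stack selected frames (optionally with a neutral-reference
    channel drawn from each recording's first 2 s)."""
    xs, ys = [], []
    for p, sel in zip(prep, frame_sel):
        z = ((p.images[sel] - stats.mean) / stats.std)[:, None]
        if referenced:
            ts = p.timestamps
            if mode == "train":
                ref_idx = np.array([pick_reference_index(ts, "train", rng) for _ in sel])
            else:
                ref_idx = np.full(len(sel), pick_reference_index(ts, "inference"))
            ref = ((p.images[ref_idx] - stats.mean) / stats.std)[:, None]
            z = np.concatenate([ref, z], axis=1)
        xs.append(z)
        ys.append(p.activations[sel])
    return np.concatenate(xs).astype(np.float32), np.concatenate(ys).astype(np.float32)


def sameset_recovery(
    seed: int = 0,
    n_recordings: int = 4,
    duration_s: float = 40.0,
    model_seeds: tuple[int, ...] = (0, 1, 2),
    epochs: int = DESK_EPOCHS,
    lr: float = DESK_LR,
    prep: "list[PreparedRecording] | None" = None,
) -> dict:
    """Parameter-recovery study: train on the first 70% of each recording's
    frames, test on the last 30%, repeat over model seeds.

    Returns per-DoF held-out R² (median across recordings, then across
    seeds) plus bookkeeping (sample count, per-seed tables).
    """
    if prep is None:
        prep = prepare_participant("SYN", seed, n_recordings, duration_s)
    rom = SessionROM(dict(DEFAULT_ROM))
    bounds = _sameset_boundaries(prep)
    train_sel = [np.arange(b) for b in bounds]
    test_sel = [np.arange(b, p.n_frames) for b, p in zip(bounds, prep)]
    stats = compute_norm_stats(
        (p.images[s] for p, s in zip(prep, train_sel)), source_split="sameset-train"
    )
    x_tr, y_tr = _assemble(prep, stats, False, None, train_sel)
    per_seed = []
    for ms in model_seeds:
        config = ModelConfig(in_channels=1, lr=lr, epochs=epochs, seed=ms)
        model = build_model(config)
        model, history = train(model, x_tr, y_tr, config)
        reports = []
        for p, sel in zip(prep, test_sel):
            x_te, y_te = _assemble([p], stats, False, None, [sel])
            pred = predict(model, x_te)
            reports.append(score_recording(pred, y_te, rom,
                                           recording_id=p.meta.recording_id))
        per_seed.append(summarize(reports))
    r2 = {dof: float(np.median([tbl.loc[dof, "r2"] for tbl in per_seed]))
          for dof in DOF_NAMES}
    rmse = {dof: float(np.median([tbl.loc[dof, "rmse_deg"] for tbl in per_seed]))
            for dof in DOF_NAMES}
    return {
        "r2": r2,
        "rmse_deg": rmse,
        "n_samples": int(sum(p.n_frames for p in prep)),
        "per_seed": per_seed,
        "last_model": model,
        "last_config": config,
        "stats": stats,
    }


def _neutral_pools(prep: "list[PreparedRecording]", stats) -> list[np.ndarray]:
    """Per recording, the z-scored images inside the 2 s neutral window."""
    pools = []
    for p in prep:
        idx = np.flatnonzero(p.timestamps < 2.0)
        pools.append(((p.images[idx] - stats.mean) / stats.std).astype(np.float32))
    return pools


def referencing_comparison(
    seed: int = 0,
    n_train_participants: int = 6,
    n_test_participants: int = 3,
    duration_s: float = 12.0,
    test_duration_s: float = 10.0,
    epochs: int = DESK_EPOCHS,
    lr: float = DESK_LR,
    model_seeds: tuple[int, ...] = (0, 1),
) -> dict:
    """Unseen-morphology study: train 1- and 2-channel models on several
    participants, test both on fresh phantoms, compare median held-out R².

    The 2-channel model's reference channel is redrawn every epoch from the
    source recording's neutral window (as at full scale, where each training
    example pairs with a random neutral frame), so the model must learn the
    reference-relative mapping rather than one fixed reference image.  At
    inference a single fixed neutral frame per recording is used, mirroring
    a new user calibrating once per session.  Medians are taken over test
    recordings, DoFs and model seeds; the claim evaluated is directional.
    """
    rom = SessionROM(dict(DEFAULT_ROM))
    train_prep: list[PreparedRecording] = []
    for pi in range(n_train_participants):
        train_prep += prepare_participant(
            f"T{pi}", seed=1000 * (seed + 1) + pi, n_recordings=2, duration_s=duration_s
        )
    test_prep: list[PreparedRecording] = []
    for ui in range(n_test_participants):
        test_prep += prepare_participant(
            f"U{ui}", seed=777_000 + 100 * seed + ui, n_recordings=2,
            duration_s=test_duration_s,
        )
    stats = compute_norm_stats((p.images for p in train_prep), source_split="xpart-train")
    all_tr = [np.arange(p.n_frames) for p in train_prep]
    all_te = [np.arange(p.n_frames) for p in test_prep]
    pools = _neutral_pools(train_prep, stats)
    rec_of_sample = np.concatenate(
        [np.full(p.n_frames, ri) for ri, p in enumerate(train_prep)])

    def redraw_references(xb, rng, idx):
        for row, i in enumerate(idx):
            pool = pools[rec_of_sample[i]]
            xb[row, 0] = pool[rng.integers(len(pool))]
        return xb

    r2_medians = {}
    for referenced in (False, True):
        rng = np.random.default_rng((seed, 42, int(referenced)))
        x_tr, y_tr = _assemble(train_prep, stats, referenced, rng, all_tr, mode="train")
        r2s = []
        for ms in model_seeds:
            config = ModelConfig(in_channels=2 if referenced else 1, lr=lr,
                                 epochs=epochs, seed=ms)
            model = build_model(config)
            model, _ = train(model, x_tr, y_tr, config,
                             augment_fn=redraw_references if referenced else None)
            for p, sel in zip(test_prep, all_te):
                x_te, y_te = _assemble([p], stats, referenced, None, [sel],
                                       mode="inference")
                pred = predict(model, x_te)
                rep = score_recording(pred, y_te, rom,
                                      recording_id=p.meta.recording_id)
                r2s.extend(rep["r2"].tolist())
        r2_medians[referenced] = float(np.median(r2s))
    return {
        "r2_unreferenced": r2_medians[False],
        "r2_referenced": r2_medians[True],
        "delta": r2_medians[True] - r2_medians[False],
        "n_train": int(sum(p.n_frames for p in train_prep)),
        "n_test": int(sum(p.n_frames for p in test_prep)),
    }
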