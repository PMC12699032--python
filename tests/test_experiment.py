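"""Cross-validation splits, neutral referencing, and metrics."""

import numpy as np
import pandas as pd
import pytest

from amodehmi.experiment import (
    DesignError,
    FrameRange,
    NoNeutralFrameError,
    make_splits,
    pair_with_reference,
    pick_reference_index,
    r_squared,
    score_recording,
    summarize,
)
from amodehmi.imaging import NormalizedSample
from amodehmi.io_core import DOF_NAMES, DatasetIndex, full_design
from amodehmi.kinematics import SessionROM


def design_index(participants=("P01",), n_frames=100) -> DatasetIndex:
    rows = []
    for pid in participants:
        for meta in full_design(pid):
            rows.append(dict(
                recording_id=meta.recording_id, participant_id=pid,
                session=meta.session, position=meta.position,
                rotation=meta.rotation, video_set=meta.video_set,
                n_frames=n_frames, path=""))
    return DatasetIndex(rows=pd.DataFrame(rows))


class TestMakeSplits:
    def test_rotation_four_folds_36_12(self):
        spec = make_splits(design_index(), "Rotation")
        assert len(spec.folds) == 4
        for fold in spec.folds:
            assert len(fold.train) == 36
            assert len(fold.test) == 12
            assert not set(fold.train) & set(fold.test)
            assert len(set(fold.train) | set(fold.test)) == 48

    def test_position_three_folds(self):
        spec = make_splits(design_index(), "Position")
        assert len(spec.folds) == 3
        for fold in spec.folds:
            assert len(fold.train) == 32 and len(fold.test) == 16

    def test_session_two_folds(self):
        spec = make_splits(design_index(), "Session")
        assert len(spec.folds) == 2
        for fold in spec.folds:
            assert len(fold.train) == len(fold.test) == 24

    def test_functional_trains_on_wrist(self):
        spec = make_splits(design_index(), "Functional")
        (fold,) = spec.folds
        assert len(fold.train) == len(fold.test) == 24
        assert all("wrist" in rid for rid in fold.train)
        assert all("functional" in rid for rid in fold.test)

    def test_sameset_70_30_boundary(self):
        spec = make_splits(design_index(n_frames=100), "SameSet")
        (fold,) = spec.folds
        by_id = {fr.recording_id: fr for fr in fold.train}
        for fr in fold.train:
            assert isinstance(fr, FrameRange)
            assert (fr.start, fr.stop) == (0, 70)
        for fr in fold.test:
            assert (fr.start, fr.stop) == (70, 100)
            assert fr.recording_id in by_id  # every recording contributes both

    def test_sameset_floor_on_odd_counts(self):
        spec = make_splits(design_index(n_frames=101), "SameSet")
        (fold,) = spec.folds
        assert all(fr.stop == 70 for fr in fold.train)  # floor(0.7 * 101)

    def test_participant_group_folds(self):
        idx = design_index(("P01", "P02", "P03"))
        spec = make_splits(idx, "Participant",
                           held_out_participants=[["P01"], ["P02", "P03"]])
        assert len(spec.folds) == 2
        assert len(spec.folds[0].test) == 48
        assert len(spec.folds[1].train) == 48

    def test_missing_design_cell_reported(self):
        idx = design_index()
        idx.rows = idx.rows[idx.rows.rotation != 180]
        with pytest.raises(DesignError, match="rotation"):
            make_splits(idx, "Rotation")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            make_splits(design_index(), "Nope")


class TestReferencing:
    def test_reference_within_first_two_seconds(self, rng):
        ts = np.arange(120) / 11.8
        for _ in range(50):
            idx = pick_reference_index(ts, "train", rng)
            assert ts[idx] < 2.0
            assert idx < 24  # 2 s x 11.8 Hz bound

    def test_inference_mode_fixed(self):
        ts = np.arange(50) / 11.8
        assert pick_reference_index(ts, "inference") == 0

    def test_seeded_draw_reproducible(self):
        ts = np.arange(120) / 11.8
        a = pick_reference_index(ts, "train", np.random.default_rng(5))
        b = pick_reference_index(ts, "train", np.random.default_rng(5))
        assert a == b

    def test_no_neutral_frame_errors(self):
        ts = 2.0 + np.arange(10) / 11.8
        with pytest.raises(NoNeutralFrameError):
            pick_reference_index(ts, "train", np.random.default_rng(0))

    def test_pairing_stacks_channels(self, rng):
        img = rng.normal(size=(1, 128, 128))
        target = NormalizedSample(tensor=img, stats_id="train")
        ref = NormalizedSample(tensor=img * 0 + 1.0, stats_id="train")
        pair = pair_with_reference(target, ref)
        assert pair.tensor.shape == (2, 128, 128)
        assert np.array_equal(pair.tensor[0], ref.tensor[0])
        assert np.array_equal(pair.tensor[1], target.tensor[0])

    def test_identical_target_and_reference(self, rng):
        img = rng.normal(size=(1, 128, 128))
        s = NormalizedSample(tensor=img, stats_id="x")
        pair = pair_with_reference(s, s)
        assert np.array_equal(pair.tensor[0], pair.tensor[1])

    def test_mismatched_stats_rejected(self, rng):
        a = NormalizedSample(tensor=rng.normal(size=(1, 128, 128)), stats_id="a")
        b = NormalizedSample(tensor=rng.normal(size=(1, 128, 128)), stats_id="b")
        with pytest.raises(ValueError):
            pair_with_reference(a, b)


@pytest.fixture()
def unit_rom():
    return SessionROM({dof: (0.0, 100.0) for dof in DOF_NAMES})


class TestMetrics:
    def test_perfect_prediction(self, unit_rom, rng):
        truth = rng.uniform(size=(50, 4))
        rep = score_recording(truth, truth, unit_rom)
        assert np.allclose(rep.r2, 1.0)
        assert np.allclose(rep.rmse_deg, 0.0)
        assert np.allclose(rep.cc, 1.0)

    def test_mean_predictor_gives_zero_r2(self, unit_rom, rng):
        truth = rng.uniform(size=(50, 4))
        pred = np.tile(truth.mean(axis=0), (50, 1))
        rep = score_recording(pred, truth, unit_rom)
        assert np.allclose(rep.r2, 0.0, atol=1e-12)

    def test_rmse_closed_form_in_degrees(self, unit_rom):
        truth = np.tile(np.array([0.0, 0.5, 1.0])[:, None], (1, 4))
        pred = np.tile(np.array([0.1, 0.5, 0.9])[:, None], (1, 4))
        rep = score_recording(pred, truth, unit_rom)
        expected = np.sqrt((10.0 ** 2 + 0 + 10.0 ** 2) / 3)
        assert np.allclose(rep.rmse_deg, expected)

    def test_rmse_scales_with_rom_span(self, rng):
        """RMSE in degrees equals activation RMSE times (max - min)."""
        truth = rng.uniform(size=(40, 4))
        pred = truth + rng.normal(0, 0.05, size=(40, 4))
        rom_wide = SessionROM({dof: (-50.0, 150.0) for dof in DOF_NAMES})
        rep = score_recording(pred, truth, rom_wide)
        act_rmse = np.sqrt(np.mean((pred - truth) ** 2, axis=0))
        assert np.allclose(rep.rmse_deg, act_rmse * 200.0)

    def test_zero_truth_variance_masked(self, unit_rom):
        truth = np.full((10, 4), 0.5)
        pred = np.random.default_rng(0).uniform(size=(10, 4))
        with pytest.warns(UserWarning, match="variance"):
            rep = score_recording(pred, truth, unit_rom)
        assert rep.r2.isna().all()

    def test_r2_upper_bound_and_affine_invariance(self, rng):
        truth = rng.uniform(size=200)
        pred = truth + rng.normal(0, 0.3, size=200)
        r2 = r_squared(truth, pred)
        assert r2 <= 1.0
        # identical affine map applied to both streams leaves R2 unchanged
        assert np.isclose(r_squared(3 * truth - 1, 3 * pred - 1), r2)

    def test_cc_invariant_to_positive_affine(self, unit_rom, rng):
        truth = rng.uniform(size=(60, 4))
        pred = truth + rng.normal(0, 0.1, size=(60, 4))
        base = score_recording(pred, truth, unit_rom).cc
        scaled = score_recording(0.2 * pred + 0.4, truth, unit_rom).cc
        assert np.allclose(scaled, base, atol=1e-12)


class TestSummarize:
    @staticmethod
    def _report(r2_values):
        rows = []
        for i, v in enumerate(r2_values):
            for dof in DOF_NAMES:
                rows.append(dict(recording_id=f"r{i}", dof=dof, r2=v,
                                 rmse_deg=1.0, cc=v))
        return pd.DataFrame(rows)

    def test_single_report_is_its_own_median(self):
        rep = self._report([0.7])
        med = summarize([rep])
        assert np.allclose(med["r2"], 0.7)

    def test_median_of_three(self):
        med = summarize([self._report([0.2, 0.9, 0.5])])
        assert np.allclose(med["r2"], 0.5)

    def test_median_robust_to_outlier(self):
        values = [0.8, 0.85, 0.9, -100.0]
        med = summarize([self._report(values)])
        assert np.allclose(med["r2"], 0.825)
        assert np.mean(values) < 0  # the mean would be dominated

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestCompareModels:
    def test_paired_wilcoxon_detects_shift(self, rng):
        from amodehmi.experiment import compare_models

        a = rng.uniform(0.5, 0.9, size=30)
        b = a + 0.1
        res = compare_models(a, b, paired=True)
        assert res["test"] == "wilcoxon"
        assert res["p_value"] < 0.01

    def test_unpaired_mannwhitney(self, rng):
        from amodehmi.experiment import compare_models

        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(0.1, 1.0, size=35)
        res = compare_models(a, b, paired=False)
        assert res["test"] == "mannwhitneyu"
        assert 0.0 <= res["p_value"] <= 1.0
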