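"""Epoch cutting, tensor layout, labels and the good/poor recall rule."""

import numpy as np
import pytest

from burstdecode import simulate as sim
from burstdecode import tensorize as tz

FS = 20.0


def _rows(schedule, n_rows):
    n = int((schedule.end_s + 2.0) * FS)
    rng = np.random.default_rng(0)
    return rng.random((n_rows, n)), n


class TestEncodingEpochs:
    def test_one_tensor_per_word(self):
        sched = sim.generate_schedule(20, seed=0)
        rows, _ = _rows(sched, 6)
        recalled = np.zeros(240, dtype=bool)
        recalled[::3] = True
        ds = tz.extract_encoding_epochs(sched, recalled, rows, FS)
        assert len(ds) == 240
        assert ds.shape == (6, int(3.0 * FS))
        assert np.array_equal(ds.labels, recalled.astype(int))

    def test_burst_rows_are_twice_contacts(self, small_datasets):
        ds = small_datasets["enc_burst"]
        assert ds.shape[0] == 2 * 2  # two bipolar contacts -> 4 rows

    def test_epoch_locked_to_onset(self):
        sched = sim.generate_schedule(1, seed=1)
        n = int((sched.end_s + 2.0) * FS)
        ramp = np.arange(n, dtype=float)[None, :]
        ds = tz.extract_encoding_epochs(sched, np.ones(12, bool), ramp, FS)
        for k, w in enumerate(sched.word_events):
            assert ds.tensors[k, 0, 0] == pytest.approx(
                round(w.onset_s * FS), abs=1.0)

    def test_epoch_past_end_dropped(self):
        sched = sim.generate_schedule(1, seed=2)
        short = np.zeros((2, int(sched.word_events[5].onset_s * FS)))
        with pytest.warns(UserWarning, match="dropped"):
            ds = tz.extract_encoding_epochs(sched, np.zeros(12, bool), short, FS)
        assert len(ds) < 12

    def test_single_class_not_trainable(self):
        sched = sim.generate_schedule(2, seed=3)
        rows, _ = _rows(sched, 2)
        ds = tz.extract_encoding_epochs(sched, np.zeros(24, bool), rows, FS)
        assert not ds.is_trainable


class TestRecallSegments:
    def test_count_and_bounds(self):
        sched = sim.generate_schedule(20, seed=4)
        rows, _ = _rows(sched, 4)
        ds = tz.extract_recall_segments(sched, rows, FS, per_list=1, seed=0)
        assert len(ds) == 20
        for (kind, li, _j) in ds.trial_ids:
            assert kind == "recall"

    def test_onsets_within_window(self):
        sched = sim.generate_schedule(3, seed=5)
        rng = np.random.default_rng(0)
        for li, (r_on, r_dur) in enumerate(sched.recall_windows):
            for _ in range(50):
                onset = rng.uniform(r_on, r_on + r_dur - 3.0)
                assert r_on <= onset <= r_on + 27.0

    def test_deterministic(self):
        sched = sim.generate_schedule(2, seed=6)
        rows, _ = _rows(sched, 2)
        a = tz.extract_recall_segments(sched, rows, FS, seed=42)
        b = tz.extract_recall_segments(sched, rows, FS, seed=42)
        assert np.array_equal(a.tensors, b.tensors)


class TestStateDataset:
    def _pair(self, n_lists=2, seed=0):
        sched = sim.generate_schedule(n_lists, seed=seed)
        rows, _ = _rows(sched, 4)
        enc = tz.extract_encoding_epochs(sched, np.zeros(12 * n_lists, bool),
                                         rows, FS)
        rec = tz.extract_recall_segments(sched, rows, FS, per_list=12, seed=seed)
        return enc, rec

    def test_union_is_balanced(self):
        enc, rec = self._pair()
        ds = tz.build_state_dataset(enc, rec, seed=1)
        assert len(ds) == len(enc) + len(rec)
        assert ds.class_balance == pytest.approx(0.5)

    def test_multiset_independent_of_seed(self):
        enc, rec = self._pair()
        a = tz.build_state_dataset(enc, rec, seed=1)
        b = tz.build_state_dataset(enc, rec, seed=2)
        assert not np.array_equal(a.tensors, b.tensors)  # order differs
        sa = np.sort(a.tensors.sum(axis=(1, 2)))
        sb = np.sort(b.tensors.sum(axis=(1, 2)))
        assert np.allclose(sa, sb)

    def test_shape_mismatch_rejected(self):
        enc, rec = self._pair()
        bad = tz.LabeledDataset(rec.tensors[:, :2, :], rec.labels,
                                rec.trial_ids, rec.kind, rec.fs_hz)
        with pytest.raises(ValueError, match="shapes differ"):
            tz.build_state_dataset(enc, bad, seed=0)

    def test_groups_follow_lists(self):
        enc, rec = self._pair(n_lists=3)
        ds = tz.build_state_dataset(enc, rec, seed=3)
        assert ds.groups is not None
        assert set(ds.groups.tolist()) == {0, 1, 2}


class TestRecallEpochs:
    def test_mode_labeling(self):
        sched = sim.generate_schedule(4, seed=7)
        rows, _ = _rows(sched, 2)
        ds = tz.extract_recall_epochs(sched, [0, 0, 2, 3], rows, FS)
        assert ds.labels.tolist() == [0, 0, 1, 1]
        assert ds.shape[1] == int(30.0 * FS)

    def test_bimodal_tie_takes_smaller_mode(self):
        sched = sim.generate_schedule(4, seed=8)
        rows, _ = _rows(sched, 2)
        ds = tz.extract_recall_epochs(sched, [2, 2, 3, 3], rows, FS)
        assert ds.labels.tolist() == [0, 0, 1, 1]

    def test_equal_counts_not_trainable(self):
        sched = sim.generate_schedule(3, seed=9)
        rows, _ = _rows(sched, 2)
        ds = tz.extract_recall_epochs(sched, [5, 5, 5], rows, FS)
        assert not ds.is_trainable

    def test_needs_two_lists(self):
        sched = sim.generate_schedule(1, seed=10)
        rows, _ = _rows(sched, 2)
        with pytest.raises(ValueError):
            tz.extract_recall_epochs(sched, [3], rows, FS)


def test_smallest_mode_tie_rule():
    assert tz.smallest_mode([0, 0, 2, 3]) == 0
    assert tz.smallest_mode([2, 2, 3, 3]) == 2
    assert tz.smallest_mode([7]) == 7


def test_dataset_roundtrip(tmp_path, small_datasets):
    ds = small_datasets["enc_burst"]
    tz.save_dataset(ds, tmp_path, "enc")
    back = tz.load_dataset(tmp_path, "enc")
    assert np.array_equal(back.tensors, ds.tensors)
    assert np.array_equal(back.labels, ds.labels)
    assert back.kind == ds.kind
    assert np.array_equal(back.groups, ds.groups)
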