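import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegstress.deap_io import (
    EEGTrial,
    ParticipantDataset,
    RatingRecord,
    StateLabel,
    assemble_datasets,
    label_state,
    load_study,
    remove_baseline,
    save_study,
    select_eeg_channels,
)
from eegstress.errors import DimensionError


def make_trial(pid=1, eid=1, n_channels=2, n_samples=8064, fill=None):
    data = (
        np.full((n_channels, n_samples), float(fill))
        if fill is not None
        else np.arange(n_channels * n_samples, dtype=float).reshape(
            n_channels, n_samples
        )
    )
    return EEGTrial(pid, eid, data, fs=128.0, baseline_samples=384)


class TestChannelSelection:
    def test_keeps_first_32_rows_unchanged(self):
        raw = np.random.default_rng(0).normal(size=(40, 8064))
        out = select_eeg_channels(raw)
        assert out.shape == (32, 8064)
        np.testing.assert_array_equal(out, raw[:32])

    def test_row_identity_on_index_matrix(self):
        raw = np.arange(40, dtype=float)[:, None]
        out = select_eeg_channels(raw)
        np.testing.assert_array_equal(out[:, 0], np.arange(32))

    def test_wrong_channel_count_raises(self):
        with pytest.raises(DimensionError, match="40"):
            select_eeg_channels(np.zeros((32, 10)))


class TestBaselineRemoval:
    def test_three_seconds_at_128hz_drops_384_samples(self):
        trial = make_trial(n_channels=32)
        out = remove_baseline(trial, 3.0)
        assert out.data.shape == (32, 7680)
        assert out.baseline_samples == 0

    def test_zero_baseline_is_identity(self):
        trial = make_trial()
        out = remove_baseline(trial, 0.0)
        np.testing.assert_array_equal(out.data, trial.data)

    def test_ramp_starts_at_384_after_removal(self):
        trial = EEGTrial(1, 1, np.arange(8064, dtype=float)[None, :], fs=128.0)
        out = remove_baseline(trial, 3.0)
        assert out.data[0, 0] == 384.0

    def test_removal_is_idempotent_with_zero_follow_up(self):
        trial = make_trial()
        once = remove_baseline(trial, 3.0)
        twice = remove_baseline(once, 0.0)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_baseline_longer_than_signal_raises(self):
        trial = make_trial(n_samples=100)
        with pytest.raises(ValueError):
            remove_baseline(trial, 10.0)


class TestStateLabelling:
    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [
            (5.0, 3.0, StateLabel.CALM),
            (2.0, 6.0, StateLabel.STRESS),
            (4.0, 3.0, StateLabel.UNLABELED),  # boundary fails strict 4 <
            (7.0, 7.0, StateLabel.UNLABELED),
            (3.0, 6.0, StateLabel.UNLABELED),  # boundary fails strict < 3
            (2.0, 5.0, StateLabel.UNLABELED),  # boundary fails strict > 5
        ],
    )
    def test_annotation_rules(self, valence, arousal, expected):
        assert label_state(RatingRecord(1, 1, valence, arousal)) is expected

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError):
            RatingRecord(1, 1, 0.5, 5.0)
        with pytest.raises(ValueError):
            RatingRecord(1, 1, 5.0, 9.5)

    @settings(derandomize=True, max_examples=300)
    @given(
        valence=st.floats(min_value=1.0, max_value=9.0),
        arousal=st.floats(min_value=1.0, max_value=9.0),
    )
    def test_labelling_partitions_the_rating_plane(self, valence, arousal):
        state = label_state(RatingRecord(1, 1, valence, arousal))
        calm = 4.0 < valence < 6.0 and arousal < 4.0
        stress = valence < 3.0 and arousal > 5.0
        assert not (calm and stress)  # regions are disjoint
        assert state is (
            StateLabel.CALM
            if calm
            else StateLabel.STRESS
            if stress
            else StateLabel.UNLABELED
        )


def ratings_for(pid, calm_eids, stress_eids, other_eids=()):
    out = []
    for eid in calm_eids:
        out.append(RatingRecord(pid, eid, 5.0, 2.0))
    for eid in stress_eids:
        out.append(RatingRecord(pid, eid, 2.0, 7.0))
    for eid in other_eids:
        out.append(RatingRecord(pid, eid, 8.0, 8.0))
    return out


class TestDatasetAssembly:
    def test_groups_labelled_trials_per_participant(self):
        ratings = ratings_for(1, [9, 14], [17, 32, 34, 35, 36, 37], [1])
        trials = [make_trial(1, r.experiment_id) for r in ratings]
        (ds,) = assemble_datasets(trials, ratings)
        assert len(ds.trials) == 8  # unlabeled experiment 1 dropped
        assert ds.labels.count(StateLabel.CALM) == 2
        assert ds.labels.count(StateLabel.STRESS) == 6

    def test_single_class_participant_excluded(self):
        ratings = ratings_for(1, [], [2, 3])
        trials = [make_trial(1, r.experiment_id) for r in ratings]
        assert assemble_datasets(trials, ratings) == []

    def test_excludes_exactly_the_single_class_participants(self):
        ratings, trials = [], []
        for pid in range(1, 9):
            if pid in (3, 6, 7):  # one class only
                rs = ratings_for(pid, [1, 2], [])
            else:
                rs = ratings_for(pid, [1], [2])
            ratings.extend(rs)
            trials.extend(make_trial(pid, r.experiment_id) for r in rs)
        datasets = assemble_datasets(trials, ratings)
        assert [d.participant_id for d in datasets] == [1, 2, 4, 5, 8]
        for d in datasets:
            assert StateLabel.CALM in d.labels and StateLabel.STRESS in d.labels

    def test_trial_without_rating_raises_key_error(self):
        with pytest.raises(KeyError, match="participant 1, experiment 5"):
            assemble_datasets([make_trial(1, 5)], ratings_for(1, [2], [3]))

    def test_dataset_invariant_requires_both_classes(self):
        with pytest.raises(ValueError, match="both calm and stress"):
            ParticipantDataset(
                participant_id=1,
                trials=[make_trial()],
                labels=[StateLabel.CALM],
            )


class TestStudyRoundTrip:
    def test_hdf5_csv_round_trip(self, tmp_path):
        ratings = ratings_for(2, [1], [2])
        trials = [
            make_trial(2, 1, n_channels=3, n_samples=256),
            make_trial(2, 2, n_channels=3, n_samples=256, fill=1.5),
        ]
        save_study(tmp_path, trials, ratings)
        trials2, ratings2 = load_study(tmp_path)
        assert len(trials2) == 2 and len(ratings2) == 2
        np.testing.assert_allclose(trials2[0].data, trials[0].data)
        assert trials2[1].fs == 128.0
        assert {r.experiment_id for r in ratings2} == {1, 2}
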