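"""Reading and annotating DEAP-style EEG trial collections.

The expected on-disk layout is a directory of per-participant HDF5 files,
each holding a 3-D array ``signals[trial, channel, sample]`` with attributes
``fs`` and ``participant_id``, next to a ``ratings.csv`` table with header
``participant_id,experiment_id,valence,arousal``.  The native DEAP pickled
``.dat`` layout (dict with ``data`` of shape 40x40x8064 and ``labels`` of
shape 40x4, where the first two label columns are valence and arousal) is
supported through :func:`load_deap_pickle`.

Trials are annotated into calm / stress / unlabeled states from the
per-trial valence and arousal self-assessments (1-9 scale):

* calm:   4 < valence < 6  and  arousal < 4
* stress: valence < 3      and  arousal > 5

with strict inequalities throughout; everything else is unlabeled and
dropped.  Participants that do not exhibit both states are excluded.
"""

from __future__ import annotations

import enum
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .errors import DimensionError

#: number of EEG channels in the DEAP montage (first 32 of 40 recorded rows)
N_EEG_CHANNELS = 32
#: number of raw recorded channels (32 EEG + 8 peripheral)
N_RAW_CHANNELS = 40
#: sampling rate of the preprocessed recordings, Hz
DEFAULT_FS = 128.0


class StateLabel(enum.Enum):
    """Mental-state annotation derived from valence/arousal ratings."""

    CALM = "calm"
    STRESS = "stress"
    UNLABELED = "unlabeled"


@dataclass
class EEGTrial:
    """One participant x experiment recording.

    ``data`` is a ``(n_channels, n_samples)`` float array; ``baseline_samples``
    counts the leading pre-trial samples still present in ``data``.
    """

    participant_id: int
    experiment_id: int
    data: np.ndarray
    fs: float = DEFAULT_FS
    baseline_samples: int = 0

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RatingRecord:
    """Valence/arousal self-assessment for one participant x experiment."""

    participant_id: int
    experiment_id: int
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"{name}={v} outside the 1-9 rating scale")


@dataclass
class ParticipantDataset:
    """All labelled (calm or stress) trials of one participant."""

    participant_id: int
    trials: list[EEGTrial] = field(default_factory=list)
    labels: list[StateLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        states = set(self.labels)
        if not {StateLabel.CALM, StateLabel.STRESS} <= states:
            raise ValueError(
                f"participant {self.participant_id}: dataset must contain "
                "both calm and stress trials"
            )
        if StateLabel.UNLABELED in states:
            raise ValueError("unlabeled trials are not allowed in a dataset")


def select_eeg_channels(raw: np.ndarray) -> np.ndarray:
    """Keep the 32 EEG channels (first 32 rows) of a 40-channel recording.

    The DEAP channel order places the 32 scalp electrodes first, followed
    by 8 peripheral channels; only the EEG rows are analysed.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[0] != N_RAW_CHANNELS:
        raise DimensionError(
            f"expected {N_RAW_CHANNELS} channel rows, got "
            f"{raw.shape[0] if raw.ndim == 2 else raw.shape}"
        )
    return raw[:N_EEG_CHANNELS]


def remove_baseline(trial: EEGTrial, baseline_seconds: float = 3.0) -> EEGTrial:
    """Drop the leading pre-trial baseline from every channel.

    DEAP recordings carry a 3-s pre-trial segment before the 60-s stimulus;
    at 128 Hz this removes 384 samples, 8064 -> 7680.
    """
    n_drop = int(round(baseline_seconds * trial.fs))
    if n_drop < 0 or n_drop > trial.n_samples:
        raise ValueError(
            f"baseline of {n_drop} samples exceeds signal length "
            f"{trial.n_samples}"
        )
    return replace(trial, data=trial.data[:, n_drop:], baseline_samples=0)


def label_state(r: RatingRecord) -> StateLabel:
    """Annotate one rating as calm, stress, or unlabeled.

    The two regions are disjoint by construction (``valence < 3`` and
    ``4 < valence`` cannot both hold), so this is a partition of the
    rating plane.
    """
    if 4.0 < r.valence < 6.0 and r.arousal < 4.0:
        return StateLabel.CALM
    if r.valence < 3.0 and r.arousal > 5.0:
        return StateLabel.STRESS
    return StateLabel.UNLABELED


def assemble_datasets(
    trials: Iterable[EEGTrial], ratings: Iterable[RatingRecord]
) -> list[ParticipantDataset]:
    """Group labelled trials per participant, dropping unusable material.

    Unlabeled trials are discarded; a participant without at least one calm
    and one stress trial is excluded entirely.  Output is sorted by
    participant id, trials within a participant by experiment id.
    """
    rating_map = {
        (r.participant_id, r.experiment_id): r for r in ratings
    }
    per_participant: dict[int, list[tuple[EEGTrial, StateLabel]]] = {}
    for trial in trials:
        key = (trial.participant_id, trial.experiment_id)
        if key not in rating_map:
            raise KeyError(
                f"no rating for participant {key[0]}, experiment {key[1]}"
            )
        state = label_state(rating_map[key])
        if state is StateLabel.UNLABELED:
            continue
        per_participant.setdefault(trial.participant_id, []).append(
            (trial, state)
        )

    datasets: list[ParticipantDataset] = []
    for pid in sorted(per_participant):
        pairs = sorted(per_participant[pid], key=lambda p: p[0].experiment_id)
        states = {s for _, s in pairs}
        if not {StateLabel.CALM, StateLabel.STRESS} <= states:
            continue
        datasets.append(
            ParticipantDataset(
                participant_id=pid,
                trials=[t for t, _ in pairs],
                labels=[s for _, s in pairs],
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# on-disk containers
# ---------------------------------------------------------------------------

def load_ratings_csv(path: str | Path) -> list[RatingRecord]:
    df = pd.read_csv(path)
    required = {"participant_id", "experiment_id", "valence", "arousal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    return [
        RatingRecord(
            participant_id=int(row.participant_id),
            experiment_id=int(row.experiment_id),
            valence=float(row.valence),
            arousal=float(row.arousal),
        )
        for row in df.itertuples()
    ]


def save_ratings_csv(ratings: Iterable[RatingRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "experiment_id": r.experiment_id,
                "valence": r.valence,
                "arousal": r.arousal,
            }
            for r in ratings
        ]
    ).to_csv(path, index=False)


def load_study(directory: str | Path) -> tuple[list[EEGTrial], list[RatingRecord]]:
    """Read a study directory: per-participant HDF5 files + ratings.csv.

    Each ``participant_*.h5`` holds ``signals[trial, channel, sample]`` with
    attributes ``fs`` and ``participant_id``; experiment ids are 1-based in
    trial order.
    """
    directory = Path(directory)
    ratings = load_ratings_csv(directory / "ratings.csv")
    trials: list[EEGTrial] = []
    for h5path in sorted(directory.glob("participant_*.h5")):
        with h5py.File(h5path, "r") as f:
            signals = f["signals"][()]
            fs = float(f["signals"].attrs["fs"])
            pid = int(f["signals"].attrs["participant_id"])
        for i in range(signals.shape[0]):
            trials.append(
                EEGTrial(
                    participant_id=pid,
                    experiment_id=i + 1,
                    data=np.asarray(signals[i], dtype=float),
                    fs=fs,
                )
            )
    return trials, ratings


def save_study(
    directory: str | Path,
    trials: Iterable[EEGTrial],
    ratings: Iterable[RatingRecord],
) -> None:
    """Write the HDF5 + CSV study layout consumed by :func:`load_study`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_pid: dict[int, list[EEGTrial]] = {}
    for t in trials:
        by_pid.setdefault(t.participant_id, []).append(t)
    for pid, ts in by_pid.items():
        ts = sorted(ts, key=lambda t: t.experiment_id)
        arr = np.stack([t.data for t in ts])
        with h5py.File(directory / f"participant_{pid:02d}.h5", "w") as f:
            dset = f.create_dataset("signals", data=arr)
            dset.attrs["fs"] = ts[0].fs
            dset.attrs["participant_id"] = pid
    save_ratings_csv(ratings, directory / "ratings.csv")


def load_deap_pickle(path: str | Path, participant_id: int) -> tuple[
    list[EEGTrial], list[RatingRecord]
]:
    """Adapter for DEAP's native per-participant ``.dat`` pickle.

    The pickle holds ``data`` (40 trials x 40 channels x 8064 samples) and
    ``labels`` (40 x 4: valence, arousal, dominance, liking).  Only the 32
    EEG channels are retained.
    """
    with open(path, "rb") as f:
        payload = pickle.load(f, encoding="latin1")
    data = np.asarray(payload["data"])
    labels = np.asarray(payload["labels"])
    trials, ratings = [], []
    for i in range(data.shape[0]):
        trials.append(
            EEGTrial(
                participant_id=participant_id,
                experiment_id=i + 1,
                data=select_eeg_channels(data[i]),
                fs=DEFAULT_FS,
            )
        )
        ratings.append(
            RatingRecord(
                participant_id=participant_id,
                experiment_id=i + 1,
                valence=float(labels[i, 0]),
                arousal=float(labels[i, 1]),
            )
        )
    return trials, ratings
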