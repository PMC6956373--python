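"""Assembly of the 19-column hybrid feature matrix.

Each (trial, channel) pair is one sample: 11 time-domain features plus 8
wavelet-band features computed on that channel's baseline-stripped signal,
labelled with the trial's state (calm = 0, stress = 1).  Sampling at the
(trial, channel) level gives 32 samples per trial, which is what makes a
60/40 split and 10-fold cross-validation meaningful for participants with
as few as two trials in a class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .deap_io import ParticipantDataset, StateLabel, remove_baseline
from .errors import DatasetError, DegenerateSignalError
from .time_features import TIME_FEATURE_NAMES, time_feature_vector
from .wavelet_features import WAVELET_FEATURE_NAMES, wavelet_feature_vector

logger = logging.getLogger(__name__)

FEATURE_NAMES: list[str] = TIME_FEATURE_NAMES + WAVELET_FEATURE_NAMES
PROVENANCE_COLUMNS = ["participant_id", "experiment_id", "channel"]

LABEL_CODES = {StateLabel.CALM: 0, StateLabel.STRESS: 1}


def extract_features(
    ds: ParticipantDataset,
    wavelet: str = "db4",
    max_level: int = 5,
    strip_baseline: bool = True,
) -> pd.DataFrame:
    """Hybrid feature matrix for one participant.

    Returns a DataFrame with provenance columns, the 19 feature columns
    F1..F19, and a binary ``label`` column.  Rows are ordered by experiment
    id, channels ascending within a trial.  Degenerate channel signals
    (constant, or constant first difference) are skipped with a warning; if
    an entire class is lost this way a :class:`DatasetError` is raised.
    """
    rows: list[dict] = []
    n_skipped = 0
    for trial, state in zip(ds.trials, ds.labels):
        t = remove_baseline(trial, trial.baseline_samples / trial.fs) \
            if (strip_baseline and trial.baseline_samples) else trial
        label = LABEL_CODES[state]
        for ch in range(t.n_channels):
            x = t.data[ch]
            try:
                feats = np.concatenate(
                    [
                        time_feature_vector(x),
                        wavelet_feature_vector(
                            x, t.fs, wavelet=wavelet, max_level=max_level
                        ),
                    ]
                )
            except DegenerateSignalError:
                n_skipped += 1
                logger.warning(
                    "skipping degenerate channel %d of participant %d "
                    "experiment %d",
                    ch, t.participant_id, t.experiment_id,
                )
                continue
            row = {
                "participant_id": t.participant_id,
                "experiment_id": t.experiment_id,
                "channel": ch,
                "label": label,
            }
            row.update(dict(zip(FEATURE_NAMES, feats)))
            rows.append(row)
    if n_skipped:
        logger.warning("skipped %d degenerate channel signals", n_skipped)
    df = pd.DataFrame(rows, columns=PROVENANCE_COLUMNS + FEATURE_NAMES + ["label"])
    for code in (0, 1):
        if not (df["label"] == code).any():
            raise DatasetError(
                f"all rows of class {code} were skipped for participant "
                f"{ds.participant_id}"
            )
    return df


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature DataFrame into (X, y) arrays."""
    return df[FEATURE_NAMES].to_numpy(dtype=float), df["label"].to_numpy(dtype=int)


def save_features_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES + ["label"]) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
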