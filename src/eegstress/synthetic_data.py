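"""DEAP-shaped surrogate studies with class-dependent band structure.

The generator emulates the geometry of the preprocessed DEAP recordings —
32 channels, 128 Hz, 63 s per trial including a 3-s baseline — with each
channel a sum of one band-limited oscillator per EEG band plus white noise.
Band amplitudes follow a state-specific relative-power profile, which gives
downstream band features a real class signal: the default profiles encode
the alpha-suppression / beta-gamma-enhancement pattern associated with
mental stress.  Ratings are drawn uniformly inside the strict calm/stress
annotation regions so that state labelling round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deap_io import DEFAULT_FS, EEGTrial, RatingRecord, StateLabel

#: analysis bands, Hz (delta is absent from the 4-45 Hz filtered data)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta_low": (14.0, 16.0),
    "beta_high": (16.0, 32.0),
    "gamma": (32.0, 40.0),
}

#: default relative band powers: calm = alpha-dominant, stress = beta/gamma
DEFAULT_CALM_POWER: dict[str, float] = {
    "theta": 1.0,
    "alpha": 2.0,
    "beta_low": 0.4,
    "beta_high": 0.5,
    "gamma": 0.3,
}
DEFAULT_STRESS_POWER: dict[str, float] = {
    "theta": 0.8,
    "alpha": 0.6,
    "beta_low": 0.9,
    "beta_high": 1.5,
    "gamma": 0.8,
}


@dataclass
class SyntheticSpec:
    """Parameters of a surrogate study.

    Band powers are mean-squared amplitudes per band (a sinusoid of
    amplitude A carries power A^2/2, so the oscillator amplitude is
    sqrt(2 * power)).  Two multiplicative lognormal variability terms emulate
    real recordings: ``amplitude_jitter`` (log-sd) is drawn per oscillator
    and models band-power fluctuation between trials, while
    ``channel_gain_sd`` (log-sd) is one gain per trial x channel applied to
    the whole signal including noise, modelling electrode-impedance and
    anatomical gain differences.  The gain term dominates the raw feature
    variance without carrying class information, which keeps the synthetic
    classification task in the accuracy regime typical of calm/stress EEG
    protocols rather than at saturation.  ``class_balance`` is the stress
    fraction per participant; the stress count is rounded and clamped to
    keep both classes present.
    """

    n_participants: int = 4
    n_trials_per_participant: int = 10
    n_channels: int = 32
    fs: float = DEFAULT_FS
    duration_s: float = 63.0
    baseline_s: float = 3.0
    band_power_calm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALM_POWER)
    )
    band_power_stress: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_POWER)
    )
    noise_sd: float = 1.0
    amplitude_jitter: float = 0.2
    channel_gain_sd: float = 0.6
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        for profile in (self.band_power_calm, self.band_power_stress):
            unknown = set(profile) - set(BANDS)
            if unknown:
                raise ValueError(f"unknown bands: {sorted(unknown)}")
            if any(p < 0 for p in profile.values()):
                raise ValueError("band powers must be non-negative")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be integral")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def baseline_samples(self) -> int:
        return int(round(self.baseline_s * self.fs))


def generate_trial(
    state: StateLabel,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    participant_id: int = 1,
    experiment_id: int = 1,
) -> EEGTrial:
    """Synthesize one multichannel trial for a calm or stress state.

    Each channel draws an independent frequency (uniform within the band)
    and phase for every band oscillator, so channels are band-coherent in
    power but not in waveform.
    """
    if state is StateLabel.UNLABELED:
        raise ValueError("cannot generate a trial for the unlabeled state")
    profile = (
        spec.band_power_calm if state is StateLabel.CALM else spec.band_power_stress
    )
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    data = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        sig = np.zeros(n)
        for band, (lo, hi) in BANDS.items():
            power = profile.get(band, 0.0)
            freq = rng.uniform(lo, hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            if power > 0:
                gain = (
                    rng.lognormal(0.0, spec.amplitude_jitter)
                    if spec.amplitude_jitter > 0
                    else 1.0
                )
                sig += gain * np.sqrt(2.0 * power) * np.sin(
                    2 * np.pi * freq * t + phase
                )
        if spec.noise_sd > 0:
            sig += spec.noise_sd * rng.standard_normal(n)
        if spec.channel_gain_sd > 0:
            sig *= rng.lognormal(0.0, spec.channel_gain_sd)
        data[ch] = sig
    return EEGTrial(
        participant_id=participant_id,
        experiment_id=experiment_id,
        data=data,
        fs=spec.fs,
        baseline_samples=spec.baseline_samples,
    )


def _draw_rating(
    state: StateLabel, rng: np.random.Generator, pid: int, eid: int
) -> RatingRecord:
    # uniform inside the open annotation region, margins keep strict
    # inequalities safe against float rounding
    if state is StateLabel.CALM:
        valence = rng.uniform(4.1, 5.9)
        arousal = rng.uniform(1.0, 3.9)
    else:
        valence = rng.uniform(1.0, 2.9)
        arousal = rng.uniform(5.1, 9.0)
    return RatingRecord(pid, eid, float(valence), float(arousal))


def generate_study(
    spec: SyntheticSpec,
) -> tuple[list[EEGTrial], list[RatingRecord]]:
    """Generate trials and consistent ratings for the whole study.

    Per participant, round(class_balance * n_trials) trials are stress
    (clamped to [1, n_trials - 1] so both classes are always present), with
    state order shuffled across experiment ids.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials_per_participant
    n_stress = int(np.clip(round(spec.class_balance * n), 1, n - 1))
    trials: list[EEGTrial] = []
    ratings: list[RatingRecord] = []
    for pid in range(1, spec.n_participants + 1):
        states = [StateLabel.STRESS] * n_stress + [StateLabel.CALM] * (n - n_stress)
        rng.shuffle(states)
        for eid, state in enumerate(states, start=1):
            trials.append(generate_trial(state, spec, rng, pid, eid))
            ratings.append(_draw_rating(state, rng, pid, eid))
    return trials, ratings
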