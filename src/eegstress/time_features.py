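"""Time-domain statistical features F1-F11 of the hybrid feature pool.

Nine statistical parameters (RMS, square mean root, peak-to-peak, kurtosis,
skewness, kurtosis factor, shape factor, crest factor, impulse factor) plus
the two Hjorth parameters mobility and complexity.  All moments use the
population (1/N) convention, and the derivative in the Hjorth parameters is
the plain first difference, so mobility is in radians/sample and complexity
is dimensionless.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateSignalError, SignalLengthError

TIME_FEATURE_NAMES = [f"F{i}" for i in range(1, 12)]

MIN_LENGTH = 4


def statistical_features(x: np.ndarray) -> np.ndarray:
    """Compute F1-F9 from a 1-D signal.

    F1  rms             sqrt(mean(x^2))
    F2  square mean root (mean(sqrt(|x|)))^2
    F3  peak to peak     max(|x|) - min(|x|)
    F4  kurtosis         mean(((x - mean)/sd)^4)       (non-excess)
    F5  skewness         mean(((x - mean)/sd)^3)
    F6  kurtosis factor  F4 / F1^4
    F7  shape factor     F1 / mean(|x|)
    F8  crest factor     max(|x|) / F1
    F9  impulse factor   max(|x|) / mean(|x|)
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < MIN_LENGTH:
        raise SignalLengthError(
            f"need at least {MIN_LENGTH} samples, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    sd = x.std()  # population
    if sd == 0.0:
        raise DegenerateSignalError("constant signal: moments undefined")

    absx = np.abs(x)
    rms = np.sqrt(np.mean(x**2))
    mean_abs = absx.mean()
    z = (x - x.mean()) / sd
    kurt = np.mean(z**4)
    skew = np.mean(z**3)
    peak = absx.max()
    return np.array(
        [
            rms,
            np.mean(np.sqrt(absx)) ** 2,
            peak - absx.min(),
            kurt,
            skew,
            kurt / rms**4,
            rms / mean_abs,
            peak / rms,
            peak / mean_abs,
        ]
    )


def _mobility(x: np.ndarray) -> float:
    dx = np.diff(x)
    var_x = x.var()
    var_dx = dx.var()
    if var_x == 0.0 or var_dx == 0.0:
        raise DegenerateSignalError(
            "constant signal or constant first difference: Hjorth "
            "parameters undefined"
        )
    return float(np.sqrt(var_dx / var_x))


def hjorth_parameters(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility (F10) and complexity (F11).

    mobility(x) = sqrt(var(x') / var(x)) with x' the first difference;
    complexity = mobility(x') / mobility(x).  For a pure sinusoid of
    angular frequency w rad/sample, mobility -> 2 sin(w/2) and
    complexity -> 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_LENGTH:
        raise SignalLengthError(
            f"need at least {MIN_LENGTH} samples, got {x.size}"
        )
    m = _mobility(x)
    m_dx = _mobility(np.diff(x))
    return m, m_dx / m


def time_feature_vector(x: np.ndarray) -> np.ndarray:
    """All 11 time-domain features in F1..F11 order."""
    mob, comp = hjorth_parameters(x)
    return np.concatenate([statistical_features(x), [mob, comp]])
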