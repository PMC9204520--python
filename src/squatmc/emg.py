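"""Surface-EMG conditioning chain used for qualitative activation checks.

Processing order: zero-phase 4th-order Butterworth band-pass (10-300 Hz by
default), offset (mean) removal, full-wave rectification, and a centred
moving-average envelope (100 ms default window).  Envelopes are normalised
by the subject-level maximum across all supplied trials, so the largest
recorded activation maps to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ValidationError

BAND_DEFAULT = (10.0, 300.0)   # Hz
MA_WINDOW_DEFAULT = 0.1        # s


@dataclass
class EMGSignal:
    """One channel of raw EMG with its processed envelope."""

    raw: np.ndarray
    sampling_rate: float
    muscle: str = ""
    trial: str = ""
    processed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")


def process_emg(
    raw: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = BAND_DEFAULT,
    ma_window: float = MA_WINDOW_DEFAULT,
) -> np.ndarray:
    """Band-pass, offset-correct, rectify and smooth a raw EMG signal.

    The sampling rate must resolve the upper band edge
    (``sampling_rate > 2 * band[1]``), otherwise an error is raised.
    Filtering is zero-phase (forward-backward) to avoid lag against
    predicted activation traces.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValidationError("EMG signal contains non-finite samples")
    lo, hi = band
    if not 0 < lo < hi:
        raise ValidationError("band edges must satisfy 0 < low < high")
    if sampling_rate <= 2 * hi:
        raise ValidationError(
            f"sampling rate {sampling_rate} Hz cannot resolve the {hi} Hz band edge"
        )
    b, a = butter(4, (lo, hi), btype="bandpass", fs=sampling_rate)
    x = filtfilt(b, a, raw)
    x = x - np.mean(x)
    x = np.abs(x)
    n = max(int(round(ma_window * sampling_rate)), 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def normalize_emg(envelopes) -> list[np.ndarray] | dict[str, np.ndarray]:
    """Normalise envelopes by the maximum across all supplied trials.

    Accepts a list of arrays or a mapping name -> array; returns the same
    structure.  The global maximum of the outputs is exactly 1.
    """
    if isinstance(envelopes, dict):
        keys = list(envelopes)
        arrays = [np.asarray(envelopes[k], dtype=float) for k in keys]
    else:
        keys = None
        arrays = [np.asarray(e, dtype=float) for e in envelopes]
    if not arrays:
        raise ValidationError("no envelopes supplied")
    peak = max(float(np.max(a)) for a in arrays)
    if peak <= 0:
        raise ValidationError("global maximum is zero; cannot normalise")
    out = [a / peak for a in arrays]
    if keys is not None:
        return dict(zip(keys, out))
    return out
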