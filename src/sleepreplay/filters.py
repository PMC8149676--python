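"""Zero-phase band-pass filters shared by detection and coupling stages.

Two filter families are used:

* FIR for event detection — filter length is three cycles of the low
  frequency cut-off (``numtaps = 3 / f_low * sfreq``, forced odd), Hamming
  window, applied forward and backward (zero phase).
* Butterworth (2nd order, applied two-pass, effectively 4th order) for the
  Hilbert phase/amplitude stage.
"""

from __future__ import annotations

import numpy as np
import scipy.signal


def fir_bandpass_taps(sfreq: float, low: float, high: float) -> np.ndarray:
    numtaps = int(round(3.0 / low * sfreq))
    if numtaps % 2 == 0:
        numtaps += 1
    return scipy.signal.firwin(
        numtaps, [low, high], fs=sfreq, pass_zero=False, window="hamming"
    )


def fir_bandpass_filtfilt(
    x: np.ndarray, sfreq: float, low: float, high: float
) -> np.ndarray:
    """Two-pass (zero-phase) FIR band-pass along the last axis."""
    taps = fir_bandpass_taps(sfreq, low, high)
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return scipy.signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def butter_bandpass_filtfilt(
    x: np.ndarray, sfreq: float, low: float, high: float, order: int = 2
) -> np.ndarray:
    """Two-pass Butterworth band-pass along the last axis."""
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)
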