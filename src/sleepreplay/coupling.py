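"""SO-spindle phase coupling and the circular statistics used to test it.

Phase convention (Hilbert phase of the SO-band signal): the SO upstate (signal
maximum) is 0, the downstate (minimum) is ±π, and the down-to-upstate
transition (rising zero crossing) is −π/2. Angles are radians in (−π, π].

Per complex-locked epoch, the coupling phase is the SO-band instantaneous
phase at the sample of maximal spindle-band amplitude, with both analytic
signals obtained from two-pass Butterworth band-passes followed by Hilbert
transforms, and the search restricted to ±1.5 s to avoid filter edge
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

from .core import EpochSet
from .events import SO_BAND, SPINDLE_BAND
from .filters import butter_bandpass_filtfilt


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (−π, π]."""
    wrapped = -(np.mod(-np.asarray(theta, dtype=float) + np.pi, 2 * np.pi) - np.pi)
    return wrapped if np.ndim(theta) else float(wrapped)


@dataclass
class CouplingResult:
    """Participant-level summary of SO-spindle coupling."""

    event_phases: np.ndarray  # radians, one per complex
    preferred_phase: float  # circular mean, radians
    resultant_length: float  # R in [0, 1]
    rayleigh_z: float
    rayleigh_p: float
    mean_reliable: bool  # False when R ≈ 0 (mean direction undefined)


def event_coupling_phase(
    complex_epochs: EpochSet,
    channel: str | None = None,
    so_band: tuple[float, float] = SO_BAND,
    spindle_band: tuple[float, float] = SPINDLE_BAND,
    search_window: float = 1.5,
    butter_order: int = 2,
) -> np.ndarray:
    """SO phase at the spindle amplitude maximum, one angle per epoch.

    ``complex_epochs`` must be locked to the SO downstate and span at least
    ``±search_window`` seconds.
    """
    if complex_epochs.times[0] > -search_window or complex_epochs.times[-1] < search_window:
        raise ValueError(
            f"epochs must span at least ±{search_window} s around the downstate"
        )
    if channel is None:
        ci = 0
    else:
        ci = complex_epochs.channel_names.index(channel)
    x = complex_epochs.data[:, ci, :]  # (events, time)
    sf = complex_epochs.sfreq

    # reflection-extend by one epoch length per side before filtering and the
    # Hilbert transform: suppresses edge transients that otherwise bias the
    # instantaneous phase of the few-cycle SO component
    n = x.shape[-1]
    ext = np.concatenate([x[:, ::-1], x, x[:, ::-1]], axis=-1)
    so = butter_bandpass_filtfilt(ext, sf, *so_band, order=butter_order)
    sp = butter_bandpass_filtfilt(ext, sf, *spindle_band, order=butter_order)
    so_phase = np.angle(scipy.signal.hilbert(so, axis=-1))[:, n : 2 * n]
    sp_amp = np.abs(scipy.signal.hilbert(sp, axis=-1))[:, n : 2 * n]

    m = complex_epochs.time_mask(-search_window, search_window)
    idx_peak = np.argmax(sp_amp[:, m], axis=1)
    phases = so_phase[:, m][np.arange(x.shape[0]), idx_peak]
    return wrap_angle(phases)


def circular_mean_and_R(phases: np.ndarray) -> tuple[float, float]:
    """Circular mean direction and resultant vector length.

    mean = arg Σ e^{iθ};  R = |Σ e^{iθ}| / n.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("cannot compute circular mean of an empty sample")
    vec = np.exp(1j * phases).mean()
    return float(wrap_angle(np.angle(vec))), float(np.abs(vec))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    z = n·R²; p uses the standard small-sample correction
    p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    _, R = circular_mean_and_R(phases)
    z = n * R**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * R) ** 2)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


def participant_coupling(phases: np.ndarray) -> CouplingResult:
    """Summarize one participant's event phases into a :class:`CouplingResult`."""
    phases = wrap_angle(np.asarray(phases, dtype=float))
    mean, R = circular_mean_and_R(phases)
    z, p = rayleigh_test(phases)
    return CouplingResult(
        event_phases=phases,
        preferred_phase=mean,
        resultant_length=R,
        rayleigh_z=z,
        rayleigh_p=p,
        mean_reliable=R > 1e-9,
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def circ_linear_corr(phases: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Circular-linear correlation between angles and a linear variable.

    With r_cx = corr(cos θ, x), r_sx = corr(sin θ, x), r_cs = corr(cos θ, sin θ):

        r = sqrt((r_cx² + r_sx² − 2 r_cx r_sx r_cs) / (1 − r_cs²))

    and p is the upper tail of χ²(2) at n·r².
    """
    phases = np.asarray(phases, dtype=float)
    x = np.asarray(x, dtype=float)
    if phases.shape != x.shape:
        raise ValueError("phases and x must have equal length")
    n = phases.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or (np.ptp(np.cos(phases)) == 0 and np.ptp(np.sin(phases)) == 0):
        raise ValueError("degenerate input: constant x or constant phases")
    return _circ_linear_from_components(np.cos(phases), np.sin(phases), x, n)


def _circ_linear_from_components(
    c: np.ndarray, s: np.ndarray, x: np.ndarray, n: int
) -> tuple[float, float]:
    rcx, rsx, rcs = _corr(c, x), _corr(s, x), _corr(c, s)
    r2 = (rcx**2 + rsx**2 - 2 * rcx * rsx * rcs) / (1 - rcs**2)
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(scipy.stats.chi2.sf(n * r**2, df=2))
    return min(r, 1.0), p


def _residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_circ_linear_corr(
    phases: np.ndarray,
    x: np.ndarray,
    covariate: np.ndarray,
    residualize: str = "all",
) -> tuple[float, float]:
    """Circular-linear correlation controlling for a linear covariate.

    ``residualize="all"`` (default) replaces x, cos θ and sin θ by their
    least-squares residuals on the covariate before applying the
    circular-linear formula; ``"linear-only"`` residualizes x alone.
    """
    phases = np.asarray(phases, dtype=float)
    x = np.asarray(x, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if not (phases.shape == x.shape == covariate.shape):
        raise ValueError("phases, x and covariate must have equal length")
    n = phases.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(covariate) == 0:
        raise ValueError("degenerate input: constant covariate")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant x")
    c, s = np.cos(phases), np.sin(phases)
    xr = _residualize(x, covariate)
    if residualize == "all":
        c, s = _residualize(c, covariate), _residualize(s, covariate)
    elif residualize != "linear-only":
        raise ValueError("residualize must be 'all' or 'linear-only'")
    # x (numerically) fully explained by the covariate: nothing left to correlate
    if np.var(xr) <= 1e-12 * np.var(x):
        return 0.0, 1.0
    return _circ_linear_from_components(c, s, xr, n)
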