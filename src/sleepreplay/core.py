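"""Shared data model: continuous EEG, hypnogram masks, epoch sets, behavior tables.

Conventions used throughout the package:

* signal amplitudes are microvolts (µV)
* time is continuous seconds; sample indices are 0-based; ``index = round(t * sfreq)``
* epoch windows are endpoint-inclusive: a window ``[t0, t1]`` at sampling rate
  ``sfreq`` contains ``round((t1 - t0) * sfreq) + 1`` samples, symmetric around
  the lock sample
* phase angles are radians wrapped to (−π, π]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Integer codes for sleep stages in :class:`HypnogramMask`.
STAGE_CODES = {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4}
STAGE_NAMES = {v: k for k, v in STAGE_CODES.items()}

#: Stages in which slow oscillations and spindles are scored.
NREM_STAGES = (STAGE_CODES["N2"], STAGE_CODES["N3"])


@dataclass
class ContinuousEEG:
    """Multichannel continuous EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels.
    channel_positions : ndarray, shape (n_channels, 3), optional
        Cartesian sensor coordinates (arbitrary units; used for searchlight
        neighborhoods, not for source modelling).
    reference : str
        Reference scheme: a recording-reference label (e.g. ``"FCz"``),
        ``"linked-mastoids"`` or ``"common-average"``.
    log : list of str
        Provenance log; every transform appends one entry.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    channel_positions: np.ndarray | None = None
    reference: str = "recording"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape != (self.data.shape[0], 3):
                raise ValueError("channel_positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not found; available: {self.channel_names}"
            ) from None

    def get_channel(self, name: str) -> np.ndarray:
        """Return one channel's trace (a view, in µV)."""
        return self.data[self.channel_index(name)]

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(
            data=self.data.copy(),
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
            reference=self.reference,
            log=list(self.log),
        )


@dataclass
class HypnogramMask:
    """Per-sample sleep stage and artifact/movement flags.

    ``stages`` holds integer codes (:data:`STAGE_CODES`); ``artifact`` marks
    movement/artifact samples that must not contribute to event detection.
    """

    stages: np.ndarray
    artifact: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int8)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.stages.shape != self.artifact.shape or self.stages.ndim != 1:
            raise ValueError("stages and artifact must be equal-length 1-D arrays")

    @classmethod
    def from_epochs(
        cls,
        stage_labels: list[str],
        sfreq: float,
        n_samples: int,
        epoch_length: float = 30.0,
        artifact_epochs: list[int] | None = None,
    ) -> "HypnogramMask":
        """Expand a standard per-30-s scored hypnogram to per-sample codes."""
        per_epoch = int(round(epoch_length * sfreq))
        codes = np.concatenate(
            [np.full(per_epoch, STAGE_CODES[s], dtype=np.int8) for s in stage_labels]
        )
        if codes.size < n_samples:
            codes = np.pad(codes, (0, n_samples - codes.size), constant_values=STAGE_CODES["W"])
        codes = codes[:n_samples]
        artifact = np.zeros(n_samples, dtype=bool)
        for i in artifact_epochs or []:
            artifact[i * per_epoch : (i + 1) * per_epoch] = True
        return cls(stages=codes, artifact=artifact, sfreq=sfreq)

    def __len__(self) -> int:
        return self.stages.size

    @property
    def valid_nrem(self) -> np.ndarray:
        """Boolean mask of movement-free N2/N3 samples."""
        return np.isin(self.stages, NREM_STAGES) & ~self.artifact


@dataclass
class EpochSet:
    """Events × channels × time array locked to a common event.

    ``lock`` names the 0-s anchor: ``"stimulus-onset"``, ``"SO-downstate"`` or
    ``"spindle-trough"``. ``labels``, when present, is one category per event.
    """

    data: np.ndarray
    times: np.ndarray
    lock: str
    channel_names: list[str]
    labels: np.ndarray | None = None
    channel_positions: np.ndarray | None = None
    participant: int | str | None = None
    session: int | str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (events x channels x time)")
        if self.times.size != self.data.shape[2]:
            raise ValueError("times length must match data time axis")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("times must be strictly increasing with uniform step")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError("labels must have one entry per event")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        if self.times.size < 2:
            raise ValueError("cannot infer sfreq from a single time point")
        return 1.0 / float(self.times[1] - self.times[0])

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1 (small tolerance)."""
        eps = 0.5 / self.sfreq
        return (self.times >= t0 - eps) & (self.times <= t1 + eps)

    def crop(self, t0: float, t1: float) -> "EpochSet":
        m = self.time_mask(t0, t1)
        return EpochSet(
            data=self.data[:, :, m],
            times=self.times[m],
            lock=self.lock,
            channel_names=list(self.channel_names),
            labels=None if self.labels is None else self.labels.copy(),
            channel_positions=self.channel_positions,
            participant=self.participant,
            session=self.session,
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            lock=self.lock,
            channel_names=list(self.channel_names),
            labels=None if self.labels is None else self.labels.copy(),
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
            participant=self.participant,
            session=self.session,
        )


BEHAVIOR_COLUMNS = [
    "participant",
    "session",
    "n_old",
    "n_new",
    "hits_pre",
    "false_alarms_pre",
    "hits_post",
    "false_alarms_post",
    "recalled_pre",
    "recalled_post",
]


def validate_behavior_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a behavior count table (one row per participant × session).

    Counts are recognition hits / false alarms and cued-recall successes for
    the pre- and post-sleep tests. Raises ``ValueError`` on any violated bound
    (``0 ≤ hits ≤ n_old``, ``0 ≤ false_alarms ≤ n_new``, ``recalled ≤ hits``).
    """
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    t = table
    for phase in ("pre", "post"):
        hits = t[f"hits_{phase}"]
        fas = t[f"false_alarms_{phase}"]
        rec = t[f"recalled_{phase}"]
        if ((hits < 0) | (hits > t["n_old"])).any():
            raise ValueError(f"hits_{phase} outside [0, n_old]")
        if ((fas < 0) | (fas > t["n_new"])).any():
            raise ValueError(f"false_alarms_{phase} outside [0, n_new]")
        if ((rec < 0) | (rec > hits)).any():
            raise ValueError(f"recalled_{phase} outside [0, hits_{phase}]")
    return table
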