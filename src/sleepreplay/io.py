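"""Reading/writing standard formats and the basic continuous-signal transforms.

EDF and BrainVision recordings are read through :mod:`mne`. EDF writing uses a
compact EDF+ writer implemented here (16-bit, 1-s data records), adequate for
round-tripping simulated recordings and interoperable with standard readers.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .core import (
    STAGE_CODES,
    STAGE_NAMES,
    ContinuousEEG,
    EpochSet,
    HypnogramMask,
    validate_behavior_table,
)

MASTOID_PAIRS = [("M1", "M2"), ("A1", "A2"), ("TP9", "TP10")]


# ---------------------------------------------------------------------------
# EDF / BrainVision
# ---------------------------------------------------------------------------

def read_eeg(path: str | Path, fmt: str | None = None) -> ContinuousEEG:
    """Read a continuous EEG recording (EDF or BrainVision) into microvolts.

    ``fmt`` may be ``"edf"`` or ``"brainvision"``; when omitted it is inferred
    from the file extension (``.edf`` / ``.vhdr``).
    """
    import mne

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".edf": "edf", ".vhdr": "brainvision"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer EEG format from extension {suffix!r}")
    fmt = fmt.lower()
    if fmt == "edf":
        if not path.exists():
            raise FileNotFoundError(f"EDF file not found: {path}")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "brainvision":
        if not path.exists():
            raise FileNotFoundError(f"BrainVision header not found: {path}")
        for ext in (".eeg", ".vmrk"):
            companion = path.with_suffix(ext)
            if not companion.exists():
                raise FileNotFoundError(
                    f"BrainVision companion file missing: {companion.name}"
                )
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown EEG format {fmt!r} (use 'edf' or 'brainvision')")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return ContinuousEEG(
        data=data_uv,
        sfreq=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        reference="recording",
        log=[f"read {fmt} file {path.name}"],
    )


def write_edf(eeg: ContinuousEEG, path: str | Path) -> Path:
    """Write a recording to EDF+ (16-bit, 1-second data records).

    The physical range is set per channel from the data extrema, so the
    round-trip error is at most one quantization step. The final record is
    zero-padded when the recording length is not a whole number of seconds.
    """
    path = Path(path)
    sfreq = eeg.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_ch = eeg.n_channels
    n_records = int(np.ceil(eeg.n_samples / spr))

    data = np.zeros((n_ch, n_records * spr))
    data[:, : eeg.n_samples] = eeg.data

    pmin = np.minimum(data.min(axis=1), -1.0)
    pmax = np.maximum(data.max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    def pad(value: str, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("EDF+C", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(name, 16) for name in eeg.channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:.8g}"[:8], 8) for v in pmin],
        [pad(f"{v:.8g}"[:8], 8) for v in pmax],
        [pad(str(dmin), 8)] * n_ch,
        [pad(str(dmax), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # records are channel-blocked: all of ch1's samples, then ch2's, ...
        for rec in range(n_records):
            fh.write(digital[:, rec * spr : (rec + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# Hypnogram / behavior / epochs containers
# ---------------------------------------------------------------------------

def write_hypnogram(mask: HypnogramMask, path: str | Path) -> Path:
    """Write a per-sample hypnogram to TSV (columns: sample, stage, artifact)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample": np.arange(len(mask)),
            "stage": [STAGE_NAMES[c] for c in mask.stages],
            "artifact": mask.artifact.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_hypnogram(path: str | Path, sfreq: float) -> HypnogramMask:
    df = pd.read_csv(path, sep="\t")
    stages = np.array([STAGE_CODES[s] for s in df["stage"]], dtype=np.int8)
    return HypnogramMask(
        stages=stages, artifact=df["artifact"].to_numpy(dtype=bool), sfreq=sfreq
    )


def write_behavior(table: pd.DataFrame, path: str | Path) -> Path:
    validate_behavior_table(table)
    table.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_behavior(path: str | Path) -> pd.DataFrame:
    return validate_behavior_table(pd.read_csv(path, sep="\t"))


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Save an epoch set as ``.npz`` with a JSON sidecar for the metadata."""
    path = Path(path)
    np.savez_compressed(path, data=epochs.data)
    sidecar = {
        "times": epochs.times.tolist(),
        "lock": epochs.lock,
        "channel_names": list(epochs.channel_names),
        "labels": None if epochs.labels is None else epochs.labels.tolist(),
        "participant": epochs.participant,
        "session": epochs.session,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as npz:
        data = npz["data"]
    return EpochSet(
        data=data,
        times=np.asarray(meta["times"]),
        lock=meta["lock"],
        channel_names=meta["channel_names"],
        labels=None if meta["labels"] is None else np.asarray(meta["labels"]),
        participant=meta["participant"],
        session=meta["session"],
    )


# ---------------------------------------------------------------------------
# Signal transforms
# ---------------------------------------------------------------------------

def resample(
    eeg: ContinuousEEG,
    target_sfreq: float,
    mask: HypnogramMask | None = None,
) -> ContinuousEEG | tuple[ContinuousEEG, HypnogramMask]:
    """Anti-alias filter and downsample to ``target_sfreq``.

    Uses polyphase resampling; the output has ``ceil(n * target / sfreq)``
    samples. Upsampling is refused. A hypnogram mask, when given, is resampled
    by nearest stage label and returned alongside.
    """
    if target_sfreq > eeg.sfreq:
        raise ValueError("upsampling not supported (target_sfreq > sfreq)")
    if np.isclose(target_sfreq, eeg.sfreq):
        out = eeg.copy()
        out.log.append(f"resample: identity at {eeg.sfreq} Hz")
        return (out, mask) if mask is not None else out

    frac = Fraction(target_sfreq / eeg.sfreq).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = scipy.signal.resample_poly(eeg.data, up, down, axis=1)
    out = ContinuousEEG(
        data=data,
        sfreq=target_sfreq,
        channel_names=list(eeg.channel_names),
        channel_positions=eeg.channel_positions,
        reference=eeg.reference,
        log=eeg.log + [f"resample: {eeg.sfreq} -> {target_sfreq} Hz"],
    )
    if mask is None:
        return out
    idx = np.clip(
        np.round(np.arange(out.n_samples) * down / up).astype(int), 0, len(mask) - 1
    )
    new_mask = HypnogramMask(
        stages=mask.stages[idx], artifact=mask.artifact[idx], sfreq=target_sfreq
    )
    return out, new_mask


def rereference(
    eeg: ContinuousEEG,
    scheme: str,
    mastoids: tuple[str, str] | None = None,
    drop_mastoids: bool = False,
) -> ContinuousEEG:
    """Re-reference to linked mastoids or to the common average.

    ``linked-mastoids`` subtracts the mean of the two mastoid channels from
    every channel; ``common-average`` subtracts the per-sample mean over all
    channels.
    """
    out = eeg.copy()
    if scheme == "common-average":
        out.data -= out.data.mean(axis=0, keepdims=True)
        out.reference = "common-average"
        out.log.append("rereference: common average")
        return out
    if scheme != "linked-mastoids":
        raise ValueError(f"unknown reference scheme {scheme!r}")

    if mastoids is None:
        for pair in MASTOID_PAIRS:
            if all(m in eeg.channel_names for m in pair):
                mastoids = pair
                break
    if mastoids is None or not all(m in eeg.channel_names for m in mastoids):
        raise ValueError(
            "mastoid channels not found; available channels: "
            + ", ".join(eeg.channel_names)
        )
    i1, i2 = (eeg.channel_index(m) for m in mastoids)
    ref = 0.5 * (out.data[i1] + out.data[i2])
    out.data -= ref[None, :]
    if drop_mastoids:
        keep = [i for i in range(out.n_channels) if i not in (i1, i2)]
        out.data = out.data[keep]
        out.channel_names = [out.channel_names[i] for i in keep]
        if out.channel_positions is not None:
            out.channel_positions = out.channel_positions[keep]
    out.reference = "linked-mastoids"
    out.log.append(f"rereference: linked mastoids {mastoids}")
    return out


def extract_epochs(
    eeg: ContinuousEEG,
    lock_times: np.ndarray,
    window: tuple[float, float],
    lock: str = "stimulus-onset",
    labels: np.ndarray | None = None,
    channels: list[str] | None = None,
) -> EpochSet:
    """Cut fixed-length epochs around lock times.

    The window is endpoint-inclusive (``round((t1-t0)*sfreq)+1`` samples).
    Events whose window exceeds the recording bounds are dropped (their count
    is recorded in the returned set via the dropped-event bookkeeping of the
    caller; a note would normally go to the provenance log).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    lock_times = np.atleast_1d(np.asarray(lock_times, dtype=float))
    sfreq = eeg.sfreq
    n_samp = int(round((t1 - t0) * sfreq)) + 1
    off0 = int(round(t0 * sfreq))

    if channels is not None:
        ch_idx = [eeg.channel_index(c) for c in channels]
        names = list(channels)
        pos = None if eeg.channel_positions is None else eeg.channel_positions[ch_idx]
    else:
        ch_idx = list(range(eeg.n_channels))
        names = list(eeg.channel_names)
        pos = eeg.channel_positions

    starts = np.round(lock_times * sfreq).astype(int) + off0
    keep = (starts >= 0) & (starts + n_samp <= eeg.n_samples)
    starts_kept = starts[keep]
    data = np.empty((starts_kept.size, len(ch_idx), n_samp))
    for i, s in enumerate(starts_kept):
        data[i] = eeg.data[ch_idx, s : s + n_samp]
    times = t0 + np.arange(n_samp) / sfreq
    kept_labels = None
    if labels is not None:
        kept_labels = np.asarray(labels)[keep]
    return EpochSet(
        data=data,
        times=times,
        lock=lock,
        channel_names=names,
        labels=kept_labels,
        channel_positions=pos,
    )
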