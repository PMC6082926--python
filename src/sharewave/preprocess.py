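"""Filtering, referencing, epoch extraction and amplitude-based trial rejection.

The cleaning chain mirrors a conventional scalp-EEG workflow: a zero-phase
0.1–45 Hz band-pass, a common average reference over the scalp channels
(ear references A1/A2 are excluded from the mean and dropped from the
output), fixed-window epoch extraction around stimulus events, and a
peak-to-peak amplitude criterion standing in for manual trial rejection.
ICA-based component cleaning is deliberately not offered: component
selection by eye is irreproducible, and the amplitude criterion is the
documented automated substitute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from scipy import signal

from .montage import Montage, REFERENCE_CHANNELS, build_default_montage
from .synthdata import EpochSet

__all__ = [
    "ContinuousRecording",
    "RejectionLog",
    "bandpass",
    "average_reference",
    "extract_epochs",
    "reject_epochs",
    "read_edf",
]


@dataclass
class ContinuousRecording:
    """Channels x samples voltage with stimulus events.

    ``events`` is a list of ``(sample_index, metadata)`` pairs with
    strictly increasing in-record sample indices; metadata keys
    (condition/rating/rt/subject) are carried into extracted epochs.
    """

    data: np.ndarray              # (n_channels, n_samples), uV
    fs: float
    montage: Montage
    channels: tuple[str, ...]
    events: list[tuple[int, dict[str, Any]]]

    def __post_init__(self) -> None:
        idx = [s for s, _m in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside the recording")


@dataclass
class RejectionLog:
    """Which trials an amplitude criterion removed, and why."""

    threshold: float
    dropped: list[dict[str, Any]]   # {"trial": i, "channels": [...], "p2p": x}
    n_in: int
    n_out: int
    warnings: list[str]


def _band_filters(low: float, high: float, fs: float):
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid band corners ({low}, {high}) for fs={fs}: "
            "need 0 < low < high < fs/2")
    hp = signal.butter(4, low, btype="highpass", fs=fs)
    lp = signal.butter(12, high, btype="lowpass", fs=fs)
    return hp, lp


def bandpass(obj: EpochSet | ContinuousRecording, low: float = 0.1,
             high: float = 45.0):
    """Zero-phase Butterworth band-pass along the sample axis.

    Realized as a high-pass (order 4, gentle at the 0.1 Hz corner) in
    cascade with a steep low-pass (order 12), each applied forward and
    backward with Gustafsson initial conditions so edge transients stay
    small on epoch-length data.  The squared magnitude response leaves a
    50 Hz mains tone at < 10% amplitude for the default 0.1–45 Hz band
    and attenuates far more than 20 dB one octave outside it.  Returns
    the same kind of object with the same shape.
    """
    (b_hp, a_hp), (b_lp, a_lp) = _band_filters(low, high, obj.fs)
    filtered = signal.filtfilt(b_hp, a_hp, obj.data, axis=-1, method="gust")
    filtered = signal.filtfilt(b_lp, a_lp, filtered, axis=-1, method="gust")
    return replace(obj, data=filtered)


def average_reference(epochs: EpochSet) -> EpochSet:
    """Common average reference over the analysis (scalp) channels.

    The per-sample mean over scalp channels is subtracted from every
    scalp channel; reference channels A1/A2 contribute nothing to the
    mean and are dropped from the output.
    """
    keep = [i for i, c in enumerate(epochs.channels)
            if c not in REFERENCE_CHANNELS]
    if len(keep) < 2:
        raise ValueError("need at least 2 analysis channels to re-reference")
    chans = tuple(epochs.channels[i] for i in keep)
    data = epochs.data[:, keep, :]
    data = data - data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data, channels=chans)


def extract_epochs(recording: ContinuousRecording, t0: float = -0.5,
                   t1: float = 10.2) -> EpochSet:
    """Cut one fixed-length epoch per event (t0 s to t1 s around each).

    Sample count per epoch is ``round((t1 - t0) * fs)``; event metadata
    fields condition/rating/rt/subject are carried into the epoch set.
    An event whose window leaves the recording raises an error naming it.
    """
    n_s = round((t1 - t0) * recording.fs)
    off0 = round(t0 * recording.fs)
    n_total = recording.data.shape[1]
    trials, meta = [], {"condition": [], "rating": [], "rt": [], "subject": []}
    for k, (samp, m) in enumerate(recording.events):
        start = samp + off0
        if start < 0 or start + n_s > n_total:
            raise ValueError(
                f"epoch window for event {k} (sample {samp}) exceeds the "
                f"recording bounds [{start}, {start + n_s})")
        trials.append(recording.data[:, start:start + n_s])
        meta["condition"].append(m.get("condition", "noshare"))
        meta["rating"].append(m.get("rating", np.nan))
        meta["rt"].append(m.get("rt", np.nan))
        meta["subject"].append(m.get("subject", 0))
    data = (np.stack(trials) if trials
            else np.empty((0, recording.data.shape[0], n_s)))
    return EpochSet(data=data, fs=recording.fs, t0=t0,
                    montage=recording.montage, channels=recording.channels,
                    condition=np.array(meta["condition"]),
                    rating=np.array(meta["rating"], dtype=float),
                    rt=np.array(meta["rt"], dtype=float),
                    subject=np.array(meta["subject"]))


def reject_epochs(epochs: EpochSet, peak_to_peak_max: float
                  ) -> tuple[EpochSet, RejectionLog]:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is dropped when any analysis channel's max-minus-min voltage
    exceeds ``peak_to_peak_max`` uV.  Surviving trials keep their order
    and metadata alignment; the log lists dropped trials with the
    offending channels.
    """
    if not peak_to_peak_max > 0:
        raise ValueError("peak_to_peak_max must be > 0")
    keep_ch = [i for i, c in enumerate(epochs.channels)
               if c not in REFERENCE_CHANNELS]
    p2p = epochs.data[:, keep_ch, :].max(axis=2) - \
        epochs.data[:, keep_ch, :].min(axis=2)
    bad = p2p > peak_to_peak_max
    dropped = []
    for i in np.flatnonzero(bad.any(axis=1)):
        offenders = [epochs.channels[keep_ch[j]]
                     for j in np.flatnonzero(bad[i])]
        dropped.append({"trial": int(i), "channels": offenders,
                        "p2p": float(p2p[i].max())})
    keep = ~bad.any(axis=1)
    out = replace(epochs, data=epochs.data[keep],
                  condition=epochs.condition[keep],
                  rating=epochs.rating[keep], rt=epochs.rt[keep],
                  subject=epochs.subject[keep])
    warnings = []
    if out.n_trials == 0 and epochs.n_trials > 0:
        warnings.append("all trials rejected — empty epoch set")
    log = RejectionLog(threshold=peak_to_peak_max, dropped=dropped,
                       n_in=epochs.n_trials, n_out=out.n_trials,
                       warnings=warnings)
    return out, log


def read_edf(path: str, montage: Montage | None = None) -> ContinuousRecording:
    """Import an EDF/EDF+ recording as a :class:`ContinuousRecording`.

    Requires the optional ``mne`` dependency; physical units are
    converted to uV.  Channels not present in the montage are dropped.
    Events are left empty — attach them before epoch extraction.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF import requires the optional 'mne' dependency "
            "(pip install sharewave[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    montage = montage or build_default_montage()
    picks = [ch for ch in raw.ch_names if ch in montage.labels]
    if not picks:
        raise ValueError("no montage channels found in the EDF file")
    raw.pick(picks)
    data = raw.get_data() * 1e6  # volts -> uV
    return ContinuousRecording(data=data, fs=float(raw.info["sfreq"]),
                               montage=montage, channels=tuple(raw.ch_names),
                               events=[])
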