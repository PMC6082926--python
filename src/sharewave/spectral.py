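"""Time-frequency power estimation and band-level summaries.

Power spectral density is estimated per trial, channel and integer
frequency with a cycle-proportional sliding window: at frequency f the
window holds a fixed number of cycles (7 by default), so windows shrink
from low to high frequencies (e.g. ~0.7 s at 10 Hz, ~0.35 s at 20 Hz).
Each window is Hann-tapered and the single-frequency spectral density is

    P(f, t) = 2 |sum_n w[n] x[t+n] exp(-i 2 pi f n / fs)|^2 / (fs sum_n w[n]^2)

i.e. the one-sided density convention normalized by the taper energy, in
uV^2/Hz.  Window centers advance on a fixed 50 ms grid and only positions
where the window lies fully inside the epoch are evaluated; cells outside
a frequency's valid range are NaN in the TFR and excluded from time
averages.

Band summaries average the time-averaged density over the grid
frequencies of each band — theta 4–8 Hz, alpha 8–12 Hz, beta 12–20 Hz,
with shared edges belonging to both adjacent bands (the band definitions
read literally) — and are natural-log transformed for group statistics.
The frontal alpha asymmetry index is ln alpha-power at F4 minus ln
alpha-power at F3, per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .synthdata import EpochSet

__all__ = [
    "TFR",
    "ChanFreqPower",
    "BandPower",
    "FAAResult",
    "DEFAULT_FREQS",
    "DEFAULT_BAND_DEFS",
    "sliding_psd",
    "time_average",
    "band_average",
    "faa_index",
    "compute_band_power",
    "band_power_frame",
]

#: Default analysis grid: 1 Hz steps, 2–30 Hz.
DEFAULT_FREQS = np.arange(2.0, 31.0)

#: Band name -> inclusive frequency interval (Hz).
DEFAULT_BAND_DEFS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
}


@dataclass
class TFR:
    """Trials x channels x frequencies x window-centers spectral density."""

    power: np.ndarray       # uV^2/Hz; NaN where the window would cross an edge
    freqs: np.ndarray       # Hz
    times: np.ndarray       # s, window centers (50 ms apart)
    fs: float
    channels: tuple[str, ...]
    window_samples: np.ndarray  # per-frequency Hann length (odd sample counts)


@dataclass
class ChanFreqPower:
    """Time-averaged density: trials x channels x frequencies."""

    power: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]


@dataclass
class BandPower:
    """Natural-log band-mean density: trials x channels x bands."""

    logpower: np.ndarray
    bands: dict[str, tuple[float, float]]
    band_names: tuple[str, ...]
    channels: tuple[str, ...]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.logpower[:, :, self.band_names.index(name)]
        except ValueError:
            raise KeyError(f"band {name!r} not present") from None

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class FAAResult:
    """Per-trial frontal alpha asymmetry: ln alpha(F4) - ln alpha(F3)."""

    faa: np.ndarray
    electrodes: tuple[str, str] = ("F4", "F3")


def window_length_samples(freq: float, cycles: int, fs: float) -> int:
    """Cycle-proportional window length, rounded to the nearest odd count."""
    n = cycles / freq * fs
    odd = 2 * round((n - 1) / 2) + 1
    return int(max(odd, 3))


def sliding_psd(epochs: EpochSet, freqs: np.ndarray | None = None,
                cycles: int = 7, step: float = 0.05) -> TFR:
    """Sliding single-taper Hann spectral density of every trial/channel.

    ``freqs`` defaults to the 2–30 Hz integer grid.  Raises if the window
    at the lowest frequency is longer than the epoch.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    data = epochs.data
    n_s = data.shape[-1]
    duration = n_s / epochs.fs
    step_samp = max(round(step * epochs.fs), 1)

    wlens = np.array([window_length_samples(f, cycles, epochs.fs)
                      for f in freqs])
    for f, w in zip(freqs, wlens):
        if w > n_s:
            raise ValueError(
                f"window of {cycles} cycles at {f:g} Hz ({w / epochs.fs:.3f} s) "
                f"exceeds the epoch duration ({duration:.3f} s)")

    # candidate centers on the step grid (sample indices from epoch start)
    min_hw = (wlens.min() - 1) // 2
    ks = np.arange(0, n_s // step_samp + 1)
    centers = ks * step_samp
    centers = centers[(centers >= min_hw) & (centers <= n_s - 1 - min_hw)]
    times = epochs.t0 + centers / epochs.fs

    shape = data.shape[:-1]
    power = np.full(shape + (len(freqs), len(centers)), np.nan)
    for fi, (f, wlen) in enumerate(zip(freqs, wlens)):
        hw = (wlen - 1) // 2
        taper = hann(wlen, sym=True)
        n_rel = np.arange(wlen) - hw
        # real/imag demodulation kernels, stacked for one matmul per window
        kern = np.stack([taper * np.cos(2 * np.pi * f * n_rel / epochs.fs),
                         taper * np.sin(2 * np.pi * f * n_rel / epochs.fs)],
                        axis=1)
        norm = 2.0 / (epochs.fs * np.sum(taper ** 2))
        valid = (centers >= hw) & (centers <= n_s - 1 - hw)
        for ti in np.flatnonzero(valid):
            c = centers[ti]
            seg = data[..., c - hw:c + hw + 1]
            xy = seg @ kern                      # (..., 2)
            power[..., fi, ti] = norm * (xy[..., 0] ** 2 + xy[..., 1] ** 2)

    return TFR(power=power, freqs=freqs, times=times, fs=epochs.fs,
               channels=epochs.channels, window_samples=wlens)


def time_average(tfr: TFR, t_start: float = 0.0, t_end: float = 9.0
                 ) -> ChanFreqPower:
    """Arithmetic mean of the TFR over window centers in [t_start, t_end].

    Centers where a frequency's window crossed the epoch edge (NaN cells)
    are excluded from that frequency's mean.  Raises when no center falls
    in the interval, or when some frequency has no valid center there.
    """
    sel = (tfr.times >= t_start - 1e-9) & (tfr.times <= t_end + 1e-9)
    if not sel.any():
        raise ValueError(
            f"no window centers inside [{t_start}, {t_end}] s")
    chunk = tfr.power[..., sel]
    if chunk.size:
        # the NaN pattern is identical for every trial and channel
        counts = np.isfinite(chunk).sum(axis=-1).reshape(-1, len(tfr.freqs))
        empty = np.flatnonzero(counts[0] == 0)
        if empty.size:
            raise ValueError(
                "no valid window centers inside "
                f"[{t_start}, {t_end}] s at {tfr.freqs[empty[0]]:g} Hz")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(chunk, axis=-1)
    return ChanFreqPower(power=mean, freqs=tfr.freqs, channels=tfr.channels)


def band_average(cfp: ChanFreqPower,
                 bands: dict[str, tuple[float, float]] | None = None
                 ) -> BandPower:
    """Mean density over each band's grid frequencies, then natural log.

    Band edges are inclusive on both sides, so a grid frequency shared by
    two bands (8 Hz, 12 Hz) contributes to both.
    """
    bands = dict(DEFAULT_BAND_DEFS) if bands is None else dict(bands)
    names = tuple(bands)
    cols = []
    for name in names:
        lo, hi = bands[name]
        sel = (cfp.freqs >= lo - 1e-9) & (cfp.freqs <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}] Hz contains no "
                             "grid frequency")
        cols.append(cfp.power[..., sel].mean(axis=-1))
    logpower = np.log(np.stack(cols, axis=-1))
    return BandPower(logpower=logpower, bands=bands, band_names=names,
                     channels=cfp.channels)


def faa_index(bp: BandPower) -> FAAResult:
    """Frontal alpha asymmetry per trial: ln alpha(F4) - ln alpha(F3).

    Note the field convention this index inherits: alpha power is
    inversely related to cortical activity, so *negative* values indicate
    relatively greater right-frontal activity.
    """
    alpha = bp.band("alpha")
    i4, i3 = bp.channel_index("F4"), bp.channel_index("F3")
    return FAAResult(faa=alpha[:, i4] - alpha[:, i3])


def compute_band_power(epochs: EpochSet, freqs: np.ndarray | None = None,
                       cycles: int = 7, step: float = 0.05,
                       t_start: float = 0.0, t_end: float = 9.0,
                       bands: dict[str, tuple[float, float]] | None = None,
                       ) -> tuple[ChanFreqPower, BandPower]:
    """Convenience chain: sliding PSD -> time average -> log band power."""
    tfr = sliding_psd(epochs, freqs=freqs, cycles=cycles, step=step)
    cfp = time_average(tfr, t_start=t_start, t_end=t_end)
    return cfp, band_average(cfp, bands=bands)


def band_power_frame(bp: BandPower, condition: np.ndarray | None = None
                     ) -> pd.DataFrame:
    """Tidy table (trial, channel, band, logpower[, condition])."""
    n_t, n_c, n_b = bp.logpower.shape
    t, c, b = np.meshgrid(np.arange(n_t), np.arange(n_c), np.arange(n_b),
                          indexing="ij")
    frame = pd.DataFrame({
        "trial": t.ravel(),
        "channel": np.array(bp.channels)[c.ravel()],
        "band": np.array(bp.band_names)[b.ravel()],
        "logpower": bp.logpower.ravel(),
    })
    if condition is not None:
        frame["condition"] = np.asarray(condition)[frame["trial"]]
    return frame
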