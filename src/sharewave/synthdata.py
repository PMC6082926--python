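"""Seeded generator of scalp-EEG epochs with a known effect structure.

Each simulated trial is a sum of a 1/f-shaped ("pink") background and one
band-limited oscillatory component per configured frequency band, drawn
independently per trial and channel.  Condition effects are multiplicative
gains on the oscillation amplitude at named (band, channel, condition)
triples, so a gain of 1 means no effect and the null is exact by
construction.  Behavioral metadata is drawn alongside: a bounded liking
rating (scaled Beta, parameterized by its median) and a right-skewed
response time (log-normal, parameterized by its median).

The default configuration emulates a video-sharing study: 316 "share" vs
1099 "not-share" trials of 10.7 s (0.5 s pre-stimulus) at 600 Hz on the
10–20 montage; elevated theta (4–8 Hz) power at F3/Fz/F4/P4/P8/O2 and
elevated alpha (8–12 Hz) power at Fz/F4/O2 in the not-share condition;
rating medians 0.75 (share) vs 0.45 (not share); response-time medians
0.95 s vs 0.74 s.  The asymmetric alpha gain at F4 simultaneously makes
the frontal alpha asymmetry (ln alpha F4 − ln alpha F3) relatively more
negative in the share condition, as observed.

Named scenarios (see :func:`scenario`) provide the full-size configuration
and compute-scaled variants used by the calibration and recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import Montage, build_default_montage

__all__ = [
    "EffectSpec",
    "SimConfig",
    "EpochSet",
    "pink_noise",
    "narrowband_component",
    "simulate_epochs",
    "scenario",
    "SCENARIOS",
    "DEFAULT_BANDS",
]

#: Band name -> (interval in Hz, baseline oscillation RMS amplitude in uV).
#: Amplitudes sit below the broadband background (10 uV RMS) so that band
#: power is an oscillation/noise mixture, as in real scalp EEG.
DEFAULT_BANDS: dict[str, tuple[tuple[float, float], float]] = {
    "theta": ((4.0, 8.0), 3.0),
    "alpha": ((8.0, 12.0), 4.0),
    "beta": ((12.0, 20.0), 2.0),
}

CONDITIONS = ("share", "noshare")


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative amplitude gain for one band/channel-set/condition."""

    band: tuple[float, float]
    channels: tuple[str, ...]
    condition: str
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        lo, hi = self.band
        if not (2.0 <= lo < hi <= 30.0):
            raise ValueError("effect band must lie within [2, 30] Hz")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated dataset (deterministic per seed)."""

    n_share: int = 316
    n_noshare: int = 1099
    fs: float = 600.0
    t0: float = -0.5
    t1: float = 10.2
    noise_sd: float = 10.0
    noise_slope: float = 1.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    effects: tuple[EffectSpec, ...] = ()
    rating_medians: tuple[float, float] = (0.75, 0.45)
    rt_medians: tuple[float, float] = (0.95, 0.74)
    rt_sigma: float = 0.6
    n_subjects: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_share < 0 or self.n_noshare < 0:
            raise ValueError("trial counts must be >= 0")
        if not (self.t0 < 0 < self.t1):
            raise ValueError("epoch must span the stimulus onset: t0 < 0 < t1")
        top = max(hi for (lo, hi), _amp in self.bands.values())
        if self.fs <= 2 * top:
            raise ValueError("fs must exceed twice the highest oscillation frequency")

    @property
    def n_samples(self) -> int:
        return round((self.t1 - self.t0) * self.fs)

    @property
    def n_trials(self) -> int:
        return self.n_share + self.n_noshare


@dataclass
class EpochSet:
    """Trials x channels x samples voltage with per-trial metadata."""

    data: np.ndarray          # (n_trials, n_channels, n_samples), uV
    fs: float
    t0: float
    montage: Montage
    channels: tuple[str, ...]  # channel order of axis 1
    condition: np.ndarray      # (n_trials,) of {"share","noshare"}
    rating: np.ndarray         # (n_trials,) in [0,1]
    rt: np.ndarray             # (n_trials,) seconds
    subject: np.ndarray        # (n_trials,) int ids

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("condition", "rating", "rt", "subject"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"metadata field {name!r} length != trial count")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite voltages in epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None


# ---------------------------------------------------------------------------
# signal kernels
# ---------------------------------------------------------------------------

def _pink_shaped(rng: np.random.Generator, shape: tuple[int, ...],
                 n_samples: int, fs: float, slope: float, sd: float,
                 dtype=np.float64) -> np.ndarray:
    """Vectorized 1/f^slope noise over leading dims; exact per-series RMS = sd."""
    white = rng.standard_normal(shape + (n_samples,), dtype=dtype)
    if sd == 0:
        return np.zeros_like(white)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-slope / 2.0)
    x = np.fft.irfft(spec * scale.astype(spec.real.dtype), n=n_samples,
                     axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x * (sd / rms)


def pink_noise(n_samples: int, fs: float, slope: float, sd: float,
               seed: int) -> np.ndarray:
    """Zero-mean background noise with power spectral density ~ f^(-slope).

    Realized by spectrally shaping Gaussian white noise in the frequency
    domain and rescaling to an exact RMS amplitude of ``sd`` uV.
    ``sd = 0`` returns the all-zero series.  Deterministic per seed.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return _pink_shaped(rng, (), n_samples, fs, slope, sd)


def _band_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _narrowband_shaped(rng: np.random.Generator, shape: tuple[int, ...],
                       band: tuple[float, float], n_samples: int, fs: float,
                       dtype=np.float64) -> np.ndarray:
    """Unit-RMS band-limited noise over leading dims.

    White noise shaped in the frequency domain by the squared magnitude
    response of a 4th-order Butterworth band-pass — the zero-phase
    (forward-backward) filter response, applied circularly.
    """
    sos = _band_sos(band, fs)
    white = rng.standard_normal(shape + (n_samples,), dtype=dtype)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    gain = (np.abs(h) ** 2).astype(dtype)   # |H|^2: filtfilt magnitude
    spec = np.fft.rfft(white, axis=-1)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def narrowband_component(band: tuple[float, float], n_samples: int, fs: float,
                         amplitude: float, seed: int) -> np.ndarray:
    """Band-limited zero-mean oscillation: band-pass-filtered white noise.

    The series is zero-phase filtered (4th-order Butterworth, forward and
    backward) and rescaled to the requested RMS ``amplitude``; at least
    90% of its periodogram power lies inside ``band``.
    """
    _band_sos(band, fs)  # validate before drawing
    if amplitude == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    return amplitude * _narrowband_shaped(rng, (), band, n_samples, fs)


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------

def _beta_params_for_median(median: float, concentration: float = 5.0
                            ) -> tuple[float, float]:
    # Median of Beta(a,b) ~ (a - 1/3)/(a + b - 2/3); solve a at fixed a+b.
    a = median * (concentration - 2.0 / 3.0) + 1.0 / 3.0
    b = concentration - a
    return max(a, 0.05), max(b, 0.05)


def simulate_epochs(config: SimConfig, montage: Montage | None = None,
                    channels: tuple[str, ...] | None = None) -> EpochSet:
    """Generate a seeded :class:`EpochSet` under ``config``.

    Per trial and channel the voltage is pink background plus one
    band-limited component per configured band; gains from
    ``config.effects`` multiply the component amplitude for matching
    (band, channel, condition) triples.  ``channels`` restricts generation
    to a subset of the montage's analysis channels (a pure compute saver —
    trials and channels are independent, so the restriction is exact).
    """
    montage = montage or build_default_montage()
    chans = tuple(channels) if channels is not None else montage.analysis_channels
    for c in chans:
        if c not in montage.labels:
            raise KeyError(f"channel {c!r} not in montage")
    for eff in config.effects:
        for c in eff.channels:
            if c not in montage.labels:
                raise KeyError(f"effect channel {c!r} not in montage")
        if not any(tuple(iv) == tuple(eff.band) for iv, _a in config.bands.values()):
            raise ValueError(
                f"effect band {eff.band} does not match a configured base band")

    rng = np.random.default_rng(config.seed)
    n_tr, n_ch, n_s = config.n_trials, len(chans), config.n_samples

    condition = np.array(["share"] * config.n_share + ["noshare"] * config.n_noshare)

    # single-precision generation: ~1e-7 relative noise on a stochastic
    # signal, halves the memory traffic of the hot simulation loops
    data = _pink_shaped(rng, (n_tr, n_ch), n_s, config.fs,
                        config.noise_slope, config.noise_sd, dtype=np.float32)
    for name, (interval, base_amp) in config.bands.items():
        comp = _narrowband_shaped(rng, (n_tr, n_ch), tuple(interval), n_s,
                                  config.fs, dtype=np.float32)
        gain = np.full((n_tr, n_ch), base_amp, dtype=np.float32)
        for eff in config.effects:
            if tuple(eff.band) != tuple(interval):
                continue
            rows = condition == eff.condition
            cols = [chans.index(c) for c in eff.channels if c in chans]
            if cols:
                gain[np.ix_(rows, cols)] *= eff.gain
        data += gain[:, :, None] * comp

    # behavioral metadata (drawn after the EEG so the voltage stream is
    # unaffected by metadata-only config changes)
    rating = np.empty(n_tr)
    rt = np.empty(n_tr)
    for cond, r_med, t_med in zip(CONDITIONS, config.rating_medians,
                                  config.rt_medians):
        m = condition == cond
        a, b = _beta_params_for_median(r_med)
        rating[m] = rng.beta(a, b, size=m.sum())
        rt[m] = np.exp(np.log(t_med) + config.rt_sigma
                       * rng.standard_normal(m.sum()))
    subject = rng.integers(0, config.n_subjects, size=n_tr)

    data = data.astype(np.float64)
    return EpochSet(data=data, fs=config.fs, t0=config.t0, montage=montage,
                    channels=chans, condition=condition, rating=rating,
                    rt=rt, subject=subject)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

_PAPER_EFFECTS = (
    EffectSpec(band=(4.0, 8.0), channels=("F3", "Fz", "F4", "P4", "P8", "O2"),
               condition="noshare", gain=1.25),
    EffectSpec(band=(8.0, 12.0), channels=("Fz", "F4", "O2"),
               condition="noshare", gain=1.25),
)

# Compute-scaled variants keep the study's trial counts and effect gains but
# use shorter epochs, a 300 Hz rate and band-limited analysis grids; the
# full-size "paper" scenario keeps every acquisition parameter.
SCENARIOS: dict[str, SimConfig] = {
    "paper": SimConfig(effects=_PAPER_EFFECTS),
    "null": SimConfig(n_share=316, n_noshare=1099, effects=()),
    "paper-small": SimConfig(n_share=80, n_noshare=280, fs=300.0,
                             t0=-0.5, t1=3.5, effects=_PAPER_EFFECTS),
    "null-small": SimConfig(n_share=100, n_noshare=100, fs=300.0,
                            t0=-0.25, t1=2.0, effects=()),
    "theta-effect": SimConfig(
        n_share=150, n_noshare=500, fs=300.0, t0=-0.25, t1=2.0,
        effects=(EffectSpec(band=(4.0, 8.0),
                            channels=("F3", "Fz", "F4", "P4", "P8", "O2"),
                            condition="noshare", gain=1.25),)),
    "tiny": SimConfig(n_share=40, n_noshare=80, fs=300.0,
                      t0=-0.25, t1=2.0, effects=_PAPER_EFFECTS),
    "faa-asymmetry": SimConfig(
        n_share=150, n_noshare=150, fs=300.0, t0=-0.25, t1=2.0,
        effects=(EffectSpec(band=(8.0, 12.0), channels=("F3",),
                            condition="share", gain=1.25),)),
}


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A named simulation scenario with the given seed (and field overrides)."""
    try:
        base = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}") from None
    return replace(base, seed=seed, **overrides)
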