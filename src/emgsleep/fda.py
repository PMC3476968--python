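"""Frequency-domain sleep/wake estimation (band-masked spectral power).

For each 30-s epoch the one-sided periodogram of the raw samples is
computed (plain FFT of the whole epoch, no taper by default, 1/30 Hz
resolution) and summed over the surface-EMG band: 10–75 Hz with the
mains band (default 55–65 Hz, for 60 Hz power systems) removed.  Below
10 Hz live movement/baseline artefacts, above 75 Hz mostly noise, and
the mains hum is instrumentation — none of it is muscle activity.

The per-epoch total power ``tp_m`` is compared against a single
whole-recording threshold ``tsf1 * mean(tp) + tsf2 * std(tp)``; epochs
strictly above it are scored WAKE.  Like the time-domain method, the
decision is invariant to positive rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .formats import EPOCH_SECONDS, SLEEP, WAKE, BinaryHypnogram, Recording

#: Retained band (Hz): surface-EMG energy concentrates here.
BAND_LOW = 10.0
BAND_HIGH = 75.0
#: Default mains-interference exclusion (Hz) for 60 Hz power systems.
DEFAULT_MAINS_BAND = (55.0, 65.0)


@dataclass(frozen=True)
class FdaParams:
    """Weights of the spectral threshold: ``tsf1*mean(tp) + tsf2*std(tp)``."""

    tsf1: float = 0.5
    tsf2: float = 3.5

    def __post_init__(self) -> None:
        if self.tsf1 < 0 or self.tsf2 < 0:
            raise ValueError("threshold weights must be non-negative")


@dataclass
class SpectralPowerSeries:
    """Per-epoch band-masked total spectral power (same units as summed x^2)."""

    values: np.ndarray
    band_mask: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _band_keep(
    freqs: np.ndarray,
    mains_band: tuple[float, float] | None,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
) -> np.ndarray:
    """Boolean mask of retained frequency bins.

    Band edges are inclusive for the retained band (a bin at exactly 10
    or 75 Hz is kept) and inclusive for the exclusion (a bin at exactly
    55 or 65 Hz is dropped).  A small tolerance absorbs floating-point
    bin positions.
    """
    tol = 1e-6
    keep = (freqs >= low - tol) & (freqs <= high + tol)
    if mains_band is not None:
        m0, m1 = mains_band
        keep &= ~((freqs >= m0 - tol) & (freqs <= m1 + tol))
    return keep


def epoch_total_power(
    samples: np.ndarray,
    fs: int,
    mains_band: tuple[float, float] | None = DEFAULT_MAINS_BAND,
    window: str = "none",
    band: tuple[float, float] | None = (BAND_LOW, BAND_HIGH),
) -> SpectralPowerSeries:
    """Band-masked total spectral power per whole 30-s epoch.

    The power scale is chosen so that with no band exclusion the sum
    over all bins equals the epoch's sum of squared samples (Parseval),
    making ``tp_m`` directly comparable to the time-domain epoch energy.

    ``window='hann'`` applies a Hann taper before the transform;
    ``mains_band=None`` disables the mains exclusion; ``band=(lo, hi)``
    moves the retained interval and ``band=None`` keeps every bin up to
    Nyquist (useful for energy-conservation checks).
    """
    fs = int(fs)
    if band is not None and fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve the retained band up to "
            f"{band[1]} Hz (need fs > {2 * band[1]:g})"
        )
    x = np.asarray(samples, dtype=float)
    spe = fs * EPOCH_SECONDS
    n_epochs = len(x) // spe
    if n_epochs == 0:
        raise ValueError("signal shorter than one 30-s epoch")
    x2d = x[: n_epochs * spe].reshape(n_epochs, spe)
    win = "boxcar" if window in ("none", None) else window
    freqs, pxx = _signal.periodogram(
        x2d, fs=fs, window=win, detrend=False, scaling="spectrum", axis=1
    )
    # 'spectrum' scaling sums to mean(x^2); rescale to energy units.
    pxx = pxx * spe
    lo, hi = band if band is not None else (0.0, fs / 2)
    keep = _band_keep(freqs, mains_band, lo, hi)
    tp = pxx[:, keep].sum(axis=1)
    mask = (
        ((lo, mains_band[0]), (mains_band[1], hi)) if mains_band else ((lo, hi),)
    )
    return SpectralPowerSeries(tp, band_mask=mask)


def recording_total_power(
    rec: Recording,
    mains_band: tuple[float, float] | None = DEFAULT_MAINS_BAND,
    window: str = "none",
) -> SpectralPowerSeries:
    """Per-epoch band power of a recording, summed across channels."""
    parts = [
        epoch_total_power(ch.samples, rec.sampling_rate, mains_band, window)
        for ch in rec.channels
    ]
    total = np.sum([p.values for p in parts], axis=0)
    return SpectralPowerSeries(total, band_mask=parts[0].band_mask)


def spectral_threshold(
    tp: SpectralPowerSeries, p: FdaParams, ddof: int = 1
) -> float:
    """``tsf1 * mean(tp) + tsf2 * std(tp)`` with sample SD (divisor N-1)."""
    v = tp.values
    if len(v) < 2:
        raise ValueError("need at least 2 epochs for the spectral threshold")
    return float(p.tsf1 * v.mean() + p.tsf2 * v.std(ddof=ddof))


def classify_fda(
    tp: SpectralPowerSeries,
    p: FdaParams,
    threshold: float | None = None,
    ddof: int = 1,
) -> BinaryHypnogram:
    """WAKE where ``tp_m`` strictly exceeds the spectral threshold.

    By default the threshold statistics come from the scored recording
    itself (the method adapts to each subject's EMG tone); passing
    ``threshold`` applies a precomputed value, e.g. one frozen from
    training recordings.
    """
    thr = spectral_threshold(tp, p, ddof=ddof) if threshold is None else threshold
    return BinaryHypnogram([WAKE if v > thr else SLEEP for v in tp.values])


def score_fda(
    rec: Recording,
    params: FdaParams | None = None,
    mains_band: tuple[float, float] | None = DEFAULT_MAINS_BAND,
    window: str = "none",
) -> tuple[BinaryHypnogram, SpectralPowerSeries, float]:
    """Full frequency-domain pipeline on a recording."""
    params = params or FdaParams()
    tp = recording_total_power(rec, mains_band=mains_band, window=window)
    thr = spectral_threshold(tp, params)
    return classify_fda(tp, params, threshold=thr), tp, thr
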