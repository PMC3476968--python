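"""Time-domain sleep/wake estimation (adaptive amplitude threshold).

Each epoch gets an adaptive energy threshold: the threshold-selection
factor ``tsf1`` times the mean per-epoch energy ``z_l`` over a centred
window of ``2*tsf2 + 1`` epochs.  The per-second energies ``y_k`` of an
epoch are compared against its threshold; the count of seconds above
threshold is the high-EMG count ``HEMG_m``.  An epoch is scored WAKE
when its count strictly exceeds the whole-night mean count, otherwise
SLEEP.  Because both the energies and the thresholds scale with the
square of the signal amplitude, the classification is invariant to any
positive rescaling of the raw EMG.

This is an offline method: the decision line (the mean count) needs the
full night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import EpochEnergy, SecondEnergy, recording_energies
from .formats import EPOCH_SECONDS, SLEEP, WAKE, BinaryHypnogram, Recording


@dataclass(frozen=True)
class TdaParams:
    """Threshold-selection factors for the time-domain method.

    ``tsf1`` is the dimensionless multiplier on the windowed mean epoch
    energy; ``tsf2`` is the half-window width in epochs (25 gives the
    51-epoch window used as the worked example setting, together with
    a multiplier of 4).
    """

    tsf1: float = 4.0
    tsf2: int = 25

    def __post_init__(self) -> None:
        if self.tsf1 <= 0:
            raise ValueError("tsf1 must be positive")
        if self.tsf2 < 0 or int(self.tsf2) != self.tsf2:
            raise ValueError("tsf2 must be a non-negative integer")


@dataclass
class ThresholdSeries:
    """Adaptive per-epoch energy threshold ``T_m``."""

    values: np.ndarray


@dataclass
class HemgSeries:
    """Per-epoch high-EMG second counts and their whole-night mean."""

    counts: np.ndarray
    mean_hemg: float


def windowed_mean(z: np.ndarray, half_window: int) -> np.ndarray:
    """Centred moving average, truncated at the boundaries.

    Near the edges the window shrinks and the divisor is the number of
    epochs actually inside it, so every epoch receives a threshold that
    is an average of observed energies.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    w = int(half_window)
    cs = np.concatenate([[0.0], np.cumsum(z)])
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    hi = np.minimum(idx + w + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def adaptive_threshold(z: EpochEnergy, p: TdaParams) -> ThresholdSeries:
    """``T_m = tsf1 x mean(z)`` over the centred ``2*tsf2+1``-epoch window."""
    if len(z.values) == 0:
        raise ValueError("no epochs")
    return ThresholdSeries(p.tsf1 * windowed_mean(z.values, p.tsf2))


def hemg_count(y: SecondEnergy, t: ThresholdSeries) -> HemgSeries:
    """Count per-second energies strictly above the epoch threshold.

    The comparison is strict (a second exactly at threshold does not
    count), so counts run 0–30 per epoch.
    """
    n_epochs = len(t.values)
    if len(y.values) != EPOCH_SECONDS * n_epochs:
        raise ValueError(
            f"need {EPOCH_SECONDS * n_epochs} per-second values for "
            f"{n_epochs} epochs, got {len(y.values)}"
        )
    y2d = y.values.reshape(n_epochs, EPOCH_SECONDS)
    counts = (y2d > t.values[:, None]).sum(axis=1)
    return HemgSeries(counts.astype(int), float(counts.mean()))


def classify_tda(h: HemgSeries) -> BinaryHypnogram:
    """WAKE where the count strictly exceeds the whole-night mean count."""
    if len(h.counts) == 0:
        raise ValueError("no epochs")
    return BinaryHypnogram(
        [WAKE if c > h.mean_hemg else SLEEP for c in h.counts]
    )


def score_tda(
    rec: Recording, params: TdaParams | None = None, remove_dc: bool = False
) -> tuple[BinaryHypnogram, HemgSeries, ThresholdSeries]:
    """Full time-domain pipeline on a recording (bilateral energies summed)."""
    params = params or TdaParams()
    y, z = recording_energies(rec, remove_dc=remove_dc)
    t = adaptive_threshold(z, params)
    h = hemg_count(y, t)
    return classify_tda(h), h, t
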