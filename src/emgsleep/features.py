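"""Time-domain energy features.

The amplitude pathway reduces the raw EMG twice: squared samples are
summed within each second (``y_k``, the per-second energy) and the
per-second energies are summed within each 30-s epoch (``z_l``, the
per-epoch energy).  Both are in squared analog units and conserve the
total signal energy over whole epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import EPOCH_SECONDS, Recording


@dataclass
class SecondEnergy:
    """Per-second summed squared amplitude, 30 values per epoch."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) % EPOCH_SECONDS != 0:
            raise ValueError("second-energy length must be a multiple of 30")

    @property
    def n_epochs(self) -> int:
        return len(self.values) // EPOCH_SECONDS


@dataclass
class EpochEnergy:
    """Per-epoch energy: sum of the 30 per-second energies of the epoch."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def second_energy(samples: np.ndarray, fs: int, remove_dc: bool = False) -> SecondEnergy:
    """Sum of squared amplitudes per second, truncated to whole epochs.

    ``remove_dc`` subtracts the per-epoch mean before squaring — off by
    default, since the estimators apply no preprocessing; it guards
    against storage formats that carry a DC offset, which squaring would
    misread as muscle tone.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    fs = int(fs)
    spe = fs * EPOCH_SECONDS
    n_epochs = len(x) // spe
    if n_epochs == 0:
        raise ValueError("signal shorter than one 30-s epoch")
    x = x[: n_epochs * spe]
    if remove_dc:
        x = (x.reshape(n_epochs, spe) - x.reshape(n_epochs, spe).mean(axis=1, keepdims=True)).ravel()
    y = (x.reshape(-1, fs) ** 2).sum(axis=1)
    return SecondEnergy(y)


def epoch_energy(y: SecondEnergy) -> EpochEnergy:
    """Sum the per-second energies within each 30-s epoch."""
    return EpochEnergy(y.values.reshape(-1, EPOCH_SECONDS).sum(axis=1))


def combine_channels(per_channel):
    """Element-wise sum of per-channel energy series (energy is additive).

    Accepts a list of :class:`SecondEnergy` or :class:`EpochEnergy`;
    a single-element list returns its element unchanged.
    """
    if not per_channel:
        raise ValueError("no channels to combine")
    first = per_channel[0]
    if len(per_channel) == 1:
        return first
    lengths = {len(c.values) for c in per_channel}
    if len(lengths) != 1:
        raise ValueError(f"channel feature lengths differ: {sorted(lengths)}")
    total = np.sum([c.values for c in per_channel], axis=0)
    return type(first)(total)


def recording_energies(
    rec: Recording, combine: str = "sum", remove_dc: bool = False
) -> tuple[SecondEnergy, EpochEnergy]:
    """Per-second and per-epoch energies of a recording.

    With ``combine='sum'`` (default) bilateral channels are summed into
    one energy series before thresholding; ``combine='none'`` is not
    offered here — use :func:`second_energy` per channel for per-channel
    pipelines.
    """
    if combine != "sum":
        raise ValueError("recording_energies only implements combine='sum'")
    per_ch = [
        second_energy(ch.samples, rec.sampling_rate, remove_dc=remove_dc)
        for ch in rec.channels
    ]
    y = combine_channels(per_ch)
    return y, epoch_energy(y)
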