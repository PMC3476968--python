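"""Data containers and text/EDF I/O for overnight EMG scoring.

The scoring unit throughout the package is the 30-second epoch, the
standard unit of clinical sleep staging.  A recording is a set of
equally long amplitude channels at an integer sampling rate; a hypnogram
is one stage label per epoch.  Stage labels follow the classical W /
S1-S4 / REM vocabulary; sleep/wake reduction maps every non-wake stage
to SLEEP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

EPOCH_SECONDS = 30

#: Full stage vocabulary.
STAGES = ("W", "S1", "S2", "S3", "S4", "REM", "UNSCORED")

#: Binary states after sleep/wake reduction.
SLEEP = "SLEEP"
WAKE = "WAKE"
EXCLUDED = "EXCLUDED"

POSTURES = ("SUPINE", "LEFT", "RIGHT", "PRONE", "UNKNOWN")

_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "0": "W",
    "1": "S1", "S1": "S1", "N1": "S1",
    "2": "S2", "S2": "S2", "N2": "S2",
    "3": "S3", "S3": "S3", "N3": "S3",
    "4": "S4", "S4": "S4", "N4": "S4",
    "R": "REM", "REM": "REM", "5": "REM",
    "MT": "UNSCORED", "?": "UNSCORED", "UNSCORED": "UNSCORED",
}

_POSTURE_ALIASES = {
    "SUP": "SUPINE", "SUPINE": "SUPINE",
    "L": "LEFT", "LEFT": "LEFT",
    "R": "RIGHT", "RIGHT": "RIGHT",
    "PRO": "PRONE", "PRONE": "PRONE",
    "UNK": "UNKNOWN", "UNKNOWN": "UNKNOWN",
}


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclass
class Channel:
    """One EMG channel: a label and its amplitude samples (arbitrary analog units)."""

    label: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("channel samples must be one-dimensional")


@dataclass
class Recording:
    """A multichannel surface-EMG recording at a fixed integer sampling rate."""

    channels: list[Channel]
    sampling_rate: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if int(self.sampling_rate) != self.sampling_rate:
            raise ValueError("only integer samples-per-second rates are supported")
        self.sampling_rate = int(self.sampling_rate)
        if not self.channels:
            raise FormatError("recording has no channels")
        lengths = {len(c.samples) for c in self.channels}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")
        if self.n_samples == 0:
            raise ValueError("recording has no samples")
        if self.n_samples < self.samples_per_epoch:
            # loadable (e.g. short excerpts), but not scorable: the
            # feature modules require at least one whole 30-s epoch
            log.warning("recording shorter than one 30-s epoch; not scorable")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].samples)

    @property
    def samples_per_epoch(self) -> int:
        return self.sampling_rate * EPOCH_SECONDS

    @property
    def n_epochs(self) -> int:
        """Number of whole 30-s epochs; a trailing partial epoch is not counted."""
        return self.n_samples // self.samples_per_epoch

    @property
    def has_partial_epoch(self) -> bool:
        return self.n_samples % self.samples_per_epoch != 0

    def channel(self, label: str) -> Channel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(f"no channel labelled {label!r}")


@dataclass
class Hypnogram:
    """Per-epoch stage labels scored on 30-s epochs."""

    stages: list[str]
    epoch_length: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.epoch_length != EPOCH_SECONDS:
            raise ValueError("epoch_length is fixed at 30 s")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class BinaryHypnogram:
    """Sleep/wake reduction of a hypnogram; EXCLUDED marks unscorable epochs."""

    states: list[str]
    epoch_length: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        bad = sorted({s for s in self.states if s not in (SLEEP, WAKE, EXCLUDED)})
        if bad:
            raise ValueError(f"unknown binary states: {bad}")

    def __len__(self) -> int:
        return len(self.states)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.states, dtype=object)

    def sleep_efficiency(self) -> float:
        """Percentage of scored (non-EXCLUDED) epochs labelled SLEEP."""
        arr = self.as_array()
        scored = arr != EXCLUDED
        if not scored.any():
            return float("nan")
        return 100.0 * float((arr[scored] == SLEEP).mean())


@dataclass
class PostureTrack:
    """One body-posture label per 30-s epoch."""

    postures: list[str]

    def __post_init__(self) -> None:
        bad = sorted({p for p in self.postures if p not in POSTURES})
        if bad:
            raise ValueError(f"unknown posture labels: {bad}")

    def __len__(self) -> int:
        return len(self.postures)


def binarize(h: Hypnogram) -> BinaryHypnogram:
    """Reduce a full hypnogram to sleep/wake.

    Stages 1-4 and REM count as sleep; W is wake; UNSCORED epochs are
    EXCLUDED from downstream agreement statistics.
    """
    mapping = {"W": WAKE, "UNSCORED": EXCLUDED}
    return BinaryHypnogram([mapping.get(s, SLEEP) for s in h.stages])


# ---------------------------------------------------------------------------
# CSV signal dialect: one column per channel, optional "# fs=<Hz>" header.
# ---------------------------------------------------------------------------

def load_recording(
    path: str | Path,
    format: str | None = None,
    channel_names: Sequence[str] | None = None,
    sampling_rate: int | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Load a recording from EDF or the plain CSV dialect.

    ``format`` defaults to the file suffix.  For CSV the sampling rate
    comes from a ``# fs=<Hz>`` header line or the ``sampling_rate``
    argument.  ``channel_names`` restricts (and orders) the channels
    kept; a missing name raises ``KeyError``.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        from .edf import read_edf

        rec = read_edf(path)
    elif format == "csv":
        rec = _read_csv_recording(path, sampling_rate)
    else:
        raise ValueError(f"unknown format {format!r}")
    if subject_id is not None:
        rec.subject_id = subject_id
    elif not rec.subject_id:
        rec.subject_id = path.stem
    if channel_names is not None:
        rec = Recording(
            [rec.channel(name) for name in channel_names],
            rec.sampling_rate,
            rec.subject_id,
        )
    if rec.has_partial_epoch:
        log.warning(
            "%s: trailing %d samples do not fill a 30-s epoch and will be "
            "dropped by feature extraction",
            path.name,
            rec.n_samples % rec.samples_per_epoch,
        )
    return rec


def _read_csv_recording(path: Path, sampling_rate: int | None) -> Recording:
    header_labels: list[str] | None = None
    fs = sampling_rate
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    data_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            data_start = i + 1
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("fs="):
                fs = int(float(body[3:]))
            data_start = i + 1
            continue
        # a non-numeric first data line is a label header
        first = stripped.split(",")[0]
        try:
            float(first)
        except ValueError:
            header_labels = [t.strip() for t in stripped.split(",")]
            data_start = i + 1
        break

    rows = []
    for ln, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip() or line.strip().startswith("#"):
            continue
        try:
            rows.append([float(t) for t in line.split(",")])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric sample") from exc
    if not rows:
        raise FormatError(f"{path}: no samples")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    data = np.asarray(rows, dtype=float)
    if fs is None:
        raise FormatError(
            f"{path}: sampling rate not given (no '# fs=' header and no argument)"
        )
    labels = header_labels or [f"EMG{i + 1}" for i in range(data.shape[1])]
    if len(labels) != data.shape[1]:
        raise FormatError(f"{path}: {len(labels)} labels for {data.shape[1]} columns")
    channels = [Channel(lbl, data[:, i]) for i, lbl in enumerate(labels)]
    return Recording(channels, fs, subject_id=path.stem)


def save_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write the CSV dialect: '# fs=' header, label row, one row per sample."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.sampling_rate}\n")
        fh.write(",".join(c.label for c in rec.channels) + "\n")
        data = np.column_stack([c.samples for c in rec.channels])
        np.savetxt(fh, data, delimiter=",", fmt="%.10g")


# ---------------------------------------------------------------------------
# Hypnogram / posture text files: one token per epoch line, or
# "epoch_index, token" two-column lines.
# ---------------------------------------------------------------------------

def _read_token_lines(path: Path) -> list[tuple[int, str]]:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    out = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = [p.strip() for p in stripped.replace(",", " ").split()]
        token = parts[-1]  # two-column files carry the epoch index first
        out.append((ln, token))
    return out


def load_hypnogram(path: str | Path) -> Hypnogram:
    """Read a stage-per-line hypnogram; tokens are mapped case-insensitively."""
    stages = []
    for ln, token in _read_token_lines(Path(path)):
        try:
            stages.append(_STAGE_ALIASES[token.upper()])
        except KeyError:
            raise FormatError(f"{path}:{ln}: unknown stage token {token!r}") from None
    return Hypnogram(stages)


def save_hypnogram(h: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(h.stages) + "\n")


def load_posture(path: str | Path) -> PostureTrack:
    postures = []
    for ln, token in _read_token_lines(Path(path)):
        try:
            postures.append(_POSTURE_ALIASES[token.upper()])
        except KeyError:
            raise FormatError(f"{path}:{ln}: unknown posture token {token!r}") from None
    return PostureTrack(postures)


def save_posture(track: PostureTrack, path: str | Path) -> None:
    short = {"SUPINE": "SUP", "LEFT": "L", "RIGHT": "R", "PRONE": "PRO", "UNKNOWN": "UNK"}
    Path(path).write_text("\n".join(short[p] for p in track.postures) + "\n")


def align_lengths(
    n_signal_epochs: int, hyp: BinaryHypnogram | Hypnogram
) -> int:
    """Reconcile signal and hypnogram lengths.

    A mismatch of at most one epoch — common in exported scorings — is
    resolved by truncating both to the shorter length (with a warning);
    anything larger is an error.  Returns the common epoch count.
    """
    n_hyp = len(hyp)
    if n_signal_epochs == n_hyp:
        return n_hyp
    if abs(n_signal_epochs - n_hyp) <= 1:
        n = min(n_signal_epochs, n_hyp)
        warnings.warn(
            f"signal has {n_signal_epochs} whole epochs but hypnogram has "
            f"{n_hyp}; truncating both to {n}",
            stacklevel=2,
        )
        return n
    raise ValueError(
        f"signal/hypnogram length mismatch: {n_signal_epochs} vs {n_hyp} epochs"
    )


def save_scored_csv(
    path: str | Path,
    predicted: BinaryHypnogram,
    reference: BinaryHypnogram | None = None,
    feature: Iterable[float] | None = None,
    feature_name: str = "feature",
) -> None:
    """Write per-epoch scoring output: epoch_index, predicted[, reference][, feature]."""
    import pandas as pd

    cols: dict[str, object] = {
        "epoch_index": np.arange(1, len(predicted) + 1),
        "predicted_state": list(predicted.states),
    }
    if reference is not None:
        cols["reference_state"] = list(reference.states)
    if feature is not None:
        cols[feature_name] = np.asarray(list(feature), dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False)
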