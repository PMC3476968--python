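"""Minimal European Data Format (EDF) reader/writer.

Covers the plain continuous-EDF subset this package produces and
consumes: one-second data records, 16-bit samples, identical sampling
rate across channels.  Amplitudes are used exactly as stored in
physical units — the estimators are self-normalizing, so no unit
rescaling is applied on read.

The 16-bit quantization bounds the write/read round-trip error at
``(physical_max - physical_min) / (2^16 - 2)`` per sample.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np

from .formats import Channel, FormatError, Recording

log = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _fmt_phys(value: float, width: int) -> str:
    """Shortest %g representation that fits an EDF numeric field."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {value!r} in {width} chars")


def write_edf(
    rec: Recording,
    path: str | Path,
    physical_dimension: str = "uV",
    start: _dt.datetime | None = None,
) -> None:
    """Write a recording as continuous EDF with 1-s data records.

    Samples are scaled linearly into the signed 16-bit digital range
    using a per-channel symmetric physical range.  Trailing samples that
    do not fill a whole second are dropped (EDF records are whole
    seconds).
    """
    fs = rec.sampling_rate
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        log.warning("dropping %d trailing samples (< 1 s)", rec.n_samples - n_records * fs)
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    start = start or _dt.datetime(2000, 1, 1, 22, 0, 0)
    ns = len(rec.channels)

    phys_min, phys_max, scaled = [], [], []
    for ch in rec.channels:
        x = ch.samples[: n_records * fs]
        amp = float(np.max(np.abs(x))) if len(x) else 0.0
        if amp == 0.0:
            amp = 1.0
        # store the range the header will carry (8 ascii chars incl. the
        # minus sign), then digitize with the affine map a reader uses
        amp = float(_fmt_phys(amp, 7))
        phys_min.append(-amp)
        phys_max.append(amp)
        gain = 2 * amp / (_DIG_MAX - _DIG_MIN)
        offset = -amp - gain * _DIG_MIN
        scaled.append(
            np.clip(np.rint((x - offset) / gain), _DIG_MIN, _DIG_MAX).astype("<i2")
        )

    header = b"".join(
        [
            _field("0", 8),
            _field(rec.subject_id or "X", 80),
            _field("Startdate 01-JAN-2000", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    sig_fields = [
        ("label", 16, [c.label for c in rec.channels]),
        ("transducer", 80, ["surface EMG"] * ns),
        ("dim", 8, [physical_dimension] * ns),
        ("pmin", 8, [_fmt_phys(v, 8) for v in phys_min]),
        ("pmax", 8, [_fmt_phys(v, 8) for v in phys_max]),
        ("dmin", 8, [str(_DIG_MIN)] * ns),
        ("dmax", 8, [str(_DIG_MAX)] * ns),
        ("prefilter", 80, [""] * ns),
        ("nsamples", 8, [str(fs)] * ns),
        ("reserved", 32, [""] * ns),
    ]
    header += b"".join(
        b"".join(_field(v, width) for v in values) for _, width, values in sig_fields
    )

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for sig in scaled:
                fh.write(sig[r * fs : (r + 1) * fs].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF file into a :class:`Recording`.

    Requires the same samples-per-record in every signal (the only
    layout this package writes); annotation channels are not supported.
    Returns amplitudes in stored physical units.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")

    def txt(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    subject_id = txt(8, 80)
    try:
        n_records = int(txt(236, 8))
        record_dur = float(txt(244, 8))
        ns = int(txt(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    if ns < 1:
        raise FormatError(f"{path}: no signals")

    # signal-header field blocks in file order: (width per signal)
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    starts = 256 + ns * np.concatenate([[0], np.cumsum(widths[:-1])])

    def sig_txt(block: int) -> list[str]:
        w = widths[block]
        return [txt(int(starts[block]) + i * w, w) for i in range(ns)]

    labels = sig_txt(0)
    pmin = [float(v) for v in sig_txt(3)]
    pmax = [float(v) for v in sig_txt(4)]
    dmin = [int(v) for v in sig_txt(5)]
    dmax = [int(v) for v in sig_txt(6)]
    spr = [int(v) for v in sig_txt(8)]
    if len(set(spr)) != 1:
        raise FormatError(f"{path}: mixed samples-per-record not supported")
    if record_dur <= 0 or spr[0] % record_dur != 0:
        raise FormatError(f"{path}: non-integer sampling rate")
    fs = int(spr[0] / record_dur)

    header_bytes = 256 * (ns + 1)
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expect = n_records * sum(spr)
    if len(body) < expect:
        raise FormatError(f"{path}: data shorter than header promises")
    body = body[:expect].reshape(n_records, ns, spr[0])

    channels = []
    for i, label in enumerate(labels):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        offset = pmin[i] - gain * dmin[i]
        samples = body[:, i, :].reshape(-1).astype(float) * gain + offset
        channels.append(Channel(label, samples))
    return Recording(channels, fs, subject_id=subject_id)


def _quantization_step(rec: Recording) -> list[float]:
    """Per-channel worst-case round-trip error of :func:`write_edf`."""
    out = []
    for ch in rec.channels:
        amp = float(np.max(np.abs(ch.samples))) or 1.0
        out.append(2 * amp / (_DIG_MAX - _DIG_MIN))
    return out
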