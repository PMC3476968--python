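"""Synthetic overnight anterior-tibialis EMG with ground-truth hypnograms.

The generator emulates the signal phenomenology the estimators rely on,
not muscle physiology: low-amplitude tonic band-limited noise during
sleep, elevated tone plus short high-amplitude movement bursts during
wake, optional mains hum, and optional periodic leg-movement (PLM)
burst trains during sleep.  Sleep/wake ground truth is a two-state
Markov chain whose stationary distribution matches the target sleep
efficiency; full stage labels are drawn on top of the sleep state for
format realism and play no role in the signal model beyond being sleep.

Default conditions describe a healthy ~8-hour night: 960 epochs at
250 Hz with ~97.5% sleep efficiency and short (~1 min) wake bouts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .calibrate import Cohort, CohortItem
from .formats import (
    EPOCH_SECONDS,
    SLEEP,
    WAKE,
    BinaryHypnogram,
    Channel,
    Hypnogram,
    PostureTrack,
    Recording,
    save_hypnogram,
    save_posture,
    save_recording_csv,
)

#: Stage proportions within sleep (light sleep dominates a normal night).
_STAGE_PROPORTIONS = {"S1": 0.10, "S2": 0.55, "S3": 0.08, "S4": 0.04, "REM": 0.23}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic night.

    Amplitudes are in arbitrary analog units; what matters to the
    estimators is only the wake/sleep contrast.  ``sigma_sleep`` is the
    tonic EMG amplitude scale in sleep, ``sigma_wake`` the elevated
    tonic scale in wake, and wake epochs additionally carry Poisson-
    placed movement bursts whose amplitude is ``burst_gain`` times the
    local tonic scale.  PLM trains place ``plm_duration_s``-wide bursts
    every ``plm_interval_s`` during affected sleep epochs; PLM activity
    occurs in sticky trains covering roughly ``plm_train_fraction`` of
    sleep, mimicking the episodic character of PLMS.
    """

    duration_epochs: int = 960
    fs: int = 250
    target_se: float = 97.5
    mean_wake_bout: float = 2.0
    sigma_sleep: float = 1.0
    sigma_wake: float = 3.0
    burst_rate_wake: float = 6.0      # bursts per minute of wake
    burst_gain: float = 8.0
    mains_amplitude: float = 0.0
    plm_enabled: bool = False
    plm_interval_s: float = 20.0
    plm_duration_s: float = 4.0
    plm_gain: float = 8.0
    plm_train_fraction: float = 0.6
    channel_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_se < 100):
            raise ValueError("target_se must be in (0, 100)")
        if self.sigma_wake < self.sigma_sleep:
            raise ValueError("sigma_wake must be >= sigma_sleep")
        if not (5.0 <= self.plm_interval_s <= 90.0):
            raise ValueError("plm_interval_s must lie in [5, 90] s")
        if not (0.5 <= self.plm_duration_s <= 10.0):
            raise ValueError("plm_duration_s must lie in [0.5, 10] s")
        if not (0.0 <= self.channel_correlation <= 1.0):
            raise ValueError("channel_correlation must lie in [0, 1]")
        if self.mean_wake_bout < 1.0:
            raise ValueError("mean_wake_bout must be at least one epoch")


def _transition_probs(spec: SyntheticSpec) -> tuple[float, float]:
    """(P(wake->sleep), P(sleep->wake)) matching target SE and wake-bout length."""
    s = spec.target_se / 100.0
    p_ws = 1.0 / spec.mean_wake_bout
    p_sw = p_ws * (1.0 - s) / s
    if p_sw > 1.0:
        raise ValueError(
            "infeasible combination: target_se too low for the given mean_wake_bout"
        )
    return p_ws, p_sw


def simulate_hypnogram(spec: SyntheticSpec) -> tuple[BinaryHypnogram, Hypnogram]:
    """Draw the ground-truth night: binary states plus cosmetic stage labels.

    The binary chain starts from its stationary distribution, so the
    expected fraction of sleep epochs equals ``target_se`` exactly and
    the empirical fraction converges to it for long nights.
    """
    rng = np.random.default_rng([int(spec.seed) % 2**31, 1])
    p_ws, p_sw = _transition_probs(spec)
    n = spec.duration_epochs
    s = spec.target_se / 100.0

    states = np.empty(n, dtype=object)
    u = rng.random(n)
    state = SLEEP if rng.random() < s else WAKE
    for i in range(n):
        states[i] = state
        if state == WAKE:
            state = SLEEP if u[i] < p_ws else WAKE
        else:
            state = WAKE if u[i] < p_sw else SLEEP

    # sticky stage chain within sleep; stationary = _STAGE_PROPORTIONS
    stage_names = list(_STAGE_PROPORTIONS)
    stage_p = np.array([_STAGE_PROPORTIONS[k] for k in stage_names])
    stages = []
    current = None
    for st in states:
        if st == WAKE:
            stages.append("W")
            current = None
        else:
            if current is None or rng.random() < 0.05:
                current = rng.choice(stage_names, p=stage_p)
            stages.append(str(current))
    return BinaryHypnogram(list(states)), Hypnogram(stages)


def _bandlimited_noise(n: int, fs: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to 10-75 Hz.

    At sampling rates too low to carry the full band the upper edge is
    capped below the Nyquist frequency.
    """
    white = rng.standard_normal(n)
    high = min(75.0, 0.45 * fs)
    sos = _signal.butter(4, [10.0, high], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    return x / x.std()


def _add_burst(env: np.ndarray, start: int, dur: int, gain: float) -> None:
    """Raise the amplitude envelope with a Hann-shaped burst."""
    stop = min(start + dur, len(env))
    if stop <= start:
        return
    shape = np.hanning(stop - start)
    seg = env[start:stop]
    np.maximum(seg, 1.0 + (gain - 1.0) * shape, out=seg)


def _plm_active_epochs(
    sleep_idx: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Sticky Markov mask over sleep epochs: PLM trains of ~10 epochs."""
    p_exit = 0.1
    p_enter = p_exit * fraction / max(1e-9, 1.0 - fraction)
    active = np.zeros(len(sleep_idx), dtype=bool)
    state = rng.random() < fraction
    u = rng.random(len(sleep_idx))
    for i in range(len(sleep_idx)):
        active[i] = state
        state = (u[i] >= p_exit) if state else (u[i] < p_enter)
    return active


def simulate_emg(hyp: BinaryHypnogram, spec: SyntheticSpec) -> Recording:
    """Synthesize the two-channel recording that realises a hypnogram.

    Channels share a common band-limited noise component weighted by
    ``channel_correlation`` and a common movement envelope (leg
    movements are modelled as bilateral); the mains component, when
    enabled, is a pure 60 Hz sinusoid added to both channels.
    """
    rng = np.random.default_rng([int(spec.seed) % 2**31, 2])
    n_epochs = len(hyp)
    fs = spec.fs
    spe = fs * EPOCH_SECONDS
    total = n_epochs * spe
    states = hyp.as_array()

    # tonic amplitude per sample
    sigma_epoch = np.where(states == WAKE, spec.sigma_wake, spec.sigma_sleep)
    sigma = np.repeat(sigma_epoch.astype(float), spe)

    # shared movement envelope (multiplies the tonic amplitude)
    env = np.ones(total)
    wake_epochs = np.flatnonzero(states == WAKE)
    mean_bursts = spec.burst_rate_wake * (EPOCH_SECONDS / 60.0)
    for m in wake_epochs:
        for _ in range(rng.poisson(mean_bursts)):
            dur = int(rng.uniform(0.5, 3.0) * fs)
            start = m * spe + rng.integers(0, spe)
            _add_burst(env, int(start), dur, spec.burst_gain)

    if spec.plm_enabled:
        sleep_epochs = np.flatnonzero(states == SLEEP)
        active = _plm_active_epochs(sleep_epochs, spec.plm_train_fraction, rng)
        dur = int(spec.plm_duration_s * fs)
        step = int(spec.plm_interval_s * fs)
        for m in sleep_epochs[active]:
            phase = int(rng.integers(0, step))
            for start in range(m * spe + phase, (m + 1) * spe, step):
                _add_burst(env, start, dur, spec.plm_gain)

    rho = spec.channel_correlation
    common = _bandlimited_noise(total, fs, rng)
    t = np.arange(total) / fs
    mains = spec.mains_amplitude * np.sin(2 * np.pi * 60.0 * t)
    channels = []
    for label in ("EMG_AT_left", "EMG_AT_right"):
        indiv = _bandlimited_noise(total, fs, rng)
        noise = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * indiv
        channels.append(Channel(label, noise * sigma * env + mains))
    return Recording(channels, fs, subject_id="synthetic")


def simulate_night(spec: SyntheticSpec) -> tuple[Recording, BinaryHypnogram, Hypnogram]:
    """Convenience wrapper: hypnogram plus its realised recording."""
    binary, stages = simulate_hypnogram(spec)
    return simulate_emg(binary, spec), binary, stages


def _simulate_posture(n_epochs: int, rng: np.random.Generator) -> PostureTrack:
    """Mostly supine with occasional lateral segments; prone never occurs."""
    postures = []
    current = "SUPINE"
    for _ in range(n_epochs):
        if rng.random() < 0.01:
            current = str(rng.choice(["SUPINE", "SUPINE", "LEFT", "RIGHT"]))
        postures.append(current)
    return PostureTrack(postures)


#: Per-profile overrides of the healthy-night defaults.  The apnea
#: profile keeps the normal signal model but fragments the night; the
#: PLM profile adds periodic leg-movement trains and slightly lower SE.
_PROFILES = {
    "normal": {},
    "osa": {"mean_wake_bout": 1.2, "target_se": 97.4},
    "plmd": {"plm_enabled": True, "target_se": 96.5},
}


def simulate_cohort(
    n: int,
    profile: str = "normal",
    seed: int = 0,
    base_spec: SyntheticSpec | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate ``n`` subjects with per-subject parameter jitter.

    With ``out_dir`` the signals (CSV dialect), hypnograms, postures and
    a manifest CSV are written to disk; otherwise everything stays in
    memory.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    base = base_spec or SyntheticSpec()
    base = replace(base, **_PROFILES[profile])

    items = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) % 2**31, 3, i])
        spec = replace(
            base,
            target_se=float(np.clip(rng.normal(base.target_se, 0.8), 90.0, 99.0)),
            sigma_wake=base.sigma_wake * float(rng.uniform(0.8, 1.2)),
            burst_rate_wake=base.burst_rate_wake * float(rng.uniform(0.8, 1.2)),
            burst_gain=base.burst_gain * float(rng.uniform(0.8, 1.2)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subject_id = f"{profile}{i + 1:02d}"
        rec, binary, stages = simulate_night(spec)
        rec.subject_id = subject_id
        posture = _simulate_posture(len(binary), rng)
        items.append(CohortItem(rec, binary, posture, subject_id))
    cohort = Cohort(items)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for item in cohort.items:
            sid = item.subject_id
            sig = out / f"{sid}.csv"
            hyp = out / f"{sid}_hypnogram.txt"
            pos = out / f"{sid}_posture.txt"
            save_recording_csv(item.recording, sig)
            save_hypnogram(_binary_as_stages(item.reference), hyp)
            save_posture(item.posture, pos)
            rows.append([sid, sig.name, hyp.name, pos.name])
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "signal_path", "hypnogram_path", "posture_path"])
            writer.writerows(rows)
    return cohort


def _binary_as_stages(binary: BinaryHypnogram) -> Hypnogram:
    """Represent the binary truth as a writable stage file (sleep -> S2)."""
    mapping = {WAKE: "W", SLEEP: "S2", "EXCLUDED": "UNSCORED"}
    return Hypnogram([mapping[s] for s in binary.states])
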