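"""Epoch-by-epoch agreement statistics and sleep-efficiency comparison.

The positive class is SLEEP: sensitivity is the proportion of reference
sleep epochs correctly identified, specificity the proportion of
reference wake epochs correctly identified.  Because overnight data are
heavily imbalanced (sleep efficiency near 97%), raw accuracy is a poor
summary and Cohen's kappa is the headline agreement figure.

The F-measure is the harmonic mean of precision (PPV) and recall
(sensitivity), the standard information-retrieval definition.  A
sensitivity/specificity harmonic-mean variant is available via
``f_variant='sens_spec'`` for comparison with reports that use it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .formats import EXCLUDED, SLEEP, WAKE, BinaryHypnogram, PostureTrack, Recording

_STAT_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "kappa", "f_measure")


@dataclass
class AgreementStats:
    """Confusion counts and the seven derived epoch-by-epoch statistics."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    kappa: float
    f_measure: float

    @property
    def n_epochs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ("tp", "tn", "fp", "fn")}
        d.update({k: getattr(self, k) for k in _STAT_NAMES})
        return d


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _paired_arrays(
    pred: BinaryHypnogram, ref: BinaryHypnogram
) -> tuple[np.ndarray, np.ndarray]:
    if len(pred) != len(ref):
        raise ValueError(
            f"prediction has {len(pred)} epochs but reference has {len(ref)}"
        )
    p = pred.as_array()
    r = ref.as_array()
    keep = (p != EXCLUDED) & (r != EXCLUDED)
    return p[keep], r[keep]


def agreement(
    pred: BinaryHypnogram,
    ref: BinaryHypnogram,
    positive: str = SLEEP,
    f_variant: str = "ppv_sens",
) -> AgreementStats:
    """All seven agreement statistics between a prediction and a reference.

    Epochs EXCLUDED in either sequence are dropped pairwise before
    counting.  If the reference contains a single class, the undefined
    ratios and kappa come back as NaN with a warning; the confusion
    counts are still valid.
    """
    p, r = _paired_arrays(pred, ref)
    pos = positive
    tp = int(((p == pos) & (r == pos)).sum())
    tn = int(((p != pos) & (r != pos)).sum())
    fp = int(((p == pos) & (r != pos)).sum())
    fn = int(((p != pos) & (r == pos)).sum())
    n = tp + tn + fp + fn

    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, fp + tn)
    ppv = _safe_ratio(tp, tp + fp)
    npv = _safe_ratio(tn, tn + fn)
    acc = _safe_ratio(tp + tn, n)

    if n == 0 or tp + fn == 0 or fp + tn == 0:
        warnings.warn(
            "reference contains a single class; kappa and some ratios are undefined",
            stacklevel=2,
        )
        kappa = float("nan")
    else:
        p_o = (tp + tn) / n
        p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 1.0

    if f_variant == "ppv_sens":
        f = _safe_ratio(2 * ppv * sens, ppv + sens) if np.isfinite(ppv + sens) else float("nan")
    elif f_variant == "sens_spec":
        f = _safe_ratio(2 * sens * spec, sens + spec) if np.isfinite(sens + spec) else float("nan")
    else:
        raise ValueError(f"unknown f_variant {f_variant!r}")

    return AgreementStats(tp, tn, fp, fn, sens, spec, ppv, npv, acc, float(kappa), f)


def f_measure(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of precision and recall."""
    return 2 * ppv * sensitivity / (ppv + sensitivity)


@dataclass
class SleepEfficiencyComparison:
    """Reference vs estimated sleep efficiency, in percent of scored epochs."""

    se_ref: float
    se_est: float
    abs_diff: float
    rel_diff: float


def sleep_efficiency_compare(
    ref: BinaryHypnogram | float, est: BinaryHypnogram | float
) -> SleepEfficiencyComparison:
    """Absolute and relative sleep-efficiency difference.

    Accepts hypnograms (efficiency computed as percent of scored epochs
    asleep) or precomputed percentages.  The relative difference is the
    absolute difference as a percentage of the *reference* efficiency.
    """
    se_ref = ref.sleep_efficiency() if isinstance(ref, BinaryHypnogram) else float(ref)
    se_est = est.sleep_efficiency() if isinstance(est, BinaryHypnogram) else float(est)
    for v in (se_ref, se_est):
        if not (0 <= v <= 100):
            raise ValueError(f"sleep efficiency {v} outside [0, 100]")
    abs_diff = abs(se_ref - se_est)
    rel_diff = 100.0 * abs_diff / se_ref if se_ref > 0 else float("nan")
    return SleepEfficiencyComparison(se_ref, se_est, abs_diff, rel_diff)


@dataclass
class PostureStratum:
    posture: str
    n_epochs: int
    kappa: float
    stats: AgreementStats | None = None


def posture_stratified(
    pred: BinaryHypnogram, ref: BinaryHypnogram, postures: PostureTrack
) -> dict[str, PostureStratum]:
    """Per-posture epoch counts and kappa.

    Postures absent from the track are reported with zero epochs and
    NaN kappa, so the output always covers the full posture vocabulary.
    """
    from .formats import POSTURES

    if len(postures) != len(pred) or len(pred) != len(ref):
        raise ValueError("posture track and hypnograms must have equal lengths")
    track = np.asarray(postures.postures, dtype=object)
    out: dict[str, PostureStratum] = {}
    for posture in POSTURES:
        idx = np.flatnonzero(track == posture)
        if len(idx) == 0:
            out[posture] = PostureStratum(posture, 0, float("nan"))
            continue
        sub_pred = BinaryHypnogram([pred.states[i] for i in idx])
        sub_ref = BinaryHypnogram([ref.states[i] for i in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = agreement(sub_pred, sub_ref)
        out[posture] = PostureStratum(posture, st.n_epochs, st.kappa, st)
    return out


@dataclass
class StateAmplitudeResult:
    """Normalized-amplitude histograms per state and their rank-test p-value."""

    bin_edges: np.ndarray
    histograms: dict[str, np.ndarray]
    epoch_means: dict[str, np.ndarray]
    p_value: float


def state_amplitude_histogram(
    rec: Recording, ref: BinaryHypnogram, bins: int = 50
) -> StateAmplitudeResult:
    """Compare normalized EMG amplitude between sleep and wake epochs.

    Absolute amplitudes (all channels pooled) are scaled by the
    recording's maximum absolute amplitude, so the support is [0, 1].
    Each state's histogram is normalized to unit mass.  A two-sample
    Wilcoxon rank-sum test compares the per-epoch mean normalized
    amplitude between the states; with a single represented state the
    test is skipped (NaN p-value) with a warning.
    """
    spe = rec.samples_per_epoch
    n = min(rec.n_epochs, len(ref))
    data = np.abs(np.concatenate([c.samples[: n * spe] for c in rec.channels]))
    peak = data.max()
    if peak == 0:
        peak = 1.0
    norm = data / peak
    states = np.asarray(ref.states[:n], dtype=object)

    edges = np.linspace(0.0, 1.0, bins + 1)
    histograms: dict[str, np.ndarray] = {}
    epoch_means: dict[str, np.ndarray] = {}
    n_ch = len(rec.channels)
    per_epoch = norm.reshape(n_ch, n, spe).mean(axis=(0, 2))
    for state in (SLEEP, WAKE):
        idx = states == state
        if not idx.any():
            continue
        sample = norm.reshape(n_ch, n, spe)[:, idx, :].ravel()
        hist, _ = np.histogram(sample, bins=edges)
        histograms[state] = hist / hist.sum()
        epoch_means[state] = per_epoch[idx]

    if len(epoch_means) < 2:
        warnings.warn("only one state present; rank test skipped", stacklevel=2)
        p_value = float("nan")
    else:
        p_value = float(
            _stats.ranksums(epoch_means[SLEEP], epoch_means[WAKE]).pvalue
        )
    return StateAmplitudeResult(edges, histograms, epoch_means, p_value)


def mean_sd(values, ddof: int = 1) -> tuple[float, float]:
    """Mean and sample SD (divisor n-1), NaN-aware, as used in summary rows."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return float("nan"), float("nan")
    sd = float(v.std(ddof=ddof)) if len(v) > ddof else float("nan")
    return float(v.mean()), sd
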