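"""Deliberately naive loop transcriptions of the scoring equations.

These serve as independent oracles: no vectorization, no windowing
shortcuts, no shared code with the package implementation.
"""

from __future__ import annotations

import math


def naive_tda(x: list[float], fs: int, tsf1: float, tsf2: int) -> list[str]:
    """Sleep/wake labels from the time-domain method, computed epoch by epoch."""
    spe = fs * 30
    n_epochs = len(x) // spe
    x = x[: n_epochs * spe]

    y = []
    for k in range(1, n_epochs * 30 + 1):
        total = 0.0
        for j in range((k - 1) * fs + 1, k * fs + 1):
            total += x[j - 1] ** 2
        y.append(total)

    z = []
    for l in range(1, n_epochs + 1):
        total = 0.0
        for k in range((l - 1) * 30 + 1, l * 30 + 1):
            total += y[k - 1]
        z.append(total)

    t = []
    for m in range(1, n_epochs + 1):
        window = [z[l - 1] for l in range(m - tsf2, m + tsf2 + 1) if 1 <= l <= n_epochs]
        t.append(tsf1 * sum(window) / len(window))

    hemg = []
    for m in range(1, n_epochs + 1):
        count = 0
        for k in range((m - 1) * 30 + 1, m * 30 + 1):
            if y[k - 1] - t[m - 1] > 0:  # sgn(y_k - T_m) = 1 iff strictly positive
                count += 1
        hemg.append(count)

    mean_hemg = sum(hemg) / n_epochs
    return ["WAKE" if h > mean_hemg else "SLEEP" for h in hemg]


def naive_agreement(pred: list[str], ref: list[str]) -> dict[str, float]:
    """Seven agreement statistics by explicit per-epoch counting; positive = SLEEP."""
    tp = tn = fp = fn = 0
    for p, r in zip(pred, ref):
        if p == "EXCLUDED" or r == "EXCLUDED":
            continue
        if p == "SLEEP" and r == "SLEEP":
            tp += 1
        elif p == "WAKE" and r == "WAKE":
            tn += 1
        elif p == "SLEEP" and r == "WAKE":
            fp += 1
        else:
            fn += 1
    n = tp + tn + fp + fn
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (fp + tn) if fp + tn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan
    acc = (tp + tn) / n if n else math.nan
    if n and (tp + fn) and (fp + tn):
        p_o = (tp + tn) / n
        p_e = ((tp + fp) / n) * ((tp + fn) / n) + ((fn + tn) / n) * ((fp + tn) / n)
        kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 1.0
    else:
        kappa = math.nan
    f = 2 * ppv * sens / (ppv + sens) if (ppv + sens) else math.nan
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
        "accuracy": acc, "kappa": kappa, "f_measure": f,
    }
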