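"""Threshold-factor calibration: grid search and leave-one-out CV.

The threshold-selection factors of both estimators are chosen on
training recordings by exhaustive grid search, maximizing the mean
Cohen's kappa against the reference scorings (accuracy is a poor
objective at ~97% sleep prevalence, so chance-corrected agreement is
the default; accuracy and F-measure are available).  The leave-one-out
harness trains on all recordings but one and scores the held-out night
with the selected factors — the held-out recording never influences its
own fold's parameter choice.  The adaptive thresholds themselves are
always recomputed on the scored recording; only the factors transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fda import FdaParams, recording_total_power, spectral_threshold
from .features import recording_energies
from .formats import (
    EPOCH_SECONDS,
    EXCLUDED,
    SLEEP,
    WAKE,
    BinaryHypnogram,
    PostureTrack,
    Recording,
    align_lengths,
)
from .metrics import AgreementStats, agreement, mean_sd
from .tda import TdaParams, windowed_mean


class CalibrationError(RuntimeError):
    """Raised when no grid point yields a defined objective."""


@dataclass
class CohortItem:
    recording: Recording
    reference: BinaryHypnogram
    posture: PostureTrack | None = None
    subject_id: str = ""


@dataclass
class Cohort:
    """A set of (recording, reference) pairs with unique subject ids."""

    items: list[CohortItem]

    def __post_init__(self) -> None:
        ids = [it.subject_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class FoldResult:
    held_out_id: str
    selected_params: TdaParams | FdaParams
    train_objective: float
    test_stats: AgreementStats


def default_tda_grid() -> list[TdaParams]:
    """Multipliers 1-10, half-windows 5-50 epochs; brackets (4, 25)."""
    return [
        TdaParams(tsf1=float(a), tsf2=int(b))
        for a in range(1, 11)
        for b in range(5, 51, 5)
    ]


def default_fda_grid() -> list[FdaParams]:
    """Mean weights 0-2 (step 0.25), SD weights 0.5-5 (step 0.5); brackets (0.5, 3.5)."""
    return [
        FdaParams(tsf1=round(0.25 * a, 2), tsf2=round(0.5 * b, 1))
        for a in range(0, 9)
        for b in range(1, 11)
    ]


def default_grid(method: str):
    if method == "tda":
        return default_tda_grid()
    if method == "fda":
        return default_fda_grid()
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cached per-item features so grid evaluation is cheap.
# ---------------------------------------------------------------------------

@dataclass
class _ItemFeatures:
    y: np.ndarray          # per-second energies, 30 per epoch
    z: np.ndarray          # per-epoch energies
    tp: np.ndarray         # per-epoch band power
    ref: BinaryHypnogram   # reference truncated to the common length


def _extract(item: CohortItem) -> _ItemFeatures:
    y, z = recording_energies(item.recording)
    tp = recording_total_power(item.recording)
    n = align_lengths(len(z.values), item.reference)
    return _ItemFeatures(
        y.values[: n * EPOCH_SECONDS],
        z.values[:n],
        tp.values[:n],
        BinaryHypnogram(item.reference.states[:n]),
    )


def _predict_tda(f: _ItemFeatures, p: TdaParams) -> BinaryHypnogram:
    t = p.tsf1 * windowed_mean(f.z, p.tsf2)
    counts = (f.y.reshape(-1, EPOCH_SECONDS) > t[:, None]).sum(axis=1)
    mean_hemg = counts.mean()
    return BinaryHypnogram([WAKE if c > mean_hemg else SLEEP for c in counts])


def _predict_fda(f: _ItemFeatures, p: FdaParams) -> BinaryHypnogram:
    from .fda import SpectralPowerSeries

    thr = spectral_threshold(SpectralPowerSeries(f.tp), p)
    return BinaryHypnogram([WAKE if v > thr else SLEEP for v in f.tp])


def _predict(f: _ItemFeatures, params) -> BinaryHypnogram:
    if isinstance(params, TdaParams):
        return _predict_tda(f, params)
    return _predict_fda(f, params)


def _objective_value(stats: AgreementStats, objective: str) -> float:
    if objective == "kappa":
        return stats.kappa
    if objective == "accuracy":
        return stats.accuracy
    if objective == "f":
        return stats.f_measure
    raise ValueError(f"unknown objective {objective!r}")


def _objective_matrix(
    features: list[_ItemFeatures], grid: list, objective: str
) -> np.ndarray:
    """Objective for every (item, grid point); NaN where undefined."""
    out = np.full((len(features), len(grid)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, f in enumerate(features):
            for j, params in enumerate(grid):
                stats = agreement(_predict(f, params), f.ref)
                out[i, j] = _objective_value(stats, objective)
    return out


def _grid_sort_order(grid: list) -> np.ndarray:
    return np.lexsort(
        ([p.tsf2 for p in grid], [p.tsf1 for p in grid])
    )


def _select(matrix: np.ndarray, grid: list, train_rows: np.ndarray):
    """Best grid point by mean objective over the training rows.

    Ties break toward smaller tsf1, then smaller tsf2.  Grid points
    undefined on every training item are skipped; if that is all of
    them, calibration fails.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix[train_rows], axis=0)
    if np.all(np.isnan(means)):
        raise CalibrationError(
            "objective undefined at every grid point (single-class references?)"
        )
    best_j, best_val = None, -np.inf
    for j in _grid_sort_order(grid):
        v = means[j]
        if np.isfinite(v) and v > best_val:
            best_j, best_val = int(j), float(v)
    return grid[best_j], best_val


def grid_search(
    train: Cohort, method: str, grid: list | None = None, objective: str = "kappa"
):
    """Select the grid point maximizing the mean objective over training items.

    Returns ``(params, mean_objective)``.
    """
    grid = grid if grid is not None else default_grid(method)
    if not grid:
        raise ValueError("empty grid")
    features = [_extract(it) for it in train.items]
    matrix = _objective_matrix(features, grid, objective)
    return _select(matrix, grid, np.arange(len(features)))


def loocv(
    cohort: Cohort,
    method: str,
    grid: list | None = None,
    objective: str = "kappa",
) -> list[FoldResult]:
    """Leave-one-out cross-validation over the cohort.

    Each fold selects threshold factors on all other recordings and
    scores the held-out one with them; one :class:`FoldResult` per
    subject, in cohort order.
    """
    if len(cohort) < 2:
        raise ValueError("LOOCV needs at least two recordings")
    grid = grid if grid is not None else default_grid(method)
    features = [_extract(it) for it in cohort.items]
    matrix = _objective_matrix(features, grid, objective)

    folds = []
    for i, item in enumerate(cohort.items):
        train_rows = np.array([j for j in range(len(cohort)) if j != i])
        try:
            params, obj = _select(matrix, grid, train_rows)
        except CalibrationError as exc:
            raise CalibrationError(f"fold {item.subject_id!r}: {exc}") from exc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = agreement(_predict(features[i], params), features[i].ref)
        folds.append(FoldResult(item.subject_id, params, obj, stats))
    return folds


def summarize_folds(folds: list[FoldResult]) -> pd.DataFrame:
    """Per-fold statistics plus a mean (sample SD) summary row."""
    rows = []
    for f in folds:
        row = {"subject": f.held_out_id, **f.test_stats.as_dict()}
        row["tsf1"] = f.selected_params.tsf1
        row["tsf2"] = f.selected_params.tsf2
        row["train_objective"] = f.train_objective
        rows.append(row)
    df = pd.DataFrame(rows)
    stat_cols = ["sensitivity", "specificity", "ppv", "npv", "accuracy", "kappa", "f_measure"]
    summary = {"subject": "mean(SD)"}
    for c in stat_cols:
        m, sd = mean_sd(df[c])
        summary[c] = m
        summary[f"{c}_sd"] = sd
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
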