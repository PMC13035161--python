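"""Vascular-age prediction under participant-level cross-validation.

Two predictors are compared on the same folds: an ordinary
least-squares regression on the three pulse features (CT, dT, RI) and
the compact 1D CNN of :mod:`pulseage.nn` operating on raw 200-sample
pulses. Folds are constructed at the participant level (all pulses of a
participant stay in one of train/validation/test), with the non-test
folds split 8:1 into training and validation participants. Each
participant receives exactly one test-fold prediction; pulse-level CNN
outputs are aggregated to a participant prediction by the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from pulseage.cohort import _stable_int
from pulseage.nn import CNN1D, CNNConfig, FitResult, TrainConfig, fit

log = logging.getLogger(__name__)

DEFAULT_GRID: tuple[TrainConfig, ...] = tuple(
    TrainConfig(lr=lr, batch_size=bs, optimizer=opt)
    for lr in (1e-3, 1e-4)
    for bs in (128, 256)
    for opt in ("adam", "sgd")
)


@dataclass(frozen=True)
class FoldAssignment:
    fold: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def assert_disjoint(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise AssertionError(
                f"participant leakage in fold {self.fold}"
            )


def make_folds(
    participant_ids: Sequence[str], k: int = 10, seed: int = 0
) -> list[FoldAssignment]:
    """Participant-level k-fold assignment with an 8:1 train:val split.

    Each participant appears in exactly one test fold; within each fold
    the remaining participants are shuffled and split 8:1 into training
    and validation. Deterministic given the seed.
    """
    ids = list(participant_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} participants")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng([seed, 211])
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_groups = [list(g) for g in np.array_split(np.array(order), k)]
    folds = []
    for f, test in enumerate(test_groups):
        rest = [pid for pid in order if pid not in set(test)]
        rng_f = np.random.default_rng([seed, 211, f])
        rest = [rest[i] for i in rng_f.permutation(len(rest))]
        n_val = max(int(round(len(rest) / 9.0)), 1)
        val, train = rest[:n_val], rest[n_val:]
        fa = FoldAssignment(
            fold=f, train=tuple(sorted(train)), val=tuple(sorted(val)),
            test=tuple(sorted(test)),
        )
        fa.assert_disjoint()
        folds.append(fa)
    all_test = [pid for fa in folds for pid in fa.test]
    if sorted(all_test) != sorted(ids):
        raise AssertionError("test folds do not partition participants")
    return folds


def select_pulses(
    pulses: Mapping[str, np.ndarray], n: int = 370, seed: int = 0
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Standardize pulse counts: n random pulses per participant.

    Participants with fewer than ``n`` accepted pulses are excluded and
    returned in the second element. Deterministic given the seed.
    """
    selected: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for pid in sorted(pulses):
        arr = pulses[pid]
        if len(arr) < n:
            excluded.append(pid)
            continue
        rng = np.random.default_rng([seed, _stable_int(str(pid)), 307])
        idx = rng.choice(len(arr), size=n, replace=False)
        selected[pid] = arr[np.sort(idx)]
    return selected, excluded


# ---------------------------------------------------------------------------
# feature regression
# ---------------------------------------------------------------------------


@dataclass
class FeatureRegression:
    model: LinearRegression
    feature_names: tuple[str, ...] = ("ct", "dt", "ri")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(
            np.asarray(features[list(self.feature_names)], dtype=float)
        )


def fit_feature_regression(
    features: pd.DataFrame, ages: np.ndarray,
    feature_names: Sequence[str] = ("ct", "dt", "ri"),
) -> FeatureRegression:
    """OLS of age on (CT, dT, RI). Rank deficiency is handled by the
    least-squares solver (minimum-norm solution) and logged."""
    X = np.asarray(features[list(feature_names)], dtype=float)
    if len(X) < 4:
        raise ValueError("need >= 4 training participants")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        log.warning("rank-deficient design; using minimum-norm solution")
    model = LinearRegression().fit(X, np.asarray(ages, dtype=float))
    return FeatureRegression(model=model, feature_names=tuple(feature_names))


def regression_cv(
    features: pd.DataFrame,
    folds: Sequence[FoldAssignment],
    feature_names: Sequence[str] = ("ct", "dt", "ri"),
) -> pd.DataFrame:
    """Cross-validated feature-regression predictions.

    ``features`` must be participant-level with columns ``participant``,
    ``age`` and the feature columns. Validation participants are pooled
    into training (the linear model has no hyperparameters).
    Returns one row per participant: fold, age, predicted, raw ΔAge.
    """
    feats = features.set_index("participant")
    rows = []
    for fa in folds:
        train_ids = [p for p in fa.train + fa.val if p in feats.index]
        test_ids = [p for p in fa.test if p in feats.index]
        if not train_ids or not test_ids:
            continue
        tr = feats.loc[train_ids]
        reg = fit_feature_regression(tr, tr["age"].to_numpy(), feature_names)
        te = feats.loc[test_ids]
        pred = reg.predict(te)
        for pid, age, y in zip(test_ids, te["age"].to_numpy(), pred):
            rows.append(
                {"participant": pid, "fold": fa.fold, "age": float(age),
                 "predicted": float(y), "raw_delta": float(y - age)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNN training and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CNNTrainOutcome:
    result: FitResult
    chosen: TrainConfig
    grid_val_mae: dict[int, float] = field(default_factory=dict)


def _stack(
    pulses: Mapping[str, np.ndarray], ages: Mapping[str, float],
    ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, ys, pid_idx = [], [], []
    for i, pid in enumerate(ids):
        arr = pulses[pid]
        xs.append(arr)
        ys.append(np.full(len(arr), ages[pid], dtype=np.float32))
        pid_idx.append(np.full(len(arr), i))
    return (
        np.concatenate(xs).astype(np.float32),
        np.concatenate(ys),
        np.concatenate(pid_idx),
    )


def train_cnn(
    train_pulses: Mapping[str, np.ndarray],
    val_pulses: Mapping[str, np.ndarray],
    ages: Mapping[str, float],
    grid: Sequence[TrainConfig] = DEFAULT_GRID,
    cfg: CNNConfig | None = None,
    seed: int = 0,
) -> CNNTrainOutcome:
    """Grid search over training hyperparameters for one fold.

    Each grid point trains a freshly initialized model with early
    stopping on validation MAE; the point with the lowest validation MAE
    wins. Participant sets must be disjoint. Deterministic given seed.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    overlap = set(train_pulses) & set(val_pulses)
    if overlap:
        raise AssertionError(f"participant leakage: {sorted(overlap)[:3]}")
    cfg = cfg or CNNConfig()
    tr_ids = sorted(train_pulses)
    va_ids = sorted(val_pulses)
    x_tr, y_tr, _ = _stack(train_pulses, ages, tr_ids)
    x_va, y_va, _ = _stack(val_pulses, ages, va_ids)
    best: FitResult | None = None
    chosen: TrainConfig | None = None
    grid_val: dict[int, float] = {}
    for gi, tc in enumerate(grid):
        model = CNN1D(cfg, seed=seed * 1009 + gi)
        res = fit(model, x_tr, y_tr, x_va, y_va, tc, seed=seed * 1013 + gi)
        grid_val[gi] = res.best_val_mae
        if best is None or res.best_val_mae < best.best_val_mae:
            best, chosen = res, tc
    assert best is not None and chosen is not None
    return CNNTrainOutcome(result=best, chosen=chosen, grid_val_mae=grid_val)


def predict_participant(model: CNN1D, pulses: np.ndarray) -> float:
    """Participant-level prediction: median over pulse-level outputs."""
    if len(pulses) == 0:
        raise ValueError("need at least one pulse")
    return float(np.median(model.predict(np.asarray(pulses, np.float32))))


def cnn_cv(
    pulses: Mapping[str, np.ndarray],
    ages: Mapping[str, float],
    folds: Sequence[FoldAssignment],
    grid: Sequence[TrainConfig] = DEFAULT_GRID,
    cfg: CNNConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CNNTrainOutcome]]:
    """Participant-level k-fold CNN cross-validation.

    Returns (predictions frame, per-fold training outcomes). The frame
    has one row per participant: fold, age, predicted, raw ΔAge.
    """
    rows = []
    outcomes = []
    for fa in folds:
        fa.assert_disjoint()
        tr = {p: pulses[p] for p in fa.train if p in pulses}
        va = {p: pulses[p] for p in fa.val if p in pulses}
        te = {p: pulses[p] for p in fa.test if p in pulses}
        if not tr or not va or not te:
            continue
        out = train_cnn(tr, va, ages, grid=grid, cfg=cfg,
                        seed=seed * 101 + fa.fold)
        outcomes.append(out)
        for pid in sorted(te):
            y = predict_participant(out.result.model, te[pid])
            rows.append(
                {"participant": pid, "fold": fa.fold,
                 "age": float(ages[pid]), "predicted": y,
                 "raw_delta": y - float(ages[pid])}
            )
    return pd.DataFrame(rows), outcomes


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (20.0, 39.0), (40.0, 59.0), (60.0, float("inf"))
)


def grad_cam(
    model: CNN1D,
    pulses: np.ndarray,
    ages: np.ndarray | None = None,
    bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    batch_size: int = 512,
) -> dict[str, np.ndarray]:
    """Group-level Grad-CAM relevance maps on the 200-sample grid.

    Per-pulse maps (rectified channel-weighted activations of the last
    conv layer) are linearly resampled to 200 samples, max-normalized,
    averaged within each age group, and max-normalized again. With
    ``ages=None`` a single "all" map is returned.
    """
    pulses = np.asarray(pulses, dtype=np.float32)
    maps = []
    for i in range(0, len(pulses), batch_size):
        maps.append(model.grad_cam_raw(pulses[i : i + batch_size]))
    raw = np.concatenate(maps) if maps else np.empty((0, model.conv_out_len))
    L = raw.shape[1]
    xs = np.linspace(0, 1, L)
    xt = np.linspace(0, 1, 200)
    up = np.stack([np.interp(xt, xs, row) for row in raw]) if len(raw) else raw
    peak = up.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    up = up / peak

    def group_map(sel: np.ndarray) -> np.ndarray:
        if not sel.any():
            return np.zeros(200)
        g = up[sel].mean(axis=0)
        return g / g.max() if g.max() > 0 else g

    out = {"all": group_map(np.ones(len(up), dtype=bool))}
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        for lo, hi in bins:
            name = f"{int(lo)}-{int(hi)}" if np.isfinite(hi) else f">={int(lo)}"
            out[name] = group_map((ages >= lo) & (ages <= hi))
    return out
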