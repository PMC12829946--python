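"""Time-resolved per-neuron regression of normalized firing rates.

For each neuron, ordinary least squares is fitted independently at every
10-ms bin.  The baseline design holds the intercept plus 16 low-level and
behavioural regressors (CE1-5, SC1-5, CEpref, CV, CEpref+/-30, RMS, running
speed); the extended design appends exactly one unpredictability column
(overall, or a single feature level).  Non-intercept columns are z-scored,
so coefficients read as fold change per predictor SD ('modulation
functions').  The unique contribution of unpredictability is quantified as
Delta-R: the increase in shuffle-split cross-validated correlation between
predicted and observed responses when the unpredictability column is added,
averaged over a report window (default 75-150 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus_features import BASELINE_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (75.0, 150.0)
PREDICTABILITY_LEVELS = ("overall", "d1", "d2", "d3", "d4", "d5")


@dataclass
class DesignMatrix:
    """Observations x columns design with its standardization record."""

    X: np.ndarray
    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    full_rank: bool

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


@dataclass
class ModulationFunction:
    """Per-predictor coefficient time courses beta(t) for one unit."""

    beta: np.ndarray  # (columns, bins)
    columns: list[str]
    time_ms: np.ndarray
    full_rank: bool = True

    def for_predictor(self, name: str) -> np.ndarray:
        return self.beta[self.columns.index(name)]


def build_design(
    features: pd.DataFrame,
    which: str = "baseline",
    level: str = "overall",
) -> DesignMatrix:
    """Assemble and z-score the per-unit design matrix.

    ``features`` has one row per observation with the 16 baseline columns
    and, for the extended design, the requested predictability column
    (``overall`` or ``d1``..``d5``, stored under those names).  Exactly one
    predictability column is ever included.  A constant column raises an
    error naming it.
    """
    cols = list(BASELINE_COLUMNS)
    if which == "extended":
        if level not in PREDICTABILITY_LEVELS:
            raise ValueError(f"unknown predictability level {level!r}")
        cols.append(level)
    elif which != "baseline":
        raise ValueError(f"unknown design {which!r}")
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    raw = features[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite feature values")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    zero = sd <= 1e-12
    if zero.any():
        raise ValueError(f"constant design column(s): {[cols[i] for i in np.flatnonzero(zero)]}")
    Z = (raw - mean) / sd
    X = np.column_stack([np.ones(len(Z)), Z])
    full_rank = np.linalg.matrix_rank(X) == X.shape[1]
    if not full_rank:
        logger.warning("rank-deficient design (%d columns)", X.shape[1])
    return DesignMatrix(X, ["intercept", *cols], mean, sd, full_rank)


def fit_timecourse(
    y: np.ndarray, design: DesignMatrix, time_ms: np.ndarray
) -> ModulationFunction:
    """OLS per 10-ms bin; ``y`` is (observations, bins) for one unit.

    Rank-deficient designs fall back to the minimum-norm solution (flagged
    on the result).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n_obs:
        raise ValueError("row mismatch between responses and design")
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    return ModulationFunction(beta, design.columns, np.asarray(time_ms), design.full_rank)


def _zscore_train(X, train_idx):
    """Refit column standardization on the training rows (intercept kept)."""
    body = X[:, 1:]
    mu = body[train_idx].mean(axis=0)
    sd = body[train_idx].std(axis=0)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    return np.column_stack([np.ones(len(X)), (body - mu) / sd])


def _cv_correlations(
    y: np.ndarray,
    X: np.ndarray,
    n_splits: int,
    train_frac: float,
    rng: np.random.Generator,
    refit_zscore: bool = True,
) -> np.ndarray:
    """Mean over shuffle splits of per-bin Pearson r(predicted, actual)."""
    n_obs, n_bins = y.shape
    n_train = int(round(train_frac * n_obs))
    rs = np.full((n_splits, n_bins), np.nan)
    for s in range(n_splits):
        perm = rng.permutation(n_obs)
        tr, te = perm[:n_train], perm[n_train:]
        Xs = _zscore_train(X, tr) if refit_zscore else X
        beta, *_ = np.linalg.lstsq(Xs[tr], y[tr], rcond=None)
        pred = Xs[te] @ beta
        obs = y[te]
        po = pred - pred.mean(axis=0)
        oo = obs - obs.mean(axis=0)
        denom = np.sqrt((po**2).sum(axis=0) * (oo**2).sum(axis=0))
        ok = denom > 0
        if not ok.all():
            logger.debug("split %d: %d zero-variance bins skipped", s, (~ok).sum())
        rs[s, ok] = (po * oo).sum(axis=0)[ok] / denom[ok]
    return np.nanmean(rs, axis=0)


def delta_r(
    y: np.ndarray,
    base: DesignMatrix,
    ext: DesignMatrix,
    time_ms: np.ndarray,
    n_splits: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    refit_zscore: bool = True,
    null_adjust: int = 0,
) -> float:
    """Window-averaged increase in cross-validated correlation (extended - baseline).

    Splits are shared between the two models so the difference is paired.
    Because an extra regressor carries an out-of-sample overfitting penalty,
    the raw difference is centred slightly below zero when the added column
    is uninformative.  With ``null_adjust`` = m > 0, the same quantity is
    recomputed m times with the unpredictability column permuted across
    observations and the average is subtracted, referencing the statistic
    to its permutation-null expectation (zero-centred under the null).
    """
    if base.n_obs != ext.n_obs:
        raise ValueError("designs must share rows")
    time_ms = np.asarray(time_ms)
    sel = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("empty report window")

    r_base = _cv_correlations(y, base.X, n_splits, train_frac,
                              np.random.default_rng(seed), refit_zscore)

    def windowed_delta(X_ext: np.ndarray) -> float:
        r_ext = _cv_correlations(y, X_ext, n_splits, train_frac,
                                 np.random.default_rng(seed), refit_zscore)
        return float(np.nanmean((r_ext - r_base)[sel]))

    dr = windowed_delta(ext.X)
    if null_adjust > 0:
        rng = np.random.default_rng(seed + 7919)
        null_vals = []
        for _ in range(null_adjust):
            Xp = ext.X.copy()
            Xp[:, -1] = Xp[rng.permutation(ext.n_obs), -1]
            null_vals.append(windowed_delta(Xp))
        dr -= float(np.mean(null_vals))
    return dr


def window_sensitivity(
    mf: ModulationFunction,
    predictor: str,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> float:
    """Mean coefficient over bins whose centres fall inside the window."""
    sel = (mf.time_ms >= window_ms[0]) & (mf.time_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window contains no time bins")
    return float(mf.for_predictor(predictor)[sel].mean())


def latency_50(mf: ModulationFunction, predictor: str) -> float | None:
    """First rising crossing (ms) of 50% of the positive peak, interpolated.

    Returns None when the curve has no positive maximum.
    """
    beta = mf.for_predictor(predictor)
    peak = beta.max()
    if peak <= 0:
        return None
    half = 0.5 * peak
    t = mf.time_ms
    above = beta >= half
    first = int(np.argmax(above))
    if first == 0:
        return float(t[0])
    b0, b1 = beta[first - 1], beta[first]
    frac = (half - b0) / (b1 - b0)
    return float(t[first - 1] + frac * (t[first] - t[first - 1]))


def modulation_table(unit_ids, mfs: list[ModulationFunction], predictors: list[str]) -> pd.DataFrame:
    """Tidy beta table: unit_id, predictor, time_ms, beta."""
    rows = []
    for uid, mf in zip(unit_ids, mfs):
        for p in predictors:
            for t, b in zip(mf.time_ms, mf.for_predictor(p)):
                rows.append(dict(unit_id=uid, predictor=p, time_ms=float(t), beta=float(b)))
    return pd.DataFrame(rows)
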