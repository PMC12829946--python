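"""Spike trains to normalized, quality-controlled, chunk-averaged rate tensors.

The fixed processing order is: bin (10 ms) -> smooth (30 ms uniform moving
average, truncated at the edges) -> normalize to fold change
(FR - baseline) / (baseline + 0.5 Hz), with baseline the mean rate over the
first 20 ms -> trial quality control (blinks, eye-position outliers beyond
2 SD of the session mean) -> average surviving repetitions into 5 balanced,
repetition-contiguous chunks per stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIN_MS = 10.0
TRIAL_MS = 250.0
SMOOTH_BINS = 3  # 30 ms uniform window
PSEUDO_BASELINE_HZ = 0.5
BASELINE_BINS = 2  # first 20 ms
N_CHUNKS = 5

TIME_MS = np.arange(BIN_MS / 2, TRIAL_MS, BIN_MS)  # bin centres
N_BINS = len(TIME_MS)


@dataclass
class RateTensor:
    """units x observations x 10-ms time bins, in fold change.

    ``obs_index`` has one row per observation with at least ``stimulus_id``
    (and ``chunk`` after chunk averaging, or ``rep`` before).
    """

    values: np.ndarray
    time_ms: np.ndarray
    obs_index: pd.DataFrame
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("rate tensor must be units x observations x bins")
        if self.values.shape[2] != len(self.time_ms):
            raise ValueError("time axis mismatch")
        if self.values.shape[1] != len(self.obs_index):
            raise ValueError("observation index mismatch")

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("unit_ids", data=np.asarray(self.unit_ids))
            g = f.create_group("obs_index")
            for col in self.obs_index.columns:
                g.create_dataset(col, data=self.obs_index[col].to_numpy())

    @classmethod
    def load_h5(cls, path) -> "RateTensor":
        import h5py

        with h5py.File(path, "r") as f:
            obs = pd.DataFrame({k: f["obs_index"][k][...] for k in f["obs_index"]})
            return cls(f["values"][...], f["time_ms"][...], obs, f["unit_ids"][...])


def moving_average_truncated(x: np.ndarray, window: int = SMOOTH_BINS, axis: int = -1) -> np.ndarray:
    """Centred uniform moving average whose window shrinks at the edges."""
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    n = x.shape[-1]
    kernel = np.ones(window)
    summed = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, x)
    coverage = np.convolve(np.ones(n), kernel, mode="same")
    out = summed / coverage
    return np.moveaxis(out, -1, axis)


def bin_and_smooth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    recording_end_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial 10-ms binned, 30-ms smoothed firing rates in Hz.

    ``spikes`` has columns ``unit_id``, ``spike_time_s``; ``trials`` has
    ``trial_id``, ``onset_s``.  Returns ``(rates, unit_ids)`` with ``rates``
    of shape (units, trials, bins).
    """
    onsets = trials["onset_s"].to_numpy(dtype=float)
    if recording_end_s is not None and np.any(onsets + TRIAL_MS / 1000.0 > recording_end_s):
        raise ValueError("trial onset outside the recording")
    unit_ids = np.unique(spikes["unit_id"].to_numpy())
    n_trials = len(onsets)
    counts = np.zeros((len(unit_ids), n_trials, N_BINS))
    edges = np.arange(0.0, TRIAL_MS + BIN_MS, BIN_MS) / 1000.0
    order = np.argsort(onsets, kind="stable")
    sorted_onsets = onsets[order]
    for ui, uid in enumerate(unit_ids):
        st = np.sort(spikes.loc[spikes["unit_id"] == uid, "spike_time_s"].to_numpy())
        # assign each spike to the latest trial starting before it
        ti = np.searchsorted(sorted_onsets, st, side="right") - 1
        valid = ti >= 0
        rel = st[valid] - sorted_onsets[ti[valid]]
        in_trial = rel < TRIAL_MS / 1000.0
        bins = np.clip(np.searchsorted(edges, rel[in_trial], side="right") - 1, 0, N_BINS - 1)
        np.add.at(counts[ui], (order[ti[valid][in_trial]], bins), 1.0)
    rates = counts / (BIN_MS / 1000.0)
    return moving_average_truncated(rates, SMOOTH_BINS, axis=-1), unit_ids


def normalize_foldchange(rates_hz: np.ndarray) -> np.ndarray:
    """(FR - b) / (b + 0.5 Hz), b = mean rate over the first two 10-ms bins."""
    rates_hz = np.asarray(rates_hz, dtype=float)
    b = rates_hz[..., :BASELINE_BINS].mean(axis=-1, keepdims=True)
    return (rates_hz - b) / (b + PSEUDO_BASELINE_HZ)


def qc_trials(
    trials: pd.DataFrame,
    eye: pd.DataFrame | None,
    n_sd: float = 2.0,
    missing_policy: str = "keep",
) -> np.ndarray:
    """Boolean keep-mask over trials.

    A trial is dropped if it contains a blink sample, or if its mean
    horizontal/vertical eye position deviates more than ``n_sd`` session
    standard deviations from the session mean.  A zero SD keeps all trials
    on that axis.  With no eye data the ``missing_policy`` applies
    ('keep' with a warning, or 'drop').
    """
    n = len(trials)
    if eye is None or len(eye) == 0:
        if missing_policy == "keep":
            logger.warning("no eye data; keeping all %d trials", n)
            return np.ones(n, dtype=bool)
        if missing_policy == "drop":
            return np.zeros(n, dtype=bool)
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    onsets = trials["onset_s"].to_numpy(dtype=float)
    t = eye["time_s"].to_numpy()
    mean_x = np.full(n, np.nan)
    mean_y = np.full(n, np.nan)
    blink = np.zeros(n, dtype=bool)
    for i, onset in enumerate(onsets):
        sel = (t >= onset) & (t < onset + TRIAL_MS / 1000.0)
        if not sel.any():
            continue
        mean_x[i] = eye["x_deg"].to_numpy()[sel].mean()
        mean_y[i] = eye["y_deg"].to_numpy()[sel].mean()
        blink[i] = bool(eye["blink"].to_numpy()[sel].any())

    keep = ~blink
    for vals in (mean_x, mean_y):
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        if sd > 0:
            keep &= ~(np.abs(vals - mu) > n_sd * sd)
    return keep


def balanced_chunk_sizes(n_reps: int, n_chunks: int = N_CHUNKS) -> list[int]:
    """Contiguous balanced partition sizes, larger chunks first (47 -> 10,10,9,9,9)."""
    base, extra = divmod(n_reps, n_chunks)
    return [base + (1 if i < extra else 0) for i in range(n_chunks)]


def chunk_average(
    values: np.ndarray,
    trials: pd.DataFrame,
    keep: np.ndarray | None = None,
    n_chunks: int = N_CHUNKS,
) -> RateTensor | tuple[np.ndarray, pd.DataFrame]:
    """Average surviving repetitions of each stimulus into contiguous chunks.

    ``values`` is (units, trials, bins) aligned with ``trials`` rows
    (columns ``stimulus_id``, ``rep``).  Chunks are contiguous in repetition
    order so the first ~n/n_chunks repetitions form chunk 0, supporting the
    first-half/second-half experience split at chunk granularity.  Stimuli
    with fewer surviving repetitions than chunks are dropped (logged).
    Returns ``(chunked_values, obs_index)``.
    """
    if keep is None:
        keep = np.ones(len(trials), dtype=bool)
    stim_ids = np.unique(trials["stimulus_id"].to_numpy())
    out_obs: list[dict] = []
    out_vals: list[np.ndarray] = []
    stim = trials["stimulus_id"].to_numpy()
    reps = trials["rep"].to_numpy()
    for sid in stim_ids:
        idx = np.flatnonzero((stim == sid) & keep)
        idx = idx[np.argsort(reps[idx], kind="stable")]
        if len(idx) < n_chunks:
            logger.warning("stimulus %s: only %d surviving reps; dropped", sid, len(idx))
            continue
        start = 0
        for c, size in enumerate(balanced_chunk_sizes(len(idx), n_chunks)):
            sel = idx[start : start + size]
            start += size
            out_vals.append(values[:, sel, :].mean(axis=1))
            out_obs.append(dict(stimulus_id=sid, chunk=c, n_reps=size))
    chunked = np.stack(out_vals, axis=1) if out_vals else np.zeros((values.shape[0], 0, values.shape[2]))
    return chunked, pd.DataFrame(out_obs)
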