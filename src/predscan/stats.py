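"""Multi-level inference: animal-level aggregation, bootstrap tests and
confidence intervals, and TFCE-corrected time-course comparisons.

Inference is two-stage: unit values are first averaged within each animal,
and tests are then performed across the animal means with every animal
weighted equally.  Hypothesis tests are equal-tail bootstrap t-tests on the
mean-centred values (>= 1e4 resamples, add-one correction so p > 0).
Time-course contrasts are corrected with threshold-free cluster enhancement
(E = 0.5, H = 2, threshold step 0.1) under a sign-flip permutation null with
max-statistic family-wise correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BOOT_DEFAULT = 10_000


def animal_average(unit_values: np.ndarray, animal_ids: np.ndarray) -> pd.Series:
    """Unweighted mean per animal (one value per animal for downstream tests).

    Along the first axis; NaN unit values propagate (exclude beforehand).
    Animals with no units simply do not appear.
    """
    unit_values = np.asarray(unit_values, dtype=float)
    df = pd.DataFrame({"animal": np.asarray(animal_ids)})
    if unit_values.ndim == 1:
        df["value"] = unit_values
        return df.groupby("animal")["value"].mean()
    # time-resolved: return a DataFrame animal x bins
    grouped = pd.DataFrame(unit_values).groupby(df["animal"]).mean()
    return grouped


def _boot_t(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = values[idx]
    m = samples.mean(axis=1)
    sd = samples.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def bootstrap_ttest(
    values: np.ndarray, n_boot: int = N_BOOT_DEFAULT, seed: int = 0
) -> tuple[float, float]:
    """Equal-tail bootstrap t-test of mean = 0 over per-animal values.

    The observed t is computed from the raw values; the null distribution
    resamples the mean-centred values.  p uses the add-one correction
    2*min((#{t* >= t}+1)/(B+1), (#{t* <= t}+1)/(B+1)), capped at 1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 animals")
    sd = values.std(ddof=1)
    if sd == 0:
        logger.warning("zero variance across animals; p = 1")
        return 0.0, 1.0
    t_obs = values.mean() / (sd / np.sqrt(len(values)))
    null = _boot_t(values - values.mean(), n_boot, np.random.default_rng(seed))
    p_hi = (np.sum(null >= t_obs) + 1) / (n_boot + 1)
    p_lo = (np.sum(null <= t_obs) + 1) / (n_boot + 1)
    return float(t_obs), float(min(1.0, 2.0 * min(p_hi, p_lo)))


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = N_BOOT_DEFAULT,
    level: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
) -> tuple[float, float]:
    """Bootstrap interval of the mean across animals.

    ``method='percentile'`` is the plain percentile interval of the
    resampled mean; ``method='studentized'`` is the bootstrap-t interval
    (pivot t* = (mean* - mean)/se*), which is second-order accurate and
    better calibrated with a small number of animals.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 animals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = values[idx]
    means = samples.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    elif method == "studentized":
        m = values.mean()
        se = values.std(ddof=1) / np.sqrt(n)
        if se == 0:
            return float(m), float(m)
        se_star = samples.std(axis=1, ddof=1) / np.sqrt(n)
        ok = se_star > 0
        tstar = (means[ok] - m) / se_star[ok]
        q_lo, q_hi = np.quantile(tstar, [alpha, 1.0 - alpha])
        lo, hi = m - q_hi * se, m - q_lo * se
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


# -- TFCE -----------------------------------------------------------------

def tfce_enhance(stat: np.ndarray, e: float = 0.5, h: float = 2.0,
                 dh: float = 0.1) -> np.ndarray:
    """1-D threshold-free cluster enhancement of a signed statistic curve.

    Positive and negative excursions are enhanced separately; the output
    keeps the input's sign.
    """
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    for sign in (1.0, -1.0):
        s = sign * stat
        top = s.max()
        thresh = dh
        while thresh <= top:
            above = s >= thresh
            # label contiguous runs
            edges = np.diff(above.astype(int))
            starts = list(np.flatnonzero(edges == 1) + 1)
            ends = list(np.flatnonzero(edges == -1) + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                ends.append(len(s))
            for a, b in zip(starts, ends):
                out[a:b] += sign * (b - a) ** e * thresh**h * dh
            thresh += dh
    return out


def tfce_timecourse(
    diff_curves: np.ndarray,
    n_perm: int = 1024,
    seed: int = 0,
    e: float = 0.5,
    h: float = 2.0,
    stat: str = "mean",
    dh: float | None = None,
    hat_sigma: float = 0.05,
    n_steps: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip permutation TFCE over per-animal difference time courses.

    ``diff_curves`` is (animals, bins).  Returns (enhanced observed map,
    per-bin FWER-corrected p-values).  When ``n_perm`` meets or exceeds the
    2^animals possible sign patterns, the null is enumerated exhaustively.

    The per-bin statistic is the unstandardized across-animal mean by
    default: with a handful of animals the df-(n-1) variance estimate is
    unstable, and spuriously small per-bin variances inflate a t statistic
    at null bins; the mean statistic avoids that while the max-statistic
    sign-flip null keeps exact family-wise control.  ``stat='t'`` (plain
    one-sample t, threshold step ``dh`` defaulting to 0.1) and
    ``stat='hat'`` (variance-regularized t) are available.  For the mean
    statistic the threshold step adapts to the observed curve
    (max / ``n_steps``) and is held fixed across permutations.
    """
    X = np.asarray(diff_curves, dtype=float)
    n_animals, n_bins = X.shape
    if n_animals < 5:
        raise ValueError("need at least 5 animals for a sign-flip null")

    def t_curve(data):
        var_n = data.var(axis=0, ddof=1) / n_animals
        if stat == "mean":
            return data.mean(axis=0)
        if stat == "hat":
            denom = np.sqrt(var_n + hat_sigma * var_n.max())
        elif stat == "t":
            denom = np.sqrt(var_n)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, data.mean(axis=0) / denom, 0.0)

    obs_stat = t_curve(X)
    if dh is None:
        dh = 0.1 if stat in ("t", "hat") else max(np.abs(obs_stat).max(), 1e-12) / n_steps
    obs = tfce_enhance(obs_stat, e, h, dh)

    if 2**n_animals <= n_perm:
        signs = np.array(
            [[1 if (i >> b) & 1 else -1 for b in range(n_animals)] for i in range(2**n_animals)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n_animals))
        signs[0] = 1  # include the identity permutation
    null_max = np.empty(len(signs))
    for i, sgn in enumerate(signs):
        enh = tfce_enhance(t_curve(X * sgn[:, None]), e, h, dh)
        null_max[i] = np.abs(enh).max()
    pvals = (np.sum(null_max[None, :] >= np.abs(obs)[:, None], axis=1)) / len(signs)
    return obs, pvals


def paired_contrast(df: pd.DataFrame, value: str, group: str, animal: str = "animal_id",
                    order: tuple[str, str] = ("superficial", "deep")) -> pd.Series:
    """Within-animal paired difference (order[0] - order[1]) of animal-mean values."""
    means = df.groupby([animal, group])[value].mean().unstack(group)
    means = means.dropna(subset=list(order))
    return means[order[0]] - means[order[1]]


def contrast_report(
    name: str,
    per_animal_values: np.ndarray,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> dict:
    """JSON-ready summary of one across-animal contrast."""
    values = np.asarray(per_animal_values, dtype=float)
    t, p = bootstrap_ttest(values, n_boot=n_boot, seed=seed)
    lo, hi = bootstrap_ci(values, n_boot=n_boot, seed=seed)
    return dict(
        contrast=name, mean=float(values.mean()), ci=[lo, hi],
        t=t, p=p, n_animals=int(len(values)), seed=seed,
    )


def noise_control(seed: int = 0, **kwargs):
    """Run the synthetic-noise control analysis; see
    :func:`predscan.simulations.noise_control_run`."""
    from .simulations import noise_control_run

    return noise_control_run(seed=seed, **kwargs)
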