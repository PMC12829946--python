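"""Encoding-based feature-sensitivity profiles.

Firing responses are predicted from the feature maps of each stage of the
convolutional hierarchy with partial least squares regression (25
components, shuffle-split cross-validation), yielding one cross-validated
correlation per stage and unit.  Profiles are normalized per unit by the
maximum correlation across stages, so each unit contributes its relative
layer preference rather than its signal-to-noise ratio.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .inpaint.features import FeatureHierarchy
from .types import StimulusImage

logger = logging.getLogger(__name__)


def _avg_pool_to(fmap: np.ndarray, max_side: int) -> np.ndarray:
    """Average-pool a (C, H, W) map so the spatial side is <= max_side."""
    C, H, W = fmap.shape
    fy = int(np.ceil(H / max_side))
    fx = int(np.ceil(W / max_side))
    if fy <= 1 and fx <= 1:
        return fmap
    Hp, Wp = (H + fy - 1) // fy * fy, (W + fx - 1) // fx * fx
    padded = np.zeros((C, Hp, Wp))
    padded[:, :H, :W] = fmap
    counts = np.zeros((1, Hp, Wp))
    counts[:, :H, :W] = 1.0
    s = padded.reshape(C, Hp // fy, fy, Wp // fx, fx).sum(axis=(2, 4))
    c = counts.reshape(1, Hp // fy, fy, Wp // fx, fx).sum(axis=(2, 4))
    return s / np.maximum(c, 1)


def layer_features(
    images: list[StimulusImage],
    extractor: FeatureHierarchy,
    pool_side: int | None = 4,
    rf=None,
) -> list[np.ndarray]:
    """Flattened per-stage feature tables, one (n_images, d_stage) array per stage.

    ``pool_side`` average-pools each feature map to at most that spatial
    side before flattening, bounding dimensionality; None keeps raw maps.
    With ``rf`` given, features are extracted from the receptive-field
    comparison rectangle instead of the full image.
    """
    from .inpaint.masking import crop_rf_rectangle

    tables: list[list[np.ndarray]] = [[] for _ in range(extractor.n_stages)]
    for im in images:
        pixels = im.pixels if rf is None else crop_rf_rectangle(im, rf)
        for s, fmap in enumerate(extractor.stages(pixels)):
            if pool_side is not None:
                fmap = _avg_pool_to(fmap, pool_side)
            tables[s].append(fmap.ravel())
    return [np.stack(rows) for rows in tables]


def pls_encode(
    features: list[np.ndarray],
    y: np.ndarray,
    n_comp: int = 25,
    n_splits: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated Pearson r per stage for one unit's responses.

    ``y`` has one value per image (chunk-averaged response).  The component
    count is reduced with a warning when it exceeds what the training set
    supports.
    """
    from sklearn.cross_decomposition import PLSRegression

    y = np.asarray(y, dtype=float)
    n = len(y)
    n_train = int(round(train_frac * n))
    rs = np.zeros(len(features))
    rng = np.random.default_rng(seed)
    splits = [rng.permutation(n) for _ in range(n_splits)]
    for s, X in enumerate(features):
        if X.shape[0] != n:
            raise ValueError("feature rows must match responses")
        k = min(n_comp, n_train - 1, X.shape[1])
        if k < n_comp:
            warnings.warn(
                f"reducing PLS components {n_comp} -> {k} (training set too small)",
                stacklevel=2,
            )
        vals = []
        for perm in splits:
            tr, te = perm[:n_train], perm[n_train:]
            pls = PLSRegression(n_components=k, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(X[tr] - X[tr].mean(axis=0), y[tr] - y[tr].mean())
            pred = pls.predict(X[te] - X[tr].mean(axis=0)).ravel()
            if np.std(pred) == 0 or np.std(y[te]) == 0:
                continue
            vals.append(np.corrcoef(pred, y[te])[0, 1])
        rs[s] = np.mean(vals) if vals else 0.0
    return rs


def normalize_profile(r_per_stage: np.ndarray) -> np.ndarray | None:
    """Divide by the maximum r across stages; None (logged) when max <= 0."""
    r = np.asarray(r_per_stage, dtype=float)
    peak = r.max()
    if peak <= 0:
        logger.warning("non-positive encoding peak; unit excluded from profiles")
        return None
    return r / peak


def profile_slope(values: np.ndarray) -> float:
    """Least-squares slope of sensitivity against stage index 1..n."""
    values = np.asarray(values, dtype=float)
    x = np.arange(1, len(values) + 1, dtype=float)
    return float(np.polyfit(x, values, 1)[0])
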