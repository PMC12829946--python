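"""Multi-level unpredictability: feature-space distance between the actual
and the inpainted receptive-field patch.

Both images are cropped to a square of side 1.5x the RF FWHM diameter
centred on the receptive field; the crop is passed through a five-stage
convolutional hierarchy, and per level the unpredictability is the plain
l2 norm of the difference of the stage feature tensors.  The overall
unpredictability is the arithmetic mean of the five level distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..types import ReceptiveField, StimulusImage
from .features import FeatureHierarchy
from .masking import crop_rf_rectangle


@dataclass
class LevelDistances:
    """Per-level l2 distances d1..d5 and their mean."""

    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(self.levels < 0):
            raise ValueError("distances must be non-negative")

    @property
    def overall(self) -> float:
        return float(self.levels.mean())

    def as_dict(self) -> dict[str, float]:
        d = {f"d{i + 1}": float(v) for i, v in enumerate(self.levels)}
        d["overall"] = self.overall
        return d


def multilevel_unpredictability(
    actual: StimulusImage,
    predicted: StimulusImage,
    rf: ReceptiveField,
    extractor: FeatureHierarchy,
    crop_scale: float = 1.5,
) -> LevelDistances:
    if actual.shape != predicted.shape:
        raise ValueError("actual/predicted image size mismatch")
    a = crop_rf_rectangle(actual, rf, crop_scale)
    p = crop_rf_rectangle(predicted, rf, crop_scale)
    fa = extractor.stages(a)
    fp = extractor.stages(p)
    d = [float(np.linalg.norm(x - y)) for x, y in zip(fa, fp)]
    return LevelDistances(np.asarray(d))


def predictability_table(rows: list[tuple[int, int, LevelDistances]]) -> pd.DataFrame:
    """Tidy table keyed by (unit_id, stimulus_id) with columns d1..d5, overall."""
    recs = []
    for unit_id, stimulus_id, d in rows:
        rec = dict(unit_id=unit_id, stimulus_id=stimulus_id)
        rec.update(d.as_dict())
        recs.append(rec)
    return pd.DataFrame(recs)
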