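"""Pairwise agreement: NA-excluded confusion matrices, precision,
sensitivity and Dice, and per-annotator summaries.

Agreement between two annotators is measured on the pixels that *both*
assigned a layer: the confusion matrix cell C[i][j] counts pixels labeled
layer i by the first annotator and layer j by the reference.  Pixels left
un-annotated (NA) by either annotator contribute to no cell, so abstention
never penalizes agreement.

From a confusion matrix, per-layer metrics follow the usual one-vs-rest
reading with TP = C[ℓ][ℓ], FP = Σ_{j≠ℓ} C[ℓ][j], FN = Σ_{i≠ℓ} C[i][ℓ]:

* precision  = TP / (TP + FP)
* sensitivity = TP / (TP + FN)
* Dice = 2·precision·sensitivity / (precision + sensitivity), the harmonic
  mean, algebraically equal to 2TP/(2TP + FP + FN) (used as a cross-check,
  not as the implementation).

Metrics are *undefined* (NaN) when their denominator is empty — e.g. the
layer appears in neither annotation — and undefined values are excluded
from means and standard deviations rather than imputed as 0, which would
bias exactly the sparsely annotated layers (SS, CBB) the analysis cares
about.  Per-annotator summaries report the mean and sample SD (ddof = 1)
of each metric over comparisons against every other annotator as the
reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import LayerLabel, LAYERS, NA_VALUE
from .raster import LabelMap

N_LAYERS = len(LAYERS)

METRICS = ("precision", "sensitivity", "dice")


@dataclass
class ConfusionMatrix:
    """5×5 pixel-count matrix for one (first, reference) annotator pair.

    ``counts[i][j]`` uses zero-based layer indices (layer code − 1);
    ``scope`` is an image_id or ``"pooled"``.  The total count equals the
    number of pixels assigned a layer by both annotators.
    """

    first_annotator: str
    reference_annotator: str
    counts: np.ndarray
    scope: str = "pooled"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_LAYERS, N_LAYERS):
            raise ValueError("confusion matrix must be 5×5")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LayerMetrics:
    """Precision / sensitivity / Dice for one layer of one comparison.

    NaN encodes "undefined" (empty denominator); it is a value, not an
    error, and is excluded from downstream averaging.
    """

    layer: LayerLabel
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    dice: float


def confusion_matrix(map_first: LabelMap, map_ref: LabelMap) -> ConfusionMatrix:
    """Count pixels per (first-annotator layer, reference layer), excluding
    pixels where either map is NA."""
    if map_first.grid.shape != map_ref.grid.shape:
        raise ValueError(
            f"dimension mismatch: {map_first.grid.shape} vs {map_ref.grid.shape}"
        )
    g1, g2 = map_first.grid, map_ref.grid
    both = (g1 != NA_VALUE) & (g2 != NA_VALUE)
    idx = (g1[both].astype(np.int64) - 1) * N_LAYERS + (g2[both].astype(np.int64) - 1)
    counts = np.bincount(idx, minlength=N_LAYERS * N_LAYERS).reshape(N_LAYERS, N_LAYERS)
    return ConfusionMatrix(
        first_annotator=map_first.annotator_id,
        reference_annotator=map_ref.annotator_id,
        counts=counts,
        scope=map_first.image_id,
    )


def accumulate(matrices: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of per-image matrices for one annotator pair
    (scope becomes "pooled")."""
    if not matrices:
        raise ValueError("nothing to accumulate")
    pair = (matrices[0].first_annotator, matrices[0].reference_annotator)
    for m in matrices[1:]:
        if (m.first_annotator, m.reference_annotator) != pair:
            raise ValueError("cannot accumulate matrices from different annotator pairs")
    total = np.sum([m.counts for m in matrices], axis=0)
    return ConfusionMatrix(pair[0], pair[1], total, scope="pooled")


def layer_metrics(cm: ConfusionMatrix, layer: LayerLabel) -> LayerMetrics:
    """One-vs-rest precision, sensitivity and Dice for one layer."""
    i = int(layer) - 1
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum() - tp)
    fn = int(cm.counts[:, i].sum() - tp)
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if math.isnan(precision) or math.isnan(sensitivity):
        dice = float("nan")
    elif precision == 0.0 and sensitivity == 0.0:
        dice = 0.0
    else:
        dice = 2.0 * precision * sensitivity / (precision + sensitivity)
    return LayerMetrics(layer, tp, fp, fn, precision, sensitivity, dice)


def pair_metrics_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    """All five layers' metrics of one comparison as a tidy DataFrame."""
    rows = []
    for layer in LAYERS:
        m = layer_metrics(cm, layer)
        rows.append(
            {
                "first": cm.first_annotator,
                "reference": cm.reference_annotator,
                "scope": cm.scope,
                "layer": layer.name,
                "TP": m.tp,
                "FP": m.fp,
                "FN": m.fn,
                "precision": m.precision,
                "sensitivity": m.sensitivity,
                "dice": m.dice,
            }
        )
    return pd.DataFrame(rows)


def confusion_long_frame(matrices: Sequence[ConfusionMatrix]) -> pd.DataFrame:
    """Long-format (first, reference, layer_i, layer_j, pixels) export table."""
    rows = []
    for cm in matrices:
        for i, li in enumerate(LAYERS):
            for j, lj in enumerate(LAYERS):
                rows.append(
                    {
                        "first": cm.first_annotator,
                        "reference": cm.reference_annotator,
                        "scope": cm.scope,
                        "layer_first": li.name,
                        "layer_reference": lj.name,
                        "pixels": int(cm.counts[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def _pair_confusions(
    label_maps: Mapping[tuple[str, str], LabelMap],
    annotator_ids: Sequence[str],
    image_ids: Sequence[str],
    first: str,
    reference: str,
) -> list[ConfusionMatrix]:
    return [
        confusion_matrix(label_maps[(first, m)], label_maps[(reference, m)])
        for m in image_ids
    ]


def annotator_summary(
    label_maps: Mapping[tuple[str, str], LabelMap],
    annotator_ids: Sequence[str],
    image_ids: Sequence[str],
    scope: str = "pooled",
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-annotator mean and SD of each metric for each layer.

    For annotator *a*, metric values are collected over comparisons where
    *a* is the first annotator and each other annotator is the reference:
    in ``"pooled"`` scope the per-image confusion matrices of a pair are
    summed before metrics are taken (≤ A − 1 values per cell); in
    ``"per-image"`` scope there is one value per (reference, image) where
    it is defined.  Undefined (NaN) values are excluded and counted in
    ``n_undefined``; the SD is the sample standard deviation (ddof = 1) and
    NaN when fewer than two defined values exist (``n_comparisons`` ≤ 1 is
    flagged that way).
    """
    if scope not in ("pooled", "per-image"):
        raise ValueError(f"unknown scope {scope!r}; choose 'pooled' or 'per-image'")
    if len(annotator_ids) < 2:
        raise ValueError("need at least 2 annotators")

    rows = []
    for a in annotator_ids:
        values: dict[tuple[LayerLabel, str], list[float]] = {
            (l, met): [] for l in LAYERS for met in METRICS
        }
        undefined: dict[tuple[LayerLabel, str], int] = {
            (l, met): 0 for l in LAYERS for met in METRICS
        }
        for b in annotator_ids:
            if b == a:
                continue
            per_image = _pair_confusions(label_maps, annotator_ids, image_ids, a, b)
            matrices = [accumulate(per_image)] if scope == "pooled" else per_image
            for cm in matrices:
                for layer in LAYERS:
                    m = layer_metrics(cm, layer)
                    for met in METRICS:
                        v = getattr(m, met)
                        if math.isnan(v):
                            undefined[(layer, met)] += 1
                        else:
                            values[(layer, met)].append(v)
        for layer in LAYERS:
            for met in METRICS:
                vals = values[(layer, met)]
                n = len(vals)
                mean = float(np.mean(vals)) if n else float("nan")
                sd = float(np.std(vals, ddof=ddof)) if n > ddof else float("nan")
                rows.append(
                    {
                        "annotator": a,
                        "layer": layer.name,
                        "metric": met,
                        "mean": mean,
                        "sd": sd,
                        "n_comparisons": n,
                        "n_undefined": undefined[(layer, met)],
                        "flagged": n == 0,
                    }
                )
    return pd.DataFrame(rows)


def all_pair_matrices(
    label_maps: Mapping[tuple[str, str], LabelMap],
    annotator_ids: Sequence[str],
    image_ids: Sequence[str],
) -> list[ConfusionMatrix]:
    """Pooled confusion matrix for every ordered annotator pair."""
    result = []
    for a, b in itertools.permutations(annotator_ids, 2):
        result.append(accumulate(_pair_confusions(label_maps, annotator_ids, image_ids, a, b)))
    return result
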