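"""Layer-wise annotation frequency and between-annotator percent differences.

How often each annotator delineated each layer across the dataset measures
their confidence in *recognizing* the layer, deliberately ignoring the
geometry of the contours: two annotators count as equally confident even if
their polygons differ.  A layer counts at most once per image — multiple
disjoint polygons of one layer in one image are a single delineation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotations import AnnotationSet, LayerLabel, LAYERS


@dataclass
class FrequencyTable:
    """Per-annotator, per-layer counts of images with ≥ 1 polygon of the layer.

    ``counts`` is a DataFrame indexed by annotator_id with one column per
    layer code, entries in [0, n_images].
    """

    counts: pd.DataFrame
    n_images: int

    def count(self, annotator_id: str, layer: LayerLabel) -> int:
        return int(self.counts.loc[annotator_id, layer.name])

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "n_images", self.n_images)
        out.to_csv(path, index_label="annotator_id")


@dataclass
class PercentDifference:
    """Maximum pairwise percent difference in annotation frequency for one layer.

    ``value`` is max over annotator pairs (a, b) of
    |count(a) − count(b)| / max(count(a), count(b)) × 100; ``pairs`` lists
    every pair attaining the maximum (ties all reported).  ``applicable`` is
    False when no annotator delineated the layer anywhere (the quantity is
    then undefined).
    """

    layer: LayerLabel
    value: float
    pairs: list[tuple[str, str]] = field(default_factory=list)
    applicable: bool = True


def annotation_frequency(annotation_set: AnnotationSet) -> FrequencyTable:
    """Count, per annotator and layer, the images containing ≥ 1 polygon of
    that layer.  Invariant to polygon geometry."""
    data = {
        a: {l.name: 0 for l in LAYERS} for a in annotation_set.annotator_ids
    }
    for (annotator, _image), ann in annotation_set.annotations.items():
        present = {poly.label for poly in ann.polygons}
        for layer in present:
            data[annotator][layer.name] += 1
    counts = pd.DataFrame.from_dict(data, orient="index").reindex(
        annotation_set.annotator_ids
    )
    return FrequencyTable(counts=counts, n_images=annotation_set.n_images)


def max_percent_difference(table: FrequencyTable, layer: LayerLabel) -> PercentDifference:
    """Largest relative frequency gap between any two annotators for a layer.

    The denominator is the larger count of the pair; with all counts zero
    the measure is undefined and a flagged not-applicable result is
    returned.
    """
    counts = table.counts[layer.name]
    annotators = list(counts.index)
    if int(counts.max()) == 0:
        return PercentDifference(layer=layer, value=float("nan"), applicable=False)
    best = 0.0
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(annotators):
        for b in annotators[i + 1:]:
            ca, cb = int(counts[a]), int(counts[b])
            denom = max(ca, cb)
            if denom == 0:
                continue  # both zero: no difference between this pair
            pct = abs(ca - cb) / denom * 100.0
            if pct > best + 1e-12:
                best, pairs = pct, [(a, b)]
            elif abs(pct - best) <= 1e-12:
                pairs.append((a, b))
    return PercentDifference(layer=layer, value=best, pairs=pairs)


def percent_difference_table(table: FrequencyTable) -> pd.DataFrame:
    """Per-layer maximum percent difference with its argmax pair(s), as a
    tidy DataFrame ready for CSV export."""
    rows = []
    for layer in LAYERS:
        pd_result = max_percent_difference(table, layer)
        rows.append(
            {
                "layer": layer.name,
                "max_percent_difference": pd_result.value,
                "argmax_pairs": ";".join(f"{a}|{b}" for a, b in pd_result.pairs),
                "applicable": pd_result.applicable,
            }
        )
    return pd.DataFrame(rows)
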