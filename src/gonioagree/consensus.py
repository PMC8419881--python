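"""Per-layer three-category consensus maps and consensus-size curves.

For a target layer and a consensus threshold n (the minimum number of
annotators that must assign a pixel to the layer), each pixel that at least
one annotator labeled as the layer falls into one of three categories:

* **consensus** (+1) — labeled as the layer by at least n annotators;
* **disagreement** (−1) — labeled as the layer by k < n annotators and as a
  *different layer* (never NA) by at least one other;
* **ignored** (0) — labeled as the layer by k < n annotators and left
  un-annotated by all the rest.

Pixels nobody labeled as the layer are background.  NA is a deliberate
abstention: it can never create disagreement, so the un-annotated periphery
of an image does not depress the measured consensus.  At n = 1 the consensus
region is the union of the annotators' layer masks; at n = A (all
annotators) it is their strict intersection.

The consensus-size curve normalizes the consensus pixel count per threshold.
Three readings of the normalization are available (see
:data:`CONSENSUS_MODES`); the default ``exclude-ignored`` removes ignored
pixels from both numerator and denominator, so the curve reflects only
actual pixel-wise classification differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import LayerLabel, LAYERS, NA_VALUE
from .raster import LabelMap

# three-category codes on an int8 grid; -2 marks background
CONSENSUS = 1
DISAGREEMENT = -1
IGNORED = 0
BACKGROUND = -2

#: normalization modes for the consensus curve
CONSENSUS_MODES = ("exclude-ignored", "union-denominator", "not-disagreeing")

#: consensus-map PNG palette codes
MAP_PALETTE = {BACKGROUND: 0, IGNORED: 1, DISAGREEMENT: 2, CONSENSUS: 3}


class ParameterError(ValueError):
    """Out-of-range analysis parameter (threshold, mode, ...)."""


@dataclass
class ConsensusMap:
    """Three-category consensus field for one image, layer and threshold.

    ``grid`` is an int8 (height, width) array over {1, −1, 0, −2}
    (consensus, disagreement, ignored, background).
    """

    image_id: str
    layer: LayerLabel
    threshold: int
    grid: np.ndarray

    def region_sizes(self) -> tuple[int, int, int, int]:
        """(consensus_px, disagreement_px, ignored_px, union_px)."""
        c = int(np.count_nonzero(self.grid == CONSENSUS))
        d = int(np.count_nonzero(self.grid == DISAGREEMENT))
        i = int(np.count_nonzero(self.grid == IGNORED))
        return c, d, i, c + d + i


@dataclass
class ConsensusCurve:
    """Normalized consensus size per threshold for one layer.

    ``ratios`` maps n ∈ [1, A] to a ratio in [0, 1] (NaN where the chosen
    normalization is undefined); ``region_sizes`` maps n to the pooled
    (consensus_px, disagreement_px, ignored_px, union_px).  ``empty`` flags
    a layer nobody annotated anywhere.
    """

    layer: LayerLabel
    mode: str
    ratios: dict[int, float] = field(default_factory=dict)
    region_sizes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)
    empty: bool = False


def _stack(maps: Sequence[LabelMap]) -> np.ndarray:
    if not maps:
        raise ParameterError("need at least one label map")
    shape = maps[0].grid.shape
    for m in maps[1:]:
        if m.grid.shape != shape:
            raise ParameterError("label maps have mismatched dimensions")
    return np.stack([m.grid for m in maps])


def consensus_map(maps: Sequence[LabelMap], layer: LayerLabel, n: int) -> ConsensusMap:
    """Classify every pixel into consensus/disagreement/ignored/background.

    ``maps`` are the per-annotator label maps of one image; ``n`` is the
    consensus threshold, 1 ≤ n ≤ len(maps).
    """
    stack = _stack(maps)
    n_annotators = stack.shape[0]
    if not 1 <= n <= n_annotators:
        raise ParameterError(
            f"consensus threshold n={n} outside [1, {n_annotators}]"
        )
    k = np.count_nonzero(stack == int(layer), axis=0)
    labeled = np.count_nonzero(stack != NA_VALUE, axis=0)
    d = labeled - k  # annotators assigning a *different* layer; NA never counts

    grid = np.full(stack.shape[1:], BACKGROUND, dtype=np.int8)
    grid[(k > 0) & (k >= n)] = CONSENSUS
    grid[(k > 0) & (k < n) & (d >= 1)] = DISAGREEMENT
    grid[(k > 0) & (k < n) & (d == 0)] = IGNORED
    return ConsensusMap(maps[0].image_id, layer, int(n), grid)


def _ratio(c: int, d: int, i: int, u: int, mode: str) -> float:
    if mode == "exclude-ignored":
        return c / (c + d) if (c + d) > 0 else float("nan")
    if mode == "union-denominator":
        return c / u if u > 0 else float("nan")
    if mode == "not-disagreeing":
        return (c + i) / u if u > 0 else float("nan")
    raise ParameterError(f"unknown consensus mode {mode!r}; choose from {CONSENSUS_MODES}")


def consensus_curve(
    maps_by_image: Mapping[str, Sequence[LabelMap]],
    layer: LayerLabel,
    mode: str = "exclude-ignored",
) -> ConsensusCurve:
    """Pool region sizes over all images, then normalize per threshold.

    Counts are summed across the dataset before taking the ratio (one curve
    per layer).  A layer annotated by nobody anywhere yields a flagged empty
    curve.
    """
    if mode not in CONSENSUS_MODES:
        raise ParameterError(f"unknown consensus mode {mode!r}; choose from {CONSENSUS_MODES}")
    n_annotators = {len(maps) for maps in maps_by_image.values()}
    if len(n_annotators) != 1:
        raise ParameterError("all images must have the same number of annotators")
    A = n_annotators.pop()
    if A < 2:
        raise ParameterError("consensus analysis needs at least 2 annotators")

    curve = ConsensusCurve(layer=layer, mode=mode)
    for n in range(1, A + 1):
        totals = np.zeros(4, dtype=np.int64)
        for maps in maps_by_image.values():
            totals += consensus_map(maps, layer, n).region_sizes()
        c, d, i, u = (int(v) for v in totals)
        curve.region_sizes[n] = (c, d, i, u)
        curve.ratios[n] = _ratio(c, d, i, u, mode)
    if curve.region_sizes[1][3] == 0:
        curve.empty = True
    return curve


def per_image_curves(
    maps_by_image: Mapping[str, Sequence[LabelMap]],
    layer: LayerLabel,
    mode: str = "exclude-ignored",
) -> dict[str, ConsensusCurve]:
    """Diagnostic per-image curves (same computation, no pooling)."""
    return {
        image_id: consensus_curve({image_id: maps}, layer, mode)
        for image_id, maps in maps_by_image.items()
    }


def curves_to_frame(curves: Sequence[ConsensusCurve]) -> pd.DataFrame:
    """Tidy (layer, n, mode, ratio, region sizes) table for CSV export."""
    rows = []
    for curve in curves:
        for n, ratio in curve.ratios.items():
            c, d, i, u = curve.region_sizes[n]
            rows.append(
                {
                    "layer": curve.layer.name,
                    "n": n,
                    "mode": curve.mode,
                    "ratio": ratio,
                    "consensus_px": c,
                    "disagreement_px": d,
                    "ignored_px": i,
                    "union_px": u,
                    "empty": curve.empty,
                }
            )
    return pd.DataFrame(rows)


def save_consensus_map(cmap: ConsensusMap, png_path: str | Path) -> None:
    """Export a consensus map as a palette PNG (background=0, ignored=1,
    disagreement=2, consensus=3) with a JSON sidecar."""
    import json

    from PIL import Image

    coded = np.zeros(cmap.grid.shape, dtype=np.uint8)
    for value, code in MAP_PALETTE.items():
        coded[cmap.grid == value] = code
    img = Image.fromarray(coded, mode="P")
    colors = [(0, 0, 0), (120, 120, 120), (200, 40, 40), (40, 200, 40)]
    img.putpalette(sum([list(c) for c in colors], []) + [0] * (768 - 12))
    img.save(png_path)
    sidecar = {
        "image_id": cmap.image_id,
        "layer": cmap.layer.name,
        "threshold": cmap.threshold,
        "palette": {"background": 0, "ignored": 1, "disagreement": 2, "consensus": 3},
    }
    Path(str(png_path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
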