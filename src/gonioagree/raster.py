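"""Polygon rasterization to per-pixel label maps with explicit NA semantics.

A :class:`LabelMap` assigns every pixel of an image exactly one value from
{NA, IR, CBB, SS, TM, C}.  NA (value 0) means "left un-annotated" — never
"background object" — and the set of non-NA pixels equals the union of the
rasterized polygon interiors.

Rasterization rule: a pixel belongs to a polygon iff its *center*
(col + 0.5, row + 0.5) lies inside the polygon under the even-odd rule.
Centers exactly on an edge are resolved by a fixed top-left tie-break: the
pixel is inside if the test point perturbed by an infinitesimal positive
amount in +x and +y is inside.  This is implemented by evaluating the
crossing-number test at the perturbed point (col + 0.5 + ε, row + 0.5 + ε)
with ε = 1e-7 px, which is deterministic and matches scanline rasterizers.
No anti-aliasing or partial coverage: the analysis is strictly categorical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import (
    NA_VALUE,
    AnnotationSet,
    ImageAnnotation,
    LayerLabel,
    LAYERS,
    OverlapError,
)

#: sub-pixel perturbation implementing the top-left edge tie-break
EDGE_EPS: float = 1e-7

PALETTE_VERSION = 1
#: label-map PNG palette: NA=0, IR=1, CBB=2, SS=3, TM=4, C=5
PALETTE = {NA_VALUE: "NA", **{int(l): l.name for l in LAYERS}}


@dataclass
class LabelMap:
    """Per-pixel layer assignment of one image by one annotator.

    ``grid`` is a (height, width) uint8 array with values 0 (NA) or the
    :class:`LayerLabel` integer codes 1–5.
    """

    image_id: str
    annotator_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.ndim != 2:
            raise ValueError("label-map grid must be 2-D (height, width)")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


def points_in_polygon(vertices: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    Test points are perturbed by +EDGE_EPS in x and y, which realises the
    top-left tie-break for points exactly on an edge or vertex.
    """
    v = np.asarray(vertices, dtype=float)
    px = np.asarray(px, dtype=float).ravel() + EDGE_EPS
    py = np.asarray(py, dtype=float).ravel() + EDGE_EPS
    inside = np.zeros(px.shape, dtype=bool)
    n = v.shape[0]
    for k in range(n):
        x1, y1 = v[k]
        x2, y2 = v[(k + 1) % n]
        if y1 == y2:  # horizontal edge never crosses a horizontal ray
            continue
        crosses = (y1 <= py) != (y2 <= py)
        if not crosses.any():
            continue
        x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
    return inside


def polygon_mask(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Boolean (height, width) mask of pixels whose centers fall inside the polygon."""
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    inside = points_in_polygon(vertices, cols + 0.5, rows + 0.5)
    return inside.reshape(height, width)


def rasterize_annotation(annotation: ImageAnnotation) -> LabelMap:
    """Convert an :class:`ImageAnnotation` to a :class:`LabelMap`.

    A pixel receives label ℓ iff its center is inside a polygon labeled ℓ;
    all other pixels are NA.  Polygons of the same label union; a pixel
    claimed by two *different* labels raises :class:`OverlapError`.  A
    polygon that encloses no pixel center contributes nothing and is
    dropped with a warning.
    """
    grid = np.zeros((annotation.height, annotation.width), dtype=np.uint8)
    for idx, poly in enumerate(annotation.polygons):
        mask = polygon_mask(poly.vertices, annotation.width, annotation.height)
        if not mask.any():
            warnings.warn(
                f"image {annotation.image_id!r}, polygon {idx} ({poly.label.name}) "
                "encloses no pixel center and was dropped",
                stacklevel=2,
            )
            continue
        conflict = mask & (grid != NA_VALUE) & (grid != int(poly.label))
        if conflict.any():
            row, col = np.argwhere(conflict)[0]
            other = LayerLabel(int(grid[row, col]))
            raise OverlapError(
                f"image {annotation.image_id!r}: pixel (col={col}, row={row}) claimed "
                f"by both {other.name} and {poly.label.name}"
            )
        grid[mask] = int(poly.label)
    return LabelMap(annotation.image_id, annotation.annotator_id, grid)


def rasterize_set(annotation_set: AnnotationSet) -> dict[tuple[str, str], LabelMap]:
    """Rasterize every (annotator, image) cell once; downstream modules
    consume these cached LabelMaps only."""
    return {
        key: rasterize_annotation(ann) for key, ann in annotation_set.annotations.items()
    }


def layer_mask(label_map: LabelMap, layer: LayerLabel) -> np.ndarray:
    """Boolean mask of pixels assigned to ``layer``."""
    return label_map.grid == int(layer)


def na_mask(label_map: LabelMap) -> np.ndarray:
    """Boolean mask of un-annotated pixels."""
    return label_map.grid == NA_VALUE


# ---------------------------------------------------------------------------
# PNG export / import
# ---------------------------------------------------------------------------

def save_label_map(label_map: LabelMap, png_path: str | Path) -> None:
    """Write a LabelMap as a single-channel palette PNG plus a JSON sidecar.

    Pixel values follow :data:`PALETTE`; the sidecar (same path with a
    ``.json`` suffix appended) records image/annotator identity and the
    palette version.
    """
    from PIL import Image

    png_path = Path(png_path)
    img = Image.fromarray(label_map.grid, mode="P")
    # visually distinct palette (NA black, layers in a fixed color cycle)
    colors = [(0, 0, 0), (180, 120, 60), (120, 60, 160), (220, 40, 40),
              (40, 160, 220), (230, 230, 230)]
    palette = sum([list(c) for c in colors], []) + [0] * (768 - 3 * len(colors))
    img.putpalette(palette)
    img.save(png_path)
    sidecar = {
        "image_id": label_map.image_id,
        "annotator_id": label_map.annotator_id,
        "palette_version": PALETTE_VERSION,
        "palette": {str(k): v for k, v in PALETTE.items()},
    }
    Path(str(png_path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_label_map(png_path: str | Path) -> LabelMap:
    """Read a LabelMap written by :func:`save_label_map`."""
    from PIL import Image

    png_path = Path(png_path)
    sidecar = json.loads(Path(str(png_path) + ".json").read_text())
    if sidecar.get("palette_version") != PALETTE_VERSION:
        raise ValueError(
            f"unsupported palette version {sidecar.get('palette_version')!r}"
        )
    grid = np.asarray(Image.open(png_path), dtype=np.uint8)
    return LabelMap(sidecar["image_id"], sidecar["annotator_id"], grid)
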