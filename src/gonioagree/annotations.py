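"""Annotation data model and VGG Image Annotator (VIA) 2.x project I/O.

The analysis operates on multi-annotator polygonal delineations of the five
anatomical layers visible in digital gonio photographs of the iridocorneal
angle (ICA).  In anatomical order from inner to outer the layers are the
iris root (IR), ciliary body band (CBB), scleral spur (SS), trabecular
meshwork (TM) and cornea (C).  An annotator outlines each layer with one or
more simple polygons; everything outside the polygons is *un-annotated*
(NA) — a deliberate "no statement" by the annotator, semantically distinct
from background and excluded from all agreement computations downstream.

Annotations are exchanged in the VIA 2.x project format (the
``_via_img_metadata`` dialect): each image entry carries a list of regions
whose ``shape_attributes`` describe a polygon (``all_points_x`` /
``all_points_y``) and whose ``region_attributes`` hold the layer label under
a configurable key.  VIA does not record image dimensions, so sizes come
from a dataset manifest (or the ``width``/``height`` file attributes this
package writes on export).

Coordinate convention: vertex coordinates are in pixel units with the
origin at the top-left corner, x rightward and y downward; the pixel at
(col, row) has its center at (col + 0.5, row + 0.5).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# label vocabulary
# ---------------------------------------------------------------------------

class LayerLabel(enum.IntEnum):
    """The five ICA layers, in canonical anatomical order (inner → outer).

    Integer values double as label-map pixel values; 0 is reserved for NA,
    which is a sentinel and never a member of this enumeration.
    """

    IR = 1
    CBB = 2
    SS = 3
    TM = 4
    C = 5

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]


NA_VALUE: int = 0  # pixel value for un-annotated; not a LayerLabel

LAYERS: tuple[LayerLabel, ...] = tuple(LayerLabel)

_DISPLAY_NAMES = {
    LayerLabel.IR: "iris root",
    LayerLabel.CBB: "ciliary body band",
    LayerLabel.SS: "scleral spur",
    LayerLabel.TM: "trabecular meshwork",
    LayerLabel.C: "cornea",
}

#: Default alias table for mapping VIA label strings to layer codes.
#: Lookup is case-insensitive and whitespace-stripped; extend or replace via
#: the ``aliases`` argument of :func:`parse_via_project` or a YAML mapping
#: file in the CLI.
DEFAULT_ALIASES: dict[str, LayerLabel] = {}
for _layer in LAYERS:
    DEFAULT_ALIASES[_layer.name.lower()] = _layer
    DEFAULT_ALIASES[_layer.display_name] = _layer


def resolve_label(raw: str, aliases: Mapping[str, LayerLabel] | None = None) -> LayerLabel:
    """Map a raw label string to a :class:`LayerLabel` through the alias table."""
    table = DEFAULT_ALIASES if aliases is None else aliases
    key = raw.strip().lower()
    if key in table:
        return table[key]
    raise LabelError(
        f"unknown layer label {raw!r}; permitted values (case-insensitive): "
        + ", ".join(sorted(table))
    )


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class AnnotationError(Exception):
    """Base class for annotation-layer errors."""


class ViaParseError(AnnotationError):
    """Malformed VIA project content."""


class LabelError(AnnotationError):
    """Region label outside the layer vocabulary (after aliasing)."""


class UnsupportedShapeError(AnnotationError):
    """Region shape other than polygon (circle, rect, polyline, ...)."""


class OverlapError(AnnotationError):
    """Two different layer labels claim the same pixel."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class PolygonAnnotation:
    """One labeled polygonal contour in pixel coordinates.

    ``vertices`` is an (N, 2) float array of (x, y) points, N ≥ 3, implicitly
    closed.  The polygon must be simple (non-self-intersecting).
    """

    label: LayerLabel
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ViaParseError(
                f"polygon needs an (N>=3, 2) vertex array, got shape {v.shape}"
            )
        self.vertices = v

    def is_simple(self) -> bool:
        """True if the closed contour does not self-intersect (zero-area
        degenerate rings also count as non-simple)."""
        import shapely

        ring = shapely.LinearRing(self.vertices)
        return bool(ring.is_simple) and bool(shapely.Polygon(self.vertices).is_valid)

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, PolygonAnnotation):
            return NotImplemented
        return self.label == other.label and np.allclose(
            self.vertices, other.vertices, atol=1e-9
        )


@dataclass
class ImageAnnotation:
    """All polygons drawn by one annotator on one image.

    ``image_size`` is (width, height) in pixels.  ``polygons`` may be empty —
    the annotator delineated nothing on this image.  Multiple polygons may
    share a label (split regions); their pixel sets are unioned downstream.
    """

    image_id: str
    image_size: tuple[int, int]
    annotator_id: str
    polygons: list[PolygonAnnotation] = field(default_factory=list)

    @property
    def width(self) -> int:
        return int(self.image_size[0])

    @property
    def height(self) -> int:
        return int(self.image_size[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageAnnotation):
            return NotImplemented
        return (
            self.image_id == other.image_id
            and tuple(self.image_size) == tuple(other.image_size)
            and self.annotator_id == other.annotator_id
            and self.polygons == other.polygons
        )


@dataclass
class AnnotationSet:
    """A complete annotator × image panel.

    Every (annotator, image) cell must be present; a cell holding an
    ImageAnnotation with zero polygons is valid (nothing delineated).  All
    annotations of one image share the same size.
    """

    annotator_ids: list[str]
    image_ids: list[str]
    annotations: dict[tuple[str, str], ImageAnnotation]

    def __post_init__(self) -> None:
        sizes: dict[str, tuple[int, int]] = {}
        for a in self.annotator_ids:
            for m in self.image_ids:
                ann = self.annotations.get((a, m))
                if ann is None:
                    raise AnnotationError(
                        f"missing annotation cell (annotator={a!r}, image={m!r})"
                    )
                prev = sizes.setdefault(m, tuple(ann.image_size))
                if prev != tuple(ann.image_size):
                    raise AnnotationError(
                        f"inconsistent image size for {m!r}: {prev} vs {tuple(ann.image_size)}"
                    )

    @property
    def n_annotators(self) -> int:
        return len(self.annotator_ids)

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def image_size(self, image_id: str) -> tuple[int, int]:
        return tuple(self.annotations[(self.annotator_ids[0], image_id)].image_size)

    def __getitem__(self, key: tuple[str, str]) -> ImageAnnotation:
        return self.annotations[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.annotator_ids == other.annotator_ids
            and self.image_ids == other.image_ids
            and self.annotations == other.annotations
        )


# ---------------------------------------------------------------------------
# VIA 2.x project parsing / writing
# ---------------------------------------------------------------------------

def _clip_vertices(
    vertices: np.ndarray, width: int, height: int, context: str
) -> np.ndarray:
    """Clamp vertices into the image rectangle [0, W] × [0, H].

    Annotators can drag points past the border in VIA; clamping (with a
    warning) is preferable to rejecting the whole polygon.
    """
    clipped = np.column_stack(
        [np.clip(vertices[:, 0], 0.0, float(width)), np.clip(vertices[:, 1], 0.0, float(height))]
    )
    if not np.allclose(clipped, vertices):
        warnings.warn(
            f"{context}: vertices outside image bounds were clipped to the image rectangle",
            stacklevel=3,
        )
    return clipped


def parse_via_project(
    file_content: str,
    label_key: str = "layer",
    annotator_id: str = "",
    aliases: Mapping[str, LayerLabel] | None = None,
    default_image_size: tuple[int, int] = (1280, 960),
    image_sizes: Mapping[str, tuple[int, int]] | None = None,
) -> list[ImageAnnotation]:
    """Parse a VIA 2.x project into one :class:`ImageAnnotation` per image.

    Parameters
    ----------
    file_content:
        JSON text of a VIA 2.x project (a full project with
        ``_via_img_metadata``, or the bare metadata dictionary that VIA's
        "export annotations" produces).
    label_key:
        Name of the region attribute holding the layer label.
    annotator_id:
        Identity stamped on every resulting ImageAnnotation.
    aliases:
        Label alias table; defaults to :data:`DEFAULT_ALIASES`.
    default_image_size, image_sizes:
        VIA projects do not record pixel dimensions.  Sizes are taken from
        ``image_sizes[image_id]`` when given, else from ``width``/``height``
        file attributes (written by :func:`write_via_project`), else from
        ``default_image_size``.
    """
    try:
        obj = json.loads(file_content)
    except json.JSONDecodeError as exc:
        raise ViaParseError(f"invalid JSON in VIA project: {exc}") from exc
    if not isinstance(obj, dict):
        raise ViaParseError("VIA project must be a JSON object")

    metadata = obj.get("_via_img_metadata", obj)
    if not isinstance(metadata, dict):
        raise ViaParseError("_via_img_metadata must be a JSON object")

    result: list[ImageAnnotation] = []
    for entry_key, entry in metadata.items():
        if entry_key.startswith("_via_"):  # settings blocks in full projects
            continue
        if not isinstance(entry, dict) or "filename" not in entry:
            raise ViaParseError(f"image entry {entry_key!r} has no filename")
        image_id = str(entry["filename"])
        file_attrs = entry.get("file_attributes", {}) or {}
        if image_sizes is not None and image_id in image_sizes:
            size = tuple(int(v) for v in image_sizes[image_id])
        elif "width" in file_attrs and "height" in file_attrs:
            size = (int(file_attrs["width"]), int(file_attrs["height"]))
        else:
            size = tuple(int(v) for v in default_image_size)

        polygons: list[PolygonAnnotation] = []
        for idx, region in enumerate(entry.get("regions", []) or []):
            context = f"image {image_id!r}, region {idx}"
            try:
                shape = region["shape_attributes"]
                attrs = region["region_attributes"]
            except (KeyError, TypeError) as exc:
                raise ViaParseError(f"{context}: missing shape/region attributes") from exc
            shape_name = shape.get("name")
            if shape_name != "polygon":
                raise UnsupportedShapeError(
                    f"{context}: shape {shape_name!r} is not supported; only polygons are"
                )
            if label_key not in attrs:
                raise ViaParseError(
                    f"{context}: region attribute {label_key!r} not present"
                )
            try:
                label = resolve_label(str(attrs[label_key]), aliases)
            except LabelError as exc:
                raise LabelError(f"{context}: {exc}") from exc
            xs = shape.get("all_points_x")
            ys = shape.get("all_points_y")
            if xs is None or ys is None or len(xs) != len(ys):
                raise ViaParseError(f"{context}: malformed polygon point lists")
            if len(xs) < 3:
                raise ViaParseError(f"{context}: polygon has fewer than 3 vertices")
            vertices = _clip_vertices(
                np.column_stack([xs, ys]).astype(float), size[0], size[1], context
            )
            poly = PolygonAnnotation(label=label, vertices=vertices)
            if not poly.is_simple():
                raise ViaParseError(f"{context}: polygon is self-intersecting")
            polygons.append(poly)
        result.append(
            ImageAnnotation(
                image_id=image_id,
                image_size=size,
                annotator_id=annotator_id,
                polygons=polygons,
            )
        )
    return result


def write_via_project(
    annotations: Sequence[ImageAnnotation], label_key: str = "layer"
) -> str:
    """Serialize annotations as a VIA 2.x project (JSON text).

    Image dimensions are stored as ``width``/``height`` file attributes so
    that ``parse_via_project(write_via_project(X))`` round-trips sizes.
    """
    metadata: dict[str, dict] = {}
    for ann in annotations:
        regions = []
        for poly in ann.polygons:
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x in poly.vertices[:, 0]],
                        "all_points_y": [float(y) for y in poly.vertices[:, 1]],
                    },
                    "region_attributes": {label_key: poly.label.name},
                }
            )
        metadata[f"{ann.image_id}-1"] = {
            "filename": ann.image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {"width": ann.width, "height": ann.height},
        }
    project = {
        "_via_settings": {
            "ui": {},
            "core": {"buffer_size": 18, "filepath": {}, "default_filepath": ""},
            "project": {"name": "gonioagree"},
        },
        "_via_img_metadata": metadata,
        "_via_attributes": {
            "region": {
                label_key: {
                    "type": "dropdown",
                    "description": "ICA layer",
                    "options": {l.name: l.display_name for l in LAYERS},
                    "default_options": {},
                }
            },
            "file": {},
        },
    }
    return json.dumps(project, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# non-overlap validation
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Pairs of polygons whose rasterized pixel sets intersect.

    ``pairs`` holds (index_i, index_j, n_shared_pixels) with i < j.  An empty
    report means the annotation satisfies the non-overlap protocol at the
    pixel level (shared continuous edges without shared pixel centers are
    permitted).
    """

    image_id: str
    annotator_id: str
    pairs: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.pairs


def validate_non_overlap(annotation: ImageAnnotation) -> OverlapReport:
    """Check that the rasterized interiors of all polygons are pairwise disjoint.

    Overlap is assessed on shared *pixel centers*, not continuous geometry,
    because the whole analysis is pixel-wise.
    """
    from .raster import polygon_mask  # local import avoids a module cycle

    masks = [
        polygon_mask(p.vertices, annotation.width, annotation.height)
        for p in annotation.polygons
    ]
    report = OverlapReport(annotation.image_id, annotation.annotator_id)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            shared = int(np.count_nonzero(masks[i] & masks[j]))
            if shared:
                report.pairs.append((i, j, shared))
    return report


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["annotator_id", "image_id", "project_path", "image_width", "image_height"]


def load_annotation_set(
    manifest_path: str | Path,
    label_key: str = "layer",
    aliases: Mapping[str, LayerLabel] | None = None,
) -> AnnotationSet:
    """Load a full panel from a manifest table.

    The manifest is a CSV with columns ``annotator_id, image_id,
    project_path, image_width, image_height`` — one row per (annotator,
    image) cell; ``project_path`` (relative to the manifest) points to that
    annotator's VIA project, which may cover many images.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype={"annotator_id": str, "image_id": str})
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise AnnotationError(f"manifest is missing columns: {sorted(missing)}")

    annotator_ids = list(dict.fromkeys(table["annotator_id"]))
    image_ids = list(dict.fromkeys(table["image_id"]))
    sizes = {
        str(row.image_id): (int(row.image_width), int(row.image_height))
        for row in table.itertuples()
    }

    parsed: dict[tuple[str, str], ImageAnnotation] = {}
    for project_rel, group in table.groupby("project_path", sort=False):
        project_file = manifest_path.parent / str(project_rel)
        annotator = str(group["annotator_id"].iloc[0])
        if group["annotator_id"].nunique() != 1:
            raise AnnotationError(
                f"project {project_rel!r} is shared by multiple annotators in the manifest"
            )
        content = project_file.read_text()
        for ann in parse_via_project(
            content,
            label_key=label_key,
            annotator_id=annotator,
            aliases=aliases,
            image_sizes=sizes,
        ):
            parsed[(annotator, ann.image_id)] = ann

    annotations: dict[tuple[str, str], ImageAnnotation] = {}
    for a in annotator_ids:
        for m in image_ids:
            ann = parsed.get((a, m))
            if ann is None:
                # a cell absent from the project = annotator drew nothing there
                ann = ImageAnnotation(
                    image_id=m, image_size=sizes[m], annotator_id=a, polygons=[]
                )
            annotations[(a, m)] = ann
    return AnnotationSet(annotator_ids, image_ids, annotations)


def load_aliases(path: str | Path) -> dict[str, LayerLabel]:
    """Read a label alias table from a YAML mapping file (alias → layer code)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise AnnotationError("alias file must be a mapping of alias -> layer code")
    table = dict(DEFAULT_ALIASES)
    for alias, code in raw.items():
        table[str(alias).strip().lower()] = LayerLabel[str(code).strip().upper()]
    return table
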