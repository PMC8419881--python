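"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-pixel Python loops, a different
geometry engine) and shares no code with the package's own vectorized
routines.
"""

from __future__ import annotations

import numpy as np
import shapely

EPS = 1e-7  # same top-left tie-break convention: perturb test points by +ε


def pip_oracle_mask(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Exhaustive pixel-center point-in-polygon test via shapely (GEOS)."""
    poly = shapely.Polygon(vertices)
    mask = np.zeros((height, width), dtype=bool)
    for row in range(height):
        for col in range(width):
            mask[row, col] = shapely.contains_xy(poly, col + 0.5 + EPS, row + 0.5 + EPS)
    return mask


def consensus_oracle_pixel(labels: list[int], layer: int, n: int) -> int:
    """Per-pixel three-category classifier; labels are per-annotator pixel
    values (0 = NA).  Returns 1, -1, 0 or -2 (background)."""
    k = sum(1 for v in labels if v == layer)
    d = sum(1 for v in labels if v != 0 and v != layer)
    if k == 0:
        return -2
    if k >= n:
        return 1
    return -1 if d >= 1 else 0


def consensus_oracle(stack: np.ndarray, layer: int, n: int) -> np.ndarray:
    """Brute-force consensus map for a (A, H, W) stack of label grids."""
    A, H, W = stack.shape
    out = np.empty((H, W), dtype=np.int8)
    for row in range(H):
        for col in range(W):
            out[row, col] = consensus_oracle_pixel(
                [int(stack[a, row, col]) for a in range(A)], layer, n
            )
    return out


def confusion_oracle(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Brute-force NA-excluded 5×5 confusion tally."""
    counts = np.zeros((5, 5), dtype=np.int64)
    for row in range(g1.shape[0]):
        for col in range(g1.shape[1]):
            a, b = int(g1[row, col]), int(g2[row, col])
            if a != 0 and b != 0:
                counts[a - 1, b - 1] += 1
    return counts


def random_star_polygon(
    rng: np.random.Generator,
    width: int,
    height: int,
    n_vertices: int | None = None,
) -> np.ndarray:
    """Random simple (star-shaped) polygon inside the image rectangle:
    vertices at sorted angles around a random center are never
    self-intersecting."""
    n = int(n_vertices or rng.integers(3, 12))
    cx = rng.uniform(0.2 * width, 0.8 * width)
    cy = rng.uniform(0.2 * height, 0.8 * height)
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    # keep angles distinct so the ring stays simple
    angles += np.linspace(0.0, 1e-3, n)
    max_r = min(cx, cy, width - cx, height - cy)
    radii = rng.uniform(0.15 * max_r, max_r, size=n)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])


def random_label_grid(rng: np.random.Generator, width: int, height: int,
                      p_na: float = 0.35) -> np.ndarray:
    """Random label map: NA with probability p_na, else a uniform layer."""
    grid = rng.integers(1, 6, size=(height, width)).astype(np.uint8)
    grid[rng.random((height, width)) < p_na] = 0
    return grid
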