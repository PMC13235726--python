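"""Standardized scatter-plot images of embeddings, colored by cluster.

Images are drawn with raster primitives only (no fonts, axes, legend or
title) so that identical inputs yield byte-identical PNGs on every
platform.  Point draw order is shuffled by a seed to mitigate the
overplotting bias of fixed draw order, where points rendered earlier can
be hidden by later ones.
"""

from __future__ import annotations

import colorsys
import io
import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

logger = logging.getLogger(__name__)

CANVAS_PX = 600
MARGIN_FRAC = 0.05
PALETTE_SIZE = 30


def _build_palette(n: int = PALETTE_SIZE) -> list[tuple[int, int, int]]:
    # Evenly spaced hues on two saturation/value rings, interleaved for
    # maximal adjacent-label contrast.
    half = n // 2
    colors = []
    for i in range(half):
        colors.append(colorsys.hsv_to_rgb(i / half, 0.85, 0.92))
        colors.append(colorsys.hsv_to_rgb((i + 0.5) / half, 0.95, 0.55))
    return [tuple(int(round(255 * c)) for c in rgb) for rgb in colors[:n]]


PALETTE: list[tuple[int, int, int]] = _build_palette()


@dataclass
class EmbeddingImage:
    """A rendered embedding scatter plot ready for pairwise judging."""

    image_bytes: bytes
    basis: str  # "umap" or "pca"
    config_id: str
    width_px: int
    height_px: int


def point_radius(n_cells: int) -> int:
    """Point size in px, shrinking with log10 cell count (min 1 px)."""
    return max(1, round(6 - np.log10(max(n_cells, 1))))


def render_embedding(
    embedding: np.ndarray,
    cluster_labels: np.ndarray,
    basis: str,
    seed: int,
    config_id: str = "",
    size: int = CANVAS_PX,
) -> EmbeddingImage:
    """Render a cells x 2 embedding as a deterministic square PNG.

    Points are colored by cluster label from a fixed 30-color palette
    (colors cycle with a logged warning beyond that), scaled into the
    canvas with a 5% margin, and drawn in seed-shuffled order on a white
    background.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    cluster_labels = np.asarray(cluster_labels)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError(f"embedding must be cells x 2, got shape {embedding.shape}")
    n = embedding.shape[0]
    if n < 1:
        raise ValueError("need at least one cell to render")
    if cluster_labels.shape[0] != n:
        raise ValueError(
            f"{cluster_labels.shape[0]} labels for {n} embedding rows"
        )
    if basis not in ("umap", "pca"):
        raise ValueError(f"basis must be 'umap' or 'pca', got {basis!r}")
    n_labels = len(np.unique(cluster_labels))
    if n_labels > PALETTE_SIZE:
        logger.warning(
            "%d clusters exceed the %d-color palette; colors will repeat",
            n_labels,
            PALETTE_SIZE,
        )

    lo = embedding.min(axis=0)
    hi = embedding.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    margin = size * MARGIN_FRAC
    avail = size - 2 * margin
    xy = (embedding - lo) / span * avail + margin
    # center degenerate axes; flip y into image coordinates
    xy[:, hi == lo] = size / 2
    xy[:, 1] = size - xy[:, 1]

    img = Image.new("RGB", (size, size), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    r = point_radius(n)
    order = np.random.default_rng(seed).permutation(n)
    for i in order:
        x, y = xy[i]
        color = PALETTE[int(cluster_labels[i]) % PALETTE_SIZE]
        draw.ellipse((x - r, y - r, x + r, y + r), fill=color)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return EmbeddingImage(
        image_bytes=buf.getvalue(),
        basis=basis,
        config_id=config_id,
        width_px=size,
        height_px=size,
    )
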