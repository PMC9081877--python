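"""Labelme-style polygon annotations: reading, writing, rasterisation.

Polygons are stored (x, y) per the Labelme convention and converted to
(row, col) at this boundary; everywhere else the package is row-major and
0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw

from .synthetic import edge_mask_from_labels


class AnnotationError(ValueError):
    """Malformed or out-of-bounds annotation content."""


@dataclass
class AnnotationRecord:
    image_path: str
    polygons: list[np.ndarray]  # each (N, 2) float array of (x, y) points
    labels: list[str]
    image_height: int
    image_width: int


def read_annotation(json_path: str | Path) -> AnnotationRecord:
    """Read a Labelme-style JSON file into an :class:`AnnotationRecord`."""
    json_path = Path(json_path)
    try:
        with open(json_path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot read annotation {json_path}: {exc}") from exc
    try:
        height = int(data["imageHeight"])
        width = int(data["imageWidth"])
        shapes = data["shapes"]
    except KeyError as exc:
        raise AnnotationError(f"{json_path}: missing key {exc}") from exc
    polygons, labels = [], []
    for i, shape in enumerate(shapes):
        pts = np.asarray(shape.get("points", []), dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise AnnotationError(
                f"{json_path}: shape {i} is not a polygon with >= 3 points"
            )
        if (
            pts[:, 0].min() < -0.5
            or pts[:, 0].max() > width - 0.5
            or pts[:, 1].min() < -0.5
            or pts[:, 1].max() > height - 0.5
        ):
            raise AnnotationError(f"{json_path}: shape {i} has out-of-bounds points")
        polygons.append(pts)
        labels.append(str(shape.get("label", "droplet")))
    return AnnotationRecord(
        image_path=str(data.get("imagePath", "")),
        polygons=polygons,
        labels=labels,
        image_height=height,
        image_width=width,
    )


def write_annotation(record: AnnotationRecord, json_path: str | Path) -> None:
    data = {
        "version": "5.0.1",
        "flags": {},
        "shapes": [
            {
                "label": label,
                "points": [[float(x), float(y)] for x, y in poly],
                "shape_type": "polygon",
            }
            for label, poly in zip(record.labels, record.polygons)
        ],
        "imagePath": record.image_path,
        "imageHeight": record.image_height,
        "imageWidth": record.image_width,
    }
    with open(json_path, "w") as fh:
        json.dump(data, fh)


def rasterize(record: AnnotationRecord) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise polygons to (label_map, consensus_edges).

    Each polygon becomes one droplet label (in file order); polygon
    boundaries become a binary edge map promoted to single-annotator
    consensus (value 1.0).
    """
    shape = (record.image_height, record.image_width)
    label_map = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(record.polygons, start=1):
        rows = poly[:, 1]
        cols = poly[:, 0]
        rr, cc = draw.polygon(rows, cols, shape=shape)
        label_map[rr, cc] = i
    consensus = edge_mask_from_labels(label_map).astype(np.float64)
    return label_map, consensus
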