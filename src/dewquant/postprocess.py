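"""Contour post-processing: from an edge map to droplet regions and areas.

An edge probability map is binarised, speck-filtered with a morphological
opening, bridged and hole-filled so that closed droplet contours become
solid regions, size-filtered (the large-area cut removes regions created
by the background-segmentation boundary, the small cut removes residual
noise), and finally measured per connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .segmentation import morph_dilate, morph_erode


@dataclass
class DropletRegion:
    """One connected dew region."""

    id: int
    area_px: int
    contour: np.ndarray  # closed (row, col) polyline, first == last
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open


@dataclass
class PostprocessConfig:
    """Parameters of the edge-to-region chain.

    threshold : binarisation threshold for probability maps; None selects
        per-image Otsu.
    open_se_side : square SE side for the speck-removing opening.
    bridge_px : dilation radius used to close 1-px gaps in contours before
        hole filling (the filled region is eroded back by the same amount).
    contour_halfwidth_px : extra erosion applied to the filled regions.
        A detected contour is at least one pixel thick and straddles the
        true boundary, so the filled region extends to the contour's
        outer extremity; shrinking by half the contour width places the
        region boundary on the contour centerline and removes the
        systematic one-pixel outward bias in measured areas.
    min_area / max_area_frac : size window for surviving regions;
        max area is ``max_area_frac`` of the image area.
    """

    threshold: float | None = None
    open_se_side: int = 3
    bridge_px: int = 1
    contour_halfwidth_px: int = 1
    min_area: int = 9
    max_area_frac: float = 0.05


def binarize(prob_map: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a probability map; pixel = 1 iff p >= threshold.

    With ``threshold=None`` the Otsu threshold of the map is used
    (falling back to 0.5 on a constant map).
    """
    prob = np.asarray(prob_map, dtype=np.float64)
    if threshold is None:
        threshold = 0.5 if prob.min() == prob.max() else float(
            filters.threshold_otsu(prob)
        )
    elif not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (prob >= threshold).astype(np.uint8)


def open_filter(mask: np.ndarray, se_side: int = 3) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a square SE.

    Removes specks smaller than the SE; never creates pixels; idempotent.
    """
    if se_side < 1 or se_side % 2 == 0:
        raise ValueError(f"se_side must be an odd positive integer, got {se_side}")
    return morph_dilate(morph_erode(mask, se_side), se_side)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set background components not connected to the image border to 1."""
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool)).astype(np.uint8)


def bridge_and_fill(mask: np.ndarray, bridge_px: int = 1) -> np.ndarray:
    """Close small contour gaps, fill interiors, undo the bridge dilation.

    Edge curves with gaps up to ~2*bridge_px are closed by a dilation so
    hole filling solidifies their interior; the erosion afterwards restores
    the outer boundary to its original position.
    """
    if bridge_px == 0:
        return fill_holes(mask)
    side = 2 * bridge_px + 1
    grown = morph_dilate(mask, side)
    filled = fill_holes(grown)
    return morph_erode(filled, side)


def area_filter(
    label_map: np.ndarray, min_area: int, max_area: int
) -> np.ndarray:
    """Remove labelled regions with area < min_area or > max_area."""
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    lab = np.asarray(label_map)
    counts = np.bincount(lab.ravel())
    out = lab.copy()
    for rid, count in enumerate(counts):
        if rid == 0 or count == 0:
            continue
        if count < min_area or count > max_area:
            out[lab == rid] = 0
    return out


def extract_droplets(mask: np.ndarray) -> list[DropletRegion]:
    """Label 8-connected components of a binary (or labelled) mask.

    Returns one :class:`DropletRegion` per component with area, centroid,
    closed outer contour and half-open bounding box.
    """
    arr = np.asarray(mask)
    binary = arr > 0
    labelled = measure.label(binary, connectivity=2)
    regions = []
    for prop in measure.regionprops(labelled):
        region_mask = np.pad(labelled == prop.label, 1).astype(np.float64)
        contours = measure.find_contours(region_mask, 0.5)
        contour = max(contours, key=len) - 1.0  # undo the pad offset
        r0, c0, r1, c1 = prop.bbox
        regions.append(
            DropletRegion(
                id=int(prop.label),
                area_px=int(prop.area),
                contour=contour,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
            )
        )
    return regions


def measure_dew(
    regions: list[DropletRegion], bins: int = 10
) -> tuple[int, pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Total dew area, per-droplet table (area-descending) and area histogram."""
    table = pd.DataFrame(
        [
            {
                "id": r.id,
                "area_px": r.area_px,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "bbox_r0": r.bbox[0],
                "bbox_c0": r.bbox[1],
                "bbox_r1": r.bbox[2],
                "bbox_c1": r.bbox[3],
            }
            for r in regions
        ],
        columns=[
            "id", "area_px", "centroid_row", "centroid_col",
            "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1",
        ],
    )
    table = table.sort_values("area_px", ascending=False, kind="stable").reset_index(
        drop=True
    )
    total = int(table["area_px"].sum()) if len(table) else 0
    areas = table["area_px"].to_numpy(dtype=np.float64)
    hist = np.histogram(areas, bins=bins) if len(areas) else (
        np.zeros(bins, dtype=np.int64),
        np.linspace(0.0, 1.0, bins + 1),
    )
    return total, table, hist


def regions_from_edges(
    edge_input: np.ndarray, config: PostprocessConfig | None = None,
    image_area: int | None = None,
) -> tuple[list[DropletRegion], np.ndarray]:
    """Full chain: (probability map or binary edges) -> droplet regions.

    binarise -> bridge + hole fill -> opening -> area filter -> label.
    The opening acts on the filled region mask rather than the raw edge
    map: detected contours can be a single pixel wide (Canny after
    non-maximum suppression), and opening a 1-px curve with any SE larger
    than one pixel would erase it before it could be filled.  Applied to
    the solid regions, the opening still removes specks and hair-line
    artefacts as intended.  Returns the regions and the final region mask.
    """
    config = config or PostprocessConfig()
    arr = np.asarray(edge_input)
    if arr.dtype == np.uint8 and arr.max() <= 1:
        mask = arr.astype(np.uint8)
    else:
        mask = binarize(arr, config.threshold)
    mask = bridge_and_fill(mask, config.bridge_px)
    if config.contour_halfwidth_px:
        mask = morph_erode(mask, 2 * config.contour_halfwidth_px + 1)
    mask = open_filter(mask, config.open_se_side)
    if image_area is None:
        image_area = mask.size
    max_area = int(config.max_area_frac * image_area)
    labelled = measure.label(mask > 0, connectivity=2)
    labelled = area_filter(labelled, config.min_area, max_area)
    regions = extract_droplets(labelled)
    return regions, (labelled > 0).astype(np.uint8)


def match_regions(
    gt_label_map: np.ndarray, det_mask: np.ndarray
) -> list[tuple[int, int]]:
    """Pair ground-truth droplets with detected regions by mask overlap.

    Greedy on overlap (pixel intersection), ties broken by centroid
    distance; unmatched ground-truth droplets pair with 0 (missed).
    Returns (s_man, s_alm) pixel-area pairs, one per ground-truth droplet.
    """
    gt = np.asarray(gt_label_map)
    det = measure.label(np.asarray(det_mask) > 0, connectivity=2)
    gt_ids = [i for i in np.unique(gt) if i > 0]
    det_counts = np.bincount(det.ravel())
    gt_props = {p.label: p for p in measure.regionprops(gt)}
    det_props = {p.label: p for p in measure.regionprops(det)}

    candidates = []
    for gid in gt_ids:
        sel = det[gt == gid]
        overlap = np.bincount(sel[sel > 0], minlength=det_counts.size)
        for did in np.nonzero(overlap)[0]:
            dist = float(
                np.hypot(
                    gt_props[gid].centroid[0] - det_props[did].centroid[0],
                    gt_props[gid].centroid[1] - det_props[did].centroid[1],
                )
            )
            candidates.append((int(overlap[did]), -dist, int(gid), int(did)))
    candidates.sort(reverse=True)
    matched_gt: dict[int, int] = {}
    used_det: set[int] = set()
    for _overlap, _negdist, gid, did in candidates:
        if gid in matched_gt or did in used_det:
            continue
        matched_gt[gid] = did
        used_det.add(did)
    pairs = []
    for gid in gt_ids:
        s_man = int((gt == gid).sum())
        did = matched_gt.get(gid)
        s_alm = int(det_counts[did]) if did is not None else 0
        pairs.append((s_man, s_alm))
    return pairs
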