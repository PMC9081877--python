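"""Synthetic droplet scenes with exact ground truth.

Renders dew-like droplets (anti-aliased ellipses with a darker rim and an
optional specular highlight) on leaf-green, neutral-glass or mixed
backgrounds, optionally contaminated by high-saturation color/light
interference patches.  Every scene carries a pixel-exact label map,
per-droplet areas and a k-annotator consensus edge map, so the whole
detection pipeline can be evaluated against known truth.

Physical scale: droplets in the field are 1-5 mm across; at the default
20 px/mm this maps to 20-100 px equivalent diameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure

from .segmentation import hsv_to_rgb, HsvImage


class PlacementError(RuntimeError):
    """Raised when droplets cannot be placed without overlap after bounded retries."""


class TransformError(ValueError):
    """Raised when an augmentation would leave no droplet in frame."""


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene.

    Droplet diameters default to the 1-5 mm field range mapped at
    ``px_per_mm`` (20 px/mm -> 20-100 px).  ``background_kind`` is one of
    ``leaf`` (saturated green with low-frequency texture), ``glass``
    (near-achromatic gray) or ``complex`` (leaf plus forced interference
    patches).  ``annotators_k`` synthetic annotators each displace the true
    contour by at most ``annotator_jitter_px`` (Euclidean) before the
    per-pixel mean forms the consensus edge map.  ``border_margin_px``
    keeps droplets at least that far from the frame edge; set it to the
    half-width of the segmentation erosion element when a scene must
    survive the analysis-mask border shrink intact.
    """

    image_width: int = 256
    image_height: int = 256
    n_droplets: int = 8
    droplet_diameter_range: tuple[float, float] = (20.0, 100.0)
    droplet_aspect_range: tuple[float, float] = (0.85, 1.18)
    px_per_mm: float = 20.0
    background_kind: str = "leaf"
    background_hue_range: tuple[float, float] = (95.0, 140.0)
    n_noise_patches: int = 0
    noise_patch_saturation_min: int = 200
    specular_highlight: bool = True
    border_margin_px: int = 0
    annotators_k: int = 4
    annotator_jitter_px: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.droplet_diameter_range
        if lo < 3:
            raise ValueError("droplet diameters below 3 px are not resolvable")
        if lo > hi:
            raise ValueError("droplet_diameter_range must be (min, max)")
        if self.background_kind not in ("leaf", "glass", "complex"):
            raise ValueError(f"unknown background_kind {self.background_kind!r}")
        if self.annotators_k < 1:
            raise ValueError("annotators_k must be >= 1")
        if self.annotator_jitter_px < 0:
            raise ValueError("annotator_jitter_px must be >= 0")
        if self.n_droplets < 0 or self.n_noise_patches < 0:
            raise ValueError("counts must be non-negative")
        if hi >= min(self.image_width, self.image_height):
            raise ValueError("largest droplet does not fit in the image")


@dataclass
class GroundTruth:
    """Exact truth for a rendered scene.

    droplet_label_map : int array, 0 = background, i = droplet i.
    per_droplet_area : pixel count per droplet (the manually-marked area
        that detection is scored against).
    consensus_edges : per-pixel fraction of annotators marking an edge,
        values in {0, 1/k, ..., 1}.
    true_edge_mask : the noise-free droplet boundary the annotators saw.
    noise_patch_mask : pixels covered by planted high-saturation
        interference patches (before droplets were composited on top).
    """

    droplet_label_map: np.ndarray
    per_droplet_area: list[int]
    consensus_edges: np.ndarray
    true_edge_mask: np.ndarray
    noise_patch_mask: np.ndarray | None = None


def edge_mask_from_labels(label_map: np.ndarray) -> np.ndarray:
    """One-pixel outer boundary of every labelled region (4-connectivity).

    The contour is drawn on the background pixels adjacent to a region,
    matching where gradient-based detectors localise a boundary (the
    first pixel outside the intensity transition); the enclosed interior
    is then exactly the labelled region.
    """
    lab = np.asarray(label_map)
    edge = np.zeros(lab.shape, dtype=np.uint8)
    outside = lab == 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.zeros_like(lab)
        rs = slice(max(dr, 0), lab.shape[0] + min(dr, 0))
        rd = slice(max(-dr, 0), lab.shape[0] + min(-dr, 0))
        cs = slice(max(dc, 0), lab.shape[1] + min(dc, 0))
        cd = slice(max(-dc, 0), lab.shape[1] + min(-dc, 0))
        shifted[rd, cd] = lab[rs, cs]
        edge |= (outside & (shifted > 0)).astype(np.uint8)
    return edge


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Render the background as float RGB in [0, 255]."""
    h, w = cfg.image_height, cfg.image_width
    if cfg.background_kind == "glass":
        base = np.full((h, w, 3), 185.0)
        base += rng.normal(0.0, 3.0, size=(h, w, 1))
    else:  # leaf or complex
        hue = rng.uniform(*cfg.background_hue_range)
        texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 8.0)
        texture = texture / (np.abs(texture).max() + 1e-9)
        # leaves photograph at modest saturation (waxy cuticle, diffuse
        # daylight): mostly below the alpha=50 segmentation threshold, so
        # the leaf surface itself remains analysable while color/light
        # interference patches (planted separately) are cut away
        hsv = HsvImage(
            hue=np.full((h, w), hue),
            saturation=np.clip(36.0 + 10.0 * texture, 0, 255),
            value=np.clip(135.0 + 40.0 * texture, 0, 255),
        )
        base = hsv_to_rgb(hsv).astype(np.float64)
        base += rng.normal(0.0, 2.0, size=(h, w, 1))
    return np.clip(base, 0, 255)


def _add_noise_patches(
    img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Plant high-saturation interference patches (colored light, reflections)."""
    patch_mask = np.zeros(img.shape[:2], dtype=np.uint8)
    n = cfg.n_noise_patches
    if cfg.background_kind == "complex":
        n = max(n, 2)
    h, w = img.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n):
        ph = rng.integers(h // 8, max(h // 3, h // 8 + 1))
        pw = rng.integers(w // 8, max(w // 3, w // 8 + 1))
        r0 = rng.integers(0, max(h - ph, 1))
        c0 = rng.integers(0, max(w - pw, 1))
        hue = rng.uniform(0.0, 360.0)
        sat = rng.uniform(cfg.noise_patch_saturation_min, 255.0)
        val = rng.uniform(180.0, 255.0)
        patch_hsv = HsvImage(
            hue=np.full((ph, pw), hue),
            saturation=np.full((ph, pw), sat),
            value=np.full((ph, pw), val),
        )
        patch = hsv_to_rgb(patch_hsv).astype(np.float64)
        if rng.random() < 0.5:  # elliptical patch
            pr, pc = np.mgrid[0:ph, 0:pw]
            inside = ((pr - ph / 2) / (ph / 2)) ** 2 + (
                (pc - pw / 2) / (pw / 2)
            ) ** 2 <= 1.0
        else:
            inside = np.ones((ph, pw), dtype=bool)
        region = img[r0 : r0 + ph, c0 : c0 + pw]
        region[inside] = patch[inside]
        patch_mask[r0 : r0 + ph, c0 : c0 + pw][inside] = 1
    return img, patch_mask


def _render_droplet(
    img: np.ndarray,
    label: np.ndarray,
    idx: int,
    center: tuple[float, float],
    radii: tuple[float, float],
    theta: float,
    specular: bool,
    rng: np.random.Generator,
) -> None:
    """Composite one anti-aliased elliptical droplet in place."""
    cr, cc = center
    ra, rb = radii
    r_max = max(ra, rb) + 3
    r0, r1 = int(max(cr - r_max, 0)), int(min(cr + r_max + 1, img.shape[0]))
    c0, c1 = int(max(cc - r_max, 0)), int(min(cc + r_max + 1, img.shape[1]))
    rr, cc_ = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    dr, dc = rr - cr, cc_ - cc
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    d = np.sqrt((u / ra) ** 2 + (v / rb) ** 2)  # 1.0 on the boundary
    r_mean = 0.5 * (ra + rb)
    signed = (1.0 - d) * r_mean  # approx. px distance inside the rim
    cov = np.clip(signed + 0.5, 0.0, 1.0)  # ~1 px anti-alias band
    inside = signed >= 0.0

    patch = img[r0:r1, c0:c1]
    # droplet interior: desaturated, slightly brightened refraction of the
    # local background; darker annular rim gives the edge its contrast
    gray = patch.mean(axis=2, keepdims=True)
    interior = 0.35 * patch + 0.65 * gray
    interior = np.clip(interior * 1.12 + 12.0, 0, 255)
    rim_w = np.clip(0.12 * r_mean, 1.5, 3.0)
    rim = (signed >= 0.0) & (signed <= rim_w)
    body = interior.copy()
    body[rim] = np.clip(interior[rim] * 0.45, 0, 255)
    if specular:
        su = u + 0.35 * ra
        sv = v + 0.35 * rb
        spot = np.sqrt((su / (0.28 * ra)) ** 2 + (sv / (0.28 * rb)) ** 2)
        glint = np.clip(1.0 - spot, 0.0, 1.0)[..., None]
        body = body * (1.0 - glint) + 250.0 * glint
    alpha = cov[..., None]
    img[r0:r1, c0:c1] = patch * (1.0 - alpha) + body * alpha
    label[r0:r1, c0:c1][inside] = idx


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a fixed config (incl. seed).

    Returns the 8-bit RGB image and its :class:`GroundTruth`.  Raises
    :class:`PlacementError` if the requested droplets cannot be placed
    without overlap inside the frame after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    img = _background(config, rng)
    img, patch_mask = _add_noise_patches(img, config, rng)
    label = np.zeros((h, w), dtype=np.int32)

    placed: list[tuple[float, float, float]] = []  # (row, col, outer radius)
    lo, hi = config.droplet_diameter_range
    for i in range(1, config.n_droplets + 1):
        for _attempt in range(200):
            diam = rng.uniform(lo, hi)
            aspect = rng.uniform(*config.droplet_aspect_range)
            ra = 0.5 * diam * np.sqrt(aspect)
            rb = 0.5 * diam / np.sqrt(aspect)
            r_out = max(ra, rb) + 2.0
            r_lim = r_out + config.border_margin_px
            cr = rng.uniform(r_lim, h - r_lim) if h > 2 * r_lim else None
            cc = rng.uniform(r_lim, w - r_lim) if w > 2 * r_lim else None
            if cr is None or cc is None:
                continue
            if all(
                np.hypot(cr - pr, cc - pc) > r_out + pr_out + 2.0
                for pr, pc, pr_out in placed
            ):
                theta = rng.uniform(0, np.pi)
                _render_droplet(
                    img, label, i, (cr, cc), (ra, rb), theta,
                    config.specular_highlight, rng,
                )
                placed.append((cr, cc, r_out))
                break
        else:
            raise PlacementError(
                f"could not place droplet {i}/{config.n_droplets} in a "
                f"{w}x{h} frame after 200 attempts"
            )

    counts = np.bincount(label.ravel(), minlength=config.n_droplets + 1)
    per_area = [int(counts[i]) for i in range(1, config.n_droplets + 1)]
    edge = edge_mask_from_labels(label)
    consensus = simulate_annotators(
        edge,
        config.annotators_k,
        config.annotator_jitter_px,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    image8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        droplet_label_map=label,
        per_droplet_area=per_area,
        consensus_edges=consensus,
        true_edge_mask=edge,
        noise_patch_mask=patch_mask,
    )
    return image8, gt


def simulate_annotators(
    true_edge_mask: np.ndarray, k: int, jitter_px: int, seed: int | None = None
) -> np.ndarray:
    """Consensus edge probability map from k jittered annotators.

    Each synthetic annotator redraws the true contour with a smooth random
    displacement of at most ``jitter_px`` (Euclidean) per pixel; the
    consensus is the per-pixel mean of the k binary maps, so values lie in
    {0, 1/k, ..., 1} and are nonzero only within ``jitter_px`` of the truth.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = (np.asarray(true_edge_mask) > 0).astype(np.uint8)
    if jitter_px == 0:
        return mask.astype(np.float64)
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    coords = np.argwhere(mask)
    acc = np.zeros((h, w), dtype=np.float64)
    for _ in range(k):
        # smooth vector displacement field, clipped to the jitter disk
        field_r = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), 4.0)
        field_c = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), 4.0)
        scale = jitter_px / (np.sqrt(field_r**2 + field_c**2).max() + 1e-12)
        off_r = field_r[coords[:, 0], coords[:, 1]] * scale
        off_c = field_c[coords[:, 0], coords[:, 1]] * scale
        ir = np.round(off_r).astype(int)
        ic = np.round(off_c).astype(int)
        # rounding may escape the jitter disk; shrink the larger component
        over = ir**2 + ic**2 > jitter_px**2
        bigger_r = np.abs(ir) >= np.abs(ic)
        ir = np.where(over & bigger_r, ir - np.sign(ir), ir)
        ic = np.where(over & ~bigger_r, ic - np.sign(ic), ic)
        rr = np.clip(coords[:, 0] + ir, 0, h - 1)
        cc = np.clip(coords[:, 1] + ic, 0, w - 1)
        annot = np.zeros((h, w), dtype=np.float64)
        annot[rr, cc] = 1.0
        acc += annot
    return acc / k


def _recount(label: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Relabel consecutively and recount areas after a geometric transform."""
    ids = np.unique(label)
    ids = ids[ids > 0]
    out = np.zeros_like(label)
    areas = []
    for new, old in enumerate(ids, start=1):
        sel = label == old
        out[sel] = new
        areas.append(int(sel.sum()))
    return out, areas


def augment(
    image: np.ndarray,
    gt: GroundTruth,
    op: str,
    params: dict,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Geometric augmentation (crop / rotate / scale) applied consistently.

    The label map and consensus map undergo the same transform as the image
    (nearest-neighbour, so label ids and consensus levels are preserved);
    per-droplet areas are recounted from the transformed label map.  Raises
    :class:`TransformError` if no droplet survives.
    """
    if op == "crop":
        r0, c0 = int(params["row"]), int(params["col"])
        ch, cw = int(params["height"]), int(params["width"])
        if ch < 1 or cw < 1:
            raise TransformError("empty crop window")
        sl = (slice(r0, r0 + ch), slice(c0, c0 + cw))
        new_img = image[sl].copy()
        new_label = gt.droplet_label_map[sl].copy()
        new_cons = gt.consensus_edges[sl].copy()
        new_edge = gt.true_edge_mask[sl].copy()
    elif op == "rotate":
        angle = float(params["angle"])
        if angle % 360.0 == 0.0:
            new_img = image.copy()
            new_label = gt.droplet_label_map.copy()
            new_cons = gt.consensus_edges.copy()
            new_edge = gt.true_edge_mask.copy()
        else:
            new_img = ndimage.rotate(image, angle, reshape=True, order=1)
            new_img = np.clip(np.round(new_img), 0, 255).astype(image.dtype)
            new_label = ndimage.rotate(
                gt.droplet_label_map, angle, reshape=True, order=0
            )
            new_cons = ndimage.rotate(gt.consensus_edges, angle, reshape=True, order=0)
            new_edge = ndimage.rotate(gt.true_edge_mask, angle, reshape=True, order=0)
    elif op == "scale":
        factor = float(params["factor"])
        if factor <= 0:
            raise TransformError("scale factor must be positive")
        new_img = ndimage.zoom(image, (factor, factor, 1), order=1)
        new_img = np.clip(np.round(new_img), 0, 255).astype(image.dtype)
        new_label = ndimage.zoom(gt.droplet_label_map, factor, order=0)
        new_cons = ndimage.zoom(gt.consensus_edges, factor, order=0)
        new_edge = ndimage.zoom(gt.true_edge_mask, factor, order=0)
    else:
        raise ValueError(f"unknown augmentation op {op!r}")

    new_label, areas = _recount(new_label)
    if not areas:
        raise TransformError(f"augmentation {op!r} left no droplet in frame")
    new_gt = GroundTruth(
        droplet_label_map=new_label,
        per_droplet_area=areas,
        consensus_edges=new_cons,
        true_edge_mask=new_edge,
    )
    return new_img, new_gt


def _labelme_record(
    label_map: np.ndarray, image_name: str
) -> dict:
    """Labelme-style annotation: one polygon per droplet, (x, y) points."""
    shapes = []
    for rid in np.unique(label_map):
        if rid == 0:
            continue
        region = (label_map == rid).astype(np.float64)
        contours = measure.find_contours(region, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        points = [[float(c), float(r)] for r, c in contour]
        shapes.append(
            {"label": "droplet", "points": points, "shape_type": "polygon"}
        )
    return {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_name,
        "imageHeight": int(label_map.shape[0]),
        "imageWidth": int(label_map.shape[1]),
    }


def write_dataset(
    directory: str | Path, n_scenes: int, config: SceneConfig
) -> dict:
    """Render and export ``n_scenes`` scenes; scene i uses seed config.seed + i.

    Per scene: 8-bit RGB PNG, 16-bit label-map PNG, float consensus map as
    .npy plus an 8-bit PNG preview (scale factor recorded in the manifest),
    and a Labelme-style polygon JSON.  Returns the manifest (also written
    as ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_scenes):
        cfg_i = replace(config, seed=config.seed + i)
        image, gt = generate_scene(cfg_i)
        stem = f"scene_{i:03d}"
        iio.imwrite(directory / f"{stem}.png", image)
        iio.imwrite(
            directory / f"{stem}_labels.png",
            gt.droplet_label_map.astype(np.uint16),
        )
        np.save(directory / f"{stem}_consensus.npy", gt.consensus_edges)
        preview_scale = 255.0
        iio.imwrite(
            directory / f"{stem}_consensus.png",
            np.round(gt.consensus_edges * preview_scale).astype(np.uint8),
        )
        record = _labelme_record(gt.droplet_label_map, f"{stem}.png")
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump(record, fh)
        entries.append(
            {
                "image": f"{stem}.png",
                "labels": f"{stem}_labels.png",
                "consensus": f"{stem}_consensus.npy",
                "consensus_preview": f"{stem}_consensus.png",
                "consensus_preview_scale": preview_scale,
                "annotation": f"{stem}.json",
                "seed": cfg_i.seed,
                "per_droplet_area": gt.per_droplet_area,
            }
        )
    manifest = {"n_scenes": n_scenes, "scenes": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
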