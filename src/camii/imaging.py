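"""Plate-image colony segmentation and morphology quantification.

Plates are imaged twice: transillumination (light from below; colonies appear
as bright blobs over a dark agar background, carrying density information) and
epi-illumination (light from above; an RGB image carrying surface colour and
texture). Segmentation runs on the trans image; the epi image contributes the
RGB intensity statistics of each colony's interior.

Every colony is summarised by 14 morphological features:

========  =====================================================
feature   definition
========  =====================================================
area      interior pixel count (px^2)
perimeter boundary length (weighted pixel-edge estimator, px)
mean radius  mean centroid-to-boundary distance (px)
circularity  4*pi*area / perimeter^2
convexity    area / convex-hull area
inertia      lambda_min / lambda_max of the second-central-moment matrix
gray mean/var   trans-image intensity over the interior
r/g/b mean/var  epi-image channel intensities over the interior
========  =====================================================

Coordinates are 0-based pixels, x = column, y = row, origin at the top-left
corner; all distances are in pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours, label as sk_label, regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: canonical order of the 14 morphology features in tables and models
MORPHOLOGY_FEATURES = [
    "area_px2",
    "perimeter_px",
    "mean_radius_px",
    "circularity",
    "convexity",
    "inertia",
    "gray_mean",
    "gray_var",
    "r_mean",
    "r_var",
    "g_mean",
    "g_var",
    "b_mean",
    "b_var",
]

#: fixed column order of colony tables on disk
COLONY_TABLE_COLUMNS = [
    "colony_id",
    "plate_barcode",
    "x_px",
    "y_px",
    "radius_px",
    "day",
] + MORPHOLOGY_FEATURES


@dataclass
class PlateImagePair:
    """Paired trans-/epi-illuminated images of one barcoded plate."""

    plate_barcode: str
    trans: np.ndarray  # (H, W) uint8 grayscale
    epi: np.ndarray  # (H, W, 3) uint8 RGB
    capture_day: int = 0

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans)
        self.epi = np.asarray(self.epi)
        if self.trans.ndim != 2:
            raise ValueError("trans image must be 2-D grayscale")
        if self.epi.ndim != 3 or self.epi.shape[2] != 3:
            raise ValueError("epi image must be H x W x 3 RGB")
        if self.trans.shape != self.epi.shape[:2]:
            raise ValueError(
                f"trans {self.trans.shape} and epi {self.epi.shape[:2]} "
                "pixel dimensions differ"
            )
        if self.capture_day < 0:
            raise ValueError("capture_day must be >= 0")


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation recipe.

    Background is estimated by a median filter on a downsampled copy of the
    trans image (window ``background_window_px`` at full resolution), then
    subtracted. Pixels above ``threshold_offset`` (or an automatic multiple
    of the estimated noise) form candidate blobs; touching blobs are split by
    a marker watershed; each blob is refined at half its peak intensity; the
    survivors pass area/circularity gates and the rim-exclusion margin.
    """

    background_window_px: int = 64
    background_downsample: int = 4
    threshold_offset: float | None = None  # None -> max(8, 5 * noise sigma)
    min_area_px2: float = 20.0
    max_area_px2: float = 50_000.0
    min_circularity: float = 0.2
    rim_margin_px: int = 10
    split_touching: bool = True

    def __post_init__(self) -> None:
        if not self.min_area_px2 < self.max_area_px2:
            raise ValueError("min_area_px2 must be < max_area_px2")
        if self.background_downsample < 1:
            raise ValueError("background_downsample must be >= 1")


@dataclass
class MorphologyVector:
    area_px2: float
    perimeter_px: float
    mean_radius_px: float
    circularity: float
    convexity: float
    inertia: float
    gray_mean: float
    gray_var: float
    r_mean: float
    r_var: float
    g_mean: float
    g_var: float
    b_mean: float
    b_var: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in MORPHOLOGY_FEATURES], dtype=float)

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("morphology vector contains non-finite values")


@dataclass
class ColonyRecord:
    colony_id: str
    plate_barcode: str
    x_px: float
    y_px: float
    radius_px: float
    contour: np.ndarray  # (n, 2) array of (y, x) boundary points, closed
    features: MorphologyVector
    day: int = 0
    label: str | None = None


# ---------------------------------------------------------------------------
# morphology feature extraction
# ---------------------------------------------------------------------------


def _hull_lattice_area(coords: np.ndarray) -> float:
    """Number of integer pixel centers inside the convex hull of ``coords``.

    Counting lattice points (rather than taking the hull polygon area, which
    systematically undercounts by half the hull perimeter) makes
    convexity == 1 for any digitally convex region such as a rasterized disk.
    """
    pts = coords.astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # collinear / degenerate
        raise ValueError("degenerate (collinear) region; convex hull undefined") from exc
    y0, x0 = np.floor(pts.min(axis=0)).astype(int)
    y1, x1 = np.ceil(pts.max(axis=0)).astype(int)
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    # half-plane test: A @ p + b <= 0 for interior points
    inside = np.ones(len(grid), dtype=bool)
    for eq in hull.equations:
        inside &= grid @ eq[:2] + eq[2] <= 1e-9
    return float(inside.sum())


def _shoelace(contour: np.ndarray) -> float:
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _arc_length(contour: np.ndarray) -> float:
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _morphology_from_mask(
    mask: np.ndarray,
    offset_yx: tuple[int, int],
    trans: np.ndarray,
    epi: np.ndarray,
    surface: np.ndarray | None = None,
    level: float | None = None,
) -> tuple[MorphologyVector, np.ndarray, tuple[float, float], float]:
    """Features of a single connected region.

    ``mask`` is a boolean crop located at ``offset_yx`` (row, col) in the full
    images. When an intensity ``surface`` and threshold ``level`` are given
    (the segmentation path), the boundary is the sub-pixel iso-contour of the
    surface at that level, and area/perimeter are the polygon area and arc
    length of that contour — free of pixel-lattice quantization. Otherwise
    the binary mask boundary is used with pixel-count area and the weighted
    pixel-edge perimeter. Returns (features, contour in full-image coords,
    (x, y) centroid, mean radius).
    """
    if mask.sum() < 3:
        raise ValueError("region too small for morphology extraction")
    props = regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid

    contour = None
    if surface is not None and level is not None:
        # interpolate across the true intensity step at the boundary, but
        # blank everything beyond the first outside ring so a nearby colony
        # cannot contribute its own iso-contour
        ring = ndi.binary_dilation(mask, iterations=1)
        vals = np.where(ring, surface, 0.0)
        for cand in find_contours(np.pad(vals, 1), level):
            cand = cand - 1.0
            if _shoelace(cand) < 1.0:
                continue
            ys = np.clip(np.round(cand[:, 0]).astype(int), 0, mask.shape[0] - 1)
            xs = np.clip(np.round(cand[:, 1]).astype(int), 0, mask.shape[1] - 1)
            if ring[ys, xs].mean() > 0.9 and (
                min(cand[:, 0]) <= cy <= max(cand[:, 0])
            ):
                contour = cand
                break
    if contour is not None:
        area = _shoelace(contour)
        perimeter = _arc_length(contour)
    else:
        area = float(props.area)
        perimeter = float(props.perimeter)
        padded = np.pad(mask.astype(float), 1)
        contour = max(find_contours(padded, 0.5), key=len) - 1.0  # undo padding
    if perimeter <= 0:
        raise ValueError("degenerate region with zero perimeter")
    dists = np.hypot(contour[:, 0] - cy, contour[:, 1] - cx)
    mean_radius = float(dists.mean())

    coords = np.column_stack(np.nonzero(mask))
    convexity = area / _hull_lattice_area(coords)
    circularity = 4.0 * np.pi * area / perimeter**2
    ev = props.inertia_tensor_eigvals  # descending
    inertia = float(ev[1] / ev[0]) if ev[0] > 0 else 1.0

    oy, ox = offset_yx
    ys, xs = np.nonzero(mask)
    ys_full, xs_full = ys + oy, xs + ox
    gray = trans[ys_full, xs_full].astype(float)
    rgb = epi[ys_full, xs_full].astype(float)

    vec = MorphologyVector(
        area_px2=area,
        perimeter_px=perimeter,
        mean_radius_px=mean_radius,
        circularity=float(circularity),
        convexity=float(convexity),
        inertia=inertia,
        gray_mean=float(gray.mean()),
        gray_var=float(gray.var()),
        r_mean=float(rgb[:, 0].mean()),
        r_var=float(rgb[:, 0].var()),
        g_mean=float(rgb[:, 1].mean()),
        g_var=float(rgb[:, 1].var()),
        b_mean=float(rgb[:, 2].mean()),
        b_var=float(rgb[:, 2].var()),
    )
    contour_full = contour + np.array([oy, ox], dtype=float)
    return vec, contour_full, (cx + ox, cy + oy), mean_radius


def extract_morphology(
    contour: np.ndarray, trans: np.ndarray, epi: np.ndarray
) -> MorphologyVector:
    """Compute the 14-feature morphology vector for a closed boundary.

    ``contour`` is an (n, 2) array of (y, x) boundary points; its interior is
    rasterized and features are measured over the interior pixels of ``trans``
    (gray statistics) and ``epi`` (RGB statistics).
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise ValueError("contour must be an (n>=3, 2) array of (y, x) points")
    rr, cc = draw_polygon(contour[:, 0], contour[:, 1], shape=trans.shape)
    if rr.size < 3:
        raise ValueError("degenerate (collinear) contour encloses no pixels")
    mask = np.zeros(trans.shape, dtype=bool)
    mask[rr, cc] = True
    vec, _, _, _ = _morphology_from_mask(mask, (0, 0), trans, epi)
    return vec


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _estimate_background(trans: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    ds = cfg.background_downsample
    small = trans[::ds, ::ds].astype(float)
    win = max(3, cfg.background_window_px // ds)
    win += 1 - win % 2  # odd
    bg_small = ndi.median_filter(small, size=win, mode="nearest")
    bg = ndi.zoom(bg_small, (trans.shape[0] / bg_small.shape[0], trans.shape[1] / bg_small.shape[1]), order=1)
    return bg[: trans.shape[0], : trans.shape[1]]


def segment_colonies(
    pair: PlateImagePair, cfg: SegmentationConfig | None = None
) -> list[ColonyRecord]:
    """Segment colonies on a plate and fill their morphology vectors.

    Returns records sorted by (y, x). A plate with no colonies yields an
    empty list. Colonies whose pixels reach into the rim-exclusion margin are
    dropped, as are blobs failing the area or circularity gates.
    """
    cfg = cfg or SegmentationConfig()
    trans = pair.trans.astype(float)
    bg = _estimate_background(pair.trans, cfg)
    sub = np.clip(trans - bg, 0.0, None)

    if cfg.threshold_offset is not None:
        thr = float(cfg.threshold_offset)
    else:
        med = np.median(sub)
        sigma = 1.4826 * np.median(np.abs(sub - med))
        thr = max(8.0, 5.0 * sigma)

    mask = sub > thr
    coarse = sk_label(mask)
    records: list[ColonyRecord] = []
    h, w = trans.shape
    m = cfg.rim_margin_px

    smooth = ndi.gaussian_filter(sub, 1.0)
    for prop in regionprops(coarse):
        if prop.area < max(3.0, cfg.min_area_px2 / 4.0):
            continue
        y0, x0, y1, x1 = prop.bbox
        crop_mask = coarse[y0:y1, x0:x1] == prop.label
        crop_sub = sub[y0:y1, x0:x1]

        sub_labels, levels = _refine_component(crop_mask, crop_sub, smooth[y0:y1, x0:x1], cfg)
        for lbl in range(1, sub_labels.max() + 1):
            blob = sub_labels == lbl
            if blob.sum() < 3:
                continue
            try:
                vec, contour, (cx, cy), mean_r = _morphology_from_mask(
                    blob, (y0, x0), pair.trans, pair.epi,
                    surface=crop_sub, level=levels.get(lbl),
                )
            except ValueError:
                continue
            if not (cfg.min_area_px2 <= vec.area_px2 <= cfg.max_area_px2):
                continue
            if vec.circularity < cfg.min_circularity:
                continue
            ys, xs = np.nonzero(blob)
            ys_f, xs_f = ys + y0, xs + x0
            if (
                ys_f.min() < m
                or xs_f.min() < m
                or ys_f.max() >= h - m
                or xs_f.max() >= w - m
            ):
                continue  # overlaps rim-exclusion margin
            records.append(
                ColonyRecord(
                    colony_id="",
                    plate_barcode=pair.plate_barcode,
                    x_px=cx,
                    y_px=cy,
                    radius_px=mean_r,
                    contour=contour,
                    features=vec,
                    day=pair.capture_day,
                )
            )

    records.sort(key=lambda r: (r.y_px, r.x_px))
    for i, rec in enumerate(records):
        rec.colony_id = f"{pair.plate_barcode}_c{i:04d}"
    return records


def _refine_component(
    crop_mask: np.ndarray,
    crop_sub: np.ndarray,
    crop_smooth: np.ndarray,
    cfg: SegmentationConfig,
) -> np.ndarray:
    """Split a coarse blob into colonies and re-threshold each at half-peak."""
    dist = ndi.distance_transform_edt(np.pad(crop_mask, 1))[1:-1, 1:-1]
    maxd = dist.max()
    markers = None
    if cfg.split_touching and maxd >= 3:
        # h-maxima on the distance transform: one marker per convex lobe,
        # insensitive to plateau/ridge noise inside a single colony
        from skimage.morphology import h_maxima

        seeds = h_maxima(dist, 0.3 * maxd)
        markers, n_seeds = ndi.label(seeds, structure=np.ones((3, 3), dtype=int))
        if n_seeds <= 1:
            markers = None
    if markers is None:
        regions = crop_mask.astype(np.int32)
    else:
        regions = watershed(-dist, markers, mask=crop_mask)

    out = np.zeros(crop_mask.shape, dtype=np.int32)
    levels: dict[int, float] = {}
    nxt = 1
    for lbl in range(1, regions.max() + 1):
        region = regions == lbl
        if not region.any():
            continue
        # robust plateau estimate: the raw maximum rides on noise and would
        # bias the half-height boundary inward
        peak = float(np.percentile(crop_sub[region], 90))
        refined = region & (crop_sub >= 0.5 * peak)
        # keep the connected piece containing the peak
        relab = sk_label(refined)
        if relab.max() == 0:
            continue
        py, px = np.unravel_index(np.argmax(np.where(region, crop_sub, -1)), region.shape)
        keep = relab[py, px]
        if keep == 0:
            keep = np.argmax(np.bincount(relab[relab > 0]))
        piece = ndi.binary_fill_holes(relab == keep)
        out[piece] = nxt
        levels[nxt] = 0.5 * peak
        nxt += 1
    return out, levels


# ---------------------------------------------------------------------------
# colony table I/O
# ---------------------------------------------------------------------------


def records_to_table(records: list[ColonyRecord]) -> pd.DataFrame:
    """Flatten colony records into the canonical colony table."""
    rows = []
    for r in records:
        row = {
            "colony_id": r.colony_id,
            "plate_barcode": r.plate_barcode,
            "x_px": r.x_px,
            "y_px": r.y_px,
            "radius_px": r.radius_px,
            "day": r.day,
        }
        row.update(dict(zip(MORPHOLOGY_FEATURES, r.features.as_array())))
        rows.append(row)
    return pd.DataFrame(rows, columns=COLONY_TABLE_COLUMNS)


def write_colony_table(records: list[ColonyRecord] | pd.DataFrame, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_table(records)
    df.to_csv(path, sep="\t", index=False)


def read_colony_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
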