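"""Detection-zone segmentation and per-zone colour measurement.

Mirrors the smartphone app's processing chain: divide the image into
detection zones, threshold, mask, and measure the mean colour intensity of
each zone in RGB, grayscale and HSV.

Segmentation strategy
---------------------
Coloured reaction products on white filter paper separate most strongly in
the *saturation* channel, so the zone mask is obtained by Otsu thresholding
of saturation (foreground strictly above the level), followed by
connected-component labelling, an area/circularity filter that rejects flow
channels and smears, reading-order ID assignment, and a 10 % equivalent-radius
erosion that excludes coffee-ring edge artefacts before any measurement.
If the image is essentially achromatic (max saturation < 5 %), inverted
grayscale is thresholded instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.measure import regionprops

from . import color
from .errors import DegenerateInputError, InputDomainError, SegmentationError

logger = logging.getLogger(__name__)

#: fraction of the equivalent radius eroded from each mask before measurement
EROSION_FRACTION = 0.10
#: minimum isoperimetric circularity 4πA/P² for a surviving component
MIN_CIRCULARITY = 0.6
#: components smaller than this fraction of the median component area are dropped
MIN_AREA_FRACTION = 0.25
#: below this maximum saturation (%) the image is treated as achromatic
ACHROMATIC_SAT_LIMIT = 5.0

CSV_COLUMNS = [
    "zone_id", "area", "centroid_row", "centroid_col",
    "mean_r", "mean_g", "mean_b", "mean_gray", "mean_h", "mean_s", "mean_v",
]


@dataclass
class ZoneMask:
    """Pixel membership of one detection zone.

    Coordinates are 0-based (row, col) with pixel centres at integers.
    """

    zone_id: int
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.size == 0 or self.rows.shape != self.cols.shape:
            raise InputDomainError("zone mask must contain at least one pixel")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def to_boolean(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class ZoneMeasurement:
    """Mask statistics of one zone: arithmetic channel means, circular hue mean."""

    zone_id: int
    area: int
    centroid: tuple[float, float]
    mean_r: float
    mean_g: float
    mean_b: float
    mean_gray: float
    mean_h: float
    mean_s: float
    mean_v: float

    def channel_value(self, channel: str) -> float:
        key = {"R": "mean_r", "G": "mean_g", "B": "mean_b", "gray": "mean_gray",
               "H": "mean_h", "S": "mean_s", "V": "mean_v"}[channel]
        return getattr(self, key)


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB PNG/TIFF as an (H, W, 3) uint8 array.

    An alpha channel, if present, is discarded with a logged warning.
    """
    with Image.open(path) as im:
        if im.mode == "RGBA":
            logger.warning("image %s has an alpha channel; ignoring it", path)
            im = im.convert("RGB")
        elif im.mode != "RGB":
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputDomainError(f"{path}: not an 8-bit RGB image")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 array as PNG/TIFF (by extension)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def threshold_otsu(histogram) -> int:
    """Otsu's threshold on a 256-bin 8-bit intensity histogram.

    Returns the level maximising the between-class variance, with foreground
    defined as *strictly above* the level.  Ties are broken towards the
    smallest maximising level so the result is deterministic.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256 or np.any(hist < 0):
        raise InputDomainError("expected a nonnegative histogram over 256 bins")
    total = hist.sum()
    occupied = np.count_nonzero(hist)
    if total < 2 or occupied < 2:
        raise DegenerateInputError(
            "histogram must contain ≥2 samples in ≥2 distinct bins"
        )
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    w1 = total - w0
    m0 = np.cumsum(hist * levels)
    m_total = m0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (m_total - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between))  # argmax returns the first (smallest) maximiser


def _threshold_channel(image: np.ndarray) -> np.ndarray:
    """8-bit channel used for zone thresholding: saturation, or inverted gray."""
    _, s, _ = color.rgb_to_hsv_array(image)
    if s.max() >= ACHROMATIC_SAT_LIMIT:
        chan = s * 2.55  # saturation % → 8-bit scale
    else:
        logger.info("image nearly achromatic; thresholding inverted grayscale")
        chan = 255.0 - color.rgb_to_gray_array(image)
    return np.clip(np.rint(chan), 0, 255).astype(np.uint8)


def _label_and_filter(chan: np.ndarray, level: int):
    """Label pixels strictly above ``level`` and apply area/circularity filters."""
    fg = chan > level
    labels, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        return labels, []
    props = regionprops(labels)
    median_area = float(np.median([p.area for p in props]))
    keep = []
    for p in props:
        if p.area < MIN_AREA_FRACTION * median_area:
            continue
        perim = p.perimeter
        circ = 4.0 * np.pi * p.area / perim**2 if perim > 0 else 0.0
        if circ < MIN_CIRCULARITY:
            continue
        keep.append(p)
    return labels, keep


def _otsu_of_lower_class(hist: np.ndarray, level: int) -> int | None:
    """Otsu threshold of the sub-histogram at or below ``level`` (None if degenerate)."""
    if level <= 0:
        return None
    sub = np.zeros(256, dtype=float)
    sub[: level + 1] = hist[: level + 1]
    try:
        lower = threshold_otsu(sub)
    except DegenerateInputError:
        return None
    return lower if lower < level else None


def _erode_component(mask: np.ndarray, margin: float) -> np.ndarray:
    if margin < 0.5:
        return mask
    edt = ndimage.distance_transform_edt(mask)
    eroded = edt > margin
    return eroded if eroded.any() else mask


def _reading_order(centroids: list[tuple[float, float]], row_tol: float) -> list[int]:
    """Indices sorted top-to-bottom then left-to-right, grouping rows by tolerance."""
    order = sorted(range(len(centroids)), key=lambda i: centroids[i][0])
    groups: list[list[int]] = []
    for i in order:
        if groups and abs(centroids[i][0] - centroids[groups[-1][0]][0]) <= row_tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    out: list[int] = []
    for grp in groups:
        out.extend(sorted(grp, key=lambda i: centroids[i][1]))
    return out


def segment_zones(image: np.ndarray, n_zones: int = 4, layout=None) -> list[ZoneMask]:
    """Segment the detection zones of a μPAD image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
    n_zones : expected number of zones (the standard device carries four
        3 mm zones)
    layout : optional iterable of expected (row, col) centres; when given,
        surviving components are matched to the nearest expected centre
        instead of relying purely on count.

    Returns exactly ``n_zones`` masks in reading order (top-to-bottom, then
    left-to-right by centroid), each eroded by 10 % of its equivalent radius.
    Raises :class:`SegmentationError` carrying the number of surviving
    components when fewer than ``n_zones`` are found.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputDomainError("expected an (H, W, 3) RGB image array")
    if n_zones < 1:
        raise InputDomainError("n_zones must be ≥ 1")

    chan = _threshold_channel(img)
    hist = np.bincount(chan.ravel(), minlength=256)
    try:
        level = threshold_otsu(hist)
    except DegenerateInputError:
        raise SegmentationError(0, n_zones, "image is constant; no zones found")

    # Zones at different analyte levels have different saturations, and one
    # global Otsu level can then split faint zones from strong zones instead
    # of paper from zones.  Apply Otsu hierarchically: while too few
    # components survive, re-threshold the lower class to admit fainter zones.
    labels, keep = _label_and_filter(chan, level)
    while len(keep) < n_zones:
        lower = _otsu_of_lower_class(hist, level)
        if lower is None:
            break
        level = lower
        labels, keep = _label_and_filter(chan, level)

    if len(keep) < n_zones:
        raise SegmentationError(len(keep), n_zones)
    if len(keep) > n_zones:
        if layout is not None:
            centres = np.asarray(list(layout), dtype=float)
            chosen, used = [], set()
            for c in centres:
                d = [np.hypot(p.centroid[0] - c[0], p.centroid[1] - c[1])
                     if i not in used else np.inf for i, p in enumerate(keep)]
                j = int(np.argmin(d))
                used.add(j)
                chosen.append(keep[j])
            keep = chosen
        else:
            keep = sorted(keep, key=lambda p: -p.area)[:n_zones]

    # reading-order ids with a row tolerance of half the median zone diameter
    diam = np.median([2.0 * np.sqrt(p.area / np.pi) for p in keep])
    centroids = [p.centroid for p in keep]
    order = _reading_order(centroids, row_tol=0.5 * diam)

    masks: list[ZoneMask] = []
    for zone_id, idx in enumerate(order, start=1):
        p = keep[idx]
        comp = labels == p.label
        margin = EROSION_FRACTION * np.sqrt(p.area / np.pi)
        eroded = _erode_component(comp, margin)
        rows, cols = np.nonzero(eroded)
        masks.append(ZoneMask(zone_id=zone_id, rows=rows, cols=cols))
    return masks


def measure_zone(image: np.ndarray, mask: ZoneMask) -> ZoneMeasurement:
    """Mean channel intensities of one zone; hue averaged circularly."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputDomainError("expected an (H, W, 3) RGB image array")
    h_img, w_img = img.shape[:2]
    if (np.any(mask.rows < 0) or np.any(mask.rows >= h_img)
            or np.any(mask.cols < 0) or np.any(mask.cols >= w_img)):
        raise InputDomainError("mask extends outside the image")
    px = img[mask.rows, mask.cols].astype(float)
    h, s, v = color.rgb_to_hsv_array(px)
    gray = color.rgb_to_gray_array(px)
    return ZoneMeasurement(
        zone_id=mask.zone_id,
        area=mask.area,
        centroid=mask.centroid,
        mean_r=float(px[:, 0].mean()),
        mean_g=float(px[:, 1].mean()),
        mean_b=float(px[:, 2].mean()),
        mean_gray=float(gray.mean()),
        mean_h=color.circular_mean_hue(h),
        mean_s=float(s.mean()),
        mean_v=float(v.mean()),
    )


def measure_image(image: np.ndarray, n_zones: int = 4, layout=None) -> list[ZoneMeasurement]:
    """segment_zones followed by measure_zone for each mask."""
    return [measure_zone(image, m) for m in segment_zones(image, n_zones, layout)]


def measurements_to_frame(measurements: list[ZoneMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "zone_id": m.zone_id, "area": m.area,
            "centroid_row": m.centroid[0], "centroid_col": m.centroid[1],
            "mean_r": m.mean_r, "mean_g": m.mean_g, "mean_b": m.mean_b,
            "mean_gray": m.mean_gray, "mean_h": m.mean_h,
            "mean_s": m.mean_s, "mean_v": m.mean_v,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_measurements_csv(measurements: list[ZoneMeasurement], path) -> None:
    """Write zone measurements as CSV, floats to 4 decimal places."""
    df = measurements_to_frame(measurements)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.4f")
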