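"""White-blood-cell segmentation from stained smear images.

The pipeline extracts three nested binary masks per leukocyte — whole cell,
nucleus, cytoplasm — from an RGB microscopy image:

1. convert RGB to the yellow (Y) channel of the naive CMYK transform, where
   basophilic cells are dark against the yellowish smear background;
2. enhance contrast by combining a linear stretch with histogram
   equalization, then suppress bright clutter with repeated 3x3 minimum
   filtering;
3. Otsu-threshold the enhanced image to obtain the cell mask and clean it
   with opening, closing and hole filling;
4. inside the cell mask, take the a* channel of CIELAB (nuclei are strongly
   magenta), blur heavily, renormalize and Otsu-threshold again to obtain
   the nucleus mask, followed by morphological cleanup and an area filter;
5. split touching cells with a marker-controlled watershed on the gradient
   of the distance transform;
6. subtract the nucleus mask from each cell mask to obtain the cytoplasm.

All geometry is 0-based, row-major; bounding boxes are half-open.  Images
are 8-bit per channel.  Absolute parameters (structuring-element radii, the
nucleus blur sigma) are expressed at the reference pixel pitch of a x1000
smear photograph (2592x3872 px full frame) and can be rescaled with
``SegmentationConfig.scale`` for other optical configurations; crops at the
reference pitch use scale 1.0 regardless of their width.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage import morphology
from skimage.color import rgb2lab
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidImageError",
    "ConstantImageError",
    "EmptyNucleusError",
    "SegmentationConfig",
    "CellRecord",
    "rgb_to_cmyk_y",
    "enhance_contrast",
    "min_filter_3x3",
    "otsu_threshold",
    "otsu_mask",
    "clean_cell_mask",
    "extract_nucleus_mask",
    "split_touching_cells",
    "make_cell_records",
    "segment_image",
    "segmentation_summary",
]


class InvalidImageError(ValueError):
    """Raised for inputs that are not valid 8-bit RGB / grayscale rasters."""


class ConstantImageError(ValueError):
    """Raised when a threshold is requested on a constant image."""


class EmptyNucleusError(ValueError):
    """Raised when no nucleus component survives cleanup for a cell."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    Lengths are pixels at the reference pitch; ``scale`` multiplies every
    length (and sigma) linearly for images acquired at a different pitch.
    """

    ei_mode: str = "mean"  # {"mean", "sum-clipped", "l-only", "h-only"}
    min_filter_repeats: int = 3
    cell_polarity: str = "dark"  # leukocytes are dark in min-filtered EI
    open_radius: float = 5.0
    close_radius: float = 10.0
    nucleus_sigma: float = 33.0
    nucleus_close_diameter: float = 10.0
    nucleus_open_diameter: float = 2.0
    nucleus_polarity: str = "bright"  # nuclei are magenta: high a*
    nucleus_area_fraction: float = 0.25
    watershed_h: float = 5.0
    scale: float = 1.0

    def scaled(self, factor: float) -> "SegmentationConfig":
        return replace(self, scale=self.scale * factor)

    @property
    def _s(self) -> float:
        return self.scale


@dataclass
class CellRecord:
    """One segmented cell: nested cell / nucleus / cytoplasm masks.

    Masks are full-frame booleans sharing the source geometry, with
    ``cytoplasm_mask == cell_mask & ~nucleus_mask`` pixel-exact.  ``bbox``
    is ``(rmin, cmin, rmax, cmax)``, half-open.  Records whose nucleus or
    cytoplasm is empty carry a flag and are excluded from classification.
    """

    cell_id: int
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    bbox: tuple[int, int, int, int]
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def classifiable(self) -> bool:
        return "empty-nucleus" not in self.flags


# --------------------------------------------------------------------------
# validation helpers
# --------------------------------------------------------------------------


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidImageError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise InvalidImageError("image smaller than 32x32 px")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise InvalidImageError("expected 8-bit channel intensities in [0, 255]")
    return img


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise InvalidImageError(f"expected HxW grayscale image, got shape {img.shape}")
    return img


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidImageError(f"expected HxW binary mask, got shape {mask.shape}")
    return mask.astype(bool)


# --------------------------------------------------------------------------
# cell-mask stages
# --------------------------------------------------------------------------


def rgb_to_cmyk_y(img: np.ndarray) -> np.ndarray:
    """Yellow channel of the naive CMYK transform, in [0, 1].

    With K = 1 - max(R, G, B)/255, Y = (1 - B/255 - K)/(1 - K), which
    simplifies to 1 - B/max(R, G, B).  Pure black (K = 1) maps to 0.
    """
    img = _check_rgb(img).astype(float) / 255.0
    mx = img.max(axis=2)
    b = img[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        y = 1.0 - b / mx
    y[mx == 0] = 0.0
    return np.clip(y, 0.0, 1.0)


def _linear_stretch(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


def _equalize(img: np.ndarray) -> np.ndarray:
    # exact empirical-cdf equalization: each pixel maps to the fraction of
    # pixels with value <= its own
    flat = img.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    # pixels with equal value share the highest rank among them
    sorted_vals = flat[order]
    # cdf value for v = count(<= v) / n
    right = np.searchsorted(sorted_vals, flat, side="right")
    return (right / flat.size).reshape(img.shape)


def enhance_contrast(y: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Combine linear stretching (L) and histogram equalization (H).

    The default combination is the arithmetic mean of L and H rescaled to
    the full [0, 1] range; alternatives: ``sum-clipped``, ``l-only``,
    ``h-only``.  A constant image is returned unchanged with a warning
    (the stretch is undefined).
    """
    y = _check_gray(y)
    if y.max() == y.min():
        warnings.warn("constant image: contrast enhancement is a no-op", stacklevel=2)
        return y.copy()
    L = _linear_stretch(y)
    H = _equalize(y)
    if mode == "mean":
        ei = (L + H) / 2.0
    elif mode == "sum-clipped":
        ei = np.clip(L + H, 0.0, 1.0)
    elif mode == "l-only":
        ei = L
    elif mode == "h-only":
        ei = H
    else:
        raise ValueError(f"unknown enhancement mode {mode!r}")
    if ei.max() > ei.min():
        ei = _linear_stretch(ei)
    return ei


def min_filter_3x3(img: np.ndarray, repeats: int = 3) -> np.ndarray:
    """Grayscale 3x3 minimum filter applied ``repeats`` times.

    Border pixels are handled by edge replication, so a constant image is a
    fixed point and isolated bright pixels vanish after one pass.
    """
    img = _check_gray(img)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    out = img
    for _ in range(repeats):
        out = ndi.minimum_filter(out, size=3, mode="nearest")
    return out


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram (maximum between-class
    variance)."""
    img = _check_gray(img)
    if img.max() == img.min():
        raise ConstantImageError("cannot threshold a constant image")
    return float(threshold_otsu(img, nbins=256))


def otsu_mask(img: np.ndarray, polarity: str = "dark") -> np.ndarray:
    """Threshold with Otsu's criterion; ``polarity`` picks the foreground
    side ("dark" keeps pixels <= threshold, "bright" keeps pixels above)."""
    t = otsu_threshold(img)
    img = _check_gray(img)
    if polarity == "dark":
        return img <= t
    if polarity == "bright":
        return img > t
    raise ValueError(f"unknown polarity {polarity!r}")


def _disk(radius: float) -> np.ndarray:
    return morphology.disk(max(1, int(round(radius))))


def clean_cell_mask(mask: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Morphological opening, closing and hole filling of the cell mask.

    Output components have no enclosed background (Euler number 1 each).
    An empty mask is returned unchanged with a warning.
    """
    cfg = cfg or SegmentationConfig()
    mask = _check_mask(mask)
    if not mask.any():
        warnings.warn("empty cell mask passed to clean_cell_mask", stacklevel=2)
        return mask.copy()
    out = ndi.binary_opening(mask, structure=_disk(cfg.open_radius * cfg._s))
    out = ndi.binary_closing(out, structure=_disk(cfg.close_radius * cfg._s))
    out = ndi.binary_fill_holes(out)
    return out


def extract_nucleus_mask(
    img: np.ndarray, cell_mask: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Nucleus mask inside ``cell_mask`` via the blurred a* channel.

    Pipeline: mask the RGB image to the cell region, convert to CIELAB,
    take a*, Gaussian-blur (sigma 33 px at reference pitch), min-max
    normalize within the cell region, Otsu-threshold the within-cell
    pixels, then closing (10 px diameter disk), opening (2 px), hole
    filling and an area filter keeping components at least
    ``nucleus_area_fraction`` of the largest.  The result is a subset of
    ``cell_mask``.
    """
    cfg = cfg or SegmentationConfig()
    img = _check_rgb(img)
    cell_mask = _check_mask(cell_mask)
    if not cell_mask.any():
        raise EmptyNucleusError("cell mask is empty")
    masked = img * cell_mask[..., None].astype(np.uint8)
    a = rgb2lab(masked)[..., 1]
    a = ndi.gaussian_filter(a, sigma=cfg.nucleus_sigma * cfg._s)
    inside = a[cell_mask]
    lo, hi = inside.min(), inside.max()
    if hi == lo:
        raise EmptyNucleusError("a* channel constant within the cell region")
    norm = np.clip((a - lo) / (hi - lo), 0.0, 1.0)
    t = float(threshold_otsu(norm[cell_mask], nbins=256))
    if cfg.nucleus_polarity == "bright":
        nuc = (norm > t) & cell_mask
    else:
        nuc = (norm <= t) & cell_mask
    nuc = ndi.binary_closing(nuc, structure=_disk(cfg.nucleus_close_diameter * cfg._s / 2))
    nuc = ndi.binary_opening(nuc, structure=_disk(cfg.nucleus_open_diameter * cfg._s / 2))
    nuc = ndi.binary_fill_holes(nuc)
    nuc &= cell_mask
    lab = cc_label(nuc, connectivity=2)
    if lab.max() == 0:
        raise EmptyNucleusError("no nucleus component survived cleanup")
    areas = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(areas >= cfg.nucleus_area_fraction * areas.max()) + 1
    return np.isin(lab, keep)


def split_touching_cells(
    cell_mask: np.ndarray, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Marker-controlled watershed separating touching cells.

    Markers are the regional maxima of the Euclidean distance transform
    after h-maxima suppression (h = 5 px default); flooding runs on the
    gradient magnitude of the distance transform, restricted to the
    foreground.  Returns an int label image partitioning the foreground;
    all zeros for an empty mask.
    """
    cfg = cfg or SegmentationConfig()
    cell_mask = _check_mask(cell_mask)
    if not cell_mask.any():
        return np.zeros(cell_mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(cell_mask)
    suppressed = morphology.h_maxima(dist, cfg.watershed_h * cfg._s)
    markers, n = ndi.label(suppressed)
    if n == 0:  # degenerate thin mask: single region
        markers, n = ndi.label(cell_mask)
    grad = sobel(dist)
    labels = watershed(grad, markers=markers, mask=cell_mask).astype(np.int32)
    # thin components can lose their marker to h-maxima suppression; label
    # any leftover foreground as additional regions so the output partitions
    # the mask
    leftover = cell_mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover)
        labels[leftover] = extra[leftover] + labels.max()
    return labels


def make_cell_records(labels: np.ndarray, nucleus_mask: np.ndarray) -> list[CellRecord]:
    """Build per-cell records; cytoplasm = cell minus nucleus, pixel-exact.

    Cells without any nucleus pixel are flagged ``empty-nucleus`` and
    excluded from classification (they are typically red-cell clutter);
    cells fully covered by nucleus are flagged ``empty-cytoplasm``.
    """
    labels = np.asarray(labels)
    nucleus_mask = _check_mask(nucleus_mask)
    if labels.shape != nucleus_mask.shape:
        raise InvalidImageError("labels and nucleus mask must share geometry")
    records: list[CellRecord] = []
    for cell_id in range(1, int(labels.max()) + 1):
        cell = labels == cell_id
        if not cell.any():
            continue
        nuc = cell & nucleus_mask
        cyt = cell & ~nuc
        rows, cols = np.nonzero(cell)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        flags = set()
        if not nuc.any():
            flags.add("empty-nucleus")
        if not cyt.any():
            flags.add("empty-cytoplasm")
        records.append(CellRecord(cell_id, cell, nuc, cyt, bbox, frozenset(flags)))
    return records


def segment_image(
    img: np.ndarray, cfg: SegmentationConfig | None = None
) -> list[CellRecord]:
    """Full segmentation: enhanced-Y cell mask, a* nucleus mask, watershed
    split, per-cell records."""
    cfg = cfg or SegmentationConfig()
    img = _check_rgb(img)
    y = rgb_to_cmyk_y(img)
    ei = enhance_contrast(y, mode=cfg.ei_mode)
    filtered = min_filter_3x3(ei, repeats=cfg.min_filter_repeats)
    try:
        cell_mask = otsu_mask(filtered, polarity=cfg.cell_polarity)
    except ConstantImageError:
        return []
    cell_mask = clean_cell_mask(cell_mask, cfg)
    if not cell_mask.any():
        return []
    try:
        nucleus_mask = extract_nucleus_mask(img, cell_mask, cfg)
    except EmptyNucleusError:
        nucleus_mask = np.zeros(cell_mask.shape, dtype=bool)
    labels = split_touching_cells(cell_mask, cfg)
    records = make_cell_records(labels, nucleus_mask)
    n_ok = sum(r.classifiable for r in records)
    logger.info("segmented %d regions (%d with nucleus)", len(records), n_ok)
    return records


def segmentation_summary(records: list[CellRecord]):
    """Per-cell summary table (cell_id, bbox, areas, flags) as a DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "rmin": r.bbox[0],
                "cmin": r.bbox[1],
                "rmax": r.bbox[2],
                "cmax": r.bbox[3],
                "cell_area": int(r.cell_mask.sum()),
                "nucleus_area": int(r.nucleus_mask.sum()),
                "cytoplasm_area": int(r.cytoplasm_mask.sum()),
                "flags": ";".join(sorted(r.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "rmin", "cmin", "rmax", "cmax",
            "cell_area", "nucleus_area", "cytoplasm_area", "flags",
        ],
    )
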