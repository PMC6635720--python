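"""Morphometric features of segmented leukocytes.

Six quantities feed the maturation-stage classifier:

* ``Num``  — number of nucleus lobes (8-connected components);
* ``AoN``  — nucleus area in pixels;
* ``ACoC`` — mean CIELAB b* over the cytoplasm (tracks the basophilic-to-
  eosinophilic color shift with maturation);
* ``T1``   — minimum thickness of the nucleus: the length of the accepted
  bottleneck chord (for convex nuclei T1 falls back to T2 so T1/T2 = 1);
* ``T2``   — minimum width of the nucleus convex hull (rotating calipers);
* ``HD``   — Hausdorff distance between the nucleus border and the cell
  border point sets (symmetric by default);
* ``P1``   — perimeter of the smaller nucleus part after a validated
  bottleneck split (0 when no split is performed).

Bottleneck detection ranks candidate boundary-point pairs by increasing
Euclidean distance among pairs that actually pinch the shape (chord no
longer than ``pinch_factor`` times the shorter boundary arc between the
points — a convex boundary never satisfies this, since a circle's
chord/arc ratio is at least 2/pi) and accepts the first pair whose
connecting segment stays on foreground pixels.  The split produced by an
accepted pair is validated with the area rule (big part more than 3.8x the
small one and total above 74 000 px at reference pitch); a rejected small
part is treated as an artifact, removed, and detection re-runs on the
remainder.  T1 always comes from the first valid pair on the original
mask — validation governs only whether a split (and hence P1) is produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import directed_hausdorff
from skimage.color import rgb2lab
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label, perimeter as polygon_perimeter

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateShapeError",
    "MorphometryConfig",
    "SplitResult",
    "FeatureVector",
    "boundary_pixels",
    "ordered_contour",
    "count_lobes",
    "nucleus_area",
    "avg_cytoplasm_b",
    "bottleneck_pair",
    "validate_split",
    "resolve_split",
    "min_convex_thickness",
    "hausdorff_distance",
    "perimeter_smaller_part",
    "pixel_perimeter",
    "extract_features",
    "feature_table",
]


class DegenerateShapeError(ValueError):
    """Raised for masks too thin or too small for a shape descriptor."""


@dataclass
class MorphometryConfig:
    """Parameters of the geometric feature extractors.

    ``split_ratio`` / ``split_min_total`` are the split-validation
    constants (area of the big part must exceed ``split_ratio`` times the
    small one, and the parts together must exceed ``split_min_total``
    pixels at reference pitch).  ``split_comparator`` may be set to
    ``"inverted"`` to flip the ratio clause.  ``acoc_scale`` and
    ``acoc_offset`` remap the b* axis if a non-standard CIELAB scale is
    wanted.  ``scale`` rescales pixel-unit constants for non-reference
    pitch (lengths linear, areas quadratic).
    """

    min_contour_steps: int = 10
    pinch_factor: float = 0.45
    contour_subsample: int = 2
    max_candidates: int = 4000
    split_ratio: float = 3.8
    split_min_total: float = 74000.0
    split_comparator: str = "as-printed"  # or "inverted"
    max_split_retries: int = 8
    perimeter_mode: str = "pixel"  # or "polygon"
    hausdorff_mode: str = "symmetric"  # or "directed"
    acoc_scale: float = 1.0
    acoc_offset: float = 0.0
    scale: float = 1.0

    def scaled(self, factor: float) -> "MorphometryConfig":
        return replace(self, scale=self.scale * factor)


@dataclass
class SplitResult:
    """Outcome of bottleneck detection / splitting on one nucleus lobe."""

    split_performed: bool
    point_a: tuple[int, int] | None = None
    point_b: tuple[int, int] | None = None
    t1: float | None = None
    part_small: np.ndarray | None = None
    part_big: np.ndarray | None = None


@dataclass
class FeatureVector:
    """The classifier inputs for one cell (pixel units at reference pitch).

    ``acoc`` is ``None`` when the cytoplasm is empty; the corresponding
    flag routes the cell to the unclassifiable outcome if a color branch
    is reached.  ``t1_over_hd`` is ``inf`` when nucleus and cell borders
    coincide.
    """

    num: int
    aon: float
    acoc: float | None
    t1: float
    t2: float
    hd: float
    p1: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def t1_over_t2(self) -> float:
        return self.t1 / self.t2

    @property
    def t1_over_hd(self) -> float:
        return self.t1 / self.hd if self.hd > 0 else float("inf")

    def to_dict(self) -> dict:
        return {
            "num": self.num,
            "aon": self.aon,
            "acoc": self.acoc,
            "t1": self.t1,
            "t2": self.t2,
            "hd": self.hd,
            "p1": self.p1,
            "t1_over_t2": self.t1_over_t2,
            "t1_over_hd": self.t1_over_hd,
            "flags": ";".join(sorted(self.flags)),
        }


# --------------------------------------------------------------------------
# boundary extraction
# --------------------------------------------------------------------------

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Moore neighborhood in clockwise order starting from West
_NBRS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_NBR_INDEX = {off: i for i, off in enumerate(_NBRS)}


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(N, 2) array of foreground pixels with at least one background
    4-neighbor (the 8-connected border)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateShapeError("empty mask has no boundary")
    interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def ordered_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered outer border of a single-component mask, by Moore tracing.

    Returns (N, 2) pixel coordinates walking the outer boundary once.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateShapeError("empty mask has no contour")
    m = np.pad(mask, 1)
    rows, cols = np.nonzero(m)
    first = np.lexsort((cols, rows))[0]
    start = (int(rows[first]), int(cols[first]))
    contour = [start]
    cur, bdir = start, 0  # backtrack points West (background for the start pixel)
    state0 = (start, 0)
    for _ in range(4 * int(m.sum()) + 8):
        moved = False
        for k in range(1, 9):
            d = (bdir + k) % 8
            nr, nc = cur[0] + _NBRS[d][0], cur[1] + _NBRS[d][1]
            if m[nr, nc]:
                prev = _NBRS[(d - 1) % 8]
                back = (cur[0] + prev[0] - nr, cur[1] + prev[1] - nc)
                cur, bdir = (nr, nc), _NBR_INDEX[back]
                moved = True
                break
        if not moved:  # isolated pixel
            break
        if (cur, bdir) == state0:
            break
        contour.append(cur)
    return np.array(contour) - 1  # undo padding


# --------------------------------------------------------------------------
# simple descriptors
# --------------------------------------------------------------------------


def count_lobes(nucleus: np.ndarray) -> int:
    """Number of 8-connected components of the nucleus mask."""
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise DegenerateShapeError("empty nucleus mask")
    return int(cc_label(nucleus, connectivity=2).max())


def nucleus_area(nucleus: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(np.asarray(nucleus, dtype=bool).sum())


def avg_cytoplasm_b(
    img: np.ndarray,
    cytoplasm: np.ndarray,
    cfg: MorphometryConfig | None = None,
    _lab: np.ndarray | None = None,
) -> float:
    """Mean CIELAB b* over cytoplasm pixels (standard sRGB/D65 scale).

    Raises :class:`DegenerateShapeError` for an empty cytoplasm; callers
    that tolerate a missing value catch it and flag the feature.
    """
    cfg = cfg or MorphometryConfig()
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if not cytoplasm.any():
        raise DegenerateShapeError("empty cytoplasm mask")
    lab = rgb2lab(np.asarray(img)) if _lab is None else _lab
    b = float(lab[..., 2][cytoplasm].mean())
    return b * cfg.acoc_scale + cfg.acoc_offset


def pixel_perimeter(mask: np.ndarray, mode: str = "pixel") -> float:
    """Perimeter of a mask: count of border pixels (default) or polygonal
    contour length (``mode="polygon"``)."""
    mask = np.asarray(mask, dtype=bool)
    if mode == "pixel":
        return float(len(boundary_pixels(mask)))
    if mode == "polygon":
        return float(polygon_perimeter(mask))
    raise ValueError(f"unknown perimeter mode {mode!r}")


# --------------------------------------------------------------------------
# convex width and Hausdorff distance
# --------------------------------------------------------------------------


def _hull_vertices(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the mask treating pixels as unit squares."""
    border = boundary_pixels(mask).astype(float)
    offs = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
    corners = (border[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def min_convex_thickness(nucleus: np.ndarray) -> float:
    """Minimum width of the convex hull (rotating calipers).

    For each hull edge the width is the largest distance from the edge
    line to any hull vertex; the minimum over edges is the smallest
    distance between two parallel supporting lines.
    """
    nucleus = np.asarray(nucleus, dtype=bool)
    if nucleus.sum() < 3:
        raise DegenerateShapeError("fewer than 3 foreground pixels")
    v = _hull_vertices(nucleus)
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 0
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lengths[good, None]
    # distance of every vertex to every edge line
    d = np.abs((v[None, :, :] - v[good][:, None, :]) @ normals[:, :, None]).squeeze(-1)
    return float(d.max(axis=1).min())


def hausdorff_distance(
    u: np.ndarray, v: np.ndarray, mode: str = "symmetric"
) -> float:
    """Hausdorff distance between two point sets (pixels).

    ``symmetric`` (default) returns max(h(U,V), h(V,U)); ``directed``
    returns h(U,V) only.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise DegenerateShapeError("empty point set")
    huv = directed_hausdorff(u, v)[0]
    if mode == "directed":
        return float(huv)
    if mode == "symmetric":
        return float(max(huv, directed_hausdorff(v, u)[0]))
    raise ValueError(f"unknown hausdorff mode {mode!r}")


# --------------------------------------------------------------------------
# modified bottleneck splitting
# --------------------------------------------------------------------------


def _pinch_candidates(mask: np.ndarray, cfg: MorphometryConfig):
    """Yield pinch point pairs ((r0,c0),(r1,c1),dist) in order of
    increasing chord length whose segment stays on foreground."""
    contour = ordered_contour(mask)
    n = len(contour)
    if n < 2 * cfg.min_contour_steps:
        return
    step = max(1, cfg.contour_subsample)
    seg = np.vstack([contour[1:] - contour[:-1], contour[:1] - contour[-1:]])
    steplen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(steplen[:-1])])
    total = float(steplen.sum())
    idx = np.arange(0, n, step)
    pts = contour[idx].astype(float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    steps_apart = np.abs(idx[:, None] - idx[None, :])
    steps_apart = np.minimum(steps_apart, n - steps_apart)
    arc = np.abs(cum[idx][:, None] - cum[idx][None, :])
    arc = np.minimum(arc, total - arc)
    ii, jj = np.nonzero(
        (steps_apart >= cfg.min_contour_steps) & (d <= cfg.pinch_factor * arc)
    )
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return
    order = np.argsort(d[ii, jj], kind="stable")[: cfg.max_candidates]
    for k in order:
        a = tuple(int(x) for x in contour[idx[ii[k]]])
        b = tuple(int(x) for x in contour[idx[jj[k]]])
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        if len(rr) > 2 and not mask[rr[1:-1], cc[1:-1]].all():
            continue  # segment crosses background: reject this pair
        yield a, b, float(d[ii[k], jj[k]])


def _cut(mask: np.ndarray, a: tuple[int, int], b: tuple[int, int]):
    """Remove a thickened cut segment; return (small, big) parts or None
    if the cut does not produce exactly two components."""
    rr, cc = draw_line(a[0], a[1], b[0], b[1])
    line = np.zeros(mask.shape, dtype=bool)
    line[rr, cc] = True
    line = ndi.binary_dilation(line, structure=_CROSS)
    lab = cc_label(mask & ~line, connectivity=2)
    if lab.max() != 2:
        return None
    p1 = lab == 1
    p2 = lab == 2
    if p1.sum() <= p2.sum():
        return p1, p2
    return p2, p1


def bottleneck_pair(
    nucleus: np.ndarray, cfg: MorphometryConfig | None = None
) -> SplitResult:
    """First valid pinch pair of a single-lobe nucleus and its split.

    Candidate boundary pairs are ranked by increasing chord length; the
    first pair whose segment stays inside the shape and actually cuts it
    into two parts is returned with ``t1`` set to the chord length.  A
    convex (or pinch-free) shape yields ``split_performed=False`` with
    ``t1=None`` (callers substitute the minimum convex thickness so that
    T1/T2 = 1).
    """
    cfg = cfg or MorphometryConfig()
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise DegenerateShapeError("empty nucleus mask")
    if not ndi.binary_erosion(nucleus, structure=_CROSS, border_value=0).any():
        raise DegenerateShapeError("mask thinner than 2 px everywhere")
    first_pair = None
    for a, b, dist in _pinch_candidates(nucleus, cfg):
        if first_pair is None:
            first_pair = (a, b, dist)
        parts = _cut(nucleus, a, b)
        if parts is not None:
            small, big = parts
            return SplitResult(True, a, b, dist, small, big)
    if first_pair is not None:
        # a pinch exists but no cut separates the shape (e.g. cut grazes
        # the boundary); keep the thickness, report no split
        a, b, dist = first_pair
        return SplitResult(False, a, b, dist, None, None)
    return SplitResult(False)


def validate_split(
    part_big: np.ndarray, part_small: np.ndarray, cfg: MorphometryConfig | None = None
) -> bool:
    """Area rule for accepting a bottleneck split.

    As printed: accept iff area(big) > ratio * area(small) and
    area(big) + area(small) > min_total (defaults 3.8 and 74 000 px at
    reference pitch).  ``split_comparator="inverted"`` flips the ratio
    clause.  A rejected split means the small part is an artifact to be
    removed before re-running detection.
    """
    cfg = cfg or MorphometryConfig()
    big = float(np.asarray(part_big, dtype=bool).sum())
    small = float(np.asarray(part_small, dtype=bool).sum())
    if big == 0 or small == 0:
        raise DegenerateShapeError("empty split part")
    if cfg.split_comparator == "as-printed":
        ratio_ok = big > cfg.split_ratio * small
    elif cfg.split_comparator == "inverted":
        ratio_ok = big <= cfg.split_ratio * small
    else:
        raise ValueError(f"unknown split comparator {cfg.split_comparator!r}")
    total_ok = big + small > cfg.split_min_total * cfg.scale**2
    return bool(ratio_ok and total_ok)


def resolve_split(
    nucleus: np.ndarray, cfg: MorphometryConfig | None = None
) -> SplitResult:
    """Bottleneck split with artifact-removal retries.

    Repeatedly detects a pinch pair and splits; a split failing the area
    rule has its small part removed (artifact) and detection re-runs on
    the remainder.  Terminates because each retry strictly shrinks the
    mask.  Returns the accepted split, or ``split_performed=False`` when
    no acceptable split exists.
    """
    cfg = cfg or MorphometryConfig()
    working = np.asarray(nucleus, dtype=bool).copy()
    for _ in range(cfg.max_split_retries):
        res = bottleneck_pair(working, cfg)
        if not res.split_performed:
            return SplitResult(False, res.point_a, res.point_b, res.t1)
        if validate_split(res.part_big, res.part_small, cfg):
            return res
        working = res.part_big
    return SplitResult(False)


def perimeter_smaller_part(
    split: SplitResult, cfg: MorphometryConfig | None = None
) -> float:
    """Perimeter (border-pixel count) of the smaller part of an accepted
    split; 0 when no split was performed."""
    cfg = cfg or MorphometryConfig()
    if not split.split_performed or split.part_small is None:
        return 0.0
    return pixel_perimeter(split.part_small, mode=cfg.perimeter_mode)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = cc_label(mask, connectivity=2)
    if lab.max() <= 1:
        return mask
    areas = np.bincount(lab.ravel())[1:]
    return lab == (int(areas.argmax()) + 1)


def extract_features(rec, img: np.ndarray, cfg: MorphometryConfig | None = None) -> FeatureVector:
    """Compute the full feature vector for one segmented cell record.

    Multi-lobed nuclei have T1/T2/HD/P1 computed on the largest lobe (the
    classifier short-circuits on the lobe count anyway); AoN is the total
    nucleus area.  A missing cytoplasm marks ACoC as unavailable.
    """
    cfg = cfg or MorphometryConfig()
    flags: set[str] = set()
    nuc = np.asarray(rec.nucleus_mask, dtype=bool)
    num = count_lobes(nuc)
    aon = float(nucleus_area(nuc))
    try:
        acoc = avg_cytoplasm_b(img, rec.cytoplasm_mask, cfg)
    except DegenerateShapeError:
        acoc = None
        flags.add("missing-acoc")
    comp = _largest_component(nuc)
    t2 = min_convex_thickness(comp)
    try:
        pair = bottleneck_pair(comp, cfg)
    except DegenerateShapeError:
        pair = SplitResult(False)
        flags.add("degenerate-lobe")
    t1 = pair.t1 if pair.t1 is not None else t2
    hd = hausdorff_distance(
        boundary_pixels(comp), boundary_pixels(rec.cell_mask), mode=cfg.hausdorff_mode
    )
    if hd == 0:
        flags.add("zero-hd")
    split = resolve_split(comp, cfg) if pair.t1 is not None else SplitResult(False)
    p1 = perimeter_smaller_part(split, cfg)
    if num > 1:
        flags.add("multi-lobed")
    return FeatureVector(num, aon, acoc, float(t1), float(t2), float(hd), float(p1),
                         frozenset(flags))


def feature_table(records, img: np.ndarray, cfg: MorphometryConfig | None = None):
    """Feature DataFrame for classifiable records (one row per cell)."""
    import pandas as pd

    cfg = cfg or MorphometryConfig()
    rows = []
    for rec in records:
        if not rec.classifiable:
            continue
        fv = extract_features(rec, img, cfg)
        row = {"cell_id": rec.cell_id}
        row.update(fv.to_dict())
        rows.append(row)
    cols = ["cell_id", "num", "aon", "acoc", "t1", "t2", "hd", "p1",
            "t1_over_t2", "t1_over_hd", "flags"]
    return pd.DataFrame(rows, columns=cols)
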