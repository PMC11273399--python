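"""Shape descriptors of a cleaned top-view mask.

Six per-frame features feed the weight regressors:

* ``Area`` — foreground pixel count (each pixel one unit square).
* ``Per`` — boundary length: Euclidean chain length of the traced contour
  (axial steps count 1, diagonal steps sqrt(2)), loop closed.
* ``PBL`` / ``PHW`` — long and short side of the minimum-area rotated
  bounding rectangle, pixel proxies for body length and hip width.
* ``Ecc`` — eccentricity of the moment-matched ellipse, 0 for a circle.
* ``Dev`` — background fraction of the frame, ``1 - Area/(H*W)``; a pinhole
  proxy for camera-to-animal distance (small animal or far camera -> high
  Dev).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .masks import EmptyMaskError, extract_contour


@dataclass(frozen=True)
class ShapeFeatures:
    area: float   # px^2
    per: float    # px
    pbl: float    # px, longer min-rect side
    phw: float    # px, shorter min-rect side
    ecc: float    # [0, 1)
    dev: float    # [0, 1]

    def as_dict(self) -> dict[str, float]:
        return {
            "area_px2": self.area,
            "per_px": self.per,
            "pbl_px": self.pbl,
            "phw_px": self.phw,
            "ecc": self.ecc,
            "dev": self.dev,
        }


def area(mask: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def perimeter(contour: np.ndarray) -> float:
    """Chain length of a closed contour: sum of consecutive-point distances.

    A single-point contour has no segments and length 0.
    """
    contour = np.asarray(contour)
    if contour.ndim != 2 or contour.shape[0] < 1:
        raise ValueError("contour must contain at least one point")
    if contour.shape[0] == 1:
        return 0.0
    closed = np.vstack([contour, contour[:1]])
    steps = np.diff(closed.astype(float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def min_area_rect(mask: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area rotated bounding rectangle of the foreground pixels.

    Rotating-calipers over the convex hull of the pixel centres: the optimal
    rectangle has one side collinear with a hull edge, so scanning hull-edge
    orientations is exact.  Returns ``(pbl, phw, angle_deg)`` with
    ``pbl >= phw``; the angle is the orientation of the long side in degrees
    measured from the column axis.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask).astype(float)  # (row, col)
    if len(pts) == 0:
        raise EmptyMaskError("cannot bound an empty mask")
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError as exc:
        raise ValueError("degenerate (collinear) foreground") from exc

    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    angles = np.arctan2(edges[:, 0], edges[:, 1])  # edge direction
    angles = np.unique(np.mod(angles, np.pi / 2.0))

    best = None
    for theta in angles:
        c, s = np.cos(theta), np.sin(theta)
        # Project onto the edge direction u = (sin t, cos t) in (row, col)
        # space and its normal n = (cos t, -sin t): ext[0] is the side
        # collinear with the hull edge, ext[1] the perpendicular side.
        proj = hp @ np.array([[s, c], [c, -s]])
        ext = proj.max(axis=0) - proj.min(axis=0)
        a = float(ext[0] * ext[1])
        if best is None or a < best[0]:
            long_side = float(max(ext))
            short_side = float(min(ext))
            ang = np.degrees(theta) if ext[0] >= ext[1] else np.degrees(theta) + 90.0
            best = (a, long_side, short_side, ang % 180.0)
    assert best is not None
    return best[1], best[2], best[3]


def eccentricity(mask: np.ndarray, min_area: int = 16) -> float:
    """Eccentricity of the ellipse matching the region's second moments.

    With principal second central moments l1 >= l2 the matched ellipse has
    semi-axes proportional to sqrt(l1), sqrt(l2) and eccentricity
    sqrt(1 - l2/l1).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < min_area:
        raise ValueError(f"region of {n} px too small for stable moments (< {min_area})")
    r, c = np.nonzero(mask)
    r = r - r.mean()
    c = c - c.mean()
    # Per-pixel 1/12 term: each pixel is a unit square, not a point.
    mu20 = float((r * r).mean()) + 1.0 / 12.0
    mu02 = float((c * c).mean()) + 1.0 / 12.0
    mu11 = float((r * c).mean())
    common = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 * mu11)
    l1 = (mu20 + mu02 + common) / 2.0
    l2 = (mu20 + mu02 - common) / 2.0
    if l1 <= 0:
        raise ValueError("zero-variance region: eccentricity undefined")
    return float(np.sqrt(max(1.0 - l2 / l1, 0.0)))


def deviation(mask: np.ndarray) -> float:
    """Background fraction of the frame: ``1 - area / (H * W)``, exact."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    return 1.0 - area(mask) / float(h * w)


def extract_features(mask: np.ndarray) -> ShapeFeatures:
    """All six descriptors of a cleaned single-component mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract features from an empty mask")
    contour = extract_contour(mask)
    pbl, phw, _ = min_area_rect(mask)
    return ShapeFeatures(
        area=float(area(mask)),
        per=perimeter(contour),
        pbl=pbl,
        phw=phw,
        ecc=eccentricity(mask),
        dev=deviation(mask),
    )


def feature_table(scenes) -> pd.DataFrame:
    """Per-frame feature rows for a list of synthetic scenes."""
    rows = []
    for s in scenes:
        f = extract_features(s.mask)
        rows.append({"frame_id": s.frame_id, "pig_id": s.biometry.pig_id, **f.as_dict()})
    return pd.DataFrame(rows)
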