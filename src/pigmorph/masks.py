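"""Binary-mask cleanup and boundary extraction.

Raw instance-segmentation output arrives as a mask raster (grayscale or
colored labels).  The cleanup chain is: threshold to binary, morphological
opening with a large elliptical (discrete disc) structuring element to
remove segmentation noise, keep the single largest connected region (one
animal per frame), and trace its closed boundary.

Conventions used throughout: images are (row, col) 0-based numpy arrays;
foreground is 8-connected, background 4-connected; morphology pads with
background outside the frame.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when an operation needs foreground but the mask has none."""


_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


def binarize(image: np.ndarray, threshold: int = 0) -> np.ndarray:
    """Threshold a mask raster: foreground iff intensity > ``threshold``.

    Multi-channel rasters (colored per-label masks) are collapsed with a
    per-pixel max over channels first, so any non-background label counts
    as animal.  The default threshold 0 keeps every nonzero label.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot binarize an empty image")
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got ndim={arr.ndim}")
    return arr > threshold


def structuring_element(kernel_size: int) -> np.ndarray:
    """Discrete disc footprint for an elliptical element of given diameter.

    ``kernel_size`` is the element diameter in pixels; the footprint is the
    centred odd grid of side ``2*floor(kernel_size/2) + 1`` containing every
    pixel within Euclidean radius ``kernel_size / 2`` of the centre.  The
    centred-odd convention keeps opening shift-free for even diameters.
    """
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    r = kernel_size / 2.0
    half = int(np.floor(r))
    ii, jj = np.mgrid[-half : half + 1, -half : half + 1]
    return (ii * ii + jj * jj) <= r * r + 1e-9


def morphological_open(mask: np.ndarray, kernel_size: int = 70) -> np.ndarray:
    """Opening (erosion then dilation) with a disc of diameter ``kernel_size``.

    Implemented with exact Euclidean distance transforms, which for a disc
    footprint is identical to the sliding min/max filter but linear-time:
    erosion keeps pixels whose nearest background lies strictly beyond the
    disc radius (background-padded), dilation keeps pixels within the radius
    of surviving foreground.  Removes connected specks smaller than the
    element; anti-extensive and idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    footprint = structuring_element(kernel_size)
    if footprint.shape[0] > min(mask.shape):
        raise ValueError(
            f"structuring element {footprint.shape[0]} px exceeds image "
            f"{mask.shape}"
        )
    r = kernel_size / 2.0
    pad = footprint.shape[0] // 2 + 1
    if not mask.any():
        return np.zeros_like(mask)
    # The opening can only differ from all-background inside the foreground
    # bounding box grown by the element radius; crop there for speed.
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + pad, mask.shape[0] - 1)
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + pad, mask.shape[1] - 1)
    sub = mask[r0 : r1 + 1, c0 : c1 + 1]
    opened_sub = _open_disc(sub, r, pad)
    out = np.zeros_like(mask)
    out[r0 : r1 + 1, c0 : c1 + 1] = opened_sub
    return out


def _open_disc(mask: np.ndarray, r: float, pad: int) -> np.ndarray:
    padded = np.pad(mask, pad, constant_values=False)
    # Erosion: survive iff every pixel of the disc around you is foreground,
    # i.e. the nearest background pixel is farther than the disc reaches.
    d_bg = ndimage.distance_transform_edt(padded)
    eroded = d_bg * d_bg > r * r + 1e-9
    # Dilation of the eroded set by the same disc.
    if not eroded.any():
        return np.zeros_like(mask)
    d_fg = ndimage.distance_transform_edt(~eroded)
    opened = d_fg * d_fg <= r * r + 1e-9
    return opened[pad:-pad, pad:-pad]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken by the component containing the earliest foreground
    pixel in row-major order (smallest top-left coordinate).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("no foreground: no animal detected in mask")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 1:
        return mask.copy()
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best_size = counts.max()
    tied = np.flatnonzero(counts == best_size) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        # First row-major foreground pixel belonging to a tied component.
        flat = labels.ravel()
        pos = np.flatnonzero(np.isin(flat, tied))[0]
        keep = flat[pos]
    return labels == keep


# Moore-neighbourhood tracing: clockwise offsets starting from West,
# in (row, col).  Clockwise in image coordinates (row grows downwards).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the closed outer boundary of a single-component mask.

    Moore-neighbourhood tracing, clockwise, starting from the topmost (then
    leftmost) foreground pixel, with Jacob's stopping criterion (terminate on
    re-entering the start pixel from the initial backtrack direction).
    Returns an (n, 2) array of (row, col) points; consecutive points are
    8-adjacent and every point touches the background (or image border).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot trace contour of an empty mask")
    _, n = ndimage.label(mask, structure=_EIGHT)
    if n != 1:
        raise ValueError(f"expected exactly one component, found {n}")

    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    # Backtrack starts at West of the start pixel (guaranteed background or
    # off-image because start is the first row-major foreground pixel).
    initial_b = (start[0], start[1] - 1)
    cur, b_cell = start, initial_b
    contour = [start]
    limit = 4 * int(mask.sum()) + 8
    for _ in range(limit):
        b_dir = _MOORE.index((b_cell[0] - cur[0], b_cell[1] - cur[1]))
        hit = None
        for k in range(1, 9):
            d = (b_dir + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                hit = (nr, nc)
                # Last background cell checked before the hit (the backtrack
                # itself when the very first candidate is foreground).
                pd = (b_dir + k - 1) % 8
                b_cell = (cur[0] + _MOORE[pd][0], cur[1] + _MOORE[pd][1])
                break
        if hit is None:
            return np.array(contour, dtype=int)  # isolated pixel
        # Jacob's stopping criterion: re-entering the start pixel with the
        # same backtrack as the initial one closes the loop.
        if hit == start and b_cell == initial_b:
            return np.array(contour, dtype=int)
        cur = hit
        contour.append(cur)
    raise RuntimeError("contour tracing failed to terminate")


def clean_mask(
    image: np.ndarray, threshold: int = 0, kernel_size: int = 70
) -> np.ndarray:
    """Full cleanup chain: binarize -> open -> keep largest component."""
    binary = binarize(image, threshold)
    opened = morphological_open(binary, kernel_size)
    return largest_component(opened)
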