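"""Skeleton-based vascular morphometry.

Four per-eye metrics are computed from a binary vessel mask and the
macula/disc landmarks:

* **vessel angle** — mean acute angle (deg) between the local vessel
  orientation and the macula–disc reference axis;
* **Df** — box-counting fractal dimension of the skeletonized vessels;
* **vessel density** — vessel pixels as a percentage of the vascular
  region, the convex hull of vessel pixels (the avascular surround is
  thereby removed);
* **branch count** — number of skeleton segments delimited by junctions
  and endpoints.

All metrics are translation invariant and (up to rasterization) invariant
under joint 90-degree rotations of mask and landmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from .core import Landmarks, as_bool_mask

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphoConfig:
    """Shared knobs of the four metrics.

    window_radius: half-width (px) of the local-orientation window.
    min_branch_len: skeleton segments shorter than this (px) are treated
        as thinning spurs and not counted.
    region_method: avascular-area removal rule for density —
        ``hull`` (convex hull of vessel pixels, default), ``fov``
        (field-of-view disc), or ``bbox``.
    df_on_skeleton: measure Df on the 1-px skeleton (default) rather than
        the full-caliber mask, removing vessel caliber as a confounder.
    """

    window_radius: int = 5
    min_branch_len: int = 5
    region_method: str = "hull"
    box_sizes: Optional[Sequence[int]] = None
    df_on_skeleton: bool = True


@dataclass
class MorphometryRecord:
    """The four metrics for one eye."""

    vessel_angle: float  # degrees in [0, 90]
    df: float  # box-counting dimension, (0, 2]
    vessel_density: float  # percent of the vascular region
    branch_count: int
    eye_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "vessel_angle_deg": self.vessel_angle,
            "df": self.df,
            "vessel_density_pct": self.vessel_density,
            "branch_count": self.branch_count,
        }


_CROSS_ORDER = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _crossing_number(skel: np.ndarray, r: int, c: int) -> int:
    """Number of 0->1 transitions around the 8-neighborhood (Rutovitz)."""
    vals = []
    for dr, dc in _CROSS_ORDER:
        rr, cc = r + dr, c + dc
        inside = 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1]
        vals.append(bool(skel[rr, cc]) if inside else False)
    return sum((not a) and b for a, b in zip(vals, vals[1:] + vals[:1]))


def _prune_square_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove redundant pixels of 2x2 all-true blocks left by thinning.

    A block pixel is deleted only if it is a simple point (crossing
    number 1), so topology is preserved.
    """
    skel = skel.copy()
    for _ in range(4):
        blocks = (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:])
        rows, cols = np.nonzero(blocks)
        if rows.size == 0:
            break
        changed = False
        for r0, c0 in zip(rows, cols):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                r, c = r0 + dr, c0 + dc
                if skel[r, c] and _crossing_number(skel, r, c) == 1:
                    skel[r, c] = False
                    changed = True
                    break
        if not changed:
            break
    return skel


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px, 8-connected skeleton.

    An empty mask yields an empty skeleton (no error).  A cleanup pass
    removes the occasional 2x2 block the raster thinning leaves behind.
    """
    mask = as_bool_mask(mask)
    if not mask.any():
        return np.zeros_like(mask)
    return _prune_square_blocks(skmorph.skeletonize(mask))


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                            mode="constant", cval=0)


def junction_pixels(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with >= 3 skeleton neighbors (8-connectivity)."""
    skel = as_bool_mask(skel)
    return skel & (_neighbor_counts(skel) >= 3)


def vessel_angle(skel: np.ndarray, axis: Landmarks | tuple,
                 window_radius: int = 5) -> float:
    """Mean acute angle (deg) between vessels and the macula–disc axis.

    Local orientation at each skeleton pixel is the principal direction of
    the skeleton pixels inside a ``(2r+1)^2`` window (coordinate PCA, a
    length-weighted orientation-field estimate); the acute angle to the
    reference axis lies in [0, 90] and the skeleton-pixel mean is
    returned.  Isolated pixels, whose windows hold fewer than 3 skeleton
    pixels, are skipped.
    """
    skel = as_bool_mask(skel)
    if not skel.any():
        raise ValueError("no vessels: skeleton is empty")
    if isinstance(axis, Landmarks):
        dr = axis.disc_center[0] - axis.macula_center[0]
        dc = axis.disc_center[1] - axis.macula_center[1]
    else:
        dr, dc = axis
    nrm = np.hypot(dr, dc)
    if nrm < 1e-12:
        raise ValueError("degenerate reference axis")
    psi = np.arctan2(dc, dr)  # axis orientation, measured from the row axis

    k = 2 * int(window_radius) + 1
    s = skel.astype(np.float64)
    rr, cc = np.mgrid[: skel.shape[0], : skel.shape[1]].astype(np.float64)

    def winsum(a):
        return ndimage.uniform_filter(a, size=k, mode="constant", cval=0.0) * (k * k)

    n = winsum(s)
    sr, sc = winsum(s * rr), winsum(s * cc)
    srr, scc = winsum(s * rr * rr), winsum(s * cc * cc)
    src = winsum(s * rr * cc)

    valid = skel & (n >= 3)
    if not valid.any():
        raise ValueError("no vessels: all skeleton pixels isolated")
    n_v = n[valid]
    mr, mc = sr[valid] / n_v, sc[valid] / n_v
    a = srr[valid] / n_v - mr * mr  # var(row)
    c = scc[valid] / n_v - mc * mc  # var(col)
    b = src[valid] / n_v - mr * mc  # cov(row, col)
    phi = 0.5 * np.arctan2(2.0 * b, a - c)  # principal orientation vs row axis

    delta = np.abs(phi - psi) % np.pi
    acute = np.minimum(delta, np.pi - delta)
    return float(np.degrees(acute.mean()))


def default_box_sizes(arr_bbox_shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 px up to a quarter of the short bbox side.

    Thin or small objects whose short side yields fewer than three sizes
    fall back to [2, 4, 8] so a straight line still has a well-defined
    slope.
    """
    limit = min(arr_bbox_shape) // 4
    sizes, e = [], 2
    while e <= limit:
        sizes.append(e)
        e *= 2
    if len(sizes) < 3:
        sizes = [2, 4, 8]
    return sizes


def box_counts(arr: np.ndarray, box_sizes: Sequence[int]) -> np.ndarray:
    """Occupied-box counts N(eps) on grids anchored at the bbox origin."""
    arr = as_bool_mask(arr)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise ValueError("empty input: nothing to box-count")
    sub = arr[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]
    counts = []
    for e in box_sizes:
        if e < 1:
            raise ValueError("box sizes must be >= 1")
        h = -(-sub.shape[0] // e) * e
        w = -(-sub.shape[1] // e) * e
        padded = np.zeros((h, w), dtype=bool)
        padded[: sub.shape[0], : sub.shape[1]] = sub
        blocks = padded.reshape(h // e, e, w // e, e)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return np.asarray(counts)


def box_counting_df(arr: np.ndarray, box_sizes: Optional[Sequence[int]] = None
                    ) -> float:
    """Box-counting fractal dimension: OLS slope of log N(eps) vs log(1/eps).

    ``arr`` is normally a skeleton; pass a full mask for mask-mode
    sensitivity analyses.  Default box sizes are powers of 2 from 2 px to
    a quarter of the shorter bounding-box side; at least 3 sizes are
    required for a meaningful regression.
    """
    arr = as_bool_mask(arr)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise ValueError("empty input: cannot estimate Df")
    if box_sizes is None:
        bbox = (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
        box_sizes = default_box_sizes(bbox)
    box_sizes = list(box_sizes)
    if len(box_sizes) < 3:
        raise ValueError("need >= 3 box sizes for the log–log regression")
    n = box_counts(arr, box_sizes)
    x = np.log(1.0 / np.asarray(box_sizes, dtype=float))
    y = np.log(n.astype(float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def vessel_density(mask: np.ndarray, region_method: str = "hull",
                   fov: Optional[np.ndarray] = None) -> float:
    """Vessel pixels as a percent of the vascular region.

    The avascular surround is removed by restricting the denominator to
    ``region_method``: the convex hull of the vessel pixels (default),
    the field-of-view disc (requires ``fov``), or the vessel bounding
    box.  A degenerate hull (collinear vessels) makes density 100% and
    emits a warning.
    """
    mask = as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask: density undefined")
    if region_method == "hull":
        region = skmorph.convex_hull_image(mask)
    elif region_method == "fov":
        if fov is None:
            raise ValueError("region_method='fov' requires a fov mask")
        region = as_bool_mask(fov)
    elif region_method == "bbox":
        rows, cols = np.nonzero(mask)
        region = np.zeros_like(mask)
        region[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1] = True
    else:
        raise ValueError(f"unknown region_method {region_method!r}")
    area = int(region.sum())
    vessels = int((mask & region).sum())
    if area <= vessels:
        if region_method == "hull":
            warnings.warn("degenerate convex hull (collinear vessels); "
                          "density saturates at 100%", stacklevel=2)
        return 100.0 * vessels / max(area, 1)
    return 100.0 * vessels / area


def count_branches(skel: np.ndarray, min_branch_len: int = 5) -> int:
    """Number of skeleton segments delimited by junctions/endpoints.

    Junction pixels (>= 3 skeleton neighbors, 8-connectivity) are removed
    and the remaining 8-connected components with at least
    ``min_branch_len`` pixels are counted; the length floor suppresses
    thinning spurs.  An empty skeleton counts 0.
    """
    skel = as_bool_mask(skel)
    if not skel.any():
        return 0
    pruned = skel & ~junction_pixels(skel)
    labels, n = ndimage.label(pruned, structure=_EIGHT)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return int((sizes >= min_branch_len).sum())


def compute_morphometry(mask: np.ndarray, landmarks: Landmarks,
                        config: MorphoConfig = MorphoConfig(),
                        eye_id: Optional[str] = None) -> MorphometryRecord:
    """Run skeletonization once and derive the four metrics."""
    mask = as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask: no vessels to measure")
    skel = skeletonize(mask)
    angle = vessel_angle(skel, landmarks, window_radius=config.window_radius)
    df_input = skel if config.df_on_skeleton else mask
    df = box_counting_df(df_input, config.box_sizes)
    fov = landmarks.fov_mask(mask.shape) if config.region_method == "fov" else None
    density = vessel_density(mask, region_method=config.region_method, fov=fov)
    branches = count_branches(skel, min_branch_len=config.min_branch_len)
    return MorphometryRecord(vessel_angle=angle, df=df, vessel_density=density,
                             branch_count=branches, eye_id=eye_id)
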