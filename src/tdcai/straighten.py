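"""Curved planar reformation: straightening a vessel along its centerline.

A square sampling plane, initially perpendicular to the z-axis, is carried
along the centerline.  At each step the plane is rotated by the angle
between consecutive tangents about their common perpendicular (a Rodrigues
rotation) and translated to the next centerline point, so every plane stays
normal to the local tangent with minimal twist — the discrete
rotation-minimizing frame.  Resampling the image on the plane stack and
stacking the planes along a new z-axis renders the curved vessel straight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .centerline import Centerline

__all__ = [
    "PlaneStack",
    "StraightenedVolume",
    "CaliberProfile",
    "rotate_vector",
    "initial_plane",
    "propagate_planes",
    "resample_on_planes",
    "straighten",
    "assess_caliber_profile",
]

SENTINEL_HU = -1024.0


# ---------------------------------------------------------------- rotation
def rotate_vector(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` (or a stack of vectors) about unit ``axis``.

    v' = cos(th) v + (1 - cos(th)) (u . v) u + sin(th) (u x v)
    """
    u = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be a unit vector")
    v = np.asarray(v, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    dot = v @ u
    return c * v + (1 - c) * np.multiply.outer(dot, u) + s * np.cross(np.broadcast_to(u, v.shape), v)


def initial_plane(half_size: int, spacing: float) -> np.ndarray:
    """(2m+1)^2 x 3 grid of sample offsets in the z=0 plane, centered on the
    origin (the plane's own center point), row-major over (y, x)."""
    if half_size < 1:
        raise ValueError("half_size must be >= 1")
    m = int(half_size)
    coords = np.arange(-m, m + 1, dtype=float) * spacing
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)


@dataclass
class PlaneStack:
    """Per-centerline-point sampling planes and the rotations that built them."""

    planes: np.ndarray  # (n, (2m+1)^2, 3) world coordinates
    half_size: int
    in_plane_spacing: float
    rotations: list = field(default_factory=list)  # (angle, axis) per step
    normals: np.ndarray | None = None


def propagate_planes(centerline: Centerline, half_size: int, spacing: float) -> PlaneStack:
    """Carry the initial plane along the centerline by sequential rotations.

    For each step the rotation angle is arccos(n_{i-1} . n_i) and the axis
    is the normalized cross product of consecutive tangents, oriented so the
    rotation maps n_{i-1} onto n_i; the plane's offsets from the previous
    centerline point are rotated and re-attached at the current point.
    Parallel tangents (zero cross product) step by pure translation;
    anti-parallel tangents are rejected as a degenerate fold-back.
    """
    pts = centerline.points
    tangents = centerline.tangents
    if len(pts) < 2:
        raise ValueError("centerline needs at least 2 points")

    template = initial_plane(half_size, spacing)
    # orient the template from z-hat to the first tangent
    z = np.array([0.0, 0.0, 1.0])
    n1 = tangents[0]
    offsets = _rotate_between(template, z, n1)

    n_pts = len(pts)
    planes = np.empty((n_pts, template.shape[0], 3))
    planes[0] = pts[0] + offsets
    rotations = []
    normal = n1
    for i in range(1, n_pts):
        n_prev, n_cur = tangents[i - 1], tangents[i]
        cosang = float(np.clip(np.dot(n_prev, n_cur), -1.0, 1.0))
        cross = np.cross(n_prev, n_cur)
        norm = np.linalg.norm(cross)
        if cosang <= -1.0 + 1e-12:
            raise ValueError(f"anti-parallel tangents at point {i}; centerline folds back")
        rel = planes[i - 1] - pts[i - 1]
        if norm < 1e-12:
            rotations.append((0.0, np.array([0.0, 0.0, 1.0])))
            planes[i] = pts[i] + rel
        else:
            angle = float(np.arccos(cosang))
            axis = cross / norm
            rotations.append((angle, axis))
            planes[i] = pts[i] + rotate_vector(rel, axis, angle)
            normal = rotate_vector(normal, axis, angle)
    return PlaneStack(
        planes=planes,
        half_size=half_size,
        in_plane_spacing=spacing,
        rotations=rotations,
        normals=tangents.copy(),
    )


def _rotate_between(vectors: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotate ``vectors`` by the minimal rotation taking unit vector a to b."""
    c = float(np.clip(np.dot(a, b), -1.0, 1.0))
    cross = np.cross(a, b)
    n = np.linalg.norm(cross)
    if n < 1e-12:
        if c > 0:
            return vectors.copy()
        # a -> -a: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotate_vector(vectors, perp / np.linalg.norm(perp), np.pi)
    return rotate_vector(vectors, cross / n, float(np.arccos(c)))


# ---------------------------------------------------------------- resample
@dataclass
class StraightenedVolume:
    """Straightened image: axis 0 runs along the vessel, axes (1, 2) are the
    in-plane (y, x) sample grid."""

    values: np.ndarray  # (n, 2m+1, 2m+1) or (T, n, 2m+1, 2m+1)
    step_mm: float
    in_plane_spacing: float
    provenance: dict = field(default_factory=dict)


def resample_on_planes(volume, stack: PlaneStack, spacing, origin,
                       step_mm: float, sentinel: float = SENTINEL_HU,
                       provenance: dict | None = None) -> StraightenedVolume:
    """Trilinear resampling of a 3D volume (or 4D series, frame by frame)
    at every plane sample; out-of-grid samples get the sentinel value."""
    side = 2 * stack.half_size + 1
    coords_world = stack.planes.reshape(-1, 3)  # (n*side^2, 3)
    sp = np.asarray(spacing, dtype=float)  # (dz, dy, dx)
    idx = (coords_world - np.asarray(origin)) / sp[::-1]  # (x, y, z) fractional
    idx_zyx = idx[:, ::-1].T  # (3, N) for map_coordinates

    def _resample_3d(vol):
        vals = ndimage.map_coordinates(vol.astype(float), idx_zyx, order=1,
                                       mode="constant", cval=sentinel)
        return vals.reshape(len(stack.planes), side, side)

    if volume.ndim == 3:
        shape = volume.shape
        out = _resample_3d(volume)
        inside = _fraction_inside(idx_zyx, shape)
        if inside == 0:
            raise ValueError("every plane sample lies outside the source grid")
        values = out
    elif volume.ndim == 4:
        shape = volume.shape[1:]
        inside = _fraction_inside(idx_zyx, shape)
        if inside == 0:
            raise ValueError("every plane sample lies outside the source grid")
        values = np.stack([_resample_3d(volume[t]) for t in range(volume.shape[0])])
    else:
        raise ValueError("volume must be 3D or 4D")
    return StraightenedVolume(
        values=values,
        step_mm=step_mm,
        in_plane_spacing=stack.in_plane_spacing,
        provenance=provenance or {},
    )


def _fraction_inside(idx_zyx, shape) -> float:
    ok = np.ones(idx_zyx.shape[1], dtype=bool)
    for k in range(3):
        ok &= (idx_zyx[k] >= 0) & (idx_zyx[k] <= shape[k] - 1)
    return float(ok.mean())


def straighten(volume, centerline: Centerline, spacing, origin,
               step_mm: float = 0.5, half_size_mm: float | None = None,
               in_plane_spacing: float | None = None, frame: str = "all",
               sentinel: float = SENTINEL_HU):
    """End-to-end straightening of a 3D volume or 4D series along a centerline.

    The centerline is first resampled to uniform ``step_mm`` arc-length
    steps (central-difference tangents behave poorly on uneven Dijkstra node
    spacing).  ``half_size_mm`` defaults to 10 mm of plane half-side;
    ``in_plane_spacing`` defaults to the source in-plane voxel spacing.
    ``frame`` selects what to straighten for a 4D input: "all" (every
    frame), "mip" (temporal maximum first), or an integer frame index.
    """
    if in_plane_spacing is None:
        in_plane_spacing = float(min(spacing[1], spacing[2]))
    if half_size_mm is None:
        half_size_mm = 10.0
    m = max(1, int(np.ceil(half_size_mm / in_plane_spacing)))
    cl = centerline.resample(step_mm)
    stack = propagate_planes(cl, m, in_plane_spacing)
    vol = np.asarray(volume)
    if vol.ndim == 4:
        if frame == "mip":
            vol = vol.max(axis=0)
        elif frame != "all":
            vol = vol[int(frame)]
    return resample_on_planes(vol, stack, spacing, origin, step_mm, sentinel=sentinel,
                              provenance={"centerline_points": len(cl.points)})


# ----------------------------------------------------------- caliber check
@dataclass
class CaliberProfile:
    areas_mm2: np.ndarray
    arc_length_mm: np.ndarray
    median_area: float
    stenosis_intervals: list  # [(s0, s1), ...] flagged narrow
    dilation_intervals: list  # [(s0, s1), ...] flagged dilated
    min_area_index: int
    max_area_index: int


def assess_caliber_profile(straightened: StraightenedVolume, lumen_threshold: float = 0.5,
                           narrow_frac: float = 0.75, dilated_frac: float = 1.25) -> CaliberProfile:
    """Per-slice lumen area along the straightened vessel, with narrow and
    dilated intervals flagged against the median area.

    A slice is narrow when its area < ``narrow_frac`` x median and dilated
    when > ``dilated_frac`` x median; contiguous flagged slices are merged
    into arc-length intervals.
    """
    vals = straightened.values
    if vals.ndim == 4:
        vals = vals.max(axis=0)
    lumen = vals >= lumen_threshold
    areas = lumen.sum(axis=(1, 2)) * straightened.in_plane_spacing**2
    if areas.sum() == 0:
        raise ValueError("no lumen above threshold in the straightened volume")
    s = np.arange(len(areas)) * straightened.step_mm
    nonzero = areas > 0
    median = float(np.median(areas[nonzero]))

    def _intervals(flags):
        out = []
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                out.append((float(s[i]), float(s[j])))
                i = j + 1
            else:
                i += 1
        return out

    narrow = nonzero & (areas < narrow_frac * median)
    dilated = areas > dilated_frac * median
    areas_for_min = np.where(nonzero, areas, np.inf)
    return CaliberProfile(
        areas_mm2=areas.astype(float),
        arc_length_mm=s,
        median_area=median,
        stenosis_intervals=_intervals(narrow),
        dilation_intervals=_intervals(dilated),
        min_area_index=int(np.argmin(areas_for_min)),
        max_area_index=int(np.argmax(areas)),
    )
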