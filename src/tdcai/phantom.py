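"""Synthetic vascular phantoms with analytic ground truth.

Two families of phantoms back the validation of every downstream stage:

* dynamic 4D CTP scenes — tubular "arteries" and "veins" whose voxels carry
  gamma-variate bolus time-attenuation curves with distinct arrival times,
  optional low-enhancing soft tissue and a high-HU skull shell;
* static geometric tube phantoms — a curved main tube with optional side
  branches (centerline-robustness tests) or with a stenosis and a dilation
  at known arc-length intervals (caliber-representation tests).

All geometry is analytic first (parametric centerline, radius profile) and
rasterized second, so the ground truth (centerline points, label volumes,
peak times, feature intervals) is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import CTPSeries, index_to_world

__all__ = [
    "ParametricCurve",
    "RadiusProfile",
    "BranchSpec",
    "TubeSpec",
    "TACModel",
    "PhantomScene",
    "rasterize_scene",
    "make_deviation_phantom",
    "make_stenosis_phantom",
]

LABEL_BACKGROUND = 0
LABEL_ARTERY = 1
LABEL_VEIN = 2
LABEL_SOFT_TISSUE = 3
LABEL_SKULL = 4


# --------------------------------------------------------------------- curves
class ParametricCurve:
    """A 3D space curve parameterized by arc length (mm).

    Built from a dense sample of points; provides arc-length lookup of
    positions and (finite-difference) unit tangents.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("curve needs an (N>=2, 3) point array")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            keep = np.concatenate([[True], seg > 0])
            pts = pts[keep]
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._points = pts
        self._s = np.concatenate([[0.0], np.cumsum(seg)])

    @classmethod
    def line(cls, p0, p1, n=200):
        t = np.linspace(0, 1, n)[:, None]
        return cls(np.asarray(p0) + t * (np.asarray(p1) - np.asarray(p0)))

    @classmethod
    def arc(cls, center, radius, angle_span, n=600, plane="xz"):
        """Circular arc of given radius spanning ``angle_span`` radians.

        The arc lies in the named coordinate plane, centered at ``center``.
        """
        th = np.linspace(-angle_span / 2, angle_span / 2, n)
        c = np.asarray(center, dtype=float)
        pts = np.tile(c, (n, 1))
        ax = {"xz": (0, 2), "xy": (0, 1), "yz": (1, 2)}[plane]
        pts[:, ax[0]] += radius * np.sin(th)
        pts[:, ax[1]] += radius * (np.cos(th) - 1.0) * -1.0  # bows away from center line
        return cls(pts)

    @classmethod
    def helix(cls, center, radius, pitch, turns, n=800):
        th = np.linspace(0, 2 * np.pi * turns, n)
        c = np.asarray(center, dtype=float)
        pts = np.stack(
            [c[0] + radius * np.cos(th), c[1] + radius * np.sin(th), c[2] + pitch * th / (2 * np.pi)],
            axis=1,
        )
        return cls(pts)

    @classmethod
    def from_control_points(cls, control_points, n=600):
        from scipy.interpolate import CubicSpline

        cp = np.asarray(control_points, dtype=float)
        t = np.linspace(0, 1, len(cp))
        spl = CubicSpline(t, cp, axis=0)
        return cls(spl(np.linspace(0, 1, n)))

    @property
    def length(self) -> float:
        return float(self._s[-1])

    def point(self, s):
        """Position(s) at arc length ``s`` (clamped to [0, length])."""
        scalar = np.ndim(s) == 0
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0, self.length)
        out = np.stack([np.interp(s, self._s, self._points[:, k]) for k in range(3)], axis=-1)
        return out[0] if scalar else out

    def tangent(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        h = max(self.length * 1e-4, 1e-3)
        p0 = self.point(np.clip(s - h, 0, self.length))
        p1 = self.point(np.clip(s + h, 0, self.length))
        d = p1 - p0
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def sample(self, ds: float):
        """(points, s) sampled at roughly uniform arc-length spacing ``ds``."""
        n = max(int(np.ceil(self.length / ds)) + 1, 2)
        s = np.linspace(0, self.length, n)
        return self.point(s), s


# ------------------------------------------------------------- radius profile
@dataclass
class RadiusProfile:
    """Piecewise-constant tube radius as a function of arc length.

    ``features`` is a list of (start_s, end_s, radius_factor) with
    factor < 1 for a stenosis and factor > 1 for a dilation; intervals must
    not overlap.
    """

    baseline: float
    features: list = field(default_factory=list)

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline radius must be positive")
        ivals = sorted((f[0], f[1]) for f in self.features)
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping radius features: [{a0},{b0}] and [{a1},{b1}]")
        for s0, s1, fac in self.features:
            if s1 <= s0:
                raise ValueError("feature interval must have positive length")
            if fac <= 0:
                raise ValueError("radius factor must be positive")

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, self.baseline)
        for s0, s1, fac in self.features:
            r[(s >= s0) & (s < s1)] = self.baseline * fac
        return r


@dataclass
class BranchSpec:
    """A straight side branch attached to the main tube's surface."""

    attachment_s: float
    direction: np.ndarray  # unit vector, world frame
    length: float
    radius: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("branch direction must be non-zero")
        self.direction = d / n
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("branch length and radius must be positive")


@dataclass
class TubeSpec:
    """One tube: analytic centerline, radius profile, optional side branches."""

    centerline_curve: ParametricCurve
    radius_profile: RadiusProfile
    side_branches: list = field(default_factory=list)
    label: str = "none"  # {artery, vein, none}
    name: str = "tube"

    def branch_axes(self):
        """Branch axis segments [(start_point_on_surface, end_point, radius), ...]."""
        out = []
        c = self.centerline_curve
        for br in self.side_branches:
            s = float(np.clip(br.attachment_s, 0, c.length))
            axis_pt = np.atleast_2d(c.point(s))[0]
            tang = np.atleast_2d(c.tangent(s))[0]
            d = br.direction
            perp = d - np.dot(d, tang) * tang
            pn = np.linalg.norm(perp)
            if pn < 1e-9:
                raise ValueError("branch direction parallel to main tube axis")
            r_here = float(self.radius_profile(np.array([s]))[0])
            start = axis_pt + (perp / pn) * r_here  # on the tube surface
            end = start + d * br.length
            out.append((start, end, br.radius))
        return out


# ---------------------------------------------------------------- TAC model
@dataclass
class TACModel:
    """Gamma-variate bolus enhancement on a flat baseline.

    enhancement(t) = amplitude * ((t-t0)/(alpha*beta))**alpha
                     * exp(alpha - (t-t0)/beta)   for t > t0, else 0.

    The curve peaks at exactly t_peak = t0 + alpha*beta with value
    ``amplitude``, which serves as closed-form ground-truth TTP.
    """

    t0: float = 4.0
    alpha: float = 3.0
    beta: float = 2.0
    amplitude: float = 300.0
    baseline: float = 40.0

    @property
    def t_peak(self) -> float:
        return self.t0 + self.alpha * self.beta

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        dt = t - self.t0
        out = np.zeros(t.shape)
        pos = dt > 0
        x = dt[pos] / (self.alpha * self.beta)
        out[pos] = self.amplitude * x**self.alpha * np.exp(self.alpha - dt[pos] / self.beta)
        return self.baseline + out


# ----------------------------------------------------------------- rasterize
def _rasterize_tube_mask(tube: TubeSpec, shape, spacing, origin) -> np.ndarray:
    """Voxelize a tube (main body + branches) onto the grid.

    A voxel is inside the main body when its distance to the nearest dense
    centerline sample is <= the local radius; branches are capsules around
    their straight axes.
    """
    nz, ny, nx = shape
    ds = min(spacing) / 4.0
    pts, s = tube.centerline_curve.sample(ds)
    radii = tube.radius_profile(s)
    rmax = float(radii.max())

    mask = np.zeros(shape, dtype=bool)

    def world_bbox_to_slices(lo, hi, margin):
        lo = np.asarray(lo) - margin
        hi = np.asarray(hi) + margin
        sp_xyz = np.asarray(spacing)[::-1]
        ilo = np.floor((lo - np.asarray(origin)) / sp_xyz).astype(int)
        ihi = np.ceil((hi - np.asarray(origin)) / sp_xyz).astype(int) + 1
        ilo = np.maximum(ilo, 0)
        ihi = np.minimum(ihi, [nx, ny, nz])
        if np.any(ihi <= ilo):
            return None
        # xyz index order -> zyx slices
        return (slice(ilo[2], ihi[2]), slice(ilo[1], ihi[1]), slice(ilo[0], ihi[0]))

    def fill_region(slices, inside_fn):
        zz, yy, xx = np.mgrid[slices]
        idx = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        w = index_to_world(idx, spacing, origin)
        inside = inside_fn(w).reshape(zz.shape)
        mask[slices] |= inside

    # main body
    sl = world_bbox_to_slices(pts.min(axis=0), pts.max(axis=0), rmax + max(spacing))
    if sl is None:
        raise ValueError(f"tube '{tube.name}' lies outside the grid")
    tree = cKDTree(pts)

    def inside_main(w):
        dist, nearest = tree.query(w, k=1, workers=-1)
        return dist <= radii[nearest]

    fill_region(sl, inside_main)

    # side branches: capsules
    for start, end, r in tube.branch_axes():
        bsl = world_bbox_to_slices(np.minimum(start, end), np.maximum(start, end), r + max(spacing))
        if bsl is None:
            raise ValueError(f"branch of tube '{tube.name}' lies outside the grid")
        axis = end - start
        L2 = float(np.dot(axis, axis))

        def inside_branch(w, start=start, axis=axis, L2=L2, r=r):
            t = np.clip((w - start) @ axis / L2, 0.0, 1.0)
            closest = start + t[:, None] * axis
            return np.linalg.norm(w - closest, axis=1) <= r

        fill_region(bsl, inside_branch)

    # tube must not touch the grid boundary (it would be clipped)
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any() \
            or mask[:, :, 0].any() or mask[:, :, -1].any():
        raise ValueError(f"tube '{tube.name}' exits the grid")
    return mask


LABEL_OF = {"artery": LABEL_ARTERY, "vein": LABEL_VEIN, "none": 0}


@dataclass
class PhantomScene:
    """A full synthetic CTP acquisition: tubes + tissue TACs + skull shell."""

    tubes: list
    artery_tac: TACModel = field(default_factory=lambda: TACModel(t0=4, alpha=3, beta=2, amplitude=300))
    vein_tac: TACModel = field(default_factory=lambda: TACModel(t0=12, alpha=4, beta=2, amplitude=250))
    soft_tissue_tac: TACModel = field(default_factory=lambda: TACModel(t0=8, alpha=4, beta=2.5, amplitude=25))
    soft_tissue_center: tuple | None = None  # ellipsoid center, world mm
    soft_tissue_radii: tuple | None = None  # ellipsoid semi-axes, mm
    skull_shell: tuple | None = None  # (center xyz, semi-axes xyz, thickness mm)
    skull_hu: float = 1000.0
    shape: tuple = (64, 64, 64)
    spacing: tuple = (0.5, 0.5, 0.5)
    origin: tuple = (0.0, 0.0, 0.0)
    times: np.ndarray = field(default_factory=lambda: np.arange(20) * 2.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.vein_tac.t_peak <= self.artery_tac.t_peak:
            raise ValueError("vein TAC must peak strictly later than artery TAC")


def rasterize_scene(scene: PhantomScene):
    """Rasterize a scene into (CTPSeries, label volume, ground-truth centerlines).

    Labels: 0 background, 1 artery, 2 vein, 3 soft tissue, 4 skull; a voxel
    gets exactly one label (vessels take precedence over tissue and skull).
    With ``noise_sigma == 0`` every voxel's TAC equals its label's TAC model
    exactly, which downstream tests exploit.
    """
    shape, spacing, origin = scene.shape, scene.spacing, scene.origin
    labels = np.zeros(shape, dtype=np.uint8)

    # skull shell first (lowest precedence)
    if scene.skull_shell is not None:
        center, semi, thick = scene.skull_shell
        zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        w = index_to_world(np.stack([zz, yy, xx], axis=-1), spacing, origin)
        rel_out = (w - np.asarray(center)) / np.asarray(semi)
        rel_in = (w - np.asarray(center)) / (np.asarray(semi) - thick)
        shell = (np.sum(rel_out**2, axis=-1) <= 1.0) & (np.sum(rel_in**2, axis=-1) >= 1.0)
        labels[shell] = LABEL_SKULL

    if scene.soft_tissue_center is not None:
        zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        w = index_to_world(np.stack([zz, yy, xx], axis=-1), spacing, origin)
        rel = (w - np.asarray(scene.soft_tissue_center)) / np.asarray(scene.soft_tissue_radii)
        labels[np.sum(rel**2, axis=-1) <= 1.0] = LABEL_SOFT_TISSUE

    centerlines = {}
    for tube in scene.tubes:
        m = _rasterize_tube_mask(tube, shape, spacing, origin)
        lab = LABEL_OF.get(tube.label, 0)
        if lab:
            labels[m] = lab
        pts, s = tube.centerline_curve.sample(min(spacing) / 2.0)
        centerlines[tube.name] = {"points": pts, "arc_length": s}

    # per-label TACs
    T = len(scene.times)
    values = np.zeros((T,) + tuple(shape), dtype=np.float32)
    tac_of = {
        LABEL_BACKGROUND: None,
        LABEL_ARTERY: scene.artery_tac,
        LABEL_VEIN: scene.vein_tac,
        LABEL_SOFT_TISSUE: scene.soft_tissue_tac,
    }
    for lab, tac in tac_of.items():
        sel = labels == lab
        if not sel.any():
            continue
        curve = tac(scene.times) if tac is not None else np.zeros(T)
        values[:, sel] = curve[:, None].astype(np.float32)
    sel = labels == LABEL_SKULL
    if sel.any():
        values[:, sel] = scene.skull_hu

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        values = values + rng.normal(0.0, scene.noise_sigma, size=values.shape).astype(np.float32)

    series = CTPSeries(values=values, times=scene.times, spacing=spacing, origin=origin)
    return series, labels, centerlines


# ------------------------------------------------- validation tube phantoms
def _branch_direction(tangent, azimuth, polar):
    """Unit branch direction at angle ``polar`` from the tube tangent."""
    t = tangent / np.linalg.norm(tangent)
    ref = np.array([0.0, 1.0, 0.0]) if abs(t[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n1 = np.cross(t, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    radial = np.cos(azimuth) * n1 + np.sin(azimuth) * n2
    return np.cos(polar) * t + np.sin(polar) * radial


def make_deviation_phantom(n_branches: int, seed: int, spacing: float = 0.5,
                           main_radius: float = 3.0, length: float = 45.0):
    """Curved tube with ``n_branches`` side branches, for centerline validation.

    Returns (tube mask volume, reference ParametricCurve, grid geometry dict).
    The reference centerline is the analytic main-tube axis; side branches
    perturb wall-based cross-section centroids, which is exactly what the
    extraction algorithm must resist.
    """
    if n_branches < 0:
        raise ValueError("n_branches must be >= 0")
    rng = np.random.default_rng(seed)
    arc_radius = rng.uniform(35.0, 50.0)
    span = length / arc_radius
    # arc bowing in the x–z plane, axis roughly along z
    th = np.linspace(-span / 2, span / 2, 800)
    pts = np.stack(
        [arc_radius * (1 - np.cos(th)), np.zeros_like(th), arc_radius * np.sin(th)], axis=1
    )
    curve = ParametricCurve(pts)

    branches = []
    if n_branches > 0:
        margin = 8.0
        s_positions = np.linspace(margin, curve.length - margin, n_branches)
        s_positions = s_positions + rng.uniform(-1.5, 1.5, size=n_branches)
        for s in s_positions:
            tang = np.atleast_2d(curve.tangent(s))[0]
            polar = rng.uniform(np.deg2rad(45), np.deg2rad(90))
            azim = rng.uniform(0, 2 * np.pi)
            d = _branch_direction(tang, azim, polar)
            branches.append(
                BranchSpec(
                    attachment_s=float(s),
                    direction=d,
                    length=rng.uniform(8.0, 12.0),
                    radius=main_radius * rng.uniform(0.4, 0.6),
                )
            )

    tube = TubeSpec(
        centerline_curve=curve,
        radius_profile=RadiusProfile(baseline=main_radius),
        side_branches=branches,
        label="none",
        name="main",
    )

    # grid sized to fit tube + branches
    all_pts = [pts]
    for start, end, r in tube.branch_axes():
        all_pts.append(np.stack([start, end]))
    allp = np.concatenate(all_pts, axis=0)
    pad = main_radius * 1.6 + 2.0
    lo = allp.min(axis=0) - pad
    hi = allp.max(axis=0) + pad
    shape_xyz = np.ceil((hi - lo) / spacing).astype(int) + 1
    geom = {
        "shape": (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])),
        "spacing": (spacing, spacing, spacing),
        "origin": tuple(float(v) for v in lo),
    }
    mask = _rasterize_tube_mask(tube, geom["shape"], geom["spacing"], geom["origin"])
    return mask, curve, geom


def make_stenosis_phantom(seed: int, spacing: float = 0.5, main_radius: float = 3.0,
                          length: float = 60.0, stenosis_factor: float = 0.5,
                          dilation_factor: float = 1.5,
                          stenosis_interval=None, dilation_interval=None):
    """Gently curved tube with one stenosis and one dilation at known intervals.

    Returns (tube mask, stenosis interval, dilation interval, reference curve,
    grid geometry).  Intervals are (start_s, end_s) in mm of arc length along
    the analytic axis; overlapping intervals raise.
    """
    if stenosis_factor > 0.6:
        raise ValueError("stenosis radius factor must be <= 0.6")
    if dilation_factor < 1.4:
        raise ValueError("dilation radius factor must be >= 1.4")
    rng = np.random.default_rng(seed)
    arc_radius = rng.uniform(80.0, 120.0)
    span = length / arc_radius
    th = np.linspace(-span / 2, span / 2, 800)
    pts = np.stack(
        [arc_radius * (1 - np.cos(th)), np.zeros_like(th), arc_radius * np.sin(th)], axis=1
    )
    curve = ParametricCurve(pts)
    L = curve.length

    feat_len = 10.0
    if stenosis_interval is None or dilation_interval is None:
        # two non-overlapping slots in [10, L-10], order randomized
        gap = 6.0
        lo0 = 10.0
        hi1 = L - 10.0 - feat_len
        first = rng.uniform(lo0, hi1 - feat_len - gap)
        second = rng.uniform(first + feat_len + gap, hi1)
        if rng.random() < 0.5:
            stenosis_interval = (first, first + feat_len)
            dilation_interval = (second, second + feat_len)
        else:
            dilation_interval = (first, first + feat_len)
            stenosis_interval = (second, second + feat_len)
    s0, s1 = stenosis_interval
    d0, d1 = dilation_interval
    if max(s0, d0) < min(s1, d1):
        raise ValueError("stenosis and dilation intervals overlap")

    profile = RadiusProfile(
        baseline=main_radius,
        features=[(s0, s1, stenosis_factor), (d0, d1, dilation_factor)],
    )
    tube = TubeSpec(centerline_curve=curve, radius_profile=profile, name="stenosed")

    pad = main_radius * dilation_factor + 3.0
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape_xyz = np.ceil((hi - lo) / spacing).astype(int) + 1
    geom = {
        "shape": (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])),
        "spacing": (spacing, spacing, spacing),
        "origin": tuple(float(v) for v in lo),
    }
    mask = _rasterize_tube_mask(tube, geom["shape"], geom["spacing"], geom["origin"])
    return mask, tuple(stenosis_interval), tuple(dilation_interval), curve, geom


def default_ctp_scene(noise_sigma: float = 0.0, seed: int = 0, with_skull: bool = True,
                      with_tissue: bool = True) -> PhantomScene:
    """Desk-scale CTP scene: straight artery + vein tubes inside an optional
    skull shell, with optional soft-tissue ellipsoid between them."""
    ext = 32.0  # mm cube
    artery = TubeSpec(
        centerline_curve=ParametricCurve.line([11.0, 16.0, 5.0], [11.0, 16.0, 27.0]),
        radius_profile=RadiusProfile(baseline=2.0),
        label="artery",
        name="artery",
    )
    vein = TubeSpec(
        centerline_curve=ParametricCurve.line([21.0, 16.0, 5.0], [21.0, 16.0, 27.0]),
        radius_profile=RadiusProfile(baseline=2.5),
        label="vein",
        name="vein",
    )
    return PhantomScene(
        tubes=[artery, vein],
        soft_tissue_center=(16.0, 16.0, 16.0) if with_tissue else None,
        soft_tissue_radii=(3.0, 3.0, 8.0) if with_tissue else None,
        skull_shell=((16.0, 16.0, 16.0), (15.0, 15.0, 15.0), 1.5) if with_skull else None,
        shape=(64, 64, 64),
        spacing=(0.5, 0.5, 0.5),
        origin=(0.0, 0.0, 0.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def write_ground_truth_json(path, payload: dict) -> None:
    """JSON sidecar with phantom ground truth (arrays become lists)."""

    def _convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_convert(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(_convert(payload), fh, indent=1)
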