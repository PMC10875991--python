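"""Core data container for 4D CT-perfusion series and voxel/world geometry.

Arrays follow the (frame, z, y, x) axis order throughout the package; voxel
spacing is stored as (dz, dy, dx) in mm and the world origin as (x0, y0, z0)
in mm.  World coordinates are always (x, y, z) mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["CTPSeries", "index_to_world", "world_to_index"]


def index_to_world(indices_zyx: np.ndarray, spacing: tuple, origin: tuple) -> np.ndarray:
    """Map fractional (z, y, x) voxel indices to (x, y, z) world mm."""
    idx = np.asarray(indices_zyx, dtype=float)
    sp = np.asarray(spacing, dtype=float)  # (dz, dy, dx)
    return np.asarray(origin, dtype=float) + idx[..., ::-1] * sp[::-1]


def world_to_index(points_xyz: np.ndarray, spacing: tuple, origin: tuple) -> np.ndarray:
    """Map (x, y, z) world mm to fractional (z, y, x) voxel indices."""
    pts = np.asarray(points_xyz, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    rel = (pts - np.asarray(origin, dtype=float)) / sp[::-1]
    return rel[..., ::-1]


@dataclass
class CTPSeries:
    """A registered 4D CT-perfusion series.

    Parameters
    ----------
    values : ndarray, shape (T, nz, ny, nx)
        Attenuation in Hounsfield units, one 3D volume per time frame.
        All frames share a single voxel grid (inputs are assumed rigidly
        registered before they reach this package).
    times : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.
    spacing : tuple of float
        Voxel size (dz, dy, dx) in mm.
    origin : tuple of float
        World (x, y, z) mm of voxel (0, 0, 0).
    """

    values: np.ndarray
    times: np.ndarray
    spacing: tuple = (0.5, 0.5, 0.5)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"values must be 4D (frame, z, y, x), got {self.values.ndim}D")
        if self.times.ndim != 1 or len(self.times) != self.values.shape[0]:
            raise ValueError("times must be 1D with one entry per frame")
        if len(self.times) < 3:
            raise ValueError("a CTP series needs at least 3 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def frame_count(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple:
        """Spatial shape (nz, ny, nx)."""
        return self.values.shape[1:]

    def index_to_world(self, indices_zyx) -> np.ndarray:
        return index_to_world(indices_zyx, self.spacing, self.origin)

    def world_to_index(self, points_xyz) -> np.ndarray:
        return world_to_index(points_xyz, self.spacing, self.origin)

    # ---------------------------------------------------------------- NIfTI
    def _affine(self) -> np.ndarray:
        dz, dy, dx = self.spacing
        aff = np.diag([dx, dy, dz, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        """Pack as a 4D NIfTI image (x, y, z, t data order)."""
        data = np.transpose(self.values, (3, 2, 1, 0))
        img = nib.Nifti1Image(np.ascontiguousarray(data), self._affine())
        dt = float(np.mean(np.diff(self.times))) if self.frame_count > 1 else 1.0
        img.header["pixdim"][4] = dt
        img.header.set_xyzt_units(xyz="mm", t="sec")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, times=None) -> "CTPSeries":
        """Load a 4D NIfTI series.

        ``times`` overrides frame timing; otherwise uniform timing at the
        header's TR (pixdim[4], default 1 s) is assumed.
        """
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"expected a 4D NIfTI, got {data.ndim}D")
        values = np.transpose(data, (3, 2, 1, 0)).astype(np.float32)
        aff = img.affine
        spacing = (abs(float(aff[2, 2])), abs(float(aff[1, 1])), abs(float(aff[0, 0])))
        origin = tuple(float(v) for v in aff[:3, 3])
        if times is None:
            dt = float(img.header["pixdim"][4]) or 1.0
            times = np.arange(values.shape[0]) * dt
        return cls(values=values, times=np.asarray(times, dtype=float), spacing=spacing, origin=origin)


def save_volume(volume: np.ndarray, spacing, origin, path) -> None:
    """Write a 3D (z, y, x) array as NIfTI with the given geometry."""
    dz, dy, dx = spacing
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = origin
    data = np.ascontiguousarray(np.transpose(np.asarray(volume), (2, 1, 0)))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, aff), str(path))


def load_volume(path):
    """Read a 3D NIfTI; returns (values (z,y,x), spacing (dz,dy,dx), origin (x,y,z))."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got {data.ndim}D")
    values = np.transpose(data, (2, 1, 0))
    aff = img.affine
    spacing = (abs(float(aff[2, 2])), abs(float(aff[1, 1])), abs(float(aff[0, 0])))
    origin = tuple(float(v) for v in aff[:3, 3])
    return values, spacing, origin
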