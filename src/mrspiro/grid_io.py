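"""Core spatial types and file I/O.

Conventions used throughout the package:

* Axes are anatomical and fixed for a whole pipeline run:
  ``x`` = superior-inferior, ``y`` = left-right, ``z`` = anterior-posterior.
* World coordinates are in mm; voxel indices are 0-based; index -> world is
  ``origin + index * spacing`` (axis-aligned grids, no shear/rotation).
* Displacement fields are Lagrangian forward: ``u(R, t_n)`` is the displacement
  of the tissue element located at reference (end-expiration) world coordinate
  ``R``, so its position at bin ``n`` is ``r = R + u(R, t_n)``.
* On disk, volumes/masks/maps are NIfTI-1; displacement fields are 4D NIfTI
  with the vector component last in order (x, y, z); symmetric tensors are
  written as 4D NIfTI with component order (xx, yy, zz, xy, yz, xz); bin
  timing tables are CSV with columns ``bin_index,time_s,phase``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

AXIS_NAMES = ("superior-inferior", "left-right", "anterior-posterior")

#: component order used for symmetric 3x3 tensors written as 6-channel volumes
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "yz", "xz")
_TENSOR_IDX = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


class GeometryError(ValueError):
    """Raised when volumes/fields that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned 3D sampling grid in world (mm) coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (diagonal; no rotation by construction)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical box size spanned by voxel centres along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays X, Y, Z, each of shape ``self.shape``."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for an (..., 3) array of world points."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def matches(self, other: "ImageGrid", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _require_same_grid(a: ImageGrid, b: ImageGrid, what: str) -> None:
    if not a.matches(b):
        raise GeometryError(f"{what}: grids differ ({a} vs {b})")


@dataclass
class VolumeSeries:
    """Motion-binned intensity volumes on a common grid.

    ``data`` has shape (n_bins, nx, ny, nz); ``reference_bin`` designates the
    end-expiration (deflated lung) state used as the registration reference.
    """

    grid: ImageGrid
    data: np.ndarray
    reference_bin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[1:] != self.grid.shape:
            raise GeometryError(
                f"data shape {self.data.shape} incompatible with grid {self.grid.shape}"
            )
        if self.n_bins < 3:
            raise ValueError(
                f"need at least 3 bins for temporal differencing, got {self.n_bins}"
            )
        if not 0 <= self.reference_bin < self.n_bins:
            raise ValueError("reference_bin out of range")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]


@dataclass
class DisplacementField4D:
    """Lagrangian forward displacement u(R, t_n) per bin, in mm.

    ``u`` has shape (n_bins, nx, ny, nz, 3). The field at ``reference_bin`` is
    identically zero: the reference tissue configuration is end-expiration.
    """

    grid: ImageGrid
    u: np.ndarray
    reference_bin: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 5 or self.u.shape[1:4] != self.grid.shape or self.u.shape[4] != 3:
            raise GeometryError(
                f"u shape {self.u.shape} incompatible with grid {self.grid.shape}"
            )
        if not 0 <= self.reference_bin < self.n_bins:
            raise ValueError("reference_bin out of range")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        if np.max(np.abs(self.u[self.reference_bin])) > 1e-9:
            raise ValueError("displacement at the reference bin must be zero")

    @property
    def n_bins(self) -> int:
        return self.u.shape[0]


@dataclass
class LungMask:
    """Boolean lung membership on a grid, with optional integer region labels."""

    grid: ImageGrid
    membership: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.membership.shape} != grid {self.grid.shape}"
            )
        if not self.membership.any():
            raise ValueError("lung mask is empty")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.grid.shape:
                raise GeometryError("label volume shape != grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


@dataclass
class BinTiming:
    """Time-stamps and respiratory phase labels of the motion bins.

    Times are seconds measured from end-expiration within the (time-averaged)
    respiratory cycle, so the reference phase sits at t = 0 and all t_n lie in
    [0, period_s). ``phase`` holds "insp"/"exp" per bin.
    """

    times: np.ndarray
    phase: np.ndarray
    period_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.times.ndim != 1 or self.phase.shape != self.times.shape:
            raise ValueError("times and phase must be 1D arrays of equal length")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if np.any(self.times < 0) or np.any(self.times >= self.period_s):
            raise ValueError("bin times must lie in [0, period)")
        bad = set(self.phase) - {"insp", "exp"}
        if bad:
            raise ValueError(f"unknown phase labels: {bad}")

    @property
    def n_bins(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_img(img: nib.Nifti1Image) -> ImageGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise GeometryError("only axis-aligned (diagonal-affine) NIfTI grids are supported")
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageGrid(shape=tuple(img.shape[:3]), spacing=spacing, origin=origin)


def _nifti(data: np.ndarray, grid: ImageGrid) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(grid.spacing + (1.0,) * (data.ndim - 3))
    return img


def read_volume(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), _grid_from_img(img)


def read_volume_series(
    paths: Sequence[str | Path], reference_bin: int = 0
) -> VolumeSeries:
    """Load per-bin volumes (one NIfTI per bin, ordered by bin index).

    All files must share shape, spacing and origin; a mismatch raises
    :class:`GeometryError` naming the offending file.
    """
    if len(paths) < 3:
        raise ValueError(f"need at least 3 bin volumes, got {len(paths)}")
    vols = []
    grid: ImageGrid | None = None
    for p in paths:
        data, g = read_volume(p)
        if data.ndim != 3:
            raise GeometryError(f"{p}: expected a 3D volume, got shape {data.shape}")
        if grid is None:
            grid = g
        elif not grid.matches(g):
            raise GeometryError(
                f"{p}: grid {g} does not match first volume's grid {grid}"
            )
        vols.append(data)
    return VolumeSeries(grid=grid, data=np.stack(vols), reference_bin=reference_bin)


def write_volume_series(series: VolumeSeries, directory: str | Path,
                        prefix: str = "bin") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in range(series.n_bins):
        p = directory / f"{prefix}_{n:02d}.nii"
        nib.save(_nifti(series.data[n], series.grid), str(p))
        paths.append(p)
    return paths


def read_mask(path: str | Path) -> LungMask:
    data, grid = read_volume(path)
    return LungMask(grid=grid, membership=data > 0.5)


def write_mask(mask: LungMask, path: str | Path) -> None:
    nib.save(_nifti(mask.membership.astype(np.uint8), mask.grid), str(path))


def write_map(data: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    """Write a scalar map (nx,ny,nz), vector field (...,3) or symmetric tensor
    map (...,3,3) as NIfTI.

    Tensor maps are stored as 6-component volumes in the order
    ``(xx, yy, zz, xy, yz, xz)``.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 5 and data.shape[-2:] == (3, 3):
        data = tensor_to_components(data)
    if data.shape[:3] != grid.shape:
        raise GeometryError(f"map shape {data.shape} incompatible with grid {grid.shape}")
    nib.save(_nifti(data, grid), str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    return read_volume(path)


def tensor_to_components(t: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensor -> (..., 6) in order (xx,yy,zz,xy,yz,xz)."""
    return np.stack([t[..., i, j] for i, j in _TENSOR_IDX], axis=-1)


def components_to_tensor(c: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tensor_to_components`."""
    t = np.zeros(c.shape[:-1] + (3, 3), dtype=c.dtype)
    for k, (i, j) in enumerate(_TENSOR_IDX):
        t[..., i, j] = c[..., k]
        t[..., j, i] = c[..., k]
    return t


# ---------------------------------------------------------------------------
# Displacement fields and convention conversion
# ---------------------------------------------------------------------------

def _interp_field(field: np.ndarray, grid: ImageGrid, points_world: np.ndarray,
                  ) -> np.ndarray:
    """Trilinear sample of an (nx,ny,nz,3) field at (...,3) world points."""
    idx = grid.world_to_index(points_world)
    coords = [idx[..., i] for i in range(3)]
    out = np.empty(points_world.shape, dtype=float)
    for c in range(3):
        out[..., c] = map_coordinates(
            field[..., c], coords, order=1, mode="nearest"
        )
    return out


def backward_to_forward(
    w: np.ndarray,
    grid: ImageGrid,
    tol_mm: float = 0.01,
    max_iter: int = 50,
) -> np.ndarray:
    """Convert a backward displacement field to the Lagrangian forward one.

    The backward convention gives, on the deformed (bin) grid, the displacement
    ``w(y)`` back to the reference: ``R = y + w(y)``. The forward field
    satisfies the fixed-point relation ``u(R) = -w(R + u(R))``, solved here by
    iteration with trilinear interpolation of ``w``.
    """
    X, Y, Z = grid.coordinates()
    R = np.stack([X, Y, Z], axis=-1)
    u = -np.asarray(w, dtype=float).copy()
    for _ in range(max_iter):
        u_new = -_interp_field(w, grid, R + u)
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol_mm:
            break
    return u


def forward_to_backward(
    u: np.ndarray,
    grid: ImageGrid,
    tol_mm: float = 0.01,
    max_iter: int = 50,
) -> np.ndarray:
    """Inverse conversion (used mainly to fabricate registration-style input)."""
    X, Y, Z = grid.coordinates()
    Ygrid = np.stack([X, Y, Z], axis=-1)
    w = -np.asarray(u, dtype=float).copy()
    for _ in range(max_iter):
        w_new = -_interp_field(u, grid, Ygrid + w)
        delta = np.max(np.abs(w_new - w))
        w = w_new
        if delta < tol_mm:
            break
    return w


def read_displacement_fields(
    paths: Sequence[str | Path],
    convention: str,
    reference_bin: int = 0,
    mask: LungMask | None = None,
    tol_mm: float = 0.01,
    max_iter: int = 50,
) -> DisplacementField4D:
    """Load one vector NIfTI per non-reference bin and assemble a 4D field.

    ``convention`` is ``"lagrangian_forward"`` (fields are used as-is) or
    ``"registration_backward"`` (each bin's field is inverted to the forward
    convention by fixed-point iteration). The reference bin is inserted as an
    exact zero field. NaNs inside the mask are a hard error.
    """
    if convention not in ("lagrangian_forward", "registration_backward"):
        raise ValueError(
            f"unknown displacement convention {convention!r}; expected "
            "'lagrangian_forward' or 'registration_backward'"
        )
    n_bins = len(paths) + 1
    fields: list[np.ndarray | None] = [None] * n_bins
    grid: ImageGrid | None = None
    non_ref = [n for n in range(n_bins) if n != reference_bin]
    for n, p in zip(non_ref, paths):
        data, g = read_volume(p)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise GeometryError(f"{p}: expected a (nx,ny,nz,3) vector volume")
        if grid is None:
            grid = g
        elif not grid.matches(g):
            raise GeometryError(f"{p}: grid mismatch with first field")
        if mask is not None:
            bad = ~np.isfinite(data[mask.membership])
            if bad.any():
                locs = np.argwhere(~np.isfinite(data).all(axis=-1) & mask.membership)
                raise ValueError(
                    f"{p}: {int(bad.sum())} non-finite displacement samples inside "
                    f"the lung mask (first voxels: {locs[:5].tolist()})"
                )
        data = np.nan_to_num(data, nan=0.0)
        if convention == "registration_backward":
            data = backward_to_forward(data, grid, tol_mm=tol_mm, max_iter=max_iter)
        fields[n] = data
    fields[reference_bin] = np.zeros(grid.shape + (3,))
    return DisplacementField4D(grid=grid, u=np.stack(fields), reference_bin=reference_bin)


def write_displacement_fields(
    field: DisplacementField4D,
    directory: str | Path,
    prefix: str = "disp",
    include_reference: bool = False,
) -> list[Path]:
    """One (nx,ny,nz,3) NIfTI per bin.

    By default the identically-zero reference bin is skipped (bin numbering in
    the filenames is preserved), matching the adapter contract of
    :func:`read_displacement_fields` which re-inserts it on load.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for n in range(field.n_bins):
        if n == field.reference_bin and not include_reference:
            continue
        p = directory / f"{prefix}_{n:02d}.nii"
        write_map(field.u[n], field.grid, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Bin timing CSV
# ---------------------------------------------------------------------------

def read_bin_timing(path: str | Path) -> BinTiming:
    df = pd.read_csv(path)
    required = {"bin_index", "time_s", "phase"}
    if not required.issubset(df.columns):
        raise ValueError(f"timing table must have columns {sorted(required)}")
    df = df.sort_values("bin_index")
    period = float(df.attrs.get("period_s", 0.0))
    if "period_s" in df.columns:
        period = float(df["period_s"].iloc[0])
    if period <= 0:
        raise ValueError("timing table must carry a positive period_s column")
    return BinTiming(
        times=df["time_s"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
        period_s=period,
    )


def write_bin_timing(timing: BinTiming, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_index": np.arange(timing.n_bins),
            "time_s": timing.times,
            "phase": timing.phase,
            "period_s": timing.period_s,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 run bundle
# ---------------------------------------------------------------------------

def write_bundle(path: str | Path, grid: ImageGrid, arrays: dict[str, np.ndarray],
                 attrs: dict | None = None) -> None:
    """Aggregate all pipeline products of one run into a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["spacing_mm"] = grid.spacing
        f.attrs["origin_mm"] = grid.origin
        f.attrs["shape"] = grid.shape
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))


def read_bundle(path: str | Path) -> tuple[ImageGrid, dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as f:
        grid = ImageGrid(
            shape=tuple(int(n) for n in f.attrs["shape"]),
            spacing=tuple(float(s) for s in f.attrs["spacing_mm"]),
            origin=tuple(float(o) for o in f.attrs["origin_mm"]),
        )
        arrays = {k: f[k][()] for k in f.keys()}
        attrs = {k: f.attrs[k] for k in f.attrs if k not in ("shape", "spacing_mm", "origin_mm")}
    return grid, arrays, attrs
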