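"""Volumetric data model, file I/O, resampling/cropping and lung segmentation.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based and arrays are indexed ``values[ix, iy, iz]``; the
  axial plane is (x, y) at fixed z.
* The physical position of voxel (i, j, k) is ``origin + index * spacing`` in
  millimetres; spacing is strictly positive on each axis.
* Phase series hold exactly ten respiratory phases T00..T90, where T00 is the
  peak-inhale anatomy and T50 the peak-exhale anatomy.  The exhale phase is the
  reference grid for ventilation maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import FormatError, GeometryError, ParameterError, SegmentationError

__all__ = [
    "Grid",
    "Volume",
    "Mask",
    "PhaseSeries",
    "PHASE_LABELS",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "crop_center",
    "segment_lungs",
]

PHASE_LABELS = tuple(f"T{10 * p:02d}" for p in range(10))

#: tolerance (mm) for declaring two grids geometrically identical
GEOM_ATOL_MM = 1e-6


@dataclass(frozen=True)
class Grid:
    """Shape + spacing + origin: the geometry of a voxel lattice."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be 3-D with dims >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical interval spanned by voxel centers on each axis, in mm."""
        return tuple(
            (o, o + (n - 1) * s) for o, n, s in zip(self.origin, self.shape, self.spacing)
        )

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of all voxels along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def close_to(self, other: "Grid", atol: float = GEOM_ATOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol, rtol=0)
            and np.allclose(self.origin, other.origin, atol=atol, rtol=0)
        )


def _check_grid_values(values: np.ndarray, grid: Grid, boolean: bool) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise FormatError(f"expected a 3-D array, got {values.ndim}-D with shape {values.shape}")
    if values.shape != grid.shape:
        raise GeometryError(f"array shape {values.shape} does not match grid shape {grid.shape}")
    if boolean:
        return values.astype(bool)
    values = values.astype(np.float64, copy=False)
    if not np.all(np.isfinite(values)):
        raise FormatError("volume contains NaN or Inf values")
    return values


@dataclass
class Volume:
    """A 3-D scalar grid with physical spacing and origin.

    ``intensity_kind`` is one of ``"HU"`` (calibrated Hounsfield units),
    ``"dimensionless"`` (e.g. ventilation) or ``"counts"`` (SPECT-like).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "HU"

    def __post_init__(self) -> None:
        grid = Grid(np.asarray(self.values).shape, tuple(self.spacing), tuple(self.origin))
        self.values = _check_grid_values(self.values, grid, boolean=False)
        self.spacing = grid.spacing
        self.origin = grid.origin
        if self.intensity_kind not in ("HU", "dimensionless", "counts"):
            raise ParameterError(f"unknown intensity_kind {self.intensity_kind!r}")

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, intensity_kind: str | None = None) -> "Volume":
        """New Volume on the same grid with different voxel values."""
        return Volume(
            values, self.spacing, self.origin,
            self.intensity_kind if intensity_kind is None else intensity_kind,
        )


@dataclass
class Mask:
    """Boolean voxel mask sharing the geometry of its parent Volume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = Grid(np.asarray(self.values).shape, tuple(self.spacing), tuple(self.origin))
        self.values = _check_grid_values(self.values, grid, boolean=True)
        self.spacing = grid.spacing
        self.origin = grid.origin

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.spacing, self.origin)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if not self.values.any():
            raise SegmentationError(f"{what} is empty")


@dataclass
class PhaseSeries:
    """Ordered ten-phase set of co-registered volumes, T00..T90.

    T00 is peak inhale and T50 peak exhale; all phases share one grid.
    """

    phases: list[Volume]

    def __post_init__(self) -> None:
        if len(self.phases) != 10:
            raise FormatError(f"a phase series has exactly 10 phases, got {len(self.phases)}")
        g0 = self.phases[0].grid
        for lab, vol in zip(PHASE_LABELS, self.phases):
            if not vol.grid.close_to(g0):
                raise GeometryError(f"phase {lab} geometry differs from T00")

    @property
    def grid(self) -> Grid:
        return self.phases[0].grid

    def __getitem__(self, label: str) -> Volume:
        try:
            return self.phases[PHASE_LABELS.index(label)]
        except ValueError:
            raise KeyError(f"unknown phase label {label!r}") from None

    @property
    def inhale(self) -> Volume:
        return self["T00"]

    @property
    def exhale(self) -> Volume:
        return self["T50"]


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 and MetaImage, via SimpleITK)
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, intensity_kind: str = "HU") -> Volume:
    """Read a 3-D NIfTI or MetaImage file into a Volume.

    Spacing and origin come from the file header.  SimpleITK returns arrays in
    (z, y, x) index order; they are transposed to this package's (x, y, z).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if img.GetDimension() != 3 or arr.ndim != 3:
        ndim = max(img.GetDimension(), arr.ndim)
        raise FormatError(f"expected a 3-D scalar image, {path} is {ndim}-D")
    values = arr.transpose(2, 1, 0)
    return Volume(values, img.GetSpacing(), img.GetOrigin(), intensity_kind)


def write_volume(volume: Volume | Mask, path: str | Path) -> None:
    """Write a Volume (or Mask, as uint8) to NIfTI or MetaImage."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    values = volume.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def _index_coordinates(target: Grid, source: Grid) -> list[np.ndarray]:
    """Source-grid fractional index coordinates of the target voxel centers."""
    axes = [
        (target.axis_coordinates(ax) - source.origin[ax]) / source.spacing[ax]
        for ax in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=False)


def resample_to_grid(
    source: Volume,
    target: Grid,
    interpolation: str = "trilinear",
    fill_value: float | None = None,
) -> Volume:
    """Resample ``source`` onto ``target`` geometry.

    ``interpolation`` is ``"nearest"`` or ``"trilinear"``.  Voxels mapping
    outside the source support take ``fill_value`` (default: the source
    minimum, an air-like background for CT).
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    for (slo, shi), (tlo, thi) in zip(source.grid.extent, target.extent):
        if thi < slo or tlo > shi:
            raise GeometryError("source and target extents do not overlap")
    if fill_value is None:
        fill_value = float(source.values.min())
    coords = np.stack(_index_coordinates(target, source.grid))
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        source.values, coords, order=order, mode="constant", cval=fill_value
    )
    return Volume(out, target.spacing, target.origin, source.intensity_kind)


def crop_center(volume: Volume, in_plane_size: tuple[int, int]) -> Volume:
    """Crop to (nx', ny') in the axial plane, centered, keeping all z slices.

    The extra-voxel tie is broken toward the low index: the offset on each
    axis is ``(n - n') // 2``.  The origin shifts so retained voxels keep
    their physical coordinates.
    """
    nx, ny, nz = volume.shape
    nxp, nyp = int(in_plane_size[0]), int(in_plane_size[1])
    if nxp > nx or nyp > ny:
        raise GeometryError(f"crop size {in_plane_size} exceeds in-plane shape {(nx, ny)}")
    ox, oy = (nx - nxp) // 2, (ny - nyp) // 2
    values = volume.values[ox : ox + nxp, oy : oy + nyp, :]
    origin = (
        volume.origin[0] + ox * volume.spacing[0],
        volume.origin[1] + oy * volume.spacing[1],
        volume.origin[2],
    )
    return Volume(values.copy(), volume.spacing, origin, volume.intensity_kind)


def crop_center_mask(mask: Mask, in_plane_size: tuple[int, int]) -> Mask:
    """crop_center for boolean masks."""
    vol = Volume(mask.values.astype(np.float64), mask.spacing, mask.origin, "dimensionless")
    cropped = crop_center(vol, in_plane_size)
    return Mask(cropped.values > 0.5, cropped.spacing, cropped.origin)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_lungs(
    volume: Volume,
    hu_low: float = -999.0,
    hu_high: float = -250.0,
    remove_airways: bool = True,
    airway_corridor_halfwidth: float = 0.15,
) -> Mask:
    """Lung parenchyma segmentation by a closed HU window [hu_low, hu_high].

    After thresholding, 26-connected components whose centroid lies inside a
    midline corridor (half-width ``airway_corridor_halfwidth`` as a fraction
    of the x-extent, centered on the volume x-midline) are dropped as
    trachea/main-stem bronchi; of the remainder, the two largest components
    are kept.
    """
    if volume.intensity_kind != "HU":
        raise ParameterError("segment_lungs requires an HU volume")
    thresh = (volume.values >= hu_low) & (volume.values <= hu_high)
    labels, n = ndimage.label(thresh, structure=_CONN26)
    if n == 0:
        raise SegmentationError("no voxels in the HU window")
    sizes = ndimage.sum_labels(thresh, labels, index=np.arange(1, n + 1))
    keep = np.arange(1, n + 1)
    if remove_airways:
        centroids = ndimage.center_of_mass(thresh, labels, index=keep)
        x_mid = (volume.shape[0] - 1) / 2.0
        half = airway_corridor_halfwidth * volume.shape[0]
        lateral = np.array([abs(c[0] - x_mid) > half for c in centroids])
        keep, sizes = keep[lateral], sizes[lateral]
    if keep.size == 0:
        raise SegmentationError("all components removed as airway candidates")
    largest = keep[np.argsort(sizes)[::-1][:2]]
    mask = np.isin(labels, largest)
    out = Mask(mask, volume.spacing, volume.origin)
    out.require_nonempty("lung mask")
    return out
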