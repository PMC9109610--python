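"""DIR-based ventilation estimators and the shared post-processing chain.

Two classical estimators derive a ventilation map from the displacement field
between peak exhale (T50, the reference grid) and peak inhale (T00):

* Jacobian method (JAC): ventilation = det(I + grad u) - 1, the local volume
  expansion ratio minus one.
* Density-change method (HU): under the air/tissue density model, regional
  air-volume change follows from the inhale/exhale HU pair of corresponding
  tissue,

      VI_HU = 1000 * (H_voi - HU_T50) / (HU_T50 * (1000 + H_voi)),

  where H_voi is the mean inhale HU over the exhale voxel's mapped volume of
  interest.

Post-processing applied to every ventilation image regardless of provenance:
multiply by the exhale lung mask, normalize by the 90th percentile of in-mask
values, median-filter with a 9x9x9 box, and re-mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np
from scipy import ndimage

from .errors import DataError, GeometryError, ParameterError
from .imagecore import Mask, Volume
from .registration import VectorField, jacobian_determinant

__all__ = [
    "VentilationImage",
    "ventilation_jacobian",
    "voi_mean_inhale",
    "ventilation_density_change",
    "postprocess",
]

PROVENANCES = ("HU", "JAC", "DL", "REF")


@dataclass
class VentilationImage:
    """Masked dimensionless ventilation map on the exhale (T50) geometry.

    ``provenance`` records how the map was obtained: HU (density change), JAC
    (Jacobian), DL (learned regressor) or REF (reference, e.g. SPECT-like).
    """

    values: np.ndarray
    mask: Mask
    provenance: str
    normalized: bool = False
    info: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.provenance not in PROVENANCES:
            raise ParameterError(f"provenance must be one of {PROVENANCES}")
        if self.values.shape != self.mask.values.shape:
            raise GeometryError(
                f"ventilation shape {self.values.shape} != mask shape {self.mask.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("ventilation image contains non-finite values")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.mask.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.mask.origin

    def as_volume(self) -> Volume:
        return Volume(self.values, self.mask.spacing, self.mask.origin, "dimensionless")

    def in_mask(self) -> np.ndarray:
        """1-D array of the in-mask ventilation values."""
        return self.values[self.mask.values]


def _check_exhale_grid(dvf: VectorField, mask: Mask) -> None:
    if not dvf.grid.close_to(mask.grid):
        raise GeometryError("displacement field and exhale mask grids differ")


def ventilation_jacobian(dvf: VectorField, exhale_mask: Mask) -> VentilationImage:
    """Jacobian ventilation: det(I + grad u) - 1 at masked voxels, 0 elsewhere."""
    _check_exhale_grid(dvf, exhale_mask)
    exhale_mask.require_nonempty("exhale lung mask")
    jac = jacobian_determinant(dvf)
    values = np.where(exhale_mask.values, jac.values - 1.0, 0.0)
    return VentilationImage(values, exhale_mask, "JAC")


# ---------------------------------------------------------------------------
# Density-change method
# ---------------------------------------------------------------------------

def _sample_components(dvf: VectorField, positions: np.ndarray) -> np.ndarray:
    """Trilinearly sample the field (mm) at physical positions (3, n)."""
    out = np.empty_like(positions)
    g = dvf.grid
    coords = np.empty_like(positions)
    for ax in range(3):
        coords[ax] = (positions[ax] - g.origin[ax]) / g.spacing[ax]
    for c in range(3):
        out[c] = ndimage.map_coordinates(dvf.u[c], coords, order=1, mode="nearest")
    return out


_CORNER_SIGNS = np.array(list(product((-0.5, 0.5), repeat=3))).T  # (3, 8)

#: cap on VOI bounding-box span per axis, in inhale voxels
_MAX_VOI_SPAN = 6


def _voi_mean_inhale_bulk(
    inhale: Volume, dvf: VectorField, indices: np.ndarray
) -> np.ndarray:
    """Mean inhale HU over the warped-cell VOI for each exhale voxel index.

    ``indices`` is (n, 3) integer exhale voxel indices.  The VOI of an exhale
    voxel is the set of inhale-grid voxel centers inside the axis-aligned
    bounding box of the voxel cell's 8 corners mapped by x + u(x); if empty,
    falls back to trilinear sampling of the inhale image at the mapped voxel
    center.
    """
    g = dvf.grid
    spacing = np.asarray(g.spacing)[:, None]
    origin = np.asarray(g.origin)[:, None]
    centers = origin + indices.T * spacing  # (3, n)
    n = centers.shape[1]

    # map the 8 cell corners through x + u(x)
    corners = centers[:, :, None] + _CORNER_SIGNS[:, None, :] * spacing[:, :, None]
    flat = corners.reshape(3, -1)
    mapped = (flat + _sample_components(dvf, flat)).reshape(3, n, 8)
    bmin, bmax = mapped.min(axis=2), mapped.max(axis=2)

    isp = np.asarray(inhale.spacing)[:, None]
    iorg = np.asarray(inhale.origin)[:, None]
    lo = np.ceil((bmin - iorg) / isp - 1e-9).astype(np.int64)
    hi = np.floor((bmax - iorg) / isp + 1e-9).astype(np.int64)
    hi = np.minimum(hi, lo + _MAX_VOI_SPAN - 1)

    shape = np.asarray(inhale.shape)[:, None]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    span = (hi - lo).max(axis=1).clip(min=0) + 1
    vals = inhale.values
    for off in product(*(range(int(s)) for s in span)):
        offv = np.asarray(off)[:, None]
        idx = lo + offv
        valid = np.all((offv <= hi - lo) & (idx >= 0) & (idx < shape), axis=0)
        if not valid.any():
            continue
        sums[valid] += vals[idx[0, valid], idx[1, valid], idx[2, valid]]
        counts[valid] += 1

    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    empty = counts == 0
    if empty.any():
        pos = centers[:, empty] + _sample_components(dvf, centers[:, empty])
        coords = (pos - iorg) / isp
        means[empty] = ndimage.map_coordinates(vals, coords, order=1, mode="nearest")
    return means


def voi_mean_inhale(
    inhale: Volume, dvf: VectorField, exhale_voxel: tuple[int, int, int]
) -> float:
    """Mean inhale HU over the mapped volume of interest of one exhale voxel."""
    idx = np.asarray([exhale_voxel], dtype=np.int64)
    return float(_voi_mean_inhale_bulk(inhale, dvf, idx)[0])


def ventilation_density_change(
    inhale: Volume,
    exhale: Volume,
    dvf: VectorField,
    exhale_mask: Mask,
    guard_fraction: float = 0.10,
) -> VentilationImage:
    """Density-change ventilation at every masked exhale voxel.

    Voxels whose denominators are degenerate (exhale HU ~ 0, or mean inhale
    HU ~ -1000) are zeroed and counted in ``info["n_guarded"]``; if more than
    ``guard_fraction`` of masked voxels are guarded a DataError is raised,
    since that indicates a broken registration or mask.
    """
    if inhale.intensity_kind != "HU" or exhale.intensity_kind != "HU":
        raise DataError("density-change method requires HU volumes")
    _check_exhale_grid(dvf, exhale_mask)
    if not exhale.grid.close_to(exhale_mask.grid):
        raise GeometryError("exhale volume and mask grids differ")
    exhale_mask.require_nonempty("exhale lung mask")

    indices = np.argwhere(exhale_mask.values)
    h_voi = _voi_mean_inhale_bulk(inhale, dvf, indices)
    hu50 = exhale.values[exhale_mask.values]

    guarded = (np.abs(hu50) < 1e-6) | (np.abs(1000.0 + h_voi) < 1e-6)
    vi = np.zeros_like(h_voi)
    ok = ~guarded
    vi[ok] = 1000.0 * (h_voi[ok] - hu50[ok]) / (hu50[ok] * (1000.0 + h_voi[ok]))

    n_guarded = int(guarded.sum())
    if n_guarded > guard_fraction * indices.shape[0]:
        raise DataError(
            f"{n_guarded}/{indices.shape[0]} masked voxels hit denominator guards; "
            "registration or masking is likely wrong"
        )
    values = np.zeros(exhale.shape)
    values[tuple(indices.T)] = vi
    return VentilationImage(values, exhale_mask, "HU", info={"n_guarded": n_guarded})


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def normalize_by_percentile(
    values: np.ndarray, mask: np.ndarray, percentile: float = 90.0
) -> np.ndarray:
    """Divide by the given percentile of in-mask values (linear interpolation)."""
    norm = float(np.percentile(values[mask], percentile))
    if norm <= 0:
        raise DataError(f"nonpositive normalization constant {norm}")
    return values / norm


def postprocess(
    vi: VentilationImage,
    exhale_mask: Mask | None = None,
    norm_percentile: float = 90.0,
    filter_size: int = 9,
) -> VentilationImage:
    """Mask, percentile-normalize, median-filter, re-mask.

    Order of operations: (1) zero outside the mask, (2) divide by the
    ``norm_percentile``-th percentile of in-mask values, (3) box median
    filter of side ``filter_size`` over the full grid (reflect padding),
    (4) re-zero outside the mask.  Scale invariance holds exactly:
    postprocess(k * vi) == postprocess(vi) for any k > 0.  Negative values
    are retained (tertile segmentation downstream is rank-based).
    """
    if filter_size < 1 or filter_size % 2 == 0:
        raise ParameterError("filter_size must be odd and >= 1")
    mask = exhale_mask if exhale_mask is not None else vi.mask
    if not mask.grid.close_to(vi.mask.grid):
        raise GeometryError("post-processing mask grid differs from ventilation grid")
    mask.require_nonempty("post-processing mask")
    m = mask.values
    values = np.where(m, vi.values, 0.0)
    values = normalize_by_percentile(values, m, norm_percentile)
    if filter_size > 1:
        values = ndimage.median_filter(values, size=filter_size, mode="reflect")
    values = np.where(m, values, 0.0)
    return VentilationImage(values, mask, vi.provenance, normalized=True, info=dict(vi.info))
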