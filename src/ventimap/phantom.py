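"""Synthetic 4D breathing-lung phantom with analytic ground truth.

The phantom emulates the statistical structure of a phase-binned 4D thoracic
acquisition paired with a coarse nuclear-medicine ventilation reference:

* A body ellipsoid (soft tissue, ~+40 HU) containing two lung ellipsoids and
  a midline trachea.
* Breathing is a dorsoventral-graded uniaxial expansion about an apex plane
  z0: the exhale-to-inhale displacement is u_z = w * a(x, y) * (z - z0)
  inside the lungs, with a(x, y) = a0 + a1 * (y - y_min)/(y_max - y_min)
  depressed inside optional defect blobs.  Because the displacement gradient
  is unit-lower-triangular, the Jacobian determinant inside the lungs is
  exactly 1 + w * a(x, y) — a closed form every downstream estimator can be
  tested against.
* Lung HU follows mass conservation across phases:
  (1000 + HU_phase) = (1000 + HU_exhale) / (1 + w * a), evaluated at the
  material (exhale) point, so density- and Jacobian-derived ventilation
  truths are mutually consistent.
* A smooth vascular-like HU texture (a fixed function of the exhale material
  coordinate, advected exactly with the deformation) gives the lung interior
  intensity structure; without it, intensity-driven registration of the
  uniform interior would be ill-posed.
* The reference ventilation image is the ground truth degraded the way a
  coarse emission scan is: Gaussian blur, ~4x coarser grid, count-like noise
  (variance proportional to the local mean), clipped at zero and interpolated
  back to the fine grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._seeds import derive_seed
from .errors import ParameterError
from .imagecore import Grid, Mask, PhaseSeries, Volume
from .registration import VectorField
from .ventilation import VentilationImage

__all__ = [
    "DefectBlob",
    "PhantomSpec",
    "PhantomSubject",
    "expansion_field",
    "analytic_dvf",
    "render_phase",
    "phase_weight_schedule",
    "make_subject",
    "degrade_to_spect_like",
    "make_cohort",
]


@dataclass(frozen=True)
class DefectBlob:
    """Ventilation defect: Gaussian-edged depression of the expansion field.

    center is (x, y) in mm; the expansion is multiplied by
    1 - depression * exp(-d^2 / (2 * (radius/2)^2)).
    """

    center: tuple[float, float]
    radius_mm: float
    depression: float


@dataclass(frozen=True)
class PhantomSpec:
    """All parameters of one synthetic subject.

    Geometry is in mm on a grid of ``shape`` voxels at ``spacing``; defaults
    give a 96x96x64 grid at 2 mm.  ``seed`` drives only the stochastic parts
    (noise, shading); masks, truth and texture are seed-independent given the
    other fields.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_center: tuple[float, float, float] = (95.0, 95.0, 63.0)
    body_semiaxes: tuple[float, float, float] = (85.0, 70.0, 75.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (58.0, 92.0, 62.0),
        (132.0, 92.0, 62.0),
    )
    lung_semiaxes: tuple[tuple[float, float, float], ...] = (
        (28.0, 40.0, 38.0),
        (28.0, 40.0, 38.0),
    )
    trachea_center_xy: tuple[float, float] = (95.0, 88.0)
    trachea_radius_mm: float = 7.0
    trachea_z_min: float = 80.0
    hu_body: float = 40.0
    hu_lung_ex: float = -800.0
    hu_trachea: float = -1000.0
    hu_air: float = -1000.0
    a0: float = 0.15
    a1: float = 0.10
    defects: tuple[DefectBlob, ...] = (DefectBlob((60.0, 80.0), 15.0, 0.7),)
    apex_z0: float = 100.0
    taper_mm: float = 6.0
    noise_sd: float = 15.0
    shading_amplitude: float = 0.05
    texture_amplitude: float = 40.0
    texture_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1000.0 < self.hu_lung_ex < -250.0):
            raise ParameterError("exhale lung HU must lie in (-1000, -250)")
        if self.a0 <= -1 or self.a0 + max(self.a1, 0.0) <= -1:
            raise ParameterError("expansion must keep 1 + a > 0")
        if len(self.lung_centers) != len(self.lung_semiaxes):
            raise ParameterError("one semi-axis triple per lung center")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)


@dataclass
class PhantomSubject:
    """Generated 4D series with masks, analytic field, truth and reference."""

    subject_id: str
    series: PhaseSeries
    lung_masks: list[Mask]
    true_dvf: VectorField
    true_ventilation: VentilationImage
    spect_like: Volume
    spec: PhantomSpec

    @property
    def exhale_mask(self) -> Mask:
        return self.lung_masks[5]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _axis_mm(spec: PhantomSpec, ax: int) -> np.ndarray:
    return spec.grid.axis_coordinates(ax)


def _lung_membership(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Boolean membership of physical points in either lung ellipsoid."""
    inside = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
    for (cx, cy, cz), (ax_, ay, az) in zip(spec.lung_centers, spec.lung_semiaxes):
        inside |= ((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    return inside


def _body_membership(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    cx, cy, cz = spec.body_center
    ax_, ay, az = spec.body_semiaxes
    return ((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _trachea_membership(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    tx, ty = spec.trachea_center_xy
    r2 = (x - tx) ** 2 + (y - ty) ** 2
    return (r2 <= spec.trachea_radius_mm**2) & (z >= spec.trachea_z_min)


def _texture(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Vascular-like additive density texture, a fixed function of the exhale
    material coordinate (mm), advected exactly with the breathing deformation.

    A sum of 10 random plane waves with wavelengths 8-25 mm (the scale of
    pulmonary vessels and bronchi), RMS ~ 0.7 * texture_amplitude.  This
    local contrast is what makes intensity-driven registration of the lung
    interior well-posed, as vessel structure does in clinical CT.
    """
    if spec.texture_amplitude == 0:
        return np.zeros(np.broadcast(x, y, z).shape)
    rng = np.random.default_rng(spec.texture_seed)
    n_waves = 10
    out = np.zeros(np.broadcast(x, y, z).shape)
    for _ in range(n_waves):
        wavelength = rng.uniform(8.0, 25.0)
        k = rng.normal(size=3)
        k *= (2 * np.pi / wavelength) / np.linalg.norm(k)
        phase = rng.uniform(0, 2 * np.pi)
        out = out + np.cos(k[0] * x + k[1] * y + k[2] * z + phase)
    return spec.texture_amplitude * out / np.sqrt(n_waves)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def expansion_field(spec: PhantomSpec) -> np.ndarray:
    """The expansion amplitude a(x, y) on the exhale grid, shape (nx, ny).

    a = a0 + a1 * (y - y_min)/(y_max - y_min), multiplied inside each defect
    blob by (1 - depression) with Gaussian edges, clipped so 1 + a >= 0.05.
    """
    x = _axis_mm(spec, 0)[:, None]
    y = _axis_mm(spec, 1)[None, :]
    y_min, y_max = float(y.min()), float(y.max())
    a = spec.a0 + spec.a1 * (y - y_min) / max(y_max - y_min, 1e-12) + 0.0 * x
    for blob in spec.defects:
        d2 = (x - blob.center[0]) ** 2 + (y - blob.center[1]) ** 2
        sigma = blob.radius_mm / 2.0
        a = a * (1.0 - blob.depression * np.exp(-d2 / (2.0 * sigma**2)))
    return np.maximum(a, -0.95)


def _taper_weight(spec: PhantomSpec) -> np.ndarray:
    """Cosine taper: 1 inside the lungs plus a one-voxel margin, ->0 over a
    taper_mm shell beyond.  The margin keeps the analytic displacement exact
    at every in-lung voxel's finite-difference neighbors, so the numeric
    Jacobian matches the closed form throughout the lung mask."""
    x = _axis_mm(spec, 0)[:, None, None]
    y = _axis_mm(spec, 1)[None, :, None]
    z = _axis_mm(spec, 2)[None, None, :]
    lungs = _lung_membership(spec, x, y, z)
    dist = ndimage.distance_transform_edt(~lungs, sampling=spec.spacing)
    margin = 1.05 * max(spec.spacing)
    s = np.clip((dist - margin) / spec.taper_mm, 0.0, 1.0)
    t = 0.5 * (1.0 + np.cos(np.pi * s))
    t[lungs] = 1.0
    return t


def analytic_dvf(spec: PhantomSpec, phase_weight: float) -> VectorField:
    """Closed-form exhale-to-inhale displacement at breathing weight w.

    u_x = u_y = 0 and u_z = w * a(x, y) * (z - z0) inside the lungs, cosine
    tapered to zero over a ``taper_mm`` shell outside.  Inside the lungs the
    displacement gradient is unit-lower-triangular, so the analytic Jacobian
    determinant is exactly 1 + w * a(x, y).
    """
    w = float(phase_weight)
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"phase weight must be in [0, 1], got {w}")
    a = expansion_field(spec)
    z = _axis_mm(spec, 2)[None, None, :]
    uz = w * a[:, :, None] * (z - spec.apex_z0) * _taper_weight(spec)
    u = np.zeros((3,) + tuple(spec.shape))
    u[2] = uz
    return VectorField(u, spec.spacing, spec.origin)


def phase_weight_schedule(phase_index: int) -> float:
    """Cosine breathing weight: w = (1 + cos(2 pi p / 10)) / 2.

    w = 1 at T00 (peak inhale) and w = 0 at T50 (peak exhale); symmetric
    about mid-cycle.
    """
    p = int(phase_index)
    if not 0 <= p <= 9:
        raise ParameterError(f"phase index must be 0..9, got {phase_index}")
    return float((1.0 + np.cos(2.0 * np.pi * p / 10.0)) / 2.0)


def _phase_geometry(spec: PhantomSpec, w: float):
    """Noiseless anatomy of the phase at weight w, on the shared grid.

    Returns (hu, lung_mask).  Each voxel's lung membership and HU are found
    through the exact inverse breathing map z = z0 + (z' - z0)/(1 + w a),
    with lung HU given by mass conservation at the material point.
    """
    a = expansion_field(spec)[:, :, None]
    x = _axis_mm(spec, 0)[:, None, None]
    y = _axis_mm(spec, 1)[None, :, None]
    zp = _axis_mm(spec, 2)[None, None, :]
    z_mat = spec.apex_z0 + (zp - spec.apex_z0) / (1.0 + w * a)

    lung = _lung_membership(spec, x, y, z_mat)
    trachea = _trachea_membership(spec, x, y, zp)
    body = _body_membership(spec, x, y, zp)

    hu = np.full(spec.shape, spec.hu_air)
    hu[body] = spec.hu_body
    hu[trachea] = spec.hu_trachea
    density_ex = 1000.0 + spec.hu_lung_ex + _texture(spec, x, y, z_mat)
    hu_lung = density_ex / (1.0 + w * a) - 1000.0
    hu = np.where(lung, np.broadcast_to(hu_lung, spec.shape), hu)
    return hu, lung


def render_phase(spec: PhantomSpec, phase_weight: float, seed: int | None = None) -> Volume:
    """Render one phase volume: analytic anatomy + shading + Gaussian noise.

    Deterministic given (spec, phase_weight, seed); the default seed derives
    from ``spec.seed`` and the phase weight.
    """
    w = float(phase_weight)
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"phase weight must be in [0, 1], got {w}")
    hu, _ = _phase_geometry(spec, w)
    if seed is None:
        seed = derive_seed(spec.seed, f"phase-w{w:.6f}")
    rng = np.random.default_rng(seed)
    if spec.shading_amplitude > 0:
        x = _axis_mm(spec, 0)[:, None, None]
        y = _axis_mm(spec, 1)[None, :, None]
        phases = rng.uniform(0, 2 * np.pi, size=2)
        extent_x = max(x.max() - x.min(), 1.0)
        extent_y = max(y.max() - y.min(), 1.0)
        s = 0.5 * (
            np.cos(2 * np.pi * x / extent_x + phases[0])
            + np.cos(2 * np.pi * y / extent_y + phases[1])
        )
        hu = (1000.0 + hu) * (1.0 + spec.shading_amplitude * s) - 1000.0
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    return Volume(hu, spec.spacing, spec.origin, "HU")


def _block_mean(v: np.ndarray, f: int) -> np.ndarray:
    pad = [(0, (-n) % f) for n in v.shape]
    vp = np.pad(v, pad, mode="edge")
    return vp.reshape(
        vp.shape[0] // f, f, vp.shape[1] // f, f, vp.shape[2] // f, f
    ).mean(axis=(1, 3, 5))


def degrade_to_spect_like(
    truth: VentilationImage,
    coarsen_factor: int = 4,
    blur_sigma_mm: float = 4.0,
    noise_scale: float = 0.002,
    seed: int = 0,
) -> Volume:
    """Degrade a ground-truth ventilation map into a coarse noisy reference.

    Gaussian blur (``blur_sigma_mm``, ~9 mm FWHM at the default) and block
    averaging onto a grid coarsened by ``coarsen_factor`` (~2 mm -> ~8 mm,
    the typical emission/CT resolution ratio) are applied as normalized
    convolutions weighted by the lung mask, so values near the lung boundary
    are local in-lung averages rather than being diluted toward the zero
    background.  Count-statistics-like noise with variance proportional to
    the local mean is then added on the coarse grid (``noise_scale`` is the
    reciprocal count level per ventilation unit; the default corresponds to
    ~100 counts at a typical in-lung value, i.e. ~10% relative noise), the
    result clipped at zero and trilinearly resampled back to the fine grid.
    """
    from .imagecore import resample_to_grid

    if np.any(truth.in_mask() < 0):
        raise ParameterError("ground-truth ventilation must be nonnegative in the mask")
    f = int(coarsen_factor)
    if f < 1:
        raise ParameterError("coarsen_factor must be >= 1")
    m = truth.mask.values.astype(np.float64)
    num = truth.values * m
    den = m.copy()
    spacing = np.asarray(truth.spacing)
    if blur_sigma_mm > 0:
        num = ndimage.gaussian_filter(num, sigma=blur_sigma_mm / spacing, mode="nearest")
        den = ndimage.gaussian_filter(den, sigma=blur_sigma_mm / spacing, mode="nearest")
    if f > 1:
        num, den = _block_mean(num, f), _block_mean(den, f)
        coarse_grid = Grid(
            num.shape,
            tuple(s * f for s in truth.spacing),
            tuple(o + (f - 1) / 2.0 * s for o, s in zip(truth.origin, truth.spacing)),
        )
    else:
        coarse_grid = Grid(num.shape, truth.spacing, truth.origin)
    coarse = np.where(den > 1e-3, num / np.maximum(den, 1e-3), 0.0)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = np.sqrt(np.maximum(coarse, 0.0) * noise_scale)
        coarse = coarse + rng.normal(size=coarse.shape) * sd
    coarse = np.clip(coarse, 0.0, None)
    if f == 1 and blur_sigma_mm == 0 and noise_scale == 0:
        return Volume(coarse, truth.spacing, truth.origin, "counts")
    cvol = Volume(coarse, coarse_grid.spacing, coarse_grid.origin, "counts")
    fine = resample_to_grid(cvol, truth.mask.grid, "trilinear", fill_value=0.0)
    fine.values = np.clip(fine.values, 0.0, None)
    return fine


def make_subject(spec: PhantomSpec, subject_id: str = "subject") -> PhantomSubject:
    """Assemble one phantom subject: 10 phases, masks, truth and reference."""
    phases = []
    masks = []
    for p in range(10):
        w = phase_weight_schedule(p)
        phases.append(render_phase(spec, w, seed=derive_seed(spec.seed, f"phase{p:02d}")))
        _, lung = _phase_geometry(spec, w)
        masks.append(Mask(lung, spec.spacing, spec.origin))
    series = PhaseSeries(phases)
    true_dvf = analytic_dvf(spec, 1.0)
    exhale_mask = masks[5]
    a = expansion_field(spec)
    truth_vals = np.where(exhale_mask.values, a[:, :, None], 0.0)
    truth = VentilationImage(truth_vals, exhale_mask, "REF")
    spect = degrade_to_spect_like(truth, seed=derive_seed(spec.seed, "spect"))
    return PhantomSubject(subject_id, series, masks, true_dvf, truth, spect, spec)


def make_cohort(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    jitter: dict | None = None,
) -> list[PhantomSubject]:
    """Generate a cohort of subjects with seeded anatomical/functional jitter.

    Geometry (lung size/position), ventilation pattern (base expansion,
    dorsoventral gradient, 0-2 defect blobs) and texture vary per subject;
    reproducible given ``seed``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    base = base_spec or PhantomSpec()
    jitter = jitter or {}
    a0_range = jitter.get("a0", (0.12, 0.22))
    a1_range = jitter.get("a1", (0.04, 0.14))
    semiaxis_rel = jitter.get("semiaxis_rel", 0.08)
    center_mm = jitter.get("center_mm", 3.0)
    # thoracic-cancer cohorts essentially always show ventilation deficits
    # (tumor obstruction, emphysema), so every subject gets at least one
    min_defects = int(jitter.get("min_defects", 1))
    max_defects = int(jitter.get("max_defects", 3))

    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    subjects = []
    for i in range(n_subjects):
        centers = []
        semiaxes = []
        for c, s in zip(base.lung_centers, base.lung_semiaxes):
            centers.append(tuple(np.asarray(c) + rng.uniform(-center_mm, center_mm, 3)))
            semiaxes.append(tuple(np.asarray(s) * rng.uniform(1 - semiaxis_rel, 1 + semiaxis_rel, 3)))
        defects = []
        for _ in range(rng.integers(min_defects, max_defects + 1)):
            lung_i = int(rng.integers(0, len(centers)))
            cx, cy, _ = centers[lung_i]
            ax_, ay, _ = semiaxes[lung_i]
            defects.append(
                DefectBlob(
                    center=(cx + rng.uniform(-0.5, 0.5) * ax_, cy + rng.uniform(-0.5, 0.5) * ay),
                    radius_mm=float(rng.uniform(10.0, 20.0)),
                    depression=float(rng.uniform(0.5, 1.0)),
                )
            )
        spec = replace(
            base,
            lung_centers=tuple(centers),
            lung_semiaxes=tuple(semiaxes),
            a0=float(rng.uniform(*a0_range)),
            a1=float(rng.uniform(*a1_range)),
            defects=tuple(defects),
            texture_seed=int(rng.integers(0, 2**31)),
            seed=int(rng.integers(0, 2**31)),
        )
        subjects.append(make_subject(spec, subject_id=f"S{i:03d}"))
    return subjects
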