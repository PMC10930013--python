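"""Synthetic CT simulator for CAC-scan calibration phantoms.

Two phantom families are modelled:

* ``CIRS_S/M/L`` — electron-density phantoms carrying nine 30-mm
  tissue-equivalent rod inserts (lung, adipose, breast, muscle, liver and
  three hydroxyapatite bone densities).  They provide the training data:
  scans are repeated while rod pairs are progressively removed so the
  network sees flat regions as well as insert edges.
* ``QRM_S/M/L`` — anthropomorphic thorax phantoms whose calibration insert
  holds nine cylindrical calcifications (1/3/5 mm diameter at 200/400/800
  mg HA/cm^3).  They are reserved for validation.

Every phantom is rasterized on the routine CAC grid (512 x 512, 22-cm
field of view) and scanned at a thin slice thickness z in {0.5, 1.0, 1.5}
mm.  The paired 3-mm image is formed by averaging the n = 3/z thin-slice
noise realizations of the same anatomy, so a scan pair shares its
noise-free content by construction.  Quantum noise is a zero-mean
spatially correlated Gaussian field whose per-material standard deviation
is anchored at the 3-mm reference value and scales as
``sqrt(3 * mA_ref / (z * mA))``; optional inter-slice correlation makes
the thin/3-mm SD ratio match measured reconstructions rather than the
``sqrt(n)`` of independent slices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

HU_AIR = -1000.0

#: default mottle correlation length: FWHM ~= 2 px of the Gaussian kernel
#: used to colour the white noise (smooth FBP-like texture).
NOISE_FWHM_PX = 2.0

#: default inter-slice noise correlation (shared-component fraction rho).
#: rho = 0 means independent thin-slice realizations; the default is
#: calibrated so that at z = 1.5 mm the thin/3-mm SD ratio is ~1.35,
#: the value observed in soft-tissue ROIs of reconstructed scans.
SLICE_CORRELATION = 0.10

CIRS_NAMES = ("CIRS_S", "CIRS_M", "CIRS_L")
QRM_NAMES = ("QRM_S", "QRM_M", "QRM_L")


@dataclass(frozen=True)
class Material:
    """A tissue-equivalent material: mean HU and noise SD at the 3-mm anchor."""

    name: str
    hu_mean: float
    sd_3mm_ref: float

    def __post_init__(self) -> None:
        if not (-1024.0 <= self.hu_mean <= 3071.0):
            raise ValueError(f"hu_mean {self.hu_mean} outside CT range")
        if self.sd_3mm_ref < 0:
            raise ValueError("sd_3mm_ref must be non-negative")


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical insert (rod or calcification) in phantom coordinates."""

    label: str
    center_xy: tuple[float, float]  # mm, phantom-centred axes
    diameter: float                 # mm
    height: float                   # mm (axial extent; informational)
    material: Material
    kind: str = "rod"               # rod | calcification | calibration
    present: bool = True

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("insert diameter must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    name: str
    body_axes: tuple[float, float]  # full axes of the body ellipse, mm
    body_material: Material
    inserts: tuple[InsertSpec, ...]
    tube_current: float             # mA
    tube_current_ref: float         # mA at which sd_3mm_ref was measured

    @property
    def present_inserts(self) -> tuple[InsertSpec, ...]:
        return tuple(i for i in self.inserts if i.present)


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: 512 x 512 over a 22-cm display field of view."""

    matrix: int = 512
    fov: float = 220.0  # mm

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) coordinates of pixel centres in mm, origin at grid centre."""
        s = self.pixel_spacing
        c = (np.arange(self.matrix) + 0.5) * s - self.fov / 2.0
        return np.meshgrid(c, c, indexing="ij")


@dataclass
class CTImage:
    """One reconstructed slice in HU with its acquisition metadata."""

    pixels: np.ndarray           # float32, HU
    grid: GridSpec
    slice_thickness: float       # mm
    tube_current: float          # mA
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage pixels must be finite")

    def copy_with(self, pixels: np.ndarray, **meta) -> "CTImage":
        kw = dict(
            grid=self.grid,
            slice_thickness=self.slice_thickness,
            tube_current=self.tube_current,
            seed=self.seed,
            provenance=self.provenance,
        )
        kw.update(meta)
        return CTImage(pixels=pixels, **kw)


@dataclass
class ScanPair:
    """A thin-slice image and its 3-mm partner from the same thin stack."""

    thin: CTImage
    thick: CTImage
    spec: PhantomSpec
    realizations: np.ndarray | None = None  # (n, H, W) thin-slice stack


# ---------------------------------------------------------------------------
# Reference material tables (3-mm anchor values measured per phantom size;
# larger bodies attenuate more, so both the means and the noise amplitudes
# differ slightly between S/M/L).
# ---------------------------------------------------------------------------

_CIRS_ROD_TABLE: dict[str, list[tuple[str, float, float]]] = {
    "CIRS_S": [
        ("lung_inhale", -829.59, 22.87),
        ("lung_exhale", -481.16, 27.53),
        ("adipose", -72.86, 27.69),
        ("breast", -25.93, 27.80),
        ("muscle", 56.77, 25.29),
        ("liver", 71.83, 24.31),
        ("bone_200", 257.64, 37.71),
        ("bone_800", 1037.05, 40.51),
        ("bone_1250", 1577.16, 42.04),
    ],
    "CIRS_M": [
        ("lung_inhale", -822.11, 25.07),
        ("lung_exhale", -467.80, 27.58),
        ("adipose", -68.26, 32.70),
        ("breast", -22.65, 29.55),
        ("muscle", 44.62, 31.71),
        ("liver", 73.83, 28.49),
        ("bone_200", 274.56, 40.76),
        ("bone_800", 955.10, 40.85),
        ("bone_1250", 1532.88, 43.65),
    ],
    "CIRS_L": [
        ("lung_inhale", -792.05, 29.97),
        ("lung_exhale", -463.03, 27.22),
        ("adipose", -64.57, 38.76),
        ("breast", -1.10, 30.99),
        ("muscle", 54.83, 38.07),
        ("liver", 78.95, 34.16),
        ("bone_200", 289.87, 44.79),
        ("bone_800", 924.29, 42.09),
        ("bone_1250", 1437.49, 48.52),
    ],
}

# QRM calibration-insert background and calcification HU (mean, at 3 mm)
# plus the background noise SD used as the quantum-noise anchor.
_QRM_TABLE: dict[str, dict] = {
    "QRM_S": {
        "background": (41.65, 22.77),
        "calc_hu": {200: 243.41, 400: 372.45, 800: 611.27},
    },
    "QRM_M": {
        "background": (40.26, 21.77),
        "calc_hu": {200: 231.04, 400: 368.88, 800: 591.05},
    },
    "QRM_L": {
        "background": (47.33, 21.33),
        "calc_hu": {200: 225.72, 400: 348.57, 800: 566.63},
    },
}

_BODY_AXES = {
    "CIRS_S": (180.0, 180.0),
    "CIRS_M": (230.0, 230.0),
    "CIRS_L": (320.0, 270.0),
    "QRM_S": (300.0, 200.0),
    "QRM_M": (350.0, 250.0),
    "QRM_L": (400.0, 300.0),
}

_TUBE_CURRENT = {
    "CIRS_S": 40.0, "CIRS_M": 80.0, "CIRS_L": 300.0,
    "QRM_S": 40.0, "QRM_M": 50.0, "QRM_L": 140.0,
}

#: removal sequence for the CIRS acquisition protocol: four rod pairs taken
#: out in this order (the centre muscle rod is never removed, so every
#: configuration keeps a soft-tissue reference).  The pairing is a protocol
#: choice of this simulator.
CIRS_REMOVAL_ORDER: tuple[tuple[str, str], ...] = (
    ("lung_inhale", "bone_1250"),
    ("lung_exhale", "bone_800"),
    ("adipose", "bone_200"),
    ("breast", "liver"),
)

_ROD_DIAMETER = 30.0
_ROD_HEIGHT = 50.0
_ROD_RING_RADIUS = 55.0

_QRM_INSERT_DIAMETER = 100.0
_QRM_CALC_RING_RADIUS = 25.0


def _cirs_inserts(name: str) -> tuple[InsertSpec, ...]:
    table = _CIRS_ROD_TABLE[name]
    mats = {label: Material(label, hu, sd) for label, hu, sd in table}
    inserts = [
        InsertSpec("muscle", (0.0, 0.0), _ROD_DIAMETER, _ROD_HEIGHT,
                   mats["muscle"], kind="rod")
    ]
    ring = [label for label, _, _ in table if label != "muscle"]
    for i, label in enumerate(ring):
        ang = 2.0 * np.pi * i / len(ring)
        cx = _ROD_RING_RADIUS * np.cos(ang)
        cy = _ROD_RING_RADIUS * np.sin(ang)
        inserts.append(
            InsertSpec(label, (float(cx), float(cy)), _ROD_DIAMETER,
                       _ROD_HEIGHT, mats[label], kind="rod")
        )
    return tuple(inserts)


def _qrm_inserts(name: str) -> tuple[InsertSpec, ...]:
    info = _QRM_TABLE[name]
    bg_hu, bg_sd = info["background"]
    insert_mat = Material("calibration_insert", bg_hu, bg_sd)
    inserts = [
        InsertSpec("calibration_insert", (0.0, 0.0), _QRM_INSERT_DIAMETER,
                   _ROD_HEIGHT, insert_mat, kind="calibration")
    ]
    i = 0
    for density in (200, 400, 800):
        hu = info["calc_hu"][density]
        mat = Material(f"HA_{density}", hu, bg_sd)
        for diameter in (5.0, 3.0, 1.0):
            ang = 2.0 * np.pi * i / 9.0
            cx = _QRM_CALC_RING_RADIUS * np.cos(ang)
            cy = _QRM_CALC_RING_RADIUS * np.sin(ang)
            inserts.append(
                InsertSpec(f"calc_{int(diameter)}mm_{density}",
                           (float(cx), float(cy)), diameter, diameter,
                           mat, kind="calcification")
            )
            i += 1
    return tuple(inserts)


def make_phantom_spec(name: str, configuration: int = 0) -> PhantomSpec:
    """Build the geometry/material specification for one phantom setup.

    ``configuration`` indexes the rod-removal acquisition protocol of the
    electron-density phantoms: configuration 0 has all nine rods present
    and each increment removes the next designated pair, so configuration
    k carries 9 - 2k rods (k = 0..4).  Thorax (QRM) phantoms have a fixed
    layout and accept only configuration 0.
    """
    if name not in _BODY_AXES:
        raise ValueError(f"unknown phantom {name!r}")
    is_cirs = name in CIRS_NAMES
    if is_cirs:
        if not 0 <= configuration <= 4:
            raise ValueError("configuration must be in 0..4")
        inserts = _cirs_inserts(name)
        removed = {label
                   for pair in CIRS_REMOVAL_ORDER[:configuration]
                   for label in pair}
        inserts = tuple(
            dataclasses.replace(ins, present=ins.label not in removed)
            for ins in inserts
        )
        body = Material("water", 0.0, _CIRS_ROD_TABLE[name][4][2])
    else:
        if configuration != 0:
            raise ValueError("QRM phantoms have a single configuration (0)")
        inserts = _qrm_inserts(name)
        bg_hu, bg_sd = _QRM_TABLE[name]["background"]
        body = Material("soft_tissue", bg_hu, bg_sd)
    ax = _BODY_AXES[name]
    mA = _TUBE_CURRENT[name]
    spec = PhantomSpec(name=name, body_axes=ax, body_material=body,
                       inserts=inserts, tube_current=mA, tube_current_ref=mA)
    _check_inserts_inside(spec)
    return spec


def _check_inserts_inside(spec: PhantomSpec) -> None:
    a, b = spec.body_axes[0] / 2.0, spec.body_axes[1] / 2.0
    for ins in spec.inserts:
        x, y = ins.center_xy
        r = ins.diameter / 2.0
        # conservative: inflate the insert radius against the tighter axis
        if (x / (a - r)) ** 2 + (y / (b - r)) ** 2 > 1.0:
            raise ValueError(f"insert {ins.label} extends outside the body")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _paint(maps: tuple[np.ndarray, np.ndarray], mask: np.ndarray,
           material: Material) -> None:
    hu, sd = maps
    hu[mask] = material.hu_mean
    sd[mask] = material.sd_3mm_ref


def _raster_maps(spec: PhantomSpec, grid: GridSpec,
                 supersample: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted HU and noise-SD maps via supersampled rasterization.

    Material boundaries are anti-aliased by evaluating the geometry at
    ``supersample^2`` sub-pixel positions and block-averaging, which
    emulates in-plane partial volume: a 1-mm calcification (~2 px across)
    is boundary-dominated and its rendered HU is correspondingly diluted.
    """
    n = grid.matrix * supersample
    s = grid.fov / n
    c = (np.arange(n) + 0.5) * s - grid.fov / 2.0
    yy, xx = np.meshgrid(c, c, indexing="ij")

    hu = np.full((n, n), HU_AIR)
    sd = np.full((n, n), spec.body_material.sd_3mm_ref)

    a, b = spec.body_axes[0] / 2.0, spec.body_axes[1] / 2.0
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    _paint((hu, sd), body, spec.body_material)

    # paint order: calibration insert first, then rods, then calcifications
    order = {"calibration": 0, "rod": 1, "calcification": 2}
    for ins in sorted(spec.present_inserts, key=lambda i: order[i.kind]):
        x0, y0 = ins.center_xy
        r = ins.diameter / 2.0
        mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= r * r
        _paint((hu, sd), mask, ins.material)

    f = supersample
    m = grid.matrix
    hu = hu.reshape(m, f, m, f).mean(axis=(1, 3))
    sd = sd.reshape(m, f, m, f).mean(axis=(1, 3))
    return hu, sd


def rasterize(spec: PhantomSpec, grid: GridSpec | None = None,
              supersample: int = 4) -> CTImage:
    """Noise-free HU image of a phantom (air outside the body at -1000 HU)."""
    grid = grid or GridSpec()
    hu, _ = _raster_maps(spec, grid, supersample)
    return CTImage(pixels=hu.astype(np.float32), grid=grid,
                   slice_thickness=3.0, tube_current=spec.tube_current,
                   provenance=f"rasterize:{spec.name}")


# ---------------------------------------------------------------------------
# Noise synthesis
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _filter_norm(sigma_px: float, shape: tuple[int, int]) -> float:
    """L2 norm of the periodic Gaussian kernel: SD shrink factor of the
    low-pass filter applied to unit white noise."""
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    k = gaussian_filter(impulse, sigma_px, mode="wrap")
    return float(np.sqrt(np.sum(k * k)))


def _correlated_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                           fwhm_px: float) -> np.ndarray:
    """Zero-mean correlated Gaussian field with unit pointwise variance."""
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = rng.standard_normal(shape)
    f = gaussian_filter(w, sigma, mode="wrap")
    return f / _filter_norm(sigma, shape)


def simulate_scan(spec: PhantomSpec, grid: GridSpec | None = None,
                  z: float = 1.5, seed: int = 0, *,
                  slice_correlation: float = SLICE_CORRELATION,
                  noise_fwhm_px: float = NOISE_FWHM_PX,
                  keep_realizations: bool = True) -> ScanPair:
    """Simulate a paired thin-slice / 3-mm acquisition of one phantom.

    The 3-mm image is the pixelwise mean of the n = 3/z thin-slice noise
    realizations; the thin image is the first realization.  Each
    realization's noise field is ``sqrt(rho) * shared + sqrt(1-rho) *
    independent`` where rho = ``slice_correlation`` (rho = 0 reproduces
    the pure 1/sqrt(n) averaging of independent slices).  Per-material SD
    of each thin realization is ``sd_3mm_ref * sqrt(3*mA_ref / (z*mA))``.
    """
    grid = grid or GridSpec()
    if z not in (0.5, 1.0, 1.5):
        raise ValueError("slice thickness z must be 0.5, 1.0 or 1.5 mm")
    n = int(round(3.0 / z))
    if abs(n * z - 3.0) > 1e-9:
        raise ValueError("3.0 mm must be an integer multiple of z")
    rho = slice_correlation
    if not 0.0 <= rho < 1.0:
        raise ValueError("slice_correlation must be in [0, 1)")

    ideal, sd_map = _raster_maps(spec, grid)
    scale = np.sqrt((3.0 * spec.tube_current_ref) / (z * spec.tube_current))
    sigma_thin = sd_map * scale

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCAC]))
    shape = (grid.matrix, grid.matrix)
    shared = _correlated_unit_field(rng, shape, noise_fwhm_px)
    stack = np.empty((n,) + shape, dtype=np.float32)
    for i in range(n):
        ind = _correlated_unit_field(rng, shape, noise_fwhm_px)
        unit = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * ind
        stack[i] = (ideal + sigma_thin * unit).astype(np.float32)

    thick_px = stack.mean(axis=0, dtype=np.float64).astype(np.float32)
    prov = f"simulate:{spec.name}:z={z}:seed={seed}"
    thin = CTImage(pixels=stack[0].copy(), grid=grid, slice_thickness=z,
                   tube_current=spec.tube_current, seed=seed,
                   provenance=prov + ":thin")
    thick = CTImage(pixels=thick_px, grid=grid, slice_thickness=3.0,
                    tube_current=spec.tube_current, seed=seed,
                    provenance=prov + ":thick")
    return ScanPair(thin=thin, thick=thick, spec=spec,
                    realizations=stack if keep_realizations else None)


def acquisition_protocol(phantoms: Sequence[str], z: float,
                         base_seed: int = 0, **sim_kw) -> list[ScanPair]:
    """Emulate the training acquisition: one scan per (phantom, rod
    configuration 0..4), i.e. 5 datasets per electron-density phantom.

    Dataset i uses seed ``base_seed + i`` so any dataset can be
    regenerated individually.
    """
    for name in phantoms:
        if name not in CIRS_NAMES:
            raise ValueError(
                f"{name!r} is not a training phantom (expected CIRS_*)")
    pairs: list[ScanPair] = []
    i = 0
    for name in phantoms:
        for cfg in range(5):
            spec = make_phantom_spec(name, cfg)
            pairs.append(simulate_scan(spec, z=z, seed=base_seed + i,
                                       **sim_kw))
            i += 1
    return pairs
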