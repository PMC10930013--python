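"""Image-quality and calcium-scoring evaluation.

Covers the validation measurements used for the denoiser: whole-image
RMSE and PSNR against the 3-mm reference, circular-ROI mean/SD with a
Welch two-sample t-test (significance at p < 0.01), calcification
segmentation at the standard 130-HU calcium-scoring threshold with Dice
overlap, and Agatston weighting-bin pixel counts (factor 1: 130-199 HU,
2: 200-299, 3: 300-399, 4: >= 400).  1-mm calcifications are excluded
from Dice analysis because they are not reliably detectable on 3-mm
images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from cacdn.phantoms import CTImage, GridSpec, InsertSpec, PhantomSpec

CALCIUM_THRESHOLD_HU = 130.0
SIGNIFICANCE_LEVEL = 0.01

#: Agatston weighting factors: half-open HU bins over [130, inf)
AGATSTON_BINS: tuple[tuple[int, float, float], ...] = (
    (1, 130.0, 200.0),
    (2, 200.0, 300.0),
    (3, 300.0, 400.0),
    (4, 400.0, np.inf),
)


@dataclass
class ROISpec:
    """Circular ROI in mm (phantom-centred axes) or an explicit pixel mask."""

    label: str
    kind: str                       # rod | background | calcification
    center_xy: tuple[float, float] | None = None
    radius: float | None = None     # mm
    mask: np.ndarray | None = None  # explicit boolean mask, overrides circle

    def pixel_mask(self, grid: GridSpec) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
        else:
            if self.center_xy is None or self.radius is None:
                raise ValueError(f"ROI {self.label!r} has no geometry")
            yy, xx = grid.pixel_centers()
            x0, y0 = self.center_xy
            m = (xx - x0) ** 2 + (yy - y0) ** 2 <= self.radius ** 2
        if not m.any():
            raise ValueError(f"ROI {self.label!r} is empty on this grid")
        return m


@dataclass
class ROIStats:
    label: str
    mean: float
    sd: float
    n: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass
class AgatstonBinCounts:
    counts: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        assert self.total == sum(self.counts.values())


@dataclass
class EvalReport:
    """Evaluation of one candidate image against the 3-mm reference."""

    image_name: str
    reference_name: str
    rmse: float
    psnr: float
    roi_stats: list[ROIStats]
    dice: dict[str, float]
    agatston: AgatstonBinCounts | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psnr"] = self.psnr if np.isfinite(self.psnr) else "inf"
        for r, stats_ in zip(d["roi_stats"], self.roi_stats):
            r["significant"] = stats_.significant
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def roi_table(self) -> pd.DataFrame:
        rows = [{"roi": r.label, "mean_hu": r.mean, "sd_hu": r.sd,
                 "n_pixels": r.n, "p_value": r.p_value,
                 "significant": r.significant} for r in self.roi_stats]
        return pd.DataFrame(rows)


def _require_same_grid(image: CTImage, reference: CTImage) -> None:
    if image.grid != reference.grid or image.pixels.shape != reference.pixels.shape:
        raise ValueError("images are on different grids")


def rmse(image: CTImage, reference: CTImage) -> float:
    """Whole-image root-mean-square difference in HU."""
    _require_same_grid(image, reference)
    d = reference.pixels.astype(np.float64) - image.pixels.astype(np.float64)
    return float(np.sqrt(np.mean(d * d)))


def psnr(image: CTImage, reference: CTImage) -> float:
    """Peak signal-to-noise ratio, 20*log10(HU_max / RMSE), in dB.

    HU_max is the maximum pixel of the *reference* image so that competing
    candidates are scored against a common ceiling.  Identical images give
    the +inf sentinel.
    """
    e = rmse(image, reference)
    hu_max = float(np.max(reference.pixels))
    if e == 0.0:
        return float("inf")
    return 20.0 * np.log10(hu_max / e)


def roi_stats(image: CTImage, roi: ROISpec, reference: CTImage) -> ROIStats:
    """Mean/SD of the ROI plus a Welch two-sample t-test against the same
    ROI of the reference image (two-sided p)."""
    _require_same_grid(image, reference)
    m = roi.pixel_mask(image.grid)
    a = image.pixels[m].astype(np.float64)
    b = reference.pixels[m].astype(np.float64)
    if np.array_equal(a, b):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ROIStats(label=roi.label, mean=float(a.mean()),
                    sd=float(a.std(ddof=1)), n=int(m.sum()), p_value=p)


def calcification_mask(image: CTImage,
                       region: ROISpec | None = None) -> np.ndarray:
    """Pixels at or above the 130-HU calcium threshold within ``region``
    (whole image when region is None)."""
    m = image.pixels.astype(np.float64) >= CALCIUM_THRESHOLD_HU
    if region is not None:
        m &= region.pixel_mask(image.grid)
    return m


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); two empty masks agree (1.0)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks are on different grids")
    denom = int(mask_a.sum()) + int(mask_b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / denom


def filter_small_calcifications(inserts: list[InsertSpec],
                                min_diameter: float = 3.0) -> list[InsertSpec]:
    """Drop calcifications below ``min_diameter`` (default keeps 3/5 mm);
    non-calcification inserts pass through unchanged."""
    return [i for i in inserts
            if i.kind != "calcification" or i.diameter >= min_diameter]


def agatston_weight(hu: float) -> int:
    """Agatston weighting factor of one pixel's HU (0 below threshold)."""
    for factor, lo, hi in AGATSTON_BINS:
        if lo <= hu < hi:
            return factor
    return 0


def count_weighted_pixels(image: CTImage,
                          region: ROISpec | None = None) -> AgatstonBinCounts:
    """Pixel counts per Agatston weighting bin over the calcification mask."""
    m = calcification_mask(image, region)
    vals = image.pixels[m].astype(np.float64)
    counts = {factor: int(np.sum((vals >= lo) & (vals < hi)))
              for factor, lo, hi in AGATSTON_BINS}
    return AgatstonBinCounts(counts=counts, total=int(m.sum()))


# ---------------------------------------------------------------------------
# ROI construction and full evaluation for simulated phantoms
# ---------------------------------------------------------------------------

def default_rois(spec: PhantomSpec, rod_roi_fraction: float = 2.0 / 3.0,
                 background_radius: float = 15.0) -> list[ROISpec]:
    """Standard ROI layout for a phantom.

    Rod inserts get a concentric circular ROI at ``rod_roi_fraction`` of
    the rod radius (keeps clear of boundary partial volume).  Thorax
    phantoms additionally get a background ROI at the centre of the
    calibration insert, inside the calcification ring.
    """
    rois = []
    for ins in spec.present_inserts:
        if ins.kind == "rod":
            rois.append(ROISpec(label=ins.label, kind="rod",
                                center_xy=ins.center_xy,
                                radius=rod_roi_fraction * ins.diameter / 2.0))
        elif ins.kind == "calibration":
            rois.append(ROISpec(label="background", kind="background",
                                center_xy=ins.center_xy,
                                radius=background_radius))
    return rois


def calcification_regions(spec: PhantomSpec, margin: float = 3.0,
                          min_diameter: float = 3.0) -> list[ROISpec]:
    """Per-calcification search regions (circle of calc radius + margin)."""
    calcs = [i for i in spec.present_inserts if i.kind == "calcification"]
    calcs = filter_small_calcifications(calcs, min_diameter)
    return [ROISpec(label=c.label, kind="calcification",
                    center_xy=c.center_xy, radius=c.diameter / 2.0 + margin)
            for c in calcs]


def density_regions(spec: PhantomSpec, grid: GridSpec, margin: float = 3.0,
                    min_diameter: float = 3.0) -> dict[str, ROISpec]:
    """One pooled search region per HA density covering its retained
    (3- and 5-mm) calcifications — the granularity at which calcification
    Dice is usually reported."""
    pooled: dict[str, np.ndarray] = {}
    for region in calcification_regions(spec, margin, min_diameter):
        density = region.label.rsplit("_", 1)[-1]
        mask = region.pixel_mask(grid)
        pooled[density] = pooled.get(density, False) | mask
    return {d: ROISpec(label=f"HA_{d}", kind="calcification", mask=m)
            for d, m in pooled.items()}


def evaluate(image: CTImage, reference: CTImage, spec: PhantomSpec,
             image_name: str = "image",
             reference_name: str = "reference") -> EvalReport:
    """Full report: RMSE/PSNR, ROI statistics, per-calcification Dice
    (3/5-mm only) and Agatston bin counts over the calibration insert."""
    rois = default_rois(spec)
    stats_ = [roi_stats(image, roi, reference) for roi in rois]
    dice_table = {}
    agatston = None
    regions = calcification_regions(spec)
    for region in regions:
        dice_table[region.label] = dice(calcification_mask(image, region),
                                        calcification_mask(reference, region))
    for label, region in density_regions(spec, image.grid).items():
        dice_table[region.label] = dice(calcification_mask(image, region),
                                        calcification_mask(reference, region))
    insert = next((i for i in spec.present_inserts
                   if i.kind == "calibration"), None)
    if insert is not None:
        whole_insert = ROISpec(label="calibration_insert", kind="background",
                               center_xy=insert.center_xy,
                               radius=insert.diameter / 2.0)
        agatston = count_weighted_pixels(image, whole_insert)
    return EvalReport(
        image_name=image_name, reference_name=reference_name,
        rmse=rmse(image, reference), psnr=psnr(image, reference),
        roi_stats=stats_, dice=dice_table, agatston=agatston,
        provenance={"image": image.provenance,
                    "reference": reference.provenance,
                    "phantom": spec.name},
    )
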