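"""CSVD surrogate markers: PSMD and white-matter-hyperintensity loads.

PSMD (peak width of skeletonised mean diffusivity) is the 95th minus 5th
percentile of the mean-diffusivity values sampled on a white-matter
skeleton — a robust width measure of the MD histogram that grows with
microstructural white-matter damage.

WMH (white matter hyperintensities of presumed vascular origin) are
quantified from a binary lesion mask. Lesion voxels within 10 mm
Euclidean distance of the ventricles are classified periventricular
(pWMH), the rest deep (dWMH). WMH load is the percentage share of lesion
volume in the brain tissue volume (intracranial minus ventricle volume),
log10-transformed for analysis because of its right-skewed distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "SkeletonSample",
    "LesionMasks",
    "CsvdMarkers",
    "psmd",
    "extract_skeleton_sample",
    "classify_wmh",
    "wmh_loads",
    "compute_markers",
    "dice",
]

logger = logging.getLogger(__name__)

#: distance from the ventricles (mm) at or below which WMH count as periventricular
PERIVENTRICULAR_THRESHOLD_MM = 10.0
_DIST_SLACK = 1e-9


@dataclass(frozen=True)
class SkeletonSample:
    """Mean-diffusivity values (mm^2/s) sampled on the TBSS-style skeleton."""

    md_values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.md_values, dtype=float).ravel()
        if v.size < 1:
            raise UndefinedMetricError("skeleton sample is empty")
        if not np.isfinite(v).all() or (v <= 0).any():
            raise ValidationError("skeleton MD values must be finite and > 0")
        v.flags.writeable = False
        object.__setattr__(self, "md_values", v)

    @property
    def n_voxels(self) -> int:
        return self.md_values.size


@dataclass(frozen=True)
class LesionMasks:
    """Binary WMH and ventricle masks plus subject-level volumes.

    ``voxel_dims`` are the (dx, dy, dz) voxel edge lengths in mm; the
    volumes ``icv_ml`` (intracranial) and ``ventricle_ml`` are measured
    at head scale and define the brain tissue volume used for loads.
    """

    wmh: np.ndarray
    ventricles: np.ndarray
    voxel_dims: Tuple[float, float, float]
    icv_ml: float
    ventricle_ml: float

    def __post_init__(self):
        wmh = np.asarray(self.wmh).astype(bool)
        vent = np.asarray(self.ventricles).astype(bool)
        if wmh.shape != vent.shape:
            raise ValidationError(
                f"mask shapes differ: {wmh.shape} vs {vent.shape}"
            )
        if wmh.ndim != 3:
            raise ValidationError("masks must be 3-D arrays")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValidationError("voxel dimensions must be three positive lengths")
        if self.brain_tissue_ml <= 0:
            raise ValidationError("brain tissue volume (ICV - ventricles) must be > 0")
        wmh.flags.writeable = False
        vent.flags.writeable = False
        object.__setattr__(self, "wmh", wmh)
        object.__setattr__(self, "ventricles", vent)
        object.__setattr__(self, "voxel_dims", dims)

    @property
    def brain_tissue_ml(self) -> float:
        return float(self.icv_ml) - float(self.ventricle_ml)

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz / 1000.0  # mm^3 -> mL


@dataclass(frozen=True)
class CsvdMarkers:
    """PSMD plus WMH volumes, percentage loads and log10 loads."""

    psmd: float
    wmh_ml: float
    pwmh_ml: float
    dwmh_ml: float
    wmh_load: float
    pwmh_load: float
    dwmh_load: float
    log_wmh_load: float
    log_pwmh_load: float
    log_dwmh_load: float


def psmd(s: SkeletonSample) -> float:
    """95th minus 5th percentile of the skeleton MD values (mm^2/s).

    Percentiles use linear interpolation between order statistics. Samples
    of fewer than 20 voxels give an unstable width and trigger a warning.
    """
    if s.n_voxels < 20:
        warnings.warn(f"PSMD from only {s.n_voxels} voxels is unstable")
    hi, lo = np.percentile(s.md_values, [95.0, 5.0])
    return float(hi - lo)


def extract_skeleton_sample(md_map: np.ndarray, skeleton_mask: np.ndarray) -> SkeletonSample:
    """MD values at skeleton voxels, in scan (C) order.

    Zero and non-finite voxels are dropped with their count logged — they
    mark background or registration failures, not tissue.
    """
    md_map = np.asarray(md_map, dtype=float)
    mask = np.asarray(skeleton_mask).astype(bool)
    if md_map.shape != mask.shape:
        raise ValidationError(
            f"MD map shape {md_map.shape} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise UndefinedMetricError("skeleton mask is empty")
    values = md_map[mask]
    keep = np.isfinite(values) & (values > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("extract_skeleton_sample: dropped %d zero/non-finite voxels", n_dropped)
    if not keep.any():
        raise UndefinedMetricError("no positive finite MD values under the mask")
    return SkeletonSample(values[keep])


def ventricle_distance_mm(m: LesionMasks) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the nearest
    ventricle voxel centre, respecting anisotropic voxel dimensions."""
    if not m.ventricles.any():
        raise ValidationError("ventricle mask is empty")
    return ndimage.distance_transform_edt(~m.ventricles, sampling=m.voxel_dims)


def classify_wmh(
    m: LesionMasks, threshold_mm: float = PERIVENTRICULAR_THRESHOLD_MM
) -> Tuple[np.ndarray, np.ndarray]:
    """Split the WMH mask into (periventricular, deep) at ``threshold_mm``.

    The boundary is inclusive: a lesion voxel exactly at the threshold
    distance counts as periventricular (a 1e-9 slack absorbs float noise
    in the distance transform). The two masks partition the WMH mask.
    """
    dist = ventricle_distance_mm(m)
    pwmh = m.wmh & (dist <= threshold_mm + _DIST_SLACK)
    dwmh = m.wmh & ~pwmh
    return pwmh, dwmh


def wmh_loads(
    m: LesionMasks,
    pwmh_ml: float,
    dwmh_ml: float,
    psmd_value: float = float("nan"),
) -> CsvdMarkers:
    """Percentage loads and log10 loads from the split lesion volumes.

    load = 100 * volume / brain_tissue_ml. A volume of exactly zero has no
    logarithm; such subjects get their load floored at half the load of a
    single voxel before log10 (warning emitted), which keeps zero-lesion
    subjects in the regression sample at the bottom of the scale.
    """
    btv = m.brain_tissue_ml
    if btv <= 0:
        raise ValidationError("brain tissue volume must be > 0")
    if pwmh_ml < 0 or dwmh_ml < 0:
        raise ValidationError("lesion volumes must be >= 0")
    wmh_ml = pwmh_ml + dwmh_ml
    floor_load = 100.0 * (m.voxel_volume_ml / 2.0) / btv

    def load_of(vol_ml: float) -> float:
        return 100.0 * vol_ml / btv

    def log_load_of(vol_ml: float) -> float:
        ld = load_of(vol_ml)
        if ld <= 0:
            warnings.warn("zero lesion volume: log-load floored at half a voxel")
            ld = floor_load
        return float(np.log10(ld))

    return CsvdMarkers(
        psmd=psmd_value,
        wmh_ml=float(wmh_ml),
        pwmh_ml=float(pwmh_ml),
        dwmh_ml=float(dwmh_ml),
        wmh_load=load_of(wmh_ml),
        pwmh_load=load_of(pwmh_ml),
        dwmh_load=load_of(dwmh_ml),
        log_wmh_load=log_load_of(wmh_ml),
        log_pwmh_load=log_load_of(pwmh_ml),
        log_dwmh_load=log_load_of(dwmh_ml),
    )


def compute_markers(
    skeleton: SkeletonSample,
    masks: LesionMasks,
    threshold_mm: float = PERIVENTRICULAR_THRESHOLD_MM,
) -> CsvdMarkers:
    """Full marker set for one subject: PSMD + classified WMH loads."""
    pwmh, dwmh = classify_wmh(masks, threshold_mm=threshold_mm)
    vox = masks.voxel_volume_ml
    return wmh_loads(
        masks,
        pwmh_ml=float(pwmh.sum()) * vox,
        dwmh_ml=float(dwmh.sum()) * vox,
        psmd_value=psmd(skeleton),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity index 2|A n B| / (|A| + |B|) of two binary masks.

    Two empty masks are defined to agree perfectly (returns 1, warning).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        warnings.warn("Dice of two empty masks defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / size
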