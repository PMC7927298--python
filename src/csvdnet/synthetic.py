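"""Mechanistic synthetic cohort generator.

The generator emulates the statistical structure a CSVD network study
assumes, at the level of mechanism rather than of injected correlations:

* a latent, age-trending CSVD *burden* per subject (lognormal, median 1
  at the reference age);
* an atlas of 84 region centres in an ellipsoidal "brain" with a medial
  ventricle locus; subject connectomes have distance-decaying edge
  weights with multiplicative lognormal noise, thresholded to a target
  density around 0.88;
* burden attenuates edges preferentially when they are *long-range* and
  when their midpoint lies *near the ventricles* — the anatomical
  hypothesis that periventricular damage severs long association tracts;
* skeleton MD values whose spread (hence PSMD) grows with burden;
* WMH rendered as voxels around a miniature ventricle mask, with
  separately noised periventricular and deep volume components, the
  periventricular one tracking burden more tightly (deep lesions are
  more idiosyncratic);
* cognition scores linked to the subject's computed network efficiency
  (plus age and education effects), so marker-cognition associations
  arise through the network, not by construction.

Because the links are mechanistic, the sign structure of the
marker-parameter correlations is an emergent property to be validated,
not an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .connectome import WeightedConnectome, global_efficiency
from .exceptions import ValidationError
from .markers import LesionMasks, SkeletonSample

__all__ = [
    "BurdenModel",
    "EdgeModel",
    "DegradationModel",
    "MdModel",
    "WmhModel",
    "CognitionModel",
    "CohortConfig",
    "SyntheticCohort",
    "make_atlas",
    "make_base_connectome",
    "degrade_connectome",
    "simulate_markers",
    "generate_cohort",
]


def _child_seed(seed: int, *path: int) -> int:
    """Deterministic sub-seed below 2^31."""
    state = np.random.SeedSequence([int(seed), *map(int, path)]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class BurdenModel:
    """Latent burden: lognormal with an age trend, median 1 at age 60."""

    age_slope: float = 0.055  # per year, on the log scale
    noise_sd: float = 0.45
    reference_age: float = 60.0


@dataclass
class EdgeModel:
    """Distance-decay edge weights with lognormal noise."""

    decay_mm: float = 30.0  # lambda of exp(-d / lambda)
    weight_scale: float = 420.0  # s: weight of a zero-length connection
    noise_sd: float = 0.5  # sigma of multiplicative lognormal noise
    density: float = 0.88  # target fraction of present connections
    density_jitter: float = 0.012  # between-subject sd of the target


@dataclass
class DegradationModel:
    """Burden-dependent edge attenuation exp(-burden * beta * g_ij)."""

    beta_long: float = 2.5
    pv_weight: float = 0.95  # pi: share of g driven by ventricle proximity
    pv_scale_mm: float = 25.0  # length scale of the midpoint proximity term


@dataclass
class MdModel:
    """Skeleton mean diffusivity: Normal, spread grows with burden."""

    mean: float = 7.4e-4  # mm^2/s
    sd0: float = 6.0e-5  # mm^2/s at zero burden
    burden_sd_coef: float = 2.5e-5  # mm^2/s per unit burden
    n_voxels: int = 2000


@dataclass
class WmhModel:
    """WMH volumes (mL) with separate periventricular/deep noise.

    Mean total volume per unit burden is ``volume_coef``; a fraction
    ``pv_fraction`` of it is periventricular. The deep component carries
    more multiplicative noise (mean-one lognormal), so the
    periventricular load tracks the latent burden more tightly.
    """

    volume_coef: float = 0.65  # mL per unit burden
    pv_fraction: float = 0.8
    pv_noise_sd: float = 0.25
    deep_noise_sd: float = 0.75
    shape: Tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 1.0


@dataclass
class CognitionModel:
    """Scores linked to standardised network efficiency + demographics."""

    mmst_base: float = 28.3
    mmst_eff: float = 0.9  # points per SD of efficiency
    mmst_age: float = -0.05  # points per year over the reference age
    mmst_edu: float = 0.12
    mmst_noise: float = 1.1
    tmta_base_s: float = 36.0
    tmtb_base_s: float = 79.0
    tmt_eff: float = -0.14  # log-seconds per SD of efficiency
    tmt_age: float = 0.013
    tmt_edu: float = -0.012
    tmt_noise: float = 0.24


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible cohort."""

    n_subjects: int = 200
    n_nodes: int = 84
    age_range: Tuple[float, float] = (45.0, 74.0)
    female_fraction: float = 0.456
    burden: BurdenModel = field(default_factory=BurdenModel)
    edges: EdgeModel = field(default_factory=EdgeModel)
    degradation: DegradationModel = field(default_factory=DegradationModel)
    md: MdModel = field(default_factory=MdModel)
    wmh: WmhModel = field(default_factory=WmhModel)
    cognition: CognitionModel = field(default_factory=CognitionModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        if not 0.0 <= self.wmh.pv_fraction <= 1.0:
            raise ValidationError("pv_fraction must lie in [0, 1]")
        if not 0.0 <= self.degradation.pv_weight <= 1.0:
            raise ValidationError("pv_weight must lie in [0, 1]")
        for name, val in (
            ("edge decay", self.edges.decay_mm),
            ("edge scale", self.edges.weight_scale),
            ("MD sd", self.md.sd0),
        ):
            if val <= 0:
                raise ValidationError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Atlas and connectomes
# ---------------------------------------------------------------------------

_SEMI_AXES = np.array([65.0, 80.0, 55.0])  # mm, roughly brain-sized ellipsoid


def make_atlas(cfg: CohortConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Region centres in an ellipsoid and the medial ventricle locus.

    The atlas is shared by all subjects of a cohort (like a parcellation);
    it depends only on the config seed and node count.
    """
    rng = np.random.default_rng(_child_seed(cfg.seed, 0xA71A5))
    pts = []
    while len(pts) < cfg.n_nodes:
        cand = rng.uniform(-1, 1, size=3)
        if (cand**2).sum() <= 1.0 and (cand**2).sum() >= 0.15:
            pts.append(cand * _SEMI_AXES)
    coords = np.array(pts)
    ventricle = np.zeros(3)
    return coords, ventricle


def _edge_geometry(coords: np.ndarray, ventricle: np.ndarray, cfg: CohortConfig):
    """Pairwise distances and the burden-susceptibility matrix g."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    mid = (coords[:, None, :] + coords[None, :, :]) / 2.0
    vdist = np.linalg.norm(mid - ventricle, axis=-1)
    prox = np.exp(-vdist / cfg.degradation.pv_scale_mm)
    dmax = d.max() if d.max() > 0 else 1.0
    pi = cfg.degradation.pv_weight
    g = (d / dmax) * ((1.0 - pi) + pi * prox)
    np.fill_diagonal(g, 0.0)
    return d, g


def make_base_connectome(cfg: CohortConfig, seed: int) -> WeightedConnectome:
    """One subject's pre-disease connectome.

    Weights are ``s * exp(-d/lambda) * eps`` with mean-one lognormal eps;
    the weakest pairs are removed down to the subject's target density
    (ties kept inclusively, so a noise-free, infinite-range configuration
    keeps every pair at weight s).
    """
    coords, ventricle = make_atlas(cfg)
    d, _ = _edge_geometry(coords, ventricle, cfg)
    rng = np.random.default_rng(seed)
    n = cfg.n_nodes
    iu = np.triu_indices(n, k=1)
    sigma = cfg.edges.noise_sd
    eps = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=iu[0].size)) if sigma > 0 else 1.0
    w_upper = cfg.edges.weight_scale * np.exp(-d[iu] / cfg.edges.decay_mm) * eps
    target = cfg.edges.density + cfg.edges.density_jitter * rng.standard_normal()
    target = float(np.clip(target, 0.05, 1.0))
    cutoff = np.quantile(w_upper, 1.0 - target)
    w_upper = np.where(w_upper >= cutoff, w_upper, 0.0)
    w = np.zeros((n, n))
    w[iu] = w_upper
    w = w + w.T
    labels = [f"region_{i:02d}" for i in range(n)]
    return WeightedConnectome(labels, w, coords)


def degrade_connectome(
    c: WeightedConnectome, burden: float, cfg: CohortConfig, seed: int = 0
) -> WeightedConnectome:
    """Attenuate edges by exp(-burden * beta * g_ij).

    g grows with inter-node distance and, weighted by pi, with proximity
    of the edge midpoint to the ventricle locus, so long-range
    periventricular edges suffer most. burden = 0 is the identity. The
    transform is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    if burden < 0:
        raise ValidationError("burden must be >= 0")
    if burden == 0:
        return c
    if c.coords is None:
        raise ValidationError("degradation needs node coordinates")
    _, g = _edge_geometry(c.coords, np.zeros(3), cfg)
    factor = np.exp(-burden * cfg.degradation.beta_long * g)
    return c.with_weights(c.weights * factor)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def _miniature_ventricle(shape: Tuple[int, int, int]) -> np.ndarray:
    """Small central ellipsoid standing in for the ventricles."""
    zz, yy, xx = np.indices(shape)
    centre = (np.array(shape) - 1) / 2.0
    semi = np.array([4.0, 7.0, 4.0])
    r2 = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    )
    return r2 <= 1.0


def simulate_markers(
    burden: float,
    cfg: CohortConfig,
    seed: int,
    icv_ml: float = 1480.0,
    ventricle_ml: float = 25.0,
) -> Tuple[SkeletonSample, LesionMasks]:
    """Skeleton MD sample and lesion masks for one subject.

    MD values: Normal(mean, sd0 + c * burden) truncated to positive, so
    PSMD increases with burden. WMH: periventricular and deep volume
    components, each ``coef * burden * mean-one lognormal noise``, placed
    as voxels inside / beyond the 10 mm shell around a miniature central
    ventricle mask (1 mm isotropic by default).
    """
    if burden < 0:
        raise ValidationError("burden must be >= 0")
    rng = np.random.default_rng(seed)
    md_sd = cfg.md.sd0 + cfg.md.burden_sd_coef * burden
    vals = rng.normal(cfg.md.mean, md_sd, size=cfg.md.n_voxels)
    vals = np.abs(vals)  # truncation; mean >> sd so folding is negligible
    vals[vals == 0] = cfg.md.mean
    skeleton = SkeletonSample(vals)

    shape = cfg.wmh.shape
    vox_mm = cfg.wmh.voxel_mm
    ventricles = _miniature_ventricle(shape)
    from scipy import ndimage

    dist = ndimage.distance_transform_edt(~ventricles, sampling=(vox_mm,) * 3)
    pv_band = (~ventricles) & (dist <= 10.0)
    deep_band = (dist > 10.0) & (dist <= 28.0)

    s_pv, s_dp = cfg.wmh.pv_noise_sd, cfg.wmh.deep_noise_sd
    pv_ml = (
        cfg.wmh.volume_coef
        * cfg.wmh.pv_fraction
        * burden
        * np.exp(rng.normal(-0.5 * s_pv**2, s_pv))
    )
    dp_ml = (
        cfg.wmh.volume_coef
        * (1.0 - cfg.wmh.pv_fraction)
        * burden
        * np.exp(rng.normal(-0.5 * s_dp**2, s_dp))
    )
    voxel_ml = vox_mm**3 / 1000.0
    wmh = np.zeros(shape, dtype=bool)
    for band, vol_ml in ((pv_band, pv_ml), (deep_band, dp_ml)):
        candidates = np.flatnonzero(band.ravel())
        n_vox = min(int(round(vol_ml / voxel_ml)), candidates.size)
        if n_vox > 0:
            chosen = rng.choice(candidates, size=n_vox, replace=False)
            wmh.ravel()[chosen] = True
    masks = LesionMasks(
        wmh=wmh,
        ventricles=ventricles,
        voxel_dims=(vox_mm,) * 3,
        icv_ml=icv_ml,
        ventricle_ml=ventricle_ml,
    )
    return skeleton, masks


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A generated cohort: covariate table plus per-subject raw data."""

    table: pd.DataFrame
    connectomes: Dict[str, WeightedConnectome]
    skeletons: Dict[str, SkeletonSample]
    masks: Dict[str, LesionMasks]
    config: CohortConfig


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort, deterministic given ``cfg.seed``.

    The covariate table stores the latent burden (for validation only)
    and cognition scores; connectomes, skeleton samples and lesion masks
    are returned per subject for the downstream metric/marker stages.
    """
    cfg.__post_init__()  # re-validate: fields may have been overridden
    rng = np.random.default_rng(_child_seed(cfg.seed, 0xC0807))
    n = cfg.n_subjects
    ids = [f"sub-{i:04d}" for i in range(n)]
    age = rng.uniform(*cfg.age_range, size=n)
    sex = (rng.random(n) < cfg.female_fraction).astype(int)
    education = np.clip(np.round(rng.normal(13.0, 3.0, size=n)), 8, 20)
    brain_volume = rng.normal(1480.0, 110.0, size=n) - 2.0 * (age - 60.0)
    ventricle_volume = np.exp(
        np.log(25.0) + 0.03 * (age - 60.0) + rng.normal(0.0, 0.35, size=n)
    )
    bm = cfg.burden
    burden = np.exp(
        bm.age_slope * (age - bm.reference_age) + rng.normal(0.0, bm.noise_sd, size=n)
    )

    connectomes: Dict[str, WeightedConnectome] = {}
    skeletons: Dict[str, SkeletonSample] = {}
    masks: Dict[str, LesionMasks] = {}
    efficiency = np.empty(n)
    for i, sid in enumerate(ids):
        base = make_base_connectome(cfg, seed=_child_seed(cfg.seed, 1, i))
        conn = degrade_connectome(base, burden[i], cfg, seed=_child_seed(cfg.seed, 2, i))
        connectomes[sid] = conn
        wmax = conn.weights.max()
        efficiency[i] = global_efficiency(
            conn.with_weights(conn.weights / wmax) if wmax > 0 else conn
        )
        skel, lm = simulate_markers(
            burden[i],
            cfg,
            seed=_child_seed(cfg.seed, 3, i),
            icv_ml=float(brain_volume[i] + ventricle_volume[i]),
            ventricle_ml=float(ventricle_volume[i]),
        )
        skeletons[sid] = skel
        masks[sid] = lm

    z_eff = (efficiency - efficiency.mean()) / efficiency.std()
    cg = cfg.cognition
    mmst = np.clip(
        np.round(
            cg.mmst_base
            + cg.mmst_eff * z_eff
            + cg.mmst_age * (age - 60.0)
            + cg.mmst_edu * (education - 13.0)
            + rng.normal(0.0, cg.mmst_noise, size=n)
        ),
        0,
        30,
    )
    tmta = np.exp(
        np.log(cg.tmta_base_s)
        + cg.tmt_eff * z_eff
        + cg.tmt_age * (age - 60.0)
        + cg.tmt_edu * (education - 13.0)
        + rng.normal(0.0, cg.tmt_noise, size=n)
    )
    tmtb = np.exp(
        np.log(cg.tmtb_base_s)
        + cg.tmt_eff * z_eff
        + cg.tmt_age * (age - 60.0)
        + cg.tmt_edu * (education - 13.0)
        + rng.normal(0.0, cg.tmt_noise, size=n)
    )

    table = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "sex": sex,
            "education_years": education,
            "brain_volume_ml": brain_volume,
            "ventricle_volume_ml": ventricle_volume,
            "latent_burden": burden,
            "mmst": mmst,
            "tmta_seconds": tmta,
            "tmtb_seconds": tmtb,
        }
    )
    return SyntheticCohort(
        table=table,
        connectomes=connectomes,
        skeletons=skeletons,
        masks=masks,
        config=cfg,
    )
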