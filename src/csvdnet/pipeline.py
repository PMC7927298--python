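"""Library layer tying the stages together: cohort-level metric and
marker tables, the merged subject table, and the end-to-end study."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .connectome import WeightedConnectome
from .markers import CsvdMarkers, LesionMasks, SkeletonSample, compute_markers
from .metrics import compute_metrics, metrics_table
from .stats import AnalysisPlan, run_association_analysis
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = [
    "compute_cohort_metrics",
    "compute_cohort_markers",
    "assemble_subject_table",
    "run_study",
    "StudyResult",
]

logger = logging.getLogger(__name__)

MARKERS_COLUMNS = [
    "subject_id",
    "psmd",
    "wmh_ml",
    "pwmh_ml",
    "dwmh_ml",
    "wmh_load",
    "pwmh_load",
    "dwmh_load",
    "log_wmh_load",
    "log_pwmh_load",
    "log_dwmh_load",
]


def compute_cohort_metrics(
    connectomes: Dict[str, WeightedConnectome],
    n_nulls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """One GraphMetricsRecord row per subject; per-subject seeds are
    derived from ``seed`` and the subject's position."""
    records = []
    for i, (sid, conn) in enumerate(sorted(connectomes.items())):
        rec = compute_metrics(conn, n_nulls=n_nulls, seed=seed + i * (n_nulls + 7))
        records.append((sid, rec))
    return metrics_table(records)


def compute_cohort_markers(
    skeletons: Dict[str, SkeletonSample],
    masks: Dict[str, LesionMasks],
) -> pd.DataFrame:
    """One CsvdMarkers row per subject."""
    rows = []
    for sid in sorted(skeletons):
        mk: CsvdMarkers = compute_markers(skeletons[sid], masks[sid])
        row = {"subject_id": sid, **mk.__dict__}
        rows.append(row)
    return pd.DataFrame(rows)[MARKERS_COLUMNS]


def assemble_subject_table(
    covariates: pd.DataFrame,
    metrics: pd.DataFrame,
    markers: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join covariates, metrics and markers on subject_id."""
    merged = covariates.merge(metrics, on="subject_id", how="inner").merge(
        markers, on="subject_id", how="inner"
    )
    n_dropped = len(covariates) - len(merged)
    if n_dropped:
        logger.info("assemble_subject_table: %d subjects without complete data", n_dropped)
    return merged


@dataclass
class StudyResult:
    """End-to-end study output: merged table + statistical tables."""

    cohort: SyntheticCohort
    subjects: pd.DataFrame
    associations: pd.DataFrame
    comparisons: pd.DataFrame
    cognition: pd.DataFrame


def run_study(
    cfg: Optional[CohortConfig] = None,
    n_nulls: int = 100,
    plan: Optional[AnalysisPlan] = None,
) -> StudyResult:
    """Generate a synthetic cohort and run the full analysis on it."""
    cfg = cfg or CohortConfig()
    cohort = generate_cohort(cfg)
    metrics = compute_cohort_metrics(cohort.connectomes, n_nulls=n_nulls, seed=cfg.seed)
    markers = compute_cohort_markers(cohort.skeletons, cohort.masks)
    subjects = assemble_subject_table(cohort.table, metrics, markers)
    results = run_association_analysis(subjects, plan=plan)
    return StudyResult(
        cohort=cohort,
        subjects=subjects,
        associations=results["associations"],
        comparisons=results["comparisons"],
        cognition=results["cognition"],
    )
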