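"""Statistical layer: linear models, dependent-correlation comparison,
multiple-testing correction, and the cohort-level association analysis.

The association analysis mirrors an epidemiological reporting style:
simple linear regressions of each global graph parameter on each CSVD
marker come first, followed by models adjusted for age, sex, brain
volume, median edge weight (and cardiovascular risk factors where
available). Correlations of a graph parameter with periventricular vs
deep WMH load — two dependent correlations sharing the parameter — are
compared with the Pearson–Filon z statistic. Cognitive outcomes (MMST,
TMT-A, TMT-B) are modelled against markers and parameters with and
without adjustment for age, sex and education.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "RegressionFit",
    "CorrelationComparison",
    "AnalysisPlan",
    "fit_linear_model",
    "pearson_filon_z",
    "adjust_pvalues",
    "run_association_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary for one outcome ~ focal predictor (+ covariates)."""

    outcome: str
    predictor: str
    covariate_names: Tuple[str, ...]
    params: Dict[str, float]
    bse: Dict[str, float]
    tvalues: Dict[str, float]
    pvalues: Dict[str, float]
    r: float  # Pearson r of outcome with focal predictor (simple model only)
    r_squared: float
    n: int

    @property
    def is_simple(self) -> bool:
        return len(self.covariate_names) == 0


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> List[str]:
    """Names of columns that add no rank beyond the preceding ones."""
    bad = []
    rank = 0
    for j in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    return bad


def fit_linear_model(
    y: np.ndarray,
    x_focal: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    outcome_name: str = "y",
    predictor_name: str = "x",
    covariate_names: Optional[Sequence[str]] = None,
) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x_focal`` (+ covariates).

    Rows must be complete (missing data are dropped upstream). The simple
    (no-covariate) model additionally reports the Pearson correlation of
    outcome and focal predictor, whose square equals the model R^2.
    """
    y = np.asarray(y, dtype=float)
    x_focal = np.asarray(x_focal, dtype=float)
    if y.ndim != 1 or x_focal.shape != y.shape:
        raise ValidationError("y and x_focal must be 1-D arrays of equal length")
    if np.isnan(y).any() or np.isnan(x_focal).any():
        raise ValidationError("missing values must be removed before fitting")
    cols = [np.ones_like(y), x_focal]
    names = ["const", predictor_name]
    cov_names: Tuple[str, ...] = ()
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if np.isnan(cov).any():
            raise ValidationError("missing values must be removed before fitting")
        if covariate_names is None:
            covariate_names = [f"cov{j}" for j in range(cov.shape[1])]
        cov_names = tuple(covariate_names)
        cols.extend(cov.T)
        names.extend(cov_names)
    x = np.column_stack(cols)
    n, p = x.shape
    if n <= p + 2:
        raise ValidationError(f"too few observations (n={n}) for {p} parameters")
    if np.linalg.matrix_rank(x) < p:
        bad = _collinear_columns(x, names)
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, x).fit()
    if covariates is None:
        r = float(np.corrcoef(y, x_focal)[0, 1])
    else:
        r = float("nan")
    return RegressionFit(
        outcome=outcome_name,
        predictor=predictor_name,
        covariate_names=cov_names,
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        tvalues=dict(zip(names, map(float, res.tvalues))),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        r=r,
        r_squared=float(res.rsquared),
        n=int(n),
    )


@dataclass(frozen=True)
class CorrelationComparison:
    """Two dependent correlations sharing one variable, and their test."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float


def pearson_filon_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> CorrelationComparison:
    """Pearson–Filon z test for two overlapping dependent correlations.

    Variable j is shared (here: the graph parameter); r_jk and r_jh are
    its correlations with the two markers and r_kh the correlation
    between the markers. The statistic is

        z = (r_jk - r_jh) * sqrt(n) / sqrt((1-r_jk^2)^2 + (1-r_jh^2)^2 - 2k)
        k = r_kh (1 - r_jk^2 - r_jh^2)
            - (r_jk r_jh / 2) (1 - r_jk^2 - r_jh^2 - r_kh^2)

    with a two-sided p-value from the standard normal.
    """
    if n < 10:
        raise ValidationError("pearson_filon_z requires n >= 10")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"{name} = {r} outside [-1, 1]")
    if abs(r_jk) == 1.0 or abs(r_jh) == 1.0 or abs(r_kh) == 1.0:
        raise ValidationError("degenerate correlation of magnitude 1")
    if r_jk == r_jh:
        return CorrelationComparison(r_jk, r_jh, r_kh, int(n), 0.0, 1.0)
    k = r_kh * (1 - r_jk**2 - r_jh**2) - 0.5 * r_jk * r_jh * (
        1 - r_jk**2 - r_jh**2 - r_kh**2
    )
    var = (1 - r_jk**2) ** 2 + (1 - r_jh**2) ** 2 - 2 * k
    z = (r_jk - r_jh) * math.sqrt(n) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(r_jk, r_jh, r_kh, int(n), float(z), float(p))


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction; order of the input is preserved.

    ``method`` is 'bonferroni' (default) or 'bh' (Benjamini-Hochberg
    step-up false-discovery-rate control).
    """
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in ("bh", "fdr_bh"):
        from statsmodels.stats.multitest import multipletests

        if p.size == 0:
            return p.copy()
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown correction method: {method!r}")


# ---------------------------------------------------------------------------
# Cohort-level association analysis
# ---------------------------------------------------------------------------

DEFAULT_MARKERS = ("psmd", "log_wmh_load", "log_pwmh_load", "log_dwmh_load")
DEFAULT_PARAMETERS = ("geff_norm", "clus_norm", "modularity_q", "swp")
DEFAULT_ADJUSTMENT = ("age", "sex", "brain_volume_ml", "median_edge_weight")
DEFAULT_RISK_FACTORS = ("smoking", "hypertension", "diabetes", "bmi")
DEFAULT_COGNITION = ("mmst", "tmta_seconds", "tmtb_seconds")
COGNITION_ADJUSTMENT = ("age", "sex", "education_years")


@dataclass
class AnalysisPlan:
    """Which markers, parameters and covariates enter the analysis."""

    markers: Tuple[str, ...] = DEFAULT_MARKERS
    parameters: Tuple[str, ...] = DEFAULT_PARAMETERS
    adjustment: Tuple[str, ...] = DEFAULT_ADJUSTMENT
    risk_factors: Tuple[str, ...] = DEFAULT_RISK_FACTORS
    cognition: Tuple[str, ...] = DEFAULT_COGNITION
    cognition_adjustment: Tuple[str, ...] = COGNITION_ADJUSTMENT
    correction_method: str = "bonferroni"


def _complete_rows(df: pd.DataFrame, cols: Sequence[str], context: str) -> pd.DataFrame:
    sub = df[list(cols)]
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d incomplete rows of %d", context, dropped, len(df))
    return df.loc[keep]

def _fit_rows(fit: RegressionFit, analysis: str, model: str) -> List[dict]:
    rows = []
    for term in fit.params:
        rows.append(
            {
                "analysis": analysis,
                "outcome": fit.outcome,
                "predictor": fit.predictor,
                "model": model,
                "term": term,
                "estimate": fit.params[term],
                "se": fit.bse[term],
                "t": fit.tvalues[term],
                "p": fit.pvalues[term],
                "r": fit.r if term == fit.predictor else float("nan"),
                "r_squared": fit.r_squared,
                "n": fit.n,
            }
        )
    return rows


def run_association_analysis(
    cohort: pd.DataFrame, plan: Optional[AnalysisPlan] = None
) -> Dict[str, pd.DataFrame]:
    """Full statistical analysis of one cohort table.

    Returns a dict with three tidy tables:

    ``associations``
        marker x parameter simple and adjusted OLS fits, long format.
    ``comparisons``
        per-parameter Pearson–Filon comparison of the correlations with
        periventricular vs deep WMH load.
    ``cognition``
        cognitive-outcome models (simple + adjusted) with Bonferroni (or
        BH) correction across the tests of each outcome.
    """
    plan = plan or AnalysisPlan()
    required = set(plan.markers) | set(plan.parameters) | set(plan.adjustment)
    required |= set(plan.cognition) | set(plan.cognition_adjustment)
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValidationError(f"cohort table is missing required columns: {missing}")
    risk = [c for c in plan.risk_factors if c in cohort.columns]

    assoc_rows: List[dict] = []
    for marker in plan.markers:
        for param in plan.parameters:
            simple_df = _complete_rows(cohort, [param, marker], f"{param}~{marker}")
            fit = fit_linear_model(
                simple_df[param].to_numpy(),
                simple_df[marker].to_numpy(),
                outcome_name=param,
                predictor_name=marker,
            )
            assoc_rows.extend(_fit_rows(fit, "marker_vs_parameter", "simple"))
            adj_cols = list(plan.adjustment) + risk
            adj_df = _complete_rows(
                cohort, [param, marker] + adj_cols, f"{param}~{marker}+covs"
            )
            fit_adj = fit_linear_model(
                adj_df[param].to_numpy(),
                adj_df[marker].to_numpy(),
                covariates=adj_df[adj_cols].to_numpy(),
                outcome_name=param,
                predictor_name=marker,
                covariate_names=adj_cols,
            )
            assoc_rows.extend(_fit_rows(fit_adj, "marker_vs_parameter", "adjusted"))
    associations = pd.DataFrame(assoc_rows)

    comp_rows: List[dict] = []
    for param in plan.parameters:
        sub = _complete_rows(
            cohort, [param, "log_pwmh_load", "log_dwmh_load"], f"PF {param}"
        )
        r_jk = float(sub[param].corr(sub["log_pwmh_load"]))
        r_jh = float(sub[param].corr(sub["log_dwmh_load"]))
        r_kh = float(sub["log_pwmh_load"].corr(sub["log_dwmh_load"]))
        comp = pearson_filon_z(r_jk, r_jh, r_kh, len(sub))
        comp_rows.append(
            {
                "parameter": param,
                "r_pwmh": comp.r_jk,
                "r_dwmh": comp.r_jh,
                "r_markers": comp.r_kh,
                "n": comp.n,
                "z": comp.z,
                "p": comp.p,
            }
        )
    comparisons = pd.DataFrame(comp_rows)

    cog_rows: List[dict] = []
    predictors = list(plan.markers[:1]) + ["log_pwmh_load", "log_dwmh_load"] + list(
        plan.parameters
    )
    for outcome in plan.cognition:
        per_model: Dict[str, List[int]] = {"simple": [], "adjusted": []}
        for pred in predictors:
            simple_df = _complete_rows(cohort, [outcome, pred], f"{outcome}~{pred}")
            fit = fit_linear_model(
                simple_df[outcome].to_numpy(),
                simple_df[pred].to_numpy(),
                outcome_name=outcome,
                predictor_name=pred,
            )
            rows = _fit_rows(fit, "cognition", "simple")
            idx = next(i for i, r in enumerate(rows) if r["term"] == pred)
            per_model["simple"].append(len(cog_rows) + idx)
            cog_rows.extend(rows)

            adj_cols = list(plan.cognition_adjustment)
            adj_df = _complete_rows(
                cohort, [outcome, pred] + adj_cols, f"{outcome}~{pred}+covs"
            )
            fit_adj = fit_linear_model(
                adj_df[outcome].to_numpy(),
                adj_df[pred].to_numpy(),
                covariates=adj_df[adj_cols].to_numpy(),
                outcome_name=outcome,
                predictor_name=pred,
                covariate_names=adj_cols,
            )
            rows = _fit_rows(fit_adj, "cognition", "adjusted")
            idx = next(i for i, r in enumerate(rows) if r["term"] == pred)
            per_model["adjusted"].append(len(cog_rows) + idx)
            cog_rows.extend(rows)
        # correct across the focal tests of this outcome, per model type
        for model, idxs in per_model.items():
            ps = [cog_rows[i]["p"] for i in idxs]
            adj = adjust_pvalues(ps, method=plan.correction_method)
            for i, pa in zip(idxs, adj):
                cog_rows[i]["p_adjusted"] = float(pa)
    cognition = pd.DataFrame(cog_rows)

    return {
        "associations": associations,
        "comparisons": comparisons,
        "cognition": cognition,
    }
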