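"""Subgroup stratification, leave-one-out sensitivity, and publication-bias checks.

Subgroup analysis re-runs the heterogeneity-driven pooling independently
within each level of a stratification label (ethnicity, or any key carried
in ``StudyRecord.extra_labels`` such as ER or BRCA status). Leave-one-out
re-pools k times, omitting each study in turn, to expose single influential
datasets. Publication bias is screened with the funnel-plot point set
(log OR against its standard error) plus Egger's regression — the ordinary
least squares of the standardized effect y_i/se_i on precision 1/se_i, whose
intercept is zero for a symmetric funnel; a two-sided t-test on the
intercept with k-2 df quantifies asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import t as t_dist

from .effects import EffectEstimate, estimate_effect
from .genetic_models import GeneticModel, build_contrast
from .pooling import InsufficientStudiesError, PooledResult, pool_auto, pool_mh_fixed
from .study_data import Dataset

__all__ = [
    "SubgroupReport",
    "LeaveOneOutReport",
    "FunnelReport",
    "subgroup_analysis",
    "leave_one_out",
    "egger_test",
]


@dataclass(frozen=True)
class SubgroupReport:
    group_key: str
    #: level -> {model -> PooledResult}
    rows: Mapping[str, Mapping[GeneticModel, PooledResult]]


@dataclass(frozen=True)
class LeaveOneOutReport:
    baseline: PooledResult
    #: omitted study_id -> pooled result over the remaining k-1 studies
    rows: Mapping[str, PooledResult]

    @property
    def max_abs_shift(self) -> float:
        """Largest |log OR change| from the baseline across omissions."""
        return max(abs(r.y - self.baseline.y) for r in self.rows.values())


@dataclass(frozen=True)
class FunnelReport:
    #: (study_id, log OR, SE) triples for funnel plotting
    points: tuple[tuple[str, float, float], ...]
    egger_intercept: float
    egger_se: float
    egger_p: float


def _group_value(study, group_key: str) -> str | None:
    if group_key == "ethnicity":
        return study.ethnicity or None
    return study.extra_labels.get(group_key) or None


def subgroup_analysis(
    ds: Dataset,
    group_key: str,
    models: Sequence[GeneticModel],
    alpha_het: float = 0.1,
) -> SubgroupReport:
    """Pool each genetic model within each level of ``group_key``.

    Studies without a value for the key are excluded. Levels with a single
    study report that study's estimate via the (degenerate) k=1 MH pool,
    flagged ``single_study``.
    """
    levels: dict[str, list] = {}
    for s in ds.studies:
        v = _group_value(s, group_key)
        if v is not None:
            levels.setdefault(v, []).append(s)
    rows: dict[str, dict[GeneticModel, PooledResult]] = {}
    for level, studies in levels.items():
        row: dict[GeneticModel, PooledResult] = {}
        for model in models:
            tables = [build_contrast(s, model) for s in studies]
            if len(tables) == 1:
                row[GeneticModel(model)] = pool_mh_fixed(tables)
            else:
                row[GeneticModel(model)] = pool_auto(tables, alpha_het=alpha_het)
        rows[level] = row
    return SubgroupReport(group_key=group_key, rows=rows)


def leave_one_out(
    ds: Dataset, model: GeneticModel, alpha_het: float = 0.1
) -> LeaveOneOutReport:
    """Re-pool after omitting each study in turn (model re-selected each time)."""
    if len(ds.studies) < 3:
        raise InsufficientStudiesError(
            f"leave-one-out needs k >= 3, got {len(ds.studies)}"
        )
    tables = {s.study_id: build_contrast(s, model) for s in ds.studies}
    baseline = pool_auto(list(tables.values()), alpha_het=alpha_het)
    rows = {
        omitted: pool_auto(
            [t for sid, t in tables.items() if sid != omitted], alpha_het=alpha_het
        )
        for omitted in tables
    }
    return LeaveOneOutReport(baseline=baseline, rows=rows)


def egger_test(effects: Sequence[EffectEstimate]) -> FunnelReport:
    """Egger regression for funnel-plot asymmetry.

    OLS of y_i/se_i on 1/se_i; the intercept estimates the small-study bias,
    tested two-sided against zero with k-2 df.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger test needs k >= 3, got {k}")
    x = np.array([1.0 / e.se for e in effects])
    z = np.array([e.y / e.se for e in effects])
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise np.linalg.LinAlgError(
            "all studies share the same precision: Egger design matrix is rank-deficient"
        )
    slope = float(np.sum((x - x.mean()) * (z - z.mean())) / sxx)
    intercept = float(z.mean() - slope * x.mean())
    resid = z - (intercept + slope * x)
    s2 = float(np.sum(resid**2)) / (k - 2)
    se_int = math.sqrt(s2 * (1.0 / k + x.mean() ** 2 / sxx))
    if se_int == 0:
        p = 1.0 if intercept == 0 else 0.0
    else:
        p = 2.0 * float(t_dist.sf(abs(intercept / se_int), k - 2))
    return FunnelReport(
        points=tuple((e.study_id, e.y, e.se) for e in effects),
        egger_intercept=intercept,
        egger_se=se_int,
        egger_p=p,
    )


def funnel_points_for(ds: Dataset, model: GeneticModel) -> list[EffectEstimate]:
    """Per-study effects for a funnel plot of one contrast."""
    return [estimate_effect(build_contrast(s, model)) for s in ds.studies]
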