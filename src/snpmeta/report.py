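"""Analysis orchestration and delimited-text report rendering.

`run_analysis` runs the full pipeline for one dataset — per-study effects,
control HWE, heterogeneity-driven pooling for every requested genetic model
overall and within subgroups, leave-one-out sensitivity, and funnel/Egger
diagnostics — and writes each piece as a tab-separated table plus a JSON run
log. Outputs are deterministic for a given config: re-running produces
byte-identical files.

ORs and CI bounds are printed to 3 decimals; P-values below 0.001 render as
``<0.001``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .effects import estimate_effect
from .genetic_models import GeneticModel, build_contrast, contrast_label
from .hwe import hwe_test
from .pooling import PooledResult, pool_auto
from .robustness import egger_test, leave_one_out, subgroup_analysis
from .study_data import Dataset, summarize

__all__ = ["AnalysisConfig", "run_analysis", "format_p", "format_or_ci"]

ALL_MODELS = tuple(GeneticModel)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one pipeline run over one dataset."""

    out_dir: str | Path
    models: tuple[GeneticModel, ...] = ALL_MODELS
    group_key: str | None = "ethnicity"
    alpha_het: float = 0.1
    alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one genetic model must be selected")
        for th in (self.alpha_het, self.alpha):
            if not 0 < th < 1:
                raise ValueError(f"thresholds must lie in (0, 1), got {th}")


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_or_ci(r: PooledResult) -> str:
    return f"{r.or_value:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})"


def _pooled_row(level: str, model: GeneticModel, ds: Dataset, r: PooledResult) -> dict:
    het = r.het
    return {
        "group": level,
        "model": model.value,
        "contrast": contrast_label(model, ds.risk_allele, ds.ref_allele),
        "k": r.k,
        "or_ci": format_or_ci(r),
        "p_h": format_p(het.p_q) if het else "",
        "model_used": r.model_used if not r.single_study else "single-study",
        "or": round(r.or_value, 6),
        "ci_low": round(r.ci_low, 6),
        "ci_high": round(r.ci_high, 6),
        "p_pooled": format_p(r.p_value),
        "q": round(het.q, 6) if het else "",
        "i2_pct": round(het.i2, 2) if het else "",
        "tau2": round(het.tau2, 6) if het else "",
    }


def pooled_table(ds: Dataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """Long-format pooled-results table: Total plus one block per subgroup level."""
    rows = []
    for model in cfg.models:
        tables = [build_contrast(s, model) for s in ds.studies]
        rows.append(_pooled_row("Total", model, ds, pool_auto(tables, cfg.alpha_het)))
    if cfg.group_key:
        rep = subgroup_analysis(ds, cfg.group_key, cfg.models, alpha_het=cfg.alpha_het)
        for level in sorted(rep.rows):
            for model in cfg.models:
                rows.append(_pooled_row(level, model, ds, rep.rows[level][model]))
    return pd.DataFrame(rows)


def effects_table(ds: Dataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-study effects under each model, with control HWE."""
    rows = []
    for s in ds.studies:
        h = hwe_test(s.controls)
        for model in cfg.models:
            e = estimate_effect(build_contrast(s, model))
            rows.append(
                {
                    "study_id": s.study_id,
                    "ethnicity": s.ethnicity,
                    "model": model.value,
                    "or": round(e.or_value, 6),
                    "ci_low": round(e.ci_low, 6),
                    "ci_high": round(e.ci_high, 6),
                    "log_or": round(e.y, 6),
                    "se": round(e.se, 6),
                    "corrected": e.corrected,
                    "hwe_p": format_p(h.p_value),
                    "control_risk_af": round(h.allele_freq, 4),
                }
            )
    return pd.DataFrame(rows)


def loo_table(ds: Dataset, model: GeneticModel, cfg: AnalysisConfig) -> pd.DataFrame:
    rep = leave_one_out(ds, model, alpha_het=cfg.alpha_het)
    rows = [
        {
            "omitted": "(none)",
            "k": rep.baseline.k,
            "or_ci": format_or_ci(rep.baseline),
            "model_used": rep.baseline.model_used,
        }
    ]
    for sid in sorted(rep.rows):
        r = rep.rows[sid]
        rows.append(
            {"omitted": sid, "k": r.k, "or_ci": format_or_ci(r), "model_used": r.model_used}
        )
    return pd.DataFrame(rows)


def funnel_table(ds: Dataset, model: GeneticModel) -> tuple[pd.DataFrame, dict]:
    effects = [estimate_effect(build_contrast(s, model)) for s in ds.studies]
    rep = egger_test(effects)
    pts = pd.DataFrame(rep.points, columns=["study_id", "log_or", "se"]).round(6)
    egger = {
        "egger_intercept": round(rep.egger_intercept, 6),
        "egger_se": round(rep.egger_se, 6),
        "egger_p": round(rep.egger_p, 6),
    }
    return pts, egger


def run_analysis(ds: Dataset, cfg: AnalysisConfig) -> dict[str, Path]:
    """Run the pipeline for one dataset and write its report bundle.

    Returns a name -> path map of everything written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not ds.studies:
        raise ValueError(f"dataset {ds.snp_id} is empty")
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out / f"{ds.snp_id}_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p

    _write("pooled", pooled_table(ds, cfg))
    _write("effects", effects_table(ds, cfg))
    egger_by_model = {}
    for model in cfg.models:
        if len(ds.studies) >= 3:
            _write(f"loo_{model.value}", loo_table(ds, model, cfg))
            pts, egger = funnel_table(ds, model)
            _write(f"funnel_{model.value}", pts)
            egger_by_model[model.value] = egger

    s = summarize(ds)
    log = {
        "package": "snpmeta",
        "version": __version__,
        "snp_id": ds.snp_id,
        "risk_allele": ds.risk_allele,
        "ref_allele": ds.ref_allele,
        "n_datasets": s.n_datasets,
        "total_cases": s.total_cases,
        "total_controls": s.total_controls,
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "out_dir"},
            "models": [m.value for m in cfg.models],
            "out_dir": str(cfg.out_dir),
        },
        "egger": egger_by_model,
    }
    log_path = out / f"{ds.snp_id}_run.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written["run_log"] = log_path
    return written
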