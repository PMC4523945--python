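"""The five genetic-model contrasts of a biallelic SNP as 2x2 case-control tables.

With R the risk allele and r the reference allele, the models compare:

==============  =======================  =========================
model           exposed                  unexposed
==============  =======================  =========================
homozygote      RR                       rr        (Rr dropped)
heterozygote    Rr                       rr        (RR dropped)
dominant        RR + Rr                  rr
recessive       RR                       Rr + rr
allele          R alleles (2*RR + Rr)    r alleles (2*rr + Rr)
==============  =======================  =========================

The two codominant models discard rather than collapse the third genotype
class, matching the usual "RR versus rr" / "Rr versus rr" table headers.
The allele model counts 2n alleles per n subjects as independent
observations, the standard crude allele-contrast convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .study_data import StudyRecord

__all__ = ["GeneticModel", "ContrastTable", "build_contrast", "contrast_label"]


class GeneticModel(str, Enum):
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ALLELE = "allele"


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure table: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int
    model: GeneticModel
    study_id: str

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table for {self.study_id!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_contrast(study: StudyRecord, model: GeneticModel) -> ContrastTable:
    """Construct the 2x2 table for one study under one genetic model."""
    model = GeneticModel(model)
    out = {}
    for arm, g in (("case", study.cases), ("control", study.controls)):
        if model is GeneticModel.HOMOZYGOTE:
            exp, unexp = g.n_hom_risk, g.n_hom_ref
        elif model is GeneticModel.HETEROZYGOTE:
            exp, unexp = g.n_het, g.n_hom_ref
        elif model is GeneticModel.DOMINANT:
            exp, unexp = g.n_hom_risk + g.n_het, g.n_hom_ref
        elif model is GeneticModel.RECESSIVE:
            exp, unexp = g.n_hom_risk, g.n_het + g.n_hom_ref
        else:  # allele
            exp, unexp = g.allele_counts
        out[arm] = (exp, unexp)
    (a, b), (c, d) = out["case"], out["control"]
    return ContrastTable(a=a, b=b, c=c, d=d, model=model, study_id=study.study_id)


def contrast_label(model: GeneticModel, risk_allele: str, ref_allele: str) -> str:
    """Human-readable contrast name, e.g. ``TT versus CC`` or ``T versus C``."""
    R, r = risk_allele, ref_allele
    return {
        GeneticModel.HOMOZYGOTE: f"{R}{R} versus {r}{r}",
        GeneticModel.HETEROZYGOTE: f"{R}{r} versus {r}{r}",
        GeneticModel.DOMINANT: f"{R}{R}+{R}{r} versus {r}{r}",
        GeneticModel.RECESSIVE: f"{R}{R} versus {R}{r}+{r}{r}",
        GeneticModel.ALLELE: f"{R} versus {r}",
    }[GeneticModel(model)]
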