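"""Chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

Estimates the risk-allele frequency p from the genotype counts and compares
observed counts against the HWE expectations (n*p^2, 2n*p*q, n*q^2) with a
1-df Pearson chi-square. No Yates continuity correction and no exact test:
the plain asymptotic statistic is what published control-group P_HWE columns
are computed with, and it is the variant this package reproduces. Departure
from HWE in controls flags genotyping error or population stratification;
flagged studies are conventionally retained and examined in sensitivity
analyses rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .study_data import GenotypeCounts

__all__ = ["HweResult", "hwe_test"]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    allele_freq: float

    @property
    def out_of_equilibrium(self) -> bool:
        """Conventional alpha = 0.05 flag."""
        return self.p_value < 0.05


def hwe_test(g: GenotypeCounts) -> HweResult:
    """Test one arm's genotype counts for Hardy-Weinberg equilibrium.

    Degenerate monomorphic arms (p = 0 or 1) fit HWE exactly and return
    chi2 = 0, p = 1.
    """
    n = g.total
    if n == 0:
        raise ValueError("cannot test HWE on an empty genotype-count vector")
    p = (2 * g.n_hom_risk + g.n_het) / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (g.n_hom_risk, g.n_het, g.n_hom_ref)
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    return HweResult(chi2=stat, df=1, p_value=float(chi2.sf(stat, 1)), allele_freq=p)
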