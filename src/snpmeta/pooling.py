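"""Fixed- and random-effect pooling of stratified 2x2 tables.

Fixed effect uses the Mantel-Haenszel estimator

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with the Robins-Breslow-Greenland (RBG) variance for log OR_MH — the
standard companion implemented by Review Manager and metafor. Random
effects use the DerSimonian-Laird moment estimator: with inverse-variance
weights w_i = 1/se_i^2 and Cochran's Q = sum w_i (y_i - ybar_w)^2,

    tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)),

re-weighting each study by w*_i = 1/(se_i^2 + tau^2). Heterogeneity is
summarised by Q, its chi-square P-value on k-1 df, and
I^2 = max(0, 100 (Q - df) / Q).

Model selection follows the conventional two-step rule: pool with the fixed
MH model when the heterogeneity P-value exceeds ``alpha_het`` (default 0.1),
otherwise with DerSimonian-Laird. Q for this rule is computed from the crude
log-OR effects with inverse-variance weights, applied independently for each
contrast and subgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import chi2

from .effects import Z_95, EffectEstimate, estimate_effect
from .genetic_models import ContrastTable

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "InsufficientStudiesError",
    "heterogeneity",
    "pool_mh_fixed",
    "pool_iv_fixed",
    "pool_dl_random",
    "pool_auto",
]


class InsufficientStudiesError(ValueError):
    """Fewer studies than the operation requires."""


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_q: float
    i2: float  # percent
    tau2: float

    @property
    def classification(self) -> str:
        """mild (<25%), moderate (25-50%), large (>50%) heterogeneity."""
        if self.i2 < 25:
            return "mild"
        if self.i2 <= 50:
            return "moderate"
        return "large"


@dataclass(frozen=True)
class PooledResult:
    """Pooled log odds ratio with 95% CI and provenance.

    ``weights`` are normalised per-study weight shares under the model that
    produced the estimate (MH stratum weights, inverse-variance, or
    DerSimonian-Laird). ``het`` is ``None`` when k = 1.
    """

    model_used: str  # "fixed" | "random"
    y: float
    se: float
    k: int
    weights: Mapping[str, float] = field(default_factory=dict)
    het: HeterogeneityResult | None = None
    single_study: bool = False

    @property
    def or_value(self) -> float:
        return math.exp(self.y)

    @property
    def ci_low(self) -> float:
        return math.exp(self.y - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.y + Z_95 * self.se)

    @property
    def p_value(self) -> float:
        """Two-sided Wald test of OR = 1."""
        return float(chi2.sf((self.y / self.se) ** 2, 1))


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q, I^2 and the DerSimonian-Laird tau^2 from per-study effects."""
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(f"heterogeneity needs k >= 2, got {k}")
    w = [1.0 / e.se**2 for e in effects]
    sw = sum(w)
    ybar = sum(wi * e.y for wi, e in zip(w, effects)) / sw
    q = sum(wi * (e.y - ybar) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    denom = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=float(chi2.sf(q, df)), i2=i2, tau2=tau2)


def _mh_cells(t: ContrastTable) -> tuple[float, float, float, float]:
    # Zero-cell studies enter the MH sums with the same +0.5-per-cell
    # correction the per-study effect uses, keeping the two routes consistent.
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise InsufficientStudiesError(
            f"study {t.study_id!r}: one arm empty, table carries no OR information"
        )
    if 0 in t.cells:
        return tuple(x + 0.5 for x in t.cells)  # type: ignore[return-value]
    return t.cells


def pool_mh_fixed(
    tables: Sequence[ContrastTable], het: HeterogeneityResult | None = None
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR with RBG variance."""
    if len(tables) < 1:
        raise InsufficientStudiesError("Mantel-Haenszel pooling needs k >= 1")
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    shares: dict[str, float] = {}
    for t in tables:
        a, b, c, d = _mh_cells(t)
        n = a + b + c + d
        Ri, Si = a * d / n, b * c / n
        Pi, Qi = (a + d) / n, (b + c) / n
        R += Ri
        S += Si
        sum_PR += Pi * Ri
        sum_PSQR += Pi * Si + Qi * Ri
        sum_QS += Qi * Si
        shares[t.study_id] = Si
    if S == 0 or R == 0:
        raise InsufficientStudiesError("all tables degenerate: Mantel-Haenszel sums vanish")
    y = math.log(R) - math.log(S)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    total = sum(shares.values())
    weights = {sid: wi / total for sid, wi in shares.items()}
    return PooledResult(
        model_used="fixed",
        y=y,
        se=math.sqrt(var),
        k=len(tables),
        weights=weights,
        het=het,
        single_study=len(tables) == 1,
    )


def _weighted_pool(
    effects: Sequence[EffectEstimate], w: Sequence[float], model_used: str,
    het: HeterogeneityResult | None,
) -> PooledResult:
    sw = sum(w)
    y = sum(wi * e.y for wi, e in zip(w, effects)) / sw
    return PooledResult(
        model_used=model_used,
        y=y,
        se=1.0 / math.sqrt(sw),
        k=len(effects),
        weights={e.study_id: wi / sw for wi, e in zip(w, effects)},
        het=het,
        single_study=len(effects) == 1,
    )


def pool_iv_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling of log-OR effects."""
    if len(effects) < 1:
        raise InsufficientStudiesError("inverse-variance pooling needs k >= 1")
    het = heterogeneity(effects) if len(effects) >= 2 else None
    return _weighted_pool(effects, [1.0 / e.se**2 for e in effects], "fixed", het)


def pool_dl_random(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effect pooling of log-OR effects.

    With tau^2 truncated to zero this reduces exactly to inverse-variance
    fixed pooling.
    """
    if len(effects) < 2:
        raise InsufficientStudiesError(f"random-effect pooling needs k >= 2, got {len(effects)}")
    het = heterogeneity(effects)
    w_star = [1.0 / (e.se**2 + het.tau2) for e in effects]
    return _weighted_pool(effects, w_star, "random", het)


def pool_auto(
    tables: Sequence[ContrastTable], alpha_het: float = 0.1
) -> PooledResult:
    """Heterogeneity-driven model selection: MH fixed if P_Q > alpha_het, else DL.

    The selection is made per call, i.e. independently for each contrast and
    each subgroup being pooled.
    """
    if len(tables) < 2:
        raise InsufficientStudiesError(f"pool_auto needs k >= 2, got {len(tables)}")
    effects = [estimate_effect(t) for t in tables]
    het = heterogeneity(effects)
    if het.p_q > alpha_het:
        return pool_mh_fixed(tables, het=het)
    return pool_dl_random(effects)
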