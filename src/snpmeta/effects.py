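"""Per-study odds ratio, log odds ratio and Woolf standard error.

For a 2x2 table (a, b, c, d) the crude odds ratio is OR = ad / bc and the
log-OR standard error is the Woolf estimate sqrt(1/a + 1/b + 1/c + 1/d).
When any cell is zero, 0.5 is added to all four cells before both
computations (the Review Manager / Haldane-Anscombe convention), and the
estimate is flagged ``corrected``. Tables with an empty arm carry no
information about the odds ratio and are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genetic_models import ContrastTable

__all__ = ["EffectEstimate", "estimate_effect", "Z_95", "DegenerateTableError"]

#: Standard-normal 97.5% quantile used for all 95% intervals.
Z_95 = 1.959964


class DegenerateTableError(ValueError):
    """The table has an empty case or control arm."""


@dataclass(frozen=True)
class EffectEstimate:
    study_id: str
    y: float  # log odds ratio
    se: float
    corrected: bool = False

    @property
    def or_value(self) -> float:
        return math.exp(self.y)

    @property
    def ci_low(self) -> float:
        return math.exp(self.y - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.y + Z_95 * self.se)


def estimate_effect(t: ContrastTable) -> EffectEstimate:
    """Crude log-OR effect estimate from one study's 2x2 contrast table."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise DegenerateTableError(
            f"study {t.study_id!r} ({t.model.value}): one arm has no observations"
        )
    corrected = 0 in t.cells
    a, b, c, d = ((x + 0.5 for x in t.cells) if corrected else t.cells)
    y = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(study_id=t.study_id, y=y, se=se, corrected=corrected)
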