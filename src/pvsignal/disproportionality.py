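"""Reporting odds ratio (ROR) with Woolf variance and Wald confidence interval.

The ROR is the disproportionality statistic ``ad/(bc)`` of a 2x2
exposure-by-event table of spontaneous reports.  On the natural-log scale
its variance is the Woolf estimate ``1/a + 1/b + 1/c + 1/d`` and the
(1-alpha) CI is ``exp(y ± z * sqrt(v))``.  An ROR whose lower confidence
bound exceeds 1.00 flags a disproportionate reporting signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .contingency import StratumTable

__all__ = ["EffectEstimate", "effect_estimate", "is_signal"]


@dataclass(frozen=True)
class EffectEstimate:
    """Per-stratum log reporting odds ratio with variance and CI."""

    stratum: str
    y: float  # log ROR
    v: float  # Woolf variance of y
    ror: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def effect_estimate(table: StratumTable, level: float = 0.95) -> EffectEstimate:
    """ROR, log-scale Woolf variance and Wald CI for one stratum table.

    All four cells must be positive; apply ``continuity_correct`` first for
    tables with zero cells.  Raw strata with an empty exposure margin have
    no meaningful estimate and are rejected.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError(
            f"stratum {table.stratum}: empty exposure margin; exclude from analysis"
        )
    if min(table.a, table.b, table.c, table.d) <= 0:
        raise ValueError(
            f"stratum {table.stratum}: zero cell; apply continuity correction first"
        )
    y = math.log(table.a * table.d / (table.b * table.c))
    v = 1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(v)
    return EffectEstimate(
        stratum=table.stratum,
        y=y,
        v=v,
        ror=math.exp(y),
        ci_low=math.exp(y - half),
        ci_high=math.exp(y + half),
        level=level,
    )


def is_signal(est: EffectEstimate) -> bool:
    """True iff the lower CI bound is strictly above 1.00."""
    return est.ci_low > 1.0
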