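"""Reporting-bias diagnostics: funnel-plot coordinates and Egger's test.

Egger's linear regression test regresses the standardized effect
``z_i = y_i / se_i`` on the precision ``prec_i = 1 / se_i`` by ordinary
(unweighted) least squares; under symmetry the intercept is zero, and a
two-sided Student-t test on k-2 df flags asymmetry.  The funnel plot is
the scatter of effect versus standard error, conventionally drawn with the
se axis increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import t as student_t

from .disproportionality import EffectEstimate

__all__ = ["EggerResult", "FunnelPoint", "egger_test", "funnel_coordinates"]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t: float
    df: int
    p: float

    @property
    def asymmetric(self) -> bool:
        """Reporting-bias flag at the conventional 0.05 level."""
        return self.p < 0.05


@dataclass(frozen=True)
class FunnelPoint:
    """One stratum's funnel-plot coordinates (se drawn increasing downward)."""

    effect: float  # log ROR
    se: float


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression asymmetry test over per-stratum estimates.

    Requires k >= 3 and at least two distinct precisions; a perfect linear
    fit (zero residual variance) is degenerate and rejected.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test requires at least 3 strata")
    prec = [1.0 / e.se for e in estimates]
    z = [e.y / e.se for e in estimates]
    xbar = sum(prec) / k
    zbar = sum(z) / k
    sxx = sum((x - xbar) ** 2 for x in prec)
    if sxx == 0:
        raise ValueError("all precisions equal: Egger regression is degenerate")
    sxy = sum((x - xbar) * (y - zbar) for x, y in zip(prec, z))
    slope = sxy / sxx
    intercept = zbar - slope * xbar
    ssr = sum((y - intercept - slope * x) ** 2 for x, y in zip(prec, z))
    df = k - 2
    s2 = ssr / df
    if s2 == 0:
        raise ValueError("zero residual variance: degenerate (collinear) input")
    se_int = math.sqrt(s2 * (1.0 / k + xbar * xbar / sxx))
    tstat = intercept / se_int
    return EggerResult(
        intercept=intercept, se_intercept=se_int, t=tstat, df=df,
        p=float(2 * student_t.sf(abs(tstat), df)),
    )


def funnel_coordinates(estimates: Sequence[EffectEstimate]) -> list[FunnelPoint]:
    """One (log ROR, se) point per stratum."""
    if not estimates:
        raise ValueError("no estimates")
    return [FunnelPoint(effect=e.y, se=e.se) for e in estimates]
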