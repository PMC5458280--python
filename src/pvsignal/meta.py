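"""Meta-analysis across yearly strata: heterogeneity, pooling, sensitivity.

Heterogeneity between years is measured by Cochran's Q (the inverse-variance
weighted sum of squared deviations from the fixed-effect mean, chi-square
with k-1 df under homogeneity), I² = 100·(Q-df)/Q floored at zero, and the
DerSimonian–Laird method-of-moments between-stratum variance

    tau² = max(0, (Q - df) / (Σw - Σw²/Σw)),   w_i = 1/v_i.

Pooling follows the classic model-selection rule: a random-effects
DerSimonian–Laird pool when the Q test is significant at ``alpha``,
otherwise a fixed-effects Mantel–Haenszel pool computed from the stratum
counts with the Robins–Breslow–Greenland variance for its log odds ratio.
Leave-one-out sensitivity re-pools every (k-1)-subset under the SAME model
family as the full analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2, norm

from .contingency import StratumTable, continuity_correct
from .disproportionality import EffectEstimate, effect_estimate

__all__ = [
    "FIXED_MH",
    "RANDOM_DL",
    "HeterogeneityResult",
    "PooledResult",
    "cochran_q",
    "i_squared",
    "dl_tau2",
    "pool_random_dl",
    "pool_fixed_mh",
    "select_model",
    "leave_one_out",
]

FIXED_MH = "fixed_MH"
RANDOM_DL = "random_DL"


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    I2: float  # percent in [0, 100)
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    model: str
    y_pooled: float
    se_pooled: float
    or_pooled: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    k: int
    het: HeterogeneityResult | None


def _weights(estimates: Sequence[EffectEstimate]) -> tuple[list[float], list[float]]:
    ys = [e.y for e in estimates]
    ws = [1.0 / e.v for e in estimates]
    return ys, ws


def i_squared(Q: float, df: int) -> float:
    """I² heterogeneity percentage: 100·(Q-df)/Q, floored at 0 (0 when Q=0)."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q == 0:
        return 0.0
    return max(0.0, 100.0 * (Q - df) / Q)


def _q_stat(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float, float]:
    ys, ws = _weights(estimates)
    sw = sum(ws)
    ybar = sum(w * y for w, y in zip(ws, ys)) / sw
    Q = sum(w * (y - ybar) ** 2 for w, y in zip(ws, ys))
    df = len(estimates) - 1
    C = sw - sum(w * w for w in ws) / sw
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return Q, df, ybar, tau2


def cochran_q(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q test with I² and the DerSimonian–Laird tau²."""
    if len(estimates) < 2:
        raise ValueError("heterogeneity requires at least 2 strata")
    Q, df, _, tau2 = _q_stat(estimates)
    return HeterogeneityResult(Q=Q, df=df, p=float(chi2.sf(Q, df)), I2=i_squared(Q, df), tau2=tau2)


def dl_tau2(estimates: Sequence[EffectEstimate]) -> float:
    """DerSimonian–Laird method-of-moments between-stratum variance."""
    if len(estimates) < 2:
        raise ValueError("tau^2 requires at least 2 strata")
    return _q_stat(estimates)[3]


def _wald(y: float, se: float, level: float, model: str, k: int,
          het: HeterogeneityResult | None) -> PooledResult:
    zq = norm.ppf(0.5 + level / 2)
    z = y / se
    return PooledResult(
        model=model, y_pooled=y, se_pooled=se, or_pooled=math.exp(y),
        ci_low=math.exp(y - zq * se), ci_high=math.exp(y + zq * se),
        z=z, p=float(2 * norm.sf(abs(z))), k=k, het=het,
    )


def pool_random_dl(estimates: Sequence[EffectEstimate], level: float = 0.95) -> PooledResult:
    """DerSimonian–Laird random-effects pool of per-stratum (y, v) pairs.

    With tau² = 0 this reduces exactly to inverse-variance fixed-effect
    pooling.
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 strata")
    het = cochran_q(estimates)
    ws = [1.0 / (e.v + het.tau2) for e in estimates]
    sw = sum(ws)
    y = sum(w * e.y for w, e in zip(ws, estimates)) / sw
    se = 1.0 / math.sqrt(sw)
    return _wald(y, se, level, RANDOM_DL, len(estimates), het)


def pool_fixed_mh(tables: Sequence[StratumTable], level: float = 0.95) -> PooledResult:
    """Mantel–Haenszel fixed-effects pooled odds ratio from stratum counts.

    OR_MH = Σ(a_i d_i / T_i) / Σ(b_i c_i / T_i).  The variance of the log
    odds ratio is the Robins–Breslow–Greenland estimator.  Strata with
    zero totals contribute nothing; with a single stratum OR_MH is the
    crude odds ratio.  Heterogeneity is reported from Woolf estimates of
    the (continuity-corrected) tables when k >= 2.
    """
    tables = [t for t in tables if t.total > 0]
    if not tables:
        raise ValueError("pooling requires at least 1 non-empty stratum")
    R = sum(t.a * t.d / t.total for t in tables)
    S = sum(t.b * t.c / t.total for t in tables)
    if S == 0 or R == 0:
        raise ValueError("Mantel-Haenszel odds ratio undefined: empty diagonal sums")
    y = math.log(R / S)

    # Robins-Breslow-Greenland variance of log(OR_MH).
    sum_pr = sum(((t.a + t.d) / t.total) * (t.a * t.d / t.total) for t in tables)
    sum_ps_qr = sum(
        ((t.a + t.d) / t.total) * (t.b * t.c / t.total)
        + ((t.b + t.c) / t.total) * (t.a * t.d / t.total)
        for t in tables
    )
    sum_qs = sum(((t.b + t.c) / t.total) * (t.b * t.c / t.total) for t in tables)
    v = sum_pr / (2 * R * R) + sum_ps_qr / (2 * R * S) + sum_qs / (2 * S * S)

    het = None
    if len(tables) >= 2:
        ests = [effect_estimate(continuity_correct(t) if not t.corrected else t, level)
                for t in tables]
        het = cochran_q(ests)
    return _wald(y, math.sqrt(v), level, FIXED_MH, len(tables), het)


def select_model(het: HeterogeneityResult, alpha: float = 0.05) -> str:
    """Random effects iff the Q test is significant (p < alpha), else fixed MH."""
    return RANDOM_DL if het.p < alpha else FIXED_MH


def leave_one_out(
    estimates: Sequence[EffectEstimate],
    model: str,
    level: float = 0.95,
    tables: Sequence[StratumTable] | None = None,
) -> list[tuple[str, PooledResult]]:
    """Re-pool every (k-1)-subset under the full analysis' model family.

    The model is NOT re-selected per subset: sensitivity is a perturbation
    of the chosen analysis.  For the Mantel–Haenszel family the stratum
    ``tables`` (aligned with ``estimates``) must be supplied.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("leave-one-out requires at least 3 strata")
    if model not in (FIXED_MH, RANDOM_DL):
        raise ValueError(f"unknown model {model!r}")
    if model == FIXED_MH:
        if tables is None or len(tables) != k:
            raise ValueError("Mantel-Haenszel leave-one-out needs tables aligned with estimates")
    out: list[tuple[str, PooledResult]] = []
    for i in range(k):
        rest = [e for j, e in enumerate(estimates) if j != i]
        if model == RANDOM_DL:
            pooled = pool_random_dl(rest, level)
        else:
            pooled = pool_fixed_mh([t for j, t in enumerate(tables) if j != i], level)
        out.append((estimates[i].stratum, pooled))
    return out
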