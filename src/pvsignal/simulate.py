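"""Synthetic spontaneous-report streams and gene universes with known truth.

The report generator emulates the structure of a FAERS-style indication
cohort so the whole disproportionality pipeline is testable offline.  Per
year ``i`` a latent log reporting odds ratio ``theta_i ~ Normal(mu, tau^2)``
is drawn; each report is independently drug-exposed with ``p_exposure``;
unexposed reports carry the event term with the baseline probability, and
exposed reports with the probability whose *odds* equal
``exp(theta_i) * odds(baseline)`` — so ``true_log_or`` is exactly the log
ROR of the generating process, making parameter recovery a sharp test.

Defaults mirror the motivating study: a 2004–2015 non-small cell lung
cancer cohort of ~19200 reports with ~20% carboplatin exposure, a pooled
ROR near 2.27 and moderate between-year heterogeneity (tau = 0.2).  The
baseline event probability (0.05) is a typical reporting fraction for a
single hematologic preferred term in oncology spontaneous reports.

All randomness flows through one ``numpy`` generator seeded from the
config; identical configs produce byte-identical JSONL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contingency import StratumTable
from .reports import SafetyReport

__all__ = [
    "SimulationConfig",
    "simulate_reports",
    "simulate_yearly_tables",
    "simulate_gene_universe",
    "DECOY_DRUGS",
    "DECOY_REACTIONS",
]

# Fixed decoy vocabularies: common co-medications and non-hematologic
# reactions in lung-cancer spontaneous reports.
DECOY_DRUGS = (
    "PACLITAXEL", "CISPLATIN", "PEMETREXED", "GEMCITABINE",
    "DOCETAXEL", "ERLOTINIB", "BEVACIZUMAB", "VINORELBINE",
)
DECOY_REACTIONS = (
    "NAUSEA", "FATIGUE", "VOMITING", "DIARRHOEA",
    "DYSPNOEA", "PYREXIA", "RASH", "DECREASED APPETITE",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating process for one synthetic indication cohort."""

    years: tuple[int, ...] = tuple(range(2004, 2016))
    reports_per_year: int | tuple[int, ...] = 1600
    p_exposure: float = 0.2
    p_event_unexposed: float = 0.05
    true_log_or: float = math.log(2.27)
    tau: float = 0.2
    seed: int = 0
    indication_term: str = "NON-SMALL CELL LUNG CANCER"
    drug_term: str = "CARBOPLATIN"
    event_term: str = "ANAEMIA"
    duplicate_fraction: float = 0.0  # extra duplicated report ids appended, for dedup tests

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if not years:
            raise ValueError("years must be non-empty")
        object.__setattr__(self, "years", years)
        counts = self.reports_per_year
        if isinstance(counts, int):
            counts = tuple(counts for _ in years)
        else:
            counts = tuple(int(c) for c in counts)
            if len(counts) != len(years):
                raise ValueError("reports_per_year list must align with years")
        if any(c < 1 for c in counts):
            raise ValueError("reports_per_year must be >= 1")
        object.__setattr__(self, "reports_per_year", counts)
        for name in ("p_exposure", "p_event_unexposed"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")

    @property
    def n_reports(self) -> int:
        return int(sum(self.reports_per_year))


def _exposed_event_prob(theta: float, p0: float) -> float:
    try:
        odds = math.exp(theta) * p0 / (1.0 - p0)
    except OverflowError as exc:
        raise ValueError(f"implied exposed-event odds overflow at theta={theta}") from exc
    if not math.isfinite(odds) or odds <= 0:
        raise ValueError(f"implied exposed-event odds {odds} outside (0, inf)")
    p1 = odds / (1.0 + odds)
    if not 0.0 < p1 < 1.0:
        raise ValueError(f"implied exposed-event probability {p1} outside (0, 1)")
    return p1


def _yearly_thetas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(config.true_log_or, config.tau, size=len(config.years))


def simulate_reports(config: SimulationConfig) -> list[SafetyReport]:
    """Draw one synthetic report stream; deterministic given ``config.seed``.

    Every report carries the study indication; exposed reports carry the
    study drug plus decoy drugs, unexposed reports decoys only.  With
    ``duplicate_fraction`` > 0, that fraction of report ids is re-emitted
    at the end of the stream (superseding case versions, for dedup tests).
    """
    rng = np.random.default_rng(config.seed)
    thetas = _yearly_thetas(config, rng)
    p1s = [_exposed_event_prob(t, config.p_event_unexposed) for t in thetas]

    reports: list[SafetyReport] = []
    for year, n_year, p1 in zip(config.years, config.reports_per_year, p1s):
        exposed = rng.random(n_year) < config.p_exposure
        p_event = np.where(exposed, p1, config.p_event_unexposed)
        event = rng.random(n_year) < p_event
        n_decoy_drugs = rng.integers(1, 3, size=n_year)
        decoy_drug_idx = rng.integers(0, len(DECOY_DRUGS), size=(n_year, 2))
        n_decoy_reacts = rng.integers(1, 3, size=n_year)
        decoy_react_idx = rng.integers(0, len(DECOY_REACTIONS), size=(n_year, 2))
        for i in range(n_year):
            drugs = {DECOY_DRUGS[j] for j in decoy_drug_idx[i, : n_decoy_drugs[i]]}
            if exposed[i]:
                drugs.add(config.drug_term)
            else:
                drugs.discard(config.drug_term)
            reacts = {DECOY_REACTIONS[j] for j in decoy_react_idx[i, : n_decoy_reacts[i]]}
            reacts.discard(config.event_term)
            if event[i]:
                reacts.add(config.event_term)
            reports.append(
                SafetyReport(
                    report_id=f"S{year}-{i:06d}",
                    year=year,
                    drugs=frozenset(drugs),
                    indications=frozenset({config.indication_term}),
                    reactions=frozenset(reacts),
                )
            )

    if config.duplicate_fraction > 0:
        n_dup = int(round(config.duplicate_fraction * len(reports)))
        idx = rng.choice(len(reports), size=n_dup, replace=False)
        reports.extend(reports[int(i)] for i in sorted(idx))
    return reports


def simulate_yearly_tables(config: SimulationConfig) -> list[StratumTable]:
    """Fast path: draw the yearly 2x2 counts directly from the same model.

    Distributionally identical to building tables from
    :func:`simulate_reports` output, without materializing reports; used
    for replicate-heavy calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    thetas = _yearly_thetas(config, rng)
    tables: list[StratumTable] = []
    for year, n_year, theta in zip(config.years, config.reports_per_year, thetas):
        p1 = _exposed_event_prob(theta, config.p_event_unexposed)
        n_exp = int(rng.binomial(n_year, config.p_exposure))
        a = int(rng.binomial(n_exp, p1)) if n_exp else 0
        c = int(rng.binomial(n_year - n_exp, config.p_event_unexposed)) if n_exp < n_year else 0
        tables.append(
            StratumTable(stratum=str(year), a=a, b=n_exp - a, c=c, d=n_year - n_exp - c)
        )
    return tables


@dataclass(frozen=True)
class _Planted:
    name: str
    fold: float


def simulate_gene_universe(
    N: int,
    n_query: int,
    categories: Sequence[tuple[str, int]],
    planted: tuple[str, float] | None = None,
    seed: int = 0,
) -> tuple[set[str], dict[str, set[str]]]:
    """Reference universe g1..gN with sampled categories and a query set.

    Categories are uniform random subsets of the stated sizes.  When
    ``planted = (name, fold)`` is given, query members hit that category at
    ``fold`` times its background rate: the number of planted hits is
    Binomial(n_query, fold*K/N) so the expected enrichment ratio equals
    ``fold``.  Deterministic given ``seed``.
    """
    if N <= 0 or n_query <= 0 or n_query > N:
        raise ValueError("need 0 < n_query <= N")
    sizes = dict()
    for name, K in categories:
        if not 0 < K <= N:
            raise ValueError(f"category {name}: need 0 < K <= N")
        sizes[name] = int(K)
    rng = np.random.default_rng(seed)
    gene = lambda i: f"g{i + 1}"  # noqa: E731

    members: dict[str, set[str]] = {
        name: {gene(i) for i in rng.choice(N, size=K, replace=False)}
        for name, K in sizes.items()
    }

    if planted is None:
        query_idx = rng.choice(N, size=n_query, replace=False)
        query = {gene(i) for i in query_idx}
        return query, members

    name, fold = planted
    if name not in members:
        raise ValueError(f"planted category {name!r} not among categories")
    if fold < 1:
        raise ValueError("planted fold must be >= 1")
    K = sizes[name]
    p_hit = fold * K / N
    if p_hit >= 1:
        raise ValueError(f"infeasible fold {fold} for K={K}, N={N}")
    k_hits = int(rng.binomial(n_query, p_hit))
    k_hits = min(k_hits, K, n_query)
    planted_members = sorted(members[name])
    hits = {planted_members[i] for i in rng.choice(K, size=k_hits, replace=False)}
    outside = np.array(sorted(set(gene(i) for i in range(N)) - members[name]))
    rest = rng.choice(len(outside), size=n_query - k_hits, replace=False)
    query = hits | {str(outside[i]) for i in rest}
    return query, members
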