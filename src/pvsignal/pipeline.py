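"""End-to-end orchestration: cohort → yearly RORs → pooled signal → diagnostics.

`run_signal_analysis` executes the full year-stratified disproportionality
analysis: select the indication cohort, build per-year 2x2 tables, apply
the continuity correction, estimate per-year RORs, test heterogeneity
(Cochran Q / I² / tau²), choose fixed Mantel–Haenszel or random
DerSimonian–Laird pooling by the Q test at ``het_alpha``, run leave-one-out
sensitivity under the chosen family, and compute Egger/funnel bias
diagnostics.  Results are returned as a bundle and optionally written to
an output directory as TSV/JSON with deterministic bytes (no timestamps,
stable ordering), so identical inputs reproduce identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import bias, contingency, disproportionality, enrichment, meta, reports

__all__ = ["RunConfig", "SignalResult", "run_signal_analysis", "run_enrichment"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one signal-analysis run."""

    input_path: str
    dialect: str = "openfda"
    indication_term: str = "NON-SMALL CELL LUNG CANCER"
    drug_term: str = "CARBOPLATIN"
    event_term: str = "ANAEMIA"
    years: tuple[int, ...] = tuple(range(2004, 2016))
    level: float = 0.95
    het_alpha: float = 0.05
    out_dir: str | None = None

    def cohort_spec(self) -> reports.CohortSpec:
        return reports.CohortSpec(
            indication_term=self.indication_term,
            drug_term=self.drug_term,
            event_term=self.event_term,
            years=self.years,
        )


@dataclass
class SignalResult:
    """Everything one signal analysis produced."""

    config: RunConfig
    load_summary: reports.LoadSummary
    cohort_size: int
    tables: list[contingency.StratumTable]
    corrected_strata: list[str]
    excluded_strata: list[str]
    estimates: list[disproportionality.EffectEstimate]
    het: meta.HeterogeneityResult
    model: str
    pooled: meta.PooledResult
    sensitivity: list[tuple[str, meta.PooledResult]]
    egger: bias.EggerResult | None
    funnel: list[bias.FunnelPoint] = field(default_factory=list)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _write_outputs(res: SignalResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "strata.tsv", "w", encoding="utf-8") as fh:
        fh.write("stratum\ta\tb\tc\td\tcorrected\tror\tci_low\tci_high\ty\tv\tsignal\n")
        ests = {e.stratum: e for e in res.estimates}
        for t in res.tables:
            e = ests.get(t.stratum)
            if e is None:
                fh.write(f"{t.stratum}\t{_fmt(t.a)}\t{_fmt(t.b)}\t{_fmt(t.c)}\t{_fmt(t.d)}"
                         f"\t{str(t.corrected).lower()}\t.\t.\t.\t.\t.\t.\n")
            else:
                fh.write(
                    f"{t.stratum}\t{_fmt(t.a)}\t{_fmt(t.b)}\t{_fmt(t.c)}\t{_fmt(t.d)}"
                    f"\t{str(t.corrected).lower()}\t{_fmt(e.ror)}\t{_fmt(e.ci_low)}"
                    f"\t{_fmt(e.ci_high)}\t{_fmt(e.y)}\t{_fmt(e.v)}"
                    f"\t{str(disproportionality.is_signal(e)).lower()}\n"
                )

    pooled = res.pooled
    summary = {
        "model": pooled.model,
        "k": pooled.k,
        "or_pooled": pooled.or_pooled,
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "y_pooled": pooled.y_pooled,
        "se_pooled": pooled.se_pooled,
        "z": pooled.z,
        "p": pooled.p,
        "heterogeneity": {
            "Q": res.het.Q, "df": res.het.df, "p": res.het.p,
            "I2": res.het.I2, "tau2": res.het.tau2,
        },
        "egger": None if res.egger is None else {
            "intercept": res.egger.intercept, "se_intercept": res.egger.se_intercept,
            "t": res.egger.t, "df": res.egger.df, "p": res.egger.p,
            "asymmetric": res.egger.asymmetric,
        },
    }
    with open(out_dir / "pooled.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")

    with open(out_dir / "sensitivity.tsv", "w", encoding="utf-8") as fh:
        fh.write("left_out\tmodel\tor_pooled\tci_low\tci_high\tp\n")
        for label, p in res.sensitivity:
            fh.write(f"{label}\t{p.model}\t{_fmt(p.or_pooled)}\t{_fmt(p.ci_low)}"
                     f"\t{_fmt(p.ci_high)}\t{_fmt(p.p)}\n")

    with open(out_dir / "funnel.tsv", "w", encoding="utf-8") as fh:
        fh.write("effect\tse\n")
        for pt in res.funnel:
            fh.write(f"{_fmt(pt.effect)}\t{_fmt(pt.se)}\n")

    log = {
        "config": {
            "input_path": str(res.config.input_path),
            "dialect": res.config.dialect,
            "indication_term": res.config.indication_term,
            "drug_term": res.config.drug_term,
            "event_term": res.config.event_term,
            "years": list(res.config.years),
            "level": res.config.level,
            "het_alpha": res.config.het_alpha,
        },
        "load_summary": res.load_summary.to_dict(),
        "cohort_size": res.cohort_size,
        "corrected_strata": res.corrected_strata,
        "excluded_strata": res.excluded_strata,
        "crude_table": _crude(res.tables),
    }
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)
        fh.write("\n")


def _crude(tables: Sequence[contingency.StratumTable]) -> dict:
    # Year-collapsed counts, for the log only: the analysis itself is
    # stratified-then-pooled.
    raw = [t for t in tables if not t.corrected]
    return {
        "a": sum(t.a for t in raw), "b": sum(t.b for t in raw),
        "c": sum(t.c for t in raw), "d": sum(t.d for t in raw),
    }


def run_signal_analysis(
    config: RunConfig,
    loaded: Sequence[reports.SafetyReport] | None = None,
) -> SignalResult:
    """Run the full stratified disproportionality analysis.

    ``loaded`` bypasses file input (e.g. an in-memory synthetic stream);
    otherwise reports are read from ``config.input_path``.  Raises
    ``ValueError`` when fewer than two usable strata remain.
    """
    if loaded is None:
        all_reports, load_summary = reports.read_reports(config.input_path, config.dialect)
    else:
        all_reports, load_summary = list(loaded), reports.LoadSummary(n_read=len(loaded))
    spec = config.cohort_spec()
    cohort = reports.select_cohort(all_reports, spec.indication_term, spec.years)

    raw_tables = contingency.build_yearly_tables(cohort, spec)
    usable, excluded = contingency.exclude_degenerate(raw_tables)
    if len(usable) < 2:
        raise ValueError(
            f"only {len(usable)} usable strata (excluded: {excluded}); need at least 2"
        )
    corrected = [contingency.continuity_correct(t) for t in usable]
    corrected_labels = [t.stratum for t in corrected if t.corrected]
    estimates = [disproportionality.effect_estimate(t, config.level) for t in corrected]

    het = meta.cochran_q(estimates)
    model = meta.select_model(het, config.het_alpha)
    if model == meta.RANDOM_DL:
        pooled = meta.pool_random_dl(estimates, config.level)
    else:
        pooled = meta.pool_fixed_mh(usable, config.level)

    sensitivity: list[tuple[str, meta.PooledResult]] = []
    if len(estimates) >= 3:
        sensitivity = meta.leave_one_out(estimates, model, config.level, tables=usable)
    egger = bias.egger_test(estimates) if len(estimates) >= 3 else None
    funnel = bias.funnel_coordinates(estimates)

    res = SignalResult(
        config=config,
        load_summary=load_summary,
        cohort_size=len(cohort),
        tables=corrected,
        corrected_strata=corrected_labels,
        excluded_strata=excluded,
        estimates=estimates,
        het=het,
        model=model,
        pooled=pooled,
        sensitivity=sensitivity,
        egger=egger,
        funnel=funnel,
    )
    if config.out_dir is not None:
        _write_outputs(res, Path(config.out_dir))
    return res


def run_enrichment(
    query_path: str | None,
    categories_path: str,
    N: int | None = None,
    alpha: float = 0.01,
    out_path: str | None = None,
    n: int | None = None,
    recover_range: tuple[int, int] = (10_000, 100_000),
) -> list[enrichment.EnrichmentRow]:
    """Run over-representation analysis from files.

    ``categories_path`` may be a GMT file (query required) or a counts CSV
    (query size ``n`` required).  When ``N`` is None and the counts carry
    printed ratios, the reference size is recovered by grid search (the
    smallest consistent N is used).
    """
    query = None
    if query_path is not None:
        # gene ids are opaque: trimmed but never case-folded
        with open(query_path, "r", encoding="utf-8") as fh:
            query = {line.strip() for line in fh if line.strip()}
    if categories_path.endswith(".gmt"):
        cats: dict | list = enrichment.read_gmt(categories_path)
        n_query = len(query) if query else n
    else:
        cats = enrichment.read_counts_csv(categories_path)
        n_query = n if n is not None else (len(query) if query else None)
        if N is None:
            with_ratio = [c for c in cats if c.printed_ratio is not None]
            if not with_ratio:
                raise ValueError("cannot recover N: counts carry no printed ratios")
            if n_query is None:
                raise ValueError("reference-size recovery requires the query size n")
            N = enrichment.recover_reference_size(with_ratio, n_query, *recover_range)[0]
    if N is None:
        raise ValueError("reference size N required for GMT categories")
    rows = enrichment.run_ora(query, cats, N=N, alpha=alpha, n=n_query)
    if out_path is not None:
        enrichment.write_ora_tsv(rows, out_path)
    return rows
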