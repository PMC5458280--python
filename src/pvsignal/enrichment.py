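"""Hypergeometric over-representation analysis (ORA) of gene sets.

Given a query set of ``n`` genes drawn from a reference universe of ``N``
genes, and a category (pathway) containing ``K`` reference genes of which
``k`` are query hits, over-representation is measured by

* the enrichment ratio ``(k/n) / (K/N)`` — the observed hit fraction over
  the category's background fraction, and
* the hypergeometric upper tail ``P(X >= k)`` for
  ``X ~ Hypergeometric(N, K, n)``, accumulated in log space so tails near
  1e-50 keep full relative accuracy,

with Benjamini–Hochberg step-up adjustment across the categories tested.

Published ORA tables often omit the reference universe size ``N``;
:func:`recover_reference_size` recovers it by grid search as the integer N
whose exact ratios ``k·N/(n·K)`` round (half away from zero) to every
printed two-decimal ratio.  The bundled counts for the 205
carboplatin-interacting human genes against KEGG pathways
(:func:`load_carboplatin_pathway_counts`) admit a unique such N.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CategoryCount",
    "EnrichmentRow",
    "enrichment_ratio",
    "round_ratio",
    "hypergeom_sf",
    "bh_adjust",
    "run_ora",
    "recover_reference_size",
    "read_gmt",
    "read_counts_csv",
    "write_ora_tsv",
    "load_carboplatin_pathway_counts",
]


@dataclass(frozen=True)
class CategoryCount:
    """One category's reference size K and query hit count k.

    ``printed_ratio`` optionally carries a published two-decimal enrichment
    ratio (used for reference-size recovery); ``printed_p_adj`` a published
    adjusted p-value (usable only as an upper bound on the raw p).
    """

    name: str
    K: int
    k: int
    printed_ratio: float | None = None
    printed_p_adj: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.K:
            raise ValueError(f"{self.name}: need 0 <= k <= K, got k={self.k}, K={self.K}")


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    K: int
    k: int
    ratio: float
    p_raw: float
    p_adj: float
    selected: bool


def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """Enrichment ratio (k/n)/(K/N) = k·N/(n·K), exact before conversion."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K, N must be positive")
    if k < 0 or K > N or n > N:
        raise ValueError("require 0 <= k, K <= N, n <= N")
    return float(Fraction(k * N, n * K))


def round_ratio(k: int, n: int, K: int, N: int, ndigits: int = 2) -> float:
    """The exact ratio rounded half away from zero to ``ndigits`` decimals.

    Computed in exact rational arithmetic so printed-table comparisons
    never hinge on binary floating point.
    """
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K, N must be positive")
    scale = 10 ** ndigits
    r = Fraction(k * N, n * K) * scale
    return float(math.floor(r + Fraction(1, 2))) / scale


def _log_binom(n: int, k) -> object:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space stable.

    Returns 1.0 for k <= 0 and 0.0 for k above min(n, K) (an empty tail is
    not an error).
    """
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K, N must be positive")
    if K > N or n > N:
        raise ValueError("require K <= N and n <= N")
    hi = min(n, K)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    lo = max(0, n + K - N)
    start = max(k, lo)
    j = np.arange(start, hi + 1)
    logpmf = _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted p_(i) = min_{j >= i} min(1, m·p_(j)/j) over the sorted order.
    """
    m = len(pvals)
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        # m*p/rank can round a ULP below p at rank == m; the adjusted
        # value is never below the raw one mathematically
        adj[i] = max(running, pvals[i])
    return adj


def run_ora(
    query: Iterable[str] | None,
    categories: Sequence[CategoryCount] | dict[str, set[str]],
    N: int,
    alpha: float = 0.01,
    n: int | None = None,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` against each category.

    Categories may be gene sets (``k`` computed by intersection with the
    query, ``K`` by set size) or precomputed :class:`CategoryCount` rows
    (then ``n``, the query size, must be given explicitly if ``query`` is
    None).  BH adjustment spans exactly the supplied categories; rows are
    sorted by adjusted p then name, with ``selected`` = (p_adj < alpha).
    """
    if isinstance(categories, dict):
        if query is None:
            raise ValueError("gene-set categories require a query gene list")
        qset = {g for g in query}
        if not qset:
            raise ValueError("empty query gene set")
        counts = [CategoryCount(name, K=len(members), k=len(qset & set(members)))
                  for name, members in categories.items()]
        n_query = len(qset)
    else:
        counts = list(categories)
        if query is not None:
            n_query = len(set(query))
        elif n is not None:
            n_query = int(n)
        else:
            raise ValueError("count-based categories require the query size n")
    if not counts:
        raise ValueError("no categories supplied")
    if n_query <= 0:
        raise ValueError("query size must be positive")

    p_raw = [hypergeom_sf(c.k, n_query, c.K, N) for c in counts]
    p_adj = bh_adjust(p_raw)
    rows = [
        EnrichmentRow(
            name=c.name, K=c.K, k=c.k,
            ratio=enrichment_ratio(c.k, n_query, c.K, N),
            p_raw=pr, p_adj=pa, selected=pa < alpha,
        )
        for c, pr, pa in zip(counts, p_raw, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.name))
    return rows


def recover_reference_size(
    rows: Sequence[CategoryCount],
    n: int,
    lo: int = 10_000,
    hi: int = 100_000,
) -> list[int]:
    """Integers N in [lo, hi] reproducing every row's printed two-decimal ratio.

    For each candidate N the exact ratio ``k·N/(n·K)`` is rounded half away
    from zero to two decimals and compared with ``printed_ratio``.  Returns
    the full candidate list (often a singleton); raises if no N is
    consistent, naming the rows that can never be matched.
    """
    rows = [r for r in rows]
    if not rows:
        raise ValueError("no rows supplied")
    for r in rows:
        if r.printed_ratio is None:
            raise ValueError(f"{r.name}: printed_ratio required for recovery")

    # Exact integer intervals: round-half-away(100kN/(nK)) == R iff
    # (2R-1)·nK <= 200·kN < (2R+1)·nK, so each row constrains N to one
    # contiguous integer range; the answer is their intersection.
    cur_lo, cur_hi = lo, hi
    for r in rows:
        R = round(r.printed_ratio * 100)
        denom = 200 * r.k
        if denom == 0:
            if R != 0:
                raise ValueError(f"no reference size fits; violated row: {r.name!r} (k=0)")
            continue
        nk = n * r.K
        row_lo = -((-(2 * R - 1) * nk) // denom)  # ceil
        row_hi = -((-(2 * R + 1) * nk) // denom) - 1
        new_lo, new_hi = max(cur_lo, row_lo), min(cur_hi, row_hi)
        if new_lo > new_hi:
            raise ValueError(
                f"no reference size in [{lo}, {hi}] fits all rows; "
                f"violated row: {r.name!r}"
            )
        cur_lo, cur_hi = new_lo, new_hi
    candidates = [N for N in range(cur_lo, cur_hi + 1)
                  if all(round_ratio(r.k, n, r.K, N) == r.printed_ratio for r in rows)]
    if not candidates:
        raise ValueError(f"no reference size in [{lo}, {hi}] fits all rows")
    return candidates


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: tab-separated name, description, members..."""
    out: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(categories: dict[str, set[str]], path) -> None:
    """Write GMT gene sets with members sorted (deterministic bytes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(categories):
            fh.write("\t".join([name, "na", *sorted(categories[name])]) + "\n")


def read_counts_csv(path) -> list[CategoryCount]:
    """Read category counts from CSV with columns name, K, k
    (optional printed_ratio, printed_p_adj)."""
    rows: list[CategoryCount] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "K", "k"}.issubset(reader.fieldnames):
            raise ValueError(f"{path}: counts CSV needs columns name, K, k")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    CategoryCount(
                        name=row["name"],
                        K=int(row["K"]),
                        k=int(row["k"]),
                        printed_ratio=float(row["printed_ratio"]) if row.get("printed_ratio") else None,
                        printed_p_adj=float(row["printed_p_adj"]) if row.get("printed_p_adj") else None,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: bad counts row on line {lineno}: {exc}") from exc
    return rows


def write_ora_tsv(rows: Sequence[EnrichmentRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tK\tk\tratio\tp_raw\tp_adj\tselected\n")
        for r in rows:
            fh.write(
                f"{r.name}\t{r.K}\t{r.k}\t{r.ratio:.6g}\t{r.p_raw:.6g}\t"
                f"{r.p_adj:.6g}\t{str(r.selected).lower()}\n"
            )


def load_carboplatin_pathway_counts() -> list[CategoryCount]:
    """Published KEGG-pathway ORA counts for the 205 carboplatin-interacting genes.

    Each row carries the pathway's human-genome size K, the number of
    carboplatin-related query hits k, and the published two-decimal
    enrichment ratio and BH-adjusted p-value.  The query size was n=205;
    the reference universe size is recoverable via
    :func:`recover_reference_size`.
    """
    ref = resources.files("pvsignal.data").joinpath("carboplatin_kegg_counts.csv")
    with resources.as_file(ref) as path:
        return read_counts_csv(path)


CARBOPLATIN_QUERY_SIZE = 205
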