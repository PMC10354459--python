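"""Over-representation of candidate sets in annotation (phenotype) sets.

Generic hypergeometric enrichment: given a query gene set (e.g. the
unique binders of one bait), user-supplied annotation sets (term ->
gene list, GMT-style) and a background universe, each term is tested
with the exact upper-tail hypergeometric probability and the p-values
are Benjamini-Hochberg adjusted across terms.

Identifier matching is exact-string after case normalization; no alias
or orthology resolution is attempted — annotation files must be mapped
to the identifiers used in the quantification table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping

from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSets:
    """Annotation terms and the background gene universe.

    ``terms`` maps ``term_id -> (term_name, genes)``. Term gene sets are
    intersected with the background at construction so that every
    tested set is a subset of the universe.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background gene set is empty")
        clipped = {
            tid: (name, genes & self.background)
            for tid, (name, genes) in self.terms.items()
        }
        object.__setattr__(self, "terms", clipped)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes annotated to the term
    K: int  # term size in background
    n: int  # query size in background
    N: int  # background size
    p: float  # upper-tail hypergeometric p-value
    q: float  # BH-adjusted value


def _norm(gene: str) -> str:
    return gene.strip().lower()


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` is the population (background) size, ``K`` the number of
    successes in the population (term size), ``n`` the draw (query)
    size and ``k`` the observed overlap. Computed with exact integer
    binomials, then converted to float.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N, got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return tail / total


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, clipped at 1."""
    if not pvalues:
        raise ValueError("empty p-value list")
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"p-value outside (0, 1]: {p!r}")
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(v) for v in q]


def enrich(query: Iterable[str], annotation: AnnotationSets) -> list[EnrichmentResult]:
    """Test every nonempty term against the query; sort by ascending p.

    Query genes outside the background are dropped (their count is
    logged); an empty effective query is an error.
    """
    query_set = {g for g in query}
    effective = query_set & annotation.background
    dropped = len(query_set) - len(effective)
    if dropped:
        logger.info("enrich: %d query gene(s) outside background dropped", dropped)
    if not effective:
        raise ValueError("no query genes found in the background universe")
    N = len(annotation.background)
    n = len(effective)
    rows: list[tuple[str, str, int, int]] = []
    for tid, (name, genes) in annotation.terms.items():
        K = len(genes)
        if K == 0:
            continue
        rows.append((tid, name, len(effective & genes), K))
    if not rows:
        return []
    ps = [hypergeometric_upper_tail(k, K, n, N) for _, _, k, K in rows]
    qs = bh_adjust(ps)
    results = [
        EnrichmentResult(tid, name, k, K, n, N, p, q)
        for (tid, name, k, K), p, q in zip(rows, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT-style annotation: ``term_id TAB term_name TAB gene...``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected term_id TAB term_name")
            tid, name = parts[0], parts[1]
            if tid in terms:
                raise ValueError(f"{path}:{line_no}: duplicate term {tid!r}")
            terms[tid] = (name, frozenset(_norm(g) for g in parts[2:] if g.strip()))
    return terms


def read_background(path: str | Path) -> frozenset[str]:
    """One gene identifier per line."""
    with Path(path).open(encoding="utf-8") as fh:
        return frozenset(_norm(line) for line in fh if line.strip())


def normalize_query(genes: Iterable[str]) -> set[str]:
    """Case-normalize query identifiers the way annotations are read."""
    return {_norm(g) for g in genes if g.strip()}


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p!r}\t{r.q!r}\n"
            )
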