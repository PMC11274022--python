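"""GO-term overrepresentation: hypergeometric upper tail + BH step-up.

For a query of n genes drawn from a universe of N annotated genes, a
term carrying K universe genes, and an observed overlap of k genes, the
overrepresentation p-value is the one-sided hypergeometric tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

(equivalent to a one-sided Fisher's exact test). p-values are corrected
per comparison with the Benjamini-Hochberg step-up; significance means
q strictly below alpha, mirroring the DEG rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import SeedgoError
from .ego_network import DegInteractorSet
from .io_formats import AnnotationMap

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term_id", "name", "k", "K", "n", "N", "p", "q", "significant"]


@dataclass
class EnrichmentTable:
    """Per-comparison term statistics (k, K, n, N, p, q, significant)."""

    comparison_id: str
    records: pd.DataFrame  # ENRICHMENT_COLUMNS
    alpha: float
    universe_label: str

    def significant_terms(self) -> set[str]:
        return set(self.records.loc[self.records["significant"], "term_id"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CommonTermSet:
    """Terms significant in every member comparison of a grouping."""

    label: str
    terms: frozenset[str]
    member_comparisons: tuple[str, ...]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed via the survival function (log-space internally, stable for
    extreme tails). k = 0 returns exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise SeedgoError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N or k > min(K, n):
        raise SeedgoError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1, then scattered back to input positions. NaN input is fatal.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise SeedgoError("bh_adjust expects a non-empty 1-D p-value vector")
    if np.isnan(p).any():
        raise SeedgoError("bh_adjust: NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise SeedgoError("bh_adjust: p-values outside [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # p * (m/j) keeps the j = m entry exactly p, so tied-at-c vectors
    # adjust to exactly c
    scaled = p[order] * (m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(q_sorted, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def overrepresent(
    query: DegInteractorSet | set[str],
    annot: AnnotationMap,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    min_term_size: int = 2,
    comparison_id: str | None = None,
) -> EnrichmentTable:
    """Test every annotation term for overrepresentation in ``query``.

    ``universe`` defaults to the annotated gene universe (every gene with
    at least one annotation); pass an explicit set for a custom reference
    list. Query genes outside the universe are dropped (count logged).
    Terms with fewer than ``min_term_size`` universe genes are skipped and
    do not enter the BH family. Records are sorted by (q, p, term_id).
    """
    if isinstance(query, DegInteractorSet):
        comparison_id = comparison_id or query.comparison_id
        query_genes = set(query.genes)
    else:
        query_genes = set(query)
    comparison_id = comparison_id or "query"
    label = "annotated" if universe is None else "custom"
    uni = annot.genes() if universe is None else set(universe)
    if not uni:
        raise SeedgoError("empty universe")
    dropped = query_genes - uni
    if dropped:
        logger.info("%s: %d query genes outside universe dropped", comparison_id, len(dropped))
    query_genes &= uni
    if not query_genes:
        logger.warning("%s: empty query after universe restriction", comparison_id)
        return EnrichmentTable(
            comparison_id, pd.DataFrame(columns=ENRICHMENT_COLUMNS), alpha, label
        )

    N, n = len(uni), len(query_genes)
    rows = []
    for term in sorted(annot.term_to_genes):
        term_genes = annot[term] & uni
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(query_genes & term_genes)
        rows.append((term, annot.name_of(term), k, K, n, N,
                     hypergeom_upper_tail(k, K, n, N)))
    if not rows:
        logger.warning("%s: no terms pass min_term_size=%d", comparison_id, min_term_size)
        return EnrichmentTable(
            comparison_id, pd.DataFrame(columns=ENRICHMENT_COLUMNS), alpha, label
        )
    df = pd.DataFrame(rows, columns=["term_id", "name", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    df = df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    return EnrichmentTable(comparison_id, df, alpha, label)


def common_terms(tables: list[EnrichmentTable], label: str = "all") -> CommonTermSet:
    """Intersect significant term sets across comparisons.

    Groupings mirror the study design: "all" (every comparison) and
    per-timepoint trios (all doses at one timepoint).
    """
    if not tables:
        raise SeedgoError("common_terms needs at least one enrichment table")
    if len(tables) == 1:
        logger.warning("grouping %r has a single comparison; returning its significant set", label)
    terms = tables[0].significant_terms()
    for t in tables[1:]:
        terms &= t.significant_terms()
    return CommonTermSet(label, frozenset(terms), tuple(t.comparison_id for t in tables))


def write_enrichment_table(table: EnrichmentTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_enrichment_table(path, comparison_id: str, alpha: float = 0.05) -> EnrichmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"term_id": str, "name": str})
    if df.empty:
        df = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return EnrichmentTable(comparison_id, df, alpha, "loaded")
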