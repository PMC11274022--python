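"""Term-impact scores behind the enrichment heatmaps.

Two scores are computed for every (term, comparison) cell:

* ``ratio``        r = |DEGs in term| / |genes in term|          (in [0,1])
* ``fc_weighted``  s = r * sum over DEGs-in-term of |log2FC|     (>= 0)

The DEG set is the comparison's DEG-interactor set, term gene counts are
taken within the analysis universe, and fold changes are on the log2
scale throughout. The fc_weighted cell is, by construction, exactly the
ratio cell times the cell's sum of absolute fold changes — an identity
the score matrix carries as per-cell provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
import re

import pandas as pd

from .errors import SeedgoError
from .ego_network import DegInteractorSet
from .io_formats import AnnotationMap

SCORE_KINDS = ("ratio", "fc_weighted")

_CMP_RE = re.compile(r"^([0-9.]+)uM_([0-9.]+)h$")


def comparison_sort_key(comparison_id: str):
    """Sort comparisons by dose then timepoint when labelled '<dose>uM_<time>h'."""
    m = _CMP_RE.match(comparison_id)
    if m:
        return (0, float(m.group(1)), float(m.group(2)), comparison_id)
    return (1, 0.0, 0.0, comparison_id)


@dataclass
class ScoreMatrix:
    """terms x comparisons score matrix with per-cell provenance.

    ``values`` holds the score of ``kind``; ``k_term`` the DEG-in-term
    counts and ``sum_abs_fc`` the per-cell sum of |log2FC|, all on the
    same (term, comparison) axes.
    """

    kind: str
    values: pd.DataFrame
    k_term: pd.DataFrame
    sum_abs_fc: pd.DataFrame

    @property
    def terms(self) -> list[str]:
        return list(self.values.index)

    @property
    def comparisons(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for term in self.values.index:
            for cmp_ in self.values.columns:
                rows.append((term, cmp_, self.values.at[term, cmp_],
                             int(self.k_term.at[term, cmp_]),
                             self.sum_abs_fc.at[term, cmp_]))
        return pd.DataFrame(rows, columns=["term_id", "comparison", self.kind,
                                           "k_term", "sum_abs_fc"])


def _term_genes(term_id: str, annot: AnnotationMap, universe: set[str] | None) -> set[str]:
    if term_id not in annot:
        raise SeedgoError(f"unknown term {term_id!r}")
    genes = annot[term_id]
    if universe is not None:
        genes = genes & universe
    if not genes:
        raise SeedgoError(f"term {term_id!r} has no annotated genes in universe")
    return genes


def ratio_score(
    term_id: str,
    deg_set: set[str],
    annot: AnnotationMap,
    universe: set[str] | None = None,
) -> float:
    """r = |DEGs in term| / |term genes| within the universe."""
    genes = _term_genes(term_id, annot, universe)
    return len(deg_set & genes) / len(genes)


def fc_weighted_score(
    term_id: str,
    deg_fc: dict[str, float],
    annot: AnnotationMap,
    universe: set[str] | None = None,
) -> float:
    """s = ratio * sum of |log2FC| over the DEGs inside the term."""
    genes = _term_genes(term_id, annot, universe)
    hits = set(deg_fc) & genes
    r = len(hits) / len(genes)
    return r * sum(abs(deg_fc[g]) for g in hits)


def build_score_matrix(
    terms,
    deg_sets: dict[str, DegInteractorSet],
    annot: AnnotationMap,
    kind: str = "ratio",
    universe: set[str] | None = None,
) -> ScoreMatrix:
    """Assemble the full score matrix for a term selection.

    Rows are term ids in lexicographic order; columns are comparisons
    ordered by dose then timepoint. Cells with no DEG overlap are 0.
    """
    if kind not in SCORE_KINDS:
        raise SeedgoError(f"unknown score kind {kind!r}")
    term_list = sorted(terms.terms if hasattr(terms, "terms") else terms)
    cmp_list = sorted(deg_sets, key=comparison_sort_key)
    ratio = pd.DataFrame(0.0, index=term_list, columns=cmp_list)
    k_term = pd.DataFrame(0, index=term_list, columns=cmp_list)
    sum_fc = pd.DataFrame(0.0, index=term_list, columns=cmp_list)
    for term in term_list:
        genes = _term_genes(term, annot, universe)
        for cmp_ in cmp_list:
            ds = deg_sets[cmp_]
            hits = ds.genes & genes
            k_term.at[term, cmp_] = len(hits)
            ratio.at[term, cmp_] = len(hits) / len(genes)
            sum_fc.at[term, cmp_] = sum(abs(ds.log2fc[g]) for g in hits)
    values = ratio if kind == "ratio" else ratio * sum_fc
    return ScoreMatrix(kind, values, k_term, sum_fc)
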