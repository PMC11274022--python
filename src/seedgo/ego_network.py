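"""DEG calling and seed-protein ego-network filtering.

The biological question downstream stages answer is "what do the
differentially expressed *interactors of the seed protein* do", so this
module (1) calls DEGs from a gene statistics table at a strict q < alpha
rule, (2) extracts the seed's first-shell interactors above a confidence
threshold, and (3) intersects the two, carrying each gene's log2 fold
change along for scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import SeedgoError
from .io_formats import GeneStatTable, Interactome

logger = logging.getLogger(__name__)


@dataclass
class DegCall:
    """DEG set for one comparison, partitioned by fold-change direction."""

    comparison_id: str
    degs: set[str]
    up: set[str]
    down: set[str]
    unchanged: set[str] = field(default_factory=set)
    alpha: float = 0.05


@dataclass
class InteractorSet:
    """First-shell interactors of the seed node at a score threshold."""

    seed_node: str
    members: set[str]
    min_score: float


@dataclass
class DegInteractorSet:
    """Genes that are both DEGs and seed interactors, with their log2FC."""

    comparison_id: str
    genes: set[str]
    log2fc: dict[str, float]

    def __len__(self) -> int:
        return len(self.genes)


def call_degs(table: GeneStatTable, alpha: float = 0.05) -> DegCall:
    """Call DEGs: genes with q-value strictly below ``alpha``.

    The boundary q == alpha is NOT a DEG. Called genes are partitioned
    into up/down by the sign of log2FC; an exactly-zero log2FC lands in
    an "unchanged-direction" bucket with a warning.
    """
    if not 0 < alpha < 1:
        raise SeedgoError(f"alpha must be in (0,1), got {alpha}")
    df = table.data
    hit = df[df["q_value"] < alpha]
    up = set(hit.loc[hit["log2fc"] > 0, "gene_id"])
    down = set(hit.loc[hit["log2fc"] < 0, "gene_id"])
    unchanged = set(hit.loc[hit["log2fc"] == 0, "gene_id"])
    if unchanged:
        logger.warning(
            "%s: %d DEGs with log2fc == 0 assigned to unchanged-direction bucket",
            table.comparison_id, len(unchanged),
        )
    return DegCall(table.comparison_id, set(hit["gene_id"]), up, down, unchanged, alpha)


def extract_ego_interactors(
    net: Interactome,
    seed: str,
    min_score: float = 0.4,
    include_seed: bool = False,
) -> InteractorSet:
    """First-shell neighbours of ``seed`` via edges with score >= ``min_score``."""
    if not 0 <= min_score <= 1:
        raise SeedgoError(f"min_score must be in [0,1], got {min_score}")
    if seed not in net.graph:
        logger.warning("seed node %r absent from interactome; empty interactor set", seed)
        return InteractorSet(seed, set(), min_score)
    members = {
        nbr
        for nbr, data in net.graph[seed].items()
        if data["score"] >= min_score
    }
    members.discard(seed)
    if include_seed:
        members.add(seed)
    return InteractorSet(seed, members, min_score)


def intersect_deg_interactors(
    degs: DegCall | set[str],
    interactors: InteractorSet,
    table: GeneStatTable,
) -> DegInteractorSet:
    """Intersect the DEG set with the interactor set; carry log2FC from ``table``."""
    deg_set = degs.degs if isinstance(degs, DegCall) else set(degs)
    genes = deg_set & interactors.members
    fc = table.log2fc_map()
    return DegInteractorSet(table.comparison_id, genes, {g: fc[g] for g in genes})
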