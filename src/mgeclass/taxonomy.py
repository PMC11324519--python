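"""Consensus viral lineage assignment by majority vote over gene taxonomies.

Each annotated gene carries the (possibly partial) lineage of its marker
over the ranks realm → kingdom → phylum → class → order → family. The
scaffold's consensus is the deepest taxon whose cumulative vote fraction
reaches the minimum fraction, descending rank by rank and stopping at a
strict tie. A conflict guard re-runs the vote at a raised fraction when
the consensus falls inside a taxon known to carry homologs of another
(e.g. giant viruses encoding tailed-phage-like proteins), preventing a
handful of shared genes from dragging a scaffold into the wrong realm.
"""

from __future__ import annotations

from typing import Sequence

RANKS = ("realm", "kingdom", "phylum", "class", "order", "family")

Lineage = tuple[str, ...]


def validate_lineage(lineage: Sequence[str]) -> Lineage:
    lineage = tuple(lineage)
    if not lineage or len(lineage) > len(RANKS):
        raise ValueError(f"lineage must be a non-empty prefix of {len(RANKS)} ranks")
    if any((not name) or (";" in name) for name in lineage):
        raise ValueError(f"malformed lineage {lineage}")
    return lineage


def consensus_lineage(
    lineages: Sequence[Sequence[str]], min_fraction: float = 0.5
) -> Lineage | None:
    """Deepest taxon with cumulative vote fraction >= min_fraction.

    One vote per gene. At each rank the winning child must reach
    ``min_fraction`` of all votes and win strictly (a tie stops the
    descent at the parent). Returns None for empty input or when no
    realm-level taxon qualifies.
    """
    if not 0.5 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0.5, 1]")
    lineages = [validate_lineage(l) for l in lineages]
    if not lineages:
        return None
    total = len(lineages)
    path: list[str] = []
    candidates = lineages
    for depth in range(len(RANKS)):
        votes: dict[str, int] = {}
        for lin in candidates:
            if len(lin) > depth:
                votes[lin[depth]] = votes.get(lin[depth], 0) + 1
        if not votes:
            break
        best = max(votes.values())
        winners = [name for name, v in votes.items() if v == best]
        if len(winners) > 1 or best / total < min_fraction:
            break
        path.append(winners[0])
        candidates = [lin for lin in candidates if len(lin) > depth and lin[depth] == path[-1]]
    return tuple(path) if path else None


def conflict_guard(
    lineages: Sequence[Sequence[str]],
    special_parent: str,
    special_conflict: str,
    raised_fraction: float = 0.85,
    min_fraction: float = 0.5,
) -> Lineage | None:
    """Re-vote at a raised fraction when a known cross-taxon conflict appears.

    If the default consensus contains ``special_parent`` while at least one
    gene votes for a lineage containing ``special_conflict``, the consensus
    is recomputed with ``raised_fraction`` as the minimum fraction.
    """
    consensus = consensus_lineage(lineages, min_fraction)
    if consensus is None:
        return None
    if special_parent in consensus and any(
        special_conflict in tuple(lin) for lin in lineages
    ):
        return consensus_lineage(lineages, raised_fraction)
    return consensus
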