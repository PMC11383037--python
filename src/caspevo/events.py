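"""Gene gain/loss reconstruction on the species tree (Dollo parsimony).

A gene arises once (at the most recent common ancestor of the species that
retain it intact, unless a deeper origin is forced) and can only be lost
thereafter. The minimum set of loss branches is the set of maximal subtrees
within the origin's clade whose leaves are all non-intact; this set is
unique, so the reconstruction is deterministic. Pseudogenized, partial, and
absent homologs all count as non-intact for loss counting: what is being
reconstructed is the loss of an intact gene, whatever the molecular route.

Duplication ages: with node ages attached (Mya), a gene present in exactly
one clade dates its birth to that clade's stem branch, i.e. the interval
(age of the origin's parent, age of the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import SpeciesTree


@dataclass
class EventReconstruction:
    gene_id: str
    origin_leaves: list[str]  # leaf set under the origin node
    loss_branches: list[list[str]]  # each branch named by its leaf set
    duplication_age: tuple[float | None, float | None] | None = None

    @property
    def loss_count(self) -> int:
        return len(self.loss_branches)


def dollo_reconstruct(
    presence: Mapping[str, bool],
    tree: SpeciesTree,
    gene_id: str,
    forced_origin: Sequence[str] | None = None,
) -> EventReconstruction:
    """Minimum-loss single-gain reconstruction of one gene's history.

    ``presence`` maps species to intact/non-intact. Species missing from the
    map are treated as non-intact. The origin is the MRCA of intact species
    unless ``forced_origin`` (a set of leaves whose MRCA to use) is given.
    """
    intact = {sp for sp, v in presence.items() if v}
    if not intact and forced_origin is None:
        raise ValueError(f"{gene_id}: gene intact nowhere and no forced origin")
    origin = tree.mrca(sorted(forced_origin)) if forced_origin else tree.mrca(sorted(intact))

    losses: list[list[str]] = []

    def visit(node) -> None:
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        if not any(presence.get(sp, False) for sp in leaves):
            losses.append(leaves)  # maximal all-lost subtree: one loss branch
            return
        for child in node.child_nodes():
            visit(child)

    for child in origin.child_nodes():
        visit(child)
    if origin.is_leaf():
        leaves = [origin.taxon.label]
        if not presence.get(leaves[0], False):
            losses.append(leaves)

    return EventReconstruction(
        gene_id=gene_id,
        origin_leaves=sorted(l.taxon.label for l in origin.leaf_iter()),
        loss_branches=sorted(losses),
    )


def date_duplication(
    presence: Mapping[str, bool],
    tree: SpeciesTree,
    gene_id: str = "duplicate",
) -> tuple[float | None, float]:
    """Age interval (older bound, younger bound) in Mya for a gene's birth.

    The gene arose on the stem branch of the clade that carries it: between
    the age of the origin node's parent and the age of the origin node. A
    duplicate present in every leaf predates the root; the older bound is
    then open-ended (None).
    """
    carriers = sorted(sp for sp, v in presence.items() if v)
    if not carriers:
        raise ValueError("duplicate present nowhere")
    origin = tree.mrca(carriers)
    young = tree.age_of(origin)
    if young is None:
        raise ValueError("node ages missing: attach ages before dating")
    parent = origin.parent_node
    if parent is None:
        return (None, young)
    old = tree.age_of(parent)
    if old is None:
        raise ValueError("node ages missing on the origin's parent")
    return (old, young)


def count_total_events(
    reconstructions: Sequence[EventReconstruction],
    clade_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate loss counts and origins per gene (and per clade label)."""
    rows = []
    for rec in reconstructions:
        rows.append(
            {
                "gene": rec.gene_id,
                "clade": (clade_of or {}).get(rec.gene_id, "all"),
                "origin_n_species": len(rec.origin_leaves),
                "loss_count": rec.loss_count,
                "loss_branches": ";".join(",".join(b) for b in rec.loss_branches),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "clade", "origin_n_species", "loss_count", "loss_branches"])
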