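"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by enumeration, sharing no code with
the implementations they check (only the stated conventions).
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table

STOPS = set(standard_dna_table.stop_codons)
TABLE = dict(standard_dna_table.forward_table)


def aa(codon: str) -> str:
    return "*" if codon in STOPS else TABLE[codon]


def ng86_site_counts_oracle(codon: str) -> tuple[float, float]:
    """(S sites, N sites) by direct enumeration of the 9 neighbours."""
    syn = 0
    for pos, base in enumerate(codon):
        for alt in "ACGT":
            if alt == base:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOPS and aa(mutant) == aa(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def ng86_pair_differences_oracle(a: str, b: str) -> tuple[float, float]:
    """(Nd, Sd) by explicit enumeration of mutation orderings.

    Pathways through stops are excluded; if all are blocked, all pathways
    are used. Matches the convention stated by the implementation.
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        current = a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOPS:
                blocked = True
            if aa(current) == aa(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((nd, sd, blocked))
    usable = [(n, s) for n, s, blk in paths if not blk] or [(n, s) for n, s, _ in paths]
    return (
        sum(p[0] for p in usable) / len(usable),
        sum(p[1] for p in usable) / len(usable),
    )


def dollo_min_losses_oracle(tree, presence: dict[str, bool], origin_node) -> int:
    """Smallest number of branches whose removal explains all non-intact
    leaves, by exhaustive subset search of increasing size.

    A branch set is feasible iff every intact leaf is NOT under any chosen
    branch and every non-intact leaf under the origin IS under some chosen
    branch.
    """
    nodes = [n for n in origin_node.preorder_iter() if n is not origin_node]
    leaves_under = []
    for n in nodes:
        leaves_under.append(frozenset(l.taxon.label for l in n.leaf_iter()))
    all_leaves = frozenset(l.taxon.label for l in origin_node.leaf_iter())
    intact = frozenset(l for l in all_leaves if presence.get(l, False))
    lost = all_leaves - intact

    if not lost:
        return 0
    for k in range(1, len(nodes) + 1):
        for combo in itertools.combinations(range(len(nodes)), k):
            covered = frozenset().union(*(leaves_under[i] for i in combo))
            if covered >= lost and not covered & intact:
                return k
    return len(nodes)


def brute_force_block_present(seq: str, iv_a, iv_b, min_len: int, min_identity: float) -> bool:
    """Does a planted tract pair qualify as a block under the thresholds?

    Direct column-wise comparison of the two equal-length intervals.
    """
    a = seq[iv_a[0] : iv_a[1]]
    b = seq[iv_b[0] : iv_b[1]]
    if len(a) != len(b) or len(a) < min_len:
        return False
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a) >= min_identity
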