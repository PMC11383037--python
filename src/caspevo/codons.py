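"""Codon arithmetic for counting-based selection analyses.

Implements the standard nuclear genetic code, per-codon synonymous and
nonsynonymous site counts, and minimal-mutational-pathway averaging of
substitution counts between codon pairs (the primitives behind NG86-style
dN/dS estimation).

Conventions (stated once, used everywhere):

* single-nucleotide changes that create a stop codon count as nonsynonymous
  in the site tallies;
* multi-step codon differences are averaged over all minimal mutational
  pathways, excluding pathways that pass through a stop codon; if every
  pathway is blocked by a stop, the average falls back to all pathways.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(BASES, repeat=3)) if c not in STOP_CODONS)
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 site to the
    synonymous or nonsynonymous tally; changes to stop codons are counted as
    nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    syn = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) substitution counts between two codons.

    Averaged over all minimal mutational pathways; pathways through stop
    codons are excluded (with fallback to all pathways when every route is
    blocked). Identical codons give (0, 0).
    """
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        nd = sd = 0.0
        current = a
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if translate_codon(current) == translate_codon(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return nd, sd, blocked

    paths = [walk(order) for order in itertools.permutations(diff_positions)]
    open_paths = [(n, s) for n, s, blocked in paths if not blocked]
    if not open_paths:
        open_paths = [(n, s) for n, s, _ in paths]
    nd = sum(p[0] for p in open_paths) / len(open_paths)
    sd = sum(p[1] for p in open_paths) / len(open_paths)
    return nd, sd


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
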