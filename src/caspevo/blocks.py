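"""Intra-locus self-similarity blocks and gene-conversion detection.

Recent segmental duplications and gene-conversion tracts leave extended runs
of high nucleotide identity inside a locus (off-diagonal lines on a self
dotplot). Blocks are found by exact k-mer seeding, per-diagonal chaining,
ungapped X-drop extension, and a final gapped-identity evaluation; a reported
block is at least ``block_min_len`` bp at ``block_min_identity`` identity
(defaults 1 kb / 50%), with gap columns counted as mismatches. Both direct
and inverted (reverse-complement) orientations are searched.

Conversion between paralogs is also detectable on trees: a converted gene is
more similar to its within-species paralog than to its own orthologs in
other species. ``detect_tree_intermixing`` formalizes that with Jukes-Cantor
distances and merges per-species calls into the minimum number of
clade-level events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .core import GenomicLocus, PipelineConfig, SpeciesTree, revcomp


@dataclass
class SimilarityBlock:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # direct | inverted
    identity: float

    def __post_init__(self) -> None:
        if self.interval_a > self.interval_b:
            self.interval_a, self.interval_b = self.interval_b, self.interval_a
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be direct or inverted")

    @property
    def length(self) -> int:
        return max(
            self.interval_a[1] - self.interval_a[0],
            self.interval_b[1] - self.interval_b[0],
        )


@dataclass
class ConversionCall:
    gene_a: str
    gene_b: str
    species: list[str]  # leaves covered by the merged clade event
    support: float  # cross-paralog vs cross-species distance margin


def _kmer_seeds(seq_a: str, seq_b: str, k: int):
    """(i, j) seed pairs between two sequences; i in a, j in b."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            yield i, j


def _chain_diagonals(seeds, k: int, max_gap: int):
    """Group seeds by diagonal band and chain runs with gaps <= max_gap."""
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i, j in seeds:
        by_diag.setdefault(i - j, []).append((i, j))
    chains = []
    band: dict[int, list] = {}
    for d in sorted(by_diag):
        for i, j in sorted(by_diag[d]):
            placed = False
            for dd in range(d - max_gap // 4, d + max_gap // 4 + 1):
                for chain in band.get(dd, ()):
                    if 0 <= i - chain[-1][0] <= max_gap:
                        chain.append((i, j))
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                band.setdefault(d, []).append([(i, j)])
    for chains_on_diag in band.values():
        chains.extend(chains_on_diag)
    return [c for c in chains if c[-1][0] + k - c[0][0] >= 3 * k]


def _xdrop_extend(seq_a: str, seq_b: str, i: int, j: int, direction: int, xdrop: int = 20):
    """Ungapped extension; returns the number of columns retained."""
    best = score = 0
    best_len = 0
    n = 0
    while True:
        i += direction
        j += direction
        if i < 0 or j < 0 or i >= len(seq_a) or j >= len(seq_b):
            break
        n += 1
        score += 1 if seq_a[i] == seq_b[j] else -2
        if score > best:
            best, best_len = score, n
        if best - score > xdrop:
            break
    return best_len


def _gapped_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance")
    dist = res["editDistance"]
    cols = max(len(a), len(b))
    return 1.0 - dist / cols if cols else 0.0


def find_similarity_blocks(
    locus: GenomicLocus | str,
    config: PipelineConfig | None = None,
) -> list[SimilarityBlock]:
    """Self-similarity blocks within one locus (the self-dotplot equivalent).

    The trivial self-diagonal is excluded; overlapping chains are merged;
    each block pair is reported once with ``interval_a`` leftmost.
    """
    config = config or PipelineConfig()
    seq = locus.seq if isinstance(locus, GenomicLocus) else locus
    k = config.block_seed_k
    out: list[SimilarityBlock] = []

    # direct orientation: self comparison, keep i > j to skip the diagonal
    seeds = [(i, j) for i, j in _kmer_seeds(seq, seq, k) if i > j + k]
    out.extend(_blocks_from_seeds(seq, seq, seeds, k, config, "direct"))

    # inverted orientation: locus vs its reverse complement
    rc = revcomp(seq)
    seeds = []
    L = len(seq)
    for i, j in _kmer_seeds(seq, rc, k):
        # map back: rc position j corresponds to forward interval end L - j
        b_start = L - (j + k)
        if i > b_start + k or b_start > i + k:  # skip the palindromic diagonal
            seeds.append((i, j))
    out.extend(_blocks_from_seeds(seq, rc, seeds, k, config, "inverted"))

    return _merge_blocks(out)


def _blocks_from_seeds(seq_a, seq_b, seeds, k, config, orientation):
    blocks = []
    L = len(seq_b)
    for chain in _chain_diagonals(seeds, k, config.block_chain_gap):
        i0, j0 = chain[0]
        i1, j1 = chain[-1]
        i1 += k
        j1 += k
        left = _xdrop_extend(seq_a, seq_b, i0, j0, -1)
        right = _xdrop_extend(seq_a, seq_b, i1 - 1, j1 - 1, +1)
        a_iv = (i0 - left, i1 + right)
        b_iv = (j0 - left, j1 + right)
        if a_iv[1] - a_iv[0] < config.block_min_len:
            continue
        ident = _gapped_identity(seq_a[a_iv[0] : a_iv[1]], seq_b[b_iv[0] : b_iv[1]])
        if ident < config.block_min_identity:
            continue
        if orientation == "inverted":
            b_iv = (L - b_iv[1], L - b_iv[0])
        overlap = min(a_iv[1], b_iv[1]) - max(a_iv[0], b_iv[0])
        if overlap > 0:
            # tandem copies touch after extension: trim the facing ends;
            # a substantial overlap means a near-diagonal self-match -> skip
            if overlap >= 0.2 * min(a_iv[1] - a_iv[0], b_iv[1] - b_iv[0]):
                continue
            if a_iv[0] <= b_iv[0]:
                a_iv = (a_iv[0], a_iv[1] - overlap)
            else:
                b_iv = (b_iv[0], b_iv[1] - overlap)
            if min(a_iv[1] - a_iv[0], b_iv[1] - b_iv[0]) < config.block_min_len:
                continue
        blocks.append(
            SimilarityBlock(interval_a=a_iv, interval_b=b_iv, orientation=orientation, identity=ident)
        )
    return blocks


def _intervals_overlap(a, b) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _merge_blocks(blocks: list[SimilarityBlock]) -> list[SimilarityBlock]:
    """Merge block pairs whose both ends overlap (chains split by indels)."""
    merged: list[SimilarityBlock] = []
    for blk in sorted(blocks, key=lambda b: (b.interval_a, b.interval_b)):
        absorbed = False
        for m in merged:
            if (
                m.orientation == blk.orientation
                and _near(m.interval_a, blk.interval_a)
                and _near(m.interval_b, blk.interval_b)
            ):
                m.interval_a = (
                    min(m.interval_a[0], blk.interval_a[0]),
                    max(m.interval_a[1], blk.interval_a[1]),
                )
                m.interval_b = (
                    min(m.interval_b[0], blk.interval_b[0]),
                    max(m.interval_b[1], blk.interval_b[1]),
                )
                m.identity = max(m.identity, blk.identity)
                absorbed = True
                break
        if not absorbed:
            merged.append(blk)
    return merged


def _near(a, b, slack: int = 300) -> bool:
    return max(a[0], b[0]) - slack < min(a[1], b[1]) + slack and not (
        a[1] + slack < b[0] or b[1] + slack < a[0]
    )


# ---------------------------------------------------------------------------
# block / gene-model overlap annotation


def annotate_block_gene_overlap(
    blocks: Sequence[SimilarityBlock],
    gene_models,  # Sequence[GeneModel]
) -> list[dict]:
    """Label each block end {coding, intronic, intergenic, mixed} + gene ids."""
    rows = []
    for blk in blocks:
        row = {"orientation": blk.orientation, "identity": round(blk.identity, 4)}
        for side, iv in (("a", blk.interval_a), ("b", blk.interval_b)):
            label, genes = _classify_interval(iv, gene_models)
            row[f"interval_{side}"] = iv
            row[f"class_{side}"] = label
            row[f"genes_{side}"] = genes
        rows.append(row)
    return rows


def _classify_interval(iv, gene_models) -> tuple[str, list[str]]:
    lo, hi = iv
    touches_exon = touches_intron = False
    genes = []
    nearest_gene = None
    nearest_dist = None
    for model in gene_models:
        if not model.exon_hits:
            continue
        g_lo, g_hi = model.span
        dist = 0 if g_lo < hi and lo < g_hi else min(abs(lo - g_hi), abs(g_lo - hi))
        if nearest_dist is None or dist < nearest_dist:
            nearest_gene, nearest_dist = model.gene_id, dist
        if g_lo < hi and lo < g_hi:
            in_exon = any(max(lo, h.start) < min(hi, h.end) for h in model.exon_hits)
            if in_exon:
                touches_exon = True
            else:
                touches_intron = True
            genes.append(model.gene_id)
    if touches_exon and touches_intron:
        label = "coding"
    elif touches_exon:
        label = "coding"
    elif touches_intron:
        label = "intronic"
    else:
        label = "intergenic"
        if nearest_gene is not None:
            genes = [f"near:{nearest_gene}"]
    if touches_exon and len(genes) == 0:
        label = "mixed"
    return label, genes


# ---------------------------------------------------------------------------
# tree-based conversion detection


def jukes_cantor(p: float) -> float:
    """JC69 distance from a raw mismatch proportion."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _pairwise_jc(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return math.inf
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    return jukes_cantor(p)


def detect_tree_intermixing(
    alignment: Mapping[str, str],
    gene_of: Mapping[str, str],
    species_of: Mapping[str, str],
    species_tree: SpeciesTree,
) -> list[ConversionCall]:
    """Call gene conversion from paralog-tree intermixing.

    ``alignment`` maps sequence labels to aligned homologous sequences (e.g.
    the CARD exons of every paralog in every species); ``gene_of`` and
    ``species_of`` map labels to gene family and species. For species ``s``
    and gene pair (g, h), conversion is called when the within-species
    cross-paralog distance d(g_s, h_s) is smaller than the smallest
    cross-species within-gene distance min_t d(g_s, g_t). Calls are merged
    into the minimum number of clade-level events on the species tree.
    """
    species = sorted(set(species_of.values()))
    if len(species) < 3:
        raise ValueError("need at least 3 species for a cross-species baseline")
    genes = sorted(set(gene_of.values()))
    if len(genes) < 2:
        raise ValueError("need at least 2 gene families")

    label_by = {(gene_of[k], species_of[k]): k for k in alignment}
    calls: list[ConversionCall] = []
    for gi in range(len(genes)):
        for hj in range(gi + 1, len(genes)):
            g, h = genes[gi], genes[hj]
            d_cross: dict[str, float] = {}
            d_within: dict[str, dict[str, float]] = {}
            for s in species:
                kg, kh = label_by.get((g, s)), label_by.get((h, s))
                if kg is None or kh is None:
                    continue
                d_cross[s] = _pairwise_jc(alignment[kg], alignment[kh])
                d_within[s] = {}
                for t in species:
                    kt = label_by.get((g, t))
                    if t != s and kt is not None:
                        d_within[s][t] = _pairwise_jc(alignment[kg], alignment[kt])

            # clade sweep: a clade is converted when every member's paralogs
            # are closer to each other than its gene is to any ortholog
            # *outside* the clade (and outside previously called species) --
            # inside a converted clade the orthologs coalesce after the
            # conversion, so they cannot serve as the baseline
            called: set[str] = set()
            changed = True
            while changed:
                changed = False
                for node in species_tree.tree.preorder_node_iter():
                    clade = {
                        l.taxon.label for l in node.leaf_iter()
                    } & set(d_cross)
                    if not clade or clade <= called:
                        continue
                    ok = True
                    for s in clade:
                        outside = [
                            d
                            for t, d in d_within[s].items()
                            if t not in called and t not in clade
                        ]
                        if not outside or d_cross[s] >= min(outside):
                            ok = False
                            break
                    if ok:
                        called |= clade
                        changed = True
            if called == set(d_cross):
                called = set()  # no unconverted reference lineage: not a conversion

            support_of = {
                s: min(
                    (d for t, d in d_within[s].items() if t not in called),
                    default=max(d_within[s].values()) if d_within[s] else math.inf,
                )
                - d_cross[s]
                for s in called
            }
            for clade in _merge_to_clades(called, species_tree):
                calls.append(
                    ConversionCall(
                        gene_a=g,
                        gene_b=h,
                        species=sorted(clade),
                        support=min(support_of[s] for s in clade),
                    )
                )
    return calls


def _merge_to_clades(called: set[str], tree: SpeciesTree) -> list[set[str]]:
    """Partition called leaves into maximal fully-called clades."""
    if not called:
        return []
    clades: list[set[str]] = []
    covered: set[str] = set()

    for node in tree.tree.preorder_node_iter():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if leaves <= called and not leaves & covered:
            clades.append(leaves & called)
            covered |= leaves
    return clades


# ---------------------------------------------------------------------------
# neighbor joining with bootstrap


def build_nj_tree(
    alignment: Mapping[str, str],
    n_bootstrap: int = 100,
    seed: int = 0,
):
    """Neighbor-joining tree on Jukes-Cantor distances with bootstrap support.

    Returns ``(skbio.TreeNode, {frozenset(leaf_labels): support_fraction})``.
    All-identical sequences yield zero-length branches.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels = sorted(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    cols = np.array([list(alignment[k]) for k in labels])

    def tree_from(cols_arr):
        n = len(labels)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = cols_arr[i], cols_arr[j]
                ok = (a != "-") & (b != "-")
                tot = int(ok.sum())
                p = float(((a != b) & ok).sum()) / tot if tot else 0.0
                d = jukes_cantor(p)
                dm[i, j] = dm[j, i] = d if math.isfinite(d) else 5.0
        return nj(DistanceMatrix(dm, labels))

    main = tree_from(cols)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncols = cols.shape[1]
    for _ in range(n_bootstrap):
        resampled = cols[:, rng.integers(0, ncols, size=ncols)]
        bt = tree_from(resampled)
        for clade in _bipartitions(bt):
            counts[clade] = counts.get(clade, 0) + 1
    support = {
        clade: counts.get(clade, 0) / n_bootstrap for clade in _bipartitions(main)
    }
    return main, support


def _bipartitions(tree) -> set[frozenset]:
    parts = set()
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips():
        tips = frozenset(t.name for t in node.tips())
        if 1 < len(tips) < len(all_tips):
            parts.add(tips)
    return parts
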