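"""Shared domain types, coordinate conventions, and file I/O.

All intervals in this package are 0-based half-open on the plus strand of the
stored sequence. GFF3 output converts to the standard 1-based closed dialect;
reading converts back, so the round trip is the identity.

Nucleotide sequences are normalized to uppercase over the alphabet
``{A, C, G, T, N}``; IUPAC ambiguity codes and other characters are collapsed
to ``N`` and the substitution count is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "PipelineConfig",
    "SpeciesTree",
    "GenomicLocus",
    "ReferenceGene",
    "ReferenceGeneSet",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "extract_locus",
    "write_gff3",
    "read_gff3",
    "revcomp",
]


class FormatError(ValueError):
    """Raised for malformed input files (FASTA/Newick/GFF3/TSV)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Thresholds applied across the pipeline.

    The defaults are the working thresholds of the analysis: exons are called
    at >=60% nucleotide identity with a bit score above 100; a homolog with
    fewer than 70% of its reference exons is "absent"; self-similarity blocks
    must be >=1 kb at >=50% identity; species beyond pairwise dS 0.3 from the
    reference are treated as outgroups; site tests run at alpha 0.05 with a
    Bonferroni-corrected gene-level threshold of 3.33e-3.
    """

    min_exon_identity: float = 0.60
    min_hit_score: float = 100.0  # bits
    min_exon_fraction: float = 0.70
    block_min_len: int = 1000  # bp
    block_min_identity: float = 0.50
    max_pairwise_ds: float = 0.3
    site_alpha: float = 0.05
    gene_alpha_bonferroni: float = 3.33e-3
    alt_cleavage_window: int = 5  # residues
    locus_flank: int = 350_000 // 2  # bp each side; the ~350 kb analysis window
    full_length_fraction: float = 0.95
    transcript_partial_fraction: float = 0.50
    block_seed_k: int = 12
    block_chain_gap: int = 200  # bp
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "min_exon_identity",
            "min_exon_fraction",
            "block_min_identity",
            "full_length_fraction",
            "transcript_partial_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must be a fraction in [0, 1]")
        if self.block_min_len < 1:
            raise ValueError("block_min_len must be >= 1")
        if self.gene_alpha_bonferroni > self.site_alpha:
            raise ValueError("gene_alpha_bonferroni must be <= site_alpha")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """A rooted species tree over uniquely-labelled leaves.

    Wraps a :class:`dendropy.Tree`. Branch lengths, when present, are in
    substitutions/site. Node ages (millions of years) are optional and can be
    attached from a side table; they must strictly decrease from root to tip.
    The topology is always an input, never inferred here.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate leaf labels in tree")
        self.ages: dict[int, float] = {}  # id(node) -> age in Mya

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- queries -----------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        if len(labels) == 1:
            return self.find_leaf(labels[0])
        taxa = [self._tree.taxon_namespace.get_taxon(x) for x in labels]
        if any(t is None for t in taxa):
            missing = [x for x, t in zip(labels, taxa) if t is None]
            raise KeyError(f"labels not in tree: {missing}")
        return self._tree.mrca(taxa=taxa)

    def find_leaf(self, label: str) -> dendropy.Node:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(label)

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}

    def root_to_leaf_length(self, label: str) -> float:
        node = self.find_leaf(label)
        total = 0.0
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
        return total

    # -- node ages ---------------------------------------------------------

    def attach_ages_from_pairs(self, rows: Sequence[tuple[str, str, float]]) -> None:
        """Attach MRCA ages from ``(species_a, species_b, age_mya)`` rows.

        Leaves default to age 0. Ages must strictly decrease root-to-leaf.
        """
        for leaf in self._tree.leaf_node_iter():
            self.ages[id(leaf)] = 0.0
        for a, b, age in rows:
            node = self.mrca([a, b])
            self.ages[id(node)] = float(age)
        self._check_age_monotone()

    def _check_age_monotone(self) -> None:
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            pa, na = self.ages.get(id(parent)), self.ages.get(id(node))
            if pa is not None and na is not None and not pa > na:
                raise ValueError(
                    f"node ages must strictly decrease from root to leaves "
                    f"(parent {pa} <= child {na})"
                )

    def age_of(self, node: dendropy.Node) -> float | None:
        return self.ages.get(id(node))


def read_newick(path: str | Path) -> SpeciesTree:
    return SpeciesTree.from_file(path)


# ---------------------------------------------------------------------------
# sequences


def _normalize_nt(seq: str, label: str) -> str:
    up = seq.upper()
    if set(up) <= NUCLEOTIDES:
        return up
    cleaned = "".join(c if c in NUCLEOTIDES else "N" for c in up)
    n_sub = sum(1 for a, b in zip(up, cleaned) if a != b)
    log.info("normalized %d non-ACGTN character(s) to N in %r", n_sub, label)
    return cleaned


def read_fasta(path: str | Path, *, alphabet: str = "nucleotide") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(label, sequence), ...]``.

    Nucleotide records are uppercased with non-ACGTN characters mapped to N
    (count logged); protein records are only uppercased. Empty files and
    duplicate labels are format errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty or non-FASTA file: {path}")
    labels = [r.id for r in records]
    if len(labels) != len(set(labels)):
        raise FormatError(f"duplicate labels in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if alphabet == "nucleotide":
            seq = _normalize_nt(seq, rec.id)
        else:
            seq = seq.upper()
        out.append((rec.id, seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    seqs = [SeqRecord(Seq(s), id=label, description="") for label, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)
    return path


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# loci and reference gene sets


@dataclass
class GenomicLocus:
    """One species' contiguous locus sequence (plus strand of the store).

    ``origin_offset`` records where the stored slice begins in the source
    assembly, so locus coordinates + offset recover assembly coordinates.
    """

    species: str
    seq: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("locus sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceGene:
    """A reference gene: exon nucleotide sequences in transcription order."""

    gene_id: str
    exons: list[str]
    strand: str = "+"
    slot: int = 0  # expected syntenic slot index along the locus

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def cds(self) -> str:
        return "".join(self.exons)


@dataclass
class ReferenceGeneSet:
    """Ordered reference gene layout used for annotation and synteny."""

    genes: list[ReferenceGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in reference set")

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> ReferenceGene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def extract_locus(
    assembly_seq: str,
    anchor_interval: tuple[int, int],
    flank: int,
    species: str = "unknown",
) -> GenomicLocus:
    """Slice ``[start - flank, end + flank)`` from an assembly, clipped to bounds.

    ``origin_offset`` records the left clip so locus coordinates can be mapped
    back to the assembly.
    """
    start, end = anchor_interval
    if end <= start:
        raise ValueError("empty anchor interval")
    if start < 0 or end > len(assembly_seq):
        raise ValueError("anchor outside sequence bounds")
    lo = max(0, start - flank)
    hi = min(len(assembly_seq), end + flank)
    return GenomicLocus(species=species, seq=assembly_seq[lo:hi], origin_offset=lo)


# ---------------------------------------------------------------------------
# GFF3 (1-based closed on disk; converted to/from 0-based half-open)


@dataclass
class Gff3Feature:
    seqid: str
    source: str
    ftype: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def write_gff3(features: Sequence[Gff3Feature], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.start + 1),  # to 1-based closed
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    return path


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"malformed GFF3 line: {line!r}")
        attrs = {}
        if parts[8] != ".":
            for item in parts[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
        feats.append(
            Gff3Feature(
                seqid=parts[0],
                source=parts[1],
                ftype=parts[2],
                start=int(parts[3]) - 1,  # back to 0-based half-open
                end=int(parts[4]),
                strand=parts[6],
                attributes=attrs,
            )
        )
    return feats
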