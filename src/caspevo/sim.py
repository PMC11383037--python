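"""Synthetic locus evolution with a known event history.

Generates per-species multi-gene locus sequences by evolving an ancestral
layout (genes with exons/introns, intergenic spacers) down a species tree
under an HKY substitution model. Coding sites evolve codon-wise with a
site-specific dN/dS (omega): nonsynonymous proposals are accepted with
probability min(1, omega) and synonymous proposals with min(1, 1/omega), so
the realized rate ratio equals omega on both sides of 1. Introns and
intergenic sequence evolve neutrally.

Gene-scale events (duplication, whole-gene loss, pseudogenizing lesions,
gene-conversion tracts, intergenic segmental duplications) are scripted on
named branches rather than drawn from rates, so every downstream detector can
be scored against an exact truth log. Identical config + seed reproduces
byte-identical output, and replaying the logged substitutions and events from
the ancestor reproduces each emitted locus exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .codons import STOP_CODONS, translate_codon
from .core import GenomicLocus, Gff3Feature, ReferenceGene, ReferenceGeneSet, SpeciesTree, revcomp, write_fasta, write_gff3
from .status import Lesion

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

EVENT_KINDS = (
    "loss",
    "duplication",
    "pseudogenization",
    "truncation",
    "conversion",
    "intergenic_duplication",
)


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneSpec:
    """Ancestral description of one gene: exon/intron sizes and selection.

    ``omega`` is either a scalar applied to every codon or a per-codon array
    (length = CDS codons, terminal stop included but never mutated).
    ``paralog_of`` seeds this gene's ancestral CDS as a diverged copy of
    another gene (codon-wise re-randomization at rate ``divergence``), which
    is how homologous paralog families (CARD-like) are built.
    """

    gene_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    strand: str = "+"
    omega: float | Sequence[float] = 0.2
    paralog_of: str | None = None
    divergence: float = 0.3

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SimConfigError(
                f"{self.gene_id}: need exactly len(exons)-1 introns"
            )
        if sum(self.exon_lengths) % 3 != 0:
            raise SimConfigError(f"{self.gene_id}: CDS length must be divisible by 3")
        if np.any(np.asarray(self.omega, dtype=float) <= 0):
            raise SimConfigError("omega values must be > 0")

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lengths)


@dataclass
class SimEvent:
    """A scripted event on the branch above the named clade.

    ``branch`` is a leaf label or a tuple of leaf labels (the MRCA's incoming
    branch). Parameters depend on ``kind``; everything an event resolves at
    run time (coordinates, indel sizes) is written to the truth log.
    """

    kind: str
    branch: str | tuple[str, ...]
    gene: str | None = None
    new_id: str | None = None  # duplication
    donor: str | None = None  # conversion
    tract_len: int = 1500  # conversion / intergenic duplication
    tract_offset: int = 0
    lesion_kind: str = "frameshift_indel"
    lesion_codon: int | None = None
    indel_len: int = 2
    flank: int = 300  # duplication flanks

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SimConfigError(f"unknown event kind {self.kind!r}")


@dataclass
class SimConfig:
    tree: SpeciesTree
    genes: list[GeneSpec]
    intergenic_lengths: list[int]
    kappa: float = 4.0
    events: list[SimEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intergenic_lengths) != len(self.genes) + 1:
            raise SimConfigError("need len(genes)+1 intergenic segments")
        ids = {g.gene_id for g in self.genes}
        leaves = set(self.tree.leaf_labels)
        for ev in self.events:
            names = [ev.branch] if isinstance(ev.branch, str) else list(ev.branch)
            if not set(names) <= leaves:
                raise SimConfigError(f"event branch {ev.branch!r} not in tree")
            for g in (ev.gene, ev.donor):
                if g is not None and g not in ids and not any(
                    e.kind == "duplication" and e.new_id == g for e in self.events
                ):
                    raise SimConfigError(f"event references unknown gene {g!r}")


# ---------------------------------------------------------------------------
# per-lineage state


@dataclass
class _GeneInstance:
    gene_id: str
    strand: str
    exons: list[list[int]]  # [[start, end), ...] genomic order
    omega: np.ndarray  # per-codon
    status: str = "present"
    lesions: list[Lesion] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class _LocusState:
    def __init__(self, seq: bytearray, genes: list[_GeneInstance]):
        self.seq = seq
        self.genes = genes
        self._rebuild_maps()

    def clone(self) -> "_LocusState":
        return _LocusState(bytearray(self.seq), copy.deepcopy(self.genes))

    # -- coordinate maps ---------------------------------------------------

    def _rebuild_maps(self) -> None:
        L = len(self.seq)
        self.gene_at = np.full(L, -1, dtype=np.int32)
        self.cds_pos = np.full(L, -1, dtype=np.int32)
        self._cds_cache: list[bytearray] = []
        for gi, gene in enumerate(self.genes):
            if gene.status == "absent":
                self._cds_cache.append(bytearray())
                continue
            positions: list[int] = []
            for s, e in gene.exons:
                positions.extend(range(s, e))
            if gene.strand == "-":
                positions = positions[::-1]
            cds = bytearray(len(positions))
            for ci, gpos in enumerate(positions):
                self.gene_at[gpos] = gi
                self.cds_pos[gpos] = ci
                base = chr(self.seq[gpos])
                cds[ci] = ord(base if gene.strand == "+" else _COMPLEMENT[base])
            self._cds_cache.append(cds)

    def cds_of(self, gene_id: str) -> str:
        for gi, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return self._cds_cache[gi].decode()
        raise KeyError(gene_id)

    def gene(self, gene_id: str) -> _GeneInstance:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def _shift(self, at: int, delta: int) -> None:
        for g in self.genes:
            for iv in g.exons:
                if iv[0] >= at:
                    iv[0] += delta
                    iv[1] += delta
                elif iv[1] > at:
                    iv[1] += delta

    # -- edits (shared by simulate and replay) -----------------------------

    def substitute(self, pos: int, new_base: str) -> None:
        self.seq[pos] = ord(new_base)
        gi = int(self.gene_at[pos])
        if gi >= 0:
            gene = self.genes[gi]
            ci = int(self.cds_pos[pos])
            b = new_base if gene.strand == "+" else _COMPLEMENT[new_base]
            self._cds_cache[gi][ci] = ord(b)

    def delete(self, start: int, length: int) -> None:
        del self.seq[start : start + length]
        self._delete_fix(start, length)
        self._rebuild_maps()

    def _delete_fix(self, start: int, length: int) -> None:
        end = start + length
        for g in self.genes:
            new_exons = []
            for s, e in [(iv[0], iv[1]) for iv in g.exons]:
                if e <= start:
                    new_exons.append([s, e])
                elif s >= end:
                    new_exons.append([s - length, e - length])
                else:  # overlap: clip
                    ns = min(s, start)
                    ne = max(start, e - length) if e > end else start
                    if ne > ns:
                        new_exons.append([ns, ne])
            g.exons = new_exons
            if not new_exons:
                g.status = "absent"

    def insert(self, at: int, content: bytes) -> None:
        self.seq[at:at] = content
        self._shift(at, len(content))
        self._rebuild_maps()

    def overwrite(self, start: int, content: bytes) -> None:
        self.seq[start : start + len(content)] = content
        self._rebuild_maps()


# ---------------------------------------------------------------------------
# truth


@dataclass
class SimulationTruth:
    """The generative record: event log, statuses, coordinates, omega."""

    tree_newick: str
    ancestral_seq: str
    ancestral_genes: list[dict]
    events: list[dict] = field(default_factory=list)
    substitutions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    statuses: dict[str, dict[str, str]] = field(default_factory=dict)
    exon_coords: dict[str, list[dict]] = field(default_factory=dict)
    cds: dict[str, dict[str, str]] = field(default_factory=dict)
    omegas: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "tree": self.tree_newick,
            "events": self.events,
            "statuses": self.statuses,
            "exon_coords": self.exon_coords,
            "omegas": self.omegas,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


# ---------------------------------------------------------------------------
# generation


def _random_noncoding(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG start, random internal sense codons, single terminal stop."""
    sense = [c for c in _all_codons() if c not in STOP_CODONS and c != "ATG"]
    codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(n_codons - 2)]
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def _all_codons() -> list[str]:
    return ["".join(p) for p in __import__("itertools").product("ACGT", repeat=3)]


def _diverge_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Codon-wise re-randomization used to seed ancestral paralogs."""
    sense = [c for c in _all_codons() if c not in STOP_CODONS]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i in range(1, len(codons) - 1):
        for j in range(3):
            if rng.random() < rate:
                codon = codons[i]
                choices = [b for b in "ACGT" if b != codon[j]]
                cand = codon[:j] + choices[rng.integers(3)] + codon[j + 1 :]
                if cand not in STOP_CODONS:
                    codons[i] = cand
    return "".join(codons)


def _build_ancestor(config: SimConfig, rng: np.random.Generator) -> _LocusState:
    parts: list[str] = []
    genes: list[_GeneInstance] = []
    cds_by_id: dict[str, str] = {}
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    for idx, spec in enumerate(config.genes):
        emit(_random_noncoding(rng, config.intergenic_lengths[idx]))
        if spec.paralog_of is not None:
            if spec.paralog_of not in cds_by_id:
                raise SimConfigError(
                    f"{spec.gene_id}: paralog_of {spec.paralog_of!r} must come earlier"
                )
            template = cds_by_id[spec.paralog_of]
            if len(template) != spec.cds_len:
                raise SimConfigError(
                    f"{spec.gene_id}: paralog CDS length must match template"
                )
            cds = _diverge_cds(rng, template, spec.divergence)
        else:
            cds = _random_cds(rng, spec.cds_len // 3)
        cds_by_id[spec.gene_id] = cds

        # split the CDS into exons along the genomic strand
        chunks = []
        acc = 0
        for elen in spec.exon_lengths:
            chunks.append(cds[acc : acc + elen])
            acc += elen
        if spec.strand == "-":
            chunks = [revcomp(c) for c in chunks][::-1]
            introns = spec.intron_lengths[::-1]
        else:
            introns = spec.intron_lengths

        exon_ivs: list[list[int]] = []
        for i, chunk in enumerate(chunks):
            start = pos
            emit(chunk)
            exon_ivs.append([start, pos])
            if i < len(chunks) - 1:
                emit(_random_noncoding(rng, introns[i]))

        omega = np.asarray(
            np.broadcast_to(np.asarray(spec.omega, dtype=float), (spec.cds_len // 3,)),
            dtype=float,
        ).copy()
        genes.append(
            _GeneInstance(gene_id=spec.gene_id, strand=spec.strand, exons=exon_ivs, omega=omega)
        )
    emit(_random_noncoding(rng, config.intergenic_lengths[-1]))

    return _LocusState(bytearray("".join(parts).encode()), genes)


# ---------------------------------------------------------------------------
# branch evolution


def _mutate_branch(
    state: _LocusState,
    t: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """HKY mutation-selection sweep along one branch; returns accepted subs."""
    L = len(state.seq)
    n_attempts = rng.poisson(t * L)
    accepted: list[tuple[int, str, str]] = []
    bases = "ACGT"
    trs = {"A": "G", "G": "A", "C": "T", "T": "C"}
    p_transition = kappa / (kappa + 2.0)
    for _ in range(n_attempts):
        pos = int(rng.integers(L))
        old = chr(state.seq[pos])
        if old == "N":
            continue
        if rng.random() < p_transition:
            new = trs[old]
        else:
            tv = [b for b in bases if b != old and b != trs[old]]
            new = tv[int(rng.integers(2))]
        gi = int(state.gene_at[pos])
        if gi >= 0 and state.genes[gi].status != "pseudogene":
            gene = state.genes[gi]
            ci = int(state.cds_pos[pos])
            codon_idx = ci // 3
            cds = state._cds_cache[gi]
            n_codons = len(cds) // 3
            if codon_idx in (0, n_codons - 1):
                continue  # intact genes keep their start and stop codons
            codon = cds[codon_idx * 3 : codon_idx * 3 + 3].decode()
            within = ci % 3
            nb = new if gene.strand == "+" else _COMPLEMENT[new]
            mutant = codon[:within] + nb + codon[within + 1 :]
            if mutant in STOP_CODONS:
                continue
            omega = float(gene.omega[codon_idx])
            if translate_codon(mutant) == translate_codon(codon):
                if omega > 1.0 and rng.random() > min(1.0, 1.0 / omega):
                    continue
            else:
                if rng.random() > min(1.0, omega):
                    continue
        state.substitute(pos, new)
        accepted.append((pos, old, new))
    return accepted


# ---------------------------------------------------------------------------
# events


def _apply_event(state: _LocusState, ev: SimEvent, rng: np.random.Generator) -> dict:
    record: dict = {"kind": ev.kind, "gene": ev.gene}
    if ev.kind == "loss":
        gene = state.gene(ev.gene)
        if gene.status == "absent":
            raise SimConfigError(f"loss of already-deleted gene {ev.gene}")
        s, e = gene.span
        record.update(start=s, end=e, length=e - s)
        state.delete(s, e - s)
        gene.exons = []
        gene.status = "absent"
        state._rebuild_maps()
    elif ev.kind == "duplication":
        gene = state.gene(ev.gene)
        if gene.status == "absent":
            raise SimConfigError(f"duplication of deleted gene {ev.gene}")
        s, e = gene.span
        lo, hi = max(0, s - ev.flank), min(len(state.seq), e + ev.flank)
        content = bytes(state.seq[lo:hi])
        new_id = ev.new_id or f"{ev.gene}~dup"
        insert_at = hi
        new_exons = [[a - lo + insert_at, b - lo + insert_at] for a, b in gene.exons]
        state.insert(insert_at, content)
        dup = _GeneInstance(
            gene_id=new_id,
            strand=gene.strand,
            exons=new_exons,
            omega=gene.omega.copy(),
            status=gene.status,
        )
        src_index = state.genes.index(gene)
        state.genes.insert(src_index + 1, dup)
        state._rebuild_maps()
        record.update(new_id=new_id, insert_at=insert_at, start=lo, end=hi, length=hi - lo)
    elif ev.kind == "pseudogenization":
        gene = state.gene(ev.gene)
        if gene.status == "absent":
            raise SimConfigError(f"pseudogenization of deleted gene {ev.gene}")
        cds_len = sum(e - s for s, e in gene.exons)
        n_codons = cds_len // 3
        codon = ev.lesion_codon if ev.lesion_codon is not None else n_codons // 2
        if ev.lesion_kind == "frameshift_indel":
            k = ev.indel_len
            if k % 3 == 0:
                raise SimConfigError("frameshift length must not be a multiple of 3")
            gpos = _genomic_of_cds(gene, codon * 3)
            state.delete(gpos, k)
            gene.status = "pseudogene"
            gene.lesions.append(Lesion("frameshift_indel", cds_pos=codon * 3, genomic_pos=gpos, length=k))
            record.update(lesion="frameshift_indel", codon=codon, genomic_pos=gpos, length=k)
        elif ev.lesion_kind == "premature_stop":
            if codon >= n_codons - 1:
                raise SimConfigError("premature stop must precede the native stop")
            positions = [_genomic_of_cds(gene, codon * 3 + j) for j in range(3)]
            stop = "TAA"
            for j, gpos in enumerate(positions):
                b = stop[j] if gene.strand == "+" else _COMPLEMENT[stop[j]]
                state.seq[gpos] = ord(b)
            state._rebuild_maps()
            gene.status = "pseudogene"
            gene.lesions.append(Lesion("premature_stop", cds_pos=codon * 3))
            record.update(lesion="premature_stop", codon=codon, positions=positions)
        elif ev.lesion_kind == "exon_loss":
            exon_idx = min(len(gene.exons) - 1, max(0, (ev.lesion_codon or 1)))
            s, e = gene.exons[exon_idx]
            state.delete(s, e - s)
            gene.status = "pseudogene"
            gene.lesions.append(Lesion("exon_loss", cds_pos=0, genomic_pos=s, length=e - s))
            record.update(lesion="exon_loss", exon=exon_idx, start=s, length=e - s)
        else:
            raise SimConfigError(f"unsupported scripted lesion {ev.lesion_kind!r}")
    elif ev.kind == "truncation":
        # in-frame partial gene: trailing exons (and their introns) removed
        gene = state.gene(ev.gene)
        if gene.status == "absent":
            raise SimConfigError(f"truncation of deleted gene {ev.gene}")
        n_removed = max(1, ev.indel_len)  # number of trailing exons
        if n_removed >= len(gene.exons):
            raise SimConfigError("truncation would remove the whole gene")
        keep = gene.exons[:-n_removed]
        cut_from = keep[-1][1]
        cut_to = gene.exons[-1][1]
        state.delete(cut_from, cut_to - cut_from)
        gene.exons = [list(iv) for iv in gene.exons[: len(keep)]]
        gene.status = "partial_in_frame"
        state._rebuild_maps()
        record.update(start=cut_from, length=cut_to - cut_from, exons_removed=n_removed)
    elif ev.kind == "conversion":
        donor = state.gene(ev.donor)
        acceptor = state.gene(ev.gene)
        ds, de = donor.span
        as_, ae = acceptor.span
        tract = min(ev.tract_len, de - ds - ev.tract_offset, ae - as_ - ev.tract_offset)
        if tract < 1:
            raise SimConfigError("conversion tract does not fit in gene spans")
        d_iv = (ds + ev.tract_offset, ds + ev.tract_offset + tract)
        a_iv = (as_ + ev.tract_offset, as_ + ev.tract_offset + tract)
        content = bytes(state.seq[d_iv[0] : d_iv[1]])
        state.overwrite(a_iv[0], content)
        record.update(donor=ev.donor, donor_interval=list(d_iv), acceptor_interval=list(a_iv), length=tract)
    elif ev.kind == "intergenic_duplication":
        gene = state.gene(ev.gene)
        _, e = gene.span
        src = (e + 50, e + 50 + ev.tract_len)
        downstream_starts = [
            g.span[0] for g in state.genes if g.exons and g.span[0] > e
        ]
        limit = min(downstream_starts) - 10 if downstream_starts else len(state.seq) - 1
        if src[1] >= limit:
            raise SimConfigError("intergenic tract does not fit between genes")
        content = bytes(state.seq[src[0] : src[1]])
        state.insert(src[1], content)
        record.update(source_interval=list(src), insert_at=src[1], length=ev.tract_len)
    return record


def _genomic_of_cds(gene: _GeneInstance, cds_index: int) -> int:
    positions: list[int] = []
    for s, e in gene.exons:
        positions.extend(range(s, e))
    if gene.strand == "-":
        positions = positions[::-1]
    return positions[cds_index]


# ---------------------------------------------------------------------------
# the driver


def _branch_label(node) -> str:
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "|".join(leaves)


def simulate_dataset(config: SimConfig) -> tuple[dict[str, GenomicLocus], SimulationTruth]:
    """Evolve the ancestral locus down the tree; return loci + truth log."""
    rng = np.random.default_rng(config.seed)
    ancestor = _build_ancestor(config, rng)

    truth = SimulationTruth(
        tree_newick=config.tree.to_newick(),
        ancestral_seq=bytes(ancestor.seq).decode(),
        ancestral_genes=[
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "exons": [list(iv) for iv in g.exons],
            }
            for g in ancestor.genes
        ],
        omegas={g.gene_id: list(map(float, g.omega)) for g in ancestor.genes},
    )

    # resolve scripted events to node ids
    tree = config.tree
    events_by_node: dict[int, list[SimEvent]] = {}
    for ev in config.events:
        node = (
            tree.find_leaf(ev.branch)
            if isinstance(ev.branch, str)
            else tree.mrca(ev.branch)
        )
        events_by_node.setdefault(id(node), []).append(ev)

    loci: dict[str, GenomicLocus] = {}

    def visit(node, state: _LocusState) -> None:
        label = _branch_label(node)
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            subs = _mutate_branch(state, t, config.kappa, rng)
            truth.substitutions[label] = subs
            for ev in events_by_node.get(id(node), []):
                record = _apply_event(state, ev, rng)
                record["branch"] = label
                truth.events.append(record)
        if node.is_leaf():
            sp = node.taxon.label
            loci[sp] = GenomicLocus(species=sp, seq=bytes(state.seq).decode())
            truth.statuses[sp] = {g.gene_id: g.status for g in state.genes}
            truth.exon_coords[sp] = [
                {
                    "gene_id": g.gene_id,
                    "strand": g.strand,
                    "exons": [list(iv) for iv in g.exons],
                }
                for g in state.genes
                if g.status != "absent"
            ]
            truth.cds[sp] = {
                g.gene_id: state.cds_of(g.gene_id)
                for g in state.genes
                if g.status != "absent"
            }
        else:
            children = list(node.child_nodes())
            for i, child in enumerate(children):
                child_state = state if i == len(children) - 1 else state.clone()
                visit(child, child_state)

    visit(tree.tree.seed_node, ancestor)
    return loci, truth


def replay_species(truth: SimulationTruth, tree: SpeciesTree, species: str) -> str:
    """Re-derive one species' locus from the truth log alone.

    Applies the logged substitutions, then the logged events, branch by branch
    along the root-to-leaf path. Used to verify log completeness.
    """
    genes = [
        _GeneInstance(
            gene_id=g["gene_id"],
            strand=g["strand"],
            exons=[list(iv) for iv in g["exons"]],
            omega=np.ones(sum(e - s for s, e in g["exons"]) // 3),
        )
        for g in truth.ancestral_genes
    ]
    state = _LocusState(bytearray(truth.ancestral_seq.encode()), genes)

    node = tree.find_leaf(species)
    path = []
    while node is not None:
        path.append(node)
        node = node.parent_node
    for node in reversed(path[:-1]):  # root-to-leaf, skipping the root itself
        label = _branch_label(node)
        for pos, _old, new in truth.substitutions.get(label, []):
            state.substitute(pos, new)
        for record in truth.events:
            if record["branch"] != label:
                continue
            _replay_event(state, record)
    return bytes(state.seq).decode()


def _replay_event(state: _LocusState, record: dict) -> None:
    kind = record["kind"]
    if kind == "loss":
        gene = state.gene(record["gene"])
        state.delete(record["start"], record["length"])
        gene.exons = []
        gene.status = "absent"
        state._rebuild_maps()
    elif kind == "duplication":
        gene = state.gene(record["gene"])
        content = bytes(state.seq[record["start"] : record["end"]])
        new_exons = [
            [a - record["start"] + record["insert_at"], b - record["start"] + record["insert_at"]]
            for a, b in gene.exons
        ]
        state.insert(record["insert_at"], content)
        dup = _GeneInstance(
            gene_id=record["new_id"], strand=gene.strand, exons=new_exons, omega=gene.omega.copy()
        )
        state.genes.insert(state.genes.index(gene) + 1, dup)
        state._rebuild_maps()
    elif kind == "pseudogenization":
        gene = state.gene(record["gene"])
        if record["lesion"] == "frameshift_indel":
            state.delete(record["genomic_pos"], record["length"])
        elif record["lesion"] == "premature_stop":
            stop = "TAA"
            for j, gpos in enumerate(record["positions"]):
                b = stop[j] if gene.strand == "+" else _COMPLEMENT[stop[j]]
                state.seq[gpos] = ord(b)
            state._rebuild_maps()
        elif record["lesion"] == "exon_loss":
            state.delete(record["start"], record["length"])
        gene.status = "pseudogene"
    elif kind == "truncation":
        gene = state.gene(record["gene"])
        state.delete(record["start"], record["length"])
        gene.status = "partial_in_frame"
    elif kind == "conversion":
        d = record["donor_interval"]
        a = record["acceptor_interval"]
        state.overwrite(a[0], bytes(state.seq[d[0] : d[1]]))
    elif kind == "intergenic_duplication":
        s = record["source_interval"]
        state.insert(record["insert_at"], bytes(state.seq[s[0] : s[1]]))


# ---------------------------------------------------------------------------
# public sequence-level operations


def apply_pseudogenizing_lesion(
    cds: str,
    lesion_kind: str,
    position: int,
    rng: np.random.Generator | None = None,
    *,
    indel_len: int = 1,
    insert: bool = False,
    exon_lengths: Sequence[int] | None = None,
) -> tuple[str, Lesion]:
    """Apply one pseudogenizing lesion to a CDS string.

    ``position`` is a codon index for frameshift/premature-stop lesions and an
    exon index for exon-level lesions (which require ``exon_lengths``).
    """
    rng = rng or np.random.default_rng(0)
    n_codons = len(cds) // 3
    if lesion_kind == "frameshift_indel":
        if indel_len % 3 == 0:
            raise ValueError("frameshift indel length must not be a multiple of 3")
        at = position * 3
        if insert:
            ins = "".join(rng.choice(list("ACGT"), size=indel_len))
            new = cds[:at] + ins + cds[at:]
        else:
            new = cds[:at] + cds[at + indel_len :]
        return new, Lesion("frameshift_indel", cds_pos=at, length=indel_len)
    if lesion_kind == "premature_stop":
        if position >= n_codons - 1:
            raise ValueError("premature stop must precede the final codon")
        at = position * 3
        new = cds[:at] + "TAA" + cds[at + 3 :]
        return new, Lesion("premature_stop", cds_pos=at)
    if lesion_kind in ("exon_loss", "exon_truncation", "splice_site_disruption"):
        if exon_lengths is None:
            raise ValueError(f"{lesion_kind} requires exon_lengths")
        bounds = np.concatenate([[0], np.cumsum(exon_lengths)])
        s, e = int(bounds[position]), int(bounds[position + 1])
        if lesion_kind == "exon_truncation":
            e = s + (e - s) // 2
        new = cds[:s] + cds[e:]
        return new, Lesion(lesion_kind, cds_pos=s, length=e - s)
    raise ValueError(f"unknown lesion kind {lesion_kind!r}")


def apply_gene_conversion(
    seq: str, donor_interval: tuple[int, int], acceptor_interval: tuple[int, int]
) -> str:
    """Overwrite the acceptor tract with the donor tract (non-reciprocal)."""
    (ds, de), (as_, ae) = donor_interval, acceptor_interval
    if de - ds != ae - as_:
        raise ValueError("donor and acceptor intervals must have equal length")
    if max(ds, as_) < min(de, ae):
        raise ValueError("donor and acceptor intervals overlap")
    return seq[:as_] + seq[ds:de] + seq[ae:]


# ---------------------------------------------------------------------------
# reference sets, presets, emission


def reference_set_from_truth(truth: SimulationTruth, species: str) -> ReferenceGeneSet:
    """Build an annotation reference from one species' truth record."""
    genes = []
    for slot, rec in enumerate(truth.exon_coords[species]):
        cds = truth.cds[species][rec["gene_id"]]
        exon_lengths = [e - s for s, e in rec["exons"]]
        if rec["strand"] == "-":
            exon_lengths = exon_lengths[::-1]
        exons, acc = [], 0
        for elen in exon_lengths:
            exons.append(cds[acc : acc + elen])
            acc += elen
        genes.append(ReferenceGene(gene_id=rec["gene_id"], exons=exons, strand=rec["strand"], slot=slot))
    return ReferenceGeneSet(genes=genes)


def emit_dataset(loci: dict[str, GenomicLocus], truth: SimulationTruth, outdir: str | Path) -> Path:
    """Write FASTA loci, GFF3 truth annotations, Newick tree, JSON truth log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, locus in loci.items():
        write_fasta([(sp, locus.seq)], outdir / f"{sp}.locus.fasta")
        feats = []
        for rec in truth.exon_coords[sp]:
            for i, (s, e) in enumerate(rec["exons"]):
                feats.append(
                    Gff3Feature(
                        seqid=sp,
                        source="caspevo-sim",
                        ftype="exon",
                        start=s,
                        end=e,
                        strand=rec["strand"],
                        attributes={"gene_id": rec["gene_id"], "exon_number": str(i + 1)},
                    )
                )
        write_gff3(feats, outdir / f"{sp}.truth.gff3")
    (outdir / "species.nwk").write_text(truth.tree_newick + "\n")
    truth.to_json(outdir / "truth.json")
    return outdir


def _caspase_like_genes(scale: float) -> tuple[list[GeneSpec], list[int]]:
    """An 8-gene caspase-locus-like layout.

    At ``scale=1`` the locus is ~350 kb (large introns and intergenic runs);
    smaller scales shrink the non-coding fraction only, keeping every coding
    feature intact for desk-size runs.
    """

    def nc(n: int) -> int:
        return max(60, int(n * scale))

    def gene(gid, exons, strand="+", omega=0.2, paralog_of=None, divergence=0.3):
        introns = [nc(3500)] * (len(exons) - 1)
        return GeneSpec(
            gene_id=gid,
            exon_lengths=exons,
            intron_lengths=introns,
            strand=strand,
            omega=omega,
            paralog_of=paralog_of,
            divergence=divergence,
        )

    genes = [
        gene("CARDA", [180, 180]),
        gene("CASP1", [180, 180, 240, 240, 180, 201], omega=0.3),
        gene("CARDB", [180, 180], paralog_of="CARDA", divergence=0.25),
        gene("CASP4", [180, 240, 240, 240, 180, 180], omega=0.2),
        gene("CASP5", [180, 240, 240, 240, 180, 180], paralog_of="CASP4", divergence=0.2, omega=0.25),
        gene("CASP12", [180, 240, 240, 240, 180, 180], omega=0.25),
    ]
    intergenic = [nc(30000)] * (len(genes) + 1)
    return genes, intergenic


PRIMATE_TREE = (
    "(((((Human:0.01,Chimp:0.01):0.01,Gorilla:0.02):0.02,Orangutan:0.04):0.02,"
    "(Macaque:0.03,Baboon:0.03):0.03):0.02,(Marmoset:0.05,SquirrelMonkey:0.05):0.04);"
)

RODENT_TREE = (
    "((((Mouse:0.04,SpretusLike:0.04):0.03,Rat:0.08):0.03,Gerbil:0.10):0.03,"
    "(Hamster:0.10,Vole:0.10):0.05);"
)


def primate_like(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Event-rich regime: duplication, losses, lesions, and conversion."""
    tree = SpeciesTree.from_newick(PRIMATE_TREE)
    genes, intergenic = _caspase_like_genes(scale)
    events = [
        SimEvent(kind="duplication", branch=("Human", "Orangutan"), gene="CASP4", new_id="CASP4LP"),
        SimEvent(kind="pseudogenization", branch=("Human", "Orangutan"), gene="CASP4LP", lesion_kind="premature_stop", lesion_codon=40),
        SimEvent(kind="loss", branch=("Marmoset", "SquirrelMonkey"), gene="CASP5"),
        SimEvent(kind="pseudogenization", branch=("Human", "Gorilla"), gene="CASP12", lesion_kind="frameshift_indel", indel_len=2),
        SimEvent(kind="pseudogenization", branch="Baboon", gene="CASP12", lesion_kind="premature_stop", lesion_codon=125),
        SimEvent(kind="conversion", branch=("Human", "Gorilla"), gene="CARDA", donor="CASP1", tract_len=1500),
        SimEvent(kind="loss", branch="SquirrelMonkey", gene="CARDB"),
        SimEvent(kind="truncation", branch="Orangutan", gene="CASP5", indel_len=1),
    ]
    return SimConfig(tree=tree, genes=genes, intergenic_lengths=intergenic, events=events, seed=seed)


def rodent_like(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Event-poor regime: no coding duplications or conversions; one
    pseudogenization and planted intergenic repeat insertions."""
    tree = SpeciesTree.from_newick(RODENT_TREE)
    genes, intergenic = _caspase_like_genes(scale)
    # rodents carry a single CASP4/11-like gene: drop the CASP5 paralog
    genes = [g for g in genes if g.gene_id != "CASP5"]
    intergenic = intergenic[:-1]
    events = [
        SimEvent(kind="pseudogenization", branch="Vole", gene="CASP12", lesion_kind="frameshift_indel", indel_len=1),
        SimEvent(kind="intergenic_duplication", branch="Mouse", gene="CASP1", tract_len=1600),
        SimEvent(kind="intergenic_duplication", branch="Mouse", gene="CASP12", tract_len=1200),
    ]
    return SimConfig(tree=tree, genes=genes, intergenic_lengths=intergenic, events=events, seed=seed)


# ---------------------------------------------------------------------------
# lightweight codon-alignment simulation (selection-test calibration)


def simulate_codon_alignment(
    tree: SpeciesTree,
    n_codons: int,
    omega: float | Sequence[float],
    kappa: float = 4.0,
    seed: int = 0,
) -> tuple[dict[str, str], np.ndarray]:
    """Evolve a single CDS down a tree; returns {species: cds} and omegas.

    Shares the mutation-selection core with the locus simulator but skips the
    genomic scaffolding; used for site-test calibration at known omega.
    """
    rng = np.random.default_rng(seed)
    omegas = np.broadcast_to(np.asarray(omega, dtype=float), (n_codons,)).copy()
    cds = _random_cds(rng, n_codons)
    gene = _GeneInstance(gene_id="g", strand="+", exons=[[0, 3 * n_codons]], omega=omegas)
    root = _LocusState(bytearray(cds.encode()), [gene])

    out: dict[str, str] = {}

    def visit(node, state: _LocusState) -> None:
        if node.parent_node is not None:
            _mutate_branch(state, node.edge.length or 0.0, kappa, rng)
        if node.is_leaf():
            out[node.taxon.label] = bytes(state.seq).decode()
        else:
            children = list(node.child_nodes())
            for i, child in enumerate(children):
                visit(child, state if i == len(children) - 1 else state.clone())

    visit(tree.tree.seed_node, root)
    return out, omegas
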