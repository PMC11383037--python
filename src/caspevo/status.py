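"""Four-way gene status calls and pseudogene lesion evidence.

Each homolog is classified as ``present``, ``partial_in_frame``,
``pseudogene``, or ``absent``. The decision order is fixed: the exon-fraction
absence test runs first (a homolog with fewer than 70% of the reference exons
is absent regardless of remnant content), then lesion-free full-length
homologs are present, lesion-free shorter in-frame spans are partial, and
everything else is a pseudogene.

Lesions unique to a single assembly are flagged low-confidence: the same
defect appearing independently in a related species is the evidence that
distinguishes a real pseudogenizing event from an assembly error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Mapping, Sequence

from Bio import Align

from .codons import STOP_CODONS
from .core import PipelineConfig, SpeciesTree

LESION_KINDS = (
    "frameshift_indel",
    "premature_stop",
    "lost_start",
    "exon_truncation",
    "exon_loss",
    "splice_site_disruption",
)

STATUS_CALLS = ("present", "partial_in_frame", "pseudogene", "absent")


@dataclass
class Lesion:
    """A coding lesion supporting a pseudogene call."""

    kind: str
    cds_pos: int  # bp coordinate in the (reference-projected) CDS
    genomic_pos: int | None = None
    length: int | None = None  # indel length in bp, where applicable
    shared_with: list[str] = field(default_factory=list)
    low_confidence: bool = False
    assembly_error: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass
class GeneStatus:
    call: str
    completeness: float
    lesions: list[Lesion] = field(default_factory=list)
    transcript_support: str = "not_checked"
    aligned_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.call not in STATUS_CALLS:
            raise ValueError(f"unknown status call {self.call!r}")


# status TSV encoding used on disk: 1 present, 0 pseudogene, -1 absent, * partial
STATUS_CODES = {"present": "1", "pseudogene": "0", "absent": "-1", "partial_in_frame": "*"}
CODES_STATUS = {v: k for k, v in STATUS_CODES.items()}


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # gap-open averse but long-gap tolerant: at high divergence, cheap gap
    # opens let the aligner fabricate compensating indel pairs that read as
    # false frameshifts, while an expensive extension would make a genuine
    # whole-exon deletion score worse than no alignment at all
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    # free end gaps on both sequences: terminal truncation is handled
    # separately, not as a giant alignment gap
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def detect_lesions(
    cds: str,
    reference_cds: str,
    reference_exon_lengths: Sequence[int] | None = None,
) -> list[Lesion]:
    """Compare a candidate CDS to the reference and list coding lesions.

    Frameshifts are internal indels whose length is not a multiple of 3;
    premature stops are in-frame stop codons upstream of the reference stop
    (frame tracked through indels); long gaps covering >=80% of a reference
    exon are reported as exon loss when exon boundaries are supplied. A
    missing ATG at the start is a lost_start lesion.
    """
    if not cds:
        raise ValueError("empty CDS")
    lesions: list[Lesion] = []

    aln = _global_aligner().align(reference_cds, cds)[0]
    ref_aligned, qry_aligned = str(aln[0]), str(aln[1])

    # walk alignment columns tracking coordinates and internal indels
    ref_pos = qry_pos = 0
    indels: list[tuple[int, int, int]] = []  # (ref_pos, qry_pos, signed length)
    col = 0
    ncols = len(ref_aligned)
    while col < ncols:
        r, q = ref_aligned[col], qry_aligned[col]
        if r == "-" or q == "-":
            gap_in_ref = r == "-"
            run = 0
            start_ref, start_qry = ref_pos, qry_pos
            while col < ncols and (ref_aligned[col] == "-") == gap_in_ref and (
                ref_aligned[col] == "-" or qry_aligned[col] == "-"
            ):
                if ref_aligned[col] == "-" and qry_aligned[col] == "-":
                    break
                if gap_in_ref and ref_aligned[col] != "-":
                    break
                if not gap_in_ref and qry_aligned[col] != "-":
                    break
                run += 1
                if gap_in_ref:
                    qry_pos += 1
                else:
                    ref_pos += 1
                col += 1
            internal = 0 < start_ref < len(reference_cds) or (
                gap_in_ref and 0 < start_qry < len(cds) and start_ref > 0
            )
            # terminal overhangs (free end gaps) are not indel lesions
            if 0 < start_ref and ref_pos < len(reference_cds):
                indels.append((start_ref, start_qry, run if gap_in_ref else -run))
            continue
        ref_pos += 1
        qry_pos += 1
        col += 1

    frame_offset = 0
    for ref_at, qry_at, signed_len in indels:
        length = abs(signed_len)
        if reference_exon_lengths and signed_len < 0:
            # deletion in the query: does it wipe out most of a reference exon?
            bounds = []
            acc = 0
            for elen in reference_exon_lengths:
                bounds.append((acc, acc + elen))
                acc += elen
            del_iv = (ref_at, ref_at + length)
            matched_exon = False
            for i, (s, e) in enumerate(bounds):
                overlap = max(0, min(e, del_iv[1]) - max(s, del_iv[0]))
                if overlap >= 0.8 * (e - s):
                    lesions.append(
                        Lesion(kind="exon_loss", cds_pos=s, length=e - s, note=f"exon {i + 1}")
                    )
                    matched_exon = True
            if matched_exon and length % 3 == 0:
                continue
        if length % 3 != 0:
            lesions.append(Lesion(kind="frameshift_indel", cds_pos=ref_at, length=length))

    # premature stops: scan the query in its own frame, shifting at indels
    shift_points = sorted((q, s) for _, q, s in indels)
    ref_stop_codon_index = len(reference_cds) // 3 - 1
    pos = 0
    for codon_index in range(len(cds) // 3):
        codon = cds[codon_index * 3 : codon_index * 3 + 3]
        if len(codon) < 3:
            break
        if codon in STOP_CODONS:
            # map query codon index to an approximate reference codon index
            # (a deletion in the query puts the reference ahead of it)
            offset = -sum(s for q, s in shift_points if q <= codon_index * 3)
            ref_codon = (codon_index * 3 + offset) // 3
            if ref_codon < ref_stop_codon_index:
                lesions.append(Lesion(kind="premature_stop", cds_pos=codon_index * 3))

    if reference_cds.startswith("ATG") and not cds.startswith("ATG"):
        lesions.append(Lesion(kind="lost_start", cds_pos=0))
    return lesions


def classify_gene_status(
    completeness: float,
    aligned_fraction: float,
    lesions: Sequence[Lesion],
    transcript_support: str = "not_checked",
    config: PipelineConfig | None = None,
) -> GeneStatus:
    """Apply the four-way decision rule.

    1. completeness < ``min_exon_fraction``  -> absent
    2. lesion-free, aligned over the (near-)full reference -> present
    3. lesion-free but a shorter in-frame span, or partial transcript -> partial
    4. otherwise -> pseudogene
    """
    config = config or PipelineConfig()
    lesions = list(lesions)
    if completeness < config.min_exon_fraction:
        return GeneStatus("absent", completeness, lesions, transcript_support, aligned_fraction)
    if not lesions:
        if aligned_fraction >= config.full_length_fraction and transcript_support in (
            "full",
            "none",
            "not_checked",
        ):
            return GeneStatus("present", completeness, lesions, transcript_support, aligned_fraction)
        return GeneStatus(
            "partial_in_frame", completeness, lesions, transcript_support, aligned_fraction
        )
    return GeneStatus("pseudogene", completeness, lesions, transcript_support, aligned_fraction)


def corroborate_lesions(
    lesions_by_species: Mapping[str, Sequence[Lesion]],
    species_tree: SpeciesTree | None = None,
    position_tolerance: int = 3,
    frame_restored_in_all_strains: Mapping[str, bool] | None = None,
) -> dict[str, list[Lesion]]:
    """Fill ``shared_with`` and flag singleton lesions as low-confidence.

    A lesion found at the homologous CDS position (same kind, position within
    ``position_tolerance`` bp) in at least one other species supports a real
    event; a lesion unique to one assembly is flagged. When resequenced-strain
    evidence says every strain of a species restores the reading frame
    (``frame_restored_in_all_strains``), the reference lesion is additionally
    marked as a probable assembly error.
    """
    out: dict[str, list[Lesion]] = {}
    species = list(lesions_by_species)
    for sp in species:
        out[sp] = []
        for lesion in lesions_by_species[sp]:
            shared = []
            for other in species:
                if other == sp:
                    continue
                for cand in lesions_by_species[other]:
                    if cand.kind == lesion.kind and abs(cand.cds_pos - lesion.cds_pos) <= position_tolerance:
                        shared.append(other)
                        break
            new = Lesion(
                kind=lesion.kind,
                cds_pos=lesion.cds_pos,
                genomic_pos=lesion.genomic_pos,
                length=lesion.length,
                shared_with=shared,
                low_confidence=not shared,
                note=lesion.note,
            )
            if frame_restored_in_all_strains and frame_restored_in_all_strains.get(sp):
                new.assembly_error = True
                new.low_confidence = True
                new.note = (new.note + "; " if new.note else "") + (
                    "all resequenced strains restore the reading frame: "
                    "probable reference assembly error"
                )
            out[sp].append(new)
    return out


def check_transcript_support(
    cds: str,
    transcripts: Sequence[str] | None,
    config: PipelineConfig | None = None,
) -> str:
    """Transcript evidence level: full / partial / none / not_checked.

    ``full`` if some transcript contains the complete CDS; ``partial`` if an
    in-frame (codon-boundary) sub-span of at least half the CDS is found.
    """
    config = config or PipelineConfig()
    if transcripts is None:
        return "not_checked"
    best = 0
    for tx in transcripts:
        if cds in tx:
            return "full"
        match = SequenceMatcher(None, cds, tx, autojunk=False).find_longest_match(
            0, len(cds), 0, len(tx)
        )
        if match.size > best and match.a % 3 == 0:
            best = match.size
    if best >= config.transcript_partial_fraction * len(cds):
        return "partial"
    return "none"


def write_status_table(
    statuses: Mapping[str, Mapping[str, GeneStatus | str]], path
) -> None:
    """Write the species x gene status matrix (1/0/-1/* encoding)."""
    genes: list[str] = sorted({g for row in statuses.values() for g in row})
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(genes) + "\n")
        for sp in statuses:
            cells = []
            for g in genes:
                entry = statuses[sp].get(g)
                call = entry.call if isinstance(entry, GeneStatus) else entry
                cells.append(STATUS_CODES.get(call, "-1") if call else "-1")
            fh.write(sp + "\t" + "\t".join(cells) + "\n")


def read_status_table(path) -> dict[str, dict[str, str]]:
    lines = [ln for ln in open(path).read().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    out: dict[str, dict[str, str]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        out[parts[0]] = {g: CODES_STATUS[c] for g, c in zip(header, parts[1:])}
    return out
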