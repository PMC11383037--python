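"""Inbred-strain missense variants: conservation-based impact classes.

A missense variant in a laboratory strain is classified against an alignment
of close relatives by a three-way rule: a variant whose alternate residue is
already carried by another species is *unlikely* to disrupt function; a
variant altering a column that is invariant across the comparison panel has
a *potential* functional impact; anything else is *unknown*. Strains are
then summarized per gene set: a strain carrying any potential/unknown
variant in a gene of interest is recommended against (avoid); a strain whose
variants are all 'unlikely' warrants caution; a strain with no variants in
the listed genes is clean.

The module also detects frame-restoring indel "variants": an indel carried
by every resequenced strain that converts a frameshifted reference CDS into
a full-length in-frame homolog points at an error in the reference assembly
rather than a real polymorphism.

Bundled fixtures (``tables/table2_rat.tsv``, ``tables/table3_mouse.tsv``)
transcribe the published rat and mouse strain variant tables, including
their shading-derived classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core import PipelineConfig

_MISSENSE_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")
_INDEL_RE = re.compile(r"^(\d+)bp_(ins|del)$")


@dataclass
class VariantRecord:
    strain: str
    gene: str
    raw: str
    kind: str  # missense | indel
    ref_residue: str | None = None
    position: int | None = None  # 1-based protein position (missense)
    alt_residue: str | None = None
    indel_len: int | None = None
    indel_kind: str | None = None  # ins | del

    @classmethod
    def parse(cls, strain: str, gene: str, descriptor: str) -> "VariantRecord":
        m = _MISSENSE_RE.match(descriptor)
        if m:
            ref, pos, alt = m.groups()
            if ref == alt:
                raise ValueError(f"{descriptor}: ref and alt residues identical")
            return cls(
                strain=strain,
                gene=gene,
                raw=descriptor,
                kind="missense",
                ref_residue=ref,
                position=int(pos),
                alt_residue=alt,
            )
        m = _INDEL_RE.match(descriptor)
        if m:
            n, which = m.groups()
            return cls(
                strain=strain,
                gene=gene,
                raw=descriptor,
                kind="indel",
                indel_len=int(n),
                indel_kind=which,
            )
        raise ValueError(f"unparseable variant descriptor {descriptor!r}")


@dataclass
class VariantClassification:
    klass: str  # potential_impact | unlikely | unknown
    rationale: str


def classify_variant(
    variant: VariantRecord,
    column_residues: Mapping[str, str] | None,
    config: PipelineConfig | None = None,
    min_species: int = 10,
    near_invariant_fraction: float | None = None,
) -> VariantClassification:
    """Three-way conservation rule for one missense variant.

    ``column_residues`` maps comparison species to the residue at the
    homologous alignment column. Rule order: shared alternate residue ->
    unlikely; invariant column (across >= ``min_species``) -> potential
    impact; otherwise unknown. ``near_invariant_fraction`` (e.g. 0.9)
    optionally relaxes strict invariance; it is off by default.
    """
    del config  # thresholds for this rule are explicit arguments
    if variant.kind != "missense":
        return VariantClassification("unknown", "not a missense variant")
    if not column_residues:
        return VariantClassification("unknown", "alignment column unavailable")
    residues = [r for r in column_residues.values() if r not in ("-", "X", "")]
    if not residues:
        return VariantClassification("unknown", "alignment column all-gap")
    if variant.alt_residue in residues:
        carriers = sorted(
            sp for sp, r in column_residues.items() if r == variant.alt_residue
        )
        return VariantClassification(
            "unlikely", f"alternate residue carried by {', '.join(carriers)}"
        )
    distinct = set(residues)
    invariant = len(distinct) == 1
    if near_invariant_fraction is not None:
        top = max(residues.count(r) for r in distinct)
        invariant = top / len(residues) >= near_invariant_fraction
    if invariant and len(residues) >= min_species:
        return VariantClassification(
            "potential_impact",
            f"column invariant ({residues[0]}) across {len(residues)} species",
        )
    return VariantClassification("unknown", f"column variable ({''.join(sorted(distinct))})")


# ---------------------------------------------------------------------------
# strain recommendations


_SHADING_TO_CLASS = {
    "unlikely": "unlikely",
    "potential": "potential_impact",
    "unknown": "unknown",
}


def load_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a strain-variant TSV (strain, gene, variant, shading_class).

    Rows with gene == 'none' declare a strain with no variants.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"strain", "gene", "variant"}
    if not required <= set(df.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    return df


def bundled_table(name: str) -> pd.DataFrame:
    """Load a bundled fixture table ('table2_rat' or 'table3_mouse')."""
    ref = resources.files("caspevo.tables").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return load_variant_table(path)


def recommend_strains(
    table: pd.DataFrame,
    genes_of_interest: Iterable[str],
    classifications: Mapping[tuple[str, str, str], str] | None = None,
) -> dict[str, str]:
    """Per-strain flags {avoid, caution, clean} for a set of genes.

    Classes come from ``classifications`` (keyed by (strain, gene, variant))
    when given, else from the table's ``shading_class`` column. Unknown
    counts toward avoidance: an untested variant is not evidence of safety.
    """
    genes = set(genes_of_interest)
    flags: dict[str, str] = {}
    for strain, grp in table.groupby("strain", sort=False):
        classes = []
        for _, row in grp.iterrows():
            if row["gene"] == "none" or row["gene"] not in genes:
                continue
            if classifications is not None:
                klass = classifications.get((strain, row["gene"], row["variant"]), "unknown")
            else:
                klass = _SHADING_TO_CLASS.get(str(row.get("shading_class", "unknown")), "unknown")
            classes.append(klass)
        if not classes:
            flags[strain] = "clean"
        elif any(c in ("potential_impact", "unknown") for c in classes):
            flags[strain] = "avoid"
        else:
            flags[strain] = "caution"
    return flags


# ---------------------------------------------------------------------------
# frame restoration


def detect_frame_restoration(
    variant: VariantRecord,
    reference_cds: str,
    homolog_cds_set: Sequence[str],
    cds_position: int,
    carried_by_all_strains: bool = False,
    length_tolerance: float = 0.05,
) -> tuple[bool, str]:
    """Does applying an indel variant restore a frameshifted reference CDS?

    The indel is applied at ``cds_position`` (0-based bp); the result
    restores the frame iff its length is a codon multiple and it translates
    full-length (within ``length_tolerance`` of the homolog median) with no
    internal stop. When the variant is carried by every resequenced strain,
    the returned note flags a probable reference assembly error.
    """
    if variant.kind != "indel":
        return False, "not an indel variant"
    homolog_lengths_ref = sorted(len(h) // 3 for h in homolog_cds_set)
    median_ref = homolog_lengths_ref[len(homolog_lengths_ref) // 2]
    if len(reference_cds) % 3 == 0:
        ref_protein = str(Seq(reference_cds).translate())
        if "*" not in ref_protein[:-1] and abs(len(ref_protein) - median_ref) <= length_tolerance * median_ref:
            return False, "reference CDS already full-length and in frame: nothing to restore"
    if variant.indel_kind == "ins":
        filler = "A" * variant.indel_len
        edited = reference_cds[:cds_position] + filler + reference_cds[cds_position:]
    else:
        edited = reference_cds[:cds_position] + reference_cds[cds_position + variant.indel_len :]
    if len(edited) % 3 != 0:
        return False, "edited CDS not a codon multiple: frame not restored"
    protein = str(Seq(edited).translate())
    internal_stop = "*" in protein[:-1]
    if internal_stop:
        return False, "edited CDS still carries an internal stop"
    homolog_lengths = sorted(len(h) // 3 for h in homolog_cds_set)
    median = homolog_lengths[len(homolog_lengths) // 2]
    if abs(len(protein) - median) > length_tolerance * median:
        return False, "edited CDS does not reach full homolog length"
    note = "variant restores a full-length in-frame CDS"
    if carried_by_all_strains:
        note += (
            "; carried by all resequenced strains: probable error in the "
            "reference genome assembly"
        )
    return True, note
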