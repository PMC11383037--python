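"""Conservation scan of the aspartate self-cleavage sites.

Inflammatory caspases are activated by self-cleavage at aspartate residues:
one at the CARD-p20 boundary and two flanking the p20-p10 linker. Given a
protein alignment and the three site positions in reference coordinates,
this reports, for every species, the residue observed at each site and
whether an aspartate exists within a small window of alignment columns that
could serve as an alternate cleavage site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import PipelineConfig

SITE_NAMES = ("CARD-p20", "p20-linker", "linker-p10")


@dataclass
class CleavageSiteRow:
    species: str
    site_name: str
    residue: str  # aligned residue observed ('-' if gapped)
    aspartate_at_site: bool
    alternate_d_within_window: bool
    alternate_offset: int | None  # alignment-column offset (gaps skipped)


def _ref_position_to_column(ref_aligned: str, position: int) -> int:
    """Alignment column of the 0-based ungapped reference ``position``."""
    count = -1
    for col, ch in enumerate(ref_aligned):
        if ch != "-":
            count += 1
            if count == position:
                return col
    raise ValueError(f"reference position {position} beyond sequence")


def scan_cleavage_sites(
    alignment: Mapping[str, str],
    reference_species: str,
    site_positions: Sequence[int],
    config: PipelineConfig | None = None,
    site_names: Sequence[str] | None = None,
) -> list[CleavageSiteRow]:
    """Report cleavage-site conservation for every species and site.

    ``site_positions`` are 0-based residue indices in the ungapped reference
    sequence. The alternate-aspartate search walks up to
    ``alt_cleavage_window`` *residues* (gap columns skipped) either side of
    the site column.
    """
    config = config or PipelineConfig()
    if reference_species not in alignment:
        raise KeyError(reference_species)
    ref = alignment[reference_species]
    names = list(site_names) if site_names else list(SITE_NAMES[: len(site_positions)])
    while len(names) < len(site_positions):
        names.append(f"site{len(names) + 1}")

    columns = []
    for pos in site_positions:
        col = _ref_position_to_column(ref, pos)
        if all(alignment[sp][col] == "-" for sp in alignment):
            raise ValueError(f"site column {col} is all-gap")
        if ref[col] == "-":
            raise ValueError(f"reference gapped at its own site {pos}")
        columns.append(col)

    rows: list[CleavageSiteRow] = []
    for sp in sorted(alignment):
        seq = alignment[sp]
        for name, col in zip(names, columns):
            residue = seq[col]
            has_d = residue == "D"
            alt, offset = False, None
            if not has_d:
                alt, offset = _find_alternate_d(seq, col, config.alt_cleavage_window)
            rows.append(
                CleavageSiteRow(
                    species=sp,
                    site_name=name,
                    residue=residue,
                    aspartate_at_site=has_d,
                    alternate_d_within_window=alt,
                    alternate_offset=offset,
                )
            )
    return rows


def _find_alternate_d(seq: str, col: int, window: int) -> tuple[bool, int | None]:
    """Nearest D within +/-window residues (gaps skipped); smaller |offset|
    wins, downstream direction breaks ties."""
    candidates: list[tuple[int, int]] = []  # (|offset|, signed offset)
    for direction in (+1, -1):
        steps = 0
        pos = col
        while steps < window:
            pos += direction
            if pos < 0 or pos >= len(seq):
                break
            if seq[pos] == "-":
                continue
            steps += 1
            if seq[pos] == "D":
                candidates.append((steps, direction * steps))
                break
    if not candidates:
        return False, None
    candidates.sort(key=lambda t: (t[0], -t[1]))
    return True, candidates[0][1]


def cleavage_report_rows(rows: Sequence[CleavageSiteRow]) -> list[dict]:
    return [
        {
            "species": r.species,
            "site": r.site_name,
            "residue": r.residue,
            "aspartate": int(r.aspartate_at_site),
            "alternate_D": int(r.alternate_d_within_window),
            "alt_offset": "" if r.alternate_offset is None else r.alternate_offset,
        }
        for r in rows
    ]
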