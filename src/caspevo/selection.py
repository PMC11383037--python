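"""Recombination-aware, counting-based selection analysis.

The module estimates dN/dS two ways:

* pairwise, by Nei-Gojobori (1986) counting with Jukes-Cantor correction —
  used to measure divergence from the reference species and apply the
  dS <= 0.3 outgroup filter;
* site-wise across a fixed species tree, SLAC-style: ancestral codons are
  reconstructed by Fitch parsimony (ties averaged uniformly over optimal
  states), each inferred substitution is classified synonymous or
  nonsynonymous by minimal-pathway averaging, and every site gets a
  one-sided binomial test for an excess of nonsynonymous change over the
  neutral expectation implied by its codon composition.

Because gene conversion gives different parts of a gene different
histories, alignments are split at supplied recombination breakpoints
(codon-snapped) and each segment is analyzed independently. A segment-level
Monte-Carlo test aggregates the per-site counts, compared against a
Bonferroni-corrected threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betainc

from .codons import (
    SENSE_CODONS,
    STOP_CODONS,
    codon_pair_differences,
    codon_site_counts,
    split_codons,
)
from .core import PipelineConfig, SpeciesTree

log = logging.getLogger(__name__)

_GAPLIKE = ("---", "NNN")


@dataclass
class NGResult:
    dn: float | None
    ds: float | None
    omega: float | None
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    saturated: bool = False


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds_ng86(cds_a: str, cds_b: str) -> NGResult:
    """Nei-Gojobori counting dN/dS for one pair of in-frame CDSs.

    Codon pairs containing gaps, Ns, or stop codons are skipped. Synonymous
    and nonsynonymous site counts are averaged over the two sequences;
    multi-step codon differences are averaged over all minimal mutational
    pathways. Proportions are Jukes-Cantor corrected; a proportion >= 3/4 is
    reported as saturated (distance undefined).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    sa = na = sb = nb = sd = nd = 0.0
    for ca, cb in zip(split_codons(cds_a), split_codons(cds_b)):
        if (
            ca in _GAPLIKE
            or cb in _GAPLIKE
            or "-" in ca
            or "-" in cb
            or "N" in ca
            or "N" in cb
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        ):
            continue
        s1, n1 = codon_site_counts(ca)
        s2, n2 = codon_site_counts(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        d_n, d_s = codon_pair_differences(ca, cb)
        nd += d_n
        sd += d_s
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    saturated = ds is None or dn is None
    if ds is None or dn is None or ds == 0.0:
        omega = None
    else:
        omega = dn / ds
    return NGResult(
        dn=dn, ds=ds, omega=omega, pn=pn, ps=ps, n_sites=n_sites, s_sites=s_sites, saturated=saturated
    )


def filter_species_by_ds(
    alignment: Mapping[str, str],
    reference_species: str,
    config: PipelineConfig | None = None,
) -> tuple[list[str], dict[str, float | None]]:
    """Drop species beyond pairwise dS ``max_pairwise_ds`` from the reference.

    Returns the retained species (reference included) and the full dS table
    (None where the correction is saturated; saturated species are dropped).
    """
    config = config or PipelineConfig()
    if reference_species not in alignment:
        raise KeyError(reference_species)
    retained = []
    table: dict[str, float | None] = {}
    for sp, seq in alignment.items():
        res = pairwise_dnds_ng86(alignment[reference_species], seq)
        table[sp] = res.ds
        if res.ds is not None and res.ds <= config.max_pairwise_ds:
            retained.append(sp)
    return retained, table


@dataclass
class RecombinationSegment:
    start: int  # codon coordinates, half-open
    end: int
    breakpoint_ids: list[str] = field(default_factory=list)

    def slice(self, alignment: Mapping[str, str]) -> dict[str, str]:
        return {sp: seq[self.start * 3 : self.end * 3] for sp, seq in alignment.items()}


def split_at_breakpoints(
    alignment_length_nt: int,
    breakpoints_nt: Sequence[int],
    breakpoint_ids: Sequence[str] | None = None,
) -> list[RecombinationSegment]:
    """Partition an alignment into n+1 codon segments at n nt breakpoints.

    Breakpoints are snapped to the nearest codon boundary (the snap is
    logged). They must be strictly increasing and strictly inside the
    alignment.
    """
    if alignment_length_nt % 3:
        raise ValueError("alignment length must be a codon multiple")
    n_codons = alignment_length_nt // 3
    ids = list(breakpoint_ids) if breakpoint_ids else [f"bp{i + 1}" for i in range(len(breakpoints_nt))]
    codon_bounds = []
    for bp, bid in zip(breakpoints_nt, ids):
        if not 0 < bp < alignment_length_nt:
            raise ValueError(f"breakpoint {bp} outside alignment")
        snapped = int(round(bp / 3.0))
        if snapped * 3 != bp:
            log.info("breakpoint %d nt snapped to codon boundary %d", bp, snapped * 3)
        codon_bounds.append((max(1, min(n_codons - 1, snapped)), bid))
    starts = [0] + [c for c, _ in codon_bounds]
    ends = [c for c, _ in codon_bounds] + [n_codons]
    if any(a >= b for a, b in zip(starts, ends)):
        raise ValueError("breakpoints must be strictly increasing")
    segments = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        seg_ids = [bid for (c, bid) in codon_bounds if c in (a, b)]
        segments.append(RecombinationSegment(start=a, end=b, breakpoint_ids=seg_ids))
    return segments


# ---------------------------------------------------------------------------
# site-wise scan


@dataclass
class SiteResult:
    site: int  # codon index within the segment
    n_obs: float
    s_obs: float
    expected_n_fraction: float  # neutral-opportunity N fraction (composition)
    null_n_fraction: float  # background-modulated null used for the site test
    p_value: float
    flagged: bool
    skipped: bool = False


@dataclass
class SelectionResult:
    sites: list[SiteResult]
    dn: float
    ds: float
    omega: float | None
    segment: RecombinationSegment | None = None
    gene_p_value: float | None = None
    significant: bool | None = None

    @property
    def flagged_sites(self) -> list[int]:
        return [s.site for s in self.sites if s.flagged]


_UNIFORM_N_FRACTION = None


def _uniform_n_fraction() -> float:
    global _UNIFORM_N_FRACTION
    if _UNIFORM_N_FRACTION is None:
        s = n = 0.0
        for c in SENSE_CODONS:
            cs, cn = codon_site_counts(c)
            s += cs
            n += cn
        _UNIFORM_N_FRACTION = n / (n + s)
    return _UNIFORM_N_FRACTION


def _binom_sf_fractional(k: float, n: float, p: float) -> float:
    """P(X >= k) for Binomial(n, p), extended to fractional counts via the
    regularized incomplete beta function."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(betainc(k, n - k + 1.0, p))


class _FitchSite:
    """Parsimony state sets and tie-averaged substitution counts, one site."""

    def __init__(self, tree: SpeciesTree, leaf_codons: Mapping[str, str | None]):
        self.tree = tree
        self.leaf_codons = leaf_codons
        self.down: dict[int, frozenset] = {}
        self._downpass()

    def _downpass(self) -> None:
        all_states = frozenset(SENSE_CODONS)
        for node in self.tree.tree.postorder_node_iter():
            if node.is_leaf():
                codon = self.leaf_codons.get(node.taxon.label)
                self.down[id(node)] = (
                    frozenset([codon]) if codon is not None else all_states
                )
            else:
                sets = [self.down[id(c)] for c in node.child_nodes()]
                inter = frozenset.intersection(*sets)
                self.down[id(node)] = inter if inter else frozenset.union(*sets)

    def expected_counts(self) -> tuple[float, float]:
        """Expected (nonsynonymous, synonymous) substitution counts over the
        tree, averaging uniformly over optimal assignments."""
        n_total = s_total = 0.0
        root = self.tree.tree.seed_node
        root_set = sorted(self.down[id(root)])
        dist: dict[int, dict[str, float]] = {
            id(root): {c: 1.0 / len(root_set) for c in root_set}
        }
        for node in self.tree.tree.preorder_node_iter():
            if node is root:
                continue
            parent_dist = dist[id(node.parent_node)]
            child_set = sorted(self.down[id(node)])
            child_dist: dict[str, float] = {}
            for p_state, w in parent_dist.items():
                if p_state in child_set:
                    child_dist[p_state] = child_dist.get(p_state, 0.0) + w
                else:
                    share = w / len(child_set)
                    for c_state in child_set:
                        child_dist[c_state] = child_dist.get(c_state, 0.0) + share
                        nd, sd = codon_pair_differences(p_state, c_state)
                        n_total += w / len(child_set) * nd
                        s_total += w / len(child_set) * sd
            dist[id(node)] = child_dist
        return n_total, s_total


def sitewise_selection_scan(
    alignment: Mapping[str, str],
    tree: SpeciesTree,
    config: PipelineConfig | None = None,
    *,
    expected_model: str = "composition",
    segment: RecombinationSegment | None = None,
) -> SelectionResult:
    """SLAC-style positive-selection scan of one (segment) codon alignment.

    Each site's substitutions are tested one-sided against a *background-
    modulated* null: the segment-wide rate ratio (estimated from the total
    inferred N and S counts relative to the segment's mutational
    opportunity) applied to the site's own neutral N fraction. This makes
    the site test a relative-rate test — "does this site exceed the gene's
    background omega" — which is the question a pervasively purifying gene
    poses; a flat neutral-opportunity null has essentially no power against
    single sites at these tree depths. A site is flagged when its p-value is
    <= ``site_alpha`` *and* its N/S ratio exceeds the segment-wide ratio.
    All-gap sites are skipped and reported as such.
    """
    config = config or PipelineConfig()
    if len(alignment) < 6:
        raise ValueError("need at least 6 sequences for a site-wise scan")
    species = sorted(alignment)
    tree_species = set(tree.leaf_labels)
    if not set(species) <= tree_species:
        raise ValueError("alignment species missing from the tree")
    if len(tree_species - set(species)):
        tree = SpeciesTree.from_newick(tree.to_newick())
        tree.tree.retain_taxa_with_labels(species)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3:
        raise ValueError("alignment must be rectangular with codon length")
    n_codons = next(iter(lengths)) // 3

    sites: list[SiteResult] = []
    for ci in range(n_codons):
        leaf_codons: dict[str, str | None] = {}
        observed = []
        for sp in species:
            codon = alignment[sp][ci * 3 : ci * 3 + 3]
            if "-" in codon or "N" in codon or codon in STOP_CODONS:
                leaf_codons[sp] = None
            else:
                leaf_codons[sp] = codon
                observed.append(codon)
        if not observed:
            sites.append(
                SiteResult(ci, 0.0, 0.0, 0.0, 0.0, 1.0, flagged=False, skipped=True)
            )
            continue
        n_obs, s_obs = _FitchSite(tree, leaf_codons).expected_counts()
        if expected_model == "uniform":
            p0 = _uniform_n_fraction()
        else:
            s_sites = n_sites = 0.0
            for codon in observed:
                cs, cn = codon_site_counts(codon)
                s_sites += cs
                n_sites += cn
            p0 = n_sites / (n_sites + s_sites)
        sites.append(SiteResult(ci, n_obs, s_obs, p0, 0.0, 1.0, flagged=False))

    total_n = sum(s.n_obs for s in sites)
    total_s = sum(s.s_obs for s in sites)
    seg_ratio = total_n / total_s if total_s > 0 else math.inf
    for s in sites:
        if s.skipped:
            continue
        # leave-one-out background rate ratio: omega_hat such that the
        # segment's N/S totals match opportunity * omega_hat
        rest_n = total_n - s.n_obs
        rest_s = total_s - s.s_obs
        p0 = s.expected_n_fraction
        others = [x.expected_n_fraction for x in sites if not x.skipped and x is not s]
        p0_seg = sum(others) / len(others) if others else p0
        if rest_s > 0 and 0.0 < p0_seg < 1.0:
            omega_hat = (rest_n / rest_s) / (p0_seg / (1.0 - p0_seg))
        else:
            omega_hat = 1.0
        null_p = omega_hat * p0 / (omega_hat * p0 + (1.0 - p0))
        s.null_n_fraction = null_p
        s.p_value = _binom_sf_fractional(s.n_obs, s.n_obs + s.s_obs, null_p)
        ratio = s.n_obs / s.s_obs if s.s_obs > 0 else (math.inf if s.n_obs > 0 else 0.0)
        excess = ratio > seg_ratio or (math.isinf(ratio) and math.isinf(seg_ratio) and s.n_obs > 0)
        s.flagged = s.p_value <= config.site_alpha and excess

    # descriptive tree-wide dN, dS over the segment
    n_opp = s_opp = 0.0
    for ci in range(n_codons):
        counts = [
            codon_site_counts(alignment[sp][ci * 3 : ci * 3 + 3])
            for sp in species
            if alignment[sp][ci * 3 : ci * 3 + 3] not in _GAPLIKE
            and "-" not in alignment[sp][ci * 3 : ci * 3 + 3]
            and "N" not in alignment[sp][ci * 3 : ci * 3 + 3]
            and alignment[sp][ci * 3 : ci * 3 + 3] not in STOP_CODONS
        ]
        if counts:
            s_opp += sum(c[0] for c in counts) / len(counts)
            n_opp += sum(c[1] for c in counts) / len(counts)
    dn = total_n / n_opp if n_opp else 0.0
    ds = total_s / s_opp if s_opp else 0.0
    omega = dn / ds if ds > 0 else None
    return SelectionResult(sites=sites, dn=dn, ds=ds, omega=omega, segment=segment)


def gene_level_test(
    result: SelectionResult,
    config: PipelineConfig | None = None,
    seed: int = 0,
    n_permutations: int = 2000,
) -> SelectionResult:
    """Segment-level one-sided test of aggregate nonsynonymous excess.

    Under the null, each site's substitutions fall nonsynonymous with its
    own expected fraction; the null distribution of the total nonsynonymous
    count is sampled by seeded Monte Carlo (>= 2000 draws). Significance is
    judged against the Bonferroni-corrected gene-level threshold.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    active = [s for s in result.sites if not s.skipped and (s.n_obs + s.s_obs) > 0]
    t_obs = sum(s.n_obs for s in active)
    if not active or t_obs == 0:
        result.gene_p_value = 1.0
        result.significant = False
        return result
    ns = np.array([int(round(s.n_obs + s.s_obs)) for s in active])
    ps = np.array([s.expected_n_fraction for s in active])
    draws = rng.binomial(ns[None, :].repeat(n_permutations, axis=0), ps[None, :])
    totals = draws.sum(axis=1)
    p = (1.0 + float((totals >= t_obs - 1e-9).sum())) / (n_permutations + 1.0)
    result.gene_p_value = p
    result.significant = p <= config.gene_alpha_bonferroni
    return result


def robustness_rerun(
    alignment: Mapping[str, str],
    tree: SpeciesTree,
    config: PipelineConfig | None = None,
    *,
    expected_models: Sequence[str] = ("composition", "uniform"),
    seeds: Sequence[int] = (0, 1, 2),
) -> dict[int, bool]:
    """Repeat the scan over a settings grid; a site is robust iff flagged
    under every setting."""
    config = config or PipelineConfig()
    flags_per_setting: list[set[int]] = []
    for model in expected_models:
        res = sitewise_selection_scan(alignment, tree, config, expected_model=model)
        for seed in seeds:
            gene_level_test(res, config, seed=seed)
            flags_per_setting.append(set(res.flagged_sites))
    all_sites = set().union(*flags_per_setting) if flags_per_setting else set()
    return {site: all(site in f for f in flags_per_setting) for site in sorted(all_sites)}


def mask_columns(alignment: Mapping[str, str], codon_intervals: Sequence[tuple[int, int]]) -> dict[str, str]:
    """Remove codon-column intervals (half-open) from every sequence — the
    alignment-trim used to test sensitivity to clade-specific insertions."""
    drop = set()
    for a, b in codon_intervals:
        drop.update(range(a, b))
    out = {}
    for sp, seq in alignment.items():
        codons = split_codons(seq)
        out[sp] = "".join(c for i, c in enumerate(codons) if i not in drop)
    return out
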