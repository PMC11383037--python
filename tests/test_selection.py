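import itertools

import numpy as np
import pytest

from caspevo.codons import SENSE_CODONS, codon_pair_differences, codon_site_counts
from caspevo.core import PipelineConfig, SpeciesTree
from caspevo.selection import (
    filter_species_by_ds,
    gene_level_test,
    mask_columns,
    pairwise_dnds_ng86,
    robustness_rerun,
    sitewise_selection_scan,
    split_at_breakpoints,
)
from caspevo.sim import simulate_codon_alignment
from oracles import ng86_pair_differences_oracle, ng86_site_counts_oracle


class TestNG86:
    def test_identical_sequences(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        res = pairwise_dnds_ng86(cds, cds)
        assert res.dn == 0.0 and res.ds == 0.0
        assert res.omega is None

    def test_single_synonymous_difference(self):
        a = "ATG" + "GAA" * 99 + "TAA"
        b = "ATG" + "GAG" + "GAA" * 98 + "TAA"
        res = pairwise_dnds_ng86(a, b)
        assert res.dn == 0.0
        assert res.ds > 0.0

    def test_site_counts_match_enumeration_for_all_codons(self):
        for codon in SENSE_CODONS:
            assert codon_site_counts(codon) == pytest.approx(
                ng86_site_counts_oracle(codon)
            )

    def test_pair_differences_match_pathway_oracle_exhaustively(self):
        for a, b in itertools.product(SENSE_CODONS, repeat=2):
            got = codon_pair_differences(a, b)
            want = ng86_pair_differences_oracle(a, b)
            assert got == pytest.approx(want), (a, b)

    def test_symmetry(self, rng):
        sense = list(SENSE_CODONS)
        for _ in range(20):
            a = "".join(rng.choice(sense, size=30))
            b = "".join(rng.choice(sense, size=30))
            r1 = pairwise_dnds_ng86(a, b)
            r2 = pairwise_dnds_ng86(b, a)
            assert r1.pn == pytest.approx(r2.pn)
            assert r1.ps == pytest.approx(r2.ps)

    def test_random_pair_matches_oracle_end_to_end(self, rng):
        sense = list(SENSE_CODONS)
        a = "".join(rng.choice(sense, size=30))
        b = "".join(rng.choice(sense, size=30))
        nd = sd = 0.0
        for ca, cb in zip(
            [a[i : i + 3] for i in range(0, 90, 3)],
            [b[i : i + 3] for i in range(0, 90, 3)],
        ):
            d_n, d_s = ng86_pair_differences_oracle(ca, cb)
            nd += d_n
            sd += d_s
        res = pairwise_dnds_ng86(a, b)
        s_sites = sum(ng86_site_counts_oracle(c)[0] for s in (a, b) for c in [s[i:i+3] for i in range(0, 90, 3)]) / 2
        assert res.ps == pytest.approx(sd / s_sites)


class TestDsFilter:
    @staticmethod
    def _pair_at_ds(target: float, seed: int = 0):
        """Mutate synonymous third positions until pairwise dS reaches the
        target; returns (ref, diverged, achieved_ds)."""
        rng = np.random.default_rng(seed)
        ref = "ATG" + "GAA CTT GGA CCT AGA".replace(" ", "") * 60 + "TAA"
        div = list(ref)
        positions = list(range(3, len(ref) - 3))
        rng.shuffle(positions)
        achieved = 0.0
        for pos in positions:
            codon_start = pos - pos % 3
            codon = "".join(div[codon_start : codon_start + 3])
            for alt in "ACGT":
                if alt == div[pos]:
                    continue
                cand = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
                from caspevo.codons import STOP_CODONS, translate_codon

                if cand not in STOP_CODONS and translate_codon(cand) == translate_codon(codon):
                    div[pos] = alt
                    break
            res = pairwise_dnds_ng86(ref, "".join(div))
            achieved = res.ds or 0.0
            if achieved >= target:
                break
        return ref, "".join(div), achieved

    def test_species_at_ds_029_retained(self):
        ref, div, ds = self._pair_at_ds(0.29)
        assert 0.28 <= ds <= 0.30
        retained, table = filter_species_by_ds({"ref": ref, "spiny": div}, "ref")
        assert "spiny" in retained

    def test_species_at_ds_031_excluded(self):
        ref, div, ds = self._pair_at_ds(0.31)
        assert ds > 0.30
        retained, _ = filter_species_by_ds({"ref": ref, "far": div}, "ref")
        assert "far" not in retained

    def test_reference_vs_itself_retained(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        retained, table = filter_species_by_ds({"ref": cds}, "ref")
        assert retained == ["ref"]
        assert table["ref"] == 0.0


class TestSplit:
    def test_zero_breakpoints_one_segment(self):
        segs = split_at_breakpoints(900, [])
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 300)

    def test_segment_arithmetic(self):
        segs = split_at_breakpoints(900, [300, 612])
        assert [(s.start, s.end) for s in segs] == [(0, 100), (100, 204), (204, 300)]

    def test_snapping_logged(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="caspevo.selection"):
            segs = split_at_breakpoints(900, [301])
        assert [(s.start, s.end) for s in segs] == [(0, 100), (100, 300)]
        assert "snapped" in caplog.text

    def test_breakpoint_outside_alignment_is_error(self):
        with pytest.raises(ValueError):
            split_at_breakpoints(900, [900])


class TestSiteScan:
    def test_invariant_alignment_no_substitutions_no_flags(self, calibration_tree):
        cds = "ATG" + "GCT" * 48 + "TAA"
        aln = {sp: cds for sp in calibration_tree.leaf_labels}
        res = sitewise_selection_scan(aln, calibration_tree)
        assert sum(s.n_obs + s.s_obs for s in res.sites) == 0
        assert res.flagged_sites == []

    def test_fewer_than_six_sequences_rejected(self, calibration_tree):
        aln = {sp: "ATGTAA" for sp in calibration_tree.leaf_labels[:4]}
        with pytest.raises(ValueError):
            sitewise_selection_scan(aln, calibration_tree)

    def test_all_gap_site_skipped(self, calibration_tree):
        cds = "ATG" + "---" + "GCT" * 20 + "TAA"
        aln = {sp: cds for sp in calibration_tree.leaf_labels}
        res = sitewise_selection_scan(aln, calibration_tree)
        assert res.sites[1].skipped

    def test_segment_additivity_of_counts(self, calibration_tree):
        aln, _ = simulate_codon_alignment(calibration_tree, 90, omega=0.5, seed=4)
        whole = sitewise_selection_scan(aln, calibration_tree)
        segs = split_at_breakpoints(270, [135])
        parts = [
            sitewise_selection_scan(seg.slice(aln), calibration_tree, segment=seg)
            for seg in segs
        ]
        total_whole = sum(s.n_obs for s in whole.sites)
        total_parts = sum(s.n_obs for p in parts for s in p.sites)
        assert total_parts == pytest.approx(total_whole, rel=1e-9)

    def test_zero_substitution_segment_gene_p_is_one(self, calibration_tree):
        cds = "ATG" + "GCT" * 48 + "TAA"
        aln = {sp: cds for sp in calibration_tree.leaf_labels}
        res = gene_level_test(sitewise_selection_scan(aln, calibration_tree))
        assert res.gene_p_value == 1.0
        assert res.significant is False

    def test_whole_segment_positive_selection_significant(self, calibration_tree):
        aln, _ = simulate_codon_alignment(calibration_tree, 150, omega=3.0, seed=9)
        res = gene_level_test(sitewise_selection_scan(aln, calibration_tree), seed=0)
        assert res.significant is True

    def test_mask_columns_removes_codons(self):
        aln = {"a": "ATGGCTGAA", "b": "ATGGCTGAA"}
        out = mask_columns(aln, [(1, 2)])
        assert out == {"a": "ATGGAA", "b": "ATGGAA"}


class TestRobustness:
    def test_definitions(self, calibration_tree):
        om = np.full(120, 0.2)
        om[30] = 4.0
        aln, _ = simulate_codon_alignment(calibration_tree, 120, omega=om, seed=12)
        rob = robustness_rerun(aln, calibration_tree)
        res = sitewise_selection_scan(aln, calibration_tree)
        uni = sitewise_selection_scan(aln, calibration_tree, expected_model="uniform")
        both = set(res.flagged_sites) & set(uni.flagged_sites)
        for site, is_robust in rob.items():
            assert is_robust == (site in both)
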