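import numpy as np
import pytest

from caspevo.annotate import (
    assemble_cds,
    assign_hits_to_genes,
    bitscore,
    find_exon_hits,
    rescue_missing_exons,
)
from caspevo.core import GenomicLocus, PipelineConfig, ReferenceGene, ReferenceGeneSet, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def planted(rng):
    """A 6 kb random locus with one exact 300 bp exon copy planted at 3000."""
    exon = _random_seq(rng, 300)
    locus = _random_seq(rng, 3000) + exon + _random_seq(rng, 2700)
    ref = ReferenceGeneSet([ReferenceGene("G", [exon], slot=0)])
    return GenomicLocus("sp", locus), ref, exon


class TestFindExonHits:
    def test_exact_planted_copy(self, planted):
        locus, ref, _ = planted
        hits = find_exon_hits(locus, ref)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (3000, 3300)
        assert hits[0].identity == pytest.approx(1.0)
        assert hits[0].strand == "+"

    def test_reverse_complement_copy(self, planted, rng):
        _, ref, exon = planted
        locus = GenomicLocus("sp", _random_seq(rng, 2000) + revcomp(exon) + _random_seq(rng, 2000))
        hits = find_exon_hits(locus, ref)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (2000, 2300)

    def test_identity_threshold_behavior(self, rng):
        """A planted copy whose full-exon identity is ~0.57 (an intact 170 bp
        core, the remaining 130 bp of the exon missing) carries a >100-bit
        local hit but fails the default 0.60 identity threshold; lowering the
        threshold to 0.50 recovers it."""
        exon = _random_seq(rng, 300)
        # intact 170 bp core, remaining 130 bp unreadable (assembly-gap Ns):
        # the N run contributes zero matches under any alignment, so the
        # full-exon identity is exactly 170/300 while the core scores 154 bits
        planted_copy = exon[:170] + "N" * 130
        locus = GenomicLocus("sp", _random_seq(rng, 2000) + planted_copy + _random_seq(rng, 2000))
        ref = ReferenceGeneSet([ReferenceGene("G", [exon], slot=0)])
        assert find_exon_hits(locus, ref, PipelineConfig()) == []
        lowered = PipelineConfig(min_exon_identity=0.50)
        hits = find_exon_hits(locus, ref, lowered)
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(170 / 300, abs=0.02)

    def test_locus_shorter_than_exon_yields_empty(self, planted):
        _, ref, _ = planted
        assert find_exon_hits(GenomicLocus("sp", "ACGT" * 10), ref) == []

    def test_planted_match_completeness_small_locus(self, rng):
        """Every planted copy above both thresholds is recovered (checked
        against direct column-wise identity of the plant)."""
        exon = _random_seq(rng, 240)
        copies = []
        locus_parts = []
        pos = 0
        for ident in (1.0, 0.92, 0.85):
            gap = _random_seq(rng, 800)
            copy = list(exon)
            n_mut = int(round((1 - ident) * len(exon)))
            for i in rng.choice(len(exon), size=n_mut, replace=False):
                copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
            locus_parts += [gap, "".join(copy)]
            pos += len(gap)
            copies.append((pos, pos + len(exon), ident))
            pos += len(exon)
        locus = GenomicLocus("sp", "".join(locus_parts) + _random_seq(rng, 800))
        ref = ReferenceGeneSet([ReferenceGene("G", [exon], slot=0)])
        hits = find_exon_hits(locus, ref)
        for start, end, ident in copies:
            covering = [h for h in hits if h.start < end and start < h.end]
            assert covering, f"planted copy at identity {ident} not recovered"

    def test_strand_symmetry(self, planted):
        locus, ref, _ = planted
        fwd = find_exon_hits(locus, ref)
        rc = GenomicLocus("sp", revcomp(locus.seq))
        rev = find_exon_hits(rc, ref)
        L = len(locus.seq)
        assert [(L - h.end, L - h.start) for h in rev] == [
            (h.start, h.end) for h in fwd
        ]
        assert {h.strand for h in rev} == {"-"}


class TestAssignment:
    def test_two_tandem_paralogs_no_cross_assignment(self, rng):
        e1, e2 = _random_seq(rng, 250), _random_seq(rng, 250)
        locus = GenomicLocus(
            "sp", _random_seq(rng, 1000) + e1 + _random_seq(rng, 2000) + e2 + _random_seq(rng, 1000)
        )
        ref = ReferenceGeneSet(
            [ReferenceGene("A", [e1], slot=0), ReferenceGene("B", [e2], slot=1)]
        )
        models = assign_hits_to_genes(find_exon_hits(locus, ref), ref)
        assert [m.gene_id for m in models] == ["A", "B"]
        assert all(len(m.exon_hits) == 1 for m in models)

    def test_exon_f1_against_simulator_truth(self, primate_calls, primate_dataset):
        from caspevo.evaluate import exon_assignment_f1

        _, _, truth = primate_dataset
        calls, _ = primate_calls
        models = {
            sp: [c.model for c in calls[sp].values() if c.model.exon_hits] for sp in calls
        }
        f1, *_ = exon_assignment_f1(truth, models)
        assert f1 >= 0.95

    def test_converted_gene_keeps_syntenic_identity(self, primate_calls):
        """Great-ape CARDA was overwritten by CASP1; synteny must still
        name the cluster CARDA."""
        calls, _ = primate_calls
        assert "CARDA" in calls["Human"]
        assert calls["Human"]["CARDA"].status.call != "absent"


class TestAssembleCds:
    def test_simulated_intact_gene_matches_truth(self, primate_calls, primate_dataset):
        _, _, truth = primate_dataset
        calls, _ = primate_calls
        cds = calls["Marmoset"]["CASP1"].cds
        assert cds.seq == truth.cds["Marmoset"]["CASP1"]

    def test_minus_strand_equals_revcomp_of_genomic_order(self, rng):
        # an in-frame CDS (no internal stops) so frame 0 is selected whole
        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
        cds = "ATG" + "".join(rng.choice(sense, size=118)) + "TAA"
        exons_tx = [cds[:120], cds[120:240], cds[240:]]
        genomic_exons = [revcomp(e) for e in exons_tx][::-1]
        locus_seq = _random_seq(rng, 500)
        intervals = []
        for e in genomic_exons:
            locus_seq += e
            intervals.append((len(locus_seq) - len(e), len(locus_seq)))
            locus_seq += _random_seq(rng, 300)
        locus = GenomicLocus("sp", locus_seq)
        ref = ReferenceGeneSet([ReferenceGene("G", exons_tx, strand="-", slot=0)])
        models = assign_hits_to_genes(find_exon_hits(locus, ref), ref)
        assert len(models) == 1
        out = assemble_cds(models[0], locus)
        assert out.seq == cds

    def test_frameshift_lesion_propagates(self, primate_calls, primate_dataset):
        from caspevo.status import detect_lesions

        _, _, truth = primate_dataset
        calls, reference = primate_calls
        # Human CASP12 carries a scripted 2 bp frameshift deletion
        cds = calls["Human"]["CASP12"].cds
        lesions = detect_lesions(cds.seq, reference["CASP12"].cds)
        assert any(l.kind == "frameshift_indel" for l in lesions)

    def test_rescue_fills_missing_exons_at_depth(self, rodent_calls):
        calls, _ = rodent_calls
        model = calls["Hamster"]["CASP1"].model
        assert model.completeness == pytest.approx(1.0)
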