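"""Transcript 5'-end classification, contribution, and LIT calling."""

import numpy as np
import pytest

from litmeth.core import (
    GenomicInterval,
    RepeatElement,
    Transcript,
    ValidationError,
    build_interval_index,
)
from litmeth import lit_caller as lc
from litmeth.meth_landscape import MethDomain
from litmeth.synthetic_cohort import CohortSpec, simulate_annotations, \
    simulate_transcriptome


def ltr(start, end, chrom="chr1", subfam="MTA", cls="LTR-MaLR"):
    return RepeatElement(GenomicInterval(chrom, start, end, "+"), cls, subfam)


def tx(tid, exons, strand="+", fpkm=5.0, gene_id=None, chrom="chr1"):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    genomic = sorted(ivs, key=lambda e: e.start)
    loc = GenomicInterval(chrom, genomic[0].start, genomic[-1].end, strand)
    ordered = tuple(reversed(genomic)) if strand == "-" else tuple(genomic)
    return Transcript(tid, loc, ordered, fpkm=fpkm, gene_id=gene_id)


def index(repeats):
    return build_interval_index(repeats, key=lambda r: r.location)


class TestStartClassification:
    def test_tss_inside_repeat_extending_past_is_up(self):
        rep = ltr(1000, 1600)
        t = tx("t", [(1300, 3600)])
        cat, r = lc.classify_transcript_start(t, index([rep]))
        assert cat == "Up" and r is rep

    def test_tss_just_upstream_of_repeat_is_upedge(self):
        rep = ltr(1000, 1600)
        t = tx("t", [(950, 3600)])
        cat, r = lc.classify_transcript_start(t, index([rep]))
        assert cat == "UpEdge" and r is rep

    def test_tss_beyond_edge_window_is_not_upedge(self):
        rep = ltr(1000, 1600)
        t = tx("t", [(800, 3600)])
        cat, _ = lc.classify_transcript_start(t, index([rep]),
                                              edge_window=100)
        # repeat inside exon 1 without containing the TSS -> EInside
        assert cat == "EInside"

    def test_repeat_inside_downstream_exon_is_einside(self):
        rep = ltr(5000, 5400)
        t = tx("t", [(1000, 1200), (3000, 3200), (4800, 5600)])
        cat, r = lc.classify_transcript_start(t, index([rep]))
        assert cat == "EInside" and r is rep

    def test_no_repeat_is_none(self):
        t = tx("t", [(1000, 2000)])
        cat, r = lc.classify_transcript_start(t, index([ltr(9000, 9500)]))
        assert cat == "none" and r is None

    def test_tss_inside_repeat_not_extending_is_einside(self):
        rep = ltr(1000, 3000)
        t = tx("t", [(1200, 2500)])
        cat, _ = lc.classify_transcript_start(t, index([rep]))
        assert cat == "EInside"

    def test_non_ltr_repeat_ignored(self):
        line = RepeatElement(GenomicInterval("chr1", 1000, 1600, "+"),
                             "other", "L1MC")
        t = tx("t", [(1300, 3600)])
        cat, r = lc.classify_transcript_start(t, index([line]))
        assert cat == "none"

    def test_strand_antisymmetry(self):
        """Mirroring coordinates and strand mirrors the category."""
        size = 100_000
        rep = ltr(1000, 1600)
        cases = [tx("a", [(1300, 3600)]), tx("b", [(950, 3600)]),
                 tx("c", [(800, 3600)])]
        mirror_rep = RepeatElement(
            GenomicInterval("chr1", size - 1600, size - 1000, "-"),
            rep.repeat_class, rep.subfamily)
        for t in cases:
            cat_fwd, _ = lc.classify_transcript_start(t, index([rep]))
            m_exons = [(size - e.end, size - e.start) for e in t.exons]
            mt = tx(t.id + "_m", m_exons, strand="-")
            cat_rev, _ = lc.classify_transcript_start(mt, index([mirror_rep]))
            assert cat_fwd == cat_rev

    def test_transcript_without_exons_rejected(self):
        with pytest.raises(ValidationError):
            Transcript("t", GenomicInterval("chr1", 0, 10, "+"), ())


class TestContribution:
    def test_raw_ratio_from_coverages(self):
        val, flagged = lc.ltr_contribution(10.0, 40.0)
        assert val == pytest.approx(0.25)
        assert not flagged

    def test_ratio_above_one_is_normalised_into_unit_interval(self):
        val, _ = lc.ltr_contribution(80.0, 20.0)
        assert val == pytest.approx(4 / 5)  # ratio 4 -> 4/(1+4)
        assert 0 <= val <= 1

    def test_zero_canonical_with_signal_is_one_flagged(self):
        val, flagged = lc.ltr_contribution(5.0, 0.0)
        assert val == 1.0 and flagged

    def test_both_zero_is_undefined_flagged(self):
        val, flagged = lc.ltr_contribution(0.0, 0.0)
        assert np.isnan(val) and flagged


def build_locus():
    """One gene with a canonical transcript and an upstream-LTR chimera."""
    rep = ltr(1000, 1600)
    gene = tx("gene1", [(5000, 5300), (7000, 7400), (9000, 9500)],
              fpkm=18.0, gene_id="g1")
    lit = tx("lit1", [(1200, 1800), (7000, 7400), (9000, 9500)],
             fpkm=9.0, gene_id=None)
    return rep, gene, lit


class TestCallLits:
    def test_sense_chimera_called_with_share(self):
        rep, gene, lit = build_locus()
        calls = lc.call_lits([lit, gene], [rep], [gene])
        assert len(calls) == 1
        c = calls[0]
        assert c.category == "Up"
        assert c.gene_overlap == "sense-chimeric"
        assert c.isoform_share == pytest.approx(9.0 / 27.0)

    def test_share_at_or_below_floor_is_not_chimeric(self):
        rep, gene, lit = build_locus()
        small = tx("lit1", [(1200, 1800), (7000, 7400)], fpkm=1.0)
        calls = lc.call_lits([small, gene], [rep],
                             [tx("gene1", [(5000, 5300), (7000, 7400),
                                           (9000, 9500)],
                                 fpkm=11.5, gene_id="g1")])
        # share 1.0/12.5 = 0.08 < 0.10 -> sense overlap not chimeric
        assert calls[0].gene_overlap != "sense-chimeric"

    def test_antisense_overlap(self):
        rep = ltr(7100, 7700)
        gene = tx("gene1", [(5000, 5300), (7000, 7400), (9000, 9500)],
                  fpkm=6.0, gene_id="g1")
        anti = tx("anti", [(4000, 7650)], strand="-", fpkm=4.0)
        calls = lc.call_lits([anti, gene], [rep], [gene])
        assert calls[0].category == "Up"
        assert calls[0].gene_overlap == "antisense"

    def test_intergenic_when_no_gene_contact(self):
        rep = ltr(50_000, 50_500)
        lit = tx("solo", [(50_100, 51_000), (52_000, 52_600)])
        gene = tx("gene1", [(5000, 5300)], fpkm=5.0, gene_id="g1")
        calls = lc.call_lits([lit, gene], [rep], [gene])
        assert calls[0].gene_overlap == "intergenic"

    def test_order_invariance(self):
        rep, gene, lit = build_locus()
        rep2 = ltr(50_000, 50_500, subfam="MTC")
        solo = tx("solo", [(50_100, 51_000), (52_000, 52_600)])
        a = lc.call_lits([lit, solo, gene], [rep, rep2], [gene])
        b = lc.call_lits([solo, gene, lit], [rep2, rep], [gene])
        assert [(c.transcript.id, c.category, c.gene_overlap) for c in a] == \
               [(c.transcript.id, c.category, c.gene_overlap) for c in b]

    def test_isoform_share_one_when_lit_is_only_isoform(self):
        rep = ltr(1000, 1600)
        lit = tx("lit1", [(1200, 1800), (7000, 7400)], fpkm=9.0)
        gene = tx("gene1", [(5000, 5300), (7000, 7400)], fpkm=0.0,
                  gene_id="g1")
        calls = lc.call_lits([lit], [rep], [gene])
        assert calls[0].isoform_share == 1.0


class TestActiveLtrScan:
    def test_strict_fpkm_threshold(self):
        reps = [ltr(100, 600), ltr(1000, 1500, subfam="MTC"),
                ltr(2000, 2500, subfam="MTD")]
        fpkm = {reps[0].location: 1.0, reps[1].location: 1.01,
                reps[2].location: 0.2}
        active = lc.active_ltr_scan(reps, fpkm)
        assert [r.subfamily for r, _ in active] == ["MTC"]

    def test_zero_coverage_genome_is_empty(self):
        reps = [ltr(100, 600)]
        assert lc.active_ltr_scan(reps, {}) == []

    def test_composition_fractions_sum_to_one(self):
        reps = [ltr(100, 600), ltr(1000, 1500, cls="LTR-ERVK", subfam="RLTR"),
                ltr(2000, 2500, subfam="MTC")]
        fpkm = {r.location: 5.0 for r in reps}
        comp = lc.class_composition(lc.active_ltr_scan(reps, fpkm))
        assert sum(comp.values()) == pytest.approx(1.0)
        assert comp["LTR-MaLR"] == pytest.approx(2 / 3)


class TestRescue:
    def domain(self, start, end, cls="hyper"):
        return MethDomain(GenomicInterval("chr1", start, end), 0.8, cls, 10)

    def test_tss_near_domain_edge_in_ltr_is_flagged(self):
        rep = ltr(10_000, 10_600)
        t = tx("cand", [(10_200, 12_000)])  # TSS 200 bp inside the domain
        out = lc.rescue_lits_by_domain([t], [self.domain(10_000, 30_000)],
                                       [rep], [])
        assert out == [t]

    def test_transcript_outside_domains_not_flagged(self):
        rep = ltr(50_000, 50_600)
        t = tx("cand", [(50_100, 52_000)])
        out = lc.rescue_lits_by_domain([t], [self.domain(10_000, 30_000)],
                                       [rep], [])
        assert out == []

    def test_candidates_disjoint_from_primary_calls(self):
        rep = ltr(10_000, 10_600)
        t = tx("cand", [(10_200, 12_000)])
        primary = lc.call_lits([t], [rep], [])
        assert primary  # it is a primary Up call
        out = lc.rescue_lits_by_domain([t], [self.domain(10_000, 30_000)],
                                       [rep], primary)
        assert out == []


class TestCohortRecovery:
    def test_planted_lits_recovered_with_high_precision_recall(self):
        spec = CohortSpec(species=("mouse",), genome_length=2_500_000,
                          n_genes=90, n_shared_ltrs=30, n_pair_ltrs=0,
                          n_private_ltrs=0, frac_ltr_active=0.5,
                          n_orphans=0, rng_seed=21)
        ann = simulate_annotations(spec)
        trans = simulate_transcriptome(ann)
        sp = "mouse"
        calls = lc.call_lits(trans.transcripts[sp],
                             ann.per_species[sp].repeats,
                             ann.per_species[sp].genes)
        planted = {l.lit_id[sp] for l in ann.truth.ltrs if l.active.get(sp)}
        called = {c.transcript.id for c in calls}
        assert planted
        tp = len(planted & called)
        assert tp / len(called) >= 0.95  # precision
        assert tp / len(planted) >= 0.95  # recall

    def test_zero_planted_lits_zero_calls(self):
        spec = CohortSpec(species=("mouse",), genome_length=1_000_000,
                          n_genes=35, n_shared_ltrs=12, n_pair_ltrs=0,
                          n_private_ltrs=0, frac_ltr_active=0.0,
                          n_orphans=0, rng_seed=22)
        ann = simulate_annotations(spec)
        trans = simulate_transcriptome(ann)
        calls = lc.call_lits(trans.transcripts["mouse"],
                             ann.per_species["mouse"].repeats,
                             ann.per_species["mouse"].genes)
        assert calls == []
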