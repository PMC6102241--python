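"""Generator contracts: determinism, chain exactness, ground-truth
consistency, and the statistical structure of the simulated methylomes."""

import numpy as np
import pytest
from scipy import stats

from litmeth.core import GenomicInterval
from litmeth import synthetic_cohort as sc
from litmeth.synthetic_cohort import (
    CohortSpec,
    SpecError,
    simulate_annotations,
    simulate_cohort,
    simulate_transcriptome,
)

from oracles import project_base


class TestSpecValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(frac_ltr_active=1.5)

    def test_placement_overflow_rejected(self):
        with pytest.raises(SpecError, match="genome_length"):
            simulate_annotations(CohortSpec(genome_length=100_000, n_genes=60))


class TestDeterminism:
    def test_same_seed_same_cohort(self, tmp_path):
        a = simulate_cohort(CohortSpec(rng_seed=5, genome_length=800_000,
                                       n_genes=18))
        b = simulate_cohort(CohortSpec(rng_seed=5, genome_length=800_000,
                                       n_genes=18))
        sp = a.spec.species[0]
        assert a.methylomes[(sp, "oocyte")].df.equals(
            b.methylomes[(sp, "oocyte")].df)
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seeds_differ(self):
        a = simulate_annotations(CohortSpec(rng_seed=5, genome_length=800_000,
                                            n_genes=18))
        b = simulate_annotations(CohortSpec(rng_seed=6, genome_length=800_000,
                                            n_genes=18))
        assert a.truth.to_json() != b.truth.to_json()

    def test_emitted_files_byte_identical(self, tmp_path):
        spec = CohortSpec(rng_seed=5, genome_length=700_000, n_genes=14)
        for d in ("one", "two"):
            sc.emit_cohort(simulate_cohort(spec), tmp_path / d)
        for rel in ("mouse/meth_oocyte.bedGraph", "mouse/transcripts.gtf",
                    "mouse_to_rat.chain", "truth.json"):
            assert (tmp_path / "one" / rel).read_bytes() == \
                   (tmp_path / "two" / rel).read_bytes()


class TestChains:
    def test_zero_private_insertions_gives_identity_chains(self):
        spec = CohortSpec(species=("a", "b"), genome_length=800_000,
                          n_genes=16, n_shared_ltrs=8, n_private_ltrs=0,
                          rng_seed=9)
        ann = simulate_annotations(spec)
        chain = ann.chains[("a", "b")][0]
        assert len(chain.blocks) == 1
        assert chain.source_interval == chain.target_interval
        # annotations identical across species
        assert ann.per_species["a"].chrom_sizes == ann.per_species["b"].chrom_sizes
        assert [g.location for g in ann.per_species["a"].genes] == \
               [g.location for g in ann.per_species["b"].genes]

    def test_private_ltr_creates_matching_chain_gap(self):
        spec = CohortSpec(species=("a", "b"), genome_length=800_000,
                          n_genes=16, n_shared_ltrs=0, n_private_ltrs=4,
                          rng_seed=9)
        ann = simulate_annotations(spec)
        chain = ann.chains[("a", "b")][0]
        a_private = [l for l in ann.truth.ltrs if l.presence == ("a",)]
        # source-side gaps between consecutive blocks == a-private lengths
        gaps = []
        for (s0, _t0, l0), (s1, _t1, _l1) in zip(chain.blocks,
                                                 chain.blocks[1:]):
            gap = s1 - (s0 + l0)
            if gap:
                gaps.append(gap)
        assert sorted(gaps) == sorted(l.length for l in a_private)

    def test_chain_maps_every_shared_feature_exactly(self, small_cohort):
        """Brute-force per-base projection of gene starts through the
        emitted chains reproduces the partner species placement."""
        ann = small_cohort.annotations
        spec = small_cohort.spec
        a, b = spec.species[0], spec.species[2]
        chain = ann.chains[(a, b)]
        fa, fb = ann.frames[a], ann.frames[b]
        for g in small_cohort.truth.genes[:20]:
            pa = fa.map_point(g.span[0])
            pb = fb.map_point(g.span[0])
            assert project_base(spec.chrom, pa, chain) == (spec.chrom, pb)


class TestTranscriptomeTruth:
    def test_every_lit_has_one_transcript_starting_in_its_ltr(self,
                                                              small_cohort):
        truth = small_cohort.truth
        for sp in small_cohort.spec.species:
            frames = small_cohort.annotations.frames[sp]
            by_id = {t.id: t for t in
                     small_cohort.transcriptome.transcripts[sp]}
            for l in truth.ltrs:
                if not l.active.get(sp):
                    continue
                t = by_id[l.lit_id[sp]]
                s, e = frames.ltr_span(l.id)
                if l.up_edge and not l.antisense:
                    assert s - 100 <= t.tss < s
                else:
                    assert s <= t.tss < e

    def test_inactive_ltrs_emit_no_transcript(self, small_cohort):
        truth = small_cohort.truth
        for sp in small_cohort.spec.species:
            ids = {t.id for t in small_cohort.transcriptome.transcripts[sp]}
            for l in truth.ltrs:
                if not l.active.get(sp):
                    assert l.lit_id.get(sp) not in ids or not l.lit_id.get(sp)

    def test_chimeric_lit_shares_an_exon_with_its_gene(self, small_cohort):
        truth = small_cohort.truth
        sp = small_cohort.spec.species[0]
        ann = small_cohort.annotations.per_species[sp]
        gene_exons = {g.id: set((e.start, e.end) for e in g.exons)
                      for g in ann.genes}
        by_id = {t.id: t for t in small_cohort.transcriptome.transcripts[sp]}
        checked = 0
        for l in truth.ltrs:
            if not l.active.get(sp) or l.antisense or not l.target_gene:
                continue
            t = by_id[l.lit_id[sp]]
            later = set((e.start, e.end) for e in t.exons[1:])
            assert later & gene_exons[l.target_gene]
            checked += 1
        assert checked > 0

    def test_planted_lit_fraction_within_binomial_interval(self):
        """Configure ~15% LIT share and check the realised fraction."""
        spec = CohortSpec(species=("mouse",), genome_length=12_000_000,
                          n_genes=500, n_shared_ltrs=110, n_private_ltrs=0,
                          frac_ltr_active=0.85, gene_expressed_frac=0.8,
                          canonical_suppression=0.0, n_orphans=0,
                          rng_seed=13)
        ann = simulate_annotations(spec)
        trans = simulate_transcriptome(ann)
        ts = trans.transcripts["mouse"]
        n_lit = sum(1 for t in ts if "_LIT_" in t.id)
        target = (110 * 0.85) / (110 * 0.85 + 500 * 0.8)
        lo, hi = stats.binom.interval(0.99, len(ts), target)
        assert lo <= n_lit <= hi


class TestMethylomes:
    def test_zero_depth_gives_all_zero_totals(self):
        spec = CohortSpec(species=("a",), genome_length=400_000, n_genes=12,
                          mean_depth=0.0, rng_seed=3)
        cohort = simulate_cohort(spec, tissues=("oocyte",), with_k36=False)
        table = cohort.methylomes[("a", "oocyte")]
        assert (table.df["total"] == 0).all()
        from litmeth.meth_landscape import score_bins
        bins = score_bins(table, min_cpgs=1, min_depth=1)
        assert not any(b.passes_filter for b in bins)

    def test_oocyte_methylation_is_bimodal_at_planted_modes(self,
                                                            small_cohort):
        """Kernel-density modes of per-CpG methylation sit near m_low
        and m_high."""
        spec = small_cohort.spec
        table = small_cohort.methylomes[(spec.species[0], "oocyte")]
        frac = table.fraction()
        frac = frac[table.df["total"] >= 10].dropna().to_numpy()
        kde = stats.gaussian_kde(frac, bw_method=0.08)
        grid = np.linspace(0, 1, 201)
        dens = kde(grid)
        lo_mode = grid[np.argmax(dens[grid <= 0.5])]
        hi_mode = grid[100 + np.argmax(dens[grid >= 0.5])]
        assert abs(lo_mode - spec.m_low) < 0.10
        assert abs(hi_mode - spec.m_high) < 0.10

    def test_sperm_high_except_cgis(self, small_cohort):
        spec = small_cohort.spec
        sp = spec.species[0]
        table = small_cohort.methylomes[(sp, "sperm")]
        fr = small_cohort.annotations.frames[sp]
        cgi = small_cohort.truth.cgis[0]
        iv = GenomicInterval(spec.chrom, *fr.map_span(*cgi.span))
        assert table.mean_over(iv, min_cpgs=6) < 0.05
        global_mean = float(table.fraction().dropna().mean())
        assert global_mean > 0.80

    def test_retained_cgis_exceed_erased_in_blastocyst(self, small_cohort):
        spec = small_cohort.spec
        sp = spec.species[0]
        fr = small_cohort.annotations.frames[sp]
        bl = small_cohort.methylomes[(sp, "blastocyst")]
        groups = {"retained": [], "erased": []}
        for c in small_cohort.truth.cgis:
            if c.expected_class.get(sp) != "hyper":
                continue
            iv = GenomicInterval(spec.chrom, *fr.map_span(*c.span))
            groups[c.retention[sp]].append(bl.mean_over(iv, min_cpgs=6))
        assert groups["retained"] and groups["erased"]
        gap = np.mean(groups["retained"]) - np.mean(groups["erased"])
        assert gap > 0.4  # planted effect: 0.70 vs 0.05 mean levels

    def test_k36_elevated_over_transcribed_units(self, small_cohort):
        spec = small_cohort.spec
        sp = spec.species[0]
        track = small_cohort.k36[sp]
        fr = small_cohort.annotations.frames[sp]
        g = next(g for g in small_cohort.truth.genes
                 if g.expressed[sp] and not g.suppressed[sp])
        s, e = fr.map_span(*g.span)
        from litmeth.synthetic_cohort import k36_mean_over
        inside = k36_mean_over(track, GenomicInterval(spec.chrom, s + 600, e))
        outside = k36_mean_over(track, GenomicInterval(spec.chrom, 0, 4000))
        assert inside - outside > 1.5


class TestTruthInvariants:
    def test_hyper_cgis_trace_to_a_unit_or_orphan(self, small_cohort):
        """Every expected-hyper CGI is covered by a planted transcription
        unit (gene body or LIT)."""
        truth = small_cohort.truth
        for sp in small_cohort.spec.species:
            fr = small_cohort.annotations.frames[sp]
            for c in truth.cgis:
                if c.expected_class.get(sp) != "hyper":
                    continue
                s, e = fr.map_span(*c.span)
                covered = False
                if c.embedded_lit.get(sp):
                    covered = True
                else:
                    for g in truth.genes:
                        if (g.id == c.gene_id and g.expressed[sp]
                                and not g.suppressed[sp]):
                            gs, ge = fr.map_span(*g.span)
                            covered = gs <= s and e <= ge
                if not covered:
                    # antisense LITs over the CGI also explain it
                    for l in truth.ltrs:
                        if l.active.get(sp) and sp in l.lit_span:
                            ls, le = l.lit_span[sp]
                            if ls <= s and e <= le:
                                covered = True
                                break
                assert covered, (sp, c.id)
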