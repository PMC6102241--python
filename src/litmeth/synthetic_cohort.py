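"""Synthetic multi-species oocyte cohort with known ground truth.

The generator emulates the statistical structure the comparative
analysis assumes, without nucleotide sequence:

* species genomes derived from one ancestral coordinate frame by
  lineage-specific LTR insertions (insertion-only indels), so pairwise
  chains are exact by construction;
* genes with a CpG island at the TSS, a subset transcriptionally
  active in oocytes;
* LTR-initiated transcripts (LITs) from a subset of planted LTRs —
  chimeric sense (splicing into a genic exon), antisense, or
  intergenic — with transcription-coupled hypermethylation downstream
  of every active unit's 5' end;
* orphan transcribed territory carrying hypermethylation that overlaps
  neither a gene nor an LIT (the unexplained-domain background class);
* oocyte / sperm / parthenogenetic-blastocyst / biparental-blastocyst /
  epiblast methylomes with per-CGI retention draws and a TET-sensitive
  subset;
* an H3K36me3 coverage track elevated over transcribed territory.

Every random draw flows from ``CohortSpec.rng_seed``; the same spec
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ChainAlignment,
    GenomicInterval,
    MethTable,
    RepeatElement,
    Transcript,
    ValidationError,
)

#: subfamily assignment per lineage category (index cycles)
LINEAGE_SUBFAMILIES = {
    "all": ["MLT1A", "MLT1B"],
    "pair": ["MTB", "MTC", "MTD"],
    "private0": ["MTA"],          # first species (mouse-like)
    "private1": ["RLTR31B"],      # second species (rat-like)
    "private2": ["LTR12C", "THE1A"],  # third species (human-like)
}

SUBFAMILY_CLASS = {
    "MLT1A": "LTR-MaLR", "MLT1B": "LTR-MaLR",
    "MTA": "LTR-MaLR", "MTB": "LTR-MaLR", "MTC": "LTR-MaLR",
    "MTD": "LTR-MaLR", "THE1A": "LTR-MaLR",
    "RLTR31B": "LTR-ERVK", "LTR12C": "LTR-ERV1",
}


class SpecError(ValidationError):
    """Raised when a CohortSpec cannot be realised (placement overflow)."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults describe a three-species (mouse/rat/human-like) oocyte
    world at desk scale: the first two species are the close pair and
    share 'pair'-lineage LTRs, the third is the outgroup. Probabilities
    must lie in [0, 1]; the genome must be able to hold the requested
    features (checked at placement).
    """

    species: tuple = ("mouse", "rat", "human")
    chrom: str = "chr1"
    genome_length: int = 1_500_000
    n_genes: int = 60

    # LTR insertion load per lineage category
    n_shared_ltrs: int = 10
    n_pair_ltrs: int = 8
    n_private_ltrs: int = 8  # per species
    ltr_length_range: tuple = (400, 800)
    frac_upstream: float = 0.4
    frac_intragenic: float = 0.25
    frac_ltr_active: float = 0.3
    antisense_prob: float = 0.25  # intragenic LITs running antisense
    up_edge_frac: float = 0.15  # LIT TSS just outside the repeat edge
    shared_ltr_active_everywhere: float = 0.7  # else active in one species

    # transcription
    gene_expressed_frac: float = 0.75
    shared_expression_frac: float = 0.9
    canonical_suppression: float = 0.8  # canonical TSS off under upstream LIT
    fpkm_log_mean: float = 1.2
    fpkm_log_sd: float = 0.8

    # methylation model
    m_high: float = 0.85
    m_low: float = 0.05
    beta_concentration: float = 30.0
    promoter_pad: int = 500  # unmethylated zone downstream of a unit's 5' end
    sperm_high: float = 0.90
    sperm_cgi: float = 0.003
    blast_attenuation: float = 0.55
    retained_level: float = 0.70
    erased_level: float = 0.05
    retention_prob_lit: float = 0.4
    retention_prob_other: float = 0.4
    epiblast_erase_prob: float = 0.7
    tet_sensitive_frac: float = 0.4

    # coverage model
    mean_depth: float = 15.0
    depth_dispersion: float = 5.0  # gamma shape of the Poisson mixing rate

    # CpG geometry
    cpg_spacing: int = 30
    cgi_cpg_spacing: int = 10
    ltr_cpg_spacing: int = 25
    cgi_width: int = 600
    intragenic_cgi_prob: float = 0.3
    #: per-species jitter (bp, uniform +/-) of annotated CGI boundaries,
    #: emulating independent CGI annotation across genomes
    cgi_boundary_drift: int = 30

    # orphan (non-gene, non-LIT) transcribed territory
    n_orphans: int = 12
    orphan_length_range: tuple = (4000, 8000)

    rng_seed: int = 0

    def __post_init__(self):
        probs = [self.frac_upstream, self.frac_intragenic, self.frac_ltr_active,
                 self.gene_expressed_frac, self.shared_expression_frac,
                 self.canonical_suppression, self.m_high, self.m_low,
                 self.retention_prob_lit, self.retention_prob_other,
                 self.epiblast_erase_prob, self.tet_sensitive_frac,
                 self.antisense_prob, self.up_edge_frac,
                 self.shared_ltr_active_everywhere, self.intragenic_cgi_prob]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise SpecError(f"probability {p} outside [0, 1]")
        if len(self.species) < 1:
            raise SpecError("need at least one species")
        if self.frac_upstream + self.frac_intragenic > 1.0:
            raise SpecError("LTR placement fractions exceed 1")


# ---------------------------------------------------------------------------
# Truth ledger

@dataclass
class LTRTruth:
    id: str
    anchor: int  # ancestral insertion point (before this base)
    length: int
    presence: tuple  # species carrying the insertion
    subfamily: str
    repeat_class: str
    kind: str  # {upstream, intragenic, intergenic}
    target_gene: str | None = None
    antisense: bool = False
    up_edge: bool = False
    active: dict = field(default_factory=dict)  # species -> bool
    suppresses: bool = False  # upstream LIT silences the canonical TSS
    lit_span: dict = field(default_factory=dict)  # species -> (start, end)
    lit_id: dict = field(default_factory=dict)  # species -> transcript id

    @property
    def privacy(self) -> str:
        return "shared" if len(self.presence) > 1 else "private"


@dataclass
class GeneTruth:
    id: str
    span: tuple  # ancestral (start, end)
    exons: tuple  # ancestral (start, end) pairs
    cgi: tuple  # promoter CGI ancestral span
    expressed: dict = field(default_factory=dict)  # species -> bool
    suppressed: dict = field(default_factory=dict)  # species -> bool
    fpkm: dict = field(default_factory=dict)


@dataclass
class CGITruth:
    id: str
    span: tuple  # ancestral (start, end)
    gene_id: str | None
    kind: str  # {promoter, intragenic}
    expected_class: dict = field(default_factory=dict)  # sp -> hyper/hypo
    embedded_lit: dict = field(default_factory=dict)  # sp -> LTR id or None
    retention: dict = field(default_factory=dict)  # sp -> retained/erased
    tet_sensitive: bool = False


@dataclass
class SimTruth:
    species: tuple
    ltrs: list
    genes: list
    cgis: list
    orphans: list  # ancestral (start, end) spans, transcribed in all species

    def lit_ltrs(self, species: str) -> list:
        return [l for l in self.ltrs if l.active.get(species)]

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        payload = {
            "species": list(self.species),
            "ltrs": [enc(asdict(l)) for l in self.ltrs],
            "genes": [enc(asdict(g)) for g in self.genes],
            "cgis": [enc(asdict(c)) for c in self.cgis],
            "orphans": [list(o) for o in self.orphans],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Coordinate frames

class SpeciesFrame:
    """Ancestor -> species coordinate map for one species.

    Built from the insertions present in that species; an insertion of
    length L anchored before ancestral base a shifts every base >= a by
    +L and occupies species range [map(a) - L, map(a)).
    """

    def __init__(self, insertions: list, genome_length: int):
        ins = sorted((l.anchor, l.length, l.id) for l in insertions)
        self.anchors = [a for a, _, _ in ins]
        self.cum = np.concatenate([[0], np.cumsum([L for _, L, _ in ins])]).astype(int)
        self.length = genome_length + int(self.cum[-1])
        self._span_by_id = {}
        for a, L, lid in ins:
            end = self.map_point(a)
            self._span_by_id[lid] = (end - L, end)

    def map_point(self, x: int) -> int:
        return x + int(self.cum[bisect_right(self.anchors, x)])

    def map_span(self, start: int, end: int) -> tuple:
        return self.map_point(start), self.map_point(end)

    def ltr_span(self, ltr_id: str) -> tuple | None:
        return self._span_by_id.get(ltr_id)

    def map_points(self, xs: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.anchors), xs, side="right")
        return xs + self.cum[idx]


def build_pair_chain(truth: SimTruth, frame_a: SpeciesFrame,
                     frame_b: SpeciesFrame, sp_a: str, sp_b: str,
                     genome_length: int, chrom: str) -> ChainAlignment:
    """Exact chain between two species frames of the same ancestor.

    Blocks are colinear; gaps appear exactly at insertions private to
    one of the two species. Insertions shared by both species align
    base-for-base (same length by construction).
    """
    events = sorted((l.anchor, l.length, sp_a in l.presence, sp_b in l.presence)
                    for l in truth.ltrs)
    blocks = []
    a_pos = b_pos = 0  # species coords of the open block start
    blen = 0
    prev = 0
    for anchor, L, in_a, in_b in events:
        blen += anchor - prev
        prev = anchor
        if in_a and in_b:
            blen += L
        elif in_a:
            if blen > 0:
                blocks.append((a_pos, b_pos, blen))
                a_pos += blen
                b_pos += blen
            a_pos += L
            blen = 0
        elif in_b:
            if blen > 0:
                blocks.append((a_pos, b_pos, blen))
                a_pos += blen
                b_pos += blen
            b_pos += L
            blen = 0
    blen += genome_length - prev
    if blen > 0:
        blocks.append((a_pos, b_pos, blen))
    if not blocks:
        raise SpecError("chain with no aligned blocks")
    a0, b0 = blocks[0][0], blocks[0][1]
    a_end = blocks[-1][0] + blocks[-1][2]
    b_end = blocks[-1][1] + blocks[-1][2]
    rel = tuple((a - a0, b - b0, ln) for a, b, ln in blocks)
    return ChainAlignment(
        GenomicInterval(chrom, a0, a_end),
        GenomicInterval(chrom, b0, b_end),
        rel, chain_id=f"{sp_a}_to_{sp_b}", score=float(a_end - a0))


# ---------------------------------------------------------------------------
# Annotation simulation

@dataclass
class SpeciesAnnotation:
    genes: list  # Transcript (canonical models, fpkm 0 here)
    repeats: list  # RepeatElement
    cgis: list  # GenomicInterval
    chrom_sizes: dict


@dataclass
class CohortAnnotations:
    spec: CohortSpec
    per_species: dict  # species -> SpeciesAnnotation
    chains: dict  # (src, dst) -> [ChainAlignment]
    frames: dict  # species -> SpeciesFrame
    truth: SimTruth


def _lineage_categories(spec: CohortSpec) -> list:
    """(category, presence tuple, count) triples for the LTR load."""
    sp = spec.species
    cats = [("all", tuple(sp), spec.n_shared_ltrs)]
    if len(sp) >= 3:
        cats.append(("pair", tuple(sp[:2]), spec.n_pair_ltrs))
    for i, s in enumerate(sp):
        key = f"private{min(i, 2)}"
        cats.append((key, (s,), spec.n_private_ltrs))
    return cats


def simulate_annotations(spec: CohortSpec) -> CohortAnnotations:
    """Lay out the ancestral genome, plant LTRs, and derive species
    annotations plus exact chains."""
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.genome_length

    # --- ancestral gene layout ------------------------------------------
    genes: list[GeneTruth] = []
    cgis: list[CGITruth] = []
    orphans: list[tuple] = []
    cursor = 5000
    half_cgi = spec.cgi_width // 2

    orphan_slots = set()
    if spec.n_orphans and spec.n_genes:
        step = max(1, spec.n_genes // spec.n_orphans)
        orphan_slots = set(range(0, spec.n_genes, step))

    for gi in range(spec.n_genes):
        gap = int(rng.integers(9000, 16000))
        if gi in orphan_slots and len(orphans) < spec.n_orphans:
            # clear of the previous gene's 2 kb genic tail on the left and
            # of the next gene's upstream-LTR zone on the right
            olen = int(rng.integers(*spec.orphan_length_range))
            gap += olen + 6000
            o_start = cursor + 3500
            orphans.append((o_start, o_start + olen))
        cursor += gap
        tss = cursor
        n_ex = int(rng.integers(3, 7))
        exons = []
        pos = tss
        for e in range(n_ex):
            elen = int(rng.integers(150, 400))
            exons.append((pos, pos + elen))
            pos += elen
            if e + 1 < n_ex:
                pos += int(rng.integers(900, 2600))
        g = GeneTruth(f"gene{gi:04d}", (tss, pos), tuple(exons),
                      (tss - half_cgi, tss + half_cgi))
        genes.append(g)
        cgis.append(CGITruth(f"cgi_{g.id}", g.cgi, g.id, "promoter"))
        if rng.random() < spec.intragenic_cgi_prob and n_ex >= 3:
            # drop a CGI into the last intron: deep in the gene body,
            # clear of the promoter pad and >500 bp from the TSS
            i_start, i_end = exons[-2][1], exons[-1][0]
            if i_end - i_start > 700:
                c_start = i_start + 100
                cgis.append(CGITruth(f"cgi_{g.id}_intra",
                                     (c_start, c_start + 400), g.id,
                                     "intragenic"))
        cursor = pos
    if cursor + 5000 > L:
        raise SpecError(
            f"genome_length {L} too small for {spec.n_genes} genes "
            f"(layout needs ~{cursor + 5000} bp)")

    # --- plant LTR insertions -------------------------------------------
    forbidden: list[tuple] = []  # exons and CGIs must not be split
    for g in genes:
        forbidden.extend(g.exons)
    for c in cgis:
        forbidden.append((c.span[0] - 50, c.span[1] + 50))
    for o in orphans:
        # keep intergenic LTRs (and the LITs they emit) out of orphan
        # territory so orphans stay a clean gene-free, LIT-free class
        forbidden.append((o[0] - 4500, o[1]))
    forbidden = _merge_spans(forbidden)  # bisect below assumes disjoint
    fb_starts = [f[0] for f in forbidden]

    def is_clear(a: int) -> bool:
        i = bisect_right(fb_starts, a) - 1
        if 0 <= i < len(forbidden) and forbidden[i][0] <= a < forbidden[i][1]:
            return False
        return True

    ltrs: list[LTRTruth] = []
    counter = 0
    for cat, presence, count in _lineage_categories(spec):
        subfams = LINEAGE_SUBFAMILIES[cat]
        for k in range(count):
            ln = int(rng.integers(*spec.ltr_length_range))
            subfam = subfams[k % len(subfams)]
            u = rng.random()
            placed = False
            for _attempt in range(40):
                if u < spec.frac_upstream and genes:
                    g = genes[int(rng.integers(len(genes)))]
                    anchor = g.span[0] - int(rng.integers(1000, 2600))
                    kind, target = "upstream", g.id
                elif u < spec.frac_upstream + spec.frac_intragenic and genes:
                    g = genes[int(rng.integers(len(genes)))]
                    introns = [(a[1] + 20, b[0] - 260)
                               for a, b in zip(g.exons, g.exons[1:])
                               if b[0] - a[1] > 600]
                    if not introns:
                        continue
                    lo, hi = introns[int(rng.integers(len(introns)))]
                    anchor = int(rng.integers(lo, hi))
                    kind, target = "intragenic", g.id
                else:
                    anchor = int(rng.integers(2000, L - 2000))
                    kind, target = "intergenic", None
                if anchor < 1000 or anchor > L - 1000 or not is_clear(anchor):
                    continue
                if any(l.anchor == anchor for l in ltrs):
                    continue
                placed = True
                break
            if not placed:
                raise SpecError("could not place LTR insertion (genome too crowded)")
            ltrs.append(LTRTruth(f"ltr{counter:04d}", anchor, ln, presence,
                                 subfam, SUBFAMILY_CLASS[subfam], kind,
                                 target_gene=target))
            counter += 1
    ltrs.sort(key=lambda l: l.anchor)

    truth = SimTruth(tuple(spec.species), ltrs, genes, cgis, orphans)

    # --- species frames, annotations, chains ----------------------------
    frames = {
        sp: SpeciesFrame([l for l in ltrs if sp in l.presence], L)
        for sp in spec.species
    }
    per_species = {}
    for sp in spec.species:
        fr = frames[sp]
        gene_models = []
        for g in genes:
            ex = tuple(GenomicInterval(spec.chrom, *fr.map_span(*e), "+")
                       for e in g.exons)
            loc = GenomicInterval(spec.chrom, ex[0].start, ex[-1].end, "+")
            gene_models.append(Transcript(g.id, loc, ex, fpkm=0.0, gene_id=g.id))
        repeats = []
        for l in ltrs:
            if sp not in l.presence:
                continue
            s, e = fr.ltr_span(l.id)
            repeats.append(RepeatElement(
                GenomicInterval(spec.chrom, s, e, "+"),
                l.repeat_class, l.subfamily, annotation_source="synthetic"))
        cgi_ivs = []
        for c in cgis:
            s, e = fr.map_span(*c.span)
            if spec.cgi_boundary_drift:
                d = spec.cgi_boundary_drift
                s = max(0, s + int(rng.integers(-d, d + 1)))
                e = max(s + 100, e + int(rng.integers(-d, d + 1)))
            cgi_ivs.append(GenomicInterval(spec.chrom, s, e))
        per_species[sp] = SpeciesAnnotation(
            gene_models, repeats, cgi_ivs, {spec.chrom: fr.length})

    chains = {}
    for a in spec.species:
        for b in spec.species:
            if a == b:
                continue
            chains[(a, b)] = [build_pair_chain(truth, frames[a], frames[b],
                                               a, b, L, spec.chrom)]
    return CohortAnnotations(spec, per_species, chains, frames, truth)


# ---------------------------------------------------------------------------
# Transcriptome simulation

@dataclass
class CohortTranscriptome:
    transcripts: dict  # species -> [Transcript] (assembled models)
    repeat_fpkm: dict  # species -> {repeat interval -> FPKM}
    coverage: dict  # species -> {lit id -> (exon1 cov, canonical exon1 cov)}


def _draw_fpkm(rng, spec: CohortSpec) -> float:
    return float(np.exp(rng.normal(spec.fpkm_log_mean, spec.fpkm_log_sd))) + 1.2


def simulate_transcriptome(ann: CohortAnnotations) -> CohortTranscriptome:
    """Emit canonical and LTR-initiated transcripts per species.

    Active LTRs emit transcripts whose 5' end lies within the repeat
    (or just outside it for the UpEdge fraction); chimeric LITs share a
    downstream exon with their target gene, and the canonical TSS of a
    gene under an upstream LIT is suppressed with the configured
    probability.
    """
    spec = ann.spec
    rng = np.random.default_rng(spec.rng_seed + 1)
    truth = ann.truth

    # activity draws (shared LTRs can lose activity in one lineage)
    for l in truth.ltrs:
        active_any = rng.random() < spec.frac_ltr_active
        everywhere = rng.random() < spec.shared_ltr_active_everywhere
        lone = l.presence[int(rng.integers(len(l.presence)))]
        l.antisense = (l.kind == "intragenic"
                       and rng.random() < spec.antisense_prob)
        l.up_edge = rng.random() < spec.up_edge_frac
        # suppression is a property of the LIT, not of the species: where
        # the LIT is active it behaves the same way in every lineage
        l.suppresses = rng.random() < spec.canonical_suppression
        for sp in spec.species:
            if sp not in l.presence or not active_any:
                l.active[sp] = False
            else:
                l.active[sp] = everywhere or (sp == lone)

    # gene expression draws (mostly conserved across species)
    for g in truth.genes:
        expressed_any = rng.random() < spec.gene_expressed_frac
        everywhere = rng.random() < spec.shared_expression_frac
        lone = spec.species[int(rng.integers(len(spec.species)))]
        base = _draw_fpkm(rng, spec)
        for sp in spec.species:
            on = expressed_any and (everywhere or sp == lone)
            g.expressed[sp] = on
            g.fpkm[sp] = base * float(np.exp(rng.normal(0, 0.1))) if on else 0.0
            g.suppressed[sp] = False

    gene_by_id = {g.id: g for g in truth.genes}
    transcripts: dict = {}
    repeat_fpkm: dict = {}
    coverage: dict = {}

    for sp in spec.species:
        fr = ann.frames[sp]
        out = []
        rep_fpkm = {}
        cov = {}
        # LITs first (they may suppress canonical starts)
        for l in truth.ltrs:
            if not l.active.get(sp):
                continue
            s, e = fr.ltr_span(l.id)
            fpkm = _draw_fpkm(rng, spec)
            tid = f"{sp}_LIT_{l.id}"
            if l.antisense:
                tss = e - 1 - int(rng.integers(50, min(150, e - s - 1)))
                ext = int(rng.integers(2500, 5000))
                exon1 = GenomicInterval(spec.chrom, max(0, s - ext), tss + 1, "-")
                loc = exon1
                t = Transcript(tid, loc, (exon1,), fpkm=fpkm, gene_id=None)
            else:
                if l.up_edge:
                    tss = max(0, s - int(rng.integers(10, 90)))
                else:
                    tss = s + int(rng.integers(50, min(200, e - s)))
                exon1_end = e + 150
                g = gene_by_id.get(l.target_gene) if l.target_gene else None
                exons = [GenomicInterval(spec.chrom, tss, exon1_end, "+")]
                if g is not None:
                    g_ex = [fr.map_span(*x) for x in g.exons]
                    downstream = [x for x in g_ex if x[0] >= exon1_end + 50]
                    for x in downstream[:3] or g_ex[-1:]:
                        if x[0] >= exon1_end + 50:
                            exons.append(GenomicInterval(spec.chrom, x[0], x[1], "+"))
                    if l.kind == "upstream" and g.expressed[sp] \
                            and l.suppresses:
                        g.suppressed[sp] = True
                if len(exons) == 1:
                    gap = int(rng.integers(400, 900))
                    e2 = int(rng.integers(800, 1600))
                    exons.append(GenomicInterval(
                        spec.chrom, exon1_end + gap, exon1_end + gap + e2, "+"))
                loc = GenomicInterval(spec.chrom, exons[0].start,
                                      exons[-1].end, "+")
                t = Transcript(tid, loc, tuple(exons), fpkm=fpkm,
                               gene_id=l.target_gene)
            out.append(t)
            l.lit_span[sp] = (t.location.start, t.location.end)
            l.lit_id[sp] = tid
            rep_fpkm[GenomicInterval(spec.chrom, s, e, "+")] = fpkm
            # read coverage for the contribution ratio: deep and
            # proportional to FPKM on both sides
            g = gene_by_id.get(l.target_gene) if l.target_gene else None
            canon_cov = (g.fpkm[sp] * 10.0 if g is not None and not g.suppressed[sp]
                         else 0.0)
            cov[tid] = (fpkm * 10.0, fpkm * 10.0 + canon_cov)
        # canonical transcripts
        for g in truth.genes:
            if not g.expressed[sp] or g.suppressed[sp]:
                continue
            ex = tuple(GenomicInterval(spec.chrom, *fr.map_span(*x), "+")
                       for x in g.exons)
            loc = GenomicInterval(spec.chrom, ex[0].start, ex[-1].end, "+")
            out.append(Transcript(f"{sp}_{g.id}_canonical", loc, ex,
                                  fpkm=g.fpkm[sp], gene_id=g.id))
        # background FPKM over inactive repeats (below the active cutoff)
        for l in truth.ltrs:
            if sp in l.presence and not l.active.get(sp):
                s, e = fr.ltr_span(l.id)
                rep_fpkm[GenomicInterval(spec.chrom, s, e, "+")] = \
                    float(rng.uniform(0.0, 0.6))
        out.sort(key=lambda t: (t.location.start, t.id))
        transcripts[sp] = out
        repeat_fpkm[sp] = rep_fpkm
        coverage[sp] = cov
    return CohortTranscriptome(transcripts, repeat_fpkm, coverage)


# ---------------------------------------------------------------------------
# Methylome simulation

DEFAULT_TISSUES = ("oocyte", "sperm", "blastocyst")
ALL_TISSUES = ("oocyte", "sperm", "blastocyst", "biparental_blastocyst",
               "epiblast", "epiblast_tet_null")


def _transcribed_high_intervals(ann: CohortAnnotations, sp: str,
                                trans: CohortTranscriptome) -> list:
    """(start, end) spans receiving transcription-coupled methylation:
    each active unit trimmed by the promoter pad at its own 5' end."""
    spec = ann.spec
    fr = ann.frames[sp]
    pad = spec.promoter_pad
    spans = []
    for g in ann.truth.genes:
        if g.expressed[sp] and not g.suppressed[sp]:
            s, e = fr.map_span(*g.span)
            if e - s > pad:
                spans.append((s + pad, e))
    for l in ann.truth.ltrs:
        if l.active.get(sp) and sp in l.lit_span:
            s, e = l.lit_span[sp]
            if l.antisense:
                spans.append((s, e - pad)) if e - s > pad else None
            else:
                if e - s > pad:
                    spans.append((s + pad, e))
    for o in ann.truth.orphans:
        spans.append(fr.map_span(*o))
    return sorted(spans)


def _in_spans(pos: np.ndarray, spans: list) -> np.ndarray:
    if not spans:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def _species_cpg_positions(ann: CohortAnnotations, sp: str,
                           rng: np.random.Generator) -> np.ndarray:
    """Species-frame CpG positions: mapped ancestral background + CGI
    dense sites + sites internal to carried LTR insertions."""
    spec = ann.spec
    fr = ann.frames[sp]
    key = f"_cpg_cache_{sp}"
    cache = getattr(ann, "_cpg_cache", None)
    if cache is None:
        cache = {}
        ann._cpg_cache = cache
    if sp in cache:
        return cache[sp]
    anc = ann._ancestral_cpgs
    pos = [fr.map_points(anc)]
    for l in ann.truth.ltrs:
        if sp in l.presence:
            s, _e = fr.ltr_span(l.id)
            offs = ann._ltr_cpg_offsets[l.id]
            if len(offs):
                pos.append(s + offs)
    merged = np.unique(np.concatenate(pos))
    cache[sp] = merged
    return merged


def _prepare_cpg_geometry(ann: CohortAnnotations) -> None:
    spec = ann.spec
    rng = np.random.default_rng(spec.rng_seed + 2)
    L = spec.genome_length
    n_bg = int(L / spec.cpg_spacing)
    bg = np.sort(rng.choice(L - 2, size=n_bg, replace=False)) + 1
    dense = []
    for c in ann.truth.cgis:
        s, e = c.span
        dense.append(np.arange(s + 2, e - 2, spec.cgi_cpg_spacing))
    anc = np.unique(np.concatenate([bg] + dense))
    # keep CpGs off insertion anchors is not needed (points map cleanly)
    ann._ancestral_cpgs = anc
    offsets = {}
    for l in ann.truth.ltrs:
        offsets[l.id] = np.arange(10, l.length - 5, spec.ltr_cpg_spacing)
    ann._ltr_cpg_offsets = offsets


def simulate_methylomes(ann: CohortAnnotations, trans: CohortTranscriptome,
                        tissues: tuple = DEFAULT_TISSUES) -> dict:
    """Per-(species, tissue) MethTables under the transcription-coupled
    methylation model, plus retention/persistence draws recorded in the
    truth ledger. Returns {(species, tissue): MethTable}."""
    spec = ann.spec
    rng = np.random.default_rng(spec.rng_seed + 3)
    if not hasattr(ann, "_ancestral_cpgs"):
        _prepare_cpg_geometry(ann)

    conc = spec.beta_concentration
    out = {}
    for sp in spec.species:
        fr = ann.frames[sp]
        cpgs = _species_cpg_positions(ann, sp, rng)
        n = len(cpgs)
        merged_high = _merge_spans(_transcribed_high_intervals(ann, sp, trans))
        high = _in_spans(cpgs, merged_high)

        # record expected CGI classes + embedding in the truth ledger
        cgi_spans_sp = {}
        for c in ann.truth.cgis:
            s, e = fr.map_span(*c.span)
            cgi_spans_sp[c.id] = (s, e)
            covered = _span_covered((s, e), merged_high)
            c.expected_class[sp] = "hyper" if covered else "hypo"
            c.embedded_lit[sp] = None
            for l in ann.truth.ltrs:
                if l.active.get(sp) and sp in l.lit_span:
                    ls, le = l.lit_span[sp]
                    if ls <= s and e <= le:
                        c.embedded_lit[sp] = l.id
                        break
            if sp not in c.retention:
                if c.expected_class[sp] == "hyper":
                    p = (spec.retention_prob_lit if c.embedded_lit[sp]
                         else spec.retention_prob_other)
                    c.retention[sp] = ("retained" if rng.random() < p
                                       else "erased")
                else:
                    c.retention[sp] = "erased"

        in_cgi = _in_spans(cpgs, sorted(cgi_spans_sp.values()))
        base_mean = np.where(high, spec.m_high, spec.m_low)

        def draw_table(mean_p, tissue):
            a = np.maximum(mean_p * conc, 1e-3)
            b = np.maximum((1 - mean_p) * conc, 1e-3)
            p = rng.beta(a, b)
            if spec.mean_depth <= 0:
                depth = np.zeros(n, dtype=int)
            else:
                lam = rng.gamma(spec.depth_dispersion,
                                spec.mean_depth / spec.depth_dispersion, n)
                depth = rng.poisson(lam)
            meth = rng.binomial(depth, p)
            df = pd.DataFrame({
                "chrom": spec.chrom, "start": cpgs, "end": cpgs + 2,
                "meth": meth, "total": depth})
            out[(sp, tissue)] = MethTable(df)

        oocyte_mean = base_mean.copy()
        if "oocyte" in tissues:
            draw_table(oocyte_mean, "oocyte")
        if "sperm" in tissues or "biparental_blastocyst" in tissues:
            sperm_mean = np.where(in_cgi, spec.sperm_cgi, spec.sperm_high)
            if "sperm" in tissues:
                draw_table(sperm_mean, "sperm")

        def cgi_level(retained_ids):
            level = oocyte_mean * spec.blast_attenuation
            for c in ann.truth.cgis:
                s, e = cgi_spans_sp[c.id]
                mask = (cpgs >= s) & (cpgs < e)
                if c.id in retained_ids:
                    level[mask] = spec.retained_level
                else:
                    level[mask] = spec.erased_level
            return level

        retained = {c.id for c in ann.truth.cgis
                    if c.retention.get(sp) == "retained"}
        if "blastocyst" in tissues:
            draw_table(cgi_level(retained), "blastocyst")
        if "biparental_blastocyst" in tissues:
            maternal = cgi_level(retained)
            paternal = np.where(in_cgi, spec.sperm_cgi, spec.sperm_high)
            draw_table((maternal + paternal) / 2.0, "biparental_blastocyst")
        if "epiblast" in tissues or "epiblast_tet_null" in tissues:
            epi_retained = set()
            for c in ann.truth.cgis:
                if c.id in retained:
                    if rng.random() < spec.epiblast_erase_prob:
                        if rng.random() < spec.tet_sensitive_frac:
                            c.tet_sensitive = True
                    else:
                        epi_retained.add(c.id)
            if "epiblast" in tissues:
                draw_table(cgi_level(epi_retained), "epiblast")
            if "epiblast_tet_null" in tissues:
                tet_ids = epi_retained | {c.id for c in ann.truth.cgis
                                          if c.tet_sensitive}
                draw_table(cgi_level(tet_ids), "epiblast_tet_null")
    return out


def _merge_spans(spans: list) -> list:
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _span_covered(span: tuple, merged: list) -> bool:
    s, e = span
    for ms, me in merged:
        if ms <= s and e <= me:
            return True
    return False


def simulate_k36_tracks(ann: CohortAnnotations, trans: CohortTranscriptome,
                        bin_width: int = 200) -> dict:
    """Binned H3K36me3-like coverage per species: baseline noise plus a
    constant enrichment over transcribed territory."""
    spec = ann.spec
    rng = np.random.default_rng(spec.rng_seed + 4)
    tracks = {}
    for sp in spec.species:
        fr = ann.frames[sp]
        size = fr.length
        starts = np.arange(0, size, bin_width)
        mids = starts + bin_width // 2
        high = _in_spans(mids, _merge_spans(
            _transcribed_high_intervals(ann, sp, trans)))
        vals = rng.normal(1.0, 0.15, len(starts)) + np.where(high, 2.5, 0.0)
        tracks[sp] = pd.DataFrame({
            "chrom": spec.chrom, "start": starts,
            "end": np.minimum(starts + bin_width, size),
            "value": np.maximum(vals, 0.0)})
    return tracks


def k36_mean_over(track: pd.DataFrame, iv: GenomicInterval) -> float:
    sub = track[(track["chrom"] == iv.chrom) & (track["start"] < iv.end)
                & (track["end"] > iv.start)]
    if not len(sub):
        return float("nan")
    return float(sub["value"].mean())


# ---------------------------------------------------------------------------
# One-call cohort bundle

@dataclass
class SimulatedCohort:
    annotations: CohortAnnotations
    transcriptome: CohortTranscriptome
    methylomes: dict
    k36: dict

    @property
    def truth(self) -> SimTruth:
        return self.annotations.truth

    @property
    def spec(self) -> CohortSpec:
        return self.annotations.spec


def simulate_cohort(spec: CohortSpec,
                    tissues: tuple = DEFAULT_TISSUES,
                    with_k36: bool = True) -> SimulatedCohort:
    ann = simulate_annotations(spec)
    trans = simulate_transcriptome(ann)
    meth = simulate_methylomes(ann, trans, tissues=tissues)
    k36 = simulate_k36_tracks(ann, trans) if with_k36 else {}
    return SimulatedCohort(ann, trans, meth, k36)


# ---------------------------------------------------------------------------
# File emission (exact formats io_formats reads)

def emit_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the cohort as the text formats the pipeline consumes.

    Returns a manifest dict of written paths.
    """
    from . import io_formats as iof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    manifest: dict = {"species": {}, "chains": {}, "truth": None}
    for sp in spec.species:
        d = outdir / sp
        d.mkdir(exist_ok=True)
        ann = cohort.annotations.per_species[sp]
        iof.write_gtf_transcripts(ann.genes, d / "genes.gtf")
        iof.write_gtf_transcripts(cohort.transcriptome.transcripts[sp],
                                  d / "transcripts.gtf")
        iof.write_repeat_bed(ann.repeats, d / "repeats.bed")
        iof.write_bed(ann.cgis, d / "cgis.bed")
        entry = {"genes": str(d / "genes.gtf"),
                 "transcripts": str(d / "transcripts.gtf"),
                 "repeats": str(d / "repeats.bed"),
                 "cgis": str(d / "cgis.bed"), "meth": {}}
        for (s, tissue), table in cohort.methylomes.items():
            if s != sp:
                continue
            p = d / f"meth_{tissue}.bedGraph"
            iof.write_cpg_report(table, p)
            entry["meth"][tissue] = str(p)
        if sp in cohort.k36:
            p = d / "k36.bedGraph"
            cohort.k36[sp].to_csv(p, sep="\t", header=False, index=False)
            entry["k36"] = str(p)
        manifest["species"][sp] = entry
    for (a, b), chains in cohort.annotations.chains.items():
        p = outdir / f"{a}_to_{b}.chain"
        iof.write_chain(
            chains, p,
            source_sizes=cohort.annotations.per_species[a].chrom_sizes,
            target_sizes=cohort.annotations.per_species[b].chrom_sizes)
        manifest["chains"][f"{a}_to_{b}"] = str(p)
    truth_path = outdir / "truth.json"
    truth_path.write_text(cohort.truth.to_json())
    manifest["truth"] = str(truth_path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
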