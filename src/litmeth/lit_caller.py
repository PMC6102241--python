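"""Classification of assembled transcripts as LTR-initiated (LITs).

A transcript is LTR-initiated when its strand-aware 5' end falls inside
(or within an edge window of) an annotated LTR/ERV repeat. Accepted
calls are the Up and UpEdge categories; EInside (repeat internal to the
transcript without containing the TSS) is kept as a manual-inspection
tier only. Genic chimerism is called from exon sharing with annotated
genes plus the isoform-share rule (the LTR-driven isoform must carry
more than 10% of the gene's summed isoform expression to count as a
sense chimera).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    RepeatElement,
    Transcript,
    ValidationError,
    build_interval_index,
    query_index,
    query_point,
)

EDGE_WINDOW = 100  # bp around a repeat edge for the UpEdge call
MIN_ISOFORM_SHARE = 0.10  # strict: share must exceed 10%
ACTIVE_FPKM = 1.0  # strict: repeat FPKM must exceed 1


@dataclass
class LITCall:
    transcript: Transcript
    initiating_repeat: RepeatElement
    category: str  # {Up, UpEdge}
    contribution: float | None  # exon-1 vs first-canonical-exon coverage
    gene_overlap: str  # {sense-chimeric, antisense, intergenic}
    isoform_share: float | None
    gene_id: str | None = None
    flagged: bool = False  # degenerate-denominator or secondary evidence


def classify_transcript_start(t: Transcript, repeat_index: dict,
                              edge_window: int = EDGE_WINDOW):
    """Categorise the transcript 5' end against LTR repeats.

    Returns (category, repeat-or-None) with category one of Up, UpEdge,
    EInside, none. Up: the TSS lies strictly inside an LTR repeat and
    exon 1 extends 3' beyond it. UpEdge: the TSS is within
    ``edge_window`` bp of a repeat edge without being inside it.
    EInside: an LTR repeat overlaps the transcript without containing
    the TSS. When several repeats qualify, the one containing — else
    nearest to — the TSS wins.
    """
    if not t.exons:
        raise ValidationError(f"transcript {t.id} has no exons")
    tss = t.tss
    chrom = t.location.chrom

    containing = [r for r in query_point(repeat_index, chrom, tss) if r.is_ltr]
    if containing:
        rep = min(containing,
                  key=lambda r: (r.location.length, r.location.start))
        exon1 = t.first_exon
        if t.strand == "-":
            extends = exon1.start < rep.location.start
        else:
            extends = exon1.end > rep.location.end
        return ("Up" if extends else "EInside", rep)

    window = GenomicInterval(chrom, max(0, tss - edge_window),
                             tss + edge_window + 1)
    nearby = [r for r in query_index(repeat_index, window) if r.is_ltr]
    if nearby:
        rep = min(nearby, key=lambda r: min(abs(tss - r.location.start),
                                            abs(tss - (r.location.end - 1))))
        return ("UpEdge", rep)

    internal = [r for r in query_index(repeat_index, t.location) if r.is_ltr]
    if internal:
        rep = min(internal, key=lambda r: min(abs(tss - r.location.start),
                                              abs(tss - (r.location.end - 1))))
        return ("EInside", rep)
    return ("none", None)


def ltr_contribution(exon1_coverage: float, canonical_coverage: float):
    """Exon-1 (LTR) read coverage relative to the first canonical exon.

    Returns (value, flagged). The raw ratio exon1/canonical is reported
    when the canonical exon has coverage; a zero canonical denominator
    with positive LTR coverage yields 1.0 with a degenerate flag; both
    zero is undefined (NaN, flagged). Values are clipped to [0, 1] via
    ratio/(1 + ratio) only when the raw ratio exceeds 1.
    """
    if exon1_coverage < 0 or canonical_coverage < 0:
        raise ValidationError("coverage must be non-negative")
    if canonical_coverage == 0:
        if exon1_coverage == 0:
            return float("nan"), True
        return 1.0, True
    ratio = exon1_coverage / canonical_coverage
    if ratio > 1.0:
        ratio = ratio / (1.0 + ratio)
    return ratio, False


def isoform_share(t: Transcript, gene_isoforms: list) -> float:
    """LIT FPKM over the summed FPKM of the gene's isoforms."""
    total = sum(x.fpkm for x in gene_isoforms)
    if total == 0:
        return 1.0 if t.fpkm == 0 else 1.0
    return t.fpkm / total


def _gene_fpkm_totals(genes: list) -> dict:
    totals: dict[str, float] = {}
    for g in genes:
        gid = g.gene_id or g.id
        totals[gid] = totals.get(gid, 0.0) + g.fpkm
    return totals


def call_lits(transcripts: list, repeats: list, genes: list,
              min_share: float = MIN_ISOFORM_SHARE,
              edge_window: int = EDGE_WINDOW,
              coverage: dict | None = None) -> list:
    """Call LTR-initiated transcription units from assembled transcripts.

    Keeps transcripts whose 5' category is Up or UpEdge. gene_overlap is
    sense-chimeric when a non-first exon of the LIT shares >= 1 bp with
    an exon of a same-strand gene AND the LIT's isoform share of that
    gene strictly exceeds ``min_share``; antisense when the LIT overlaps
    a gene on the opposite strand; intergenic otherwise.

    ``coverage`` optionally maps transcript id -> (exon1 cov, first
    canonical exon cov) for the contribution ratio.
    """
    repeat_index = build_interval_index(repeats, key=lambda r: r.location)
    gene_exon_items = []
    for g in genes:
        for e in g.exons:
            gene_exon_items.append((e, g))
    exon_index = build_interval_index(gene_exon_items, key=lambda x: x[0])
    gene_index = build_interval_index(genes, key=lambda g: g.location)
    gene_totals = _gene_fpkm_totals(genes)

    calls = []
    for t in sorted(transcripts, key=lambda x: (x.location.chrom,
                                                x.location.start, x.id)):
        category, rep = classify_transcript_start(t, repeat_index,
                                                  edge_window=edge_window)
        if category not in ("Up", "UpEdge"):
            continue

        overlap = "intergenic"
        share = None
        gene_id = None
        sense_genes = set()
        for exon in t.exons[1:]:
            for e, g in query_index(exon_index, exon):
                if g.strand == t.strand and exon.overlap_bp(e) >= 1:
                    sense_genes.add(g.gene_id or g.id)
        # exon 1 extending into a downstream genic exon also counts,
        # but only the part beyond the repeat (the spliced-in gene side)
        if rep is not None and len(t.exons) == 1:
            for e, g in query_index(exon_index, t.first_exon):
                if g.strand == t.strand and t.first_exon.overlap_bp(e) >= 1 \
                        and not rep.location.contains(e):
                    sense_genes.add(g.gene_id or g.id)
        def share_of(gid: str) -> float:
            # denominator covers all of the gene's isoforms, the
            # LTR-driven one included
            denom = gene_totals.get(gid, 0.0) + t.fpkm
            return t.fpkm / denom if denom > 0 else 1.0

        chosen = None
        for gid in sorted(sense_genes):
            s = share_of(gid)
            if s > min_share:
                chosen = (gid, s)
                break
        if chosen:
            overlap = "sense-chimeric"
            gene_id, share = chosen
        else:
            for g in query_index(gene_index, t.location):
                if g.strand != t.strand and g.strand in "+-" and t.strand in "+-":
                    overlap = "antisense"
                    gene_id = g.gene_id or g.id
                    break
            if overlap == "intergenic" and sense_genes:
                # sense overlap below the share floor stays non-chimeric;
                # record the share for reporting
                share = share_of(sorted(sense_genes)[0])

        contribution, flagged = None, False
        if coverage and t.id in coverage:
            contribution, flagged = ltr_contribution(*coverage[t.id])
        calls.append(LITCall(t, rep, category, contribution, overlap,
                             share, gene_id=gene_id, flagged=flagged))
    return calls


def active_ltr_scan(repeats: list, repeat_fpkm: dict,
                    min_fpkm: float = ACTIVE_FPKM) -> list:
    """All annotated LTR/ERV repeats with transcript level > ``min_fpkm``.

    ``repeat_fpkm`` maps repeat location -> FPKM over the repeat span.
    Returns (repeat, fpkm) pairs, strict threshold.
    """
    out = []
    for r in repeats:
        if not r.is_ltr:
            continue
        fpkm = repeat_fpkm.get(r.location, 0.0)
        if fpkm > min_fpkm:
            out.append((r, fpkm))
    return out


def class_composition(active: list) -> dict:
    """Fraction of active elements per repeat class; sums to 1."""
    counts: dict[str, int] = {}
    for r, _ in active:
        counts[r.repeat_class] = counts.get(r.repeat_class, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def rescue_lits_by_domain(transcripts: list, hyper_domains: list,
                          repeats: list, primary_calls: list,
                          boundary_window: int = 1000) -> list:
    """Secondary-evidence LIT candidates from hypermethylated domain edges.

    Flags transcripts whose 5' end lies within ``boundary_window`` bp of
    a hyper-domain 5' boundary and whose TSS overlaps an LTR repeat.
    Candidates never duplicate primary Up/UpEdge calls.
    """
    primary_ids = {c.transcript.id for c in primary_calls}
    repeat_index = build_interval_index(repeats, key=lambda r: r.location)
    out = []
    for t in transcripts:
        if t.id in primary_ids:
            continue
        tss = t.tss
        in_ltr = any(r.is_ltr for r in
                     query_point(repeat_index, t.location.chrom, tss))
        if not in_ltr:
            continue
        for d in hyper_domains:
            if d.meth_class != "hyper" or d.span.chrom != t.location.chrom:
                continue
            edge = d.span.end - 1 if t.strand == "-" else d.span.start
            if d.span.contains_point(tss) and abs(tss - edge) <= boundary_window:
                out.append(t)
                break
    return out


def calls_to_frame(calls: list) -> pd.DataFrame:
    return pd.DataFrame({
        "transcript": [c.transcript.id for c in calls],
        "chrom": [c.transcript.location.chrom for c in calls],
        "tss": [c.transcript.tss for c in calls],
        "strand": [c.transcript.strand for c in calls],
        "repeat_class": [c.initiating_repeat.repeat_class if c.initiating_repeat
                         else "." for c in calls],
        "subfamily": [c.initiating_repeat.subfamily if c.initiating_repeat
                      else "." for c in calls],
        "category": [c.category for c in calls],
        "contribution": [np.nan if c.contribution is None else c.contribution
                         for c in calls],
        "isoform_share": [np.nan if c.isoform_share is None else c.isoform_share
                          for c in calls],
        "gene_overlap": [c.gene_overlap for c in calls],
        "gene_id": [c.gene_id or "." for c in calls],
    })
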