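"""Cross-species coordinate projection and syntenic unit construction.

Intervals are projected through UCSC-style chain alignments (liftover),
fixed-width bins are paired across genomes by the reciprocal-best rule,
and CpG-island orthology is scored by post-projection identity
(Jaccard by default). Three-species units are assembled through a hub
genome, mirroring mouse-centered chain sets.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .core import ChainAlignment, GenomicInterval, Transcript, ValidationError

DEFAULT_MIN_MATCH = 0.5
IDENTITY_THRESHOLD = 0.5  # strict: identity > 0.5 is syntenic
PROMOTER_WINDOW = 500
INTRAGENIC_TSS_DISTANCE = 500
GENE_TAIL = 2000  # genic territory extends TSS..TTS + 2 kb


@dataclass
class SyntenicUnit:
    """A bin or CGI with per-species placement and methylation."""

    unit_kind: str  # {bin, cgi}
    intervals: dict  # species -> GenomicInterval
    mean_meth: dict = field(default_factory=dict)  # species -> fraction or NaN
    identity: float | None = None  # cgi only
    context: dict = field(default_factory=dict)  # species -> context label


# ---------------------------------------------------------------------------
# Liftover

class ChainSet:
    """Chains for one directed species pair, indexed by source chromosome."""

    def __init__(self, chains: list):
        self.by_chrom: dict[str, list] = {}
        for c in chains:
            self.by_chrom.setdefault(c.source_interval.chrom, []).append(c)

    def __iter__(self):
        for chains in self.by_chrom.values():
            yield from chains


def _project_ranges(iv: GenomicInterval, chains) -> list:
    """All (target_chrom, target_start, target_end, n_bases) aligned runs
    of ``iv`` through ``chains``."""
    runs = []
    chain_list = chains.by_chrom.get(iv.chrom, []) if isinstance(chains, ChainSet) \
        else [c for c in chains if c.source_interval.chrom == iv.chrom]
    for c in chain_list:
        s0 = c.source_interval.start
        t0 = c.target_interval.start
        t_chrom = c.target_interval.chrom
        for s_off, t_off, ln in c.blocks:
            bs, be = s0 + s_off, s0 + s_off + ln
            lo, hi = max(iv.start, bs), min(iv.end, be)
            if lo < hi:
                shift = t0 + t_off - bs
                runs.append((t_chrom, lo + shift, hi + shift, hi - lo))
    return runs


def liftover(iv: GenomicInterval, chains,
             min_match: float = DEFAULT_MIN_MATCH) -> GenomicInterval | None:
    """Project ``iv`` to the chain target genome.

    Returns the minimal target interval covering every aligned base, or
    None when the aligned fraction of ``iv`` falls below ``min_match``
    or the aligned bases land on more than one target chromosome.
    """
    runs = _project_ranges(iv, chains)
    if not runs:
        return None
    chroms = {r[0] for r in runs}
    if len(chroms) > 1:
        return None
    mapped = sum(r[3] for r in runs)
    if mapped / iv.length < min_match or mapped == 0:
        return None
    start = min(r[1] for r in runs)
    end = max(r[2] for r in runs)
    return GenomicInterval(chroms.pop(), start, end, iv.strand)


def mapped_fraction(iv: GenomicInterval, chains) -> float:
    """Fraction of ``iv`` bases aligned through any chain block."""
    runs = _project_ranges(iv, chains)
    return sum(r[3] for r in runs) / iv.length


# ---------------------------------------------------------------------------
# Reciprocal-best syntenic bins

def _best_overlap_bin(target_iv: GenomicInterval, index: dict):
    """The bin with strictly greatest overlap with ``target_iv``."""
    entry = index.get(target_iv.chrom)
    if entry is None:
        return None
    bins, starts = entry
    # bins are sorted and non-overlapping; candidates lie in a bisect window
    lo = bisect_left(starts, target_iv.start)
    if lo > 0 and bins[lo - 1].end > target_iv.start:
        lo -= 1
    hi = bisect_left(starts, target_iv.end)
    best, best_ov, tied = None, 0, False
    for b in bins[lo:hi]:
        ov = b.overlap_bp(target_iv)
        if ov > best_ov:
            best, best_ov, tied = b, ov, False
        elif ov == best_ov and ov > 0:
            tied = True
    if best is None or tied:
        return None
    return best


def _index_bins(bins: list) -> dict:
    by_chrom: dict[str, list] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = {}
    for chrom, v in by_chrom.items():
        v.sort()
        out[chrom] = (v, [b.start for b in v])
    return out


def reciprocal_best_pairs(bins_a: list, bins_b: list, chains_ab,
                          chains_ba, min_match: float = DEFAULT_MIN_MATCH) -> list:
    """Reciprocal-best (a, b) bin pairs between two species.

    a pairs with b iff a's projection overlaps b more than any other
    B-bin AND b's back-projection overlaps a more than any other A-bin.
    The result is a partial matching: no bin occurs in two pairs.
    """
    idx_b = _index_bins(bins_b)
    idx_a = _index_bins(bins_a)
    pairs = []
    claimed_b = set()
    for a in bins_a:
        proj = liftover(a, chains_ab, min_match=min_match)
        if proj is None:
            continue
        b = _best_overlap_bin(proj, idx_b)
        if b is None or b in claimed_b:
            continue
        back = liftover(b, chains_ba, min_match=min_match)
        if back is None:
            continue
        if _best_overlap_bin(back, idx_a) == a:
            pairs.append((a, b))
            claimed_b.add(b)
    return pairs


def reciprocal_best_units(bins_by_species: dict, chains: dict,
                          hub: str, meth_by_species: dict | None = None,
                          min_match: float = DEFAULT_MIN_MATCH) -> list:
    """Multi-species syntenic bin units via reciprocal-best through a hub.

    ``bins_by_species``: species -> list of GenomicInterval (passing bins).
    ``chains``: (src, dst) -> ChainSet/list for both directions between the
    hub and every other species. ``meth_by_species``: optional species ->
    {interval: mean_meth}; units lacking a methylation value in any
    species are dropped (coverage-complete requirement).
    """
    others = [s for s in bins_by_species if s != hub]
    pair_maps = {}
    for sp in others:
        pairs = reciprocal_best_pairs(
            bins_by_species[hub], bins_by_species[sp],
            chains[(hub, sp)], chains[(sp, hub)], min_match=min_match)
        pair_maps[sp] = dict(pairs)
    units = []
    for hub_bin in bins_by_species[hub]:
        intervals = {hub: hub_bin}
        ok = True
        for sp in others:
            partner = pair_maps[sp].get(hub_bin)
            if partner is None:
                ok = False
                break
            intervals[sp] = partner
        if not ok:
            continue
        unit = SyntenicUnit("bin", intervals)
        if meth_by_species is not None:
            meths = {}
            complete = True
            for sp, iv in intervals.items():
                m = meth_by_species[sp].get(iv)
                if m is None or m != m:  # NaN check
                    complete = False
                    break
                meths[sp] = m
            if not complete:
                continue
            unit.mean_meth = meths
        units.append(unit)
    return units


# ---------------------------------------------------------------------------
# CGI identity

def cgi_identity(cgi_a: GenomicInterval, cgi_b: GenomicInterval, chains,
                 mode: str = "jaccard",
                 min_match: float = DEFAULT_MIN_MATCH) -> float:
    """Orthology identity between two CGIs after projecting a onto b's genome.

    Modes: ``jaccard`` (intersection over union, default), ``smaller``
    (intersection over the smaller interval), ``reciprocal`` (minimum of
    the two overlap fractions). Returns 0 when the projection fails.
    """
    proj = liftover(cgi_a, chains, min_match=min_match)
    if proj is None or proj.chrom != cgi_b.chrom:
        return 0.0
    ov = proj.overlap_bp(cgi_b)
    if ov == 0:
        return 0.0
    if mode == "jaccard":
        union = proj.length + cgi_b.length - ov
        return ov / union
    if mode == "smaller":
        return ov / min(proj.length, cgi_b.length)
    if mode == "reciprocal":
        return min(ov / proj.length, ov / cgi_b.length)
    raise ValidationError(f"unknown identity mode {mode!r}")


def match_syntenic_cgis(cgis_a: list, cgis_b: list, chains,
                        mode: str = "jaccard",
                        threshold: float = IDENTITY_THRESHOLD) -> list:
    """(cgi_a, cgi_b, identity) for pairs with identity strictly above
    ``threshold``; each a maps to its best-identity b."""
    idx_b: dict[str, list] = {}
    for b in cgis_b:
        idx_b.setdefault(b.chrom, []).append(b)
    out = []
    for a in cgis_a:
        proj = liftover(a, chains)
        if proj is None:
            continue
        best, best_id = None, 0.0
        for b in idx_b.get(proj.chrom, []):
            if not proj.overlaps(b):
                continue
            ident = cgi_identity(a, b, chains, mode=mode)
            if ident > best_id:
                best, best_id = b, ident
        if best is not None and best_id > threshold:
            out.append((a, best, best_id))
    return out


# ---------------------------------------------------------------------------
# Genomic context

def gene_spans(genes: list) -> list:
    """Genic territory per gene: TSS..TTS extended 2 kb past the TTS."""
    spans = []
    for g in genes:
        loc = g.location
        if loc.strand == "-":
            spans.append(GenomicInterval(loc.chrom, max(0, loc.start - GENE_TAIL),
                                         loc.end, loc.strand))
        else:
            spans.append(GenomicInterval(loc.chrom, loc.start,
                                         loc.end + GENE_TAIL, loc.strand))
    return spans


def is_genic(iv: GenomicInterval, genes: list) -> bool:
    """Overlap with any annotated gene span (TSS to TTS + 2 kb)."""
    return any(iv.overlaps(s) for s in gene_spans(genes))


def classify_context(iv: GenomicInterval, genes: list,
                     tss_window: int = PROMOTER_WINDOW) -> str:
    """CGI context: promoter, intragenic, proximal, or intergenic.

    promoter: overlaps a TSS +/- ``tss_window``; intragenic: inside a
    gene body and more than 500 bp from every TSS; proximal: inside a
    gene but within 500 bp of a TSS without touching the promoter
    window (possible when tss_window < 500); intergenic otherwise.
    """
    in_body = False
    min_tss_dist = None
    for g in genes:
        loc = g.location
        if loc.chrom != iv.chrom:
            continue
        tss = g.tss
        lo = max(0, tss - tss_window)
        if iv.overlaps(GenomicInterval(iv.chrom, lo, tss + tss_window + 1)):
            return "promoter"
        dist = max(iv.start - tss, tss - (iv.end - 1), 0)
        if min_tss_dist is None or dist < min_tss_dist:
            min_tss_dist = dist
        if iv.overlaps(loc):
            in_body = True
    if in_body:
        if min_tss_dist is not None and min_tss_dist > INTRAGENIC_TSS_DISTANCE:
            return "intragenic"
        return "proximal"
    return "intergenic"
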