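"""Headline comparative classifications.

Multi-species Venn partitions of hypermethylated syntenic units,
bp-weighted attribution of hypermethylated domains to LITs and genes,
methylated-CGI (meCGI) labelling by LIT embedding, the cross-species
expression Z statistic, strain-differential CGI calling, and pairwise
profile correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError, build_interval_index, query_index
from .synteny_map import SyntenicUnit

HYPER_THRESHOLD = 0.70  # strict: mean methylation must exceed 70%
DELTA_MET_THRESHOLD = 0.40  # strict: strain delta must exceed 40 points
MECGI_MIN_CPGS = 6  # ">5 CpGs covered" read as at least 6


@dataclass
class VennPartition:
    counts: dict  # frozenset of species -> unit count
    total: int  # units hypermethylated in >= 1 species
    excluded: int  # units dropped for missing methylation
    stratum: str = "all"

    def fraction(self, species_set) -> float:
        if self.total == 0:
            return 0.0
        return self.counts.get(frozenset(species_set), 0) / self.total

    def singletons(self) -> int:
        return sum(v for k, v in self.counts.items() if len(k) == 1)


@dataclass
class DomainAttribution:
    fractions: dict  # class -> bp-weighted fraction of hyper territory
    bp: dict  # class -> total bp
    total_bp: int


def venn_partition(units: list, hyper_threshold: float = HYPER_THRESHOLD,
                   stratum: str = "all",
                   lit_overlap: dict | None = None) -> VennPartition:
    """Partition syntenic units by which species show hypermethylation.

    A unit is hyper in species S iff its mean methylation in S strictly
    exceeds ``hyper_threshold``. Units hyper in no species are excluded
    from the partition (but not counted as ``excluded``, which tracks
    missing-methylation drops). ``stratum`` of "lit" / "non-lit" filters
    by ``lit_overlap`` (unit id -> bool, any-species LIT overlap).
    """
    counts: dict = {}
    total = 0
    excluded = 0
    for i, u in enumerate(units):
        if lit_overlap is not None:
            is_lit = lit_overlap.get(i, False)
            if stratum == "lit" and not is_lit:
                continue
            if stratum == "non-lit" and is_lit:
                continue
        if not u.mean_meth or any(m != m for m in u.mean_meth.values()):
            excluded += 1
            continue
        hyper = frozenset(sp for sp, m in u.mean_meth.items()
                          if m > hyper_threshold)
        if not hyper:
            continue
        counts[hyper] = counts.get(hyper, 0) + 1
        total += 1
    return VennPartition(counts, total, excluded, stratum=stratum)


def unit_lit_overlap(units: list, lits_by_species: dict) -> dict:
    """unit index -> True when the unit overlaps a called LIT in any species."""
    indexes = {
        sp: build_interval_index(
            [c.transcript.location for c in calls], key=lambda iv: iv)
        for sp, calls in lits_by_species.items()
    }
    out = {}
    for i, u in enumerate(units):
        hit = False
        for sp, iv in u.intervals.items():
            if sp in indexes and query_index(indexes[sp], iv):
                hit = True
                break
        out[i] = hit
    return out


def attribute_domains(hyper_domains: list, lits: list,
                      gene_spans: list) -> DomainAttribution:
    """bp-weighted attribution of hypermethylated territory.

    Each hyper domain is classed by any-overlap (>= 1 bp) with called
    LIT transcript spans and/or genic spans (TSS..TTS + 2 kb); fractions
    are sums of domain lengths per class over total hyper territory.
    """
    hyper = [d for d in hyper_domains if d.meth_class == "hyper"]
    if not hyper:
        raise ValidationError("no hyper territory to attribute")
    lit_idx = build_interval_index(
        [c.transcript.location for c in lits], key=lambda iv: iv)
    gene_idx = build_interval_index(gene_spans, key=lambda iv: iv)
    bp = {"lit_only": 0, "gene_only": 0, "lit_and_gene": 0, "neither": 0}
    for d in hyper:
        has_lit = bool(query_index(lit_idx, d.span))
        has_gene = bool(query_index(gene_idx, d.span))
        if has_lit and has_gene:
            key = "lit_and_gene"
        elif has_lit:
            key = "lit_only"
        elif has_gene:
            key = "gene_only"
        else:
            key = "neither"
        bp[key] += d.span.length
    total = sum(bp.values())
    return DomainAttribution({k: v / total for k, v in bp.items()}, bp, total)


# ---------------------------------------------------------------------------
# meCGI classification

def subfamily_group(subfamily: str) -> str:
    """MTA / MT (non-MTA) / LTR grouping of an initiating repeat."""
    if subfamily.startswith("MTA"):
        return "MTA"
    if subfamily.startswith(("MTB", "MTC", "MTD", "MTE", "MT2")) or subfamily == "MT":
        return "MT"
    return "LTR"


@dataclass
class MeCGILabel:
    cgi: dict  # species -> GenomicInterval
    meth: dict  # species -> mean methylation
    hyper_in: frozenset  # species with meth > threshold
    specificity: str  # {shared, species-specific, none}
    lit_embedded_in: frozenset  # species where the CGI lies inside a LIT
    subfamily_class: str | None  # MTA / MT / LTR for the initiating repeat


def classify_mecgi(cgi_units: list, lits_by_species: dict,
                   hyper_threshold: float = HYPER_THRESHOLD) -> list:
    """Label syntenic CGIs by methylation sharing and LIT embedding.

    A CGI is an meCGI in species S when its mean methylation there
    strictly exceeds ``hyper_threshold``; it is LIT-embedded in S when
    its interval lies within the transcript span of a called LIT. CGIs
    with undefined methylation in any species are skipped (the CpG-count
    floor is applied upstream when methylation is computed).
    """
    lit_idx = {
        sp: build_interval_index(calls, key=lambda c: c.transcript.location)
        for sp, calls in lits_by_species.items()
    }
    out = []
    for u in cgi_units:
        if not u.mean_meth or any(m != m for m in u.mean_meth.values()):
            continue
        hyper = frozenset(sp for sp, m in u.mean_meth.items()
                          if m > hyper_threshold)
        if not hyper:
            spec = "none"
        elif len(hyper) == len(u.mean_meth):
            spec = "shared"
        else:
            spec = "species-specific"
        embedded = set()
        subfam = None
        for sp, iv in u.intervals.items():
            for call in query_index(lit_idx.get(sp, {}), iv):
                if call.transcript.location.contains(iv):
                    embedded.add(sp)
                    if sp in hyper or subfam is None:
                        subfam = subfamily_group(
                            call.initiating_repeat.subfamily)
                    break
        out.append(MeCGILabel(u.intervals, dict(u.mean_meth), hyper, spec,
                              frozenset(embedded),
                              subfam if embedded else None))
    return out


# ---------------------------------------------------------------------------
# Expression comparison

def expression_zscore(fpkm_a: float, fpkm_b: float) -> float:
    """Cross-species expression Z: (A - B) / (sqrt(A + B) + 0.01)."""
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValidationError("FPKM must be non-negative")
    return (fpkm_a - fpkm_b) / (np.sqrt(fpkm_a + fpkm_b) + 0.01)


# ---------------------------------------------------------------------------
# Strain-differential calling

def strain_differential(meth_a: dict, meth_b: dict, k36_a: dict, k36_b: dict,
                        d_meth: float = DELTA_MET_THRESHOLD,
                        k36_quantile: float = 0.75) -> pd.DataFrame:
    """Strain-specific hypermethylation with concordant H3K36me3 excess.

    ``meth_*`` and ``k36_*`` map unit -> methylation fraction /
    depth-normalised coverage over shared-coordinate units. A unit is
    strain-A-specific iff meth_A - meth_B strictly exceeds ``d_meth``
    AND the H3K36me3 difference has the same sign and exceeds the
    ``k36_quantile`` quantile of the genome-wide |delta| distribution
    (and symmetrically for strain B).
    """
    units = [u for u in meth_a if u in meth_b and u in k36_a and u in k36_b
             and meth_a[u] == meth_a[u] and meth_b[u] == meth_b[u]]
    dk = np.array([k36_a[u] - k36_b[u] for u in units])
    thresh = float(np.quantile(np.abs(dk), k36_quantile)) if len(dk) else 0.0
    rows = []
    for u, dkv in zip(units, dk):
        dm = meth_a[u] - meth_b[u]
        call = "none"
        if dm > d_meth and dkv > 0 and dkv > thresh:
            call = "strain_a"
        elif -dm > d_meth and dkv < 0 and -dkv > thresh:
            call = "strain_b"
        rows.append({"unit": u, "delta_meth": dm, "delta_k36": dkv,
                     "call": call})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation

def correlate_profiles(profiles: dict) -> pd.DataFrame:
    """Pairwise Pearson correlation over complete-case shared units.

    ``profiles``: name -> aligned 1-D array. Entries with fewer than 3
    complete-case units are NaN.
    """
    names = list(profiles)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        x = np.asarray(profiles[a], dtype=float)
        y = np.asarray(profiles[b], dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            r = np.nan
        else:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat
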