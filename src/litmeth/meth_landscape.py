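"""Binned methylation scores, changepoint domain segmentation, and
genome-fraction summaries.

The methylome of a growing oocyte is bimodal: transcribed territory is
de novo methylated to high levels while untranscribed territory stays
low. Domains of constant mean methylation are recovered from binned
per-CpG fractions by exact penalized changepoint detection (PELT with a
squared-error cost), then classified as hypomethylated (< lo),
intermediate, or hypermethylated (> hi); the default class bounds are
0.30 and 0.70 with strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, MethTable, Transcript, ValidationError

DEFAULT_LO = 0.30
DEFAULT_HI = 0.70

#: coverage rule for high-resolution libraries: >=5 CpGs each at >=5 reads
DEFAULT_MIN_CPGS = 5
DEFAULT_MIN_DEPTH = 5
#: low-resolution rule for sparse libraries: >=3 CpGs at >=1 read
LOWRES_MIN_CPGS = 3
LOWRES_MIN_DEPTH = 1


@dataclass(frozen=True)
class BinScore:
    bin: GenomicInterval
    mean_meth: float
    n_cpgs_pass: int
    passes_filter: bool


@dataclass(frozen=True)
class MethDomain:
    span: GenomicInterval
    mean_meth: float
    meth_class: str
    n_bins: int


def classify_region(value: float, lo: float = DEFAULT_LO,
                    hi: float = DEFAULT_HI) -> str:
    """Hypo/intermediate/hyper call with strict boundaries.

    value < lo -> hypo; value > hi -> hyper; values equal to a boundary
    fall in the intermediate class.
    """
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"methylation value {value} outside [0, 1]")
    if lo >= hi:
        raise ValidationError("class bounds require lo < hi")
    if value < lo:
        return "hypo"
    if value > hi:
        return "hyper"
    return "intermediate"


def score_bins(meth: MethTable, bin_width: int = 1000,
               min_cpgs: int = DEFAULT_MIN_CPGS,
               min_depth: int = DEFAULT_MIN_DEPTH,
               chrom_sizes: dict | None = None) -> list:
    """Tile each chromosome with fixed-width bins and score methylation.

    A bin's mean is the unweighted mean of per-CpG fractional methylation
    over CpGs with depth >= ``min_depth``; bins with fewer than
    ``min_cpgs`` such CpGs fail the coverage filter and are excluded from
    all downstream denominators.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    out: list[BinScore] = []
    for chrom in sorted(set(meth.chroms()) | set(chrom_sizes or {})):
        sub = meth.for_chrom(chrom)
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        if size is None:
            if not len(sub):
                continue
            size = int(sub["end"].max())
        n_bins = int(np.ceil(size / bin_width))
        pos = sub["start"].to_numpy()
        depth_ok = sub["total"].to_numpy() >= min_depth
        frac = np.where(sub["total"].to_numpy() > 0,
                        sub["meth"].to_numpy() / np.maximum(sub["total"].to_numpy(), 1),
                        np.nan)
        idx = np.minimum(pos // bin_width, n_bins - 1) if len(pos) else pos
        counts = np.zeros(n_bins, dtype=int)
        sums = np.zeros(n_bins, dtype=float)
        if len(pos):
            np.add.at(counts, idx[depth_ok], 1)
            np.add.at(sums, idx[depth_ok], frac[depth_ok])
        for b in range(n_bins):
            iv = GenomicInterval(chrom, b * bin_width,
                                 min((b + 1) * bin_width, size))
            ok = counts[b] >= min_cpgs
            mean = sums[b] / counts[b] if ok else float("nan")
            out.append(BinScore(iv, mean, int(counts[b]), ok))
    return out


# ---------------------------------------------------------------------------
# Changepoint segmentation (PELT, squared-error cost)

def _l2_cost_factory(y: np.ndarray):
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i: int, j: int) -> float:
        # sum of squared deviations from the segment mean over y[i:j];
        # floored at 0 so float cancellation cannot beat the penalty
        n = j - i
        s = cs[j] - cs[i]
        return max(0.0, (cs2[j] - cs2[i]) - s * s / n)

    return cost


def default_penalty(y: np.ndarray) -> float:
    """MBIC-like penalty 2*log(n)*sigma^2.

    sigma is estimated robustly from the median absolute deviation of
    first differences (scaled by 1.4826/sqrt(2)), so flat stretches with
    occasional jumps do not inflate it.
    """
    n = len(y)
    if n < 2:
        return 1.0
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    if sigma <= 0:
        sigma = np.std(d) / np.sqrt(2.0)
    # floor above accumulated float error in the cumulative-sum cost so a
    # noiseless constant series is never split
    return max(2.0 * np.log(n) * sigma * sigma, 1e-10 * n)


def pelt_changepoints(y: np.ndarray, penalty: float | None = None,
                      min_segment: int = 1) -> list:
    """Exact penalized changepoint positions by PELT.

    Minimizes sum of per-segment squared errors plus ``penalty`` per
    changepoint, with every segment at least ``min_segment`` points long.
    Returns the sorted interior breakpoints (segment start indices,
    excluding 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if min_segment < 1:
        raise ValidationError("min_segment must be >= 1")
    if n < 2 * min_segment:
        return []
    if penalty is None:
        penalty = default_penalty(y)
    cost = _l2_cost_factory(y)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(min_segment, n + 1):
        best, arg = np.inf, 0
        for s in candidates:
            if t - s < min_segment:
                continue
            val = F[s] + cost(s, t) + penalty
            if val < best:
                best, arg = val, s
        F[t] = best
        prev[t] = arg
        # PELT pruning: s can never be optimal again if it already loses
        # to the current best by more than the (non-negative) penalty.
        candidates = [s for s in candidates
                      if t - s < min_segment or F[s] + cost(s, t) <= F[t]]
        candidates.append(t - min_segment + 1)
        candidates = sorted(set(c for c in candidates if c <= t))
    bkps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bkps.append(s)
        t = s
    return sorted(bkps)


def segment_domains(bins: list, penalty: float | None = None,
                    min_segment: int = 1, lo: float = DEFAULT_LO,
                    hi: float = DEFAULT_HI) -> list:
    """Segment passing bins into constant-mean methylation domains.

    Non-passing bins are bridged: segmentation runs on the ordered series
    of passing bins per chromosome and the genomic gaps reappear inside
    the output spans. Each domain carries the mean of its bins and the
    hypo/intermediate/hyper class of that mean.
    """
    out: list[MethDomain] = []
    by_chrom: dict[str, list] = {}
    for b in bins:
        if b.passes_filter:
            by_chrom.setdefault(b.bin.chrom, []).append(b)
    for chrom in sorted(by_chrom):
        chrom_bins = sorted(by_chrom[chrom], key=lambda b: b.bin.start)
        y = np.array([b.mean_meth for b in chrom_bins])
        bkps = pelt_changepoints(y, penalty=penalty, min_segment=min_segment)
        edges = [0] + bkps + [len(y)]
        for i, j in zip(edges, edges[1:]):
            seg = chrom_bins[i:j]
            mean = float(np.mean(y[i:j]))
            span = GenomicInterval(chrom, seg[0].bin.start, seg[-1].bin.end)
            out.append(MethDomain(span, mean,
                                  classify_region(min(max(mean, 0.0), 1.0), lo, hi),
                                  n_bins=j - i))
    return out


def genome_fraction_by_class(items: list) -> dict:
    """bp-weighted genome fraction per methylation class.

    Accepts MethDomains or passing BinScores; fractions are over passing
    territory only and sum to 1.
    """
    lengths: dict[str, int] = {}
    for it in items:
        if isinstance(it, MethDomain):
            cls, ln = it.meth_class, it.span.length
        else:
            if not it.passes_filter:
                continue
            cls, ln = classify_region(min(max(it.mean_meth, 0.0), 1.0)), it.bin.length
        lengths[cls] = lengths.get(cls, 0) + ln
    total = sum(lengths.values())
    if total == 0:
        return {}
    return {cls: ln / total for cls, ln in lengths.items()}


# ---------------------------------------------------------------------------
# Region summaries and anchored profiles

def gene_body_methylation(gene: Transcript, meth: MethTable,
                          min_depth: int = 1, min_cpgs: int = 1) -> float:
    """Mean CpG methylation over the TSS..TTS span; NaN when uncovered."""
    return meth.mean_over(gene.location, min_depth=min_depth, min_cpgs=min_cpgs)


def profile_around(anchors: list, meth: MethTable, flank: int = 20000,
                   n_bins: int = 40) -> np.ndarray:
    """Mean methylation in ``n_bins`` windows across anchor +/- ``flank``.

    ``anchors`` are (chrom, position, strand) triples; rows of the
    returned matrix are strand-oriented so downstream of the anchor is
    rightward. Windows with no covered CpG are NaN.
    """
    mat = np.full((len(anchors), n_bins), np.nan)
    width = 2 * flank / n_bins
    for r, (chrom, pos, strand) in enumerate(anchors):
        sub = meth.for_chrom(chrom)
        sub = sub[(sub["start"] >= pos - flank) & (sub["start"] < pos + flank)
                  & (sub["total"] > 0)]
        if not len(sub):
            continue
        rel = sub["start"].to_numpy() - (pos - flank)
        idx = np.minimum((rel / width).astype(int), n_bins - 1)
        frac = sub["meth"].to_numpy() / sub["total"].to_numpy()
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        np.add.at(sums, idx, frac)
        np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            row = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if strand == "-":
            row = row[::-1]
        mat[r] = row
    return mat


def bins_to_frame(bins: list) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [b.bin.chrom for b in bins],
        "start": [b.bin.start for b in bins],
        "end": [b.bin.end for b in bins],
        "mean_meth": [b.mean_meth for b in bins],
        "n_cpgs_pass": [b.n_cpgs_pass for b in bins],
        "passes_filter": [b.passes_filter for b in bins],
    })


def domains_to_frame(domains: list) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [d.span.chrom for d in domains],
        "start": [d.span.start for d in domains],
        "end": [d.span.end for d in domains],
        "mean_meth": [d.mean_meth for d in domains],
        "meth_class": [d.meth_class for d in domains],
        "n_bins": [d.n_bins for d in domains],
    })
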