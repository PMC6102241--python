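"""Readers and writers for the genomic text formats the pipeline touches.

Supported: bedGraph-style CpG reports, BED3/6, GTF, RepeatMasker .out,
UCSC chain, and TSV result tables. All conversion between 1-based
(GTF, .out) and the internal 0-based half-open convention happens here
and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    ChainAlignment,
    FormatError,
    GenomicInterval,
    LTR_CLASS_MAP,
    MethTable,
    RepeatElement,
    Transcript,
    ValidationError,
    merge_dyads,
)


def normalize_chrom(name: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Apply the configured chromosome alias map ('1' -> 'chr1' etc.)."""
    if alias_map and name in alias_map:
        return alias_map[name]
    return name


# ---------------------------------------------------------------------------
# CpG reports

def read_cpg_report(path, merge_dyads_flag: bool = True,
                    alias_map: Mapping[str, str] | None = None) -> MethTable:
    """Read a bedGraph-style CpG report into a MethTable.

    Expected columns: chrom, start, end, methylated count, unmethylated
    count (Bismark coverage-file dialect: counts, not percentages).
    When ``merge_dyads_flag`` is set, plus/minus strand calls at adjacent
    positions are summed into one symmetric-CpG record.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns, got {len(parts)}")
            try:
                chrom = normalize_chrom(parts[0], alias_map)
                start, end = int(parts[1]), int(parts[2])
                meth, unmeth = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, start, end, meth, meth + unmeth))
    if not rows:
        return MethTable.empty()
    df = pd.DataFrame(rows, columns=list(MethTable.COLUMNS))
    if merge_dyads_flag:
        df = merge_dyads(df)
    return MethTable(df)


def write_cpg_report(meth: MethTable, path) -> None:
    df = meth.df
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "meth": df["meth"], "unmeth": df["total"] - df["meth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# RepeatMasker

_RMSK_HEADER = re.compile(r"^\s*(SW|score|\s*$)")

#: trailing species tag ("MTA_Mm") or internal-region tag ("MERVL-int")
_SUBFAM_SUFFIX = re.compile(r"(?:-int|_[A-Z][a-z]{1,2})$")


def base_subfamily(name: str) -> str:
    """Strip species/-int suffixes from a RepeatMasker repeat name."""
    return _SUBFAM_SUFFIX.sub("", name)


def _split_class_family(token: str) -> tuple[str, str]:
    """Map a RepeatMasker class/family token to (internal class, family)."""
    if "/" in token:
        cls, fam = token.split("/", 1)
    else:
        cls, fam = token, token
    if cls in LTR_CLASS_MAP.values():
        # already an internal class name (round-trip of our own BED output)
        return cls, fam
    # longest key first so ERVL-MaLR is not swallowed by ERVL
    for key in sorted(LTR_CLASS_MAP, key=len, reverse=True):
        if fam.startswith(key) or cls == key:
            return LTR_CLASS_MAP[key], fam
    if cls == "LTR":
        # LTR class with an unrecognised family
        for key, mapped in LTR_CLASS_MAP.items():
            if key in fam:
                return mapped, fam
    return "other", fam


def read_repeatmasker(path, alias_map: Mapping[str, str] | None = None) -> list:
    """Parse RepeatMasker .out (1-based inclusive) or BED6+ repeat files.

    Returns a list of RepeatElement with 0-based half-open coordinates.
    The subfamily is the repeat name column; the class is mapped through
    the class/family token.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [ln for ln in lines if ln.strip()]
    if not body:
        return []
    first = body[0].split()
    is_out = body[0].lstrip().startswith(("SW", "score")) or (
        len(first) >= 11 and first[0].isdigit() and not first[1].isdigit())
    if is_out:
        return _read_rmsk_out(body, str(path), alias_map)
    if len(first) >= 4 and first[1].isdigit() and first[2].isdigit():
        return _read_repeat_bed(body, str(path), alias_map)
    raise FormatError(f"{path}: unrecognised repeat annotation format")


def _read_rmsk_out(lines, src, alias_map):
    out = []
    for ln in lines:
        parts = ln.split()
        if not parts or _RMSK_HEADER.match(ln) or parts[0] in ("SW", "score"):
            continue
        if not parts[0].replace(".", "").isdigit():
            continue  # header / continuation
        if len(parts) < 11:
            raise FormatError(f"{src}: short RepeatMasker row: {ln!r}")
        chrom = normalize_chrom(parts[4], alias_map)
        start1, end1 = int(parts[5]), int(parts[6])
        strand = "+" if parts[8] == "+" else "-"
        subfam = base_subfamily(parts[9])
        cls, fam = _split_class_family(parts[10])
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        out.append(RepeatElement(iv, cls, subfam, annotation_source=src))
    return out


def _read_repeat_bed(lines, src, alias_map):
    out = []
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        chrom = normalize_chrom(parts[0], alias_map)
        start, end = int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else "."
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        # name is 'class/family/subfamily' or 'family/subfamily'
        bits = name.split("/")
        if len(bits) >= 2:
            cls, fam = _split_class_family("/".join(bits[:-1]))
            subfam = base_subfamily(bits[-1])
        else:
            cls, fam, subfam = "other", name, base_subfamily(name)
        iv = GenomicInterval(chrom, start, end, strand)
        out.append(RepeatElement(iv, cls, subfam, annotation_source=src))
    return out


def write_repeat_bed(repeats: Iterable[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            name = f"{r.repeat_class}/{r.subfamily}"
            strand = r.location.strand if r.location.strand != "." else "+"
            fh.write(f"{r.location.chrom}\t{r.location.start}\t{r.location.end}"
                     f"\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path, alias_map: Mapping[str, str] | None = None,
                         fpkm_attr: str = "FPKM") -> list:
    """Read transcript models (exon features) from a GTF file.

    GTF is 1-based inclusive; intervals are converted to 0-based
    half-open. Exons are grouped by transcript_id and ordered 5'->3'.
    FPKM is taken from the ``fpkm_attr`` attribute when present.
    """
    exons: dict[str, list] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = parts[:9]
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            iv = GenomicInterval(normalize_chrom(chrom, alias_map),
                                 int(start1) - 1, int(end1),
                                 strand if strand in "+-" else ".")
            exons.setdefault(tid, []).append(iv)
            m = meta.setdefault(tid, {"gene_id": attr.get("gene_id"), "fpkm": 0.0})
            if fpkm_attr in attr:
                m["fpkm"] = float(attr[fpkm_attr])
    out = []
    for tid, ivs in exons.items():
        ivs = sorted(ivs, key=lambda e: e.start)
        strand = ivs[0].strand
        if strand == "-":
            ordered = tuple(reversed(ivs))
        else:
            ordered = tuple(ivs)
        loc = GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end, strand)
        out.append(Transcript(tid, loc, ordered,
                              fpkm=meta[tid]["fpkm"], gene_id=meta[tid]["gene_id"]))
    out.sort(key=lambda t: (t.location.chrom, t.location.start, t.id))
    return out


def write_gtf_transcripts(transcripts: Iterable[Transcript], path,
                          source: str = "litmeth") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            strand = t.strand if t.strand != "." else "+"
            attrs = f'gene_id "{t.gene_id or t.id}"; transcript_id "{t.id}"; FPKM "{t.fpkm:.6g}";'
            for iv in sorted(t.exons, key=lambda e: e.start):
                fh.write(f"{iv.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}"
                         f"\t.\t{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path, alias_map: Mapping[str, str] | None = None) -> list:
    """Read BED3/BED6 into GenomicInterval list (names discarded)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(GenomicInterval(normalize_chrom(parts[0], alias_map),
                                       int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Iterable[str] | None = None,
              scores: Iterable[float] | None = None) -> None:
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand if iv.strand != "." else "+")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain

def read_chain(path, alias_map: Mapping[str, str] | None = None) -> list:
    """Parse a UCSC chain file into ChainAlignment objects.

    Chain grammar: header line
    ``chain score tName tSize tStrand tStart tEnd qName qSize qStrand
    qStart qEnd id`` followed by block lines ``size [dt dq]``; the final
    block line carries only ``size``. The chain's target (tName) side is
    the projection *source* here, matching liftover usage where the chain
    file is named source-to-destination.
    """
    chains = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if not ln or ln.startswith("#"):
            i += 1
            continue
        parts = ln.split()
        if parts[0] != "chain":
            raise FormatError(f"{path}: expected chain header, got {ln!r}")
        if len(parts) < 12:
            raise FormatError(f"{path}: short chain header")
        (score, t_name, _t_size, t_strand, t_start, t_end,
         q_name, _q_size, q_strand, q_start, q_end) = parts[1:12]
        chain_id = parts[12] if len(parts) > 12 else ""
        if t_strand != "+" or q_strand != "+":
            raise FormatError(f"{path}: only forward-strand chains supported")
        blocks = []
        s_off = t_off = 0
        i += 1
        while i < len(lines) and lines[i]:
            bits = lines[i].split()
            size = int(bits[0])
            blocks.append((s_off, t_off, size))
            if len(bits) == 1:
                i += 1
                break
            if len(bits) != 3:
                raise FormatError(f"{path}: malformed block line {lines[i]!r}")
            s_off += size + int(bits[1])
            t_off += size + int(bits[2])
            i += 1
        src = GenomicInterval(normalize_chrom(t_name, alias_map),
                              int(t_start), int(t_end))
        tgt = GenomicInterval(normalize_chrom(q_name, alias_map),
                              int(q_start), int(q_end))
        last_s, last_t, last_len = blocks[-1]
        if last_s + last_len != src.length or last_t + last_len != tgt.length:
            raise FormatError(
                f"{path}: chain {chain_id or score} blocks do not tile header spans")
        chains.append(ChainAlignment(src, tgt, tuple(blocks),
                                     chain_id=chain_id, score=float(score)))
    return chains


def write_chain(chains: Iterable[ChainAlignment], path,
                source_sizes: Mapping[str, int] | None = None,
                target_sizes: Mapping[str, int] | None = None) -> None:
    source_sizes = source_sizes or {}
    target_sizes = target_sizes or {}
    with open(path, "w") as fh:
        for c in chains:
            s, t = c.source_interval, c.target_interval
            s_size = source_sizes.get(s.chrom, s.end)
            t_size = target_sizes.get(t.chrom, t.end)
            fh.write(f"chain {int(c.score)} {s.chrom} {s_size} + {s.start} {s.end} "
                     f"{t.chrom} {t_size} + {t.start} {t.end} {c.chain_id or 1}\n")
            for j, (s_off, t_off, ln) in enumerate(c.blocks):
                if j + 1 < len(c.blocks):
                    ns, nt, _ = c.blocks[j + 1]
                    fh.write(f"{ln}\t{ns - (s_off + ln)}\t{nt - (t_off + ln)}\n")
                else:
                    fh.write(f"{ln}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
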