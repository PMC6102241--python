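"""End-to-end orchestration: config, staged run, result bundle.

``run_all`` consumes a manifest of per-species input files (the layout
``synthetic_cohort.emit_cohort`` writes, or equivalently prepared real
data), runs domain segmentation, LIT calling, syntenic-unit
construction, Venn partitioning, domain attribution, meCGI labelling,
and persistence classification, and writes plain TSV/BED/JSON outputs
so any stage can be rerun standalone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import meth_landscape as ml
from . import lit_caller as lc
from . import synteny_map as sm
from . import comparative_epigenome as ce
from . import persistence as ps
from .core import GenomicInterval, ValidationError


@dataclass
class RunConfig:
    """Declarative run configuration; every threshold is explicit."""

    species: list
    hub: str
    manifest: dict  # species -> {genes, transcripts, repeats, cgis, meth{}, k36}
    chains: dict  # "A_to_B" -> path
    outdir: str
    seed: int = 0
    bin_width: int = 1000
    min_cpgs: int = ml.DEFAULT_MIN_CPGS
    min_depth: int = ml.DEFAULT_MIN_DEPTH
    lo: float = ml.DEFAULT_LO
    hi: float = ml.DEFAULT_HI
    hyper_threshold: float = ce.HYPER_THRESHOLD
    min_share: float = lc.MIN_ISOFORM_SHARE
    edge_window: int = lc.EDGE_WINDOW
    identity_mode: str = "jaccard"
    identity_threshold: float = sm.IDENTITY_THRESHOLD
    min_match: float = sm.DEFAULT_MIN_MATCH
    cgi_min_cpgs: int = ce.MECGI_MIN_CPGS
    cgi_min_depth: int = 1
    persistence_mode: str = "pg_mode"
    t_retain: float = ps.T_RETAIN
    t_sperm: float = ps.T_SPERM
    t_blast: float = ps.T_BLAST
    d_meth: float = ce.DELTA_MET_THRESHOLD
    k36_quantile: float = 0.75
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_cohort_manifest(cls, manifest_path, outdir,
                             hub: str | None = None, **overrides) -> "RunConfig":
        with open(manifest_path) as fh:
            m = json.load(fh)
        species = sorted(m["species"])
        return cls(species=species, hub=hub or species[0],
                   manifest=m["species"], chains=m["chains"],
                   outdir=str(outdir), **overrides)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(entry: dict, key: str, sp: str):
    if key not in entry or not Path(entry[key]).exists():
        raise ValidationError(f"manifest entry {sp}/{key} missing or not found")
    return entry[key]


@dataclass
class RunResult:
    domains: dict
    lits: dict
    units: list
    venn: dict
    attribution: dict
    mecgi: pd.DataFrame
    persistence_calls: list
    outputs: dict


def run_all(config: RunConfig) -> RunResult:
    """Run every stage and write the result bundle to config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    checks: dict = {}

    per_sp = {}
    for sp in config.species:
        entry = config.manifest[sp]
        meth_paths = entry.get("meth", {})
        if "oocyte" not in meth_paths:
            raise ValidationError(f"manifest entry {sp}/meth/oocyte missing")
        meth = iof.read_cpg_report(_require(meth_paths, "oocyte", sp))
        genes = iof.read_gtf_transcripts(_require(entry, "genes", sp))
        transcripts = iof.read_gtf_transcripts(_require(entry, "transcripts", sp))
        repeats = iof.read_repeatmasker(_require(entry, "repeats", sp))
        cgis = iof.read_bed(_require(entry, "cgis", sp))
        for key in ("genes", "transcripts", "repeats", "cgis"):
            checks[f"{sp}/{key}"] = _checksum(entry[key])
        per_sp[sp] = dict(meth=meth, genes=genes, transcripts=transcripts,
                          repeats=repeats, cgis=cgis, meth_paths=meth_paths)

    # --- stage 1: domains ------------------------------------------------
    domains = {}
    bins = {}
    for sp in config.species:
        d = per_sp[sp]
        b = ml.score_bins(d["meth"], bin_width=config.bin_width,
                          min_cpgs=config.min_cpgs, min_depth=config.min_depth)
        doms = ml.segment_domains(b, lo=config.lo, hi=config.hi)
        bins[sp] = b
        domains[sp] = doms
        path = outdir / f"domains_{sp}.bed"
        iof.write_bed([x.span for x in doms], path,
                      names=[x.meth_class for x in doms],
                      scores=[int(round(x.mean_meth * 1000)) for x in doms])
        outputs[f"domains_{sp}"] = str(path)

    # --- stage 2: LIT calls ----------------------------------------------
    lits = {}
    for sp in config.species:
        d = per_sp[sp]
        calls = lc.call_lits(d["transcripts"], d["repeats"], d["genes"],
                             min_share=config.min_share,
                             edge_window=config.edge_window)
        lits[sp] = calls
        path = outdir / f"lits_{sp}.tsv"
        iof.write_tsv(lc.calls_to_frame(calls), path)
        outputs[f"lits_{sp}"] = str(path)

    # --- stage 3: syntenic units + Venn ----------------------------------
    chains = {}
    for key, path in config.chains.items():
        a, b = key.split("_to_")
        chains[(a, b)] = sm.ChainSet(iof.read_chain(path))
    bin_ivs = {sp: [x.bin for x in bins[sp] if x.passes_filter]
               for sp in config.species}
    bin_meth = {sp: {x.bin: x.mean_meth for x in bins[sp] if x.passes_filter}
                for sp in config.species}
    units = sm.reciprocal_best_units(bin_ivs, chains, config.hub,
                                     meth_by_species=bin_meth,
                                     min_match=config.min_match)
    upath = outdir / "syntenic_units.tsv"
    iof.write_tsv(pd.DataFrame([
        {f"{sp}_{f}": getattr(u.intervals[sp], f)
         for sp in config.species for f in ("chrom", "start", "end")}
        | {f"{sp}_meth": u.mean_meth.get(sp) for sp in config.species}
        for u in units]), upath)
    outputs["syntenic_units"] = str(upath)

    lit_overlap = ce.unit_lit_overlap(units, lits)
    venn = {}
    for stratum in ("all", "lit", "non-lit"):
        part = ce.venn_partition(units, hyper_threshold=config.hyper_threshold,
                                 stratum=stratum, lit_overlap=lit_overlap)
        venn[stratum] = {
            "counts": {"".join(sorted(k)): v for k, v in part.counts.items()},
            "total_hyper": part.total, "excluded": part.excluded,
            "input_units": len(units),
        }
    vpath = outdir / "venn.json"
    vpath.write_text(json.dumps(venn, indent=1, sort_keys=True))
    outputs["venn"] = str(vpath)

    # --- stage 4: hyper-domain attribution -------------------------------
    attribution = {}
    for sp in config.species:
        spans = sm.gene_spans(per_sp[sp]["genes"])
        try:
            att = ce.attribute_domains(domains[sp], lits[sp], spans)
            attribution[sp] = att.fractions
        except ValidationError:
            attribution[sp] = {}
    apath = outdir / "attribution.tsv"
    iof.write_tsv(pd.DataFrame(
        [{"species": sp} | fr for sp, fr in sorted(attribution.items())]),
        apath)
    outputs["attribution"] = str(apath)

    # --- stage 5: syntenic CGIs + meCGI labels ---------------------------
    cgi_units = build_cgi_units(per_sp, chains, config)
    labels = ce.classify_mecgi(cgi_units, lits,
                               hyper_threshold=config.hyper_threshold)
    mecgi = pd.DataFrame([
        {"hub_chrom": l.cgi[config.hub].chrom,
         "hub_start": l.cgi[config.hub].start,
         "hub_end": l.cgi[config.hub].end,
         "specificity": l.specificity,
         "hyper_in": ",".join(sorted(l.hyper_in)) or ".",
         "lit_embedded_in": ",".join(sorted(l.lit_embedded_in)) or ".",
         "subfamily_class": l.subfamily_class or "."}
        | {f"{sp}_meth": l.meth.get(sp) for sp in config.species}
        for l in labels])
    mpath = outdir / "mecgi.tsv"
    iof.write_tsv(mecgi, mpath)
    outputs["mecgi"] = str(mpath)

    # --- stage 6: persistence (hub species tissues) -----------------------
    persistence_calls = []
    hub_meths = per_sp[config.hub]["meth_paths"]
    blast_key = ("blastocyst" if config.persistence_mode == "pg_mode"
                 else "biparental_blastocyst")
    if blast_key in hub_meths:
        tissue_tables = {"oocyte": per_sp[config.hub]["meth"]}
        for tissue in (blast_key, "sperm", "epiblast", "epiblast_tet_null"):
            if tissue in hub_meths:
                tissue_tables[tissue] = iof.read_cpg_report(hub_meths[tissue])
        hub_lit_index = {l.cgi[config.hub]: (config.hub in l.lit_embedded_in)
                         for l in labels}
        meth_by_tissue = {}
        for tissue, table in tissue_tables.items():
            key = "blastocyst" if tissue == blast_key else tissue
            meth_by_tissue[key] = {
                cgi: table.mean_over(cgi, min_depth=config.cgi_min_depth,
                                     min_cpgs=config.cgi_min_cpgs)
                for cgi in hub_lit_index}
        persistence_calls = ps.classify_persistence_table(
            sorted(hub_lit_index), meth_by_tissue,
            mode=config.persistence_mode, t_retain=config.t_retain,
            t_sperm=config.t_sperm, t_blast=config.t_blast)
        ppath = outdir / "persistence.tsv"
        iof.write_tsv(ps.calls_to_frame(persistence_calls), ppath)
        outputs["persistence"] = str(ppath)
        table = ps.persistence_by_lit(persistence_calls, hub_lit_index)
        tpath = outdir / "persistence_by_lit.tsv"
        table.to_csv(tpath, sep="\t")
        outputs["persistence_by_lit"] = str(tpath)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "parameters": asdict(config),
        "input_checksums": checks,
        "outputs": outputs,
        "n_units": len(units),
        "n_cgi_units": len(cgi_units),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return RunResult(domains, lits, units, venn, attribution, mecgi,
                     persistence_calls, outputs)


def build_cgi_units(per_sp: dict, chains: dict, config: RunConfig) -> list:
    """Syntenic CGI units: hub CGIs matched to each partner species by
    identity above the configured threshold, with per-species mean
    methylation under the CGI coverage rule."""
    hub = config.hub
    others = [sp for sp in config.species if sp != hub]
    matches = {}
    for sp in others:
        pairs = sm.match_syntenic_cgis(
            per_sp[hub]["cgis"], per_sp[sp]["cgis"], chains[(hub, sp)],
            mode=config.identity_mode, threshold=config.identity_threshold)
        matches[sp] = {a: (b, ident) for a, b, ident in pairs}
    units = []
    for cgi in sorted(per_sp[hub]["cgis"]):
        intervals = {hub: cgi}
        idents = []
        ok = True
        for sp in others:
            hit = matches[sp].get(cgi)
            if hit is None:
                ok = False
                break
            intervals[sp] = hit[0]
            idents.append(hit[1])
        if not ok:
            continue
        meths = {
            sp: per_sp[sp]["meth"].mean_over(
                intervals[sp], min_depth=config.cgi_min_depth,
                min_cpgs=config.cgi_min_cpgs)
            for sp in config.species}
        u = sm.SyntenicUnit("cgi", intervals, meths,
                            identity=min(idents) if idents else None)
        for sp in config.species:
            u.context[sp] = sm.classify_context(intervals[sp],
                                                per_sp[sp]["genes"])
        units.append(u)
    return units
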