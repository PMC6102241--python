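"""Post-fertilization fate of oocyte-methylated CGIs.

Two maternal-origin inferences are kept as named presets:

* ``pg_mode`` — maternal-only material (parthenogenetic blastocyst or
  maternal-allele ICM): retained iff blastocyst methylation stays above
  45%.
* ``biparental_mode`` — biparental tissue (human blastocyst/placenta):
  a maternal-DMR candidate iff sperm is essentially unmethylated (< 1%)
  while the biparental tissue keeps > 30%, so the remaining methylation
  must sit on the maternal genome.

All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ValidationError

T_OOCYTE = 0.70
T_RETAIN = 0.45
T_SPERM = 0.01
T_BLAST = 0.30


@dataclass
class PersistenceCall:
    cgi: object
    meth: dict  # tissue -> fraction (oocyte, sperm, blastocyst, epiblast...)
    fate: str  # {retained, erased, maternal_dmr_candidate, unclassifiable}
    tet_sensitive: bool | None = None


def classify_persistence(cgi, meth: dict, mode: str = "pg_mode",
                         t_oo: float = T_OOCYTE, t_retain: float = T_RETAIN,
                         t_sperm: float = T_SPERM, t_blast: float = T_BLAST,
                         tet_margin: float = 0.20) -> PersistenceCall:
    """Classify one oocyte-methylated CGI's post-fertilization fate.

    ``meth`` maps tissue names to methylation fractions; required keys
    are ``oocyte`` plus ``blastocyst`` (pg_mode: PG blastocyst or
    maternal-allele ICM; biparental_mode: biparental blastocyst or
    placenta, with ``sperm`` also required). Optional ``epiblast`` and
    ``epiblast_tet_null`` set the TET-sensitivity annotation when the
    TET-null profile exceeds wild type by ``tet_margin``.
    """
    for tissue, v in meth.items():
        if v == v and not (0.0 <= v <= 1.0):
            raise ValidationError(f"{tissue} methylation {v} outside [0, 1]")
    oo = meth.get("oocyte")
    if oo is None or oo != oo:
        return PersistenceCall(cgi, meth, "unclassifiable")
    if not oo > t_oo:
        return PersistenceCall(cgi, meth, "unclassifiable")

    blast = meth.get("blastocyst")
    if mode == "pg_mode":
        if blast is None or blast != blast:
            fate = "unclassifiable"
        elif blast > t_retain:
            fate = "retained"
        else:
            fate = "erased"
    elif mode == "biparental_mode":
        sperm = meth.get("sperm")
        if blast is None or blast != blast or sperm is None or sperm != sperm:
            fate = "unclassifiable"
        elif sperm < t_sperm and blast > t_blast:
            fate = "maternal_dmr_candidate"
        else:
            fate = "erased"
    else:
        raise ValidationError(f"unknown persistence mode {mode!r}")

    tet = None
    wt, ko = meth.get("epiblast"), meth.get("epiblast_tet_null")
    if wt is not None and ko is not None and wt == wt and ko == ko:
        tet = (ko - wt) > tet_margin
    return PersistenceCall(cgi, meth, fate, tet_sensitive=tet)


def classify_persistence_table(cgis: list, meth_by_tissue: dict,
                               mode: str = "pg_mode", **kwargs) -> list:
    """Vectorised wrapper: ``meth_by_tissue`` maps tissue -> {cgi: meth}."""
    calls = []
    for cgi in cgis:
        meth = {t: vals.get(cgi, float("nan"))
                for t, vals in meth_by_tissue.items()}
        calls.append(classify_persistence(cgi, meth, mode=mode, **kwargs))
    return calls


def persistence_by_lit(calls: list, lit_embedded: dict,
                       lit_privacy: dict | None = None) -> pd.DataFrame:
    """Cross-tabulate fate x LIT embedding (x LIT privacy).

    ``lit_embedded``: cgi -> bool; ``lit_privacy``: cgi -> "shared" /
    "private" for LIT-embedded CGIs. Row/column sums conserve the
    classified input.
    """
    rows = []
    for c in calls:
        embedded = lit_embedded.get(c.cgi, False)
        if embedded:
            privacy = (lit_privacy or {}).get(c.cgi, "shared")
            col = f"lit_{privacy}"
        else:
            col = "non_lit"
        rows.append({"fate": c.fate, "group": col})
    df = pd.DataFrame(rows)
    if not len(df):
        return pd.DataFrame()
    table = df.groupby(["fate", "group"]).size().unstack(fill_value=0)
    return table


def calls_to_frame(calls: list) -> pd.DataFrame:
    tissues = sorted({t for c in calls for t in c.meth})
    data = {"cgi": [str(c.cgi) for c in calls], "fate": [c.fate for c in calls]}
    for t in tissues:
        data[t] = [c.meth.get(t, float("nan")) for c in calls]
    data["tet_sensitive"] = [c.tet_sensitive for c in calls]
    return pd.DataFrame(data)
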