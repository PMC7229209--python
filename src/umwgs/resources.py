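"""Loaders for the bundled reference tables.

The signature matrices shipped with the package are synthetic stand-ins with
the qualitative features relevant to uveal melanoma (a flat clock-like
signature, an NpCpG deamination signature, two UV dipyrimidine signatures and
a CC>TT-dominated doublet signature).  COSMIC v3 files in the standard TSV
dialects are accepted wherever a signature matrix is taken.
"""

from __future__ import annotations

from importlib import resources as _ir

import numpy as np
import pandas as pd

_DATA = _ir.files("umwgs") / "data"


def _read(name: str) -> pd.DataFrame:
    with _ir.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def load_signature_matrix(path=None, kind: str = "sbs") -> pd.DataFrame:
    """Read a COSMIC-format signature matrix (classes x signatures).

    Accepts both the single ``Type`` column dialect (``A[C>A]A``) and the
    two-column ``Type``/``Subtype`` dialect (``C>A`` + ``ACA``).  With no
    path, returns the bundled synthetic matrix for *kind* (``sbs``/``dbs``).
    Columns are renormalised to sum to one.
    """
    if path is None:
        name = {
            "sbs": "signatures_sbs96_synthetic.tsv",
            "dbs": "signatures_dbs78_synthetic.tsv",
        }[kind]
        df = _read(name)
    else:
        df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "subtype" in cols:  # two-column dialect: Type "C>A", Subtype "ACA"
        sub = df[cols["subtype"]].astype(str)
        typ = df[cols["type"]].astype(str)
        labels = sub.str[0] + "[" + typ + "]" + sub.str[2]
        df = df.drop(columns=[cols["type"], cols["subtype"]])
        df.index = labels
    else:
        df = df.set_index(cols["type"])
    df.index.name = "Type"
    mat = df.astype(float)
    if (mat.to_numpy() < 0).any():
        raise ValueError("signature matrix contains negative entries")
    colsums = mat.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("signature matrix contains an all-zero column")
    return mat / colsums


def arm_table() -> pd.DataFrame:
    """GRCh37 cytoband-derived chromosome-arm coordinates (1-based, closed)."""
    return _read("arms_grch37.tsv")


def gene_loci() -> pd.DataFrame:
    """GRCh37 whole-gene envelopes for the uveal-melanoma genes of interest."""
    return _read("gene_loci_grch37.tsv")


def hotspot_panel() -> pd.DataFrame:
    """Default rescue panel: the recurrent Gαq-pathway / splicing / translation
    hotspots (GNAQ p.48/p.183/p.209, GNA11 p.183/p.209, SF3B1 p.625/p.666/p.700,
    EIF1AX codons 1-20, PLCB4 p.630, CYSLTR2 p.129)."""
    df = _read("hotspot_panel_grch37.tsv")
    if df["pos"].duplicated().any() and df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate panel positions")
    return df


def chromosome_lengths() -> dict[str, int]:
    arms = arm_table()
    return {str(c): int(g["end"].max()) for c, g in arms.groupby("chrom")}


def panel_site_keys(panel: pd.DataFrame | None = None) -> list[str]:
    """Stable ``chrom:pos:ref>alt`` keys for the panel positions."""
    if panel is None:
        panel = hotspot_panel()
    return [
        f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}" for r in panel.itertuples(index=False)
    ]
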