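"""Readers and writers for the flat-file interchange formats.

Tables travel as TSV; mutations can additionally be round-tripped through a
minimal VCF (CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO with SAMPLE, CTX, GENE,
PCHANGE, CLASS, AC, DP tags).  All coordinates are 1-based with closed
intervals.  Floats are written with fixed precision so a rerun with the same
seed is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MutationRecord, SegmentProfile

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide or dinucleotide context class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Functional consequence">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Variant read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read count">
##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Germline variant">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_table(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_mutations_vcf(mutations: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for r in mutations.itertuples(index=False):
            ctx = getattr(r, "context", None)
            info = [f"SAMPLE={r.sample}"]
            if isinstance(ctx, str):
                info.append(f"CTX={ctx}")
            if getattr(r, "gene", ""):
                info.append(f"GENE={r.gene}")
                info.append(f"PCHANGE={r.protein_change}")
            info.append(f"CLASS={r.consequence}")
            info.append(f"AC={int(r.alt_count)};DP={int(r.total_count)}")
            if bool(getattr(r, "germline", False)):
                info.append("GERMLINE")
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )


def read_mutations_vcf(path) -> pd.DataFrame:
    """Parse a minimal mutation VCF back into the flat table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            rows.append(
                {
                    "sample": info.get("SAMPLE", ""),
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else "",
                    "context": info.get("CTX", None),
                    "gene": info.get("GENE", ""),
                    "protein_change": info.get("PCHANGE", ""),
                    "consequence": info.get("CLASS", "silent"),
                    "alt_count": int(info.get("AC", 0)),
                    "total_count": int(info.get("DP", 0)),
                    "germline": bool(info.get("GERMLINE", False)),
                }
            )
    return pd.DataFrame(rows)


def mutations_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    out = []
    for r in df.itertuples(index=False):
        ctx = getattr(r, "context", None)
        if isinstance(ctx, float) and math.isnan(ctx):
            ctx = None
        out.append(
            MutationRecord(
                sample_id=str(r.sample),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                context=ctx,
                gene=str(getattr(r, "gene", "") or ""),
                protein_change=str(getattr(r, "protein_change", "") or ""),
                consequence=str(getattr(r, "consequence", "silent")),
                alt_count=int(getattr(r, "alt_count", 0)),
                total_count=int(getattr(r, "total_count", 0)),
                germline=bool(getattr(r, "germline", False)),
            )
        )
    return out


def segment_profiles(
    segments: pd.DataFrame, purity_ploidy: pd.DataFrame
) -> dict[str, SegmentProfile]:
    """Assemble per-sample ``SegmentProfile`` objects from the two tables."""
    pp = purity_ploidy.set_index("sample")
    out = {}
    for sample, grp in segments.groupby("sample", sort=False):
        if sample not in pp.index:
            raise ValueError(f"sample {sample} missing from purity/ploidy table")
        out[str(sample)] = SegmentProfile(
            str(sample),
            grp.drop(columns=["sample"]).reset_index(drop=True),
            float(pp.loc[sample, "purity"]),
            float(pp.loc[sample, "ploidy"]),
        )
    return out


def validate_segment_table(segments: pd.DataFrame, path: str = "<segments>") -> None:
    """Raise a format error naming the offending line of a segment table."""
    required = ["sample", "chrom", "startpos", "endpos", "nMajor", "nMinor"]
    missing = [c for c in required if c not in segments.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("startpos", "endpos", "nMajor", "nMinor"):
        bad = pd.to_numeric(segments[col], errors="coerce").isna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # 1-based incl. header
            raise ValueError(f"{path}: line {line}: non-numeric value in {col!r}")


def write_cohort(tables, outdir) -> dict[str, Path]:
    """Write all simulated cohort tables (TSV + mutation VCF) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("mutations", "segments", "purity_ploidy", "pileups", "clinical", "truth"):
        df = getattr(tables, name)
        paths[name] = outdir / f"{name}.tsv"
        write_table(df, paths[name])
    paths["vcf"] = outdir / "mutations.vcf"
    write_mutations_vcf(tables.mutations, paths["vcf"])
    return paths
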