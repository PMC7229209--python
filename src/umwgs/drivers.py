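"""Driver-gene annotation: Gαq-pathway hotspots, double hits and TP53 scores.

Nearly every uveal melanoma carries exactly one activating mutation in the
Gαq pathway (GNAQ, GNA11, PLCB4 or CYSLTR2); these are mutually exclusive
except for the known co-occurrence of PLCB4 p.D630 with the minor p.R183
hotspot of GNAQ/GNA11.  Tumour suppressors (BAP1, TP53, RPL5) are inactivated
by double hits: a mutation plus loss of heterozygosity (LOH), or two
mutations on opposite alleles.  Relative allele representation of two
mutations in one gene is assessed with a two-sided Fisher's exact test on
their read counts.  TP53 missense variants are classified from three
published scoring systems consumed as inputs: PHANTM (~0 for benign
polymorphisms, ~1 for recurrent hotspots), the relative fitness score RFS
(mean -2.50 for synonymous, 0.42 for truncating variants) and FATHMM
(> 0.5 deleterious).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .resources import gene_loci
from .types import MutationRecord

#: Consequences that count as loss of function.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice", "sv_breakpoint"})

#: Gαq-pathway hotspot codons per gene.
GQ_HOTSPOTS = {
    "GNAQ": {48, 183, 209},
    "GNA11": {183, 209},
    "PLCB4": {630},
    "CYSLTR2": {129},
}

PHANTM_CUTOFF = 0.5  # scores near 1 mark recurrent somatic hotspots
FATHMM_CUTOFF = 0.5  # published deleteriousness threshold
RFS_CUTOFF = 0.0  # closer to the truncating mean (0.42) than synonymous (-2.50)

#: VAF below which a biallelic call gets a subclonality caveat.
SUBCLONAL_VAF = 0.15


def classify_lof(m: MutationRecord) -> bool:
    """True iff the record's consequence is loss of function."""
    return m.consequence in LOF_CONSEQUENCES


def _codon(protein_change: str) -> int | None:
    m = re.search(r"(\d+)", protein_change or "")
    return int(m.group(1)) if m else None


@dataclass
class GqSummary:
    sample_id: str
    hits: list[str]  # e.g. ["GNAQ p.Q209P"]
    multiple: bool
    known_co_occurrence: bool  # PLCB4 p.D630 with GNAQ/GNA11 p.R183
    exclusivity_violation: bool


def gq_pathway_summary(mutations: list[MutationRecord], sample_id: str | None = None) -> GqSummary:
    """Collect a sample's Gαq-pathway hotspot hits and exclusivity status.

    More than one hit is flagged; the PLCB4 p.D630 + p.R183 pattern is
    annotated as the known co-occurrence rather than a violation.
    """
    if sample_id is None:
        sample_id = mutations[0].sample_id if mutations else ""
    hits = []
    genes_codons = []
    for m in mutations:
        codon = _codon(m.protein_change)
        if m.gene in GQ_HOTSPOTS and codon in GQ_HOTSPOTS[m.gene]:
            hits.append(f"{m.gene} {m.protein_change}")
            genes_codons.append((m.gene, codon))
    multiple = len(hits) > 1
    has_plcb4 = any(g == "PLCB4" and c == 630 for g, c in genes_codons)
    has_r183 = any(g in ("GNAQ", "GNA11") and c == 183 for g, c in genes_codons)
    known = multiple and has_plcb4 and has_r183 and len(hits) == 2
    return GqSummary(sample_id, hits, multiple, known, multiple and not known)


@dataclass
class BiallelicCall:
    gene: str
    status: str  # none | monoallelic | biallelic_mut_loh | biallelic_two_mut | cn_loh
    loh: bool
    cn_loh: bool
    n_mutations: int
    phase: str | None = None  # "trans" | "unknown" for two-mutation calls
    subclonal_caveat: bool = False
    notes: list[str] = field(default_factory=list)


def biallelic_status(
    gene: str,
    mutations: list[MutationRecord],
    segments,
    loci: pd.DataFrame | None = None,
    phase: str | None = None,
) -> BiallelicCall:
    """Double-hit detection for one tumour-suppressor locus.

    LOH at the locus means minor CN = 0; copy-neutral LOH additionally has
    total CN >= 2.  A mutation plus LOH is a double hit
    (``biallelic_mut_loh``); two mutations are a double hit when phased
    trans, and flagged ``phase="unknown"`` otherwise.  A biallelic call whose
    supporting mutation has a subclonal VAF is annotated, not suppressed.
    """
    if loci is None:
        loci = gene_loci()
    row = loci[loci["gene"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} absent from locus table")
    chrom, start, end = (
        str(row["chrom"].iloc[0]),
        int(row["start"].iloc[0]),
        int(row["end"].iloc[0]),
    )
    seg = segments.segments
    on = seg[
        (seg["chrom"].astype(str) == chrom)
        & (seg["startpos"] <= end)
        & (seg["endpos"] >= start)
    ]
    if on.empty:
        loh = False
        cn_loh = False
    else:
        loh = bool((on["nMinor"] == 0).all())
        cn_loh = loh and bool((on["nMajor"] + on["nMinor"] >= 2).all())
    muts = [m for m in mutations if m.gene == gene and m.consequence != "silent"]
    n = len(muts)
    caveat = any(
        m.total_count > 0 and m.vaf < SUBCLONAL_VAF for m in muts
    )
    notes = []
    if n >= 1 and loh:
        status = "biallelic_mut_loh"
        if cn_loh:
            notes.append("copy-neutral LOH")
    elif n >= 2:
        status = "biallelic_two_mut"
        phase = phase or "unknown"
        if phase not in ("trans", "unknown", "cis"):
            raise ValueError(f"unknown phase {phase!r}")
        if phase == "cis":
            status = "monoallelic"
    elif n == 1:
        status = "monoallelic"
    elif loh and cn_loh:
        status = "cn_loh"
    else:
        status = "none"
        if loh:
            notes.append("hemizygous loss without mutation")
    return BiallelicCall(gene, status, loh, cn_loh, n, phase if n >= 2 else None,
                         caveat and status.startswith("biallelic"), notes)


def phase_by_vaf(site_a: tuple[int, int], site_b: tuple[int, int]) -> dict:
    """Compare allele representation of two mutations by read counts.

    Two-sided Fisher's exact test on [[altA, refA], [altB, refB]]; p < 0.001
    is interpreted as unequal allele representation (e.g. one allele's
    transcripts degraded by nonsense-mediated decay in RNA data).
    """
    (a_alt, a_tot), (b_alt, b_tot) = site_a, site_b
    if a_tot <= 0 or b_tot <= 0:
        raise ValueError("site totals must be positive")
    if not (0 <= a_alt <= a_tot and 0 <= b_alt <= b_tot):
        raise ValueError("alt counts must lie within totals")
    table = [[a_alt, a_tot - a_alt], [b_alt, b_tot - b_alt]]
    p = float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "p_two_sided": p,
        "interpretation": "unequal allele representation" if p < 1e-3 else "no evidence",
    }


@dataclass
class Tp53ScoreRow:
    variant: str
    phantm: float | None = None
    rfs: float | None = None
    fathmm: float | None = None
    iarc_count: int | None = None

    def __post_init__(self) -> None:
        if self.phantm is None and self.rfs is None and self.fathmm is None:
            raise ValueError("at least one score must be present")


def tp53_classify(row: Tp53ScoreRow, consequence: str) -> dict:
    """Three-score TP53 variant classification.

    Per-score deleterious verdicts: PHANTM >= 0.5, FATHMM > 0.5, RFS >= 0.
    Overall: truncating consequences (nonsense/frameshift/splice) are
    pathogenic outright; otherwise pathogenic with >= 2 deleterious verdicts,
    benign-leaning with none, uncertain in between.
    """
    truncating = consequence in ("nonsense", "frameshift", "splice", "sv_breakpoint")
    verdicts: dict[str, bool | None] = {
        "phantm": None if row.phantm is None else row.phantm >= PHANTM_CUTOFF,
        "rfs": None if row.rfs is None else row.rfs >= RFS_CUTOFF,
        "fathmm": None if row.fathmm is None else row.fathmm > FATHMM_CUTOFF,
    }
    available = [v for v in verdicts.values() if v is not None]
    if not available and not truncating:
        raise ValueError("no scores available for a non-truncating variant")
    n_del = sum(available)
    if truncating:
        overall = "pathogenic"
    elif n_del >= 2:
        overall = "pathogenic"
    elif n_del == 0:
        overall = "benign-leaning"
    else:
        overall = "uncertain"
    return {"overall": overall, "verdicts": verdicts, "truncating": truncating}


def pathway_8q_association(disrupted: np.ndarray, gain_8q: np.ndarray) -> dict:
    """Association between RPL5/TP53-pathway disruption and 8q gain.

    Two-sided Fisher's exact test on the 2x2 of disruption status against 8q
    status across the cohort.
    """
    disrupted = np.asarray(disrupted, dtype=bool)
    gain_8q = np.asarray(gain_8q, dtype=bool)
    if disrupted.shape != gain_8q.shape:
        raise ValueError("flag vectors must align")
    a = int(np.sum(disrupted & gain_8q))
    b = int(np.sum(~disrupted & gain_8q))
    c = int(np.sum(disrupted & ~gain_8q))
    d = int(np.sum(~disrupted & ~gain_8q))
    if (a + c == 0 or b + d == 0) or (a + b == 0 or c + d == 0):
        if a + b + c + d == 0:
            raise ValueError("empty cohort")
    table = [[a, c], [b, d]]
    odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    rate_with = a / (a + b) if a + b else float("nan")
    rate_without = c / (c + d) if c + d else float("nan")
    return {
        "table": table,
        "p_two_sided": float(p),
        "rate_with_8q": rate_with,
        "rate_without_8q": rate_without,
    }


def load_tp53_scores(path) -> list[Tp53ScoreRow]:
    """Read a TP53 score table (variant, effect, phantm, rfs, fathmm, iarc_count)."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        def _f(x):
            return None if pd.isna(x) else float(x)
        rows.append(
            Tp53ScoreRow(
                str(r.variant),
                _f(getattr(r, "phantm", np.nan)),
                _f(getattr(r, "rfs", np.nan)),
                _f(getattr(r, "fathmm", np.nan)),
                None if pd.isna(getattr(r, "iarc_count", np.nan)) else int(r.iarc_count),
            )
        )
    return rows
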