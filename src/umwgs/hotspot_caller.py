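"""Sensitive rescue calling of known hotspot mutations.

Standard genome-wide callers can miss recurrent driver hotspots at modest
depth or purity, so the recurrent uveal-melanoma hotspots are re-tested
directly: at each panel position, a tumour's variant/reference read counts
are compared against the pooled counts of all normal/germline samples with a
two-sided Fisher's exact test, and a Bonferroni-corrected p-value below
``alpha`` (default 0.001) calls the site somatic.  The pooled normals act as
a position-specific sequencing-error background.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd
import scipy.stats

from .resources import hotspot_panel, panel_site_keys
from .types import SiteCounts

DEFAULT_ALPHA = 1e-3


@dataclass
class RescueCall:
    sample_id: str
    site: str
    tumour_alt: int
    tumour_ref: int
    pooled_alt: int
    pooled_ref: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def pool_normals(normal_counts: Iterable[SiteCounts]) -> dict[str, SiteCounts]:
    """Element-wise sum of alt/ref counts across normals, per position."""
    pooled: dict[str, list[int]] = {}
    n = 0
    for sc in normal_counts:
        n += 1
        acc = pooled.setdefault(sc.site, [0, 0])
        acc[0] += sc.alt_count
        acc[1] += sc.ref_count
    if n == 0:
        raise ValueError("empty normal pool")
    return {
        site: SiteCounts("pooled_normals", site, alt, ref)
        for site, (alt, ref) in pooled.items()
    }


def rescue_call(
    tumour: SiteCounts,
    pooled: SiteCounts,
    n_tests: int,
    alpha: float = DEFAULT_ALPHA,
) -> RescueCall:
    """Fisher's exact test of tumour vs pooled-normal allele counts.

    The test is two-sided on the table ``[[t.alt, t.ref], [pool.alt,
    pool.ref]]``; the raw p-value is Bonferroni-corrected by ``n_tests``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    table = [[tumour.alt_count, tumour.ref_count], [pooled.alt_count, pooled.ref_count]]
    if sum(table[0]) + sum(table[1]) == 0:
        raise ValueError("all-zero contingency table")
    p_raw = float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    p_bonf = min(1.0, p_raw * n_tests)
    return RescueCall(
        tumour.sample_id,
        tumour.site,
        tumour.alt_count,
        tumour.ref_count,
        pooled.alt_count,
        pooled.ref_count,
        p_raw,
        p_bonf,
        bool(p_bonf < alpha),
    )


def _to_site_counts(df: pd.DataFrame) -> list[SiteCounts]:
    return [
        SiteCounts(
            str(r.sample),
            f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}",
            int(r.alt_count),
            int(r.total_count) - int(r.alt_count),
        )
        for r in df.itertuples(index=False)
    ]


def call_cohort(
    pileups: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude_matched_normal: bool = False,
) -> pd.DataFrame:
    """Run the rescue caller over a cohort pileup table.

    ``pileups`` columns: sample, chrom, pos, ref, alt, alt_count,
    total_count, is_normal.  The Bonferroni family defaults to
    (panel positions x tumour samples).  With ``exclude_matched_normal`` the
    tested tumour's own normal is removed from the pool for its tests.
    """
    if panel is None:
        panel = hotspot_panel()
    keys = set(panel_site_keys(panel))
    pileups = pileups.copy()
    pileups["site"] = (
        pileups["chrom"].astype(str)
        + ":"
        + pileups["pos"].astype(str)
        + ":"
        + pileups["ref"].astype(str)
        + ">"
        + pileups["alt"].astype(str)
    )
    pileups = pileups[pileups["site"].isin(keys)]
    normals = pileups[pileups["is_normal"].astype(bool)]
    tumours = pileups[~pileups["is_normal"].astype(bool)]
    if normals.empty:
        raise ValueError("no normal samples in pileup table")
    pooled = pool_normals(_to_site_counts(normals))
    n_tests = tumours["sample"].nunique() * len(keys)
    rows = []
    for r in tumours.itertuples(index=False):
        tc = SiteCounts(
            str(r.sample), r.site, int(r.alt_count), int(r.total_count) - int(r.alt_count)
        )
        pool = pooled.get(r.site)
        if pool is None:
            continue
        if exclude_matched_normal:
            own = normals[(normals["sample"] == r.sample) & (normals["site"] == r.site)]
            alt = pool.alt_count - int(own["alt_count"].sum())
            ref = pool.ref_count - int(
                (own["total_count"].sum() - own["alt_count"].sum())
            )
            pool = SiteCounts("pooled_normals", r.site, alt, ref)
        call = rescue_call(tc, pool, n_tests, alpha)
        rows.append(call.__dict__)
    return pd.DataFrame(rows)
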