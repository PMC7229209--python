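"""Arm-level copy-number calls, genomic categories and derived statistics.

Uveal melanomas stratify into four prognostic categories from two
chromosome-level events: monosomy 3 (M3) versus disomy 3 (D3), and gain of
chromosome arm 8q.  Category 1 is D3 without 8q gain, category 2 is D3 with
8q gain (typically with 6p gain), category 3 is M3 without 8q gain and
category 4 — the poorest prognosis group — is M3 with 8q gain.

Arm statuses are called by length-weighted vote against the sample's
baseline total copy number (round(ploidy)): an arm is a gain (loss) when at
least half of its length carries total CN above (below) the baseline.
Fraction of genome altered and high-gain segments (total CN >= 6) are
computed from the same segment profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resources import arm_table
from .types import SegmentProfile

#: Minimum fraction of an arm that must be covered by segments for a call.
COVERAGE_FLOOR = 0.5
#: Fraction of arm length that must be aberrant to call a gain/loss.
ARM_CALL_THRESHOLD = 0.5
#: Total copy number at or above which a segment counts as high gain.
HIGH_GAIN_CN = 6


@dataclass
class ArmStatus:
    arm: str
    status: str | None  # "gain" | "loss" | "neutral" | None (insufficient coverage)
    fraction_covered: float
    gain_fraction: float
    loss_fraction: float


def arm_status(
    profile: SegmentProfile,
    arms: pd.DataFrame | None = None,
    coverage_floor: float = COVERAGE_FLOOR,
    call_threshold: float = ARM_CALL_THRESHOLD,
) -> list[ArmStatus]:
    """Length-weighted arm-level gain/loss calls against the ploidy baseline."""
    if arms is None:
        arms = arm_table()
    seg = profile.segments
    baseline = int(round(profile.ploidy))
    chrom_len = {str(c): int(g["end"].max()) for c, g in arms.groupby("chrom")}
    for chrom, grp in seg.groupby("chrom"):
        limit = chrom_len.get(str(chrom))
        if limit is not None and int(grp["endpos"].max()) > limit:
            raise ValueError(
                f"segment on chromosome {chrom} extends past {limit}: assembly mismatch"
            )
    out = []
    total = seg["nMajor"].to_numpy() + seg["nMinor"].to_numpy()
    for r in arms.itertuples(index=False):
        on = seg[seg["chrom"].astype(str) == str(r.chrom)]
        if on.empty:
            out.append(ArmStatus(r.arm, None, 0.0, 0.0, 0.0))
            continue
        ov = (
            np.minimum(on["endpos"].to_numpy(), r.end)
            - np.maximum(on["startpos"].to_numpy(), r.start)
            + 1
        ).clip(min=0)
        tot_cn = on["nMajor"].to_numpy() + on["nMinor"].to_numpy()
        arm_len = r.end - r.start + 1
        covered = ov.sum() / arm_len
        gain = ov[tot_cn > baseline].sum() / arm_len
        loss = ov[tot_cn < baseline].sum() / arm_len
        if covered < coverage_floor:
            status = None
        elif gain >= call_threshold:
            status = "gain"
        elif loss >= call_threshold:
            status = "loss"
        else:
            status = "neutral"
        out.append(ArmStatus(r.arm, status, float(covered), float(gain), float(loss)))
    return out


def _arm_map(arms: list[ArmStatus]) -> dict[str, ArmStatus]:
    return {a.arm: a for a in arms}


def classify_category(arms: list[ArmStatus]) -> int:
    """Assign the 4-way genomic category from chr3 and 8q arm statuses.

    M3 is loss of both 3p and 3q (whole-chromosome monosomy).  Mapping:
    (D3, no 8q gain) -> 1, (D3, 8q gain) -> 2, (M3, no 8q gain) -> 3,
    (M3, 8q gain) -> 4.
    """
    m = _arm_map(arms)
    for needed in ("3p", "3q", "8q"):
        if needed not in m or m[needed].status is None:
            raise ValueError(f"arm {needed} status undefined; cannot categorise")
    m3 = m["3p"].status == "loss" and m["3q"].status == "loss"
    gain8q = m["8q"].status == "gain"
    return {(False, False): 1, (False, True): 2, (True, False): 3, (True, True): 4}[
        (m3, gain8q)
    ]


def fraction_genome_altered(profile: SegmentProfile) -> float:
    """Fraction of covered genome with non-baseline allele-specific CN.

    Baseline is (1,1) for (adjusted) diploids and (2,2) for unadjusted
    tetraploids, chosen by round(ploidy).
    """
    seg = profile.segments
    if seg.empty:
        raise ValueError("empty segment profile")
    base = 2 if round(profile.ploidy) == 4 else 1
    lengths = profile.lengths()
    altered = (seg["nMajor"].to_numpy() != base) | (seg["nMinor"].to_numpy() != base)
    return float(lengths[altered].sum() / lengths.sum())


def high_gain_flags(profile: SegmentProfile, threshold: int = HIGH_GAIN_CN) -> pd.DataFrame:
    """Segments whose total copy number reaches the high-gain threshold."""
    seg = profile.segments
    return seg[(seg["nMajor"] + seg["nMinor"]) >= threshold].copy()


def isochromosome_8q_check(cohort_arms: dict[str, list[ArmStatus]]) -> list[str]:
    """Samples violating the isochromosome-8q pattern (8p loss => 8q gain).

    8p loss without 8q gain is biologically unexpected in this tumour type;
    an empty list means the cohort conforms.
    """
    violations = []
    for sample, arms in cohort_arms.items():
        m = _arm_map(arms)
        p8 = m.get("8p")
        q8 = m.get("8q")
        if p8 is None or q8 is None or p8.status is None or q8.status is None:
            continue
        if p8.status == "loss" and q8.status != "gain":
            violations.append(sample)
    return violations
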