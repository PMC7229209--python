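"""Shared record types used across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed set of functional consequences carried by mutation records.
CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "silent", "sv_breakpoint")


@dataclass
class MutationRecord:
    """One somatic substitution or indel with context and read support."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str | None = None  # "T[C>T]T" (SBS) or "CC>TT" (DBS); None for indels
    gene: str = ""
    protein_change: str = ""
    consequence: str = "silent"
    alt_count: int = 0
    total_count: int = 0
    germline: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.alt_count > self.total_count:
            raise ValueError("alt_count exceeds total_count")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.total_count if self.total_count else float("nan")


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments plus purity/ploidy for one sample.

    ``segments`` columns: chrom, startpos, endpos, nMajor, nMinor
    (1-based, closed intervals).
    """

    sample_id: str
    segments: pd.DataFrame
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        seg = self.segments
        required = {"chrom", "startpos", "endpos", "nMajor", "nMinor"}
        missing = required - set(seg.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if (seg["startpos"] > seg["endpos"]).any():
            raise ValueError("segment with startpos > endpos")
        if (seg["nMajor"] < seg["nMinor"]).any() or (seg["nMinor"] < 0).any():
            raise ValueError("copy numbers must satisfy nMajor >= nMinor >= 0")
        for chrom, grp in seg.groupby("chrom", sort=False):
            g = grp.sort_values("startpos")
            if (g["startpos"].to_numpy()[1:] <= g["endpos"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on chromosome {chrom}")

    def total_cn(self) -> np.ndarray:
        return (self.segments["nMajor"] + self.segments["nMinor"]).to_numpy()

    def lengths(self) -> np.ndarray:
        return (self.segments["endpos"] - self.segments["startpos"] + 1).to_numpy()


@dataclass
class ExposureVector:
    """Non-negative per-signature contributions, on mutation-count scale."""

    signatures: tuple[str, ...]
    values: np.ndarray
    residual_norm: float
    empty_input: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("exposures must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signatures, self.values))

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def fraction(self, name: str) -> float:
        """Fraction of the fitted total attributed to one signature."""
        if self.total == 0:
            raise ValueError("all-zero exposure vector has no fractions")
        return self.as_dict()[name] / self.total


@dataclass
class SiteCounts:
    """Allele counts for one sample (or a pool) at one panel position."""

    sample_id: str
    site: str  # "chrom:pos:ref>alt" key
    alt_count: int
    ref_count: int

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count


@dataclass
class ClinicalRecord:
    sample_id: str
    site: str
    time_years: float
    event: bool
    age: float | None = None
    labels: dict = field(default_factory=dict)
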