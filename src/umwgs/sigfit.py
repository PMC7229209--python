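"""Mutational-signature refitting and burden phenotypes.

A sample's substitutions are binned into the 96 trinucleotide (SBS) and,
when doublets are present, the 78 dinucleotide (DBS) classes.  The catalogue
``c`` is then approximated as a non-negative linear combination of reference
signature columns ``S`` by solving

    min_e || c - S e ||_2   subject to   e >= 0,

so each exposure ``e_k`` reads directly as the number of mutations
attributable to signature ``k``.  Tumour mutation burden (TMB) and the two
phenotype flags used throughout the cohort analysis — a UV-radiation
phenotype (SBS7a/7b-dominated spectrum with high TMB, seen in iris tumours)
and a deamination hypermutator phenotype (SBS1-dominated spectrum with
TMB > 3/Mb, seen with MBD4 loss) — are derived from the fitted exposures.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .contexts import (
    DBS78_CLASSES,
    SBS96_CLASSES,
    normalise_dbs_context,
    normalise_sbs_context,
    sbs_index,
    dbs_index,
)
from .types import ExposureVector, MutationRecord

#: Default callable genome size (Mb) used for TMB; configurable everywhere.
DEFAULT_CALLABLE_MB = 2800.0

#: Default exposure-fraction thresholds for the phenotype flags.
UV_FRACTION_THRESHOLD = 0.1
SBS1_FRACTION_THRESHOLD = 0.5
HYPERMUTATOR_TMB = 3.0


class MutationCatalogue:
    """Counts over the canonical SBS96 (and optionally DBS78) classes."""

    def __init__(self, sample_id: str, sbs_counts, dbs_counts=None):
        self.sample_id = sample_id
        self.sbs_counts = np.asarray(sbs_counts, dtype=float)
        if self.sbs_counts.shape != (96,):
            raise ValueError("sbs_counts must have length 96")
        if (self.sbs_counts < 0).any():
            raise ValueError("negative catalogue counts")
        if dbs_counts is not None:
            dbs_counts = np.asarray(dbs_counts, dtype=float)
            if dbs_counts.shape != (78,):
                raise ValueError("dbs_counts must have length 78")
            if (dbs_counts < 0).any():
                raise ValueError("negative catalogue counts")
        self.dbs_counts = dbs_counts

    def sbs_series(self) -> pd.Series:
        return pd.Series(self.sbs_counts, index=list(SBS96_CLASSES))

    def dbs_series(self) -> pd.Series | None:
        if self.dbs_counts is None:
            return None
        return pd.Series(self.dbs_counts, index=list(DBS78_CLASSES))

    @property
    def n_sbs(self) -> int:
        return int(self.sbs_counts.sum())

    @property
    def n_dbs(self) -> int:
        return 0 if self.dbs_counts is None else int(self.dbs_counts.sum())


def build_catalogue(
    mutations: Iterable[MutationRecord] | pd.DataFrame, sample_id: str | None = None
) -> MutationCatalogue:
    """Bin substitutions into SBS96/DBS78 classes; indels are excluded.

    Purine-centred contexts are reverse-complemented onto the canonical
    pyrimidine-centred classes.  A context inconsistent with the record's
    ref allele raises ``ValueError``.
    """
    sbs = np.zeros(96)
    dbs = np.zeros(78)
    seen_dbs = False
    if isinstance(mutations, pd.DataFrame):
        rows = mutations.itertuples(index=False)
        get = lambda r, k, d="": getattr(r, k, d)
        records = (
            (get(r, "context", None), str(get(r, "ref")), str(get(r, "alt")))
            for r in rows
        )
        if sample_id is None:
            sample_id = str(mutations["sample"].iloc[0]) if len(mutations) else ""
    else:
        mutations = list(mutations)
        records = ((m.context, m.ref, m.alt) for m in mutations)
        if sample_id is None:
            sample_id = mutations[0].sample_id if mutations else ""
    for context, ref, alt in records:
        if context is None or (isinstance(context, float) and np.isnan(context)):
            continue  # indel or unannotated: excluded from both catalogues
        context = str(context)
        if len(ref) == 1 and len(alt) == 1:
            if context[2] != ref:
                raise ValueError(
                    f"context {context!r} inconsistent with ref allele {ref!r}"
                )
            sbs[sbs_index(context)] += 1
        elif len(ref) == 2 and len(alt) == 2:
            if not context.startswith(ref):
                raise ValueError(
                    f"doublet context {context!r} inconsistent with ref {ref!r}"
                )
            dbs[dbs_index(context)] += 1
            seen_dbs = True
        # longer alleles are indels: excluded
    return MutationCatalogue(sample_id, sbs, dbs if seen_dbs else None)


def _validate_matrix(signatures: pd.DataFrame, labels: Sequence[str]) -> None:
    if list(signatures.index) != list(labels):
        if set(signatures.index) == set(labels):
            raise ValueError("signature matrix rows are not in canonical order")
        raise ValueError("signature matrix row labels do not match catalogue classes")
    colsums = signatures.sum(axis=0).to_numpy()
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")


def fit_exposures(
    catalogue: MutationCatalogue, signatures: pd.DataFrame, kind: str = "sbs"
) -> ExposureVector:
    """Non-negative least-squares refit of a catalogue onto signature columns.

    Returns the exact minimiser of ``||c - S e||_2`` with ``e >= 0`` (active
    set method); ``residual_norm`` is the achieved objective.  An all-zero
    catalogue yields all-zero exposures flagged via ``empty_input``.
    """
    if kind == "sbs":
        c = catalogue.sbs_counts
        _validate_matrix(signatures, SBS96_CLASSES)
    elif kind == "dbs":
        if catalogue.dbs_counts is None:
            raise ValueError("catalogue has no doublet counts")
        c = catalogue.dbs_counts
        _validate_matrix(signatures, DBS78_CLASSES)
    else:
        raise ValueError(f"unknown catalogue kind {kind!r}")
    names = tuple(signatures.columns)
    if c.sum() == 0:
        return ExposureVector(names, np.zeros(len(names)), 0.0, empty_input=True)
    S = signatures.to_numpy(dtype=float)
    e, rnorm = scipy.optimize.nnls(S, c)
    return ExposureVector(names, e, float(rnorm))


def exposure_fractions(exposures: ExposureVector) -> dict[str, float]:
    """Per-signature fractions of the fitted total; sums to one."""
    total = exposures.total
    if total <= 0:
        raise ValueError("cannot take fractions of an all-zero exposure vector")
    return {k: v / total for k, v in exposures.as_dict().items()}


def tmb(mutation_count: int, callable_mb: float = DEFAULT_CALLABLE_MB) -> float:
    """Tumour mutation burden in mutations per callable megabase."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    return mutation_count / callable_mb


def phenotype_flags(
    exposures: ExposureVector,
    tmb_value: float,
    cohort_median_tmb: float,
    dbs_exposures: ExposureVector | None = None,
    threshold_uv: float = UV_FRACTION_THRESHOLD,
    threshold_sbs1: float = SBS1_FRACTION_THRESHOLD,
) -> dict[str, bool]:
    """Derive the UVR and deamination-hypermutator phenotype flags.

    uvr: combined SBS7a+SBS7b fraction at least *threshold_uv* AND TMB above
    the cohort median ("high TMB").  When DBS exposures are supplied, a
    DBS1-dominated doublet spectrum is reported alongside for corroboration
    but is not required for the flag.
    deamination_hypermutator: SBS1 fraction at least *threshold_sbs1* AND
    TMB > 3 mutations/Mb.
    """
    names = set(exposures.signatures)
    required = {"SBS1", "SBS7a", "SBS7b"}
    if not required <= names:
        raise ValueError(f"missing required signature columns: {sorted(required - names)}")
    if exposures.total > 0:
        frac = exposure_fractions(exposures)
    else:
        frac = {k: 0.0 for k in exposures.signatures}
    uv_frac = frac["SBS7a"] + frac["SBS7b"]
    flags = {
        "uvr": uv_frac >= threshold_uv and tmb_value > cohort_median_tmb,
        "deamination_hypermutator": frac["SBS1"] >= threshold_sbs1
        and tmb_value > HYPERMUTATOR_TMB,
    }
    if dbs_exposures is not None and dbs_exposures.total > 0:
        dfrac = exposure_fractions(dbs_exposures)
        flags["dbs1_dominant"] = dfrac.get("DBS1", 0.0) >= 0.5
    return flags


def dominant_signature(exposures: ExposureVector) -> str:
    """Name of the signature with the largest fitted exposure."""
    if exposures.total <= 0:
        return ""
    d = exposures.as_dict()
    return max(d, key=d.get)
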