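"""Whole-genome duplication versus tumour heterogeneity from VAF mixtures.

ASCAT-style copy-number fitting assumes exactly two cell populations (tumour
and normal contamination), so a heterogeneous diploid tumour with a large
subclone can be mis-fit as tetraploid.  The two situations leave different
fingerprints in the variant-allele-fraction (VAF) distribution of somatic
mutations inside allelically balanced regions (major CN == minor CN):

* genuine tetraploidy: two VAF peaks from mutations acquired before and
  after the duplication, the late peak at exactly *half* the early peak
  (atoms theta and theta/2);
* diploid + subclone: a clonal peak theta and a subclonal peak phi that can
  sit anywhere below theta.

Both are two-component binomial mixtures over (alt, depth) counts,

    L = prod_i [ w Bin(a_i; n_i, theta) + (1-w) Bin(a_i; n_i, theta') ],

with theta' = theta/2 (tetraploid, 2 free parameters) or theta' = phi free
(heterogeneous diploid, 3 free parameters).  The tetraploid model is the
phi = theta/2 slice of the heterogeneous model, so a likelihood-ratio test
with one degree of freedom compares them; when heterogeneity is
significantly more likely (default P < 0.001) the inflated copy numbers are
halved.  Theta is left free rather than pinned at its purity-implied value
so purity estimation error is absorbed by the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .types import MutationRecord, SegmentProfile

#: Minimum number of balanced-region mutations to attempt the comparison.
MIN_SITES = 20

DEFAULT_ALPHA = 1e-3
_EPS = 1e-9
_N_STARTS = 10


class InsufficientSitesError(ValueError):
    """Raised when too few balanced-region mutations exist to fit the model."""


@dataclass
class BalancedVafSet:
    sample_id: str
    alt: np.ndarray
    total: np.ndarray
    purity: float

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if (self.alt < 0).any() or (self.alt > self.total).any():
            raise ValueError("require 0 <= alt <= total")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.alt)


@dataclass
class ModelFit:
    model: str  # "tetraploid" | "het_diploid"
    loglik: float
    theta: float
    weight: float
    phi: float  # second atom; theta/2 for the tetraploid model
    n_sites: int


def extract_balanced_vafs(
    segments: SegmentProfile, mutations: list[MutationRecord] | pd.DataFrame
) -> BalancedVafSet:
    """Restrict a sample's mutations to allelically balanced segments.

    A mutation is kept iff its position falls inside a segment with
    major CN == minor CN; positions outside any segment are dropped.
    """
    seg = segments.segments
    bal = seg[seg["nMajor"] == seg["nMinor"]]
    by_chrom = {
        str(c): (g["startpos"].to_numpy(), g["endpos"].to_numpy())
        for c, g in bal.sort_values("startpos").groupby("chrom")
    }
    if isinstance(mutations, pd.DataFrame):
        trip = zip(
            mutations["chrom"].astype(str),
            mutations["pos"].astype(int),
            mutations["alt_count"].astype(int),
            mutations["total_count"].astype(int),
        )
    else:
        trip = ((m.chrom, m.pos, m.alt_count, m.total_count) for m in mutations)
    alts, totals = [], []
    for chrom, pos, a, n in trip:
        arr = by_chrom.get(str(chrom))
        if arr is None:
            continue
        starts, ends = arr
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos <= ends[i]:
            alts.append(a)
            totals.append(n)
    return BalancedVafSet(segments.sample_id, np.array(alts, dtype=np.int64),
                          np.array(totals, dtype=np.int64), segments.purity)


def _loglik(alt, total, logcoef, theta, phi, w):
    t1 = alt * np.log(theta) + (total - alt) * np.log1p(-theta)
    t2 = alt * np.log(phi) + (total - alt) * np.log1p(-phi)
    return float(np.sum(logcoef + np.logaddexp(np.log(w) + t1, np.log1p(-w) + t2)))


def _em(alt, total, logcoef, theta0, w0, tetraploid, phi0=None, max_iter=500, tol=1e-9):
    theta = float(np.clip(theta0, _EPS, 1 - _EPS))
    w = float(np.clip(w0, _EPS, 1 - _EPS))
    phi = theta / 2 if tetraploid else float(np.clip(phi0, _EPS, 1 - _EPS))
    ll = -np.inf
    for _ in range(max_iter):
        l1 = np.log(w) + alt * np.log(theta) + (total - alt) * np.log1p(-theta)
        l2 = np.log1p(-w) + alt * np.log(phi) + (total - alt) * np.log1p(-phi)
        denom = np.logaddexp(l1, l2)
        r = np.exp(l1 - denom)  # responsibility of the clonal atom
        w = float(np.clip(r.mean(), _EPS, 1 - _EPS))
        if tetraploid:
            # stationarity of theta is a quadratic:
            # (A1+A2)(1-t)(2-t) - B1 t(2-t) - B2 t(1-t) = 0
            A = float(np.sum(r * alt) + np.sum((1 - r) * alt))
            B1 = float(np.sum(r * (total - alt)))
            B2 = float(np.sum((1 - r) * (total - alt)))
            a2 = A + B1 + B2
            b2 = -(3 * A + 2 * B1 + B2)
            disc = max(b2 * b2 - 8 * a2 * A, 0.0)
            theta = (-b2 - np.sqrt(disc)) / (2 * a2)
            theta = float(np.clip(theta, _EPS, 1 - _EPS))
            phi = theta / 2
        else:
            s1 = float(np.sum(r * total))
            s2 = float(np.sum((1 - r) * total))
            if s1 > 0:
                theta = float(np.clip(np.sum(r * alt) / s1, _EPS, 1 - _EPS))
            if s2 > 0:
                phi = float(np.clip(np.sum((1 - r) * alt) / s2, _EPS, 1 - _EPS))
            if phi > theta:  # relabel so theta is the clonal (larger) atom
                theta, phi = phi, theta
                w = 1 - w
        new_ll = _loglik(alt, total, logcoef, theta, phi, w)
        if new_ll - ll < tol and new_ll >= ll:
            ll = new_ll
            break
        ll = new_ll
    return ll, theta, phi, w


def fit_mixture(vafs: BalancedVafSet, model: str, n_starts: int = _N_STARTS) -> ModelFit:
    """Maximum-likelihood fit of a two-atom binomial VAF mixture.

    ``model`` is ``"tetraploid"`` (second atom fixed at theta/2) or
    ``"het_diploid"`` (second atom free below theta).  EM from *n_starts*
    quantile-spaced starting atoms guards against local optima; for the
    heterogeneous model, the tetraploid solution is also used as a start so
    the nested model never scores below its special case.
    """
    if model not in ("tetraploid", "het_diploid"):
        raise ValueError(f"unknown model {model!r}")
    if len(vafs) < MIN_SITES:
        raise InsufficientSitesError(
            f"{len(vafs)} balanced-region sites < required {MIN_SITES}"
        )
    alt, total = vafs.alt, vafs.total
    if np.all(alt == alt[0]) and np.all(total == total[0]) and len(np.unique(alt)) == 1:
        if np.unique(total).size == 1 and (alt[0] == 0 or alt[0] == total[0]):
            raise ValueError("degenerate all-equal counts")
    logcoef = (
        scipy.special.gammaln(total + 1)
        - scipy.special.gammaln(alt + 1)
        - scipy.special.gammaln(total - alt + 1)
    )
    vaf = np.clip(alt / np.maximum(total, 1), 1e-4, 1 - 1e-4)
    qs = np.quantile(vaf, np.linspace(0.15, 0.95, n_starts))
    best = (-np.inf, 0.5, 0.25, 0.5)
    starts = [(q, w0) for q in qs for w0 in (0.5,)]
    starts += [(np.quantile(vaf, 0.75), 0.3), (np.quantile(vaf, 0.9), 0.7)]
    for theta0, w0 in starts:
        if model == "tetraploid":
            res = _em(alt, total, logcoef, theta0, w0, tetraploid=True)
        else:
            res = _em(alt, total, logcoef, theta0, w0, tetraploid=False,
                      phi0=max(theta0 * 0.4, _EPS))
        if res[0] > best[0]:
            best = res
    if model == "het_diploid":
        # seed with the tetraploid optimum so nesting holds numerically
        tet = fit_mixture(vafs, "tetraploid", n_starts=n_starts)
        res = _em(alt, total, logcoef, tet.theta, tet.weight, tetraploid=False,
                  phi0=tet.theta / 2)
        if res[0] > best[0]:
            best = res
        tet_ll_as_het = _loglik(alt, total, logcoef, tet.theta, tet.theta / 2, tet.weight)
        if tet_ll_as_het > best[0]:
            best = (tet_ll_as_het, tet.theta, tet.theta / 2, tet.weight)
    ll, theta, phi, w = best
    return ModelFit(model, ll, theta, w, phi, len(vafs))


@dataclass
class WgdCall:
    call: str  # "tetraploid" | "het_diploid"
    lrt_stat: float
    lrt_p: float
    adjusted: bool


def resolve_wgd(tet: ModelFit, het: ModelFit, alpha: float = DEFAULT_ALPHA) -> WgdCall:
    """Likelihood-ratio test of heterogeneity against genuine tetraploidy.

    The tetraploid model is nested in the heterogeneous one (df = 1); when
    the heterogeneity is significantly more likely the copy-number profile
    should be adjusted (halved).
    """
    if tet.model != "tetraploid" or het.model != "het_diploid":
        raise ValueError("pass the tetraploid fit first, the heterogeneous fit second")
    if het.loglik < tet.loglik - 1e-6:
        raise RuntimeError(
            "heterogeneous-model likelihood below its nested special case; "
            "optimiser failure"
        )
    stat = max(0.0, 2.0 * (het.loglik - tet.loglik))
    p = float(scipy.stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    adjusted = p < alpha
    return WgdCall("het_diploid" if adjusted else "tetraploid", stat, p, adjusted)


def adjust_copy_numbers(profile: SegmentProfile) -> SegmentProfile:
    """Halve an inflated tetraploid profile back to diploid.

    Major/minor copy numbers are halved and rounded to the nearest integer
    (ties to even); the ploidy field is halved.
    """
    seg = profile.segments.copy()
    seg["nMajor"] = np.rint(seg["nMajor"] / 2).astype(int)
    seg["nMinor"] = np.rint(seg["nMinor"] / 2).astype(int)
    return SegmentProfile(profile.sample_id, seg, profile.purity, profile.ploidy / 2)
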