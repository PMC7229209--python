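"""Synthetic uveal-melanoma cohort generator.

Produces cohorts with the statistical structure the downstream stages
assume, with full ground truth, so every stage can be validated against a
known answer:

* most samples at low mutation burden (~0.5/Mb) dominated by a flat
  clock-like signature (SBS5-like);
* a small MBD4-like subset with SBS1-dominated hypermutation (TMB > 3/Mb);
* iris samples with UV signatures (SBS7a/7b plus CC>TT doublets) and high
  TMB;
* copy-number profiles following the four genomic categories
  (disomy/monosomy 3 x 8q gain), with 8p loss only alongside 8q gain and a
  built-in association between 8q gain and RPL5/TP53 disruption;
* purity and clonal structure governing VAFs, including rare genuine
  tetraploids and diploid-plus-subclone samples whose segment profiles are
  emitted doubled (mimicking the two-population assumption of ASCAT-style
  fitting overestimating copy number);
* category-dependent exponential relapse hazards with administrative
  censoring.

Mutation contexts are sampled directly from the signature probability
vectors, so no reference genome is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import DBS78_CLASSES, SBS96_CLASSES
from .resources import (
    arm_table,
    chromosome_lengths,
    gene_loci,
    hotspot_panel,
    load_signature_matrix,
)

_SITES = ("choroid", "iris", "ciliary_body")


def _default_site_mixtures() -> dict:
    base = {"SBS5": 0.85, "SBS1": 0.15}
    return {
        "choroid": dict(base),
        "ciliary_body": dict(base),
        "iris": {"SBS7a": 0.45, "SBS7b": 0.25, "SBS5": 0.30},
    }


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate a 103-sample whole-genome cohort: category mix
    24/11/13/55, ~8% iris primaries, a couple of MBD4-like hypermutators,
    baseline burden 0.5 mutations/Mb over 2,800 callable Mb, and relapse
    hazards ordered category 4 >> 2 ~ 3 > 1.
    """

    n_samples: int = 103
    category_probs: tuple = (24 / 103, 11 / 103, 13 / 103, 55 / 103)
    purity_range: tuple = (0.35, 0.95)
    site_probs: dict = field(
        default_factory=lambda: {"choroid": 0.88, "iris": 0.08, "ciliary_body": 0.04}
    )
    site_signature_mixtures: dict = field(default_factory=_default_site_mixtures)
    mbd4_mixture: dict = field(default_factory=lambda: {"SBS1": 0.80, "SBS5": 0.20})
    tmb_per_mb: dict = field(
        default_factory=lambda: {"baseline": 0.5, "iris": 4.0, "mbd4": 5.0}
    )
    mbd4_prob: float = 2 / 103
    wgd_prob: float = 2 / 103
    inflated_het_prob: float = 3 / 103
    subclone_fraction: float = 0.5
    subclone_mut_weight: float = 0.6  # fraction of mutations in the clonal atom
    wgd_early_weight: float = 0.6  # fraction of mutations preceding the WGD
    depth_mean: int = 60
    normal_depth: int = 40
    error_rate: float = 1e-3
    callable_mb: float = 2800.0
    hazard_by_category: tuple = (0.03, 0.10, 0.09, 0.28)  # events / year
    censor_horizon_years: float = 10.0
    disruption_rate_with_8q: float = 0.48
    disruption_rate_without_8q: float = 0.22
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if abs(sum(self.category_probs) - 1.0) > 1e-9 or len(self.category_probs) != 4:
            raise ValueError("category_probs must be a 4-vector summing to 1")
        if any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must be non-negative")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-9:
            raise ValueError("site_probs must sum to 1")
        if any(v <= 0 for v in self.tmb_per_mb.values()):
            raise ValueError("tmb rates must be strictly positive")
        if not 0 < self.subclone_fraction < 1:
            raise ValueError("subclone_fraction must be in (0, 1)")
        if any(h <= 0 for h in self.hazard_by_category) or len(self.hazard_by_category) != 4:
            raise ValueError("hazard_by_category must be 4 positive rates")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class CohortTables:
    """All simulated inputs plus the ground-truth table."""

    mutations: pd.DataFrame
    segments: pd.DataFrame
    purity_ploidy: pd.DataFrame
    pileups: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame


def expected_vaf(multiplicity: int, total_cn: int, purity: float) -> float:
    """Expected VAF of a mutation on ``multiplicity`` of ``total_cn`` tumour
    copies at cellular purity ``purity`` (normal cells contribute 2 copies)."""
    return multiplicity * purity / (total_cn * purity + 2 * (1 - purity))


def _draw_depth(rng: np.random.Generator, n: int, mean: int) -> np.ndarray:
    # Poisson around the mean with a floor of 10 avoids zero-depth sites
    return np.maximum(rng.poisson(mean, size=n), 10)


def simulate_vaf_counts(
    n_mut: int,
    model: str,
    purity: float,
    subclone_fraction: float | None,
    depth_mean: int,
    seed: int,
    clonal_weight: float = 0.6,
) -> list[tuple[int, int]]:
    """Draw (alt, total) read counts from the two VAF-atom models.

    ``tetraploid``: atoms 2p/(4p+2(1-p)) (pre-duplication) and half that
    (post-duplication).  ``het_diploid``: atoms p/2 (clonal) and f*p/2 for a
    subclone of cellular fraction ``f``.  Depths are Poisson around
    ``depth_mean`` (floor 10), alt counts binomial at the site's atom.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if n_mut < 1:
        raise ValueError("n_mut must be at least 1")
    rng = np.random.default_rng(seed)
    if model == "tetraploid":
        hi = expected_vaf(2, 4, purity)
        lo = hi / 2
    elif model == "het_diploid":
        if subclone_fraction is None or not 0 < subclone_fraction < 1:
            raise ValueError("het_diploid requires subclone_fraction in (0, 1)")
        hi = expected_vaf(1, 2, purity)
        lo = subclone_fraction * hi
    else:
        raise ValueError(f"unknown model {model!r}")
    atoms = np.where(rng.random(n_mut) < clonal_weight, hi, lo)
    depth = _draw_depth(rng, n_mut, depth_mean)
    alt = rng.binomial(depth, atoms)
    return list(zip(alt.tolist(), depth.tolist()))


def simulate_catalogue(
    n_mut: int, fractions: dict[str, float], signatures: pd.DataFrame, seed: int
):
    """Multinomial draw of an SBS96 catalogue from a signature mixture."""
    from .sigfit import MutationCatalogue

    rng = np.random.default_rng(seed)
    p = np.zeros(96)
    for name, f in fractions.items():
        p += f * signatures[name].to_numpy()
    p = p / p.sum()
    counts = rng.multinomial(n_mut, p)
    return MutationCatalogue("sim", counts)


# --- cohort assembly -------------------------------------------------------

_GQ_DRIVERS = [
    # (gene, protein_change, consequence, weight)
    ("GNAQ", "p.Q209P", "missense", 0.24),
    ("GNAQ", "p.Q209L", "missense", 0.22),
    ("GNA11", "p.Q209L", "missense", 0.28),
    ("GNA11", "p.Q209P", "missense", 0.14),
    ("GNAQ", "p.R183Q", "missense", 0.02),
    ("GNA11", "p.R183C", "missense", 0.02),
    ("GNAQ", "p.G48L", "missense", 0.01),
    ("PLCB4", "p.D630Y", "missense", 0.03),
    ("PLCB4", "p.D630N", "missense", 0.02),
    ("CYSLTR2", "p.L129Q", "missense", 0.01),
    (None, None, None, 0.01),  # the rare driver-negative tumour
]


def _sample_arm_cn(cat: int, rng: np.random.Generator, cfg: SimConfig):
    """Assign per-arm (nMajor, nMinor) for one sample; returns (dict, flags)."""
    cn: dict[str, tuple[int, int]] = {}
    m3 = cat in (3, 4)
    gain8q = cat in (2, 4)
    if m3:
        cn["3p"] = cn["3q"] = (1, 0)
    if gain8q:
        cn["8q"] = (2, 1)
        if rng.random() < 0.5:  # isochromosome 8q: 8p loss only with 8q gain
            cn["8p"] = (1, 0)
    if cat == 2:
        cn["6p"] = (2, 1)
    if cat == 4 and rng.random() < 0.4:
        cn["6q"] = (1, 0)
    if rng.random() < 0.2:
        cn["16q"] = (1, 0)
    if cat in (2, 4) and rng.random() < 0.3:
        cn["1q"] = (2, 1)
    # RPL5/TP53 disruption, more frequent with 8q gain
    rate = cfg.disruption_rate_with_8q if gain8q else cfg.disruption_rate_without_8q
    disrupted = rng.random() < rate
    route = None
    if disrupted:
        u = rng.random()
        if u < 0.70:
            cn["1p"] = (1, 0)  # RPL5 loss via chromosome 1p
            route = "rpl5_loh"
        elif u < 0.88:
            cn["17p"] = (1, 0)  # TP53 LOH
            route = "tp53_loh"
        else:
            route = "tp53_mut"
    return cn, disrupted, route


def _context_for(ref: str, alt: str) -> str:
    return f"A[{ref}>{alt}]A"


def simulate_cohort(config: SimConfig) -> CohortTables:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sbs = load_signature_matrix(kind="sbs")
    dbs = load_signature_matrix(kind="dbs")
    arms = arm_table()
    arm_coords = {r.arm: r for r in arms.itertuples(index=False)}
    lengths = chromosome_lengths()
    chroms = list(lengths)
    chrom_w = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    panel = hotspot_panel()
    loci = gene_loci().set_index("gene")
    sbs_classes = np.array(SBS96_CLASSES)
    dbs_classes = np.array(DBS78_CLASSES)
    sites = list(config.site_probs)
    site_p = np.array([config.site_probs[s] for s in sites])

    mut_frames, seg_rows, pp_rows, pile_rows, clin_rows, truth_rows = [], [], [], [], [], []

    for i in range(config.n_samples):
        sample = f"SIM_{i:04d}"
        cat = int(rng.choice(4, p=np.asarray(config.category_probs))) + 1
        site = str(rng.choice(sites, p=site_p))
        if site == "iris":
            phenotype = "iris_uvr"
        elif rng.random() < config.mbd4_prob:
            phenotype = "mbd4"
        else:
            phenotype = "baseline"
        purity = float(rng.uniform(*config.purity_range))
        u = rng.random()
        if u < config.wgd_prob:
            ploidy_state = "tetraploid"
        elif u < config.wgd_prob + config.inflated_het_prob:
            ploidy_state = "inflated_het"
        else:
            ploidy_state = "diploid"

        # --- signature mixture and burden ---------------------------------
        if phenotype == "mbd4":
            mixture = config.mbd4_mixture
            tmb_true = max(
                config.tmb_per_mb["mbd4"] * rng.lognormal(0.0, 0.15), 3.5
            )
        elif phenotype == "iris_uvr":
            mixture = config.site_signature_mixtures["iris"]
            tmb_true = config.tmb_per_mb["iris"] * rng.lognormal(0.0, 0.25)
        else:
            mixture = config.site_signature_mixtures[site]
            tmb_true = config.tmb_per_mb["baseline"] * rng.lognormal(0.0, 0.35)
        names = list(mixture)
        conc = np.array([mixture[k] for k in names]) * 300.0
        frac = rng.dirichlet(conc)
        fractions = {k: 0.0 for k in sbs.columns}
        fractions.update(dict(zip(names, frac)))
        n_mut = max(int(rng.poisson(tmb_true * config.callable_mb)), 50)

        # --- copy-number profile ------------------------------------------
        cn_arms, disrupted, route = _sample_arm_cn(cat, rng, config)
        doubled = ploidy_state in ("tetraploid", "inflated_het")
        for arm, r in arm_coords.items():
            maj, mnr = cn_arms.get(arm, (1, 1))
            if doubled:
                maj, mnr = maj * 2, mnr * 2
            seg_rows.append(
                {
                    "sample": sample,
                    "chrom": r.chrom,
                    "startpos": int(r.start),
                    "endpos": int(r.end),
                    "nMajor": maj,
                    "nMinor": mnr,
                }
            )
        reported_ploidy = 4.0 if doubled else 2.0
        pp_rows.append({"sample": sample, "purity": purity, "ploidy": reported_ploidy})

        # --- passenger substitutions --------------------------------------
        p = np.zeros(96)
        for k, f in fractions.items():
            p += f * sbs[k].to_numpy()
        p /= p.sum()
        cls_idx = rng.choice(96, size=n_mut, p=p)
        ctx = sbs_classes[cls_idx]
        mchrom = np.asarray(chroms, dtype=object)[rng.choice(len(chroms), size=n_mut, p=chrom_w)]
        highs = np.array([lengths[c] for c in mchrom], dtype=np.int64)
        mpos = rng.integers(1, highs, endpoint=True)
        # true (undoubled) CN at each position decides the clonal VAF atom
        tot_cn = np.full(n_mut, 2)
        for arm, (maj, mnr) in cn_arms.items():
            r = arm_coords[arm]
            mask = (mchrom == r.chrom) & (mpos >= r.start) & (mpos <= r.end)
            tot_cn[mask] = maj + mnr
        if ploidy_state == "tetraploid":
            mult = np.where(rng.random(n_mut) < config.wgd_early_weight, 2, 1)
            vaf = mult * purity / (2 * tot_cn * purity + 2 * (1 - purity))
            subclone = np.nan
        elif ploidy_state == "inflated_het":
            subclone = config.subclone_fraction
            clonal = rng.random(n_mut) < config.subclone_mut_weight
            vaf = purity / (tot_cn * purity + 2 * (1 - purity))
            vaf = np.where(clonal, vaf, subclone * vaf)
        else:
            vaf = purity / (tot_cn * purity + 2 * (1 - purity))
            subclone = np.nan
        depth = _draw_depth(rng, n_mut, config.depth_mean)
        alt = rng.binomial(depth, vaf)
        ref = np.array([c[2] for c in ctx])
        alt_base = np.array([c[4] for c in ctx])
        frame = pd.DataFrame(
            {
                "sample": sample,
                "chrom": mchrom,
                "pos": mpos,
                "ref": ref,
                "alt": alt_base,
                "context": ctx,
                "gene": "",
                "protein_change": "",
                "consequence": "silent",
                "alt_count": alt,
                "total_count": depth,
                "germline": False,
            }
        )
        mut_frames.append(frame)

        # --- doublet substitutions ----------------------------------------
        if phenotype == "iris_uvr":
            n_dbs = int(rng.poisson(0.03 * n_mut))
            dmix = 0.9 * dbs["DBS1"].to_numpy() + 0.1 * dbs["DBSflat"].to_numpy()
        else:
            n_dbs = int(rng.poisson(0.002 * n_mut))
            dmix = dbs["DBSflat"].to_numpy()
        if n_dbs > 0:
            dmix = dmix / dmix.sum()
            didx = rng.choice(78, size=n_dbs, p=dmix)
            dctx = dbs_classes[didx]
            dchrom = np.asarray(chroms, dtype=object)[
                rng.choice(len(chroms), size=n_dbs, p=chrom_w)
            ]
            dpos = np.array([rng.integers(1, lengths[c]) for c in dchrom], dtype=np.int64)
            ddepth = _draw_depth(rng, n_dbs, config.depth_mean)
            dalt = rng.binomial(ddepth, expected_vaf(1, 2, purity))
            mut_frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": dchrom,
                        "pos": dpos,
                        "ref": [c[:2] for c in dctx],
                        "alt": [c[3:] for c in dctx],
                        "context": dctx,
                        "gene": "",
                        "protein_change": "",
                        "consequence": "silent",
                        "alt_count": dalt,
                        "total_count": ddepth,
                        "germline": False,
                    }
                )
            )

        # --- driver mutations ---------------------------------------------
        driver_rows = []
        weights = np.array([w for *_, w in _GQ_DRIVERS])
        gene, pchg, csq, _ = _GQ_DRIVERS[
            int(rng.choice(len(_GQ_DRIVERS), p=weights / weights.sum()))
        ]
        driver_label = ""
        if gene is not None:
            driver_rows.append((gene, pchg, csq))
            driver_label = f"{gene} {pchg}"
            if gene == "PLCB4" and rng.random() < 0.4:
                co_gene = "GNAQ" if rng.random() < 0.5 else "GNA11"
                co_chg = "p.R183Q" if co_gene == "GNAQ" else "p.R183C"
                driver_rows.append((co_gene, co_chg, "missense"))
        bap1 = False
        if cat in (3, 4) and rng.random() < 0.75:
            bap1 = True
            kind = rng.choice(["nonsense", "frameshift", "splice"], p=[0.5, 0.3, 0.2])
            driver_rows.append(("BAP1", "p.Q267*", str(kind)))
        elif cat in (1, 2) and rng.random() < 0.05:
            bap1 = True
            driver_rows.append(("BAP1", "p.E402K", "missense"))
        if cat == 2 and rng.random() < 0.6:
            driver_rows.append(("SF3B1", "p.R625G", "missense"))
        elif rng.random() < 0.05:
            driver_rows.append(("SF3B1", "p.R625H", "missense"))
        if cat == 1 and rng.random() < 0.5:
            driver_rows.append(("EIF1AX", "p.G8R", "missense"))
        elif rng.random() < 0.05:
            driver_rows.append(("EIF1AX", "p.G15D", "missense"))
        if route == "tp53_mut":
            driver_rows.append(("TP53", "p.H193R", "missense"))
        if phenotype == "mbd4":
            driver_rows.append(("MBD4", "p.R468*", "nonsense"))

        for gname, gchg, gcsq in driver_rows:
            locus = loci.loc[gname]
            codon = int("".join(ch for ch in gchg if ch.isdigit()) or 0)
            prow = panel[(panel["gene"] == gname) & (panel["codon"] == codon)]
            if not prow.empty:
                gchrom = str(prow["chrom"].iloc[0])
                gpos = int(prow["pos"].iloc[0])
                gref, galt = str(prow["ref"].iloc[0]), str(prow["alt"].iloc[0])
            else:
                gchrom = str(locus["chrom"])
                gpos = int(rng.integers(locus["start"], locus["end"]))
                gref, galt = "C", "T"
            t = 2
            for arm, (maj, mnr) in cn_arms.items():
                r = arm_coords[arm]
                if gchrom == str(r.chrom) and r.start <= gpos <= r.end:
                    t = maj + mnr
            if ploidy_state == "tetraploid":
                v = expected_vaf(2, 2 * t, purity)  # drivers precede the WGD
            else:
                v = expected_vaf(1, t, purity)
            gdepth = int(_draw_depth(rng, 1, config.depth_mean)[0])
            galt_n = int(rng.binomial(gdepth, min(v, 0.999)))
            is_sbs = len(gref) == 1 and gcsq != "frameshift"
            mut_frames.append(
                pd.DataFrame(
                    [
                        {
                            "sample": sample,
                            "chrom": gchrom,
                            "pos": gpos,
                            "ref": gref if gcsq != "frameshift" else gref + "A",
                            "alt": galt if gcsq != "frameshift" else gref,
                            "context": _context_for(gref, galt) if is_sbs else None,
                            "gene": gname,
                            "protein_change": gchg,
                            "consequence": gcsq,
                            "alt_count": galt_n,
                            "total_count": gdepth,
                            "germline": gname == "MBD4",
                        }
                    ]
                )
            )

        # --- hotspot pileups ----------------------------------------------
        driver_sites = {
            (g, int("".join(ch for ch in c if ch.isdigit()) or 0)) for g, c, _ in driver_rows
        }
        for prow in panel.itertuples(index=False):
            tdepth = int(_draw_depth(rng, 1, config.depth_mean)[0])
            if (prow.gene, int(prow.codon)) in driver_sites:
                if ploidy_state == "tetraploid":
                    v = expected_vaf(2, 4, purity)
                else:
                    v = expected_vaf(1, 2, purity)
            else:
                v = config.error_rate
            pile_rows.append(
                {
                    "sample": sample,
                    "chrom": prow.chrom,
                    "pos": prow.pos,
                    "ref": prow.ref,
                    "alt": prow.alt,
                    "alt_count": int(rng.binomial(tdepth, v)),
                    "total_count": tdepth,
                    "is_normal": 0,
                }
            )
            ndepth = int(np.maximum(rng.poisson(config.normal_depth), 10))
            pile_rows.append(
                {
                    "sample": sample,
                    "chrom": prow.chrom,
                    "pos": prow.pos,
                    "ref": prow.ref,
                    "alt": prow.alt,
                    "alt_count": int(rng.binomial(ndepth, config.error_rate)),
                    "total_count": ndepth,
                    "is_normal": 1,
                }
            )

        # --- clinical -------------------------------------------------------
        hazard = config.hazard_by_category[cat - 1]
        t_event = float(rng.exponential(1.0 / hazard))
        event = t_event <= config.censor_horizon_years
        clin_rows.append(
            {
                "sample": sample,
                "site": site,
                "time_years": round(min(t_event, config.censor_horizon_years), 6),
                "event": int(event),
                "age": round(float(np.clip(rng.normal(62, 10), 20, 95)), 1),
            }
        )
        truth_rows.append(
            {
                "sample": sample,
                "category": cat,
                "purity": purity,
                "ploidy": 4 if ploidy_state == "tetraploid" else 2,
                "ploidy_state": ploidy_state,
                "subclone_fraction": subclone,
                "site": site,
                "phenotype": phenotype,
                "tmb_true": tmb_true,
                "n_mut": n_mut,
                "hazard_group": cat,
                "driver": driver_label,
                "bap1_mutant": bap1,
                "pathway_disrupted": disrupted,
                "disruption_route": route or "",
                **{f"frac_{k}": fractions[k] for k in sbs.columns},
            }
        )

    mutations = pd.concat(mut_frames, ignore_index=True)
    return CohortTables(
        mutations=mutations,
        segments=pd.DataFrame(seg_rows),
        purity_ploidy=pd.DataFrame(pp_rows),
        pileups=pd.DataFrame(pile_rows),
        clinical=pd.DataFrame(clin_rows),
        truth=pd.DataFrame(truth_rows),
    )
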