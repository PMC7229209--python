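"""End-to-end cohort analysis: simulate/load -> signatures -> hotspots ->
ploidy -> categories -> drivers -> survival.

``run_cohort`` operates on in-memory tables and returns a per-sample report
(one row per sample: TMB, dominant signature, phenotype flags, ploidy call,
category, driver, double-hit statuses, survival group) plus cohort-level
test results.  ``run_pipeline`` wraps it with file input/output, a flat
key=value config format and a JSON run manifest, and is what the command
line drives.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cna import arm_status, classify_category, fraction_genome_altered, high_gain_flags, isochromosome_8q_check
from .cohort_sim import SimConfig, simulate_cohort
from .drivers import (
    biallelic_status,
    gq_pathway_summary,
    pathway_8q_association,
)
from .hotspot_caller import call_cohort
from .io import (
    mutations_to_records,
    read_table,
    segment_profiles,
    validate_segment_table,
    write_cohort,
    write_table,
)
from .ploidy import (
    InsufficientSitesError,
    adjust_copy_numbers,
    extract_balanced_vafs,
    fit_mixture,
    resolve_wgd,
)
from .resources import load_signature_matrix
from .sigfit import (
    build_catalogue,
    dominant_signature,
    exposure_fractions,
    fit_exposures,
    phenotype_flags,
    tmb,
)
from .survival import compare_groups

logger = logging.getLogger("umwgs")

#: Cap on balanced-region sites used per sample in the WGD test; keeps the
#: mixture fits fast on hypermutated samples without hurting power.
MAX_PLOIDY_SITES = 2000


@dataclass
class RunConfig:
    outdir: str = "umwgs_run"
    seed: int = 0
    n_samples: int = 103
    callable_mb: float = 2800.0
    alpha_hotspot: float = 1e-3
    alpha_wgd: float = 1e-3
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "signatures": True,
            "hotspots": True,
            "ploidy": True,
            "categorize": True,
            "drivers": True,
            "survival": True,
        }
    )
    inputs: dict = field(default_factory=dict)  # optional paths overriding simulate

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` config; ``stage.<name> = on|off`` toggles."""
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("stage."):
                cfg.stages[key[6:]] = value.lower() in ("on", "true", "1", "yes")
            elif key.startswith("input."):
                cfg.inputs[key[6:]] = value
            elif key in ("outdir",):
                cfg.outdir = value
            elif key in ("seed", "n_samples"):
                setattr(cfg, key, int(value))
            elif key in ("callable_mb", "alpha_hotspot", "alpha_wgd"):
                setattr(cfg, key, float(value))
            else:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        return cfg


def run_cohort(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    purity_ploidy: pd.DataFrame,
    pileups: pd.DataFrame | None,
    clinical: pd.DataFrame | None,
    callable_mb: float = 2800.0,
    alpha_hotspot: float = 1e-3,
    alpha_wgd: float = 1e-3,
    signatures: pd.DataFrame | None = None,
    dbs_signatures: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every analysis stage over in-memory cohort tables."""
    if signatures is None:
        signatures = load_signature_matrix(kind="sbs")
    if dbs_signatures is None:
        dbs_signatures = load_signature_matrix(kind="dbs")
    profiles = segment_profiles(segments, purity_ploidy)
    samples = sorted(profiles)
    by_sample = dict(tuple(mutations.groupby("sample", sort=False)))

    # --- signatures and burden -------------------------------------------
    sig_rows = {}
    for s in samples:
        mdf = by_sample.get(s, mutations.iloc[0:0])
        somatic = mdf[~mdf["germline"].astype(bool)] if len(mdf) else mdf
        cat = build_catalogue(somatic, sample_id=s)
        exp = fit_exposures(cat, signatures, kind="sbs")
        dbs_exp = (
            fit_exposures(cat, dbs_signatures, kind="dbs")
            if cat.dbs_counts is not None
            else None
        )
        sig_rows[s] = {
            "catalogue": cat,
            "exposures": exp,
            "dbs_exposures": dbs_exp,
            "tmb": tmb(cat.n_sbs + cat.n_dbs, callable_mb),
        }
    median_tmb = float(np.median([v["tmb"] for v in sig_rows.values()]))
    for s in samples:
        v = sig_rows[s]
        v["flags"] = phenotype_flags(
            v["exposures"], v["tmb"], median_tmb, dbs_exposures=v["dbs_exposures"]
        )

    # --- hotspot rescue ---------------------------------------------------
    hotspot_calls = None
    if pileups is not None and len(pileups):
        hotspot_calls = call_cohort(pileups, alpha=alpha_hotspot)

    # --- WGD vs heterogeneity --------------------------------------------
    ploidy_rows = {}
    for s in samples:
        prof = profiles[s]
        mdf = by_sample.get(s)
        row = {"call": "diploid", "lrt_p": np.nan, "adjusted": False}
        if round(prof.ploidy) >= 4 and mdf is not None:
            vafs = extract_balanced_vafs(prof, mdf)
            if len(vafs) > MAX_PLOIDY_SITES:
                rng = np.random.default_rng(0)
                idx = rng.choice(len(vafs), MAX_PLOIDY_SITES, replace=False)
                vafs.alt, vafs.total = vafs.alt[idx], vafs.total[idx]
            try:
                tet = fit_mixture(vafs, "tetraploid")
                het = fit_mixture(vafs, "het_diploid")
                res = resolve_wgd(tet, het, alpha=alpha_wgd)
                row = {"call": res.call, "lrt_p": res.lrt_p, "adjusted": res.adjusted}
                if res.adjusted:
                    profiles[s] = adjust_copy_numbers(prof)
            except InsufficientSitesError:
                row = {"call": "tetraploid", "lrt_p": np.nan, "adjusted": False}
        ploidy_rows[s] = row

    # --- CNA categories ---------------------------------------------------
    cohort_arms = {}
    cna_rows = {}
    for s in samples:
        prof = profiles[s]
        arms = arm_status(prof)
        cohort_arms[s] = arms
        by_arm = {a.arm: a for a in arms}
        category = classify_category(arms)
        m3 = by_arm["3p"].status == "loss" and by_arm["3q"].status == "loss"
        cna_rows[s] = {
            "category": category,
            "m3": m3,
            "gain_8q": by_arm["8q"].status == "gain",
            "fga": fraction_genome_altered(prof),
            "n_high_gain": len(high_gain_flags(prof)),
        }
    iso_violations = isochromosome_8q_check(cohort_arms)

    # --- drivers ----------------------------------------------------------
    driver_rows = {}
    for s in samples:
        mdf = by_sample.get(s)
        recs = mutations_to_records(mdf) if mdf is not None else []
        annotated = [m for m in recs if m.gene]
        gq = gq_pathway_summary(annotated, sample_id=s)
        calls = {}
        for gene in ("BAP1", "TP53", "RPL5"):
            calls[gene] = biallelic_status(gene, annotated, profiles[s])
        disrupted = (
            calls["TP53"].status != "none"
            or calls["TP53"].loh
            or calls["RPL5"].status != "none"
            or calls["RPL5"].loh
        )
        driver_rows[s] = {
            "driver": "; ".join(gq.hits),
            "gq_exception": gq.exclusivity_violation,
            "gq_known_co_occurrence": gq.known_co_occurrence,
            "bap1_status": calls["BAP1"].status,
            "tp53_status": calls["TP53"].status,
            "rpl5_status": calls["RPL5"].status,
            "rpl5_tp53_disrupted": disrupted,
        }
    assoc = pathway_8q_association(
        np.array([driver_rows[s]["rpl5_tp53_disrupted"] for s in samples]),
        np.array([cna_rows[s]["gain_8q"] for s in samples]),
    )

    # --- report -----------------------------------------------------------
    report = pd.DataFrame(
        [
            {
                "sample": s,
                "tmb": sig_rows[s]["tmb"],
                "dominant_signature": dominant_signature(sig_rows[s]["exposures"]),
                "uvr": sig_rows[s]["flags"]["uvr"],
                "deamination_hypermutator": sig_rows[s]["flags"][
                    "deamination_hypermutator"
                ],
                "ploidy_call": ploidy_rows[s]["call"],
                "wgd_adjusted": ploidy_rows[s]["adjusted"],
                **cna_rows[s],
                **driver_rows[s],
            }
            for s in samples
        ]
    )
    summary = {
        "median_tmb": median_tmb,
        "isochromosome_8q_violations": iso_violations,
        "rpl5_tp53_8q_association": assoc,
    }

    # --- survival ---------------------------------------------------------
    if clinical is not None and len(clinical):
        joined = clinical.merge(
            report[["sample", "category", "m3"]], on="sample", how="inner"
        )
        joined["m3_label"] = np.where(joined["m3"], "M3", "D3")
        joined["event"] = joined["event"].astype(bool)
        surv = {}
        try:
            surv["M3_vs_D3"] = compare_groups(joined, "m3_label", "M3", "D3")
            for a, b in ((1, 2), (3, 4)):
                if {a, b} <= set(joined["category"]):
                    surv[f"cat{a}_vs_cat{b}"] = compare_groups(
                        joined, "category", str(a), str(b)
                    )
        except ValueError as exc:  # e.g. a group absent in tiny cohorts
            logger.warning("survival comparison skipped: %s", exc)
        summary["survival"] = surv
    if hotspot_calls is not None:
        summary["hotspot_calls"] = hotspot_calls
    return report, summary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> pd.DataFrame | None:
    """File-driven pipeline run; writes stage outputs and a run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not any(config.stages.values()):
        logger.warning("all stages toggled off: nothing to do")
        return None
    if config.stages.get("simulate", True) and not config.inputs:
        sim = SimConfig(
            n_samples=config.n_samples, callable_mb=config.callable_mb, seed=config.seed
        )
        tables = simulate_cohort(sim)
        inputs = write_cohort(tables, outdir / "inputs")
        mutations = tables.mutations
        segments = tables.segments
        purity_ploidy = tables.purity_ploidy
        pileups = tables.pileups
        clinical = tables.clinical
    else:
        inputs = {k: Path(v) for k, v in config.inputs.items()}
        mutations = read_table(inputs["mutations"])
        segments = read_table(inputs["segments"])
        validate_segment_table(segments, str(inputs["segments"]))
        purity_ploidy = read_table(inputs["purity_ploidy"])
        pileups = read_table(inputs["pileups"]) if "pileups" in inputs else None
        clinical = read_table(inputs["clinical"]) if "clinical" in inputs else None

    report, summary = run_cohort(
        mutations,
        segments,
        purity_ploidy,
        pileups if config.stages.get("hotspots", True) else None,
        clinical if config.stages.get("survival", True) else None,
        callable_mb=config.callable_mb,
        alpha_hotspot=config.alpha_hotspot,
        alpha_wgd=config.alpha_wgd,
    )
    write_table(report, outdir / "report.tsv")
    if "hotspot_calls" in summary:
        write_table(summary["hotspot_calls"], outdir / "hotspot_calls.tsv")
    manifest = {
        "umwgs_version": __version__,
        "seed": config.seed,
        "n_samples": config.n_samples,
        "callable_mb": config.callable_mb,
        "alpha_hotspot": config.alpha_hotspot,
        "alpha_wgd": config.alpha_wgd,
        "stages": config.stages,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "input_sha256": {
            k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).exists()
        },
        "median_tmb": summary["median_tmb"],
        "isochromosome_8q_violations": summary["isochromosome_8q_violations"],
        "rpl5_tp53_8q_p": summary["rpl5_tp53_8q_association"]["p_two_sided"],
        "survival": {
            k: {kk: vv for kk, vv in v.items() if kk in ("chi_square", "p", "n")}
            for k, v in summary.get("survival", {}).items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("report written to %s", outdir / "report.tsv")
    return report
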