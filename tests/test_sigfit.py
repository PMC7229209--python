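import numpy as np
import pandas as pd
import pytest
import scipy.stats

from umwgs.cohort_sim import simulate_catalogue
from umwgs.sigfit import (
    MutationCatalogue,
    build_catalogue,
    dominant_signature,
    exposure_fractions,
    fit_exposures,
    phenotype_flags,
    tmb,
)
from umwgs.types import ExposureVector, MutationRecord


def _mut(ctx, ref=None, alt=None, **kw):
    if ref is None:
        ref, alt = ctx[2], ctx[4]
    defaults = dict(
        sample_id="S", chrom="1", pos=100, ref=ref, alt=alt, context=ctx,
        alt_count=5, total_count=20,
    )
    defaults.update(kw)
    return MutationRecord(**defaults)


class TestBuildCatalogue:
    def test_single_mutation_single_class(self):
        cat = build_catalogue([_mut("T[C>T]T")])
        s = cat.sbs_series()
        assert s["T[C>T]T"] == 1 and s.sum() == 1

    def test_purine_centred_context_is_strand_normalised(self):
        cat = build_catalogue(
            [MutationRecord("S", "1", 1, "G", "A", context="A[G>A]C")]
        )
        assert cat.sbs_series()["G[C>T]T"] == 1

    def test_doublets_and_indels_binned_separately(self):
        muts = [
            _mut("T[C>T]T"),
            MutationRecord("S", "1", 5, "CC", "TT", context="CC>TT"),
            MutationRecord("S", "1", 9, "CTT", "C", context=None),  # indel
        ]
        cat = build_catalogue(muts)
        assert cat.n_sbs == 1
        assert cat.dbs_series()["CC>TT"] == 1
        assert cat.n_sbs + cat.n_dbs == 2  # indel excluded

    def test_context_inconsistent_with_ref_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            build_catalogue([MutationRecord("S", "1", 1, "A", "T", context="T[C>T]T")])

    def test_counts_conserved(self, sbs_signatures):
        rng = np.random.default_rng(3)
        classes = rng.choice(
            sbs_signatures.index.to_numpy(),
            size=100,
            p=sbs_signatures["SBS7a"].to_numpy(),
        )
        muts = [_mut(c) for c in classes]
        cat = build_catalogue(muts)
        assert cat.n_sbs == 100
        res = scipy.stats.chisquare(
            cat.sbs_counts, f_exp=100 * sbs_signatures["SBS7a"].to_numpy()
        )
        assert res.pvalue > 0.01


class TestFitExposures:
    def test_pure_column_recovered_exactly(self, sbs_signatures):
        cat = MutationCatalogue("S", 100 * sbs_signatures["SBS1"].to_numpy())
        exp = fit_exposures(cat, sbs_signatures)
        d = exp.as_dict()
        assert d["SBS1"] == pytest.approx(100, abs=1e-6)
        assert sum(v for k, v in d.items() if k != "SBS1") == pytest.approx(0, abs=1e-6)
        assert exp.residual_norm == pytest.approx(0, abs=1e-6)

    def test_noise_free_mixture_recovered(self, sbs_signatures):
        c = 60 * sbs_signatures["SBS1"] + 40 * sbs_signatures["SBS7a"]
        exp = fit_exposures(MutationCatalogue("S", c.to_numpy()), sbs_signatures)
        d = exp.as_dict()
        assert d["SBS1"] == pytest.approx(60, abs=1e-6)
        assert d["SBS7a"] == pytest.approx(40, abs=1e-6)

    def test_kkt_conditions(self, sbs_signatures):
        cat = simulate_catalogue(
            500, {"SBS5": 0.7, "SBS1": 0.3}, sbs_signatures, seed=5
        )
        exp = fit_exposures(cat, sbs_signatures)
        S = sbs_signatures.to_numpy()
        grad = S.T @ (S @ exp.values - cat.sbs_counts)
        active = exp.values > 1e-9
        assert np.all(np.abs(grad[active]) < 1e-6)
        assert np.all(grad[~active] >= -1e-6)

    def test_no_feasible_perturbation_improves_residual(self, sbs_signatures):
        """NNLS optimality: 1,000 random non-negativity-respecting nudges."""
        cat = simulate_catalogue(
            300, {"SBS5": 0.5, "SBS7a": 0.3, "SBS1": 0.2}, sbs_signatures, seed=8
        )
        exp = fit_exposures(cat, sbs_signatures)
        S = sbs_signatures.to_numpy()
        base = np.linalg.norm(cat.sbs_counts - S @ exp.values)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            step = rng.normal(0, 1.0, size=len(exp.values))
            cand = np.clip(exp.values + step, 0, None)
            assert np.linalg.norm(cat.sbs_counts - S @ cand) >= base - 1e-9

    def test_scale_equivariance(self, sbs_signatures):
        c = 30 * sbs_signatures["SBS1"] + 70 * sbs_signatures["SBS5"]
        e1 = fit_exposures(MutationCatalogue("S", c.to_numpy()), sbs_signatures).values
        e5 = fit_exposures(MutationCatalogue("S", 5 * c.to_numpy()), sbs_signatures).values
        np.testing.assert_allclose(e5, 5 * e1, atol=1e-6)

    def test_empty_catalogue_flagged(self, sbs_signatures):
        exp = fit_exposures(MutationCatalogue("S", np.zeros(96)), sbs_signatures)
        assert exp.empty_input and exp.total == 0

    def test_label_mismatch_rejected(self, sbs_signatures):
        shuffled = sbs_signatures.sample(frac=1.0, random_state=1)
        with pytest.raises(ValueError):
            fit_exposures(MutationCatalogue("S", np.ones(96)), shuffled)

    def test_matches_simplex_grid_oracle(self, sbs_signatures):
        """NNLS equals a dense direction-grid search with optimal scaling."""
        cols = ["SBS1", "SBS5", "SBS7a"]
        S = sbs_signatures[cols].to_numpy()
        G = S.T @ S
        rng = np.random.default_rng(17)
        step = 0.001
        fr = np.arange(0, 1 + step / 2, step)
        grid = np.array(
            [(a, b, 1 - a - b) for a in fr for b in fr if a + b <= 1 + 1e-12]
        )
        for trial in range(5):
            w = rng.dirichlet(np.ones(3))
            c = rng.multinomial(400, (S @ w) / (S @ w).sum()).astype(float)
            cat = MutationCatalogue("S", c)
            fit = fit_exposures(cat, sbs_signatures[cols])
            # oracle: for each direction e, optimal scale t* = c'Se / e'Ge
            cS = c @ S
            num = grid @ cS
            den = np.einsum("ij,jk,ik->i", grid, G, grid)
            t = np.clip(num / np.maximum(den, 1e-300), 0, None)
            resid2 = c @ c - 2 * t * num + t**2 * den
            best = np.min(resid2)
            assert fit.residual_norm**2 <= best + 1e-6


def test_exposure_fractions():
    e = ExposureVector(("a", "b", "c"), np.array([60.0, 40.0, 0.0]), 0.0)
    assert exposure_fractions(e) == pytest.approx({"a": 0.6, "b": 0.4, "c": 0.0})
    e2 = ExposureVector(("a", "b", "c"), np.array([0.0, 0.0, 5.0]), 0.0)
    assert exposure_fractions(e2)["c"] == 1.0
    with pytest.raises(ValueError):
        exposure_fractions(ExposureVector(("a",), np.array([0.0]), 0.0))


def test_tmb():
    assert tmb(1500, 3000) == pytest.approx(0.5)
    assert tmb(0, 2800) == 0.0
    with pytest.raises(ValueError):
        tmb(10, 0)


class TestPhenotypeFlags:
    def _exp(self, d):
        names = ("SBS1", "SBS5", "SBS7a", "SBS7b")
        return ExposureVector(names, np.array([d.get(k, 0.0) for k in names]), 0.0)

    def test_uvr_requires_fraction_and_high_tmb(self):
        flags = phenotype_flags(self._exp({"SBS7a": 60, "SBS5": 40}), 4.0, 0.5)
        assert flags["uvr"] and not flags["deamination_hypermutator"]
        flags = phenotype_flags(self._exp({"SBS7a": 60, "SBS5": 40}), 0.4, 0.5)
        assert not flags["uvr"]

    def test_flat_low_burden_sample_unflagged(self):
        flags = phenotype_flags(self._exp({"SBS5": 100}), 0.4, 0.5)
        assert not flags["uvr"] and not flags["deamination_hypermutator"]

    def test_deamination_needs_tmb_above_3(self):
        assert phenotype_flags(self._exp({"SBS1": 90, "SBS5": 10}), 5.0, 0.5)[
            "deamination_hypermutator"
        ]
        assert not phenotype_flags(self._exp({"SBS1": 90, "SBS5": 10}), 2.0, 0.5)[
            "deamination_hypermutator"
        ]

    def test_missing_columns_rejected(self):
        e = ExposureVector(("SBS5",), np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            phenotype_flags(e, 1.0, 0.5)


def test_exposure_recovery_on_simulated_cohort(sbs_signatures):
    """Mean absolute error of refitted fractions < 0.05 at 1,000 mutations."""
    rng = np.random.default_rng(13)
    errs = []
    for i in range(50):
        w = rng.dirichlet(np.ones(4) * 2)
        truth = dict(zip(sbs_signatures.columns, w))
        cat = simulate_catalogue(1000, truth, sbs_signatures, seed=1000 + i)
        frac = exposure_fractions(fit_exposures(cat, sbs_signatures))
        errs.append(np.mean([abs(frac[k] - truth[k]) for k in truth]))
    assert np.mean(errs) < 0.05


def test_uvr_flag_recovery_on_cohort(cohort200, sbs_signatures, dbs_signatures):
    """UVR-positive fraction tracks the simulated iris fraction; flag
    sensitivity and specificity both >= 0.95 against ground truth."""
    from umwgs.pipeline import run_cohort

    cfg, tab = cohort200
    report, _ = run_cohort(
        tab.mutations, tab.segments, tab.purity_ploidy, None, None,
        callable_mb=cfg.callable_mb,
    )
    m = report.merge(tab.truth, on="sample")
    truth_uv = m["phenotype"] == "iris_uvr"
    called = m["uvr"].astype(bool)
    assert abs(called.mean() - 0.10) <= 0.05
    sens = (called & truth_uv).sum() / truth_uv.sum()
    spec = (~called & ~truth_uv).sum() / (~truth_uv).sum()
    assert sens >= 0.95 and spec >= 0.95
    mbd4_truth = m["phenotype"] == "mbd4"
    if mbd4_truth.any():
        assert (m.loc[mbd4_truth, "deamination_hypermutator"]).all()
        assert (m.loc[mbd4_truth, "tmb"] > 3).all()


def test_dominant_signature():
    e = ExposureVector(("SBS1", "SBS5"), np.array([10.0, 90.0]), 0.0)
    assert dominant_signature(e) == "SBS5"
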