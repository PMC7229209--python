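import itertools

import numpy as np
import pandas as pd
import pytest

from umwgs.cna import (
    ArmStatus,
    arm_status,
    classify_category,
    fraction_genome_altered,
    high_gain_flags,
    isochromosome_8q_check,
)
from umwgs.types import SegmentProfile

TOY_ARMS = pd.DataFrame(
    {
        "arm": ["1p", "1q", "3p", "3q", "8p", "8q"],
        "chrom": ["1", "1", "3", "3", "8", "8"],
        "start": [1, 10_001, 1, 10_001, 1, 10_001],
        "end": [10_000, 20_000, 10_000, 20_000, 10_000, 20_000],
    }
)


def _profile(segs, purity=0.8, ploidy=2.0, sample="S"):
    df = pd.DataFrame(segs, columns=["chrom", "startpos", "endpos", "nMajor", "nMinor"])
    return SegmentProfile(sample, df, purity, ploidy)


def _full(cn_by_arm):
    segs = []
    for r in TOY_ARMS.itertuples(index=False):
        maj, mnr = cn_by_arm.get(r.arm, (1, 1))
        segs.append((r.chrom, r.start, r.end, maj, mnr))
    return _profile(segs)


class TestArmStatus:
    def test_whole_chromosome_loss_called_on_both_arms(self):
        arms = arm_status(_full({"3p": (1, 0), "3q": (1, 0)}), TOY_ARMS)
        m = {a.arm: a.status for a in arms}
        assert m["3p"] == "loss" and m["3q"] == "loss" and m["1p"] == "neutral"

    def test_whole_arm_gain(self):
        arms = arm_status(_full({"8q": (2, 1)}), TOY_ARMS)
        assert {a.arm: a.status for a in arms}["8q"] == "gain"

    def test_half_arm_event_is_boundary(self):
        """Exactly 50% of arm length aberrant meets the call threshold."""
        segs = [("1", 1, 5_000, 2, 1), ("1", 5_001, 10_000, 1, 1),
                ("1", 10_001, 20_000, 1, 1), ("3", 1, 10_000, 1, 1),
                ("3", 10_001, 20_000, 1, 1), ("8", 1, 10_000, 1, 1),
                ("8", 10_001, 20_000, 1, 1)]
        arms = arm_status(_profile(segs), TOY_ARMS)
        assert {a.arm: a.status for a in arms}["1p"] == "gain"

    def test_insufficient_coverage_undefined(self):
        segs = [("1", 1, 2_000, 2, 1)]
        arms = arm_status(_profile(segs), TOY_ARMS)
        m = {a.arm: a for a in arms}
        assert m["1p"].status is None and m["1p"].fraction_covered == pytest.approx(0.2)

    def test_tetraploid_baseline(self):
        segs = [(r.chrom, r.start, r.end, 2, 2) for r in TOY_ARMS.itertuples(index=False)]
        prof = _profile(segs, ploidy=4.0)
        assert all(a.status == "neutral" for a in arm_status(prof, TOY_ARMS))

    def test_assembly_mismatch_rejected(self):
        segs = [("1", 1, 50_000, 1, 1)]
        with pytest.raises(ValueError, match="assembly"):
            arm_status(_profile(segs), TOY_ARMS)

    def test_matches_per_base_majority_oracle(self):
        """Random segmentations agree with a per-base vote."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            bounds = np.sort(rng.choice(np.arange(2, 20_000), size=6, replace=False))
            edges = [1, *bounds.tolist(), 20_000]
            segs = []
            for lo, hi in zip(edges[:-1], edges[1:]):
                maj = int(rng.integers(0, 4))
                mnr = int(rng.integers(0, maj + 1))
                segs.append(("1", lo if lo == 1 else lo, hi, maj, mnr))
            # make closed non-overlapping intervals
            fixed = []
            prev_end = 0
            for chrom, lo, hi, maj, mnr in segs:
                lo = prev_end + 1
                if lo > hi:
                    continue
                fixed.append((chrom, lo, hi, maj, mnr))
                prev_end = hi
            arms_df = TOY_ARMS[TOY_ARMS["chrom"] == "1"]
            prof = _profile(fixed)
            calls = {a.arm: a.status for a in arm_status(prof, arms_df)}
            # oracle: per-base copy state over each arm
            base = np.zeros(20_001, dtype=int)
            covered = np.zeros(20_001, dtype=bool)
            for chrom, lo, hi, maj, mnr in fixed:
                base[lo : hi + 1] = maj + mnr
                covered[lo : hi + 1] = True
            for r in arms_df.itertuples(index=False):
                span = slice(r.start, r.end + 1)
                n = r.end - r.start + 1
                cov = covered[span]
                if cov.sum() / n < 0.5:
                    expected = None
                elif (base[span][cov] > 2).sum() / n >= 0.5:
                    expected = "gain"
                elif (base[span][cov] < 2).sum() / n >= 0.5:
                    expected = "loss"
                else:
                    expected = "neutral"
                assert calls[r.arm] == expected


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "chr3,gain8q,expected",
        [("neutral", False, 1), ("neutral", True, 2), ("loss", False, 3), ("loss", True, 4)],
    )
    def test_category_mapping(self, chr3, gain8q, expected):
        arms = [
            ArmStatus("3p", chr3, 1.0, 0.0, 1.0 if chr3 == "loss" else 0.0),
            ArmStatus("3q", chr3, 1.0, 0.0, 1.0 if chr3 == "loss" else 0.0),
            ArmStatus("8q", "gain" if gain8q else "neutral", 1.0, 0.0, 0.0),
        ]
        assert classify_category(arms) == expected

    def test_exhaustive_truth_table(self):
        """All 9 combinations of chr3 x 8q statuses map deterministically;
        only loss-of-both-arms counts as monosomy 3."""
        for s3, s8 in itertools.product(("loss", "neutral", "gain"), repeat=2):
            arms = [
                ArmStatus("3p", s3, 1.0, 0, 0),
                ArmStatus("3q", s3, 1.0, 0, 0),
                ArmStatus("8q", s8, 1.0, 0, 0),
            ]
            cat = classify_category(arms)
            m3 = s3 == "loss"
            gain = s8 == "gain"
            assert cat == {(False, False): 1, (False, True): 2,
                           (True, False): 3, (True, True): 4}[(m3, gain)]

    def test_one_arm_loss_is_not_monosomy(self):
        arms = [
            ArmStatus("3p", "loss", 1.0, 0, 1),
            ArmStatus("3q", "neutral", 1.0, 0, 0),
            ArmStatus("8q", "neutral", 1.0, 0, 0),
        ]
        assert classify_category(arms) == 1

    def test_undefined_required_arm_rejected(self):
        arms = [
            ArmStatus("3p", None, 0.1, 0, 0),
            ArmStatus("3q", "loss", 1.0, 0, 1),
            ArmStatus("8q", "gain", 1.0, 1, 0),
        ]
        with pytest.raises(ValueError, match="undefined"):
            classify_category(arms)

    def test_cohort_recovery(self, cohort200):
        from umwgs.io import segment_profiles

        _, tab = cohort200
        profiles = segment_profiles(tab.segments, tab.purity_ploidy)
        truth = tab.truth.set_index("sample")
        hits = [
            classify_category(arm_status(prof)) == truth.loc[s, "category"]
            for s, prof in profiles.items()
        ]
        assert np.mean(hits) >= 0.99


class TestFractionGenomeAltered:
    def test_unaltered_diploid_is_zero(self):
        assert fraction_genome_altered(_full({})) == 0.0

    def test_half_genome_altered(self):
        segs = [("1", 1, 10_000, 2, 1), ("1", 10_001, 20_000, 1, 1)]
        assert fraction_genome_altered(_profile(segs)) == pytest.approx(0.5)

    def test_cn_loh_counts_as_altered(self):
        segs = [("1", 1, 10_000, 2, 0)]
        assert fraction_genome_altered(_profile(segs)) == 1.0

    def test_tetraploid_baseline_is_2_2(self):
        segs = [("1", 1, 10_000, 2, 2), ("1", 10_001, 20_000, 4, 2)]
        assert fraction_genome_altered(_profile(segs, ploidy=4.0)) == pytest.approx(0.5)

    def test_invariant_to_segment_splitting(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            segs = [("1", 1, 10_000, 2, 1), ("1", 10_001, 20_000, 1, 1)]
            cut = int(rng.integers(2, 10_000))
            split = [("1", 1, cut, 2, 1), ("1", cut + 1, 10_000, 2, 1),
                     ("1", 10_001, 20_000, 1, 1)]
            assert fraction_genome_altered(_profile(split)) == pytest.approx(
                fraction_genome_altered(_profile(segs))
            )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            fraction_genome_altered(
                SegmentProfile(
                    "S",
                    pd.DataFrame(
                        columns=["chrom", "startpos", "endpos", "nMajor", "nMinor"]
                    ),
                    0.8,
                    2.0,
                )
            )


class TestHighGain:
    @pytest.mark.parametrize("cn,flagged", [((3, 2), False), ((4, 2), True), ((5, 3), True)])
    def test_total_cn_threshold_of_6(self, cn, flagged):
        prof = _profile([("1", 1, 1000, cn[0], cn[1])])
        assert (len(high_gain_flags(prof)) == 1) is flagged


class TestIsochromosome8q:
    def test_8p_loss_with_8q_gain_conforms(self):
        arms = {"S1": [ArmStatus("8p", "loss", 1, 0, 1), ArmStatus("8q", "gain", 1, 1, 0)]}
        assert isochromosome_8q_check(arms) == []

    def test_8p_loss_without_8q_gain_reported(self):
        arms = {"S1": [ArmStatus("8p", "loss", 1, 0, 1), ArmStatus("8q", "neutral", 1, 0, 0)]}
        assert isochromosome_8q_check(arms) == ["S1"]

    def test_simulator_enforces_constraint(self, cohort200):
        from umwgs.io import segment_profiles

        _, tab = cohort200
        profiles = segment_profiles(tab.segments, tab.purity_ploidy)
        cohort_arms = {s: arm_status(p) for s, p in profiles.items()}
        assert isochromosome_8q_check(cohort_arms) == []
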