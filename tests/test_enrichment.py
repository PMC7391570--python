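"""Odds-ratio statistic, classification thresholds, Wilcoxon/BH, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tmamine as tm
from tmamine.enrichment import AF_ENRICHED, CTR_ENRICHED, NOT_SIGNIFICANT, Contrast

from conftest import balanced_metadata, random_abundance


def printed_or_oracle(data: pd.DataFrame, ctr_samples, af_samples, feature):
    """Loop transliteration of the literal formula (control arm numerator)."""
    s_ctr = sum(data.loc[feature, s] for s in ctr_samples)
    s_af = sum(data.loc[feature, s] for s in af_samples)
    comp_ctr = sum(data.loc[i, s] for s in ctr_samples
                   for i in data.index if i != feature)
    comp_af = sum(data.loc[i, s] for s in af_samples
                  for i in data.index if i != feature)
    return (s_ctr / comp_ctr) / (s_af / comp_af)


class TestOddsRatio:
    def test_hand_computed_toy(self):
        """CTR sums (k: 1, rest: 9), AF sums (k: 4, rest: 6):
        OR = (4/6)/(1/9) = 6 under the AF-numerator orientation."""
        data = pd.DataFrame(
            [[0.5, 0.5, 2.0, 2.0],    # feature k
             [4.5, 4.5, 3.0, 3.0]],   # the rest
            index=["k", "rest"], columns=["c1", "c2", "a1", "a2"])
        abund = tm.AbundanceMatrix(data)
        meta = balanced_metadata(2, 2)
        meta["sample_id"] = ["c1", "c2", "a1", "a2"]
        value = tm.odds_ratio(abund, meta, "k")
        assert value == pytest.approx(6.0)
        assert tm.classify_enrichment(value) == AF_ENRICHED

    def test_symmetric_feature_is_one(self):
        data = pd.DataFrame([[1.0, 2.0, 2.0, 1.0], [3.0, 1.0, 1.0, 3.0]],
                            index=["k", "rest"], columns=["c1", "c2", "a1", "a2"])
        meta = balanced_metadata(2, 2)
        meta["sample_id"] = ["c1", "c2", "a1", "a2"]
        value = tm.odds_ratio(tm.AbundanceMatrix(data), meta, "k")
        assert value == pytest.approx(1.0)
        assert tm.classify_enrichment(value) == NOT_SIGNIFICANT

    def test_label_swap_gives_exact_reciprocal(self):
        rng = np.random.default_rng(10)
        abund = random_abundance(rng, 6, 8)
        meta = balanced_metadata(4, 4)
        swapped = meta.copy()
        swapped["group"] = np.where(meta["group"] == "CTR", "AF", "CTR")
        for feature in abund.features:
            a = tm.odds_ratio(abund, meta, feature)
            b = tm.odds_ratio(abund, swapped, feature)
            assert a * b == pytest.approx(1.0, rel=1e-12)

    def test_printed_orientation_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            abund = random_abundance(rng, rng.integers(2, 8), 8)
            meta = balanced_metadata(4, 4)
            ctr, af = meta.sample_id[:4], meta.sample_id[4:]
            for feature in abund.features:
                oracle = printed_or_oracle(abund.data, ctr, af, feature)
                got = tm.odds_ratio(abund, meta, feature, orientation="printed")
                assert got == pytest.approx(oracle, rel=1e-12)
                flipped = tm.odds_ratio(abund, meta, feature)
                assert flipped == pytest.approx(1.0 / oracle, rel=1e-12)

    def test_zero_feature_sum_pseudo_mode_finite(self):
        data = pd.DataFrame([[0.0, 0.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
                            index=["k", "rest"], columns=["c1", "c2", "a1", "a2"])
        meta = balanced_metadata(2, 2)
        meta["sample_id"] = ["c1", "c2", "a1", "a2"]
        value = tm.odds_ratio(tm.AbundanceMatrix(data), meta, "k")
        assert np.isfinite(value) and value > 1

    def test_zero_feature_sum_exact_mode_infinite(self):
        data = pd.DataFrame([[0.0, 0.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
                            index=["k", "rest"], columns=["c1", "c2", "a1", "a2"])
        meta = balanced_metadata(2, 2)
        meta["sample_id"] = ["c1", "c2", "a1", "a2"]
        value = tm.odds_ratio(tm.AbundanceMatrix(data), meta, "k",
                              zero_mode="exact")
        assert np.isinf(value)
        assert tm.classify_enrichment(value) == AF_ENRICHED

    def test_all_zero_matrix_rejected(self):
        data = pd.DataFrame(np.zeros((2, 4)), index=["k", "r"],
                            columns=["c1", "c2", "a1", "a2"])
        meta = balanced_metadata(2, 2)
        meta["sample_id"] = ["c1", "c2", "a1", "a2"]
        with pytest.raises(ValueError, match="all zero"):
            tm.odds_ratio(tm.AbundanceMatrix(data), meta, "k")

    def test_empty_arm_rejected(self):
        rng = np.random.default_rng(12)
        abund = random_abundance(rng, 3, 4)
        meta = balanced_metadata(4, 0)
        with pytest.raises(ValueError, match="non-empty"):
            tm.odds_ratio(abund, meta, "f0")

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(13)
        abund = random_abundance(rng, 3, 4)
        with pytest.raises(KeyError):
            tm.odds_ratio(abund, balanced_metadata(2, 2), "missing")


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (2.0, NOT_SIGNIFICANT),    # strict >
        (0.5, NOT_SIGNIFICANT),    # strict <
        (2.0000001, AF_ENRICHED),
        (0.49, CTR_ENRICHED),
        (float("inf"), AF_ENRICHED),
        (0.0, CTR_ENRICHED),
        (1.0, NOT_SIGNIFICANT),
    ])
    def test_thresholds(self, value, expected):
        assert tm.classify_enrichment(value) == expected


class TestWilcoxonBH:
    def test_constant_feature_p_is_one(self):
        data = pd.DataFrame([[1.0] * 8], index=["k"],
                            columns=[f"s{j}" for j in range(8)])
        table = tm.wilcoxon_bh(tm.AbundanceMatrix(data), balanced_metadata(4, 4),
                               tm.DEFAULT_CONTRASTS[0])
        assert table.loc["k", "p_value"] == 1.0

    def test_bh_hand_example(self):
        """BH on (0.01, 0.02, 0.03, 0.04): q_i = min over j>=i of p_j * 4/j = 0.04."""
        q = tm.bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_monotone_in_p_on_null_features(self):
        rng = np.random.default_rng(14)
        abund = random_abundance(rng, 200, 20)
        table = tm.wilcoxon_bh(abund, balanced_metadata(10, 10),
                               tm.DEFAULT_CONTRASTS[0])
        ordered = table.sort_values("p_value")
        assert (np.diff(ordered["q_value"]) >= -1e-15).all()

    def test_small_arms_use_exact_distribution(self):
        """With tie-free arms of 3, the p-value matches the exact rank-sum
        null enumerated by hand: most extreme split has p = 2/20."""
        data = pd.DataFrame([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]], index=["k"],
                            columns=[f"s{j}" for j in range(6)])
        table = tm.wilcoxon_bh(tm.AbundanceMatrix(data), balanced_metadata(3, 3),
                               tm.DEFAULT_CONTRASTS[0])
        assert table.loc["k", "p_value"] == pytest.approx(0.1)

    def test_degenerate_arm_rejected(self):
        rng = np.random.default_rng(15)
        abund = random_abundance(rng, 3, 5)
        with pytest.raises(ValueError, match="CTR_vs_AF"):
            tm.wilcoxon_bh(abund, balanced_metadata(1, 4), tm.DEFAULT_CONTRASTS[0])

    def test_enrichment_table_has_or_for_group_contrast(self):
        rng = np.random.default_rng(16)
        abund = random_abundance(rng, 5, 10)
        table = tm.enrichment_table(abund, balanced_metadata(5, 5))
        assert {"or_value", "enrichment_class", "p_value", "q_value",
                "median_ctr", "median_af"} <= set(table.columns)

    def test_subtype_contrast_reports_ranksum_only(self):
        meta = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(8)],
            "group": ["AF"] * 8,
            "subtype": ["PAF"] * 4 + ["PersLt12m", "PersLt12m",
                                      "PersGt12m", "PersGt12m"]})
        rng = np.random.default_rng(17)
        abund = random_abundance(rng, 4, 8)
        table = tm.enrichment_table(abund, meta, tm.DEFAULT_CONTRASTS[1])
        assert "or_value" not in table.columns
        assert "q_value" in table.columns


class TestZScore:
    def test_simple_row(self):
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["k"], columns=list("abc"))
        z = tm.zscore_profile(tm.AbundanceMatrix(data))
        np.testing.assert_allclose(z.loc["k"], [-1.0, 0.0, 1.0])

    def test_constant_row_is_zero(self):
        data = pd.DataFrame([[2.0, 2.0, 2.0]], index=["k"], columns=list("abc"))
        z = tm.zscore_profile(tm.AbundanceMatrix(data))
        np.testing.assert_allclose(z.loc["k"], 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(18)
        abund = random_abundance(rng, 10, 12)
        z = tm.zscore_profile(abund)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_single_sample_rejected(self):
        data = pd.DataFrame([[1.0]], index=["k"], columns=["s"])
        with pytest.raises(ValueError, match="two samples"):
            tm.zscore_profile(tm.AbundanceMatrix(data))


@given(st.floats(0.01, 100.0))
def test_classification_partition_is_total(value):
    """Every finite positive OR lands in exactly one class."""
    assert tm.classify_enrichment(value) in (AF_ENRICHED, CTR_ENRICHED,
                                             NOT_SIGNIFICANT)


def test_composition_effect_is_real():
    """Scaling a sample's whole column (a depth change hitting all features)
    cancels out of ORs computed on relative abundances; scaling a single
    entry does not — the composition effect is real."""
    rng = np.random.default_rng(19)
    raw = random_abundance(rng, 5, 8)
    meta = balanced_metadata(4, 4)
    before = tm.odds_ratio_table(tm.to_relative(raw), meta)
    whole_column = raw.data.copy()
    whole_column["s0"] *= 7.0
    after_column = tm.odds_ratio_table(
        tm.to_relative(tm.AbundanceMatrix(whole_column)), meta)
    np.testing.assert_allclose(after_column, before, rtol=1e-12)
    one_entry = raw.data.copy()
    one_entry.loc["f0", "s0"] *= 7.0
    after_entry = tm.odds_ratio_table(
        tm.to_relative(tm.AbundanceMatrix(one_entry)), meta)
    assert not np.allclose(after_entry.drop("f0"), before.drop("f0"))
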