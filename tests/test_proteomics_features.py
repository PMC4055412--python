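import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bowtievar.proteomics_features import (
    IntensityMatrix,
    compare_reference_sets,
    compute_features,
    confound_check,
    f_value,
    filter_detected,
    mean_abundance,
    mouse_quartile_sets,
    raw_protein_sd,
    standardize_samples,
)
from conftest import make_matrix


class TestFilterDetected:
    def test_boundary_half_detected_is_retained(self):
        vals = np.ones((1, 6))
        vals[0, :3] = np.nan
        m = make_matrix(vals, columns=[f"L1.rep{i}" for i in range(1, 7)])
        kept = filter_detected(m, 0.5)
        assert list(kept.values.index) == ["P00000"]

    def test_full_matrix_identity_at_one(self):
        m = make_matrix(np.random.default_rng(0).uniform(1, 2, (10, 6)))
        kept = filter_detected(m, 1.0)
        pd.testing.assert_frame_equal(kept.values, m.values)

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 2, (200, 12))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        m = make_matrix(vals, columns=[f"L{c}.r" for c in range(12)])
        kept = filter_detected(m, 0.5)
        expected = [i for i, row in enumerate(vals)
                    if np.isfinite(row).sum() / 12 >= 0.5]
        assert list(kept.values.index) == [f"P{i:05d}" for i in expected]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 2, (50, 6))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = make_matrix(vals, columns=[f"L{c}.r" for c in range(6)])
        once = filter_detected(m, 0.5)
        twice = filter_detected(once, 0.5)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestStandardize:
    def test_arithmetic_progression_becomes_unit_zscores(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]), columns=["L1.r1"])
        std = standardize_samples(m, log_transform=False)
        assert std.values["L1.r1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 100, (300, 8))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = make_matrix(vals, columns=[f"L{c}.r" for c in range(8)])
        std = standardize_samples(m, log_transform=True)
        assert np.allclose(std.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(std.values.std(axis=0, ddof=1), 1, atol=1e-9)
        assert std.values.isna().equals(m.values.isna())

    def test_constant_column_named_in_error(self):
        m = make_matrix(np.ones((5, 1)), columns=["HeLa.rep1"])
        with pytest.raises(ValueError, match="HeLa.rep1"):
            standardize_samples(m, log_transform=False)

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(0, 3, (100, 5)), columns=[f"L{c}.r" for c in range(5)])
        once = standardize_samples(m, log_transform=False)
        twice = standardize_samples(once, log_transform=False)
        assert np.nanmax(np.abs(once.values.to_numpy()
                                - twice.values.to_numpy())) < 1e-9


class TestMeanAbundance:
    def test_simple_rows(self):
        m = make_matrix(np.array([[-1.0, 0.0, 1.0], [5.0, np.nan, np.nan]]),
                        columns=["A.r1", "B.r1", "C.r1"])
        means = mean_abundance(m)
        assert means["P00000"] == pytest.approx(0.0)
        assert means["P00001"] == pytest.approx(5.0)

    def test_all_missing_row_excluded_with_warning(self):
        m = make_matrix(np.array([[1.0, 2.0], [np.nan, np.nan]]),
                        columns=["A.r1", "B.r1"])
        with pytest.warns(UserWarning):
            means = mean_abundance(m)
        assert "P00001" not in means.index


class TestFValue:
    def test_hand_computed_two_group_example(self):
        # lines {0,2} and {1,3}: MSB = 1, MSW = 2 -> F = 0.5
        m = make_matrix(np.array([[0.0, 2.0, 1.0, 3.0]]),
                        columns=["A.r1", "A.r2", "B.r1", "B.r2"])
        fv = f_value(m)
        assert fv.loc["P00000", "f_value"] == pytest.approx(0.5)

    def test_equal_group_means_give_zero(self):
        m = make_matrix(np.array([[1.0, 3.0, 1.0, 3.0]]),
                        columns=["A.r1", "A.r2", "B.r1", "B.r2"])
        fv = f_value(m)
        assert fv.loc["P00000", "f_value"] == pytest.approx(0.0)

    def test_matches_scipy_oneway_anova(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (100, 12))
        cols = [f"L{l}.rep{r}" for l in range(4) for r in range(3)]
        m = make_matrix(vals, columns=cols)
        fv = f_value(m)
        for i in range(100):
            groups = [vals[i, 3 * l:3 * l + 3] for l in range(4)]
            want = stats.f_oneway(*groups).statistic
            assert fv["f_value"].iloc[i] == pytest.approx(want, rel=1e-10)

    def test_invariant_under_shift_and_positive_scaling(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (50, 9))
        cols = [f"L{l}.rep{r}" for l in range(3) for r in range(3)]
        f0 = f_value(make_matrix(vals, columns=cols))["f_value"]
        f1 = f_value(make_matrix(vals * 3.7 + 11.0, columns=cols))["f_value"]
        assert np.allclose(f0, f1, rtol=1e-9)

    def test_zero_within_variance_flagged_infinite(self):
        m = make_matrix(np.array([[1.0, 1.0, 2.0, 2.0]]),
                        columns=["A.r1", "A.r2", "B.r1", "B.r2"])
        fv = f_value(m)
        assert fv.loc["P00000", "status"] == "undefined_msw_zero"
        assert np.isinf(fv.loc["P00000", "f_value"])

    def test_insufficient_groups_excluded(self):
        # only one cell line with >= 2 replicates
        m = make_matrix(np.array([[1.0, 2.0, 3.0, np.nan]]),
                        columns=["A.r1", "A.r2", "B.r1", "B.r2"])
        fv = f_value(m)
        assert fv.loc["P00000", "status"] == "insufficient_groups"
        assert np.isnan(fv.loc["P00000", "f_value"])


class TestConfoundCheck:
    def test_planted_confound_detected_and_removed_by_f(self, small_world,
                                                        small_features):
        sd = raw_protein_sd(small_world.intensities)
        out = confound_check(small_features, sd)
        assert out["raw_sd_vs_abundance"].coefficient < -0.3
        assert abs(out["log_f_vs_abundance"].coefficient) < 0.15

    def test_permuted_abundance_breaks_association(self, small_world,
                                                   small_features):
        rng = np.random.default_rng(8)
        shuffled = small_features.copy()
        shuffled["mean_abundance"] = rng.permutation(
            shuffled["mean_abundance"].to_numpy())
        sd = raw_protein_sd(small_world.intensities)
        out = confound_check(shuffled, sd)
        assert abs(out["raw_sd_vs_abundance"].coefficient) < 0.1
        assert abs(out["log_f_vs_abundance"].coefficient) < 0.1

    def test_constant_f_flagged(self, small_world, small_features):
        const = small_features.copy()
        const["log10_f"] = 1.0
        sd = raw_protein_sd(small_world.intensities)
        out = confound_check(const, sd)
        assert out["log_f_vs_abundance"].undefined


class TestReferenceSets:
    def test_planted_low_vs_high_strata(self, small_world, small_features):
        truth = small_world.truth.loc[small_features.index]
        v = truth["variability_factor"]
        low = set(v.index[v <= v.quantile(0.25)])
        high = set(v.index[v >= v.quantile(0.75)])
        res = compare_reference_sets(small_features["f_value"], low, high)
        assert res.p_value < 1e-10
        assert res.direction == "lower"

    def test_identical_sets_show_no_difference(self, small_features):
        ids = set(small_features.index[:100])
        res = compare_reference_sets(small_features["f_value"], ids, ids)
        assert res.direction == "none"

    def test_disjoint_empty_intersection_rejected(self, small_features):
        with pytest.raises(ValueError):
            compare_reference_sets(small_features["f_value"], {"nope"}, {"nada"})


class TestMouseQuartiles:
    def test_quartile_arithmetic_on_eight_proteins(self):
        # eight abundant proteins with sds 1..8, plus two lowly abundant
        # ones that fail the above-global-mean filter and a priori cannot
        # enter either quartile set
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 6)
        base = (base - base.mean()) / base.std(ddof=1)
        rows = [base * sd + 20 for sd in range(1, 9)]
        rows += [base * 0.5 + 1, base * 0.5 + 2]  # low-abundance dummies
        vals = np.power(10.0, np.stack(rows))
        m = make_matrix(vals, columns=[f"T{c}.t" for c in range(6)],
                        index=[f"m{i}" for i in range(1, 11)])
        ortho = {f"m{i}": f"h{i}" for i in range(1, 11)}
        low, high = mouse_quartile_sets(m, ortho)
        assert low == {"h1", "h2"}
        assert high == {"h7", "h8"}

    def test_protein_missing_in_one_tissue_excluded(self):
        vals = np.exp(np.random.default_rng(10).normal(10, 1, (8, 4)))
        vals[0, 2] = np.nan
        m = make_matrix(vals, columns=[f"T{c}.t" for c in range(4)],
                        index=[f"m{i}" for i in range(8)])
        ortho = {f"m{i}": f"h{i}" for i in range(8)}
        low, high = mouse_quartile_sets(m, ortho)
        assert "h0" not in low | high

    def test_unmapped_orthologs_dropped(self):
        rng = np.random.default_rng(12)
        vals = np.exp(rng.normal(10, 1, (12, 5)))
        m = make_matrix(vals, columns=[f"T{c}.t" for c in range(5)],
                        index=[f"m{i}" for i in range(12)])
        low, high = mouse_quartile_sets(m, {})
        assert low == set() and high == set()


def test_compute_features_table_contract(small_world, small_features):
    assert {"mean_abundance", "f_value", "log10_f",
            "detected_fraction"} <= set(small_features.columns)
    assert (small_features["detected_fraction"] >= 0.5).all()
    defined = small_features["f_value"].dropna()
    defined = defined[np.isfinite(defined)]
    assert (defined >= 0).all()
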