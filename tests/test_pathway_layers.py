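import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bowtievar import pathway_layers as pl


def table(rows):
    return pd.DataFrame(rows, columns=["protein_id", "pathway_id", "source",
                                       "raw_class"])


class TestFunctionalClasses:
    def test_single_annotation_kept(self):
        ann = pl.assign_functional_class(
            table([("p1", "ST", "reactome", "receptor")]))
        assert ann.loc["p1", "functional_class"] == "receptor"

    def test_conflicting_annotations_become_ambiguous(self):
        ann = pl.assign_functional_class(table([
            ("p1", "ST", "reactome", "kinase"),
            ("p1", "GE", "reactome", "transcription_factor"),
        ]))
        assert ann.loc["p1", "functional_class"] == "ambiguous"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown raw_class"):
            pl.assign_functional_class(table([("p1", "ST", "reactome", "gpcr")]))

    def test_counts_match_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        classes = sorted(pl.VALID_CLASSES)
        rows = [(f"p{rng.integers(40)}", f"PW{rng.integers(5)}", "reactome",
                 classes[rng.integers(len(classes))]) for _ in range(300)]
        ann = pl.assign_functional_class(table(rows))
        by_protein = {}
        for pid, pw, _, rc in rows:
            by_protein.setdefault(pid, {"classes": set(), "pws": set()})
            if rc != "none":
                by_protein[pid]["classes"].add(rc)
            by_protein[pid]["pws"].add(pw)
        for pid, info in by_protein.items():
            want = ("none" if not info["classes"]
                    else info["classes"].copy().pop() if len(info["classes"]) == 1
                    else "ambiguous")
            assert ann.loc[pid, "functional_class"] == want
            assert ann.loc[pid, "pathway_count"] == len(info["pws"])
            assert bool(ann.loc[pid, "exclusive"]) == (len(info["pws"]) == 1)


class TestLayerPooling:
    @pytest.mark.parametrize("cls,layer", [
        ("receptor", "input"),
        ("kinase", "transmission"),
        ("phosphatase", "transmission"),
        ("adaptor", "transmission"),
        ("gtpase_binding", "transmission"),
        ("mediator", "transmission"),
        ("cofactor", "transmission"),
        ("transcription_factor", "output"),
        ("ligand", "unassigned"),
        ("none", "unassigned"),
    ])
    def test_class_to_layer_map(self, cls, layer):
        ann = pl.annotate(table([("p1", "ST", "signalink", cls)]))
        assert ann.loc["p1", "layer"] == layer

    def test_mediator_that_is_also_receptor_is_excluded(self):
        # a cofactor/mediator only reaches the transmission layer when it
        # is neither a receptor nor a transcription factor
        ann = pl.annotate(table([
            ("p1", "ST", "signalink", "mediator"),
            ("p1", "ST", "reactome", "receptor"),
        ]))
        assert ann.loc["p1", "functional_class"] == "ambiguous"
        assert ann.loc["p1", "layer"] == "unassigned"

    def test_layer_sizes_match_tally(self, small_world):
        ann = pl.annotate(small_world.pathways)
        want = (ann["functional_class"].map(pl.LAYER_OF_CLASS)
                .value_counts().to_dict())
        got = ann["layer"].value_counts().to_dict()
        assert got == want
        # partition: every protein in exactly one layer bucket
        assert ann["layer"].isin(["input", "transmission", "output",
                                  "unassigned"]).all()


class TestClassFeatureTest:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        universe = [f"p{i}" for i in range(200)]
        feature = pd.Series(rng.normal(0, 1, 200), index=universe)
        members = universe[:100]
        feature[members] += 1.0
        res = pl.class_feature_test(feature, members, universe)
        assert res.p_value < 0.01 and res.direction == "higher"

    def test_type_i_rate_calibrated(self):
        rng = np.random.default_rng(2)
        universe = [f"p{i}" for i in range(200)]
        hits = 0
        n_runs = 300
        for _ in range(n_runs):
            feature = pd.Series(rng.normal(0, 1, 200), index=universe)
            members = rng.choice(universe, size=80, replace=False)
            res = pl.class_feature_test(feature, members, universe, alpha=0.05)
            hits += res.p_value < 0.05
        # ~5% nominal; binomial(300, 0.05) 99.9% envelope
        assert hits <= 30

    def test_identical_constant_sides(self):
        universe = [f"p{i}" for i in range(40)]
        feature = pd.Series(1.0, index=universe)
        res = pl.class_feature_test(feature, universe[:20], universe)
        assert res.p_value == 1.0 and res.direction == "none"

    def test_symmetry_under_complement_swap(self):
        rng = np.random.default_rng(3)
        universe = [f"p{i}" for i in range(100)]
        feature = pd.Series(rng.normal(0, 1, 100), index=universe)
        members = set(universe[:40])
        rest = set(universe) - members
        r1 = pl.class_feature_test(feature, members, universe, alpha=0.05)
        r2 = pl.class_feature_test(feature, rest, universe, alpha=0.05)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        flip = {"higher": "lower", "lower": "higher", "none": "none"}
        assert r2.direction == flip[r1.direction]


class TestLayerSummary:
    def test_planted_gradient_recovered(self, small_world, small_features):
        from bowtievar import conservation as cons
        scores = cons.conservation_scores(small_world.tree, small_world.homology)
        feat = small_features.join(scores["score"])
        ann = pl.annotate(small_world.pathways)
        summary = pl.layer_feature_summary(feat, ann)
        var = summary["log10_f"]["pairwise"]["input_vs_transmission"]
        assert var.p_value < 0.01 and var.direction == "higher"
        c1 = summary["score"]["pairwise"]["input_vs_transmission"]
        c2 = summary["score"]["pairwise"]["transmission_vs_output"]
        assert c1.direction == "lower" and c2.direction == "higher"
        for layer_stats in summary["log10_f"]["per_layer"].values():
            assert {"n", "median", "iqr"} <= set(layer_stats)


class TestExclusiveMultiple:
    def test_single_pathway_world_has_empty_multiple_set(self):
        t = table([(f"p{i}", "ST", "reactome", "kinase") for i in range(10)])
        features = pd.DataFrame({"log10_f": np.zeros(10)},
                                index=[f"p{i}" for i in range(10)])
        out = pl.split_exclusive_multiple(t, features)
        assert out["multiple"] == set()
        assert out["comparisons"] == {}

    def test_fold_ratio_matches_hand_enumeration(self):
        # 4 kinases (2 multi), 4 receptors (1 multi), 2 ligands (0 multi)
        rows = []
        for i in range(4):
            rows.append((f"k{i}", "ST", "reactome", "kinase"))
        rows += [("k0", "GE", "reactome", "kinase"),
                 ("k1", "MB", "reactome", "kinase")]
        for i in range(4):
            rows.append((f"r{i}", "ST", "reactome", "receptor"))
        rows.append(("r0", "GE", "reactome", "receptor"))
        rows += [("l0", "ST", "reactome", "ligand"),
                 ("l1", "ST", "reactome", "ligand")]
        ids = sorted({r[0] for r in rows})
        features = pd.DataFrame({"log10_f": np.zeros(len(ids))}, index=ids)
        out = pl.split_exclusive_multiple(table(rows), features)
        # multiple set = {k0, k1, r0}: 3 of 10 proteins
        assert out["multiple"] == {"k0", "k1", "r0"}
        # kinases: observed 2 multi vs expected (4/10)*3 = 1.2 -> 5/3
        assert out["fold_over_expectation"]["kinase"] == pytest.approx(2 / 1.2)
        assert out["fold_over_expectation"]["receptor"] == pytest.approx(1 / 1.2)

    def test_planted_conserved_multiple_proteins_detected(self, small_world,
                                                          small_features):
        from bowtievar import conservation as cons
        scores = cons.conservation_scores(small_world.tree, small_world.homology)
        feat = small_features.join(scores["score"])
        out = pl.split_exclusive_multiple(small_world.pathways, feat)
        res = out["comparisons"]["score"]
        # multi-pathway membership planted to favor conserved proteins
        assert res.p_value < 0.01 and res.direction == "lower"


class TestQuantileBin:
    def test_equal_bins_for_distinct_values(self):
        bins, edges = pl.quantile_bin(np.arange(1, 11, dtype=float), 5)
        assert np.bincount(bins).tolist() == [2, 2, 2, 2, 2]
        assert edges[0] == 1 and edges[-1] == 10

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pl.quantile_bin(np.ones(20), 4)

    def test_ties_assigned_to_lower_bin(self):
        # tie group straddling a bin boundary lands as a block in the
        # lower bin
        values = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        bins, _ = pl.quantile_bin(values, 3)
        tied = bins[values == 2.0]
        assert len(set(tied)) == 1
        assert tied[0] == 0

    def test_nan_values_get_sentinel(self):
        bins, _ = pl.quantile_bin(np.array([1.0, np.nan, 2.0, 3.0]), 2)
        assert bins[1] == -1

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_occupancy_bounded_by_tie_groups(self, seed, k):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 30, size=120).astype(float)
        if np.unique(values).size < k:
            return
        bins, _ = pl.quantile_bin(values, k)
        sizes = np.bincount(bins, minlength=k)
        largest_tie = pd.Series(values).value_counts().max()
        # each bin boundary moves by less than one tie group, so every
        # bin's occupancy deviates from n/k by less than the largest one
        assert np.abs(sizes - len(values) / k).max() < largest_tie

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, 100)
        b1, _ = pl.quantile_bin(values, 5)
        b2, _ = pl.quantile_bin(np.exp(values), 5)
        assert (b1 == b2).all()
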