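"""σ classifiers, the 9-cell energy grid, meta-class matrix, k-means groups."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from krasdyn.classify import (
    EINT_GRID_LABELS,
    ClassificationConfig,
    build_metaclass_matrix,
    defining_features,
    eint_grid_classify,
    group_difference_tests,
    kmeans_groups,
    load_variant_catalogue,
    rmsd_reference_classify,
    sigma_classify,
)


class TestSigmaClassify:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (0.0, "wt_like"),
            (1.0, "high"),  # boundary inclusive
            (-1.0, "low"),
            (-1.5, "low"),
            (0.99, "wt_like"),
            (2.3, "high"),
        ],
    )
    def test_thresholds(self, z, expected):
        assert sigma_classify(z, 1.0) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 5), st.floats(0.1, 3))
    def test_exactly_one_class_and_symmetry(self, z, sigma):
        c = sigma_classify(z, sigma)
        flipped = sigma_classify(-z, sigma)
        assert {("high", "low"), ("low", "high"), ("wt_like", "wt_like")} >= {(c, flipped)}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sigma_classify(float("nan"))


class TestEintGrid:
    def test_vocabulary_has_exactly_nine_labels(self):
        assert len(EINT_GRID_LABELS) == 9
        assert len(set(EINT_GRID_LABELS)) == 9

    def test_neutral_neutral_at_origin(self):
        assert eint_grid_classify(0.0, 0.0) == "Eint GDP Neutral GTP Neutral"

    def test_gdp_stable_gtp_unstable_sense(self):
        # within 1σ of WT GDP but >1σ destabilized for GTP
        assert eint_grid_classify(0.2, 2.1) == "Eint GDP Neutral GTP Unstable"
        # more favorable than WT on both axes
        assert eint_grid_classify(-1.5, -2.0) == "Eint GDP Stable GTP Stable"

    def test_matches_exhaustive_cell_enumeration(self):
        # independent re-derivation of the grid on a z lattice
        def oracle(zg, zt, s=1.0):
            def axis(z):
                if z <= -s:
                    return "Stable"
                if z >= s:
                    return "Unstable"
                return "Neutral"

            return f"Eint GDP {axis(zg)} GTP {axis(zt)}"

        lattice = [-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]
        seen = set()
        for zg, zt in itertools.product(lattice, repeat=2):
            lab = eint_grid_classify(zg, zt)
            assert lab == oracle(zg, zt)
            seen.add(lab)
        assert seen == set(EINT_GRID_LABELS)


class TestRMSDReferenceClassify:
    def test_wt_is_wt_like_both_states(self):
        assert rmsd_reference_classify(0.0, 0.0, reference="NF1") == (
            "RMSD NF1 GTP WT-like GDP WT-like"
        )

    def test_closed_both_states(self):
        # 2σ closer to the NF1 pose than WT in both states
        assert rmsd_reference_classify(-2.0, -2.0, reference="NF1") == (
            "RMSD NF1 GTP Closed GDP Closed"
        )

    def test_nine_combined_labels_per_reference(self):
        lattice = [-2.0, 0.0, 2.0]
        labels = {
            rmsd_reference_classify(zg, zt, reference="SOS1")
            for zg, zt in itertools.product(lattice, repeat=2)
        }
        assert len(labels) == 9


def _monitor_score_row(names, z=0.0):
    row = {}
    for name in names:
        for state in ("GDP", "GTP"):
            row[f"monitor_z:{name}:{state}"] = z
    return row


class TestMetaclassMatrix:
    def test_monitors_only_gives_twenty_one_hot_assignments(self):
        names = [f"m{i}" for i in range(10)]
        table = pd.DataFrame([_monitor_score_row(names)], index=["V1"])
        cfg = ClassificationConfig(families=("monitors",))
        mat = build_metaclass_matrix(table, cfg, names)
        assert mat.loc["V1"].sum() == 20  # 10 monitors × 2 states

    def test_one_hot_within_every_family(self):
        rng = np.random.default_rng(0)
        names = ["mA", "mB"]
        rows = {}
        for v in ["WT", "V1", "V2"]:
            row = {f"monitor_z:{n}:{s}": rng.normal() for n in names for s in ("GDP", "GTP")}
            row.update(
                eint_z_GDP=rng.normal(), eint_z_GTP=rng.normal(),
                rmsd_nf1_z_GDP=rng.normal(), rmsd_nf1_z_GTP=rng.normal(),
                rmsd_sos1_z_GDP=rng.normal(), rmsd_sos1_z_GTP=rng.normal(),
                pc1_fraction_z=rng.normal(), ssr_GDP=rng.random(), ssr_GTP=rng.random(),
            )
            rows[v] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        mat = build_metaclass_matrix(table, ClassificationConfig(), names)
        # families: eint(1) + 2 refs(2) + pc1(1) + 4 monitor-state(4) + 2 ssr(2)
        assert (mat.sum(axis=1) == 10).all()

    def test_wt_zero_scores_map_to_neutral_labels(self):
        names = ["mA"]
        row = _monitor_score_row(names)
        row.update(
            eint_z_GDP=0.0, eint_z_GTP=0.0,
            rmsd_nf1_z_GDP=0.0, rmsd_nf1_z_GTP=0.0,
            rmsd_sos1_z_GDP=0.0, rmsd_sos1_z_GTP=0.0,
            pc1_fraction_z=0.0, ssr_GDP=0.0, ssr_GTP=0.0,
        )
        table = pd.DataFrame([row], index=["WT"])
        mat = build_metaclass_matrix(table, ClassificationConfig(), names)
        on = set(mat.columns[mat.loc["WT"] == 1])
        assert "Eint GDP Neutral GTP Neutral" in on
        assert "PC1 Fraction WT-like" in on
        assert "SSR WT-like GDP" in on and "SSR WT-like GTP" in on

    def test_missing_score_lists_variant_and_family(self):
        table = pd.DataFrame([{"eint_z_GDP": 0.0}], index=["V1"])
        with pytest.raises(ValueError, match="V1"):
            build_metaclass_matrix(table, ClassificationConfig(families=("eint",)), [])


def _two_block_matrix():
    labels = [f"L{i} GDP" for i in range(6)]
    rows = {}
    for i in range(4):
        rows[f"A{i}"] = [1, 1, 1, 0, 0, 0]
    for i in range(4):
        rows[f"B{i}"] = [0, 0, 0, 1, 1, 1]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


class TestKMeans:
    def test_k1_puts_everything_in_one_group(self):
        mat = _two_block_matrix()
        assign = kmeans_groups(mat, "GDP", k=1)
        assert assign.sizes() == {1: 8}

    def test_perfectly_separated_blocks_recovered_exactly(self):
        mat = _two_block_matrix()
        assign = kmeans_groups(mat, "GDP", k=2, seed=0)
        planted = [0] * 4 + [1] * 4
        got = [assign.groups[v] for v in mat.index]
        assert adjusted_rand_score(planted, got) == 1.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(12, 8)),
            index=[f"V{i}" for i in range(12)],
            columns=[f"L{i} GTP" for i in range(8)],
        )
        a = kmeans_groups(mat, "GTP", k=3, seed=7)
        b = kmeans_groups(mat, "GTP", k=3, seed=7)
        assert a.groups == b.groups

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_groups(_two_block_matrix(), "GDP", k=9)

    def test_planted_three_group_recovery(self):
        """ARI ≥ 0.9 on planted 3-group matrices with 0.9 label agreement."""
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            protos = rng.integers(0, 2, size=(3, 30))
            rows, planted = [], []
            for g in range(3):
                for _ in range(10):
                    flip = rng.random(30) < 0.1
                    rows.append(np.where(flip, 1 - protos[g], protos[g]))
                    planted.append(g)
            mat = pd.DataFrame(
                rows,
                index=[f"V{i}" for i in range(30)],
                columns=[f"L{i} GDP" for i in range(30)],
            )
            assign = kmeans_groups(mat, "GDP", k=3, seed=seed)
            aris.append(
                adjusted_rand_score(planted, [assign.groups[v] for v in mat.index])
            )
        assert np.mean(aris) >= 0.9


class TestDefiningFeatures:
    def test_exclusive_label_ranks_first(self):
        mat = _two_block_matrix()
        assign = kmeans_groups(mat, "GDP", k=2, seed=0)
        per_group, retained = defining_features(assign, mat, top_n=2)
        for g, feats in per_group.items():
            members = assign.members(g)
            # the group's own block labels lead the ranking
            assert mat.loc[members, feats[0]].mean() == 1.0
        assert set(retained) <= set(mat.columns)

    def test_uninformative_label_never_retained(self):
        mat = _two_block_matrix()
        mat["Luniform GDP"] = 1  # identical frequency everywhere
        assign = kmeans_groups(mat[[c for c in mat.columns if c != "Luniform GDP"]], "GDP", 2)
        _, retained = defining_features(assign, mat, top_n=3)
        assert "Luniform GDP" not in retained

    def test_top_n_caps_each_group(self):
        mat = _two_block_matrix()
        assign = kmeans_groups(mat, "GDP", k=2)
        per_group, _ = defining_features(assign, mat, top_n=1)
        assert all(len(f) <= 1 for f in per_group.values())


class TestGroupDifferenceTests:
    def _assignment(self, groups):
        from krasdyn.classify import GroupAssignment

        return GroupAssignment("GDP", groups)

    def test_identical_groups_give_p_one(self):
        table = pd.DataFrame({"s": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                             index=[f"V{i}" for i in range(6)])
        assign = self._assignment({f"V{i}": 1 + i // 3 for i in range(6)})
        out = group_difference_tests(table, assign)
        assert np.isclose(out["p"].iloc[0], 1.0)

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([np.zeros(4), np.ones(4)]) + 1e-6 * rng.standard_normal(8)
        table = pd.DataFrame({"s": vals}, index=[f"V{i}" for i in range(8)])
        assign = self._assignment({f"V{i}": 1 + i // 4 for i in range(8)})
        out = group_difference_tests(table, assign)
        assert out["p"].iloc[0] < 1e-6

    def test_small_group_skipped_with_warning(self, caplog):
        table = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        assign = self._assignment({"a": 1, "b": 1, "c": 2})
        with caplog.at_level("WARNING"):
            out = group_difference_tests(table, assign)
        assert out.empty


class TestVariantCatalogue:
    def test_eighty_six_mutations_plus_wt(self):
        cat = load_variant_catalogue()
        assert len(cat) == 87
        assert (cat["variant"] == "WT").sum() == 1

    def test_six_groups_per_state_and_smallest_gtp_group(self):
        cat = load_variant_catalogue()
        assert set(cat["gdp_group"]) == set(range(1, 7))
        assert set(cat["gtp_group"]) == set(range(1, 7))
        assert cat["gtp_group"].value_counts().min() == 5

    def test_hotspot_positions(self):
        cat = load_variant_catalogue()
        hot = cat[cat["hotspot"] == 1]
        assert set(hot["position"].astype(int)) == {12, 13, 61}
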