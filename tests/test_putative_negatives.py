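import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpidebias import (
    BalanceParams,
    InputError,
    balance_dataset,
    eligible_clusters,
    eligible_families,
    pn_quota,
    positive_prevalence,
    rectified_half_sigmoid,
    sample_pn_compounds,
    sample_pn_targets,
    target_profiles,
)
from cpidebias.curation import FAMILIES
from cpidebias.putative_negatives import AUGMENTED_YEAR, compound_profiles

from conftest import make_interactions


def rhs_oracle(x, g=3.0, m=0.4):
    """Independent closed-form evaluation."""
    return max(x, (2 - 2 * m) / (1 + math.exp(-g * (x - 1))) + m)


def quota_oracle(alpha, n_pos, n_neg):
    """Round-half-up and clamp."""
    return max(0, int(math.floor(alpha * n_pos - n_neg + 0.5)))


class TestRectifiedHalfSigmoid:
    def test_fixed_point_at_one(self):
        assert rectified_half_sigmoid(1.0) == 1.0

    def test_at_zero(self):
        assert rectified_half_sigmoid(0.0) == pytest.approx(0.45691, abs=1e-4)
        assert rectified_half_sigmoid(0.0) == pytest.approx(rhs_oracle(0.0), abs=1e-12)

    def test_identity_branch_at_two(self):
        # sigmoid branch evaluates to ~1.543 < 2, so the max returns x
        assert rectified_half_sigmoid(2.0) == 2.0

    def test_grid_properties(self):
        xs = np.arange(0, 2.0001, 0.01)
        alphas = [rectified_half_sigmoid(x) for x in xs]
        for x, a in zip(xs, alphas):
            sig = (2 - 0.8) / (1 + math.exp(-3 * (x - 1))) + 0.4
            assert a >= x - 1e-12 and a >= sig - 1e-12
        assert all(b >= a - 1e-12 for a, b in zip(alphas, alphas[1:]))  # non-decreasing

    @given(st.floats(min_value=0, max_value=10),
           st.floats(min_value=0.5, max_value=10),
           st.floats(min_value=0.05, max_value=0.95))
    def test_matches_oracle(self, x, g, m):
        assert rectified_half_sigmoid(x, g, m) == pytest.approx(rhs_oracle(x, g, m))

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -0.5])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(InputError):
            rectified_half_sigmoid(bad)


class TestPnQuota:
    def test_simple_difference(self):
        assert pn_quota(1.0, 100, 20) == 80

    def test_rounding(self):
        assert pn_quota(rectified_half_sigmoid(0.0), 100, 0) == 46

    def test_clamped_at_zero(self):
        assert pn_quota(0.6189, 50, 50) == 0

    def test_zero_whenever_negatives_dominate(self):
        # balanced or negative-dominant targets must stay untouched
        for n_pos in range(0, 30):
            for n_neg in range(n_pos, n_pos + 30):
                total = n_pos + n_neg
                if total == 0:
                    continue
                alpha = rectified_half_sigmoid(n_neg / total)
                assert pn_quota(alpha, n_pos, n_neg) == 0

    @given(st.floats(min_value=0, max_value=3), st.integers(0, 1000), st.integers(0, 1000))
    def test_matches_oracle(self, alpha, n_pos, n_neg):
        assert pn_quota(alpha, n_pos, n_neg) == quota_oracle(alpha, n_pos, n_neg)


class TestProfiles:
    def test_target_profile_counts(self):
        df = make_interactions([
            ("A", "T1", "positive"), ("B", "T1", "positive"), ("C", "T1", "negative"),
            ("A", "T2", "negative"),
        ])
        prof = target_profiles(df).set_index("target_id")
        assert prof.loc["T1", "N_P"] == 2 and prof.loc["T1", "N_N"] == 1
        assert prof.loc["T1", "x"] == pytest.approx(1 / 3)
        assert prof.loc["T2", "N_PN"] == 0  # no positives -> nothing to add

    def test_compound_profile_ratio_convention(self):
        df = make_interactions([
            ("A", "T1", "positive"), ("A", "T2", "negative"), ("A", "T3", "negative"),
            ("B", "T1", "negative"),
        ])
        prof = compound_profiles(df).set_index("compound_id")
        assert prof.loc["A", "x"] == pytest.approx(2.0)  # N_N / N_P
        assert "B" not in prof.index  # no positive record -> excluded

    def test_compound_balanced_gets_zero_quota(self):
        rows = ([("A", f"T{i}", "positive") for i in range(4)]
                + [("A", f"U{i}", "negative") for i in range(4)])
        prof = compound_profiles(make_interactions(rows)).set_index("compound_id")
        assert prof.loc["A", "alpha"] == 1.0
        assert prof.loc["A", "N_PN"] == 0


class TestEligibleClusters:
    def _table(self):
        return make_interactions([
            ("A", "T", "positive", {"cluster_id": 1}),
            ("B", "T", "negative", {"cluster_id": 2}),
            ("C", "U", "positive", {"cluster_id": 3}),
            ("D", "U", "negative", {"cluster_id": 4}),
        ])

    def _cluster_map(self, df):
        return dict(zip(df["compound_id"], df["cluster_id"]))

    def test_complement_oracle(self):
        df = self._table()
        elig = eligible_clusters("T", df, self._cluster_map(df), range(1, 6))
        assert elig.all_eligible >= {3, 4, 5}
        assert not ({1, 2} & elig.all_eligible)

    def test_tiering(self):
        df = self._table()
        elig = eligible_clusters("T", df, self._cluster_map(df), range(1, 6))
        assert elig.tier1 == {3}        # has records, all positive
        assert elig.tier2 == {4, 5}     # has a negative / no records at all

    def test_target_touching_everything(self):
        df = make_interactions([
            ("A", "T", "positive", {"cluster_id": 0}),
            ("B", "T", "negative", {"cluster_id": 1}),
        ])
        elig = eligible_clusters("T", df, self._cluster_map(df), [0, 1])
        assert not elig.all_eligible

    def test_empty_table_all_eligible(self):
        df = self._table().iloc[:0]
        elig = eligible_clusters("T", df, {}, [0, 1, 2], mode="tiered")
        assert elig.all_eligible == {0, 1, 2}

    def test_interaction_free_mode(self):
        df = self._table()
        elig = eligible_clusters("T", df, self._cluster_map(df), range(1, 6),
                                 mode="interaction_free")
        assert elig.all_eligible == {5}


class TestSamplePnCompounds:
    def _pool(self, clusters, per_cluster=5):
        rows = []
        for c in clusters:
            for i in range(per_cluster):
                rows.append({"compound_id": f"P{c}_{i}", "cluster_id": c})
        return pd.DataFrame(rows)

    def _eligibility(self, clusters):
        from cpidebias.putative_negatives import ClusterEligibility
        return ClusterEligibility(frozenset(), frozenset(clusters))

    def test_quota_and_per_cluster_cap(self):
        out = sample_pn_compounds("T", 6, self._eligibility([1, 2, 3]), self._pool([1, 2, 3]),
                                  "Kinase", max_per_cluster=3, seed=0)
        assert len(out) == 6
        assert (out.groupby("cluster_id").size() <= 3).all()
        assert (out["label"] == "negative").all()
        assert (out["provenance"] == "putative").all()
        assert (out["year"] == AUGMENTED_YEAR).all()

    def test_quota_zero(self):
        out = sample_pn_compounds("T", 0, self._eligibility([1]), self._pool([1]), "Kinase")
        assert out.empty

    def test_determinism(self):
        args = ("T", 7, self._eligibility([1, 2, 3]), self._pool([1, 2, 3]), "Kinase")
        a = sample_pn_compounds(*args, seed=13)
        b = sample_pn_compounds(*args, seed=13)
        pd.testing.assert_frame_equal(a, b)

    def test_eligibility_respected(self):
        pool = self._pool([1, 2, 3, 4])
        out = sample_pn_compounds("T", 20, self._eligibility([2, 4]), pool, "Kinase", seed=1)
        assert set(out["cluster_id"]) <= {2, 4}

    def test_shortfall_warns(self):
        with pytest.warns(UserWarning, match="shortfall"):
            out = sample_pn_compounds("T", 50, self._eligibility([1]), self._pool([1]),
                                      "Kinase", max_per_cluster=3, seed=0)
        assert len(out) == 3

    def test_cluster_diversity_first(self):
        # quota of 3 over 3 clusters: round-robin puts one in each
        out = sample_pn_compounds("T", 3, self._eligibility([1, 2, 3]), self._pool([1, 2, 3]),
                                  "Kinase", seed=5)
        assert out["cluster_id"].nunique() == 3


class TestSamplePnTargets:
    def test_family_complement(self):
        df = make_interactions([("A", "T1", "positive", {"family": "Kinase"})])
        fam_map = {f"X{i}": fam for i, fam in enumerate(FAMILIES)}
        out = sample_pn_targets("A", 5, df, fam_map, cluster_id=0, seed=0)
        families = {fam_map[t] for t in out["target_id"]}
        assert "Kinase" not in families
        assert len(out) == 5

    def test_all_families_touched(self):
        df = make_interactions(
            [("A", f"T{i}", "positive", {"family": fam}) for i, fam in enumerate(FAMILIES)]
        )
        assert eligible_families("A", df) == set()
        fam_map = {f"T{i}": fam for i, fam in enumerate(FAMILIES)}
        out = sample_pn_targets("A", 3, df, fam_map, cluster_id=0, seed=0)
        assert out.empty

    def test_balanced_compound_zero_quota(self):
        rows = ([("A", f"T{i}", "positive") for i in range(4)]
                + [("A", f"U{i}", "negative") for i in range(4)])
        prof = compound_profiles(make_interactions(rows)).set_index("compound_id")
        assert prof.loc["A", "N_PN"] == 0


class TestBalanceDataset:
    def _setup(self, rows, n_clusters=6):
        df = make_interactions(rows)
        cluster_map = dict(zip(df["compound_id"], df["cluster_id"]))
        pool_rows = [{"compound_id": f"POOL{c}_{i}", "cluster_id": c}
                     for c in range(n_clusters) for i in range(10)]
        for cid, cl in cluster_map.items():
            pool_rows.append({"compound_id": cid, "cluster_id": cl})
        pool = pd.DataFrame(pool_rows)
        cluster_map.update({r["compound_id"]: r["cluster_id"] for r in pool_rows})
        return df, cluster_map, pool

    def test_skewed_target_receives_pns(self):
        # ratio exactly 2:1 with counts large enough for a nonzero quota
        rows = ([("A%d" % i, "T", "positive", {"cluster_id": 0}) for i in range(40)]
                + [("B%d" % i, "T", "negative", {"cluster_id": 1}) for i in range(20)])
        df, cmap, pool = self._setup(rows)
        out = balance_dataset(df, cmap, pool, BalanceParams(seed=0))
        added = out[(out["provenance"] == "putative") & (out["target_id"] == "T")]
        assert len(added) > 0

    def test_below_trigger_unchanged_in_stage1(self):
        rows = ([("A%d" % i, "T", "positive", {"cluster_id": 0}) for i in range(10)]
                + [("B%d" % i, "T", "negative", {"cluster_id": 1}) for i in range(6)])
        df, cmap, pool = self._setup(rows)
        out = balance_dataset(df, cmap, pool, BalanceParams(seed=0))
        added = out[(out["provenance"] == "putative") & (out["target_id"] == "T")]
        # ratio 10:6 < 2: stage 1 adds nothing for T (stage 2 may add rows for
        # other targets but never compound-level rows against T's family here)
        assert added.empty

    def test_no_positives_is_identity(self):
        rows = [("A", "T1", "negative"), ("B", "T2", "negative")]
        df, cmap, pool = self._setup(rows)
        out = balance_dataset(df, cmap, pool, BalanceParams(seed=0))
        pd.testing.assert_frame_equal(out, df)

    def test_measured_rows_conserved(self, small_activity, small_compounds):
        from cpidebias import curate
        df = curate(small_activity)
        df["cluster_id"] = df["compound_id"].map(
            dict(zip(small_compounds["compound_id"], small_compounds["planted_cluster"]))
        ).astype(int)
        cmap = dict(zip(small_compounds["compound_id"], small_compounds["planted_cluster"]))
        pool = small_compounds[["compound_id"]].assign(
            cluster_id=small_compounds["planted_cluster"]
        )
        out = balance_dataset(df, cmap, pool, BalanceParams(seed=2))
        measured = out[out["provenance"] == "measured"].reset_index(drop=True)
        pd.testing.assert_frame_equal(measured, df.reset_index(drop=True))
        assert (out.loc[out["provenance"] == "putative", "label"] == "negative").all()

    def test_eligibility_safety_exhaustive(self, small_activity, small_compounds):
        from cpidebias import curate
        from cpidebias.putative_negatives import augment_compounds, augment_targets
        df = curate(small_activity)
        cmap = dict(zip(small_compounds["compound_id"], small_compounds["planted_cluster"]))
        df["cluster_id"] = df["compound_id"].map(cmap).astype(int)
        pool = small_compounds[["compound_id"]].assign(
            cluster_id=small_compounds["planted_cluster"]
        )
        params = BalanceParams(seed=3)
        fam_of_target = dict(zip(df["target_id"], df["family"]))
        touched_clusters = {t: set(g["cluster_id"]) for t, g in df.groupby("target_id")}

        stage1 = augment_targets(df, cmap, pool, params, fam_of_target)
        for _, row in stage1.iterrows():
            # PN compound for a target: cluster must have no record with it
            assert row["cluster_id"] not in touched_clusters[row["target_id"]]

        combined = pd.concat([df, stage1], ignore_index=True)
        touched_families = {
            c: set(g["family"]) for c, g in combined.groupby("compound_id")
        }
        stage2 = augment_compounds(combined, cmap, params, fam_of_target)
        for _, row in stage2.iterrows():
            # PN target for a compound: family must have no record with it
            assert row["family"] not in touched_families[row["compound_id"]]

        out = balance_dataset(df, cmap, pool, params)
        expected = len(df) + len(stage1) + len(stage2)
        assert len(out) == expected

    def test_balance_improvement_beta_skew(self):
        rng = np.random.default_rng(21)
        rows = []
        for t in range(40):
            p = rng.beta(5, 1)
            n = 30
            for i in range(n):
                lab = "positive" if rng.random() < p else "negative"
                rows.append((f"C{t}_{i}", f"T{t}", lab, {"cluster_id": int(rng.integers(8))}))
        # pool spans 40 clusters so skewed targets have eligible clusters left
        df, cmap, pool = self._setup(rows, n_clusters=40)
        out = balance_dataset(df, cmap, pool, BalanceParams(seed=4))
        before = positive_prevalence(df, by="target")
        after = positive_prevalence(out, by="target")
        assert (after > 0.8).sum() < (before > 0.8).sum()
        # negative-dominant targets are never pushed toward positive
        for t, prev in before.items():
            if prev <= 0.5:
                assert after[t] <= prev + 1e-12

    def test_determinism(self):
        rows = ([("A%d" % i, "T", "positive", {"cluster_id": 0}) for i in range(30)]
                + [("B%d" % i, "T", "negative", {"cluster_id": 1}) for i in range(5)])
        df, cmap, pool = self._setup(rows)
        a = balance_dataset(df, cmap, pool, BalanceParams(seed=9))
        b = balance_dataset(df, cmap, pool, BalanceParams(seed=9))
        pd.testing.assert_frame_equal(a, b)
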