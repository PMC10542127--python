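import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from myoimmune.sharing import (
    fatal_association_test,
    map_shared_clones_to_heart_subsets,
    mark_heart_expanded_in_blood,
    sharing_2x2_logistic,
    subset_sharing_test,
)


class TestMarkFlags:
    def _blood(self):
        return pd.DataFrame(
            {
                "donor": ["d1", "d1", "d2", "d3"],
                "clone_key": ["A", "B", "A", "C"],
                "cluster": [0, 1, 0, 1],
            }
        )

    def test_within_donor_rule(self):
        flagged, skipped = mark_heart_expanded_in_blood(
            {"d1": {"A"}, "d2": {"X"}, "d3": {"C"}}, self._blood()
        )
        by_cell = flagged.set_index(["donor", "clone_key"])["myo_clone"]
        assert by_cell[("d1", "A")]
        # the same key in another donor's blood is never flagged
        assert not by_cell[("d2", "A")]
        assert skipped == []

    def test_bulk_sc_union(self):
        flagged, _ = mark_heart_expanded_in_blood(
            {"d1": {"A"} | {"B"}, "d2": set(), "d3": set()}, self._blood()
        )
        assert flagged.loc[flagged["donor"] == "d1", "myo_clone"].all()

    def test_missing_donor_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            flagged, skipped = mark_heart_expanded_in_blood({"d1": {"A"}}, self._blood())
        assert skipped == ["d2", "d3"]
        assert set(flagged["donor"]) == {"d1"}


class TestSubsetLogistic:
    def test_closed_form_2x2(self):
        beta1, stat, p, unstable = sharing_2x2_logistic(20, 30, 80, 870)
        assert np.exp(beta1) == pytest.approx(7.25, rel=1e-9)
        assert beta1 == pytest.approx(np.log(7.25), rel=1e-9)
        assert not unstable

    def test_matches_cell_level_logistic(self):
        a, b, c, d = 20, 30, 80, 870
        beta1, stat, _, _ = sharing_2x2_logistic(a, b, c, d)
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        fit = sm.Logit(y, np.column_stack([np.ones(len(y)), x])).fit(disp=0)
        assert beta1 == pytest.approx(fit.params[1], abs=1e-6)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        assert stat == pytest.approx(2 * (fit.llf - null.llf), abs=1e-6)

    def test_separation_flagged_but_p_reported(self):
        beta1, stat, p, unstable = sharing_2x2_logistic(10, 0, 0, 90)
        assert unstable
        assert np.isinf(beta1)
        assert 0 <= p < 1

    def test_null_lrt_calibration(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            flags = rng.random(600) < 0.1
            in_sub = rng.random(600) < 0.25
            a = int((flags & in_sub).sum())
            b = int((flags & ~in_sub).sum())
            c = int((~flags & in_sub).sum())
            d = int((~flags & ~in_sub).sum())
            _, _, p, _ = sharing_2x2_logistic(a, b, c, d)
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_permuting_flags_destroys_significance(self, rng):
        # strong planted sharing in subset 1, then flag permutation
        donor = pd.DataFrame(
            {
                "donor": "d1",
                "cluster": rng.integers(0, 4, size=800),
                "clone_key": [f"K{i}" for i in range(800)],
            }
        )
        donor["myo_clone"] = (donor["cluster"] == 1) & (rng.random(800) < 0.5)
        obs = subset_sharing_test(donor, "d1")
        assert obs.loc[obs["blood_subset"] == 1, "significant"].iloc[0]
        perm_ps = []
        for _ in range(30):
            shuffled = donor.copy()
            shuffled["myo_clone"] = rng.permutation(donor["myo_clone"].to_numpy())
            out = subset_sharing_test(shuffled, "d1")
            perm_ps.append(out.loc[out["blood_subset"] == 1, "lrt_p"].iloc[0])
        assert np.median(perm_ps) > 0.2


class TestSubsetSharingTable:
    def test_zero_flags_undefined(self):
        donor = pd.DataFrame(
            {"donor": "d1", "cluster": [0, 0, 1], "clone_key": list("XYZ"),
             "myo_clone": [False] * 3}
        )
        out = subset_sharing_test(donor, "d1")
        assert out["lrt_p"].isna().all()
        assert (out["reason"] != "").all()

    def test_fdr_within_donor(self, rng):
        donor = pd.DataFrame(
            {
                "donor": "d1",
                "cluster": rng.integers(0, 5, size=500),
                "clone_key": [f"K{i}" for i in range(500)],
            }
        )
        donor["myo_clone"] = rng.random(500) < 0.1
        out = subset_sharing_test(donor, "d1")
        assert len(out) == 5
        assert (out["fdr"] >= out["lrt_p"] - 1e-12).all()


class TestFatalAssociation:
    def _series(self, sharing, fatal):
        donors = [f"d{i}" for i in range(len(sharing))]
        return (pd.Series(sharing, index=donors), pd.Series(fatal, index=donors))

    def test_printed_three_of_four(self):
        s, f = self._series(
            [1, 1, 1, 0] + [1, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, 1, 1] + [0] * 9,
        )
        table, p = fatal_association_test(s, f)
        assert table.tolist() == [[3, 1], [1, 8]]
        assert round(p, 3) == 0.052

    def test_identical_rates(self):
        s, f = self._series([1, 1, 0, 0] + [1, 1, 1, 1, 0, 0, 0, 0],
                            [1, 1, 1, 1] + [0] * 8)
        _, p = fatal_association_test(s, f)
        assert p == 1.0

    def test_extreme_table_enumeration(self):
        s, f = self._series([1] * 4 + [0] * 9, [1] * 4 + [0] * 9)
        _, p = fatal_association_test(s, f)
        assert p == pytest.approx(0.0014, abs=5e-5)

    def test_empty_class_warns(self):
        s, f = self._series([1, 0, 1], [0, 0, 0])
        with pytest.warns(UserWarning, match="empty"):
            _, p = fatal_association_test(s, f)
        assert p == 1.0


class TestHeartMapping:
    def test_counts_and_low_evidence(self):
        heart = pd.DataFrame(
            {"cluster": ["c1"] * 5 + ["c2"] * 5, "clone_key": [f"K{i}" for i in range(10)]}
        )
        counts, low = map_shared_clones_to_heart_subsets(heart, {"K0", "K1", "K5"})
        got = counts.set_index("cluster")["n_shared_cells"]
        assert got["c1"] == 2 and got["c2"] == 1
        assert low  # 3 qualifying cells <= 10

    def test_no_shared_keys(self):
        heart = pd.DataFrame({"cluster": ["c1", "c2"], "clone_key": ["A", "B"]})
        counts, low = map_shared_clones_to_heart_subsets(heart, set())
        assert (counts["n_shared_cells"] == 0).all()

    def test_all_in_one_subset(self):
        heart = pd.DataFrame(
            {"cluster": ["c1"] * 12 + ["c2"] * 3,
             "clone_key": ["S"] * 12 + ["X", "Y", "Z"]}
        )
        counts, low = map_shared_clones_to_heart_subsets(heart, {"S"})
        got = counts.set_index("cluster")["n_shared_cells"]
        assert got["c1"] == 12 and got["c2"] == 0
        assert not low
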