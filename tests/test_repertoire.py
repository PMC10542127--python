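import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoimmune.repertoire import (
    call_expanded,
    fisher_exact_2x2,
    heart_tumor_overlap,
    hill_diversity,
    tissue_enrichment,
)


def _clones(counts, keys=None):
    keys = keys or [f"K{i}" for i in range(len(counts))]
    counts = np.asarray(counts)
    return pd.DataFrame(
        {"clone_key": keys, "count": counts, "frequency": counts / counts.sum()}
    )


class TestExpansion:
    @pytest.mark.parametrize(
        "count,total,expanded",
        [
            (6, 1000, True),    # 0.6% and >= 2 reads
            (5, 1000, False),   # exactly 0.5%: strict >
            (1, 100, False),    # 1% but a single read
        ],
    )
    def test_joint_rule(self, count, total, expanded):
        table = _clones([count, total - count])
        out = call_expanded(table)
        assert bool(out["expanded"].iloc[0]) is expanded

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            call_expanded(pd.DataFrame({"clone_key": [], "count": []}))


def enumeration_fisher(table):
    """Exhaustive hypergeometric oracle for the two-sided Fisher test."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    denom = comb(n, k)
    probs = {}
    for x in range(max(0, k - r2), min(r1, k) + 1):
        probs[x] = comb(r1, x) * comb(r2, k - x) / denom
    p_obs = probs[a]
    two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    greater = sum(p for x, p in probs.items() if x >= a)
    return two, greater


class TestFisher:
    def test_printed_fatal_sharing_table(self):
        p_two, _ = fisher_exact_2x2([[3, 1], [1, 8]])
        assert round(p_two, 3) == 0.052

    def test_empty_margin(self):
        assert fisher_exact_2x2([[0, 5], [0, 5]])[0] == 1.0

    def test_diagonal_table_vs_enumeration(self):
        p_two, _ = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p_two == pytest.approx(2 / 184756, rel=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestTissueEnrichment:
    def test_strong_enrichment_detected(self):
        tissue = _clones([50] + [10] * 95)
        control = _clones([1] + [10] * 95)
        out = tissue_enrichment(tissue, control)
        row = out.loc[out["clone_key"] == "K0"].iloc[0]
        oracle_p = enumeration_fisher(
            [[50, tissue["count"].sum() - 50], [1, control["count"].sum() - 1]]
        )[1]
        assert row["fisher_p"] == pytest.approx(oracle_p, rel=1e-6)
        assert row["enriched"]

    def test_equal_frequencies_not_enriched(self):
        tissue = _clones([50, 950])
        control = _clones([50, 950])
        out = tissue_enrichment(tissue, control)
        row = out.loc[out["clone_key"] == "K0"].iloc[0]
        assert row["fisher_p"] >= 0.5
        assert not row["enriched"]

    def test_control_absent_uses_pseudo_denominator(self):
        tissue = _clones([10, 990], keys=["A", "B"])
        control = _clones([1000], keys=["B"])
        out = tissue_enrichment(tissue, control)
        row = out.loc[out["clone_key"] == "A"].iloc[0]
        assert row["normalized_ratio"] == pytest.approx(0.01 / 0.0005)

    def test_candidates_restricted_to_expanded(self):
        tissue = _clones([4] * 250)  # every clone at 0.4%: none expanded
        control = _clones([4] * 250)
        with pytest.warns(UserWarning, match="no expanded"):
            out = tissue_enrichment(tissue, control)
        assert out.empty


class TestHillDiversity:
    def test_uniform_repertoire(self):
        table = _clones([10] * 10)
        out = hill_diversity(table, q_grid=[0, 0.5, 1, 2, 4])
        assert np.allclose(out["qD"], 10.0)

    def test_closed_forms(self):
        table = _clones([50, 25, 25])
        out = hill_diversity(table, q_grid=[0, 1, 2]).set_index("q")["qD"]
        assert out[0] == pytest.approx(3.0)
        assert out[1] == pytest.approx(2 ** 1.5, rel=1e-9)
        assert out[2] == pytest.approx(8 / 3, rel=1e-9)

    def test_minimum_sequence_rule(self):
        with pytest.raises(ValueError, match=">= 100"):
            hill_diversity(_clones([33, 33, 33]))

    def test_continuity_at_q1(self, rng):
        counts = rng.integers(1, 50, size=30)
        table = _clones(counts)
        out = hill_diversity(table, q_grid=[1 - 1e-4, 1, 1 + 1e-4])["qD"]
        assert abs(out.iloc[0] - out.iloc[1]) < 1e-3
        assert abs(out.iloc[2] - out.iloc[1]) < 1e-3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=200), min_size=12, max_size=40))
    def test_monotone_nonincreasing_in_q(self, counts):
        counts = [c + 10 for c in counts]  # ensure >= 100 sequences
        out = hill_diversity(_clones(counts), q_grid=np.linspace(0, 4, 17))["qD"]
        assert (np.diff(out) <= 1e-9).all()

    def test_rarefaction_seeded(self):
        table = _clones([60, 50, 40, 30])
        a = hill_diversity(table, q_grid=[0, 2], rarefy_depth=100, seed=5)
        b = hill_diversity(table, q_grid=[0, 2], rarefy_depth=100, seed=5)
        assert np.array_equal(a["qD"], b["qD"])
        with pytest.raises(ValueError, match="depth"):
            hill_diversity(table, rarefy_depth=1000)


class TestOverlap:
    def test_printed_counts(self):
        heart = {f"H{i}" for i in range(14)} | {f"S{i}" for i in range(5)}
        tumor = {f"T{i}" for i in range(23)} | {f"S{i}" for i in range(5)}
        out = heart_tumor_overlap(heart, tumor)
        assert (out["n_heart"], out["n_tumor"], out["n_shared"]) == (19, 28, 5)
        assert out["pct_of_heart_display"] == 26
        assert out["pct_of_tumor_display"] == 18

    def test_disjoint_and_identical(self):
        assert heart_tumor_overlap({"A"}, {"B"})["n_shared"] == 0
        full = heart_tumor_overlap(set("ABCDEFG"), set("ABCDEFG"))
        assert full["n_shared"] == 7
        assert full["pct_of_heart"] == 100.0
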