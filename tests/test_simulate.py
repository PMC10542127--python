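import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myoimmune.simulate import (
    SimConfig,
    generate_cells_and_counts,
    generate_cohort,
    generate_repertoires,
    generate_serum,
    simulate_study,
)


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_case_donors=0)
        with pytest.raises(ValueError):
            SimConfig(n_fatal=20, n_case_donors=4)
        with pytest.raises(ValueError):
            SimConfig(heart_tumor_overlap_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(case_log_odds=np.zeros(3), n_clusters=5)


class TestCohort:
    def test_counts_forced_by_config(self):
        meta = generate_cohort(SimConfig(n_case_donors=12, n_control_donors=8))
        assert len(meta) == 20
        assert (meta["group"] == "case").sum() == 12
        assert meta["fatal"].sum() == 4
        assert (meta.loc[meta["group"] == "case", "steroid_timing"]
                == "pre-corticosteroid").all()

    def test_determinism(self):
        cfg = SimConfig(seed=5)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_zero_noise_troponin_affine(self):
        cfg = SimConfig(seed=2, troponin_link=(1.5, 1.0, 0.0))
        meta = generate_cohort(cfg)
        pred = 1.5 + np.log(meta["troponin_truth_abundance"])
        assert np.allclose(np.log(meta["troponin"]), pred)


class TestCellsAndCounts:
    def test_null_composition_balanced(self):
        cfg = SimConfig(
            seed=3, donor_sd=0.0, case_log_odds=np.zeros(8),
            cells_per_donor=2000, n_genes=50,
        )
        meta = generate_cohort(cfg)
        cells, _, _ = generate_cells_and_counts(cfg, meta)
        merged = cells.merge(meta[["donor", "group"]], on="donor")
        table = pd.crosstab(merged["group"], merged["cluster"])
        chi2 = stats.chi2_contingency(table)
        assert chi2.pvalue > 1e-3

    def test_case_odds_ratio_recovered_at_large_n(self):
        cfg = SimConfig(
            seed=4, donor_sd=0.0, cells_per_donor=5000, n_genes=30,
            n_case_donors=10, n_control_donors=10,
        )
        meta = generate_cohort(cfg)
        cells, _, _ = generate_cells_and_counts(cfg, meta)
        merged = cells.merge(meta[["donor", "group"]], on="donor")
        in0 = merged["cluster"] == 0
        case = merged["group"] == "case"
        odds_case = (in0 & case).sum() / (~in0 & case).sum()
        odds_ctrl = (in0 & ~case).sum() / (~in0 & ~case).sum()
        assert odds_case / odds_ctrl == pytest.approx(4.0, rel=0.1)

    def test_poisson_limit_variance(self):
        cfg = SimConfig(
            seed=5, nb_dispersion=1e-8, libsize_lognormal=(0.0, 0.0),
            cells_per_donor=3000, n_genes=20, n_case_donors=1, n_control_donors=1,
            n_fatal=0, n_tcr_donors=1, donor_sd=0.0, marker_log2fc=0.0,
            de_spec=[], case_log_odds=np.zeros(8),
        )
        meta = generate_cohort(cfg)
        cells, counts, _ = generate_cells_and_counts(cfg, meta)
        x = np.asarray(counts.todense(), dtype=float)
        ratio = x.var(axis=0) / x.mean(axis=0)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_qc_failures_injected(self):
        cfg = SimConfig(seed=6, mito_fail_fraction=0.2, lowgene_fail_fraction=0.2)
        meta = generate_cohort(cfg)
        cells, _, _ = generate_cells_and_counts(cfg, meta)
        frac_mito = (cells["mito_frac"] >= 0.2).mean()
        assert 0.15 < frac_mito < 0.25


class TestRepertoires:
    def test_overlap_counts_match_config(self):
        cfg = SimConfig(seed=7)
        meta = generate_cohort(cfg)
        *_, truth = generate_repertoires(cfg, meta)
        n_heart = sum(len(v) for d, v in truth["heart_enriched"].items()
                      if d in truth["heart_tumor_shared"])
        n_shared = sum(len(v) for v in truth["heart_tumor_shared"].values())
        assert n_heart == 19
        assert sum(len(v) for v in truth["tumor_enriched"].values()) == 28
        assert n_shared == 5

    def test_zero_overlap_disjoint(self):
        cfg = SimConfig(seed=8, heart_tumor_overlap_fraction=0.0)
        meta = generate_cohort(cfg)
        *_, truth = generate_repertoires(cfg, meta)
        for donor in truth["heart_tumor_shared"]:
            assert truth["heart_enriched"][donor].isdisjoint(
                truth["tumor_enriched"][donor]
            )

    def test_frequencies_sum_to_one(self):
        cfg = SimConfig(seed=9)
        meta = generate_cohort(cfg)
        heart, tumor, control, _, _ = generate_repertoires(cfg, meta)
        for tables in (heart, tumor, control):
            for table in tables.values():
                assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_fatal_donors_share_more(self):
        cfg = SimConfig(seed=10)
        meta = generate_cohort(cfg)
        heart, _, _, blood, truth = generate_repertoires(cfg, meta)
        fatal = set(meta.loc[meta["fatal"], "donor"])
        rates = {}
        for donor, sub in blood.groupby("donor"):
            target = sub.loc[sub["cluster"] == cfg.fatal_sharing_subset]
            expanded = set(
                heart[donor].loc[
                    (heart[donor]["frequency"] > 0.005) & (heart[donor]["count"] >= 2),
                    "clone_key",
                ]
            )
            rates[donor] = target["clone_key"].isin(expanded).mean()
        fatal_rates = [r for d, r in rates.items() if d in fatal]
        nonfatal_rates = [r for d, r in rates.items() if d not in fatal]
        if fatal_rates and nonfatal_rates:
            assert min(fatal_rates) > max(nonfatal_rates)


class TestSerumGenerator:
    def test_panel_size(self):
        cfg = SimConfig(seed=11)
        meta = generate_cohort(cfg)
        table = generate_serum(cfg, meta)
        assert table.groupby("donor").size().eq(71).all()


class TestFullStudy:
    def test_byte_identical_reruns(self):
        cfg = SimConfig(seed=12, cells_per_donor=100, n_genes=40)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a.cell_table, b.cell_table)
        pd.testing.assert_frame_equal(a.sample_meta, b.sample_meta)
        pd.testing.assert_frame_equal(a.serum_table, b.serum_table)
        pd.testing.assert_frame_equal(a.blood_cells, b.blood_cells)
        assert (a.counts != b.counts).nnz == 0
        for donor in a.heart_bulk_clones:
            pd.testing.assert_frame_equal(
                a.heart_bulk_clones[donor], b.heart_bulk_clones[donor]
            )

    def test_truth_sufficient_for_scoring(self):
        st_ = simulate_study(SimConfig(seed=13, cells_per_donor=100, n_genes=40))
        assert set(st_.truth) >= {
            "case_log_odds", "de_spec", "shifted_analytes",
            "heart_enriched", "tumor_enriched", "heart_tumor_shared",
        }
        assert set(st_.cell_table["sample"]) <= set(st_.sample_meta["sample"])
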