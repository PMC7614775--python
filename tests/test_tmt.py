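"""Competition quantification: fractions, QC filters, aggregation, calls."""

import numpy as np
import pandas as pd
import pytest

from cysengage import (
    ChannelLayout,
    QcThresholds,
    aggregate_sites,
    apply_qc_filters,
    call_engagement,
    compute_psm_fractions,
    duplicate_design,
    generate_psm_table,
    generate_truths,
    occupancy,
    quantify,
)
from tests.conftest import make_psm


class TestComputePsmFractions:
    def test_quarter_intensity_gives_fraction_and_ratio_four(self, two_channel_layout):
        psm = make_psm(intensities={"126": 100_000, "127N": 100_000,
                                    "127C": 25_000, "128N": 25_000})
        out = compute_psm_fractions(psm, two_channel_layout)
        assert out["frac_127C"].iloc[0] == pytest.approx(0.25)
        assert 1.0 / out["frac_127C"].iloc[0] == pytest.approx(4.0)

    def test_equal_channels_give_unit_fractions(self, two_channel_layout):
        psm = make_psm(intensities={c: 7e4 for c in ("126", "127N", "127C", "128N")})
        out = compute_psm_fractions(psm, two_channel_layout)
        for ch in ("126", "127N", "127C", "128N"):
            assert out[f"frac_{ch}"].iloc[0] == pytest.approx(1.0)

    def test_fraction_uses_dmso_mean(self, two_channel_layout):
        # DMSO (80k, 120k): mean 100k; compound 50k -> fraction 0.5
        psm = make_psm(intensities={"126": 80_000, "127N": 120_000,
                                    "127C": 50_000, "128N": 50_000})
        out = compute_psm_fractions(psm, two_channel_layout)
        assert out["frac_127C"].iloc[0] == pytest.approx(0.5)

    def test_zero_dmso_flagged_unquantifiable_not_raised(self, two_channel_layout):
        psm = make_psm(intensities={"126": 0.0, "127N": 0.0,
                                    "127C": 1e4, "128N": 1e4})
        out = compute_psm_fractions(psm, two_channel_layout)
        assert not out["quantifiable"].iloc[0]
        assert np.isnan(out["frac_127C"].iloc[0])


class TestQcFilters:
    def test_low_dmso_sum_excluded(self, two_channel_layout):
        psm = make_psm(intensities={"126": 4_000, "127N": 5_000,
                                    "127C": 1e4, "128N": 1e4})
        kept, report = apply_qc_filters(psm, two_channel_layout)
        assert len(kept) == 0
        assert report.excluded["low_dmso_sum"] == 1

    def test_boundary_sum_retained(self, two_channel_layout):
        # exclusion is strictly < 10,000
        psm = make_psm(intensities={"126": 5_000, "127N": 5_000,
                                    "127C": 1e4, "128N": 1e4})
        kept, _ = apply_qc_filters(psm, two_channel_layout)
        assert len(kept) == 1

    def test_high_dmso_cv_excluded(self, two_channel_layout):
        # DMSO (10000, 30000): sample sd 14142.14, mean 20000 -> CV 0.7071
        psm = make_psm(intensities={"126": 10_000, "127N": 30_000,
                                    "127C": 1e4, "128N": 1e4})
        kept, report = apply_qc_filters(psm, two_channel_layout)
        assert len(kept) == 0
        assert report.excluded["high_dmso_cv"] == 1

    def test_boundary_cv_retained(self, two_channel_layout):
        # CV exactly 0.5: DMSO pair (x, y) with sd/mean = 0.5
        # mean 20000, sd 10000 -> (20000 - 10000/sqrt(2), 20000 + 10000/sqrt(2))
        lo = 20_000 - 10_000 / np.sqrt(2)
        hi = 20_000 + 10_000 / np.sqrt(2)
        psm = make_psm(intensities={"126": lo, "127N": hi,
                                    "127C": 1e4, "128N": 1e4})
        kept, _ = apply_qc_filters(psm, two_channel_layout)
        assert len(kept) == 1

    def test_rule_attribution_order_and_tallies(self, two_channel_layout):
        good = {"126": 1e5, "127N": 1e5, "127C": 1e4, "128N": 1e4}
        table = pd.concat([
            make_psm(intensities={"126": 4_000, "127N": 5_000,
                                  "127C": 1e4, "128N": 1e4}),      # low sum
            make_psm(intensities={"126": 10_000, "127N": 30_000,
                                  "127C": 1e4, "128N": 1e4}),      # high CV
            make_psm(intensities=good, reverse=True),              # reverse
            make_psm(intensities=good),                            # clean
            make_psm(intensities=good),                            # clean
        ], ignore_index=True)
        kept, report = apply_qc_filters(table, two_channel_layout)
        assert len(kept) == 2
        assert report.excluded == {"reverse": 1, "nontryptic": 0,
                                   "short_peptide": 0, "low_dmso_sum": 1,
                                   "high_dmso_cv": 1}
        assert report.retained + report.total_excluded == len(table)

    def test_short_and_nontryptic_sequences_excluded(self, two_channel_layout):
        good = {"126": 1e5, "127N": 1e5, "127C": 1e4, "128N": 1e4}
        table = pd.concat([
            make_psm(intensities=good, peptide="ACK"),             # short
            make_psm(intensities=good, tryptic=False),             # non-tryptic
        ], ignore_index=True)
        _, report = apply_qc_filters(table, two_channel_layout)
        assert report.excluded["short_peptide"] == 1
        assert report.excluded["nontryptic"] == 1

    def test_filtering_is_idempotent(self, noise_free_experiment):
        layout = noise_free_experiment["layout"]
        kept, _ = apply_qc_filters(noise_free_experiment["psms"], layout)
        kept2, report2 = apply_qc_filters(kept, layout)
        assert report2.total_excluded == 0
        pd.testing.assert_frame_equal(kept, kept2)

    def test_exclusions_match_generator_ledger_exactly(self):
        rates = {"low_intensity": 0.05, "high_cv": 0.04,
                 "reverse": 0.03, "nontryptic": 0.03}
        truths = generate_truths(400, seed=7)
        design = duplicate_design([0.1, 1.0], noise_cv=0.0, seed=8,
                                  qc_violation_rates=rates)
        psms, ledger = generate_psm_table(truths, design)
        layout = ChannelLayout.from_design(design)
        _, report = apply_qc_filters(psms, layout)
        truth_counts = ledger["violation"].value_counts()
        assert report.excluded["low_dmso_sum"] == truth_counts.get("low_intensity", 0)
        assert report.excluded["high_dmso_cv"] == truth_counts.get("high_cv", 0)
        assert report.excluded["reverse"] == truth_counts.get("reverse", 0)
        assert report.excluded["nontryptic"] == truth_counts.get("nontryptic", 0)
        assert report.retained == truth_counts.get("clean", 0)


class TestAggregateSites:
    def test_median_of_two_psms_is_their_mean(self, two_channel_layout):
        # replicate-averaged fractions 0.2 and 0.3 -> site fraction 0.25
        table = pd.concat([
            make_psm(intensities={"126": 1e5, "127N": 1e5,
                                  "127C": 20_000, "128N": 20_000}),
            make_psm(intensities={"126": 1e5, "127N": 1e5,
                                  "127C": 30_000, "128N": 30_000}),
        ], ignore_index=True)
        sites = aggregate_sites(table, two_channel_layout)
        assert len(sites) == 1
        row = sites.iloc[0]
        assert row["fraction"] == pytest.approx(0.25)
        assert row["ratio"] == pytest.approx(4.0)
        assert row["engagement_pct"] == pytest.approx(75.0)
        assert row["n_psms"] == 2

    def test_single_psm_duplicate_channels_average(self, two_channel_layout):
        psm = make_psm(intensities={"126": 1e5, "127N": 1e5,
                                    "127C": 25_000, "128N": 25_000})
        sites = aggregate_sites(psm, two_channel_layout)
        assert sites["fraction"].iloc[0] == pytest.approx(0.25)

    def test_multi_cysteine_peptide_emitted_for_both_residues(self, two_channel_layout):
        psm = make_psm(residues="810;817",
                       intensities={"126": 1e5, "127N": 1e5,
                                    "127C": 25_000, "128N": 25_000})
        sites = aggregate_sites(psm, two_channel_layout)
        assert sorted(sites["residue"]) == [810, 817]
        assert sites["ambiguous"].all()
        assert sites["fraction"].nunique() == 1

    def test_site_without_retained_psms_absent(self, two_channel_layout):
        psm = make_psm(intensities={"126": 0.0, "127N": 0.0,
                                    "127C": 1e4, "128N": 1e4})
        sites = aggregate_sites(psm, two_channel_layout)
        assert sites.empty

    def test_mean_aggregation_option(self, two_channel_layout):
        table = pd.concat([
            make_psm(intensities={"126": 1e5, "127N": 1e5,
                                  "127C": 10_000, "128N": 10_000}),
            make_psm(intensities={"126": 1e5, "127N": 1e5,
                                  "127C": 20_000, "128N": 20_000}),
            make_psm(intensities={"126": 1e5, "127N": 1e5,
                                  "127C": 60_000, "128N": 60_000}),
        ], ignore_index=True)
        med = aggregate_sites(table, two_channel_layout, agg="median")
        mean = aggregate_sites(table, two_channel_layout, agg="mean")
        assert med["fraction"].iloc[0] == pytest.approx(0.2)
        assert mean["fraction"].iloc[0] == pytest.approx(0.3)


class TestCallEngagement:
    def make_sites(self, ratios):
        fractions = [1.0 / r if r > 0 else np.inf for r in ratios]
        return pd.DataFrame({
            "site_id": [f"S{i}_C1" for i in range(len(ratios))],
            "protein": [f"S{i}" for i in range(len(ratios))],
            "residue": 1, "condition": "c",
            "fraction": fractions, "ratio": ratios,
            "engagement_pct": [100 * (1 - f) for f in fractions],
            "n_psms": 1, "ambiguous": False,
        })

    def test_threshold_boundary(self):
        called = call_engagement(self.make_sites([4.0, 3.9]))
        assert called["engaged"].tolist() == [True, False]
        assert called["engagement_pct"].iloc[0] == pytest.approx(75.0)

    def test_infinite_ratio_reported_at_cap(self):
        called = call_engagement(self.make_sites([np.inf]))
        assert called["ratio"].iloc[0] == 20.0
        assert called["engaged"].iloc[0]
        assert called["engagement_pct"].iloc[0] == pytest.approx(95.0)

    def test_engagement_identity_on_every_row(self):
        called = call_engagement(self.make_sites([0.5, 1.0, 2.0, 4.0, 19.0, 50.0]))
        np.testing.assert_allclose(
            called["engagement_pct"], 100.0 * (1.0 - 1.0 / called["ratio"]))

    def test_cap_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_engagement(self.make_sites([2.0]), ratio_threshold=4, ratio_cap=3)


class TestEndToEnd:
    def test_noise_free_engagement_equals_planted_occupancy(self, noise_free_experiment):
        sites, _ = quantify(noise_free_experiment["psms"],
                            noise_free_experiment["layout"])
        truth = noise_free_experiment["truths"][0]
        design = noise_free_experiment["design"]
        for _, row in sites[sites.site_id == truth.site_id].iterrows():
            conc = float(row["condition"].split("@")[1].rstrip("uM"))
            occ = occupancy(truth, conc, design.preincubation_time)
            expected = min(100.0 * occ, 100.0 * (1 - 1 / 20.0))  # ratio cap
            assert row["engagement_pct"] == pytest.approx(expected, abs=1e-9)

    def test_noisy_engagement_tracks_occupancy_within_5_points(self):
        truths = generate_truths(250, liganded={"T_C1": 0.5}, seed=31)
        design = duplicate_design([1.0], noise_cv=0.10, seed=32)
        psms, _ = generate_psm_table(truths, design)
        sites, _ = quantify(psms, ChannelLayout.from_design(design))
        decoys = sites[sites.protein.str.startswith("DECOY")]
        # unliganded truth: engagement 0; median absolute error under noise
        assert decoys["engagement_pct"].abs().median() < 5.0
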