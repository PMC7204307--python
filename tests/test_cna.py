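"""Copy-number event classification and score formulas."""

import numpy as np
import pandas as pd
import pytest

from cinscore.cna import (
    SegmentError,
    broad_cna_score,
    call_events,
    cna_frequency_profile,
    focal_cna_score,
    fusion_score,
    score_correlation_matrix,
    score_segments,
    split_segments_by_arm,
    threshold_segments,
    tmb_score,
)
from cinscore.genome import GenomeArmModel

from ._oracles import brute_force_cna, interval_union_runs, random_segment_table


def seg(sample, chrom, start, end, value):
    return {"sample": sample, "chrom": chrom, "start": start, "end": end,
            "value": value}


def seg_table(*rows):
    return pd.DataFrame(list(rows))


class TestThresholding:
    @pytest.mark.parametrize("value,direction", [
        (0.5, "gain"), (0.31, "gain"), (-0.5, "loss"), (-0.31, "loss"),
    ])
    def test_altered_values_labelled(self, value, direction):
        out = threshold_segments(seg_table(seg("s", "chr1", 0, 100, value)))
        assert list(out["direction"]) == [direction]

    @pytest.mark.parametrize("value", [0.3, -0.3, 0.0, 0.29, -0.29])
    def test_boundary_and_neutral_values_dropped(self, value):
        out = threshold_segments(seg_table(seg("s", "chr1", 0, 100, value)))
        assert len(out) == 0

    def test_malformed_segment_rejected(self):
        with pytest.raises(SegmentError, match="end <= start"):
            threshold_segments(seg_table(seg("s", "chr1", 100, 100, 0.5)))

    def test_threshold_order_enforced(self):
        with pytest.raises(SegmentError):
            threshold_segments(seg_table(seg("s", "chr1", 0, 1, 0.5)),
                               gain_threshold=-0.3, loss_threshold=0.3)


class TestArmSplitting:
    def test_segment_within_arm_unchanged(self, toy_model):
        t = seg_table(seg("s", "chr1", 100, 900_000, 0.5))
        out = split_segments_by_arm(t, toy_model)
        assert len(out) == 1
        assert out.loc[0, "start"] == 100 and out.loc[0, "end"] == 900_000
        assert out.loc[0, "arm"] == "p"

    def test_centromere_spanning_segment_split_conserves_length(self, toy_model):
        t = seg_table(seg("s", "chr1", 500_000, 1_500_000, 0.5))
        out = split_segments_by_arm(t, toy_model)
        assert len(out) == 2
        assert (out["end"] - out["start"]).sum() == 1_000_000
        assert set(out["arm"]) == {"p", "q"}
        assert (out["value"] == 0.5).all()

    def test_unknown_chromosome_rejected(self, toy_model):
        with pytest.raises(SegmentError, match="not in arm model"):
            split_segments_by_arm(seg_table(seg("s", "chrZ", 0, 10, 0.5)), toy_model)

    def test_random_tables_match_interval_intersection_oracle(self, toy_model, rng):
        samples = [f"s{i}" for i in range(6)]
        table = random_segment_table(rng, toy_model, samples)
        out = split_segments_by_arm(table, toy_model)
        # per-arm totals equal brute-force base-pair intersection
        for _, arm in toy_model.arms.iterrows():
            for sample in samples:
                sub = table[(table["sample"] == sample)
                            & (table["chrom"] == arm["chrom"])]
                expected = sum(
                    max(0, min(e, arm["end"]) - max(s, arm["start"]))
                    for s, e in zip(sub["start"], sub["end"])
                )
                got = out[(out["sample"] == sample)
                          & (out["chrom"] == arm["chrom"])
                          & (out["arm"] == arm["arm"])]
                assert (got["end"] - got["start"]).sum() == expected
        # conservation of total altered bp
        assert (out["end"] - out["start"]).sum() == \
            (table["end"] - table["start"]).sum()


class TestEventCalling:
    def prep(self, model, *rows):
        return split_segments_by_arm(threshold_segments(seg_table(*rows)), model)

    def test_gain_covering_985_percent_is_broad(self, toy_model):
        t = self.prep(toy_model, seg("s", "chr1", 5_000, 990_000, 0.5))
        events = call_events(t, toy_model)
        assert list(events["breadth"]) == ["broad"]
        assert list(events["direction"]) == ["gain"]

    def test_exactly_98_percent_is_focal(self, toy_model):
        t = self.prep(toy_model, seg("s", "chr1", 0, 980_000, 0.5))
        events = call_events(t, toy_model)
        assert list(events["breadth"]) == ["focal"]

    def test_three_disjoint_focal_losses(self, toy_model):
        t = self.prep(
            toy_model,
            seg("s", "chr1", 0, 20_000, -0.5),
            seg("s", "chr1", 40_000, 60_000, -0.5),
            seg("s", "chr1", 80_000, 90_000, -0.5),
        )
        events = call_events(t, toy_model)
        assert (events["breadth"] == "focal").sum() == 3
        assert (events["breadth"] == "broad").sum() == 0
        assert (events["direction"] == "loss").all()

    def test_fragmented_broad_event_merged(self, toy_model):
        # two abutting pieces jointly covering 99% count as one broad event
        t = self.prep(
            toy_model,
            seg("s", "chr1", 0, 500_000, 0.5),
            seg("s", "chr1", 500_000, 990_000, 0.6),
        )
        events = call_events(t, toy_model)
        assert list(events["breadth"]) == ["broad"]

    def test_gain_and_loss_counted_separately_on_one_arm(self, toy_model):
        t = self.prep(
            toy_model,
            seg("s", "chr1", 0, 10_000, 0.5),
            seg("s", "chr1", 20_000, 30_000, -0.5),
        )
        events = call_events(t, toy_model)
        assert set(events["direction"]) == {"gain", "loss"}
        assert (events["breadth"] == "focal").all()

    def test_bad_broad_fraction_rejected(self, toy_model):
        t = self.prep(toy_model, seg("s", "chr1", 0, 10_000, 0.5))
        with pytest.raises(SegmentError):
            call_events(t, toy_model, broad_fraction=1.5)


class TestScores:
    def test_broad_score_formula(self, toy_model):
        events = pd.DataFrame({
            "sample": ["s", "s"], "chrom": ["chr1", "chr2"], "arm": ["p", "q"],
            "direction": ["gain", "loss"], "breadth": ["broad", "broad"],
            "span": [990_000, 990_000], "arm_fraction": [0.99, 0.99],
        })
        assert broad_cna_score(events, toy_model)["s"] == pytest.approx(0.5)

    def test_focal_score_formula(self, toy_model):
        events = pd.DataFrame({
            "sample": ["s"] * 5, "chrom": ["chr1"] * 5, "arm": ["p"] * 5,
            "direction": ["gain"] * 5, "breadth": ["focal"] * 5,
            "span": [1000] * 5, "arm_fraction": [0.001] * 5,
        })
        expected = 5 / toy_model.total_genes
        assert focal_cna_score(events, toy_model)["s"] == pytest.approx(expected)

    def test_no_events_scores_zero(self, toy_model):
        empty = pd.DataFrame(columns=["sample", "chrom", "arm", "direction",
                                      "breadth", "span", "arm_fraction"])
        assert broad_cna_score(empty, toy_model, samples=["s"])["s"] == 0.0
        assert focal_cna_score(empty, toy_model, samples=["s"])["s"] == 0.0

    def test_empty_gene_catalog_rejected(self):
        arms = pd.DataFrame({"chrom": ["chr1"], "arm": ["p"],
                             "start": [0], "end": [1000]})
        genes = pd.DataFrame(columns=["gene", "chrom", "start", "end"])
        model = GenomeArmModel(arms, genes)
        empty = pd.DataFrame(columns=["sample", "chrom", "arm", "direction",
                                      "breadth", "span", "arm_fraction"])
        with pytest.raises(SegmentError):
            focal_cna_score(empty, model)

    def test_tmb_formula_and_linearity(self):
        assert tmb_score(0) == 0.0
        assert tmb_score(2990) == pytest.approx(2990 / 299.029409, abs=1e-12)
        for k in (1, 17, 250):
            assert tmb_score(2 * k) == pytest.approx(2 * tmb_score(k), rel=1e-12)
        with pytest.raises(ValueError):
            tmb_score(-1)

    def test_fusion_score_formula(self):
        assert fusion_score(3, 6) == pytest.approx(0.5)
        assert fusion_score(0, 6) == 0.0
        with pytest.raises(ValueError):
            fusion_score(3, 0)

    def test_monotonicity_under_added_events(self, toy_model):
        base = pd.DataFrame({
            "sample": ["s"], "chrom": ["chr1"], "arm": ["p"],
            "direction": ["gain"], "breadth": ["broad"],
            "span": [990_000], "arm_fraction": [0.99],
        })
        extra = pd.concat([base, base.assign(chrom="chr2")], ignore_index=True)
        assert (broad_cna_score(extra, toy_model)["s"]
                >= broad_cna_score(base, toy_model)["s"])


class TestFrequencyProfile:
    def test_single_gain_marks_its_bins(self, toy_model):
        t = threshold_segments(seg_table(seg("s", "chr1", 0, 250_000, 0.5)))
        prof = cna_frequency_profile(t, toy_model, bin_bp=250_000)
        hit = prof[(prof["chrom"] == "chr1") & (prof["start"] == 0)]
        assert hit["gain_freq"].iloc[0] == 1.0
        assert prof["gain_freq"].sum() == 1.0
        assert (prof["loss_freq"] == 0).all()

    def test_empty_cohort_rejected(self, toy_model):
        empty = pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                      "value", "direction"])
        with pytest.raises(SegmentError):
            cna_frequency_profile(empty, toy_model, bin_bp=1000)

    def test_random_cohort_matches_membership_oracle(self, toy_model, rng):
        samples = [f"s{i}" for i in range(5)]
        table = threshold_segments(random_segment_table(rng, toy_model, samples))
        bin_bp = 200_000
        prof = cna_frequency_profile(table, toy_model, bin_bp=bin_bp)
        assert prof["gain_freq"].between(0, 1).all()
        check = prof.sample(n=min(25, len(prof)), random_state=1)
        for _, row in check.iterrows():
            for direction, col in (("gain", "gain_freq"), ("loss", "loss_freq")):
                n_hit = sum(
                    any(
                        (r["chrom"] == row["chrom"]) and (r["direction"] == direction)
                        and r["start"] < row["end"] and r["end"] > row["start"]
                        for _, r in table[table["sample"] == s].iterrows()
                    )
                    for s in samples
                )
                assert row[col] == pytest.approx(n_hit / len(samples))


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        panel = pd.DataFrame({"a": x, "b": x, "c": -x})
        corr = score_correlation_matrix(panel)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_column_is_undefined_not_zero(self):
        panel = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = score_correlation_matrix(panel)
        assert np.isnan(corr.loc["a", "b"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            score_correlation_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestOracleEquivalence:
    """Event calls and scores equal direct interval arithmetic exactly."""

    def test_random_tables_match_brute_force(self, toy_model, rng):
        samples = [f"s{i}" for i in range(8)]
        for _ in range(10):
            table = random_segment_table(rng, toy_model, samples)
            expected, detail = brute_force_cna(table, toy_model, samples=samples)
            scores = score_segments(table, toy_model, samples=samples)
            for s in samples:
                nb, nf = expected[s]
                assert scores.loc[s, "broad_cna_score"] == \
                    pytest.approx(nb / toy_model.total_arms)
                assert scores.loc[s, "focal_cna_score"] == \
                    pytest.approx(nf / toy_model.total_genes)

    def test_union_runs_oracle_self_consistent(self):
        runs = interval_union_runs([(0, 10), (5, 20), (30, 40)])
        assert runs == [(0, 20), (30, 40)]
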