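"""Livak quantification, significance, classification and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from markermine.datasets import table3
from markermine.io import validate_ct_frame
from markermine.qpcr import (
    classify_expression,
    classify_table,
    cross_patient_summary,
    delta_ct,
    fold_change,
    quantify,
    reference_ct,
    summarize_patient,
)
from markermine.qpcr import test_significance as ttest_dct
from markermine.simulate import SimulationConfig, simulate_ct_data


def ct_frame(rows):
    return validate_ct_frame(
        pd.DataFrame(rows, columns=["gene", "patient", "tissue", "replicate", "ct"])
    )


class TestReferenceCt:
    def test_single_reference_is_identity(self):
        df = ct_frame([("GAPDH", "P1", "cancer", r, 18.0 + r) for r in (1, 2, 3)])
        assert reference_ct(df, "P1", "cancer", ["GAPDH"]) == {
            1: 19.0,
            2: 20.0,
            3: 21.0,
        }

    def test_mean_of_three_references(self):
        rows = [(g, "P1", "cancer", 1, ct) for g, ct in
                (("GAPDH", 18.0), ("RNA18S", 20.0), ("RNA28S", 22.0))]
        df = ct_frame(rows)
        assert reference_ct(df, "P1", "cancer", ["GAPDH", "RNA18S", "RNA28S"]) == {1: 20.0}

    def test_missing_reference_replicate_is_error(self):
        rows = [("GAPDH", "P1", "cancer", 1, 18.0),
                ("RNA18S", "P1", "cancer", 1, 20.0),
                ("GAPDH", "P1", "cancer", 2, 18.1),
                ("TP53", "P1", "cancer", 2, 25.0)]
        df = ct_frame(rows)
        with pytest.raises(ValueError, match="RNA18S"):
            reference_ct(df, "P1", "cancer", ["GAPDH", "RNA18S"])

    def test_shared_shift_makes_multi_ref_equal_single_ref(self):
        # three noiseless references with one common Ct shift between
        # tissues give the same ddCt as any single one of them
        cfg = SimulationConfig(ct_noise_sd=0.0, n_patients=1, rng_seed=5)
        ct = simulate_ct_data(cfg, {"MKR0001": 4.0})
        q3 = quantify(ct, ["GAPDH", "RNA18S", "RNA28S"])
        q1 = quantify(ct[ct.gene.isin(["MKR0001", "GAPDH"])], ["GAPDH"])
        assert q3.loc[0, "ratio"] == pytest.approx(q1.loc[0, "ratio"])


class TestDeltaCtAndFold:
    def test_delta_ct_values(self):
        assert delta_ct(25.0, 20.0) == 5.0
        assert delta_ct(20.0, 20.0) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(5, 45, size=(20, 2)):
            assert delta_ct(a, b) == -delta_ct(b, a)

    def test_fold_change_closed_form(self):
        assert fold_change(0.0) == 1.0
        assert fold_change(-3.0) == 8.0

    @given(st.floats(-5, 5))
    @settings(derandomize=True)
    def test_log2_fold_equals_minus_ddct(self, ddct):
        assert np.log2(fold_change(ddct)) == pytest.approx(-ddct, abs=1e-12)

    def test_fold_change_strictly_decreasing_in_ddct(self):
        grid = np.linspace(-6, 6, 50)
        values = [fold_change(x) for x in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_efficiency_correction(self):
        # 85% efficient primers amplify 1.85-fold per cycle
        assert fold_change(-1.0, efficiency=0.85) == pytest.approx(1.85)
        with pytest.raises(ValueError):
            fold_change(1.0, efficiency=1.5)


class TestSignificance:
    def test_identical_groups_give_p_one(self):
        assert ttest_dct([3, 3, 3], [3, 3, 3]) == 1.0

    def test_separated_groups_match_textbook_welch(self):
        a, b = [1.0, 1.1, 0.9], [5.0, 5.1, 4.9]
        p = ttest_dct(a, b)
        # oracle: Welch t statistic and df by the textbook formulae
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / 3 + vb / 3
        t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
        df = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        oracle = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p < 0.001

    def test_symmetry_in_group_order(self):
        a, b = [1.2, 0.8, 1.1], [2.0, 2.2, 1.7]
        assert ttest_dct(a, b) == pytest.approx(ttest_dct(b, a))

    def test_fewer_than_two_replicates_is_error(self):
        with pytest.raises(ValueError):
            ttest_dct([1.0], [2.0, 3.0])

    def test_degenerate_zero_variance_unequal_means(self):
        assert ttest_dct([1, 1, 1], [2, 2, 2]) == 0.0

    def test_paired_variant(self):
        a, b = [1.0, 1.2, 0.9], [2.0, 2.3, 1.8]
        expected = stats.ttest_rel(a, b).pvalue
        assert ttest_dct(a, b, variant="paired") == pytest.approx(expected)


class TestClassifyExpression:
    @pytest.mark.parametrize(
        "ratio,p,expected",
        [
            (15.74, 0.0001, ("up", 4)),
            (1.333, 0.1679, ("none", 0)),
            (0.123, 0.0023, ("down", 4)),
            (5.847, 0.0008, ("up", 3)),
            (1.917, 0.0000, ("up", 1)),
            (0.567, 0.0114, ("down", 1)),
            (0.380, 0.0088, ("down", 2)),
            (7.947, 0.0001, ("up", 3)),
        ],
    )
    def test_published_cells(self, ratio, p, expected):
        assert classify_expression(ratio, p) == expected

    def test_boundaries_half_open(self):
        assert classify_expression(2.0, 0.01) == ("up", 2)
        assert classify_expression(4.0, 0.01) == ("up", 3)
        assert classify_expression(8.0, 0.01) == ("up", 4)
        assert classify_expression(1.999, 0.01) == ("up", 1)
        assert classify_expression(0.5, 0.01) == ("down", 2)

    def test_alpha_boundary_and_unit_ratio(self):
        assert classify_expression(3.0, 0.05) == ("none", 0)
        assert classify_expression(1.0, 0.0001) == ("none", 0)

    def test_nonpositive_ratio_is_error(self):
        with pytest.raises(ValueError):
            classify_expression(0.0, 0.01)

    @given(
        log2r=st.floats(-4, 4),
        bump=st.floats(0.1, 2.0),
    )
    @settings(derandomize=True)
    def test_arrows_nondecreasing_in_fold_magnitude(self, log2r, bump):
        _, arrows_small = classify_expression(2.0**log2r, 0.001)
        sign = 1 if log2r >= 0 else -1
        _, arrows_big = classify_expression(2.0 ** (log2r + sign * bump), 0.001)
        assert arrows_big >= arrows_small


class TestPublishedTableParity:
    def test_every_printed_annotation_reproduced(self):
        df = classify_table(table3())
        assert len(df) == 126
        assert (df["direction"] == df["printed_direction"]).all()
        assert (df["arrows"] == df["printed_arrows"]).all()


class TestSummaries:
    def test_patient_tallies_match_publication(self):
        df = classify_table(table3())
        expected = {"1": (17, 6), "2": (25, 2), "3": (32, 6)}
        for patient, group in df.groupby("patient"):
            s = summarize_patient(group)
            assert (s.n_up, s.n_down) == expected[patient]
            assert s.n_up + s.n_down + s.n_ns == s.n_tested == 42
        assert summarize_patient(df[df.patient == "1"]).n_up + \
            summarize_patient(df[df.patient == "1"]).n_down == 23

    def test_cross_patient_counts_match_publication(self):
        cross = cross_patient_summary(classify_table(table3()))
        assert cross.genes_up_all == (
            "BID", "CDK2", "CDK4", "CDK6", "IRS2", "PDGFRB", "SHC1",
        )
        assert cross.n_up_any == 40
        assert cross.n_altered_any == 41
        assert cross.genes_never_altered == ("CDKN1A",)

    def test_duplicate_gene_rejected(self):
        df = pd.DataFrame(
            {"gene": ["A", "A"], "patient": ["1", "1"],
             "direction": ["up", "up"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            summarize_patient(df)

    def test_all_nonsignificant_tally(self):
        df = pd.DataFrame(
            {"gene": list("ABC"), "patient": ["1"] * 3,
             "direction": ["none"] * 3}
        )
        s = summarize_patient(df)
        assert (s.n_up, s.n_down, s.n_ns) == (0, 0, 3)

    def test_random_records_match_brute_force_tally(self):
        rng = np.random.default_rng(17)
        dirs = rng.choice(["up", "down", "none"], size=30)
        df = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(30)],
             "patient": ["7"] * 30, "direction": dirs}
        )
        s = summarize_patient(df)
        assert s.n_up == sum(d == "up" for d in dirs)
        assert s.n_down == sum(d == "down" for d in dirs)

    def test_single_patient_degenerate_cross_summary(self):
        df = classify_table(table3())
        one = df[df.patient == "1"]
        cross = cross_patient_summary(one)
        assert cross.n_up_all == cross.n_up_any

    def test_unequal_panels_rejected(self):
        df = classify_table(table3())
        trimmed = df.drop(df[(df.patient == "2") & (df.gene == "BID")].index)
        with pytest.raises(ValueError, match="unequal"):
            cross_patient_summary(trimmed)


class TestPipelineRecovery:
    def test_noiseless_fold_recovered_exactly(self):
        cfg = SimulationConfig(ct_noise_sd=0.0, n_patients=1, rng_seed=2)
        ct = simulate_ct_data(cfg, {"MKR0001": 8.0, "MKR0002": 1.0})
        q = quantify(ct, cfg.reference_genes).set_index("gene")
        assert q.loc["MKR0001", "ratio"] == pytest.approx(8.0, abs=1e-9)
        assert q.loc["MKR0002", "ratio"] == pytest.approx(1.0, abs=1e-9)
        assert q.loc["MKR0002", "p_value"] == 1.0

    def test_noisy_fold_recovered_within_30_percent_95_of_the_time(self):
        # true fold 4, replicate noise sd 0.1 cycles, triplicates
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            cfg = SimulationConfig(ct_noise_sd=0.1, n_patients=1, rng_seed=10_000 + i)
            ct = simulate_ct_data(cfg, {"MKR0001": 4.0})
            ratio = quantify(ct, cfg.reference_genes).loc[0, "ratio"]
            if 4.0 / 1.3 <= ratio <= 4.0 * 1.3:
                hits += 1
        assert hits / n_sim >= 0.95
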