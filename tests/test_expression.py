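"""Selection classing, DE calling and TE-proximity expression effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fractiomics.config import SimulationConfig
from fractiomics.expression import (
    assign_te_bins,
    call_de,
    call_de_counts,
    classify_selection,
    de_table,
    expressed_flags,
    expression_selection_regression,
    max_expression,
    te_proximity_effect,
    trigger_sets,
)

from conftest import make_tpm


class TestClassifySelection:
    @pytest.mark.parametrize(
        "omega,expected",
        [
            (0.787, "purifying"),  # boundary inclusive
            (0.7871, "neutral"),
            (1.0, "neutral"),
            (1.213, "neutral"),  # boundary inclusive
            (1.2131, "positive"),
            (0.0, "purifying"),
            (np.nan, "undefined"),
        ],
    )
    def test_banded_thresholds(self, omega, expected):
        assert classify_selection(omega) == expected

    def test_vectorised(self):
        out = classify_selection(np.array([0.1, 1.0, 1.5, np.nan]))
        assert list(out) == ["purifying", "neutral", "positive", "undefined"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_selection(-0.1)

    @given(st.lists(st.floats(0, 3), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving_step_function(self, omegas):
        # class index must be nondecreasing in omega
        rank = {"purifying": 0, "neutral": 1, "positive": 2}
        ordered = sorted(omegas)
        classes = [rank[classify_selection(o)] for o in ordered]
        assert classes == sorted(classes)


COLS = ["control_1", "control_2", "cold_1", "cold_2"]


class TestCallDe:
    def test_pseudocounted_fold_change(self):
        tpm = make_tpm({"g1": [2, 2, 8, 8]}, COLS)
        res = call_de(tpm, "cold")
        assert res.loc["g1", "log2fc"] == pytest.approx(np.log2(9 / 3))

    def test_null_gene_not_de(self):
        tpm = make_tpm({"g1": [5, 5, 5, 5]}, COLS)
        res = call_de(tpm, "cold")
        assert res.loc["g1", "log2fc"] == 0.0
        assert not res.loc["g1", "de_flag"]

    def test_relabel_symmetry(self):
        tpm = make_tpm({"g1": [2, 3, 9, 8], "g2": [4, 4, 4, 5]}, COLS)
        fwd = call_de(tpm, "cold", control="control")
        rev = call_de(tpm, "control", control="cold")
        assert fwd["log2fc"].to_numpy() == pytest.approx(-rev["log2fc"].to_numpy())
        assert (fwd["de_flag"] == rev["de_flag"]).all()

    def test_single_replicate_needs_flag(self):
        tpm = make_tpm({"g1": [2, 8]}, ["control_1", "cold_1"])
        with pytest.raises(ValueError, match="replicates"):
            call_de(tpm, "cold")
        res = call_de(tpm, "cold", fold_change_only=True)
        assert res.loc["g1", "de_flag"]

    def test_negative_tpm_rejected(self):
        tpm = make_tpm({"g1": [2, -1, 8, 8]}, COLS)
        with pytest.raises(ValueError):
            call_de(tpm, "cold")

    def test_unexpressed_gene_never_de(self):
        tpm = make_tpm({"g1": [0.01, 0.01, 0.9, 0.9]}, COLS)
        res = call_de(tpm, "cold")
        assert not res.loc["g1", "de_flag"]

    def test_power_simulation(self):
        # 1,000 genes, 100 with a planted 2-log2 effect, 3 replicates at the
        # generator's replicate noise: sensitivity >= 0.9, FDR <= 0.1
        rng = np.random.default_rng(2024)
        cfg = SimulationConfig()
        n, ntrue, reps = 1000, 100, 3
        mu = rng.normal(3, 2, n)
        true = np.zeros(n, bool)
        true[:ntrue] = True
        cols, data = [], []
        for cond in ("control", "cold"):
            for r in range(1, reps + 1):
                boost = np.where(true & (cond == "cold"), 2.0, 0.0)
                data.append(2 ** (mu + boost + rng.normal(0, cfg.replicate_noise_sd, n)))
                cols.append(f"{cond}_{r}")
        tpm = pd.DataFrame(
            np.column_stack(data), index=[f"g{i}" for i in range(n)], columns=cols
        )
        res = call_de(tpm, "cold")
        flag = res["de_flag"].to_numpy()
        sensitivity = flag[true].mean()
        fdr = (flag & ~true).sum() / max(flag.sum(), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1


class TestCallDeCounts:
    def test_exact_binomial_matches_scipy(self):
        from scipy.stats import binomtest

        counts = make_tpm({"g1": [100, 110, 400, 420], "g2": [50, 60, 55, 52]}, COLS)
        res = call_de_counts(counts, "cold")
        kt, kc = 820, 210
        lib_t, lib_c = 820 + 107, 210 + 110  # per-condition library sums
        p0 = lib_t / (lib_t + lib_c)
        expected = binomtest(kt, kt + kc, p0).pvalue
        assert res.loc["g1", "p"] == pytest.approx(expected, rel=1e-12)

    def test_balanced_gene_not_de(self):
        counts = make_tpm({"g1": [100, 100, 100, 100]}, COLS)
        res = call_de_counts(counts, "cold")
        assert res.loc["g1", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert not res.loc["g1", "de_flag"]

    def test_clear_shift_detected(self):
        rows = {f"bg{i}": [100, 100, 100, 100] for i in range(20)}
        rows["g_up"] = [50, 50, 400, 420]
        counts = make_tpm(rows, COLS)
        res = call_de_counts(counts, "cold")
        assert res.loc["g_up", "de_flag"]


class TestMaxExpression:
    def test_all_zero_gene(self):
        tpm = make_tpm({"g1": [0, 0, 0, 0]}, COLS)
        assert max_expression(tpm).loc["g1"] == 0.0

    def test_arithmetic(self):
        cols = [f"{c}_1" for c in ("a", "b", "c", "d", "e")]
        tpm = make_tpm({"g1": [1, 3, 7, 0, 2]}, cols)
        assert max_expression(tpm).loc["g1"] == pytest.approx(3.0)

    def test_condition_permutation_invariant(self):
        tpm = make_tpm({"g1": [2, 3, 9, 8]}, COLS)
        perm = tpm[["cold_1", "cold_2", "control_1", "control_2"]]
        assert max_expression(tpm).loc["g1"] == max_expression(perm).loc["g1"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_expression(pd.DataFrame())


def brute_force_bins(genes, tes):
    """All-pairs minimum-distance oracle."""
    out = {}
    for gid, g in genes.iterrows():
        best = np.inf
        for _, t in tes.iterrows():
            if t["chrom"] != g["chrom"]:
                continue
            if t["start"] < g["end"] and t["end"] > g["start"]:
                d = 0
            else:
                d = max(g["start"] - t["end"], t["start"] - g["end"])
            best = min(best, d)
        if best == 0:
            out[gid] = "overlapping"
        elif best <= 200:
            out[gid] = "near"
        elif best <= 2000:
            out[gid] = "mid"
        else:
            out[gid] = "far"
    return out


class TestTeProximity:
    def test_minimum_distance_rule(self):
        genes = pd.DataFrame(
            {"chrom": ["c1"], "start": [10_000], "end": [12_000]}, index=["g1"]
        )
        tes = pd.DataFrame(
            {
                "chrom": ["c1", "c1"],
                "start": [9_650, 15_000],  # 150 bp upstream, 3,000 bp downstream
                "end": [9_850, 15_500],
            }
        )
        bins = assign_te_bins(genes, tes)
        assert bins.loc["g1", "bin"] == "near"
        assert bins.loc["g1", "distance"] == 150

    def test_no_tes_all_far_reductions_undefined(self):
        genes = pd.DataFrame(
            {"chrom": ["c1", "c1"], "start": [0, 5000], "end": [100, 5100]},
            index=["g1", "g2"],
        )
        tes = pd.DataFrame({"chrom": [], "start": [], "end": []})
        expr = pd.Series([5.0, 7.0], index=["g1", "g2"])
        tbl = te_proximity_effect(genes, tes, expr)
        assert (tbl["n_genes"] == [0, 0, 0, 2]).all()
        assert np.isnan(tbl.loc["mid", "pct_reduction_vs_far"])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bins_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], 200),
                "start": rng.integers(0, 500_000, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        genes["end"] = genes["start"] + rng.integers(500, 3000, 200)
        tes = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], 200),
                "start": rng.integers(0, 500_000, 200),
            }
        )
        tes["end"] = tes["start"] + rng.integers(100, 2000, 200)
        bins = assign_te_bins(genes, tes)
        assert bins["bin"].to_dict() == brute_force_bins(genes, tes)

    def test_planted_suppression_recovered(self, mid_bundle):
        # ~3,000 genes with a planted 1.83-log2 mid-bin suppression
        bundle, truth = mid_bundle
        ctrl = bundle.tpm[[c for c in bundle.tpm.columns if c.startswith("control_")]]
        tbl = te_proximity_effect(bundle.genes, bundle.tes, ctrl.mean(axis=1))
        planted = bundle.config.te_expr_log2_reduction
        assert tbl.loc["mid", "log2_reduction_vs_far"] == pytest.approx(planted, abs=0.15)
        # percent reduction within 5 points of the planted median effect
        assert tbl.loc["mid", "pct_reduction_vs_far"] == pytest.approx(
            (1 - 2**-planted) * 100, abs=5
        )
        assert tbl.loc["mid", "p_vs_far"] < 1e-6


class TestExpressionSelectionRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 50)
        y = -0.1 * x + 0.3
        slope, p = expression_selection_regression(x, y)
        assert slope == pytest.approx(-0.10, abs=1e-12)
        assert p < 1e-30

    def test_permuted_pairing_null(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 2000)
        y = -0.1 * x + 0.3 + rng.normal(0, 0.05, 2000)
        slope, _ = expression_selection_regression(x, rng.permutation(y))
        assert slope == pytest.approx(0.0, abs=0.01)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 2, 5000)
        y = 0.45 - 0.1 * x + rng.normal(0, 0.08, 5000)
        slope, p = expression_selection_regression(x, y)
        assert slope == pytest.approx(-0.10, abs=0.01)
        assert p < 1e-10

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            expression_selection_regression([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            expression_selection_regression([1, 2], [0.1, 0.2])


class TestDeTableHelpers:
    def test_trigger_sets_roundtrip(self):
        cols = ["control_1", "control_2", "cold_1", "cold_2", "heat_1", "heat_2"]
        tpm = make_tpm(
            {"g1": [2, 2, 30, 32, 2, 2], "g2": [5, 5, 5, 5, 5, 5]}, cols
        )
        flags = de_table(tpm, ["cold", "heat"])
        trig = trigger_sets(flags, ["cold", "heat"])
        assert trig.loc["g1"] == frozenset({"cold"})
        assert trig.loc["g2"] == frozenset()

    def test_expressed_threshold(self):
        tpm = make_tpm({"g1": [0.4, 0.6, 0.9, 1.0], "g2": [0.0, 0.0, 1.5, 1.9]}, COLS)
        flags = expressed_flags(tpm)
        assert not flags.loc["g1"]  # max condition mean is 0.95
        assert flags.loc["g2"]
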