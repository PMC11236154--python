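"""Group statistics (ANOVA, t-test, significance letters) and the pipeline."""

import filecmp

import numpy as np
import pytest

import spermshape as ss
from spermshape import DegenerateVarianceError, ParameterError, ValidationError
from spermshape.stats_report import (
    compare_to_control,
    one_way_anova,
    run_pipeline,
    significance_letter,
    t_test,
)


def anova_oracle(groups):
    """Brute-force sum-of-squares decomposition of the one-way layout."""
    flat = np.concatenate(groups)
    grand = flat.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, N = len(groups), len(flat)
    return (ssb / (k - 1)) / (ssw / (N - k))


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        F, p = one_way_anova(groups)
        assert F == pytest.approx(anova_oracle(groups), abs=1e-12)
        assert 0.0 < p < 1.0

    def test_identical_groups_convention(self):
        F, p = one_way_anova([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert F == pytest.approx(0.0, abs=1e-12)
        # zero within variance with equal means
        F0, p0 = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert (F0, p0) == (0.0, 1.0)

    def test_zero_within_variance_unequal_means(self):
        F, p = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(F) and p == 0.0

    def test_two_groups_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.5]
        F, pF = one_way_anova([a, b])
        t, pt = t_test(a, b)
        assert F == pytest.approx(t**2, abs=1e-12)
        assert pF == pytest.approx(pt, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ParameterError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_pooled_oracle(self):
        """Hand-computed pooled-variance t for {1,2,3,4} vs {3,4,5,6}."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        from scipy import stats as sps

        expected_p = 2 * sps.t.sf(abs(expected_t), df=6)
        t, p = t_test(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_welch_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 6, 40)
        _, p_student = t_test(a, b, welch=False)
        _, p_welch = t_test(a, b, welch=True)
        assert p_student != p_welch

    def test_degenerate_constant_samples(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0


class TestLetters:
    @pytest.mark.parametrize(
        "p,letter",
        [(0.2, ""), (0.05, ""), (0.049, "a"), (0.01, "a"), (0.009, "b"),
         (0.001, "b"), (0.0009, "c"), (1e-12, "c")],
    )
    def test_threshold_mapping(self, p, letter):
        assert significance_letter(p) == letter


class TestCompareToControl:
    def test_strong_shift_gets_letter_c(self):
        rng = np.random.default_rng(0)
        comp = compare_to_control(
            {"WT": rng.normal(0, 1, 50), "KO": rng.normal(-2, 1, 50)}, "WT"
        )
        row = comp.table.set_index("group")
        assert row.loc["KO", "letter"] == "c"
        assert np.isnan(row.loc["WT", "p_vs_control"])

    def test_null_type_i_rate(self):
        """Same-distribution control vs KO keeps the letter empty in >= 90%
        of replicates at the 0.05 level."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 100
        for _ in range(reps):
            comp = compare_to_control(
                {"WT": rng.normal(0, 1, 50), "KO": rng.normal(0, 1, 50)}, "WT"
            )
            if comp.table.set_index("group").loc["KO", "letter"] != "":
                hits += 1
        assert hits / reps <= 0.10

    def test_holm_method_close_to_single_t(self):
        rng = np.random.default_rng(5)
        groups = {"WT": rng.normal(0, 1, 30), "KO": rng.normal(-1, 1, 30)}
        comp = compare_to_control(groups, "WT", method="holm_t")
        _, p_single = t_test(groups["KO"], groups["WT"])
        got = comp.table.set_index("group").loc["KO", "p_vs_control"]
        assert got == pytest.approx(p_single)  # one comparison: no adjustment

    def test_three_groups_dunnett_adjusts(self):
        rng = np.random.default_rng(8)
        groups = {
            "WT": rng.normal(0, 1, 30),
            "KO1": rng.normal(-0.5, 1, 30),
            "KO2": rng.normal(0.5, 1, 30),
        }
        comp = compare_to_control(groups, "WT")
        tab = comp.table.set_index("group")
        for ko in ("KO1", "KO2"):
            _, p_single = t_test(groups[ko], groups["WT"])
            assert tab.loc[ko, "p_vs_control"] >= p_single - 1e-12

    def test_missing_control_errors(self):
        with pytest.raises(ParameterError):
            compare_to_control({"A": [1.0, 2.0], "B": [2.0, 3.0]}, "WT")


SIM_CONFIG = {
    "mode": "simulate",
    "seed": 17,
    "n_points": 200,
    "harmonics": 20,
    "n_components": 2,
    "groups": [
        {
            "label": "WT",
            "n": 15,
            "head_params": {"hook_length": 18.0},
            "head_params_sd": {"hook_length": 2.0, "body_width": 1.5},
        },
        {
            "label": "KO",
            "n": 15,
            "head_params": {"hook_length": 12.0},
            "head_params_sd": {"hook_length": 2.0, "body_width": 1.5},
        },
    ],
}


class TestPipeline:
    def test_bundle_contents(self, tmp_path):
        bundle = run_pipeline(dict(SIM_CONFIG), outdir=tmp_path / "out")
        assert len(bundle["tables"]["coefficients"]) == 30
        assert {"specimen_id", "group", "PC1", "PC2"} <= set(bundle["tables"]["scores"].columns)
        assert len(bundle["mean_shapes"]) == 6  # 2 PCs x {-2, 0, +2} SD
        assert (tmp_path / "out" / "summary.json").exists()
        assert (tmp_path / "out" / "scores.tsv").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        run_pipeline(dict(SIM_CONFIG), outdir=tmp_path / "a")
        run_pipeline(dict(SIM_CONFIG), outdir=tmp_path / "b")
        for name in ("coefficients.tsv", "scores.tsv", "comparisons.tsv",
                     "mean_shapes.csv", "summary.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_hook_shift_flagged_on_some_pc(self):
        bundle = run_pipeline(dict(SIM_CONFIG))
        comp = bundle["tables"]["comparisons"]
        ko = comp[(comp["group"] == "KO")]
        assert (ko["letter"] != "").any()

    def test_contour_mode_with_manifest(self, tmp_path):
        recs = []
        for i, hook in enumerate([18.0, 18.5, 12.0, 12.5]):
            c = ss.make_head_contour(ss.HeadParams(hook_length=hook, seed=i), 200)
            recs.append((f"s{i}", c))
        contours = tmp_path / "contours.csv"
        ss.write_contours(contours, recs)
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text(
            "specimen_id\tgroup\ns0\tWT\ns1\tWT\ns2\tKO\ns3\tKO\n"
        )
        bundle = run_pipeline(
            {"mode": "contours", "contours": str(contours), "manifest": str(manifest),
             "control": "WT", "n_components": 2}
        )
        assert len(bundle["tables"]["scores"]) == 4

    def test_manifest_mismatch_lists_ids(self, tmp_path):
        c = ss.make_head_contour(ss.HeadParams(), 200)
        contours = tmp_path / "contours.csv"
        ss.write_contours(contours, [("s0", c), ("orphan", c)])
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("specimen_id\tgroup\ns0\tWT\n")
        with pytest.raises(ValidationError, match="orphan"):
            run_pipeline(
                {"mode": "contours", "contours": str(contours), "manifest": str(manifest)}
            )

    def test_measurements_and_kinematics_sections(self, tmp_path):
        conf = dict(SIM_CONFIG)
        conf["groups"] = [dict(g, n=8) for g in conf["groups"]]
        conf["render"] = {"vacuole_count": 1, "image_shape": [160, 160]}
        conf["tracks"] = {"default": {"n": 8, "speed": 100.0, "speed_sd": 10.0}}
        bundle = run_pipeline(conf, outdir=tmp_path / "out")
        assert len(bundle["tables"]["measurements"]) == 16
        assert len(bundle["tables"]["kinematics"]) == 16
        assert "vacuole_prevalence" in bundle
        variables = set(bundle["tables"]["comparisons"]["variable"])
        assert {"PC1", "PC2", "acrosome_area_um2", "VSL", "VCL", "VAP"} <= variables
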