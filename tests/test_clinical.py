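import numpy as np
import pandas as pd
import pytest

from segeval import tables
from segeval.clinical import (
    build_study_report,
    cohen_kappa,
    kappa_by_clinician,
    make_blinding_schedule,
    mcnemar_test,
    per_slice_mean_score,
    score_summary,
    turing_summary,
    validate_score_table,
)
from segeval.study_sim import RaterStudyConfig, simulate_scoring_study, simulate_turing_study


class TestBlinding:
    def test_same_seed_reproduces_schedule(self):
        ids = [f"c{i}" for i in range(20)]
        sl = [f"s{i}" for i in range(10)]
        assert make_blinding_schedule(ids, sl, 7) == make_blinding_schedule(ids, sl, 7)

    def test_sessions_randomized_independently(self):
        ids = [f"c{i}" for i in range(50)]
        sched = make_blinding_schedule(ids, ["s0"], seed=3)
        s = sched["sessions"]
        assert s["week0"]["presentation_order"] != s["week2"]["presentation_order"]

    def test_color_assignment_balanced(self):
        sl = [f"s{i}" for i in range(1000)]
        sched = make_blinding_schedule(["c0"], sl, seed=11)
        colors = list(sched["sessions"]["week0"]["ai_color"].values())
        frac_red = np.mean([c == "red" for c in colors])
        assert frac_red == pytest.approx(0.5, abs=0.05)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            make_blinding_schedule(["a", "a"], ["s"], 0)


class TestScoreSummary:
    @pytest.fixture(scope="class")
    @staticmethod
    def reference():
        return tables.scoring_counts_to_table()

    def test_reference_clinician_a_week0_ai_mean(self, reference):
        s = score_summary(reference, "week0")
        assert s.per_clinician["A"]["AI"]["mean"] == pytest.approx(2.84)
        assert s.per_clinician["A"]["GT"]["mean"] == pytest.approx(2.70)

    def test_reference_overall_means_both_sessions(self, reference):
        s0 = score_summary(reference, "week0")
        s2 = score_summary(reference, "week2")
        assert s0.overall_mean["AI"] == pytest.approx(2.59, abs=0.005)
        assert s0.overall_mean["GT"] == pytest.approx(2.52, abs=0.005)
        assert s2.overall_mean["AI"] == pytest.approx(2.55, abs=0.005)
        assert s2.overall_mean["GT"] == pytest.approx(2.47, abs=0.005)

    def test_all_threes_mean_and_acceptability(self):
        df = pd.DataFrame(
            {
                "clinician_id": ["A"] * 4,
                "contour_id": ["a", "b", "c", "d"],
                "session": ["week0"] * 2 + ["week0"] * 2,
                "arm": ["AI", "AI", "GT", "GT"],
                "score": [3, 3, 3, 3],
            }
        )
        s = score_summary(df, "week0")
        assert s.overall_mean["AI"] == 3.0
        assert s.acceptability_percent["AI"] == 100.0
        assert s.fully_acceptable_percent["AI"] == 100.0

    def test_percentages_sum_to_hundred_and_mean_conventions_differ(self):
        df = simulate_scoring_study(RaterStudyConfig(seed=13))
        # unbalance: drop half of one clinician's AI ratings
        drop = df[(df.clinician_id == "C00") & (df.arm == "AI")].index[:25]
        s = score_summary(df.drop(drop), "week0")
        for arm in ("AI", "GT"):
            assert sum(s.pooled_percent[arm].values()) == pytest.approx(100.0)
        assert s.overall_mean["AI"] != pytest.approx(s.pooled_mean["AI"], abs=1e-6)

    def test_missing_cells_reported(self):
        df = pd.DataFrame(
            {
                "clinician_id": ["A", "A"],
                "contour_id": ["x", "y"],
                "session": ["week0", "week0"],
                "arm": ["AI", "AI"],
                "score": [2, 3],
            }
        )
        s = score_summary(df, "week0")
        assert {"clinician_id": "A", "arm": "GT", "session": "week0"} in s.missing_cells

    def test_invalid_tables_rejected(self):
        bad = pd.DataFrame(
            {
                "clinician_id": ["A"],
                "contour_id": ["x"],
                "session": ["week0"],
                "arm": ["AI"],
                "score": [5],
            }
        )
        with pytest.raises(ValueError):
            validate_score_table(bad)


class TestKappa:
    def test_identical_ratings_give_one(self):
        s = [0, 1, 2, 3, 2, 1]
        assert cohen_kappa(s, s) == pytest.approx(1.0)

    def test_independent_uniform_ratings_near_zero(self):
        r = np.random.default_rng(5)
        a, b = r.integers(0, 4, 10_000), r.integers(0, 4, 10_000)
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=0.03)

    def test_contingency_fixture_matches_direct_formula(self):
        # fixed 4x4 contingency table, expanded to paired ratings
        table = np.array(
            [[10, 2, 1, 0], [3, 20, 4, 1], [0, 5, 30, 6], [1, 0, 2, 15]]
        )
        s1, s2 = [], []
        for i in range(4):
            for j in range(4):
                s1 += [i] * table[i, j]
                s2 += [j] * table[i, j]
        n = table.sum()
        po = np.trace(table) / n
        pe = (table.sum(1) / n) @ (table.sum(0) / n)
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa(s1, s2) == pytest.approx(expected)

    def test_undefined_when_no_variation(self):
        assert cohen_kappa([2, 2, 2], [2, 2, 2]) is None

    def test_weighted_variant_available(self):
        from sklearn.metrics import cohen_kappa_score

        r = np.random.default_rng(2)
        a, b = r.integers(0, 4, 200), r.integers(0, 4, 200)
        got = cohen_kappa(a, b, weights="linear")
        assert got == pytest.approx(
            float(cohen_kappa_score(a, b, labels=[0, 1, 2, 3], weights="linear"))
        )

    def test_per_clinician_kappa_on_simulated_study(self):
        df = simulate_scoring_study(RaterStudyConfig(seed=20))
        out = kappa_by_clinician(df)
        assert len(out) == 10
        for v in out.values():
            assert v["n"] == 100
            assert v["kappa"] is None or -1 <= v["kappa"] <= 1


class TestMcNemar:
    def test_identical_sessions_give_p_one(self):
        b = [0, 1, 1, 0, 1]
        assert mcnemar_test(b, b)["p"] == 1.0

    def test_one_sided_discordance_closed_form(self):
        # 10 discordant pairs, all in one direction: p = 2 * 0.5^10
        s1 = [1] * 10 + [0] * 10
        s2 = [0] * 10 + [0] * 10
        out = mcnemar_test(s1, s2)
        assert out["method"] == "exact-binomial"
        assert out["p"] == pytest.approx(2 * 0.5**10)

    def test_exact_branch_matches_binomial_enumeration(self, rng):
        from scipy.stats import binom

        s1 = rng.integers(0, 2, 100)
        s2 = s1.copy()
        flip = rng.choice(100, size=14, replace=False)
        s2[flip] = 1 - s2[flip]
        out = mcnemar_test(s1, s2)
        n01 = int(((s1 == 0) & (s2 == 1)).sum())
        n = out["discordant"]
        k = min(n01, n - n01)
        expected = min(1.0, 2 * binom.cdf(k, n, 0.5))
        assert out["p"] == pytest.approx(expected, abs=1e-9)

    def test_chi2_branch_used_for_many_discordant_pairs(self, rng):
        s1 = rng.integers(0, 2, 200)
        s2 = rng.integers(0, 2, 200)
        out = mcnemar_test(s1, s2)
        assert out["discordant"] >= 25
        assert out["method"] == "chi2-corrected"
        assert 0 <= out["p"] <= 1


class TestTuring:
    @pytest.fixture(scope="class")
    @staticmethod
    def reference():
        return tables.turing_counts_to_table()

    def test_reference_mean_positive_rates(self, reference):
        t0 = turing_summary(reference, "week0")
        t2 = turing_summary(reference, "week2")
        assert 100 * t0.mean_positive_rate == pytest.approx(40.5)
        assert 100 * t2.mean_positive_rate == pytest.approx(45.2)

    def test_reference_verdict_all_clinicians_pass(self, reference):
        for session in ("week0", "week2"):
            assert turing_summary(reference, session).verdict_all_clinicians

    def test_verdict_monotone_in_criterion(self, reference):
        t_03 = turing_summary(reference, "week0", criterion=0.30)
        for lower in (0.2, 0.1, 0.0):
            assert (
                turing_summary(reference, "week0", criterion=lower).verdict_all_clinicians
                >= t_03.verdict_all_clinicians
            )
        # strict criterion above the minimum rate must fail
        assert not turing_summary(reference, "week0", criterion=0.35).verdict_all_clinicians

    def test_all_negative_fails(self):
        df = pd.DataFrame(
            {
                "clinician_id": ["A"] * 3,
                "slice_id": ["s0", "s1", "s2"],
                "session": ["week0"] * 3,
                "chosen_color": ["green"] * 3,
                "ai_color": ["red"] * 3,
            }
        )
        t = turing_summary(df, "week0")
        assert t.mean_positive_rate == 0.0
        assert not t.verdict_all_clinicians


class TestPerSliceScore:
    def test_three_of_ten_positive_gives_03(self):
        rows = []
        for c in range(10):
            rows.append(
                (f"C{c}", "s0", "week0", "red" if c < 3 else "green", "red")
            )
        df = pd.DataFrame(
            rows, columns=["clinician_id", "slice_id", "session",
                           "chosen_color", "ai_color"]
        )
        out = per_slice_mean_score(df, "week0")
        assert out["per_slice"]["s0"] == pytest.approx(0.3)
        assert out["n_ge_03"] == 1 and out["n_ge_05"] == 0

    def test_simulator_recovery_of_slice_probabilities(self):
        cfg = RaterStudyConfig(n_clinicians=50, n_slices=20,
                               turing_positive_prob=0.4, seed=44)
        df = simulate_turing_study(cfg)
        out = per_slice_mean_score(df, "week0")
        mean_over_slices = np.mean(list(out["per_slice"].values()))
        assert mean_over_slices == pytest.approx(0.4, abs=0.1)


class TestStudyReport:
    def test_full_report_from_simulated_study(self):
        cfg = RaterStudyConfig(seed=30)
        report = build_study_report(
            simulate_scoring_study(cfg), simulate_turing_study(cfg)
        )
        d = report.to_dict()
        assert set(d["scoring"]) == {"week0", "week2"}
        assert set(d["turing"]) == {"week0", "week2"}
        assert len(d["kappa"]) == 10
        assert len(d["mcnemar"]) == 10

    def test_unblinded_aggregation_recovers_arm_ordering(self):
        cfg = RaterStudyConfig(
            latent_quality_mean_ai=2.8, latent_quality_mean_gt=2.2, seed=31
        )
        report = build_study_report(simulate_scoring_study(cfg), None)
        s = report.scoring["week0"]
        assert s.overall_mean["AI"] > s.overall_mean["GT"]

    def test_report_rendering_contains_key_rows(self):
        from segeval.report import render_report_markdown

        cfg = RaterStudyConfig(seed=32)
        report = build_study_report(
            simulate_scoring_study(cfg), simulate_turing_study(cfg)
        )
        md = render_report_markdown(report)
        assert "Mean score" in md
        assert "Intelligence criterion" in md
        assert render_report_markdown(build_study_report(None, None)) == "(empty study)"
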