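import numpy as np
import pytest

from genolaws.cohort import (
    build_cohort,
    fit_regression,
    panel_regressions,
    rank_outliers,
    read_composition_table,
    write_cohort_tsv,
)
from genolaws.composition import BaseCounts, count_bases
from genolaws.designer import DesignSpec, design_sequence


def _designed_cohort(s_values, r=0.5, length=2000, mode="exact", seed0=100):
    genomes = []
    for i, s in enumerate(s_values):
        spec = DesignSpec(target_s=float(s), target_r=r, length=length, seed=seed0 + i, mode=mode)
        genomes.append((f"g{i:03d}", count_bases(design_sequence(spec).sequence)))
    return build_cohort(genomes)


class TestBuildCohort:
    def test_rows_and_invariants(self):
        table = _designed_cohort([0.3, 0.5, 0.7])
        assert len(table) == 3
        for row in table.rows:
            assert row.profile.p_s + row.profile.p_w == pytest.approx(1.0, abs=1e-12)

    def test_single_genome_refused_by_regressions(self):
        table = build_cohort([("solo", BaseCounts(10, 10, 10, 10))])
        assert len(table) == 1
        with pytest.raises(ValueError):
            panel_regressions(table)

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            build_cohort([("dup", BaseCounts(1, 1, 1, 1)), ("dup", BaseCounts(2, 2, 2, 2))])

    def test_unprofilable_genome_named_in_error(self):
        with pytest.raises(ValueError, match="allN"):
            build_cohort([("allN", BaseCounts(0, 0, 0, 0, n_ambiguous=5))])


class TestFitRegression:
    def test_perfect_line(self):
        fit = fit_regression([0, 1, 2], [0, 1, 2])
        assert (fit.slope, fit.intercept, fit.r_squared) == (1.0, 0.0, 1.0)

    def test_constant_response_flags_r_squared_undefined(self):
        fit = fit_regression([0, 1, 2], [1, 1, 1])
        assert fit.slope == 0.0
        assert fit.intercept == 1.0
        assert fit.r_squared is None

    def test_hand_computed_ols(self):
        # Sxy=2, Sxx=2, SStot=8/3, SSres=2/3
        fit = fit_regression([0, 1, 2], [0, 2, 2])
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1 / 3, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("x, y", [([1], [2]), ([3, 3, 3], [1, 2, 3])])
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            fit_regression(x, y)

    def test_matches_statsmodels_on_random_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 40)
        y = 0.3 + 0.9 * x + rng.normal(0, 0.05, 40)
        fit = fit_regression(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_agrees_with_brute_force_grid(self):
        """OLS minimizes SSres: a grid around the fit finds nothing better."""
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 15)
        y = rng.uniform(0, 1, 15)
        fit = fit_regression(x, y)

        def ss_res(a, b):
            return float(np.sum((y - (a + b * x)) ** 2))

        best = ss_res(fit.intercept, fit.slope)
        for da in np.linspace(-0.01, 0.01, 21):
            for db in np.linspace(-0.01, 0.01, 21):
                assert ss_res(fit.intercept + da, fit.slope + db) >= best - 1e-12


class TestPanelRegressions:
    def test_eight_panels_with_labels(self):
        panels = panel_regressions(_designed_cohort([0.3, 0.4, 0.5, 0.6]))
        assert len(panels) == 8
        assert [p.y_label for p in panels[:4]] == ["p_t", "p_c", "p_r - p_y", "p_r"]
        assert [p.x_label for p in panels[4:]] == [f"est_p_{b}" for b in "atgc"]
        assert [p.y_label for p in panels[4:]] == [f"obs_p_{b}" for b in "atgc"]

    def test_exact_mode_cohort_forces_flat_purine_panel(self):
        """Exact-count design at r=0.5 pins p_r, so the p_r vs p_s panel has
        slope ~0 and intercept ~0.5 up to the 2/length apportionment bound."""
        table = _designed_cohort(np.linspace(0.25, 0.75, 8), length=1000)
        panel = panel_regressions(table)[3]
        assert abs(panel.slope) < 0.02
        assert panel.intercept == pytest.approx(0.5, abs=0.01)

    def test_factorizing_cohort_gives_identity_fits(self):
        # every genome's counts factorize (n_g·n_t = n_a·n_c) → estimates
        # equal observations and all four obs-vs-est panels are y = x
        genomes = [
            ("g1", BaseCounts(9, 9, 1, 1)),
            ("g2", BaseCounts(4, 4, 4, 4)),
            ("g3", BaseCounts(1, 4, 1, 4)),
        ]
        for panel in panel_regressions(build_cohort(genomes))[4:]:
            assert panel.slope == pytest.approx(1.0, abs=1e-9)
            assert panel.intercept == pytest.approx(0.0, abs=1e-9)
            assert panel.r_squared == pytest.approx(1.0, abs=1e-12)


class TestRankOutliers:
    def test_published_outlier_ranks_first(self, tmp_path):
        path = tmp_path / "profiles.tsv"
        path.write_text(
            "genome_id\tp_a\tp_t\tp_g\tp_c\n"
            "S_cerevisiae\t0.3098\t0.3087\t0.1906\t0.1909\n"
            "Ca_Chazhemtobacterium\t0.2787\t0.2733\t0.1497\t0.2983\n"
        )
        ranked = rank_outliers(read_composition_table(path), top_k=2)
        assert ranked[0][0] == "Ca_Chazhemtobacterium"
        assert ranked[0][1] == pytest.approx(0.1486, abs=1e-12)
        assert ranked[1][1] == pytest.approx(0.0011, abs=1e-12)

    def test_ties_break_by_id(self):
        table = build_cohort([("b", BaseCounts(5, 5, 5, 5)), ("a", BaseCounts(5, 5, 5, 5))])
        assert [g for g, _ in rank_outliers(table)] == ["a", "b"]

    def test_top_k_truncates_and_validates(self):
        table = _designed_cohort([0.3, 0.5])
        assert len(rank_outliers(table, top_k=1)) == 1
        assert len(rank_outliers(table, top_k=99)) == 2
        with pytest.raises(ValueError):
            rank_outliers(table, top_k=0)


class TestReadCompositionTable:
    def test_counts_table_populates_contingency_test(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "genome_id\tn_a\tn_t\tn_g\tn_c\ng1\t30\t10\t10\t30\ng2\t9\t9\t1\t1\n"
        )
        table = read_composition_table(path)
        assert table.rows[0].report.chi2 == pytest.approx(20.0)
        assert table.rows[1].report.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_proportions_table_flags_chi2_unavailable(self, tmp_path):
        path = tmp_path / "props.tsv"
        path.write_text("genome_id\tp_a\tp_t\tp_g\tp_c\ng1\t0.3\t0.3\t0.2\t0.2\n")
        table = read_composition_table(path)
        assert table.rows[0].report.chi2 is None

    def test_percentages_auto_detected(self, tmp_path):
        path = tmp_path / "pct.tsv"
        path.write_text("genome_id\tp_a\tp_t\tp_g\tp_c\ng1\t27.87\t27.33\t14.97\t29.83\n")
        table = read_composition_table(path)
        assert table.rows[0].profile.p_a == pytest.approx(0.2787)

    def test_bad_sum_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\tp_a\tp_t\tp_g\tp_c\nbadrow\t0.3\t0.3\t0.2\t0.1\n")
        with pytest.raises(ValueError, match="badrow"):
            read_composition_table(path)

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("genome_id\tp_a\tp_t\ng1\t0.5\t0.5\n")
        with pytest.raises(ValueError, match="p_g"):
            read_composition_table(path)

    def test_cohort_tsv_round_trip(self, tmp_path):
        table = _designed_cohort([0.3, 0.6])
        out = tmp_path / "cohort.tsv"
        write_cohort_tsv(table, out, decimals=6)
        import pandas as pd

        frame = pd.read_csv(out, sep="\t")
        assert list(frame["genome_id"]) == ["g000", "g001"]
        assert "chi2" in frame.columns
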