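"""Community function: summary tests, ANOVA, cell geometry, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import lvcoex as lx
from lvcoex.community import (
    GroupSummary,
    cell_volume_esd,
    cell_volume_prolate,
    function_table,
    one_way_anova,
    spectrum_biovolume,
    summary_ttest,
)

PARAMECIUM = GroupSummary("paramecium", 8.56e4, 2.96e3, 86)
COLPIDIUM = GroupSummary("colpidium", 5.04e4, 1.82e3, 81)


class TestSummaryTTest:
    @pytest.mark.parametrize("mode", ["pooled", "welch"])
    def test_ciliate_cell_volume_contrast(self, mode):
        """The two ciliates' published cell-volume summaries, read as SEs,
        give t near 10; the SD reading would give t near 93."""
        t, df, p = summary_ttest(PARAMECIUM, COLPIDIUM, mode=mode, dispersion_is="se")
        assert t == pytest.approx(10.04, rel=0.02)
        assert p < 1e-15
        t_sd, _, _ = summary_ttest(PARAMECIUM, COLPIDIUM, mode=mode, dispersion_is="sd")
        assert t_sd > 80

    def test_equal_means_zero_t(self):
        g = GroupSummary("a", 1.0, 0.5, 10)
        h = GroupSummary("b", 1.0, 0.7, 12)
        t, _, p = summary_ttest(g, h)
        assert (t, p) == (0.0, 1.0)

    def test_unpooled_unit_se_formula(self):
        g = GroupSummary("a", 1.0, 1.0, 10_000)
        h = GroupSummary("b", 0.0, 1.0, 10_000)
        t, _, _ = summary_ttest(g, h, mode="welch", dispersion_is="se")
        assert t == pytest.approx(1 / np.sqrt(2), rel=1e-6)

    def test_matches_raw_data_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(3, 1, 40), rng.normal(2.5, 1.4, 35)
        gx = GroupSummary("x", x.mean(), x.std(ddof=1), x.size)
        gy = GroupSummary("y", y.mean(), y.std(ddof=1), y.size)
        for mode, equal_var in (("pooled", True), ("welch", False)):
            t, _, p = summary_ttest(gx, gy, mode=mode, dispersion_is="sd")
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_df_satterthwaite(self):
        t, df, _ = summary_ttest(PARAMECIUM, COLPIDIUM, mode="welch")
        v1 = PARAMECIUM.dispersion**2
        v2 = COLPIDIUM.dispersion**2
        expected = (v1 + v2) ** 2 / (v1**2 / 85 + v2**2 / 80)
        assert df == pytest.approx(expected)

    def test_degenerate_zero_dispersion_equal_means(self):
        g = GroupSummary("a", 1.0, 0.0, 5)
        with pytest.raises(ValueError, match="undefined"):
            summary_ttest(g, g)


class TestAnova:
    def test_identical_groups(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (f, df1, df2, p) == (0.0, 2.0, 6.0, 1.0)

    def test_hand_computed_example(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5)
        assert (df1, df2) == (1.0, 4.0)

    def test_two_groups_f_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.5, 2.2], [2.0, 3.1, 4.0, 2.9]
        f, _, _, p_f = one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [3]])


class TestCellGeometry:
    def test_prolate_equals_sphere_when_round(self):
        d = 7.3
        assert cell_volume_prolate(d, d) == pytest.approx(cell_volume_esd(d))

    def test_prolate_direct_value(self):
        assert cell_volume_prolate(10, 5) == pytest.approx(np.pi / 6 * 10 * 25)
        assert cell_volume_prolate(10, 5) == pytest.approx(130.8997, abs=1e-3)

    @pytest.mark.parametrize("l, w", [(0, 1), (1, 0), (2, 3)])
    def test_prolate_invalid_dimensions(self, l, w):
        with pytest.raises(ValueError):
            cell_volume_prolate(l, w)

    def test_esd_values(self):
        assert cell_volume_esd(2) == pytest.approx(4 * np.pi / 3)
        assert cell_volume_esd(1) == pytest.approx(np.pi / 6)
        with pytest.raises(ValueError):
            cell_volume_esd(0)

    @given(st.floats(1.0, 50.0), st.floats(0.1, 1.0), st.floats(1.001, 2.0))
    def test_prolate_monotone(self, length, width_frac, grow):
        w = length * width_frac
        v = cell_volume_prolate(length, w)
        assert cell_volume_prolate(length * grow, w) > v
        if w * grow <= length:
            assert cell_volume_prolate(length, w * grow) > v

    def test_spectrum_biovolume_linearity(self):
        hist = pd.Series({2.0: 1e6})
        assert spectrum_biovolume(hist) == pytest.approx(4 * np.pi / 3 * 1e6)
        double = pd.Series({2.0: 2e6})
        assert spectrum_biovolume(double) == pytest.approx(2 * spectrum_biovolume(hist))


class TestFunctionTable:
    def test_resource_rows_excluded(self, noisy_table):
        levels, _ = function_table(noisy_table)
        assert "resource_alone" not in set(levels.treatment)

    def test_detects_doubled_biovolume(self, noisy_table):
        doubled = noisy_table.copy()
        mask = doubled.treatment == "both"
        doubled.loc[mask, "biovolume_um3"] *= 4
        _, contrasts = function_table(doubled)
        sub = contrasts[(contrasts.treatment_a == "both") | (contrasts.treatment_b == "both")]
        assert (sub.p < 0.05).all()

    def test_neutral_null_rarely_significant(self):
        """Two-species communities built from ecologically equivalent species
        show no detectable gain or loss of total biovolume vs monocultures."""
        design = lx.ExperimentDesign(
            treatments=("species1_alone", "species2_alone", "both")
        )
        lv = lx.neutral_lv_params()
        quiet = 0
        n_runs = 100
        for i in range(n_runs):
            tab = lx.generate_experiment(design, lx.GeneratorParams(lv=lv, seed=40_000 + i))
            _, contrasts = function_table(tab)
            sub = contrasts[
                (contrasts.treatment_a == "both") | (contrasts.treatment_b == "both")
            ]
            quiet += (sub.p > 0.05).all()
        assert quiet >= 0.88 * n_runs

    def test_empty_window_rejected(self, noisy_table):
        with pytest.raises(ValueError):
            function_table(noisy_table, window=(40, 50))

    def test_flux_passthrough_contrast(self, noisy_table):
        flux = pd.DataFrame(
            {
                "treatment": ["species1_alone"] * 6 + ["both"] * 6,
                "replicate": list(range(1, 7)) * 2,
                "flux": [1.0, 1.1, 0.9, 1.05, 0.98, 1.02] * 2,
            }
        )
        _, contrasts = function_table(noisy_table, flux=flux)
        fluxrows = contrasts[contrasts.variable == "flux"]
        assert len(fluxrows) == 1
        assert fluxrows.p.iloc[0] > 0.9
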