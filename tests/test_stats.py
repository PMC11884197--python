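import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from subkin import (
    OutcomeModel,
    aggregate,
    mixed_anova,
    posthoc_holm,
    slope_test,
    ttest_power_n,
)

FREQS = [0.25, 0.3125, 0.375, 0.4375, 0.5, 0.5625]


def _cohort_table(n_per_group=10, group_shift=(0.0, 0.0, 0.0), freq_slope=-2.0,
                  noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in zip(("PwP", "OC", "YC"), group_shift):
        for i in range(n_per_group):
            base = 2.0 + shift + rng.normal(0, 0.4)
            for f in FREQS:
                rows.append(
                    dict(
                        participant_id=f"{g}{i}",
                        group=g,
                        frequency=f,
                        y=base + freq_slope * f + rng.normal(0, noise),
                    )
                )
    return pd.DataFrame(rows)


def mixed_anova_reference(table, dv, within="frequency"):
    """Independent sums-of-squares oracle for the balanced mixed design."""
    wide = table.pivot_table(index=["group", "participant_id"], columns=within, values=dv)
    y = wide.to_numpy()
    groups = wide.index.get_level_values("group")
    glabels = groups.unique()
    a, b = len(glabels), y.shape[1]
    n = y.shape[0] // a
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[groups == g].mean() for g in glabels])
    level_means = y.mean(axis=0)
    ss_group = n * b * ((group_means - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_level = a * n * ((level_means - grand) ** 2).sum()
    cell = np.vstack([y[groups == g].mean(axis=0) for g in glabels])
    ss_inter = n * (
        (cell - group_means[:, None] - level_means[None, :] + grand) ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_within - ss_level - ss_inter
    f_group = (ss_group / (a - 1)) / (ss_subj_within / (a * (n - 1)))
    f_level = (ss_level / (b - 1)) / (ss_err / ((b - 1) * a * (n - 1)))
    f_inter = (ss_inter / ((a - 1) * (b - 1))) / (ss_err / ((b - 1) * a * (n - 1)))
    return f_group, f_level, f_inter


class TestAggregate:
    def test_cell_means(self):
        df = pd.DataFrame(
            dict(
                participant_id=["p", "p"],
                group=["OC", "OC"],
                trial_index=[0, 1],
                frequency=[0.25, 0.25],
                y=[0.4, 0.6],
            )
        )
        table, missing = aggregate(df)
        assert len(table) == 1 and table["y"].iloc[0] == pytest.approx(0.5)
        assert len(missing) == 0

    def test_complete_design_size(self):
        table, missing = aggregate(_cohort_table(n_per_group=4))
        assert len(table) == 3 * 4 * 6
        assert missing.empty

    def test_missing_cell_reported(self):
        df = _cohort_table(n_per_group=3)
        df = df[~((df.participant_id == "OC0") & (df.frequency == 0.25))]
        with pytest.warns(UserWarning, match="missing"):
            table, missing = aggregate(df)
        assert len(missing) == 1
        assert missing["participant_id"].iloc[0] == "OC0"


class TestSlopeTest:
    def test_recovers_true_slope(self):
        table, _ = aggregate(_cohort_table(freq_slope=-2.0, noise=0.1, seed=1))
        res = slope_test(table, "y")
        half_ci = 2 * res.slopes["slope"].std() / np.sqrt(len(res.slopes))
        assert res.mean_slope == pytest.approx(-2.0, abs=max(half_ci, 0.2))
        assert res.p < 1e-6 and res.t < 0

    def test_degenerate_identical_slopes(self):
        rows = [
            dict(participant_id=f"p{i}", group="OC", frequency=f, y=-1.0 * f)
            for i in range(5)
            for f in FREQS
        ]
        res = slope_test(pd.DataFrame(rows), "y")
        assert res.mean_slope == pytest.approx(-1.0)
        assert np.isinf(res.t) and np.isnan(res.d)

    def test_single_level_rejected(self):
        df = pd.DataFrame(
            dict(participant_id=["p"], group=["OC"], frequency=[0.25], y=[1.0])
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            slope_test(df, "y")

    def test_group_slope_difference_detected(self):
        # steeper PwP slope against OC, as in the dX-vs-frequency analysis
        rng = np.random.default_rng(3)
        rows = []
        for g, slope_mean, slope_sd in (("PwP", 1.16, 0.73), ("OC", 0.75, 0.49)):
            for i in range(60):
                s = rng.normal(slope_mean, slope_sd)
                for f in FREQS:
                    rows.append(
                        dict(participant_id=f"{g}{i}", group=g, frequency=f,
                             y=s * f + rng.normal(0, 0.02))
                    )
        res = slope_test(pd.DataFrame(rows), "y")
        s = res.slopes
        t, p = sps.ttest_ind(
            s.loc[s.group == "PwP", "slope"], s.loc[s.group == "OC", "slope"]
        )
        assert p < 0.05 and t > 0


class TestMixedAnova:
    def test_f_values_match_reference_implementation(self):
        table, _ = aggregate(_cohort_table(group_shift=(0.5, 0.0, -0.2), seed=2))
        aov = mixed_anova(table, "y").set_index("effect")
        fg, fl, fi = mixed_anova_reference(table, "y")
        assert aov.loc["group", "F"] == pytest.approx(fg, abs=1e-6)
        assert aov.loc["frequency", "F"] == pytest.approx(fl, abs=1e-6)
        assert aov.loc["interaction", "F"] == pytest.approx(fi, abs=1e-6)

    def test_pure_frequency_effect(self):
        table, _ = aggregate(_cohort_table(freq_slope=-2.0, noise=0.2, seed=4))
        aov = mixed_anova(table, "y").set_index("effect")
        assert aov.loc["frequency", "p"] < 1e-6
        assert aov.loc["group", "p"] > 0.01

    def test_incomplete_design_rejected(self):
        df = _cohort_table(n_per_group=3)
        df = df[~((df.participant_id == "OC0") & (df.frequency == 0.25))]
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(df, "y")

    def test_gg_correction_applied_when_sphericity_violated(self):
        # heteroscedastic random-walk within-factor structure violates
        # sphericity, so the within dfs must shrink (eps < 1)
        rng = np.random.default_rng(5)
        rows = []
        for g in ("PwP", "OC", "YC"):
            for i in range(12):
                walk = 0.0
                base = rng.normal()
                for k, f in enumerate(FREQS):
                    walk += rng.normal(0, 0.05 * (k + 1) ** 2)
                    rows.append(
                        dict(participant_id=f"{g}{i}", group=g, frequency=f,
                             y=base + walk)
                    )
        aov = mixed_anova(pd.DataFrame(rows), "y")
        assert not aov.attrs["mauchly_ok"]
        freq = aov.set_index("effect").loc["frequency"]
        assert freq["gg_corrected"] and freq["df1"] < 5.0


class TestPosthocHolm:
    def test_hand_computed_holm_sequence(self):
        raw = np.array([0.01, 0.02, 0.60])
        adj = multipletests(raw, method="holm")[1]
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.60], atol=1e-12)

    def test_identical_groups_not_significant(self):
        table, _ = aggregate(_cohort_table(seed=6))
        ph = posthoc_holm(table, "y")
        assert (ph["p_holm"] > 0.05).all()

    def test_shifted_group_detected_with_effect_size(self):
        table, _ = aggregate(
            _cohort_table(group_shift=(1.0, 0.0, 0.0), n_per_group=15, seed=7)
        )
        ph = posthoc_holm(table, "y")
        pwp_rows = ph[(ph.group1 == "PwP") | (ph.group2 == "PwP")]
        other = ph[(ph.group1 != "PwP") & (ph.group2 != "PwP")]
        assert (pwp_rows["p_holm"] < 0.01).all()
        assert (other["p_holm"] > 0.05).all()
        assert pwp_rows["d"].abs().min() > 0.8

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
    def test_holm_is_monotone_and_never_below_raw(self, raws):
        raw = np.array(raws)
        adj = multipletests(raw, method="holm")[1]
        assert np.all(adj >= raw - 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPower:
    def test_published_sample_size_reproduced(self):
        assert ttest_power_n(66.0, 2.9, 69.5, 4.2, power=0.95, alpha=0.05) == 29

    def test_extreme_effect_needs_minimal_n(self):
        assert ttest_power_n(0.0, 1.0, 10.0, 1.0, power=0.8) <= 3

    def test_unit_effect_at_80_power(self):
        # classic benchmark: d = 1.0, power 0.8, alpha .05 -> 17 per group
        assert ttest_power_n(0.0, 1.0, 1.0, 1.0, power=0.8, alpha=0.05) == 17

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="zero effect"):
            ttest_power_n(1.0, 1.0, 1.0, 1.0)

    def test_monotone_in_effect_and_sd(self):
        base = ttest_power_n(0.0, 1.0, 0.8, 1.0)
        assert ttest_power_n(0.0, 1.0, 1.2, 1.0) <= base
        assert ttest_power_n(0.0, 1.5, 0.8, 1.5) >= base


class TestOutcomeModel:
    def test_fit_bundles_all_analyses(self):
        df = _cohort_table(group_shift=(0.6, 0.0, 0.0), seed=8)
        df["trial_index"] = 0
        res = OutcomeModel.from_dataframe(df, "y").fit()
        assert set(res.anova["effect"]) == {"group", "frequency", "interaction"}
        assert len(res.posthoc) == 3
        assert res.slopes.mean_slope < 0
        text = res.summary()
        assert "Mixed-design ANOVA" in text and "Holm" in text

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            OutcomeModel(_cohort_table(), "nope")
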