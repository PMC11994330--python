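"""Group inference: multiplicity oracles, contrast oracle, robustness, nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetalsurf.inference import (
    bh_q,
    delta_z_group_test,
    fit_group_model,
    holm_adjust,
    subtype_contrasts,
)
from fetalsurf.normative import delta_z_table, fit_all_charts, score_table
from fetalsurf.simulate import simulate_cohort


class TestHolm:
    def test_hand_evaluated_step_down(self):
        # sorted p: 0.01, 0.04 -> 2*0.01=0.02, max(0.02, 1*0.04)=0.04
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        # classic three-value example
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_identity_and_empty(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)
        assert holm_adjust([]).size == 0

    def test_dominance_and_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 25)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestBH:
    def test_hand_evaluated_step_up(self):
        # q_i = min over j>=i of p_(j) * m / j = (0.03, 0.03, 0.03)
        np.testing.assert_allclose(bh_q([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identical_ps_share_q(self):
        q = bh_q([0.04, 0.04, 0.04])
        assert np.unique(q).size == 1

    def test_dominance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 30)
        assert (bh_q(p) >= p - 1e-15).all()


def _balanced_z_table(rng, n_per_group=20, regions=("L_a", "L_b", "L_c"),
                      shift=None):
    """One scan per subject, identical GA values in both groups."""
    rows = []
    ga = np.linspace(30, 38, n_per_group)
    for region in regions:
        for g, grp in enumerate(("Control", "CHD")):
            z = rng.normal(0, 1, n_per_group)
            if shift and grp == "CHD":
                z = z + shift.get(region, 0.0)
            for i in range(n_per_group):
                rows.append(
                    (f"{grp}{i}_s1", f"{grp}{i}", grp, "none", 1, ga[i],
                     region, "surface_area", z[i])
                )
    return pd.DataFrame(
        rows,
        columns=["scan_id", "subject_id", "group", "chd_subtype",
                 "scan_index", "ga_weeks", "region", "metric", "z"],
    )


class TestGroupModelOracle:
    def test_contrast_equals_group_mean_difference_and_t_test(self):
        """Robustness off, balanced GA: factorial contrast == mean diff,
        p == two-sample (pooled) t-test p."""
        rng = np.random.default_rng(2)
        z = _balanced_z_table(rng)
        res = fit_group_model(z, stratum="all", robust=False, adjust_ga=False,
                              family_size=None)
        for _, row in res.iterrows():
            d = z[z.region == row.region]
            chd = d[d.group == "CHD"].z
            ctl = d[d.group == "Control"].z
            assert row.delta_z_group == pytest.approx(chd.mean() - ctl.mean(),
                                                      abs=1e-8)
            t = stats.ttest_ind(chd, ctl, equal_var=True)
            assert row.p == pytest.approx(t.pvalue, abs=1e-6)

    def test_ga_adjustment_with_matched_ga_preserves_contrast(self):
        rng = np.random.default_rng(3)
        z = _balanced_z_table(rng)
        res_adj = fit_group_model(z, stratum="all", robust=False, adjust_ga=True,
                                  family_size=None)
        res_raw = fit_group_model(z, stratum="all", robust=False, adjust_ga=False,
                                  family_size=None)
        np.testing.assert_allclose(
            res_adj.delta_z_group, res_raw.delta_z_group, atol=1e-8
        )

    def test_outlier_influence_bounded(self):
        """One |z|=10 outlier moves the robust contrast far less than OLS."""
        rng = np.random.default_rng(4)
        z = _balanced_z_table(rng, regions=("L_a",))
        poisoned = z.copy()
        idx = poisoned.index[poisoned.group == "CHD"][0]
        poisoned.loc[idx, "z"] = 10.0

        def contrast(table, robust):
            return fit_group_model(table, robust=robust, adjust_ga=False,
                                   family_size=None).delta_z_group[0]

        ols_change = contrast(poisoned, False) - contrast(z, False)
        rob_change = contrast(poisoned, True) - contrast(z, True)
        assert abs(rob_change) < 0.25 * abs(ols_change)

    def test_untestable_region_flagged(self):
        rng = np.random.default_rng(5)
        z = _balanced_z_table(rng, regions=("L_a", "L_b"))
        z = z[~((z.region == "L_b") & (z.group == "CHD"))]
        res = fit_group_model(z, robust=False, family_size=None)
        row = res[res.region == "L_b"].iloc[0]
        assert not row.testable
        assert np.isnan(row.delta_z_group)

    def test_family_size_padding_scales_adjustment(self):
        rng = np.random.default_rng(6)
        z = _balanced_z_table(rng, regions=("L_a",), shift={"L_a": -2.0})
        res30 = fit_group_model(z, robust=False, family_size=30)
        res1 = fit_group_model(z, robust=False, family_size=None)
        p = res1.p[0]
        assert res30.p_holm[0] == pytest.approx(min(30 * p, 1.0), rel=1e-9)


class TestDeltaZModel:
    def _dz_table(self, rng, shift=0.0, const_dga=False):
        rows = []
        for g, grp in enumerate(("Control", "CHD")):
            for i in range(25):
                dga = 8.0 if const_dga else rng.uniform(5, 12)
                dz = rng.normal(0, 1) + (shift if grp == "CHD" else 0.0)
                rows.append((f"{grp}{i}", "L_a", "surface_area", dz, dga, grp))
        return pd.DataFrame(
            rows, columns=["subject_id", "region", "metric", "delta_z",
                           "delta_ga", "group"]
        )

    def test_constant_delta_ga_equivalent_to_unadjusted(self):
        rng = np.random.default_rng(7)
        d = self._dz_table(rng, const_dga=True)
        res = delta_z_group_test(d, robust=False, family_size=None)
        chd = d[d.group == "CHD"].delta_z
        ctl = d[d.group == "Control"].delta_z
        assert res.delta_z_group[0] == pytest.approx(chd.mean() - ctl.mean(),
                                                     abs=1e-8)

    def test_deficit_sign_recovered(self):
        rng = np.random.default_rng(8)
        d = self._dz_table(rng, shift=-1.5)
        res = delta_z_group_test(d, robust=False, family_size=None)
        assert res.delta_z_group[0] < 0
        assert res.p[0] < 0.01


class TestPipelineCalibration:
    def test_null_familywise_error_controlled(self, small_cohort_config):
        """Full pipeline, no deficit: Holm-significant sets are rare."""
        cfg = small_cohort_config.with_(affected_regions=(), deficit_slope=0.0)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            scans, metrics, _ = simulate_cohort(cfg.with_(seed=5000 + rep))
            charts = fit_all_charts(metrics, scans[scans.group == "Control"])
            z = score_table(charts, metrics, scans)
            res = fit_group_model(z, stratum="scan2", family_size=None)
            hits += int((res.p_holm < 0.05).any())
        # expect <= 5% family-wise; allow 2 MC standard errors
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_deficit_detection_localised(self, small_cohort_config):
        """Injected deficit regions are detected; unaffected regions are not."""
        detected, false_pos = 0, 0
        n_rep = 3
        n_aff = len(small_cohort_config.affected_regions)
        for rep in range(n_rep):
            scans, metrics, _ = simulate_cohort(
                small_cohort_config.with_(seed=700 + rep)
            )
            charts = fit_all_charts(metrics, scans[scans.group == "Control"])
            z = score_table(charts, metrics, scans)
            res = fit_group_model(z, stratum="ga_ge_30", family_size=None)
            sig = set(res[res.p_holm < 0.05].region)
            aff = set(small_cohort_config.affected_regions)
            detected += len(sig & aff)
            false_pos += len(sig - aff)
        assert detected / (n_rep * n_aff) >= 0.8
        assert false_pos <= 1

    def test_subtype_contrasts_run_and_share_sign(self, small_cohort_config):
        scans, metrics, _ = simulate_cohort(small_cohort_config.with_(seed=31))
        charts = fit_all_charts(metrics, scans[scans.group == "Control"])
        z = score_table(charts, metrics, scans)
        res = subtype_contrasts(z, stratum="ga_ge_30", family_size=None)
        assert set(res.contrast.str.split(" ").str[0]) == {"HLHS_TGA", "Other"}
        aff = res[res.region.isin(small_cohort_config.affected_regions)]
        vs_ctl = aff[aff.contrast.str.contains("vs Control")]
        assert (vs_ctl.delta_z_group < 0).mean() > 0.8
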