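"""Outcome GLMs: stepwise AIC selection, slope recovery, epoch localisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetalsurf.outcome import (
    DegenerateDesignError,
    fit_glm1,
    fit_glm2,
    fit_outcome_models,
    stepwise_aic,
)


def _outcome_frame(rng, n=89, ga_coef=1.0, edu_coef=5.0, noise=8.0,
                   extra_noise_covariates=0):
    d = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "ga_at_birth": rng.normal(39, 1.5, n),
            "maternal_education": rng.integers(0, 2, n).astype(float),
            "birth_weight": rng.normal(3300, 400, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "maternal_age": rng.normal(32, 4, n),
        }
    )
    for j in range(extra_noise_covariates):
        d[f"noise{j}"] = rng.normal(size=n)
    d["score"] = (
        100
        + ga_coef * (d.ga_at_birth - 39)
        + edu_coef * d.maternal_education
        + rng.normal(0, noise, n)
    )
    return d


CANDIDATES = ["ga_at_birth", "maternal_education", "birth_weight", "sex",
              "maternal_age"]


class TestStepwiseAIC:
    def test_recovers_true_covariates(self):
        """GA at birth + maternal education drive the outcome; both are
        selected in at least 90% of replicates, mirroring the screened
        covariate set used by the outcome models."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            d = _outcome_frame(rng, noise=5.0)
            selected, _ = stepwise_aic(d, "score", CANDIDATES)
            hits += int({"ga_at_birth", "maternal_education"} <= set(selected))
        assert hits / n_rep >= 0.9

    def test_pure_noise_selects_little(self):
        sizes = []
        for rep in range(40):
            rng = np.random.default_rng(200 + rep)
            d = _outcome_frame(rng, ga_coef=0.0, edu_coef=0.0, noise=10.0)
            selected, _ = stepwise_aic(d, "score", CANDIDATES)
            sizes.append(len(selected))
        assert np.mean(sizes) <= 1.0

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(9)
        d = _outcome_frame(rng)
        s1, t1 = stepwise_aic(d, "score", CANDIDATES)
        s2, t2 = stepwise_aic(d, "score", CANDIDATES)
        assert s1 == s2 and t1 == t2

    def test_constant_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        d = _outcome_frame(rng)
        d["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            selected, _ = stepwise_aic(d, "score", CANDIDATES + ["flat"])
        assert "flat" not in selected

    def test_aic_trace_monotone_decreasing(self):
        rng = np.random.default_rng(11)
        d = _outcome_frame(rng)
        _, trace = stepwise_aic(d, "score", CANDIDATES)
        aics = [a for _, a in trace]
        assert (np.diff(aics) < 0).all()


def _z_outcome_tables(rng, n_chd=51, n_ctl=38, slope=5.0, noise=8.0,
                      region="L_precentral", couple="post"):
    """Subjects with one pre-30 and one post-30 scan; outcome coupled to the
    chosen epoch's z in the CHD group only."""
    rows, orows = [], []
    for grp, n in (("CHD", n_chd), ("Control", n_ctl)):
        for i in range(n):
            sid = f"{grp}{i}"
            z_pre = rng.normal(0, 1)
            z_post = rng.normal(-1.0 if grp == "CHD" else 0.0, 1)
            rows.append((f"{sid}_s1", sid, grp, "none", 1, 26.0, region,
                         "surface_area", z_pre))
            rows.append((f"{sid}_s2", sid, grp, "none", 2, 35.0, region,
                         "surface_area", z_post))
            zc = z_post if couple == "post" else z_pre
            ga_b = rng.normal(39, 1.5)
            edu = float(rng.integers(0, 2))
            score = (
                100 + (slope * zc if grp == "CHD" else 0.0)
                + 1.0 * (ga_b - 39) + 5.0 * edu + rng.normal(0, noise)
            )
            orows.append((sid, grp, score, score, score, ga_b, edu))
    z = pd.DataFrame(rows, columns=["scan_id", "subject_id", "group",
                                    "chd_subtype", "scan_index", "ga_weeks",
                                    "region", "metric", "z"])
    out = pd.DataFrame(orows, columns=["subject_id", "group", "cognitive",
                                       "language", "motor", "ga_at_birth",
                                       "maternal_education"])
    return z, out


class TestGLM1:
    def test_chd_slope_recovered_control_slope_null(self):
        rng = np.random.default_rng(12)
        z, out = _z_outcome_tables(rng, slope=5.0)
        r = fit_glm1(z, out, "L_precentral", "surface_area", "motor")
        assert r.beta - 1.96 * r.se < 5.0 < r.beta + 1.96 * r.se
        # control slope: z main effect alone
        import statsmodels.api as sm

        d = z[z.scan_index == 2].merge(out, on="subject_id")
        d["chd"] = (d.group_x == "CHD").astype(float)
        d["z_chd"] = d.z * d.chd
        X = sm.add_constant(d[["z", "chd", "z_chd", "ga_at_birth",
                               "maternal_education"]].to_numpy())
        res = sm.OLS(d.motor.to_numpy(), X).fit()
        ci = res.conf_int()[1]
        assert ci[0] < 0.0 < ci[1]

    def test_degenerate_z_rejected(self):
        rng = np.random.default_rng(13)
        z, out = _z_outcome_tables(rng)
        z["z"] = 1.0
        with pytest.raises(DegenerateDesignError, match="variance"):
            fit_glm1(z, out, "L_precentral", "surface_area", "motor")

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(14)
        z, out = _z_outcome_tables(rng, n_chd=4, n_ctl=4)
        with pytest.raises(DegenerateDesignError, match="too small"):
            fit_glm1(z, out, "L_precentral", "surface_area", "motor")

    def test_null_coupling_calibrated_after_fdr(self):
        """slope 0: ~5% raw p < .05 across regions, none after FDR."""
        rng = np.random.default_rng(15)
        regions = [f"L_r{i}" for i in range(30)]
        frames = []
        for reg in regions:
            zi, out = _z_outcome_tables(rng, slope=0.0, region=reg)
            frames.append(zi)
        z = pd.concat(frames, ignore_index=True)
        res = fit_outcome_models(z, out, model="GLM1", domains=("motor",),
                                 family_size=60)
        assert (res.p < 0.05).mean() < 0.2
        assert (res.q < 0.05).sum() == 0


class TestGLM2:
    def test_post30_coupling_localised(self):
        """Outcome coupled only post-30: post slope significant, pre covers 0."""
        hits_post, hits_pre_null = 0, 0
        n_rep = 25
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            z, out = _z_outcome_tables(rng, slope=5.0, couple="post")
            r = fit_glm2(z, out, "L_precentral", "surface_area", "motor")
            hits_post += int(r.p_post30 < 0.05)
            hits_pre_null += int(r.p_pre30 >= 0.05)
        assert hits_post / n_rep >= 0.8
        assert hits_pre_null / n_rep >= 0.8

    def test_equal_coupling_interaction_covers_zero(self):
        rng = np.random.default_rng(16)
        rows_z, rows_o = [], []
        # same slope in both epochs: pre and post slopes agree
        z, out = _z_outcome_tables(rng, slope=4.0, couple="post")
        # rebuild with coupling to both epochs equally
        z2 = z.copy()
        out2 = out.copy()
        merged = z.pivot_table(index="subject_id", columns="scan_index",
                               values="z").rename(columns={1: "z1", 2: "z2"})
        out2 = out2.merge(merged, on="subject_id")
        chd = (out2.group == "CHD").astype(float)
        rng2 = np.random.default_rng(17)
        out2["motor"] = (100 + 4.0 * chd * (out2.z1 + out2.z2) / 2
                         + rng2.normal(0, 6.0, len(out2)))
        r = fit_glm2(z2, out2[["subject_id", "group", "cognitive", "language",
                               "motor", "ga_at_birth", "maternal_education"]],
                     "L_precentral", "surface_area", "motor")
        # pre and post CHD slopes should not differ significantly
        diff = r.beta_post30 - r.beta_pre30
        assert abs(diff) < 4.0

    def test_stratified_fit_oracle(self):
        """With one scan per subject and no noise, the joint model's epoch
        slopes coincide with separately fitted per-stratum models."""
        import statsmodels.api as sm

        rng = np.random.default_rng(18)
        # exact coefficients of the joint model (no triple interaction):
        # y = 100 + 0.5 z + 2 chd + 1.5 z*chd + 1 post + 1 z*post
        rows, orows = [], []
        for grp, n in (("CHD", 40), ("Control", 30)):
            for i in range(n):
                sid = f"{grp}{i}"
                post = i % 2
                ga = 35.0 if post else 26.0
                chd = float(grp == "CHD")
                zv = rng.normal(-1.0 * chd, 1.0)
                score = (100.0 + 0.5 * zv + 2.0 * chd + 1.5 * zv * chd
                         + 1.0 * post + 1.0 * zv * post)
                rows.append((f"{sid}_s1", sid, grp, "none", 1, ga,
                             "L_precentral", "surface_area", zv))
                orows.append((sid, grp, score, score, score, 39.0, 0.0))
        z = pd.DataFrame(rows, columns=["scan_id", "subject_id", "group",
                                        "chd_subtype", "scan_index", "ga_weeks",
                                        "region", "metric", "z"])
        out = pd.DataFrame(orows, columns=["subject_id", "group", "cognitive",
                                           "language", "motor", "ga_at_birth",
                                           "maternal_education"])
        # covariates are constant and get dropped into the intercept by OLS
        out["ga_at_birth"] = out.ga_at_birth + rng.normal(0, 1e-9, len(out))
        r = fit_glm2(z, out, "L_precentral", "surface_area", "motor")
        assert r.beta_pre30 == pytest.approx(2.0, abs=1e-6)
        assert r.beta_post30 == pytest.approx(3.0, abs=1e-6)

        # brute-force per-stratum fits agree: CHD slope 0.5+1.5=2 pre,
        # 0.5+1.5+1 = 3 post
        for post_flag, expect in ((0, 2.0), (1, 3.0)):
            d = z.merge(out, on="subject_id")
            d = d[(d.ga_weeks >= 30.0) == bool(post_flag)]
            chd = (d.group_x == "CHD").astype(float).to_numpy()
            X = sm.add_constant(np.column_stack([d.z, chd, d.z * chd]))
            res = sm.OLS(d.motor.to_numpy(), X).fit()
            assert res.params[1] + res.params[3] == pytest.approx(expect, abs=1e-6)


class TestOutcomeSweep:
    def test_q_family_is_sixty_and_dominates_p(self, small_cohort_config):
        from fetalsurf.normative import fit_all_charts, score_table
        from fetalsurf.simulate import simulate_cohort

        scans, metrics, outcomes = simulate_cohort(
            small_cohort_config.with_(seed=41)
        )
        charts = fit_all_charts(metrics, scans[scans.group == "Control"])
        z = score_table(charts, metrics, scans)
        res = fit_outcome_models(z, outcomes, model="GLM1", domains=("motor",))
        ok = res.dropna(subset=["p"])
        assert (ok.q >= ok.p - 1e-12).all()
        # family padded to 60 even with 8 simulated regions
        assert (ok.q >= ok.p * 60 / 8 / 8).all()
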