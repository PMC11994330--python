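"""Region-wise group comparison of deviation scores with robust inference.

The factorial model ``Z ~ group x region`` with a per-subject random
intercept is fitted with a separate residual variance per region, which
makes the per-region group contrast (``dZ_Group``, CHD minus Control)
estimable region by region: ordinary least squares when every subject
contributes one scan to the stratum, a random-intercept mixed model
(REML) otherwise.  Outliers are handled by iterative reweighting with
Huber weights.  The per-region p-values are corrected with the Holm
step-down procedure, and Benjamini-Hochberg q-values are reported over
the same family.

Longitudinal change is compared with ``dZ ~ group + dGA`` per region
(adjusting for the between-scan GA interval), with the same multiplicity
handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

HUBER_C = 1.345
STRATA = ("all", "scan1", "scan2", "ga_lt_30", "ga_ge_30")


@dataclass(frozen=True)
class GroupTestResult:
    region: str
    metric: str
    contrast: str
    delta_z_group: float
    se: float
    p: float
    p_holm: float = np.nan
    q: float = np.nan
    n: int = 0
    testable: bool = True


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (clipped at 1, monotone).

    Ties in the sort are broken by original index (stable sort).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_q(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_stratum(z_df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Scan subsets for the group analyses.

    ``scan1`` / ``scan2`` restrict to subjects with both in-utero scans
    (the longitudinal sub-cohort), while ``ga_lt_30`` / ``ga_ge_30`` split
    every scan by gestational age, mirroring the cross-sectional analyses.
    """
    if stratum == "all":
        return z_df
    if stratum in ("scan1", "scan2"):
        per_subj = z_df.groupby("subject_id").scan_index.nunique()
        longitudinal = set(per_subj[per_subj == 2].index)
        sub = z_df[z_df.subject_id.isin(longitudinal)]
        return sub[sub.scan_index == (1 if stratum == "scan1" else 2)]
    if stratum == "ga_lt_30":
        return z_df[z_df.ga_weeks < 30.0]
    if stratum == "ga_ge_30":
        return z_df[z_df.ga_weeks >= 30.0]
    raise ValueError(f"unknown stratum {stratum!r}; choose from {STRATA}")


def _huber_weights(resid: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    scale = stats.median_abs_deviation(resid, scale="normal")
    if scale < 1e-12:
        return np.ones_like(resid)
    u = np.abs(resid) / (c * scale)
    return np.where(u <= 1.0, 1.0, 1.0 / u)


def _gls_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    subject_codes: np.ndarray,
    w: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted GLS under a per-subject random intercept with known variances.

    Marginal covariance per subject is ``sigma_e2 * diag(1/w) + sigma_u2 *
    11'``; its inverse enters via the Sherman-Morrison identity, so the
    whole estimate is a few vectorised reductions.  Returns (beta,
    cov(beta), residuals).
    """
    k = X.shape[1]
    n_sub = subject_codes.max() + 1
    a = w / sigma_e2  # diag of V^-1 before the rank-1 correction
    aX = X * a[:, None]
    xtvx = X.T @ aX
    xtvy = aX.T @ y
    sum_aX = np.zeros((n_sub, k))
    np.add.at(sum_aX, subject_codes, aX)
    sum_ay = np.bincount(subject_codes, weights=a * y, minlength=n_sub)
    sum_a = np.bincount(subject_codes, weights=a, minlength=n_sub)
    c = sigma_u2 / (1.0 + sigma_u2 * sum_a) if sigma_u2 > 0 else np.zeros(n_sub)
    xtvx -= (sum_aX * c[:, None]).T @ sum_aX
    xtvy -= sum_aX.T @ (c * sum_ay)
    bread = np.linalg.inv(xtvx)
    beta = bread @ xtvy
    resid = y - X @ beta

    # cluster-robust (by subject) sandwich covariance: tolerant to the
    # Huber reweighting and to variance-component misspecification
    aXe = aX * resid[:, None]
    score = np.zeros((n_sub, k))
    np.add.at(score, subject_codes, aXe)
    sum_ae = np.bincount(subject_codes, weights=a * resid, minlength=n_sub)
    score -= (c * sum_ae)[:, None] * sum_aX
    meat = score.T @ score
    cov = bread @ meat @ bread
    return beta, cov, resid


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, subject_codes: np.ndarray
) -> tuple[float, float]:
    """REML variance components (sigma_u2, sigma_e2) for a random intercept.

    The REML criterion is concentrated to the single variance ratio
    ``lambda = sigma_u2 / sigma_e2`` and profiled with bounded scalar
    optimisation; every evaluation uses the Sherman-Morrison identity, so
    the whole fit is O(n) per step.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    n_sub = subject_codes.max() + 1

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        sum_X = np.zeros((n_sub, p))
        np.add.at(sum_X, subject_codes, X)
        sum_y = np.bincount(subject_codes, weights=y, minlength=n_sub)
        m = np.bincount(subject_codes, minlength=n_sub).astype(float)
        c = lam / (1.0 + lam * m)
        xtvx = X.T @ X - (sum_X * c[:, None]).T @ sum_X
        xtvy = X.T @ y - sum_X.T @ (c * sum_y)
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return np.inf
        e = y - X @ beta
        sum_e = np.bincount(subject_codes, weights=e, minlength=n_sub)
        quad = e @ e - np.sum(c * sum_e**2)
        if quad <= 0:
            return np.inf
        sigma_e2 = quad / (n - p)
        logdet_v = np.log1p(lam * m).sum()
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(sigma_e2) + logdet_v + logdet_x)

    res = minimize_scalar(neg_reml, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if neg_reml(np.log(1e-10)) <= res.fun:  # boundary: no subject variance
        lam = 0.0
    sum_X = np.zeros((n_sub, p))
    np.add.at(sum_X, subject_codes, X)
    sum_y = np.bincount(subject_codes, weights=y, minlength=n_sub)
    m = np.bincount(subject_codes, minlength=n_sub).astype(float)
    c = lam / (1.0 + lam * m) if lam > 0 else np.zeros(n_sub)
    xtvx = X.T @ X - (sum_X * c[:, None]).T @ sum_X
    xtvy = X.T @ y - sum_X.T @ (c * sum_y)
    beta = np.linalg.solve(xtvx, xtvy)
    e = y - X @ beta
    sum_e = np.bincount(subject_codes, weights=e, minlength=n_sub)
    sigma_e2 = float((e @ e - np.sum(c * sum_e**2)) / (n - p))
    return lam * sigma_e2, sigma_e2


def _fit_region(
    y: np.ndarray,
    group_ind: np.ndarray,
    subjects: np.ndarray,
    covariates: np.ndarray | None = None,
    robust: bool = True,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[float, float, float, int]:
    """Group contrast (coef of the indicator), its SE and two-sided p.

    When any subject contributes repeated scans, the random-intercept
    variance is estimated once by REML; the (optionally Huber-reweighted)
    contrast is then a fixed-variance GLS.  With one scan per subject the
    random-intercept variance is pinned at zero and the fit is (weighted)
    least squares.  Robust IRLS recomputes Huber weights from scaled
    residuals until the contrast stabilises.
    """
    X = sm.add_constant(group_ind.astype(float), has_constant="add")
    if covariates is not None and covariates.size:
        X = np.column_stack([X, covariates])
    _, subject_codes = np.unique(subjects, return_inverse=True)
    repeated = subject_codes.max() + 1 < len(subjects)

    if not repeated:
        if robust:
            res = sm.RLM(y, X, M=sm.robust.norms.HuberT(HUBER_C)).fit(
                maxiter=max_iter, tol=tol
            )
        else:
            res = sm.OLS(y, X).fit()
        est, se = float(res.params[1]), float(res.bse[1])
        p = float(res.pvalues[1])
        return est, se, p, len(y)

    sigma_u2, sigma_e2 = _reml_random_intercept(y, X, subject_codes)

    w = np.ones(len(y))
    est_prev = np.inf
    for _ in range(max_iter if robust else 1):
        beta, cov, resid = _gls_random_intercept(
            y, X, subject_codes, w, sigma_u2, sigma_e2
        )
        est, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
        if not robust or abs(est - est_prev) <= tol * max(1.0, abs(est)):
            break
        est_prev = est
        w = _huber_weights(resid)
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return est, se, float(p), len(y)


def fit_group_model(
    z_df: pd.DataFrame,
    stratum: str = "all",
    contrast: tuple[str, str] = ("CHD", "Control"),
    family_size: int | None = None,
    robust: bool = True,
    metrics: list[str] | None = None,
    adjust_ga: bool = True,
) -> pd.DataFrame:
    """Per-region group contrasts of Z within a stratum, Holm + BH adjusted.

    ``contrast = (a, b)`` estimates mean(a) - mean(b); the Holm family is
    the set of per-region p-values within each metric (its size may be
    overridden with ``family_size`` for sub-family analyses, which only
    rescales the adjustment).  ``adjust_ga`` includes centred linear and
    quadratic GA terms in each region's model, absorbing residual
    GA trends in z (the groups' GA distributions differ, and chart error
    near the edge of the control GA range would otherwise masquerade as a
    group effect).
    """
    sub = select_stratum(z_df, stratum)
    a, b = contrast
    sub = sub[sub.group.isin([a, b])]
    if metrics is not None:
        sub = sub[sub.metric.isin(metrics)]
    name = f"{a} vs {b} [{stratum}]"
    results: list[GroupTestResult] = []
    for (metric, region), d in sub.groupby(["metric", "region"], sort=False):
        groups_present = set(d.group)
        if not {a, b} <= groups_present or d.group.nunique() < 2 or any(
            (d.group == g).sum() < 2 for g in (a, b)
        ):
            results.append(
                GroupTestResult(region, metric, name, np.nan, np.nan, np.nan,
                                n=len(d), testable=False)
            )
            continue
        cov = None
        if adjust_ga:
            ga = d.ga_weeks.to_numpy(dtype=float)
            ga = ga - ga.mean()
            if np.ptp(ga) > 1e-12:
                cov = np.column_stack([ga, ga**2])
        est, se, p, n = _fit_region(
            d.z.to_numpy(),
            (d.group == a).to_numpy(),
            d.subject_id.to_numpy(),
            covariates=cov,
            robust=robust,
        )
        results.append(GroupTestResult(region, metric, name, est, se, p, n=n))
    return _adjust(results, family_size)


def delta_z_group_test(
    delta_df: pd.DataFrame,
    contrast: tuple[str, str] = ("CHD", "Control"),
    family_size: int | None = None,
    robust: bool = True,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region contrasts of longitudinal dZ, adjusting for dGA.

    Subjects lacking either scan are absent from the dZ table by
    construction; a constant dGA column is dropped (it is absorbed by the
    intercept).
    """
    a, b = contrast
    sub = delta_df[delta_df.group.isin([a, b])]
    if metrics is not None:
        sub = sub[sub.metric.isin(metrics)]
    name = f"{a} vs {b} [dZ]"
    results: list[GroupTestResult] = []
    for (metric, region), d in sub.groupby(["metric", "region"], sort=False):
        if not {a, b} <= set(d.group) or any(
            (d.group == g).sum() < 2 for g in (a, b)
        ):
            results.append(
                GroupTestResult(region, metric, name, np.nan, np.nan, np.nan,
                                n=len(d), testable=False)
            )
            continue
        dga = d.delta_ga.to_numpy()
        cov = dga[:, None] if np.ptp(dga) > 1e-12 else None
        est, se, p, n = _fit_region(
            d.delta_z.to_numpy(),
            (d.group == a).to_numpy(),
            d.subject_id.to_numpy(),
            covariates=cov,
            robust=robust,
        )
        results.append(GroupTestResult(region, metric, name, est, se, p, n=n))
    return _adjust(results, family_size)


def _adjust(results: list[GroupTestResult], family_size: int | None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    df["p_holm"] = np.nan
    df["q"] = np.nan
    for metric, idx in df.groupby("metric").groups.items():
        mask = df.loc[idx, "testable"] & df.loc[idx, "p"].notna()
        rows = df.loc[idx][mask.to_numpy()].index
        if not len(rows):
            continue
        p = df.loc[rows, "p"].to_numpy()
        m = family_size if family_size is not None else len(p)
        if m < len(p):
            raise ValueError("family_size smaller than number of tests")
        # pad the family with untested hypotheses (p=1) if m exceeds it
        pad = np.ones(m - len(p))
        full = np.concatenate([p, pad])
        df.loc[rows, "p_holm"] = holm_adjust(full)[: len(p)]
        df.loc[rows, "q"] = bh_q(full)[: len(p)]
    return df


def subtype_contrasts(
    z_df: pd.DataFrame,
    stratum: str,
    family_size: int | None = None,
    robust: bool = True,
    metrics: list[str] | None = None,
    adjust_ga: bool = True,
) -> pd.DataFrame:
    """HLHS/TGA vs Control, Other vs Control and HLHS/TGA vs Other contrasts.

    Implemented by relabelling the group column with the CHD subtype and
    re-running the factorial contrast.
    """
    relabelled = z_df.copy()
    relabelled["group"] = np.where(
        relabelled.group == "CHD", relabelled.chd_subtype, relabelled.group
    )
    frames = []
    for pair in (("HLHS_TGA", "Control"), ("Other", "Control"), ("HLHS_TGA", "Other")):
        frames.append(
            fit_group_model(
                relabelled, stratum=stratum, contrast=pair,
                family_size=family_size, robust=robust, metrics=metrics,
                adjust_ga=adjust_ga,
            )
        )
    return pd.concat(frames, ignore_index=True)
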