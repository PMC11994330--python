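"""Linking regional deviation scores to 2-year Bayley-III outcomes.

Two general linear models relate a region's surface-metric deviation
score (z) to a Bayley-III composite score:

* **GLM 1**: ``score ~ z + group + z:group + GA_at_birth + maternal_education``
  -- the reported coefficient is the CHD-group z slope (main effect plus
  interaction under Control=0 / CHD=1 coding), with a delta-method SE.
* **GLM 2** adds ``post30 + z:post30`` terms, where scans are labelled by
  whether they were acquired before or after 30 gestational weeks; the
  CHD pre-30 and post-30 slopes are reported separately.

Candidate covariates are screened once per domain with bidirectional
stepwise search minimising the Akaike information criterion, starting
from the intercept-only model.  q-values are computed per domain per
model over the family of 60 regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from fetalsurf.inference import bh_q

DOMAINS = ("cognitive", "language", "motor")


@dataclass(frozen=True)
class OutcomeModelResult:
    region: str
    metric: str
    domain: str
    model: str  # "GLM1" | "GLM2"
    beta: float
    se: float
    p: float
    q: float = np.nan
    beta_pre30: float = np.nan
    beta_post30: float = np.nan
    p_pre30: float = np.nan
    p_post30: float = np.nan
    n: int = 0


class DegenerateDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stepwise AIC


def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    base_terms: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Bidirectional stepwise covariate selection minimising AIC.

    Starts from the model with only the intercept (plus any ``base_terms``,
    which are never dropped); at each step the single add or drop move with
    the largest AIC reduction is taken.  Deterministic given the input.
    Zero-variance candidates are dropped with a warning.

    Returns the selected covariates and the (move, AIC) trace.
    """
    base_terms = list(base_terms or [])
    usable = []
    for c in candidates:
        col = pd.to_numeric(data[c], errors="coerce")
        if col.std(ddof=0) < 1e-12 or col.isna().any():
            warnings.warn(f"dropping covariate {c!r} (constant or non-numeric)")
        else:
            usable.append(c)

    def fit_aic(terms: list[str]) -> float:
        X = sm.add_constant(
            data[terms].to_numpy(dtype=float)
            if terms
            else np.empty((len(data), 0)),
            has_constant="add",
        )
        return float(sm.OLS(data[response].to_numpy(dtype=float), X).fit().aic)

    selected: list[str] = []
    trace = [("<start>", fit_aic(base_terms))]
    current = trace[0][1]
    while True:
        moves: list[tuple[float, str, str]] = []
        for c in usable:
            if c in selected:
                moves.append(
                    (fit_aic(base_terms + [s for s in selected if s != c]), "drop", c)
                )
            else:
                moves.append((fit_aic(base_terms + selected + [c]), "add", c))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))  # deterministic tie-break by name
        best_aic, action, cov = moves[0]
        if best_aic >= current - 1e-9:
            break
        if action == "add":
            selected.append(cov)
        else:
            selected.remove(cov)
        trace.append((f"{action} {cov}", best_aic))
        current = best_aic
    return selected, trace


# ---------------------------------------------------------------------------
# GLMs


def _prepare_glm_frame(
    z_df: pd.DataFrame,
    outcomes: pd.DataFrame,
    region: str,
    metric: str,
    scan_rule: str = "latest",
) -> pd.DataFrame:
    """One row per subject (GLM1) with the scan chosen by ``scan_rule``.

    ``scan_rule='latest'`` keeps each subject's latest scan; ``'all'``
    keeps every scan (long format, for GLM2 or the scan-covariate mode).
    """
    sub = z_df[(z_df.region == region) & (z_df.metric == metric)].copy()
    if scan_rule == "latest":
        sub = sub.sort_values(["subject_id", "ga_weeks"]).groupby("subject_id").tail(1)
    elif scan_rule != "all":
        raise ValueError("scan_rule must be 'latest' or 'all'")
    merged = sub.merge(outcomes, on="subject_id", how="inner", suffixes=("", "_out"))
    merged["chd"] = (merged.group == "CHD").astype(float)
    merged["post30"] = (merged.ga_weeks >= 30.0).astype(float)
    return merged


def _contrast_test(res, vec: np.ndarray) -> tuple[float, float, float]:
    est = float(vec @ res.params)
    var = float(vec @ res.cov_params() @ vec)
    se = np.sqrt(var)
    if se == 0:
        return est, se, np.nan
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df=res.df_resid)
    return est, se, float(p)


def fit_glm1(
    z_df: pd.DataFrame,
    outcomes: pd.DataFrame,
    region: str,
    metric: str,
    domain: str,
    scan_rule: str = "latest",
) -> OutcomeModelResult:
    """GLM 1 for one region x metric x domain.

    Reports the CHD-group z slope (z main effect + z:group interaction)
    with delta-method SE and its p-value.
    """
    d = _prepare_glm_frame(z_df, outcomes, region, metric, scan_rule)
    cols = ["z", "chd", "z_chd", "ga_at_birth", "maternal_education"]
    d["z_chd"] = d.z * d.chd
    X = sm.add_constant(d[cols].to_numpy(dtype=float), has_constant="add")
    if len(d) < X.shape[1] + 5:
        raise DegenerateDesignError(
            f"{region}/{metric}/{domain}: n={len(d)} too small for {X.shape[1]} parameters"
        )
    if d.z.std(ddof=0) < 1e-12:
        raise DegenerateDesignError(
            f"{region}/{metric}/{domain}: z has no variance; slope inestimable"
        )
    res = sm.OLS(d[domain].to_numpy(dtype=float), X).fit()
    vec = np.zeros(X.shape[1])
    vec[1] = 1.0  # z
    vec[3] = 1.0  # z:chd
    beta, se, p = _contrast_test(res, vec)
    return OutcomeModelResult(
        region=region, metric=metric, domain=domain, model="GLM1",
        beta=beta, se=se, p=p, n=len(d),
    )


def fit_glm2(
    z_df: pd.DataFrame,
    outcomes: pd.DataFrame,
    region: str,
    metric: str,
    domain: str,
) -> OutcomeModelResult:
    """GLM 2: adds pre/post-30-GW terms; scans enter in long format.

    Reports the CHD pre-30 slope (z + z:group) and post-30 slope
    (z + z:group + z:post30); ``beta``/``p`` carry the post-30 slope,
    the epoch of interest.
    """
    d = _prepare_glm_frame(z_df, outcomes, region, metric, scan_rule="all")
    d["z_chd"] = d.z * d.chd
    d["z_post30"] = d.z * d.post30
    cols = ["z", "chd", "z_chd", "post30", "z_post30", "ga_at_birth",
            "maternal_education"]
    X = sm.add_constant(d[cols].to_numpy(dtype=float), has_constant="add")
    if len(d) < X.shape[1] + 5:
        raise DegenerateDesignError(
            f"{region}/{metric}/{domain}: n={len(d)} too small for {X.shape[1]} parameters"
        )
    missing_strata = [s for s in (0.0, 1.0) if not (d.post30 == s).any()]
    if missing_strata:
        raise DegenerateDesignError(
            f"{region}/{metric}/{domain}: pre/post-30 stratum entirely missing"
        )
    res = sm.OLS(d[domain].to_numpy(dtype=float), X).fit()
    k = X.shape[1]
    pre = np.zeros(k)
    pre[[1, 3]] = 1.0  # z + z:chd
    post = np.zeros(k)
    post[[1, 3, 5]] = 1.0  # z + z:chd + z:post30
    b_pre, _, p_pre = _contrast_test(res, pre)
    b_post, se_post, p_post = _contrast_test(res, post)
    return OutcomeModelResult(
        region=region, metric=metric, domain=domain, model="GLM2",
        beta=b_post, se=se_post, p=p_post,
        beta_pre30=b_pre, beta_post30=b_post, p_pre30=p_pre, p_post30=p_post,
        n=len(d),
    )


def fit_outcome_models(
    z_df: pd.DataFrame,
    outcomes: pd.DataFrame,
    model: str = "GLM1",
    metric: str = "surface_area",
    domains: tuple[str, ...] = DOMAINS,
    regions: list[str] | None = None,
    family_size: int = 60,
    scan_rule: str = "latest",
) -> pd.DataFrame:
    """All-region sweep of GLM1 or GLM2 with per-domain BH q over 60 regions."""
    if regions is None:
        regions = sorted(z_df.region.unique())
    rows = []
    for domain in domains:
        for region in regions:
            try:
                if model == "GLM1":
                    r = fit_glm1(z_df, outcomes, region, metric, domain, scan_rule)
                elif model == "GLM2":
                    r = fit_glm2(z_df, outcomes, region, metric, domain)
                else:
                    raise ValueError("model must be 'GLM1' or 'GLM2'")
            except DegenerateDesignError as err:
                warnings.warn(str(err))
                r = OutcomeModelResult(
                    region=region, metric=metric, domain=domain, model=model,
                    beta=np.nan, se=np.nan, p=np.nan,
                )
            rows.append(r.__dict__)
    df = pd.DataFrame(rows)
    for domain in domains:
        idx = df.index[(df.domain == domain) & df.p.notna()]
        if not len(idx):
            continue
        p = df.loc[idx, "p"].to_numpy()
        m = max(family_size, len(p))
        full = np.concatenate([p, np.ones(m - len(p))])
        df.loc[idx, "q"] = bh_q(full)[: len(p)]
    return df
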