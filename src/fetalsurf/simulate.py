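"""Synthetic longitudinal fetal cohorts with the structure the analysis assumes.

The generator produces scan metadata, regional metric tables and 2-year
outcome tables for a case-control fetal cohort:

* subjects are Controls or CHD (congenital heart disease), a configurable
  fraction with two in-utero scans; gestational ages (GA) are drawn
  uniformly within per-scan windows matching the study cohort
  (scan 1 roughly 20-30 gestational weeks, scan 2 roughly 30-39);
* each region x metric follows a Gompertz growth law
  ``K * exp(-exp(-k (GA - t0)))`` with an additive shared per-subject
  random effect and measurement noise; the total residual is scaled so
  that, after standardisation by the control mean/SD, it matches the
  fixed noise level of the normative Gaussian-process charts (SD 0.1 on
  the standardised scale), which is what makes held-out control deviation
  scores approximately standard normal;
* CHD subjects carry a surface-area deficit in a configurable region set
  that is zero before an onset GA (default 30 weeks) and grows linearly
  after it, expressed in control-SD units per week -- emulating growth
  curves that fall below the norm only in the third trimester;
* Bayley-III composite outcomes for a follow-up subset are linearly
  coupled, in the CHD group only, to the subject's mean late-gestation
  deviation over the affected regions, plus GA-at-birth and
  maternal-education covariate effects and residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from fetalsurf.metrics import METRIC_COLUMNS, all_region_ids

GROUP_CONTROL = "Control"
GROUP_CHD = "CHD"

#: Regions carrying the default surface-area deficit: bilateral pre/post
#: central, lateral orbitofrontal, lingual, superior temporal and
#: pericalcarine gyri plus the right transverse temporal gyrus (13 total),
#: the pattern reported for late-gestation CHD cohorts.
DEFAULT_AFFECTED_REGIONS = (
    "L_precentral",
    "R_precentral",
    "L_postcentral",
    "R_postcentral",
    "L_lateralorbitofrontal",
    "R_lateralorbitofrontal",
    "L_lingual",
    "R_lingual",
    "L_superiortemporal",
    "R_superiortemporal",
    "L_pericalcarine",
    "R_pericalcarine",
    "R_transversetemporal",
)

#: Gompertz rate (1/week), inflection GA (weeks) and asymptote scale per
#: metric.  Region asymptotes K_r are spread deterministically around the
#: scale so charts differ by region.
METRIC_GROWTH = {
    "surface_area": {"k": 0.18, "t0": 29.0, "K_scale": 600.0},  # mm^2
    "sulcal_depth": {"k": 0.22, "t0": 31.0, "K_scale": 6.0},  # mm
    "mean_curvature": {"k": 0.15, "t0": 27.0, "K_scale": 0.35},  # 1/mm
}


def growth_curve(ga, K: float, k: float, t0: float):
    """Gompertz growth value ``K * exp(-exp(-k (ga - t0)))``.

    Strictly increasing in GA; equals ``K/e`` at the inflection ``t0`` and
    approaches the asymptote ``K`` as GA grows.
    """
    if K <= 0 or k <= 0:
        raise ValueError("K and k must be positive")
    ga = np.asarray(ga, dtype=float)
    return K * np.exp(-np.exp(-k * (ga - t0)))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Defaults reproduce the study cohort's bookkeeping: 125 control
    subjects (32 longitudinal, 157 scans) and 91 CHD subjects (44
    longitudinal, 135 scans; 39 with HLHS/TGA physiology), 292 scans in
    total, with a 51 + 38 subject Bayley-III follow-up subset.
    """

    n_control_subjects: int = 125
    n_chd_subjects: int = 91
    fraction_longitudinal_control: float = 32 / 125
    fraction_longitudinal_chd: float = 44 / 91
    fraction_hlhs_tga: float = 39 / 91

    # GA sampling windows (weeks): (scan1 lo, scan1 hi, scan2 lo, scan2 hi)
    ga_windows_control: tuple[float, float, float, float] = (22.0, 30.0, 29.1, 38.7)
    ga_windows_chd: tuple[float, float, float, float] = (19.6, 30.4, 30.0, 38.8)
    min_interscan_weeks: float = 3.3

    regions: tuple[str, ...] = tuple(all_region_ids())
    metrics: tuple[str, ...] = ("surface_area", "sulcal_depth", "mean_curvature")

    #: total residual SD as a fraction of the between-GA spread of the
    #: growth curve; 0.1 matches the charts' fixed noise SD on the
    #: standardised scale
    noise_to_signal: float = 0.1
    #: share of residual variance carried by the shared subject effect
    between_subject_share: float = 0.5

    affected_regions: tuple[str, ...] = DEFAULT_AFFECTED_REGIONS
    affected_metric: str = "surface_area"
    #: deficit slope in control-SD units per week after onset
    deficit_slope: float = 0.4
    onset_ga: float = 30.0
    #: extra deficit slope applied to the HLHS/TGA subtype (0 = same law)
    subtype_extra_slope: float = 0.0

    # outcome generation
    n_followup_chd: int = 51
    n_followup_control: int = 38
    outcome_intercept: float = 100.0
    #: outcome points per unit of mean affected-region z (CHD only)
    outcome_slopes: tuple[tuple[str, float], ...] = (
        ("cognitive", 2.0),
        ("language", 4.0),
        ("motor", 2.75),
    )
    ga_birth_coef: float = 1.0  # points per week, centred at 39 weeks
    maternal_education_coef: float = 5.0  # college+ vs other
    outcome_resid_sd: float = 8.0
    fraction_college_education: float = 0.33

    seed: int = 0

    def validate(self) -> None:
        for name, frac in (
            ("fraction_longitudinal_control", self.fraction_longitudinal_control),
            ("fraction_longitudinal_chd", self.fraction_longitudinal_chd),
            ("fraction_hlhs_tga", self.fraction_hlhs_tga),
            ("fraction_college_education", self.fraction_college_education),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.noise_to_signal <= 0 or self.noise_to_signal >= 1:
            raise ValueError("noise_to_signal must be in (0, 1)")
        if not 0 <= self.between_subject_share <= 1:
            raise ValueError("between_subject_share must be in [0, 1]")
        if self.deficit_slope < 0 or self.outcome_resid_sd < 0:
            raise ValueError("SDs and deficit slope must be non-negative")
        lo = min(self.ga_windows_control[0], self.ga_windows_chd[0])
        hi = max(self.ga_windows_control[3], self.ga_windows_chd[3])
        if not lo <= self.onset_ga <= hi:
            raise ValueError("onset_ga must lie within the scanned GA range")
        if self.n_followup_chd > self.n_chd_subjects:
            raise ValueError("more CHD follow-ups than subjects")
        if self.n_followup_control > self.n_control_subjects:
            raise ValueError("more control follow-ups than subjects")
        unknown = set(self.affected_regions) - set(self.regions)
        if unknown:
            raise ValueError(f"affected regions not simulated: {sorted(unknown)}")
        if self.affected_metric not in self.metrics:
            raise ValueError("affected_metric not in simulated metrics")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def region_asymptote(region: str, metric: str) -> float:
    """Deterministic per-region Gompertz asymptote K_r.

    Regions are spread multiplicatively over roughly [0.5, 1.5] x the
    metric scale using a hash of the region name, so charts are
    region-specific but reproducible without a seed.
    """
    g = METRIC_GROWTH[metric]
    h = (hash_region(region) % 1000) / 1000.0
    return g["K_scale"] * (0.5 + h)


def hash_region(region: str) -> int:
    # stable across processes (builtin hash() is salted)
    acc = 0
    for ch in region:
        acc = (acc * 131 + ord(ch)) % 2_147_483_647
    return acc


def _unit_trend_spread(config: SimulationConfig, metric: str) -> float:
    """SD of the unit-asymptote growth curve under the control GA design.

    The control scan GA distribution is a mixture of three uniform
    segments: singleton scans over the full window, and the scan-1 /
    scan-2 windows of the longitudinal subjects.  The spread of the
    growth trend over this design is the 'signal' scale against which the
    residual noise is calibrated.
    """
    g = METRIC_GROWTH[metric]
    s1lo, s1hi, s2lo, s2hi = config.ga_windows_control
    n = config.n_control_subjects
    n_long = int(round(config.fraction_longitudinal_control * n))
    segments = [(s1lo, s2hi, n - n_long), (s1lo, s1hi, n_long), (s2lo, s2hi, n_long)]
    moments = np.zeros(2)
    total = 0.0
    for lo, hi, weight in segments:
        if weight <= 0:
            continue
        grid = np.linspace(lo, hi, 401)
        vals = growth_curve(grid, 1.0, g["k"], g["t0"])
        moments += weight * np.array([vals.mean(), (vals**2).mean()])
        total += weight
    mean, second = moments / total
    return float(np.sqrt(max(second - mean**2, 0.0)))


def residual_sd(config: SimulationConfig, region: str, metric: str) -> float:
    """Total residual SD (native units) for one region x metric.

    Chosen so residual / total control SD = ``noise_to_signal``:
    ``sd = nts * signal_sd / sqrt(1 - nts^2)``, with the signal SD taken
    over the control GA design.
    """
    K = region_asymptote(region, metric)
    s = K * _unit_trend_spread(config, metric)
    nts = config.noise_to_signal
    return nts * s / np.sqrt(1.0 - nts**2)


def _sample_subjects(config: SimulationConfig, rng: np.random.Generator):
    """Subject frame: id, group, subtype, longitudinal flag, scan GAs."""
    rows = []
    for group, n, frac_long, windows, prefix in (
        (GROUP_CONTROL, config.n_control_subjects,
         config.fraction_longitudinal_control, config.ga_windows_control, "ctl"),
        (GROUP_CHD, config.n_chd_subjects,
         config.fraction_longitudinal_chd, config.ga_windows_chd, "chd"),
    ):
        n_long = int(round(frac_long * n))
        long_flags = np.zeros(n, dtype=bool)
        long_flags[rng.choice(n, size=n_long, replace=False)] = True
        if group == GROUP_CHD:
            n_sub = int(round(config.fraction_hlhs_tga * n))
            sub_flags = np.zeros(n, dtype=bool)
            sub_flags[rng.choice(n, size=n_sub, replace=False)] = True
        else:
            sub_flags = np.zeros(n, dtype=bool)
        s1lo, s1hi, s2lo, s2hi = windows
        for i in range(n):
            sid = f"{prefix}{i:03d}"
            subtype = (
                "HLHS_TGA" if sub_flags[i] else ("Other" if group == GROUP_CHD else "none")
            )
            if long_flags[i]:
                ga1 = rng.uniform(s1lo, s1hi)
                ga2 = rng.uniform(s2lo, s2hi)
                while ga2 - ga1 < config.min_interscan_weeks:
                    ga2 = rng.uniform(s2lo, s2hi)
                gas = [(1, ga1), (2, ga2)]
            else:
                # cross-sectional scan anywhere in the cohort window; its
                # index records which scan window (1: <30.5 GW) it falls in
                ga = rng.uniform(s1lo, s2hi)
                gas = [(1 if ga < 30.5 else 2, ga)]
            for scan_index, ga in gas:
                rows.append((sid, group, subtype, scan_index, ga))
    scans = pd.DataFrame(
        rows, columns=["subject_id", "group", "chd_subtype", "scan_index", "ga_weeks"]
    )
    scans.insert(0, "scan_id", [
        f"{s}_s{ix}" for s, ix in zip(scans.subject_id, scans.scan_index)
    ])
    return scans


def true_z_deficit(config: SimulationConfig, ga, subtype: str = "Other"):
    """Deterministic part of the deficit on the z (control-SD) scale."""
    slope = config.deficit_slope
    if subtype == "HLHS_TGA":
        slope = slope + config.subtype_extra_slope
    return slope * np.maximum(np.asarray(ga, dtype=float) - config.onset_ga, 0.0)


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (scans, regional metric table, outcomes) for one cohort.

    Fully reproducible given the config seed (``seed`` overrides it).
    The metric table is in the wide CSV schema of
    :data:`fetalsurf.metrics.METRIC_COLUMNS`; the scans frame additionally
    carries a hidden ``_z_true`` column block used internally for outcome
    coupling is *not* exposed -- outcomes are returned separately.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = config.with_(seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    scans = _sample_subjects(config, rng)
    subjects = scans.drop_duplicates("subject_id")[
        ["subject_id", "group", "chd_subtype"]
    ].reset_index(drop=True)
    subj_effect = dict(
        zip(subjects.subject_id, rng.standard_normal(len(subjects)))
    )

    n_scan = len(scans)
    ga = scans.ga_weeks.to_numpy()
    is_chd = (scans.group == GROUP_CHD).to_numpy()
    b_s = scans.subject_id.map(subj_effect).to_numpy()

    # latent z per scan per affected region accumulates for outcome coupling
    z_true_sum = np.zeros(n_scan)

    frames = []
    for metric in config.metrics:
        g = METRIC_GROWTH[metric]
        cols = {}
        for region in config.regions:
            K = region_asymptote(region, metric)
            sd_tot = residual_sd(config, region, metric)
            sd_b = np.sqrt(config.between_subject_share) * sd_tot
            sd_e = np.sqrt(1.0 - config.between_subject_share) * sd_tot
            noise = rng.normal(0.0, sd_e, size=n_scan)
            value = growth_curve(ga, K, g["k"], g["t0"]) + sd_b * b_s + noise
            if metric == config.affected_metric and region in config.affected_regions:
                deficit_z = np.where(
                    is_chd,
                    true_z_deficit(config, ga, "Other"),
                    0.0,
                )
                extra = (scans.chd_subtype == "HLHS_TGA").to_numpy() * (
                    config.subtype_extra_slope
                    * np.maximum(ga - config.onset_ga, 0.0)
                )
                deficit_z = deficit_z + np.where(is_chd, extra, 0.0)
                value = value - deficit_z * sd_tot
                z_true_sum += np.where(
                    is_chd,
                    (value - growth_curve(ga, K, g["k"], g["t0"])) / sd_tot,
                    0.0,
                )
            cols[region] = value
        long = pd.DataFrame(cols, index=scans.scan_id).stack().rename("value")
        long = long.reset_index().rename(columns={"level_1": "region"})
        long["metric"] = metric
        frames.append(long)
    melted = pd.concat(frames, ignore_index=True)
    wide = melted.pivot_table(
        index=["scan_id", "region"], columns="metric", values="value"
    ).reset_index()
    wide = wide.rename(columns=METRIC_COLUMNS)
    wide["hemisphere"] = wide.region.str[0]
    order = ["scan_id", "region", "hemisphere"] + [
        METRIC_COLUMNS[m] for m in config.metrics
    ]
    # keep scan, then region order stable
    wide = (
        wide.set_index(["scan_id", "region"])
        .loc[
            pd.MultiIndex.from_product(
                [scans.scan_id, list(config.regions)], names=["scan_id", "region"]
            )
        ]
        .reset_index()[order]
    )

    scans = scans.copy()
    scans["z_affected_mean"] = z_true_sum / max(len(config.affected_regions), 1)

    outcomes = _simulate_outcomes(config, scans, rng)
    return scans, wide, outcomes


def _simulate_outcomes(
    config: SimulationConfig, scans: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Bayley-III composites for the follow-up subset.

    Outcome = intercept + slope * (mean affected-region z at the latest
    scan, CHD only) + GA-at-birth and maternal-education effects + noise,
    clipped to the instrument range 40-160.
    """
    latest = (
        scans.sort_values("scan_index").groupby("subject_id").tail(1).set_index(
            "subject_id"
        )
    )
    rows = []
    for group, n_fu in (
        (GROUP_CONTROL, config.n_followup_control),
        (GROUP_CHD, config.n_followup_chd),
    ):
        ids = latest.index[latest.group == group].to_numpy()
        chosen = rng.choice(ids, size=n_fu, replace=False)
        for sid in chosen:
            ga_birth = float(np.clip(rng.normal(39.0, 1.5), 32.0, 42.0))
            edu = int(rng.uniform() < config.fraction_college_education)
            z = latest.at[sid, "z_affected_mean"] if group == GROUP_CHD else 0.0
            scores = {}
            for domain, slope in config.outcome_slopes:
                mu = (
                    config.outcome_intercept
                    + slope * z
                    + config.ga_birth_coef * (ga_birth - 39.0)
                    + config.maternal_education_coef * edu
                )
                scores[domain] = float(
                    np.clip(mu + rng.normal(0.0, config.outcome_resid_sd), 40.0, 160.0)
                )
            rows.append(
                (
                    sid,
                    latest.at[sid, "group"],
                    scores.get("cognitive", np.nan),
                    scores.get("language", np.nan),
                    scores.get("motor", np.nan),
                    ga_birth,
                    edu,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "cognitive",
            "language",
            "motor",
            "ga_at_birth",
            "maternal_education",
        ],
    )
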