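"""Gaussian-process normative growth charts and deviation (Z) scores.

One chart is fitted per region x metric on control scans only, regressing
the metric on gestational age (GA) with a radial-basis-function kernel.
The metric is first standardised by the control mean/SD (the fixed noise
variance of 0.01 is only dimensionally sensible on that scale); the kernel
signal variance and length scale are then optimised by maximising the log
marginal likelihood from the initial values (variance 1.0, length scale
2.0 weeks) under a positivity constraint, with the Gaussian noise variance
held fixed at 0.01 to prevent interpolation of noise.

A scan's deviation score is ``z = (observed - predicted mean) /
predictive SD`` (below-curve deviations are negative); longitudinal pairs
yield ``dZ = z(scan 2) - z(scan 1)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

GA_BOUNDS = (15.0, 45.0)
INIT_SIGNAL_VARIANCE = 1.0
INIT_LENGTH_SCALE = 2.0
FIXED_NOISE_VARIANCE = 0.01

METRIC_FROM_COLUMN = {
    "surface_area_mm2": "surface_area",
    "mean_sulcal_depth_mm": "sulcal_depth",
    "mean_abs_curvature_per_mm": "mean_curvature",
}


class NormativeFitError(RuntimeError):
    pass


@dataclass
class NormativeModel:
    """Fitted growth chart for one region x metric."""

    region: str
    metric: str
    signal_variance: float
    length_scale: float
    noise_variance: float
    y_mean: float  # control mean, native units
    y_sd: float  # control SD, native units
    ga_train: np.ndarray  # (n,) weeks
    y_train: np.ndarray  # (n,) standardised
    _chol: object = field(default=None, repr=False, compare=False)
    _alpha: np.ndarray = field(default=None, repr=False, compare=False)

    def kernel_matrix(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = a[:, None] - b[None, :]
        return self.signal_variance * np.exp(-0.5 * (d / self.length_scale) ** 2)

    def _factor(self):
        if self._chol is None:
            K = self.kernel_matrix(self.ga_train, self.ga_train)
            K[np.diag_indices_from(K)] += self.noise_variance
            self._chol = cho_factor(K, lower=True)
            self._alpha = cho_solve(self._chol, self.y_train)
        return self._chol, self._alpha

    def log_marginal_likelihood(
        self, signal_variance: float | None = None, length_scale: float | None = None
    ) -> float:
        s2 = self.signal_variance if signal_variance is None else signal_variance
        ls = self.length_scale if length_scale is None else length_scale
        d = self.ga_train[:, None] - self.ga_train[None, :]
        K = s2 * np.exp(-0.5 * (d / ls) ** 2)
        K[np.diag_indices_from(K)] += self.noise_variance
        c = cho_factor(K, lower=True)
        alpha = cho_solve(c, self.y_train)
        n = len(self.y_train)
        return float(
            -0.5 * self.y_train @ alpha
            - np.log(np.diag(c[0])).sum()
            - 0.5 * n * np.log(2 * np.pi)
        )

    # --- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "metric": self.metric,
            "signal_variance": self.signal_variance,
            "length_scale": self.length_scale,
            "noise_variance": self.noise_variance,
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "ga_train": self.ga_train.tolist(),
            "y_train": self.y_train.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            region=d["region"],
            metric=d["metric"],
            signal_variance=float(d["signal_variance"]),
            length_scale=float(d["length_scale"]),
            noise_variance=float(d["noise_variance"]),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            ga_train=np.asarray(d["ga_train"], dtype=float),
            y_train=np.asarray(d["y_train"], dtype=float),
        )


@dataclass(frozen=True)
class ZScoreRecord:
    scan_id: str
    region: str
    metric: str
    z: float
    ga_weeks: float
    subject_id: str | None = None


@dataclass(frozen=True)
class DeltaZRecord:
    subject_id: str
    region: str
    metric: str
    delta_z: float
    delta_ga: float


def fit_normative(
    ga: np.ndarray,
    values: np.ndarray,
    region: str = "",
    metric: str = "",
    noise_variance: float = FIXED_NOISE_VARIANCE,
    max_iter: int = 100,
    min_n: int = 10,
    min_span_weeks: float = 8.0,
) -> NormativeModel:
    """Fit one growth chart on control scans.

    The log marginal likelihood at the returned hyperparameters is never
    below its value at the initial ones (the optimiser result is discarded
    if it fails to improve).
    """
    ga = np.asarray(ga, dtype=float)
    values = np.asarray(values, dtype=float)
    if ga.shape != values.shape or ga.ndim != 1:
        raise ValueError("ga and values must be 1-D arrays of equal length")
    if not (np.isfinite(ga).all() and np.isfinite(values).all()):
        raise NormativeFitError(f"non-finite training data for {region}/{metric}")
    if len(ga) < min_n:
        raise NormativeFitError(
            f"{region}/{metric}: {len(ga)} control scans < minimum {min_n}"
        )
    if ga.max() - ga.min() < min_span_weeks:
        raise NormativeFitError(
            f"{region}/{metric}: GA span {ga.max() - ga.min():.1f} weeks "
            f"< minimum {min_span_weeks}"
        )
    y_mean = float(values.mean())
    y_sd = float(values.std(ddof=0))
    if y_sd < 1e-12:
        y_sd = 1.0  # constant data; chart degenerates to the constant
    y = (values - y_mean) / y_sd

    kernel = ConstantKernel(
        INIT_SIGNAL_VARIANCE, constant_value_bounds=(1e-3, 1e3)
    ) * RBF(INIT_LENGTH_SCALE, length_scale_bounds=(1e-1, 1e2))

    def optimizer(obj_func, initial_theta, bounds):
        res = minimize(
            obj_func,
            initial_theta,
            jac=True,
            bounds=bounds,
            method="L-BFGS-B",
            options={"maxiter": max_iter},
        )
        f0 = obj_func(initial_theta, eval_gradient=False)
        if not np.isfinite(res.fun):
            raise NormativeFitError(
                f"{region}/{metric}: optimiser produced non-finite likelihood"
            )
        if res.fun <= f0:
            return res.x, res.fun
        return initial_theta, f0

    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=noise_variance,
        optimizer=optimizer,
        normalize_y=False,
    )
    with warnings.catch_warnings():
        # bound-proximity notes from the kernel are expected for
        # degenerate (e.g. constant) inputs
        warnings.simplefilter("ignore")
        gp.fit(ga[:, None], y)
    s2 = float(gp.kernel_.k1.constant_value)
    ls = float(gp.kernel_.k2.length_scale)
    model = NormativeModel(
        region=region,
        metric=metric,
        signal_variance=s2,
        length_scale=ls,
        noise_variance=noise_variance,
        y_mean=y_mean,
        y_sd=y_sd,
        ga_train=ga,
        y_train=y,
    )
    return model


def predict(
    model: NormativeModel, ga, include_noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, predictive SD) on the metric's native scale.

    ``include_noise`` adds the fixed noise variance to the predictive
    variance (the default, so that deviation scores of fresh observations
    are calibrated rather than scores of the latent mean).
    """
    ga_arr = np.atleast_1d(np.asarray(ga, dtype=float))
    if np.any((ga_arr < GA_BOUNDS[0]) | (ga_arr > GA_BOUNDS[1])):
        raise ValueError(
            f"GA outside supported range {GA_BOUNDS} weeks (extrapolation guard)"
        )
    chol, alpha = model._factor()
    ks = model.kernel_matrix(ga_arr, model.ga_train)
    mean_std = ks @ alpha
    v = cho_solve(chol, ks.T)
    var = model.signal_variance - np.einsum("ij,ji->i", ks, v)
    var = np.maximum(var, 0.0)
    if include_noise:
        var = var + model.noise_variance
    mean = mean_std * model.y_sd + model.y_mean
    sd = np.sqrt(var) * model.y_sd
    if np.isscalar(ga) or np.ndim(ga) == 0:
        return float(mean[0]), float(sd[0])
    return mean, sd


def z_score(
    model: NormativeModel,
    observed: float,
    ga: float,
    scan_id: str = "",
    subject_id: str | None = None,
    include_noise: bool = True,
) -> ZScoreRecord:
    """Deviation of one observation from its chart.

    ``z = (observed - predicted mean) / predictive SD``; observations below
    the normative curve score negative.
    """
    if not np.isfinite(observed):
        raise ValueError("observed value must be finite")
    mean, sd = predict(model, float(ga), include_noise=include_noise)
    return ZScoreRecord(
        scan_id=scan_id,
        region=model.region,
        metric=model.metric,
        z=float((observed - mean) / sd),
        ga_weeks=float(ga),
        subject_id=subject_id,
    )


def delta_z(z1: ZScoreRecord, z2: ZScoreRecord) -> DeltaZRecord:
    """Longitudinal score change ``dZ = z2 - z1`` for one subject."""
    if z1.subject_id != z2.subject_id or z1.subject_id is None:
        raise ValueError("records must share a (non-null) subject_id")
    if (z1.region, z1.metric) != (z2.region, z2.metric):
        raise ValueError("records must share region and metric")
    if not z2.ga_weeks > z1.ga_weeks:
        raise ValueError("scan 2 GA must exceed scan 1 GA")
    return DeltaZRecord(
        subject_id=z1.subject_id,
        region=z1.region,
        metric=z1.metric,
        delta_z=z2.z - z1.z,
        delta_ga=z2.ga_weeks - z1.ga_weeks,
    )


# ---------------------------------------------------------------------------
# table-level helpers


def _melt_metrics(metrics_df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in METRIC_FROM_COLUMN if c in metrics_df.columns]
    long = metrics_df.melt(
        id_vars=["scan_id", "region"],
        value_vars=cols,
        var_name="metric",
        value_name="value",
    )
    long["metric"] = long.metric.map(METRIC_FROM_COLUMN)
    return long


def fit_all_charts(
    metrics_df: pd.DataFrame,
    scans_df: pd.DataFrame,
    control_group: str = "Control",
    metrics: list[str] | None = None,
) -> dict[tuple[str, str], NormativeModel]:
    """Fit one chart per region x metric on the control scans."""
    ctl_ids = set(scans_df.scan_id[scans_df.group == control_group])
    long = _melt_metrics(metrics_df)
    long = long[long.scan_id.isin(ctl_ids)]
    if metrics is not None:
        long = long[long.metric.isin(metrics)]
    ga = scans_df.set_index("scan_id").ga_weeks
    charts = {}
    for (region, metric), sub in long.groupby(["region", "metric"], sort=False):
        charts[(region, metric)] = fit_normative(
            ga.loc[sub.scan_id].to_numpy(), sub.value.to_numpy(), region, metric
        )
    return charts


def score_table(
    charts: dict[tuple[str, str], NormativeModel],
    metrics_df: pd.DataFrame,
    scans_df: pd.DataFrame,
    include_noise: bool = True,
) -> pd.DataFrame:
    """Z-scores for every scan x region x metric with a fitted chart."""
    long = _melt_metrics(metrics_df)
    meta = scans_df.set_index("scan_id")
    long = long[long.scan_id.isin(meta.index)]
    out = []
    for (region, metric), sub in long.groupby(["region", "metric"], sort=False):
        model = charts.get((region, metric))
        if model is None:
            continue
        ga = meta.ga_weeks.loc[sub.scan_id].to_numpy()
        mean, sd = predict(model, ga, include_noise=include_noise)
        z = (sub.value.to_numpy() - mean) / sd
        out.append(
            pd.DataFrame(
                {
                    "scan_id": sub.scan_id.to_numpy(),
                    "region": region,
                    "metric": metric,
                    "z": z,
                }
            )
        )
    zdf = pd.concat(out, ignore_index=True)
    keep = ["subject_id", "group", "chd_subtype", "scan_index", "ga_weeks"]
    keep = [c for c in keep if c in scans_df.columns]
    return zdf.merge(scans_df[["scan_id"] + keep], on="scan_id", how="left")


def delta_z_table(z_df: pd.DataFrame) -> pd.DataFrame:
    """dZ per longitudinal subject x region x metric, with dGA."""
    needed = {"subject_id", "scan_index", "ga_weeks"}
    if not needed <= set(z_df.columns):
        raise ValueError(f"z table must carry {sorted(needed)}")
    s1 = z_df[z_df.scan_index == 1]
    s2 = z_df[z_df.scan_index == 2]
    merged = s1.merge(
        s2,
        on=["subject_id", "region", "metric"],
        suffixes=("_1", "_2"),
    )
    out = pd.DataFrame(
        {
            "subject_id": merged.subject_id,
            "region": merged.region,
            "metric": merged.metric,
            "delta_z": merged.z_2 - merged.z_1,
            "delta_ga": merged.ga_weeks_2 - merged.ga_weeks_1,
        }
    )
    for c in ("group", "chd_subtype"):
        if f"{c}_1" in merged.columns:
            out[c] = merged[f"{c}_1"]
    if (out.delta_ga <= 0).any():
        raise ValueError("found scan pairs with non-positive dGA")
    return out


def plot_chart(
    model: NormativeModel,
    path: str | Path,
    observations: pd.DataFrame | None = None,
) -> None:
    """Growth-chart PNG: posterior mean with +/-1, 2, 3 SD bands over GA.

    ``observations`` may carry ``ga_weeks``/``value`` columns (e.g. the CHD
    scans) to overlay on the control chart.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = model.ga_train.min(), model.ga_train.max()
    grid = np.linspace(lo, hi, 200)
    mean, sd = predict(model, grid)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for k, alpha in ((3, 0.08), (2, 0.15), (1, 0.25)):
        ax.fill_between(grid, mean - k * sd, mean + k * sd,
                        color="grey", alpha=alpha, lw=0)
    ax.plot(grid, mean, color="black", lw=1.5)
    train_native = model.y_train * model.y_sd + model.y_mean
    ax.scatter(model.ga_train, train_native, s=8, color="grey", label="controls")
    if observations is not None:
        ax.scatter(observations.ga_weeks, observations.value, s=8,
                   color="firebrick", label="cases")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("gestational age (weeks)")
    ax.set_ylabel(f"{model.metric} ({model.region})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_charts(charts: dict, out_dir: str | Path) -> None:
    """One JSON file per chart, ``<region>__<metric>.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (region, metric), model in charts.items():
        path = out_dir / f"{region}__{metric}.json"
        path.write_text(json.dumps(model.to_dict()))


def load_charts(in_dir: str | Path) -> dict[tuple[str, str], NormativeModel]:
    charts = {}
    for path in sorted(Path(in_dir).glob("*__*.json")):
        model = NormativeModel.from_dict(json.loads(path.read_text()))
        charts[(model.region, model.metric)] = model
    return charts
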