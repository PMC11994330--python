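"""End-to-end pipeline: simulate -> charts -> z -> group tests -> outcome GLMs.

Each stage writes its outputs under the configured directory and is
skipped on rerun when its outputs are newer than its inputs.  Every run
logs the seed, a hash of the configuration and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import fetalsurf
from fetalsurf import io as fio
from fetalsurf.inference import delta_z_group_test, fit_group_model
from fetalsurf.normative import (
    delta_z_table,
    fit_all_charts,
    load_charts,
    save_charts,
    score_table,
)
from fetalsurf.outcome import fit_outcome_models
from fetalsurf.simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("fetalsurf")


class StageError(RuntimeError):
    pass


def _config_hash(config: fio.PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    oldest_out = min(p.stat().st_mtime for p in outputs)
    return oldest_out >= newest_in


def run_pipeline(config: fio.PipelineConfig) -> Path:
    """Run (or resume) the full analysis; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info(
        "fetalsurf %s | seed=%d | config=%s",
        fetalsurf.__version__, config.seed, _config_hash(config),
    )

    scans_p = out / "scans.csv"
    metrics_p = out / "metrics.csv"
    outcomes_p = out / "outcomes.csv"
    charts_p = out / "charts"
    z_p = out / "z.csv"
    dz_p = out / "delta_z.csv"
    group_p = out / "group_results.csv"
    dz_group_p = out / "delta_z_results.csv"
    glm1_p = out / "outcome_glm1.csv"
    glm2_p = out / "outcome_glm2.csv"

    def stage(name, outputs, inputs, fn):
        if _fresh(outputs, inputs):
            log.info("stage %-12s skipped (outputs up to date)", name)
            return
        try:
            fn()
        except Exception as err:  # noqa: BLE001 - name the failing stage
            raise StageError(f"stage {name!r} failed: {err}") from err
        log.info("stage %-12s done -> %s", name, ", ".join(str(p) for p in outputs))

    def do_simulate():
        sim = SimulationConfig(**config.simulation).with_(seed=config.seed)
        scans, metrics, outcomes = simulate_cohort(sim)
        fio.write_table(scans.drop(columns=["z_affected_mean"]), scans_p)
        fio.write_table(metrics, metrics_p)
        fio.write_table(outcomes, outcomes_p)
        log.info("simulated %d scans, %d metric rows, %d outcomes",
                 len(scans), len(metrics), len(outcomes))

    stage("simulate", [scans_p, metrics_p, outcomes_p], [], do_simulate)

    def do_charts():
        scans = fio.read_table(scans_p)
        metrics = fio.read_table(metrics_p)
        charts = fit_all_charts(scans_df=scans, metrics_df=metrics,
                                metrics=list(config.metrics))
        save_charts(charts, charts_p)
        log.info("fitted %d charts", len(charts))

    stage("fit-norm", [charts_p], [scans_p, metrics_p], do_charts)

    def do_z():
        scans = fio.read_table(scans_p)
        metrics = fio.read_table(metrics_p)
        charts = load_charts(charts_p)
        z = score_table(charts, metrics, scans, include_noise=config.z_include_noise)
        fio.write_table(z, z_p)
        fio.write_table(delta_z_table(z), dz_p)
        log.info("scored %d scan x region x metric rows", len(z))

    stage("zscores", [z_p, dz_p], [scans_p, metrics_p, charts_p], do_z)

    def do_group():
        z = fio.read_table(z_p)
        frames = [
            fit_group_model(z, stratum=s, family_size=config.family_size,
                            robust=config.robust)
            for s in ("scan1", "scan2", "ga_lt_30", "ga_ge_30")
        ]
        import pandas as pd

        fio.write_table(pd.concat(frames, ignore_index=True), group_p)
        dz = fio.read_table(dz_p)
        fio.write_table(
            delta_z_group_test(dz, family_size=config.family_size,
                               robust=config.robust),
            dz_group_p,
        )

    stage("group-test", [group_p, dz_group_p], [z_p, dz_p], do_group)

    def do_outcome():
        z = fio.read_table(z_p)
        outcomes = fio.read_table(outcomes_p)
        fio.write_table(
            fit_outcome_models(z, outcomes, model="GLM1",
                               family_size=config.family_size), glm1_p
        )
        fio.write_table(
            fit_outcome_models(z, outcomes, model="GLM2",
                               family_size=config.family_size), glm2_p
        )

    stage("outcome", [glm1_p, glm2_p], [z_p, outcomes_p], do_outcome)
    return out
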