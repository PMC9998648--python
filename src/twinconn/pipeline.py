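"""End-to-end orchestration: simulate/read -> FC -> features -> twin models -> summaries.

Every stage logs its parameters; a run manifest (YAML echo of the effective
configuration plus the seed) is written next to the outputs so any run can
be reproduced exactly.  Output files are written atomically (temp file +
rename) in the tab-separated formats of :mod:`twinconn.io_model`.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import connectivity, graph_metrics, summaries, synthetic_data, twin_models
from .io_model import (
    AAL90,
    ParcellationLabels,
    ValidationError,
    default_rsn_map,
    read_pair_manifest,
    read_roi_timeseries,
    read_rsn_map,
    write_matrix,
    write_pair_manifest,
    write_results_table,
    write_roi_timeseries,
)

__all__ = ["PipelineConfig", "StageError", "run_full_pipeline", "STAGE_EXIT_CODES"]

log = logging.getLogger("twinconn")

#: Distinct process exit code per failing stage.
STAGE_EXIT_CODES = {
    "inputs": 2,
    "simulate": 3,
    "fc": 4,
    "metrics": 5,
    "twin": 6,
    "summarize": 7,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and its exit code."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """Parameters of a full run; defaults follow the analysis conventions
    (link alpha 0.05, binarization threshold 0.5, twin alpha 0.05)."""

    out_dir: str = "twinconn_out"
    # real-data inputs (ignored when simulate=True)
    manifest_path: str | None = None
    timeseries_dir: str | None = None
    rsn_map_path: str | None = None
    # simulation inputs
    simulate: bool = False
    sim_a2: float = 0.0
    sim_c2: float = 0.0
    sim_d2: float = 0.0
    sim_e2: float = 1.0
    n_mz: int = 18
    n_dz: int = 25
    t: int = 200
    n_roi: int = 90
    n_blocks: int = 3
    r_within: float = 0.6
    link_sigma: float = 0.3
    # analysis thresholds
    alpha_link: float = 0.05
    tau: float = 0.5
    alpha_twin: float = 0.05
    require_significant_r: bool = False
    double_entry: bool = False
    seed: int = 0


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate_inputs(config: PipelineConfig, out: Path):
    parcellation = (
        AAL90
        if config.n_roi == 90
        else ParcellationLabels(tuple(f"ROI{i + 1:03d}" for i in range(config.n_roi)))
    )
    spec = synthetic_data.VarianceComponentsSpec(
        a2=config.sim_a2, c2=config.sim_c2, d2=config.sim_d2, e2=config.sim_e2
    )
    sim_cfg = synthetic_data.SimulationConfig(
        n_mz=config.n_mz, n_dz=config.n_dz, t=config.t, n_roi=config.n_roi,
        seed=config.seed,
    )
    n = config.n_roi
    edges = np.linspace(0, n, config.n_blocks + 1).astype(int)
    blocks = tuple(
        (int(lo), int(hi)) for lo, hi in zip(edges[:-1], edges[1:]) if hi - lo >= 2
    )
    base = synthetic_data.block_template(parcellation, blocks, config.r_within)
    manifest, series = synthetic_data.simulate_timeseries_cohort(
        sim_cfg, base=base, link_spec=spec, link_sigma=config.link_sigma,
        parcellation=parcellation,
    )
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    _atomic_write(out / "manifest.tsv", lambda p: write_pair_manifest(manifest, p))
    for sid, ts in series.items():
        _atomic_write(ts_dir / f"{sid}.tsv", lambda p, ts=ts: write_roi_timeseries(ts, p))
    log.info("simulated %d pairs, %d ROIs, T=%d", len(manifest.pairs), n, config.t)
    return manifest, series, parcellation


@_stage("inputs")
def _read_inputs(config: PipelineConfig):
    if config.manifest_path is None:
        raise ValidationError("manifest path is required when not simulating")
    if config.timeseries_dir is None:
        raise ValidationError("timeseries directory is required when not simulating")
    manifest = read_pair_manifest(config.manifest_path)
    parcellation = (
        AAL90
        if config.n_roi == 90
        else ParcellationLabels(tuple(f"ROI{i + 1:03d}" for i in range(config.n_roi)))
    )
    ts_dir = Path(config.timeseries_dir)
    series = {}
    for sid in manifest.subject_ids:
        path = ts_dir / f"{sid}.tsv"
        if not path.exists():
            raise ValidationError(f"missing time-series file for subject {sid}: {path}")
        series[sid] = read_roi_timeseries(path, parcellation, subject_id=sid)
    return manifest, series, parcellation


@_stage("fc")
def _fc_stage(config: PipelineConfig, series, out: Path):
    fc_dir = out / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)
    cohort = {}
    for sid, ts in series.items():
        weighted, binary = connectivity.fc_pipeline(
            ts, alpha=config.alpha_link, tau=config.tau
        )
        cohort[sid] = (weighted, binary)
        _atomic_write(
            fc_dir / f"{sid}_weighted.tsv", lambda p, w=weighted: write_matrix(w, p)
        )
        _atomic_write(
            fc_dir / f"{sid}_binary.tsv", lambda p, b=binary: write_matrix(b, p)
        )
    return cohort


@_stage("metrics")
def _metrics_stage(config: PipelineConfig, cohort, out: Path) -> pd.DataFrame:
    features = graph_metrics.extract_feature_table(cohort, seed=config.seed)
    _atomic_write(
        out / "features.tsv",
        lambda p: features.to_csv(p, sep="\t", float_format="%.10g"),
    )
    return features


@_stage("twin")
def _twin_stage(config: PipelineConfig, features, manifest, out: Path) -> pd.DataFrame:
    results = twin_models.run_twin_analysis(
        features,
        manifest,
        alpha=config.alpha_twin,
        require_significant_r=config.require_significant_r,
        double_entry=config.double_entry,
    )
    _atomic_write(out / "results.tsv", lambda p: write_results_table(results, p))
    return results


@_stage("summarize")
def _summary_stage(config: PipelineConfig, results, parcellation, out: Path):
    if config.rsn_map_path is not None:
        rsn_map = read_rsn_map(config.rsn_map_path, parcellation)
    elif len(parcellation) == 90 and parcellation.labels == AAL90.labels:
        rsn_map = default_rsn_map(parcellation)
    else:
        log.info("no RSN map for a non-default parcellation; skipping RSN summary")
        return None
    table = summaries.rsn_effect_percentages(results, rsn_map)
    _atomic_write(
        out / "rsn_summary.tsv",
        lambda p: table.to_csv(p, sep="\t", index=False, float_format="%.10g"),
    )
    return table


def run_full_pipeline(config: PipelineConfig):
    """Execute every stage and return (results table, RSN summary or None).

    All outputs land under ``config.out_dir``; a ``run_manifest.yaml``
    echoing the configuration is written first so failed runs are equally
    reproducible.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write(
        out / "run_manifest.yaml",
        lambda p: p.write_text(yaml.safe_dump(asdict(config), sort_keys=True)),
    )
    if config.simulate:
        manifest, series, parcellation = _simulate_inputs(config, out)
    else:
        manifest, series, parcellation = _read_inputs(config)
    cohort = _fc_stage(config, series, out)
    features = _metrics_stage(config, cohort, out)
    results = _twin_stage(config, features, manifest, out)
    rsn_table = _summary_stage(config, results, parcellation, out)
    log.info("pipeline complete: %d features analyzed", len(results))
    return results, rsn_table
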