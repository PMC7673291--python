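"""Readers, writers, pipeline orchestration and reproducibility plumbing.

File conventions: comma-separated UTF-8 CSV with a mandatory header and '.'
decimals; germination times in minutes, trace times in hours, ages in days
(unit suffixes embedded in the column names); glucose in % w/v; landscapes
as TSV matrices with a JSON sidecar carrying bin edges, counts and flags;
configs as YAML. Every pipeline artifact is recorded in a manifest with the
seed and a sha256 checksum so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import TraceSeries
from .records import MANDATORY_COLUMNS, RECORD_COLUMNS, frame_to_records, records_to_frame

logger = logging.getLogger("sporelife")

__all__ = [
    "PipelineConfig",
    "read_config",
    "read_records",
    "read_traces",
    "run_pipeline",
    "write_config",
    "write_landscape",
    "write_records",
    "write_traces",
]


# --------------------------------------------------------------------------
# records


def write_records(records, path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def read_records(path):
    """Read spore-bag records from CSV.

    Raises a schema error naming any missing mandatory column and a
    row-level error (citing the row index) for unparseable numerics.
    Unknown columns are preserved as opaque metadata.
    """
    frame = pd.read_csv(path, dtype=object)
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"records file {path}: missing mandatory column {col!r}")
    numeric_cols = [
        c
        for c in frame.columns
        if c in RECORD_COLUMNS and c not in ("bag_id", "condition", "germinated", "primed")
    ]
    for col in numeric_cols:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            raise ValueError(
                f"records file {path}: column {col!r} unparseable at row(s) "
                f"{[int(i) for i in bad[:5]]}"
            ) from None
    for col in ("germinated", "primed"):
        if col in frame.columns:
            frame[col] = (
                frame[col].astype(str).str.lower().map({"true": True, "false": False})
            )
    records = frame_to_records(frame)
    logger.info("read %d record(s) from %s", len(records), path)
    return records


# --------------------------------------------------------------------------
# traces (long format: bag_id, time_h, fluor_au + per-bag metadata)


def write_traces(traces, path) -> None:
    rows = []
    for tr in traces:
        for t, f in zip(tr.times_h, tr.fluor_au):
            rows.append(
                {
                    "bag_id": tr.bag_id,
                    "time_h": t,
                    "fluor_au": f,
                    "baseline_au": tr.baseline_au,
                    "background_au": tr.background_au,
                    "germination_time_h": tr.germination_time_h,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path) -> list:
    frame = pd.read_csv(path)
    for col in ("bag_id", "time_h", "fluor_au", "baseline_au"):
        if col not in frame.columns:
            raise ValueError(f"traces file {path}: missing mandatory column {col!r}")
    traces = []
    for bag_id, group in frame.groupby("bag_id", sort=False):
        group = group.sort_values("time_h")
        germ = group["germination_time_h"].iloc[0] if "germination_time_h" in group else None
        if germ is not None and pd.isna(germ):
            germ = None
        traces.append(
            TraceSeries(
                bag_id=str(bag_id),
                times_h=group["time_h"].to_numpy(float),
                fluor_au=group["fluor_au"].to_numpy(float),
                baseline_au=float(group["baseline_au"].iloc[0]),
                background_au=float(group["background_au"].iloc[0])
                if "background_au" in group
                else 0.0,
                germination_time_h=float(germ) if germ is not None else None,
            )
        )
    return traces


# --------------------------------------------------------------------------
# landscape (TSV matrix + JSON sidecar)


def write_landscape(grid, path) -> None:
    """Write the probability matrix as TSV plus a JSON sidecar with bin
    edges, counts and reliability flags."""
    path = Path(path)
    frame = pd.DataFrame(
        grid.prob,
        index=pd.Index(grid.glucose_levels, name="glucose_pct"),
        columns=[f"bin_{i}" for i in range(grid.prob.shape[1])],
    )
    frame.to_csv(path, sep="\t")
    sidecar = {
        "marker_name": grid.marker_name,
        "glucose_levels": [float(g) for g in grid.glucose_levels],
        "bin_edges": [float(e) for e in grid.bin_edges],
        "counts": grid.counts.tolist(),
        "reliable": grid.reliable.astype(bool).tolist(),
        "n_replicates": None
        if grid.n_replicates is None
        else np.asarray(grid.n_replicates).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


# --------------------------------------------------------------------------
# config


def write_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path):
    from .synthetic import GeneratorConfig

    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Which stages to run and where to put the outputs."""

    output_dir: str
    seed: int = 0
    generator: Optional[object] = None  # GeneratorConfig; defaults applied at run
    run_generate: bool = False
    run_landscape: bool = False
    run_kinetics: bool = False
    run_simulate: bool = False
    run_priming: bool = False
    landscape_marker: str = "gfp_inducibility"
    simulate_days: tuple = (0, 4, 8, 12, 16, 20, 24, 28, 32, 36, 40)
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages and write a manifest.

    Stage order: generate -> landscape -> kinetics -> simulate -> priming.
    Later stages consume the outputs of the generate stage, so they enable
    it implicitly. The manifest records inputs, seed, package version and
    output checksums; a rerun with the same manifest settings reproduces
    byte-identical outputs.
    """
    from . import deathmodel, kinetics, landscape, priming, synthetic

    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator or synthetic.GeneratorConfig(seed=config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "generator": gen.to_dict(),
        "stages": [],
        "outputs": {},
    }

    def record_output(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        needs_data = (
            config.run_generate
            or config.run_landscape
            or config.run_kinetics
            or config.run_priming
        )
        records = None
        if needs_data:
            records = synthetic.generate_population(gen, seed=config.seed)
            path = outdir / "records.csv"
            write_records(records, path)
            record_output("records", path)
            manifest["stages"].append("generate")

        if config.run_landscape:
            grid = landscape.estimate_landscape(records, marker=config.landscape_marker)
            path = outdir / "landscape.tsv"
            write_landscape(grid, path)
            record_output("landscape", path)
            record_output("landscape_sidecar", path.with_suffix(".tsv.json"))
            manifest["stages"].append("landscape")

        if config.run_kinetics:
            _, traces = synthetic.generate_trace_cohort(gen, 38, 32, seed=config.seed)
            tpath = outdir / "traces.csv"
            write_traces(traces, tpath)
            record_output("traces", tpath)
            fits = kinetics.fit_trace_cohort(traces)
            fpath = outdir / "trace_fits.csv"
            fits.to_csv(fpath, index=False)
            record_output("trace_fits", fpath)
            manifest["stages"].append("kinetics")

        if config.run_simulate:
            params = deathmodel.DeathModelParams(
                species=deathmodel.default_two_species(),
                n_spores=1000,
                seed=config.seed,
            )
            result = deathmodel.ThresholdDeathModel(params).simulate(config.simulate_days)
            spath = outdir / "survival.csv"
            pd.DataFrame(
                {"day": result.sample_days, "fraction_alive": result.survival}
            ).to_csv(spath, index=False)
            record_output("survival", spath)
            dpath = outdir / "death_days.csv"
            pd.DataFrame({"death_day": result.death_days}).to_csv(dpath, index=False)
            record_output("death_days", dpath)
            manifest["stages"].append("simulate")

        if config.run_priming:
            ds = synthetic.generate_priming_dataset(gen, delay_h=16.0, seed=config.seed)
            stat = priming.relative_delta_tau(
                ds.primed_times_min, ds.unprimed_times_min, seed=config.seed
            )
            ratios = priming.module_expression_ratio(
                ds.expr_primed, ds.expr_unprimed, ds.module_map
            )
            ppath = outdir / "priming.json"
            ppath.write_text(
                json.dumps(
                    {
                        "delta_tau_min": stat.delta_tau_min,
                        "relative_delta_tau": stat.relative_delta_tau,
                        "ci": [stat.ci_low, stat.ci_high],
                    },
                    indent=1,
                )
            )
            record_output("priming", ppath)
            rpath = outdir / "module_ratios.tsv"
            ratios.ratio.to_csv(rpath, sep="\t")
            record_output("module_ratios", rpath)
            manifest["stages"].append("priming")
    except Exception as err:  # halt with a partial-output manifest
        manifest["error"] = repr(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
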