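"""Pipeline orchestration and the run manifest.

`run_pipeline` executes the configured stages in dependency order and writes
a plain-text/CSV report bundle. Every output directory gets a
``manifest.json`` recording the tool version, a hash of the configuration,
hashes of every input file, and the seeds used, so identical inputs produce
identical bundles (modulo the timestamp field).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .correlation import correlation_frame, correlation_table, permanova_table
from .data_model import Tank
from .errors import AnsbrError, MissingInputError
from .io import (
    read_asv_inputs,
    read_measurements,
    read_operations,
    read_psd,
    read_settling,
)
from .microbiome import (
    alpha_diversity,
    core_microbiome,
    pcoa,
    rarefy,
    relative_abundance,
    unifrac_distance_matrix,
)
from .process_metrics import compute_performance_series, phase_aggregate, phase_summary_frame
from .settling import fit_vesilind, psd_fractions, settling_distance_summary

logger = logging.getLogger(__name__)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(paths: dict, key: str) -> Path:
    if key not in paths:
        raise MissingInputError(f"configuration lacks required input {key!r}")
    p = Path(paths[key])
    if not p.exists():
        raise MissingInputError(f"input file not found: {p}")
    return p


def run_pipeline(config: dict, out_dir: str | Path, seed: Optional[int] = None) -> dict:
    """Run every stage for which inputs are configured; write a report bundle.

    Returns the manifest dict. Stages whose inputs are absent from the
    configuration are skipped and listed under ``manifest["gaps"]``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    params = config.get("parameters", {})
    reactor = config["reactor"]
    phases = config["phases"]
    manifest: dict = {
        "tool": "ansbr",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
        ).hexdigest()[:16],
        "input_hashes": {},
        "outputs": [],
        "gaps": [],
    }

    def record(path: Path) -> None:
        manifest["input_hashes"][str(path)] = _hash_file(path)

    def emit(df: pd.DataFrame, name: str, **kwargs) -> None:
        df.to_csv(out / name, **kwargs)
        manifest["outputs"].append(name)

    series = None
    if "measurements" in inputs and "operations" in inputs:
        mpath = _require(inputs, "measurements")
        opath = _require(inputs, "operations")
        record(mpath)
        record(opath)
        records = read_measurements(mpath)
        operations = read_operations(opath)
        ref = Tank(params.get("acidification_reference_tank", "influent"))
        series = compute_performance_series(
            records, operations, reactor, acidification_reference_tank=ref
        )
        emit(series, "performance_series.csv")
        emit(phase_summary_frame(phase_aggregate(series, phases)), "phase_summary.csv", index=False)
    else:
        manifest["gaps"].append("metrics: measurements/operations not configured")

    zsv_series = None
    if "settling" in inputs:
        spath = _require(inputs, "settling")
        record(spath)
        observations = read_settling(spath)
        column_height = float(params.get("settling_column_height", 40.0))
        rows = []
        for obs in observations:
            summary = settling_distance_summary(obs, column_height=column_height)
            rows.append(
                {
                    "day": obs.day, "X": obs.sludge_concentration_X,
                    "zsv": obs.measured_zsv, "degenerate": summary.degenerate,
                    "total_fraction": summary.total_fraction,
                    **{f"frac_{int(c)}min": f for c, f in zip(summary.checkpoint_min, summary.fractions)},
                }
            )
        emit(pd.DataFrame(rows), "settling_summary.csv", index=False)
        pairs = [
            (o.sludge_concentration_X, o.measured_zsv)
            for o in observations if o.measured_zsv is not None
        ]
        if len({p[0] for p in pairs}) >= 2:
            fit = fit_vesilind(pairs)
            emit(
                pd.DataFrame(
                    [{"v0_m_per_h": fit.v0, "k_L_per_gTSS": fit.k,
                      "n_points": fit.n_points, "r_squared": fit.r_squared}]
                ),
                "vesilind_fit.csv", index=False,
            )
        zsv_series = pd.Series(
            {o.day: o.measured_zsv for o in observations if o.measured_zsv is not None},
            name="zsv",
        )
    else:
        manifest["gaps"].append("settling: not configured")

    if "psd" in inputs:
        ppath = _require(inputs, "psd")
        record(ppath)
        rows = [
            {"day": rec.day, **psd_fractions(rec)} for rec in read_psd(ppath)
        ]
        emit(pd.DataFrame(rows), "psd_fractions.csv", index=False)

    dm = None
    covariates = None
    if all(k in inputs for k in ("counts", "taxonomy", "tree")):
        cpath = _require(inputs, "counts")
        tpath = _require(inputs, "taxonomy")
        trpath = _require(inputs, "tree")
        for p in (cpath, tpath, trpath):
            record(p)
        table, taxonomy, tree = read_asv_inputs(
            cpath, tpath, trpath, orientation=params.get("counts_orientation", "asv_rows")
        )
        depth = int(params.get("rarefaction_depth", 50_000))
        rarefied = rarefy(table, depth=depth, seed=seed)
        div = alpha_diversity(rarefied)
        emit(div.per_sample, "alpha_diversity.csv")
        emit(relative_abundance(rarefied, taxonomy, "genus"), "relative_abundance_genus.csv")
        dm = unifrac_distance_matrix(tree, rarefied)
        emit(dm.to_frame(), "unifrac_distance.csv")
        ord_res = pcoa(dm, n_axes=2)
        emit(
            pd.DataFrame(
                ord_res.coordinates, index=list(ord_res.sample_ids), columns=["PC1", "PC2"]
            ),
            "pcoa_coordinates.csv",
        )
        core = core_microbiome(
            rarefied,
            n_resamples=int(params.get("core_resamples", 1000)),
            threshold=float(params.get("core_threshold", 0.95)),
            seed=seed,
        )
        emit(
            pd.DataFrame(
                sorted(
                    ({"asv_id": a, "prevalence_fraction": f, "core": a in core.core_asv_ids}
                     for a, f in core.prevalence_fraction.items()),
                    key=lambda r: -r["prevalence_fraction"],
                )
            ),
            "core_microbiome.csv", index=False,
        )
        if "covariates" in inputs:
            covpath = _require(inputs, "covariates")
            record(covpath)
            covariates = pd.read_csv(covpath, index_col=0)
    else:
        manifest["gaps"].append("microbiome: counts/taxonomy/tree not configured")

    if series is not None:
        series_map = {c: series[c].dropna() for c in series.columns if series[c].notna().sum() >= 3}
        if zsv_series is not None and zsv_series.notna().sum() >= 3:
            series_map["zsv"] = zsv_series
        outputs = [c for c in ("tcod_removal", "scod_removal", "zsv") if c in series_map]
        results = correlation_table(series_map, outputs)
        emit(correlation_frame(results), "correlation_table.csv", index=False)
    else:
        manifest["gaps"].append("correlate: no performance series")

    if dm is not None and covariates is not None:
        emit(
            permanova_table(dm, covariates, seed=seed,
                            n_permutations=int(params.get("permanova_permutations", 999))),
            "permanova_table.csv", index=False,
        )
    elif dm is not None:
        manifest["gaps"].append("permanova: no per-sample covariates configured")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
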