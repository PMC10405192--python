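"""Readers and writers for the external file formats.

Everything on disk is plain text: measurements, settling tests and PSDs as
CSV; ASV counts and taxonomy as TSV; the phylogeny as newick; run
configuration as YAML. Tabular parsing goes through pandas and the tree
through scikit-bio's newick reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .data_model import (
    ANALYTE_UNITS,
    Analyte,
    ASVTable,
    MeasurementRecord,
    PhaseDefinition,
    PSDRecord,
    ReactorConfig,
    SettlingObservation,
    SizeFraction,
    Tank,
    Taxonomy,
    TAXONOMY_RANKS,
    validate_phases,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("day", "tank", "analyte", "size_fraction", "value", "hour_in_cycle")


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurements CSV into typed records.

    Required columns: day, tank, analyte, value. Optional: size_fraction,
    hour_in_cycle, units (validated against the analyte's fixed unit if
    present). Unknown extra columns are ignored with a warning; rows with a
    missing value are skipped with a warning; unknown analytes or negative
    values raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    required = {"day", "tank", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - set(MEASUREMENT_COLUMNS) - {"units"}
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))

    records: list[MeasurementRecord] = []
    for i, row in df.iterrows():
        if pd.isna(row["value"]):
            logger.warning("%s row %d: missing value, skipped", path, i)
            continue
        try:
            analyte = Analyte(str(row["analyte"]))
        except ValueError:
            raise ValidationError(f"{path} row {i}: unknown analyte {row['analyte']!r}")
        try:
            tank = Tank(str(row["tank"]))
        except ValueError:
            raise ValidationError(f"{path} row {i}: unknown tank {row['tank']!r}")
        if "units" in df.columns and not pd.isna(row["units"]):
            expected = ANALYTE_UNITS[analyte]
            if str(row["units"]) != expected:
                raise ValidationError(
                    f"{path} row {i}: units {row['units']!r} != fixed unit "
                    f"{expected!r} for {analyte.value}"
                )
        frac = SizeFraction.total
        if "size_fraction" in df.columns and not pd.isna(row.get("size_fraction")):
            frac = SizeFraction(str(row["size_fraction"]))
        hour = None
        if "hour_in_cycle" in df.columns and not pd.isna(row.get("hour_in_cycle")):
            hour = int(row["hour_in_cycle"])
        value = float(row["value"])
        if value < 0:
            raise ValidationError(f"{path} row {i}: negative value {value}")
        records.append(
            MeasurementRecord(
                day=float(row["day"]), tank=tank, analyte=analyte,
                value=value, size_fraction=frac, hour_in_cycle=hour,
            )
        )
    return records


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    rows = [
        {
            "day": r.day,
            "tank": r.tank.value,
            "analyte": r.analyte.value,
            "size_fraction": r.size_fraction.value,
            "value": r.value,
            "hour_in_cycle": r.hour_in_cycle,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(path, index=False)


def read_settling(path: str | Path) -> list[SettlingObservation]:
    """Read settling tests from CSV (day, X, time_min, interface_depth[, zsv])."""
    df = pd.read_csv(path)
    required = {"day", "X", "time_min", "interface_depth"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    observations = []
    for (day, X), grp in df.groupby(["day", "X"], sort=True):
        grp = grp.sort_values("time_min")
        zsv = None
        if "zsv" in grp.columns and grp["zsv"].notna().any():
            zsv = float(grp["zsv"].dropna().iloc[0])
        observations.append(
            SettlingObservation(
                day=float(day),
                sludge_concentration_X=float(X),
                trajectory=tuple(zip(grp["time_min"].astype(float), grp["interface_depth"].astype(float))),
                measured_zsv=zsv,
            )
        )
    return observations


def write_settling(observations: Sequence[SettlingObservation], path: str | Path) -> None:
    rows = []
    for obs in observations:
        for t, d in obs.trajectory:
            rows.append(
                {
                    "day": obs.day, "X": obs.sludge_concentration_X,
                    "time_min": t, "interface_depth": d, "zsv": obs.measured_zsv,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_psd(path: str | Path) -> list[PSDRecord]:
    """Read particle-size distributions from CSV (day, diameter_um, volume_fraction)."""
    df = pd.read_csv(path)
    required = {"day", "diameter_um", "volume_fraction"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    records = []
    for day, grp in df.groupby("day", sort=True):
        grp = grp.sort_values("diameter_um")
        records.append(
            PSDRecord(
                day=float(day),
                distribution=tuple(
                    zip(grp["diameter_um"].astype(float), grp["volume_fraction"].astype(float))
                ),
            )
        )
    return records


OPERATION_COLUMNS = (
    "day", "influent_tcod", "fed_volume", "reactor_vss_mass", "wasted_sludge", "total_sludge"
)


def read_operations(path: str | Path) -> list["DailyOperation"]:
    """Read daily operational bookkeeping (feed, sludge inventory) from CSV."""
    from .data_model import DailyOperation

    df = pd.read_csv(path)
    missing = set(OPERATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        DailyOperation(**{c: float(row[c]) for c in OPERATION_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_operations(operations, path: str | Path) -> None:
    rows = [{c: getattr(op, c) for c in OPERATION_COLUMNS} for op in operations]
    pd.DataFrame(rows, columns=list(OPERATION_COLUMNS)).to_csv(path, index=False)


def _parse_lineage(lineage: str) -> dict[str, Optional[str]]:
    """Parse a 'k__...;p__...;c__...' style lineage string into ranks."""
    prefix_to_rank = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}
    out: dict[str, Optional[str]] = {r: None for r in TAXONOMY_RANKS}
    for token in str(lineage).split(";"):
        token = token.strip()
        if len(token) >= 3 and token[1:3] == "__":
            rank = prefix_to_rank.get(token[0].lower())
            label = token[3:].strip()
            if rank and label:
                out[rank] = label
    return out


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy TSV.

    Accepts either per-rank columns (phylum..genus) or a single lineage
    column named 'Taxon'/'taxonomy'/'lineage' in 'k__;p__;...' form. The
    first column holds the ASV id.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy needs an id column plus ranks or a lineage")
    id_col = df.columns[0]
    lineage_cols = [c for c in df.columns if c.lower() in ("taxon", "taxonomy", "lineage")]
    assignments: dict[str, dict[str, Optional[str]]] = {}
    for _, row in df.iterrows():
        asv = str(row[id_col])
        if asv in assignments:
            raise ValidationError(f"{path}: duplicate ASV id {asv!r}")
        if lineage_cols:
            assignments[asv] = _parse_lineage(row[lineage_cols[0]])
        else:
            assignments[asv] = {
                r: (None if pd.isna(row.get(r)) else str(row.get(r)) or None)
                for r in TAXONOMY_RANKS
            }
    return Taxonomy(assignments)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        {"asv_id": asv, **{r: ranks.get(r) for r in TAXONOMY_RANKS}}
        for asv, ranks in taxonomy.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, orientation: str = "asv_rows") -> ASVTable:
    """Read an ASV count TSV.

    ``orientation`` declares the layout: 'asv_rows' (default; rows are ASVs,
    columns are samples) or 'sample_rows'.
    """
    if orientation not in ("asv_rows", "sample_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse counts TSV {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: counts table is empty")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate row ids {dupes[:5]}")
    if orientation == "asv_rows":
        df = df.T  # -> samples x ASVs
    return ASVTable(
        sample_ids=[str(s) for s in df.index],
        asv_ids=[str(a) for a in df.columns],
        counts=df.to_numpy(),
    )


def write_counts(table: ASVTable, path: str | Path, orientation: str = "asv_rows") -> None:
    df = table.to_frame()
    if orientation == "asv_rows":
        df = df.T
        df.index.name = "asv_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; negative branch lengths are rejected."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse newick tree {path}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is not None and (not np.isfinite(node.length) or node.length < 0):
            raise ValidationError(f"{path}: invalid branch length {node.length}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_asv_inputs(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    tree_path: str | Path,
    orientation: str = "asv_rows",
) -> tuple[ASVTable, Taxonomy, TreeNode]:
    """Load the count table, taxonomy and phylogeny and cross-check ids.

    ASVs present in the counts but absent from the tree or taxonomy are
    reported with a warning (UniFrac will refuse them later; purely
    taxonomic analyses still work).
    """
    table = read_counts(counts_path, orientation=orientation)
    taxonomy = read_taxonomy(taxonomy_path)
    tree = read_tree(tree_path)
    tips = {tip.name for tip in tree.tips()}
    missing_in_tree = sorted(set(table.asv_ids) - tips)
    if missing_in_tree:
        logger.warning(
            "%d ASV(s) absent from the tree: %s", len(missing_in_tree), missing_in_tree[:10]
        )
    missing_in_tax = sorted(a for a in table.asv_ids if a not in taxonomy)
    if missing_in_tax:
        logger.warning(
            "%d ASV(s) absent from the taxonomy (treated as Unassigned): %s",
            len(missing_in_tax), missing_in_tax[:10],
        )
    return table, taxonomy, tree


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration.

    Returns a dict with keys 'reactor' (ReactorConfig), 'phases'
    (list of PhaseDefinition) and 'parameters' (raw analysis parameters).
    Sections that are absent fall back to the study defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reactor = ReactorConfig(**(raw.get("reactor") or {}))
    phases_raw = raw.get("phases")
    if phases_raw:
        phases = [
            PhaseDefinition(str(p["name"]), float(p["day_start"]), float(p["day_end"]))
            for p in phases_raw
        ]
    else:
        from .data_model import DEFAULT_PHASES

        phases = list(DEFAULT_PHASES)
    validate_phases(phases)
    return {
        "reactor": reactor,
        "phases": phases,
        "parameters": dict(raw.get("parameters") or {}),
        "inputs": dict(raw.get("inputs") or {}),
    }
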