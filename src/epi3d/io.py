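"""File I/O: label stacks (multi-page TIFF), tidy CSV tables, configs.

CSV dialect: comma-separated, UTF-8, mandatory header row; ID sets are
serialised as semicolon-joined integers.  Label stacks are multi-page
TIFFs with one page per apical-basal section, page 0 apical by default,
0 = background and cells labelled 1..N.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from epi3d.datatypes import (
    CellColumn,
    ColumnEntry,
    NucleusModel,
    SimulationConfig,
    SyntheticTissue,
    TubeGeometry,
)

__all__ = [
    "read_label_stack",
    "write_label_stack",
    "tissue_to_cells_df",
    "tissue_to_nuclei_df",
    "columns_from_cells_df",
    "nuclei_from_df",
    "write_tissue",
    "layer_stats_tables",
    "events_to_df",
    "transition_stats_to_dict",
    "read_boundaries",
    "read_geometry",
    "write_geometry",
    "load_simulation_config",
]


# --- label stacks ----------------------------------------------------------


def read_label_stack(path, axis_order: str = "apical_to_basal") -> np.ndarray:
    """Read a multi-page TIFF label stack, page 0 = apical after reordering.

    Raises
    ------
    ValueError
        For float pixel types, inconsistent page shapes, or an unknown
        ``axis_order`` (must be 'apical_to_basal' or 'basal_to_apical').
    """
    if axis_order not in ("apical_to_basal", "basal_to_apical"):
        raise ValueError(f"unknown axis_order {axis_order!r}")
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path}: {shapes}")
        stack = tif.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    if not np.issubdtype(stack.dtype, np.integer):
        raise ValueError(f"label stack must have integer pixels, got {stack.dtype}")
    if axis_order == "basal_to_apical":
        stack = stack[::-1]
    return stack


def write_label_stack(path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    if not np.issubdtype(stack.dtype, np.integer):
        raise ValueError("label stack must be integer-typed")
    tifffile.imwrite(str(path), stack.astype(np.int32), photometric="minisblack")


# --- tidy tables -----------------------------------------------------------


def _join_ids(ids) -> str:
    return ";".join(str(i) for i in sorted(ids))


def _split_ids(s) -> frozenset:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return frozenset()
    return frozenset(int(tok) for tok in str(s).split(";"))


def tissue_to_cells_df(tissue: SyntheticTissue) -> pd.DataFrame:
    """Tidy per-cell per-layer table (cells.csv dialect)."""
    rows = []
    for col in tissue.columns:
        for e in col.entries:
            rows.append(
                {
                    "cell_id": col.cell_id,
                    "layer": e.layer_index,
                    "z": e.z,
                    "area_um2": e.area,
                    "neighbour_ids": _join_ids(e.neighbour_ids),
                    "nuclear_area_um2": (
                        e.nuclear_area if e.nuclear_area is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def tissue_to_nuclei_df(tissue: SyntheticTissue) -> pd.DataFrame:
    rows = []
    for nuc in tissue.nuclei:
        ax, ay, az = nuc.semi_axes
        rows.append(
            {
                "cell_id": nuc.cell_id,
                "centre_z": nuc.centre_z,
                "volume_um3": nuc.volume,
                "semi_axis_x_um": ax,
                "semi_axis_y_um": ay,
                "semi_axis_z_um": az,
            }
        )
    return pd.DataFrame(rows)


def columns_from_cells_df(df: pd.DataFrame, height: float) -> list:
    """Rebuild cell columns from a cells.csv-dialect table."""
    required = {"cell_id", "layer", "z", "area_um2", "neighbour_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    columns = []
    for cid, group in df.groupby("cell_id"):
        group = group.sort_values("layer")
        entries = [
            ColumnEntry(
                layer_index=int(r.layer),
                z=float(r.z),
                area=float(r.area_um2),
                neighbour_ids=_split_ids(r.neighbour_ids),
                nuclear_area=(
                    float(r.nuclear_area_um2)
                    if "nuclear_area_um2" in df.columns
                    and not pd.isna(r.nuclear_area_um2)
                    else None
                ),
            )
            for r in group.itertuples()
        ]
        columns.append(CellColumn(cell_id=int(cid), entries=entries, height=height))
    return columns


def nuclei_from_df(df: pd.DataFrame) -> list:
    return [
        NucleusModel(
            cell_id=int(r.cell_id),
            centre_z=float(r.centre_z),
            semi_axes=(
                float(r.semi_axis_x_um),
                float(r.semi_axis_y_um),
                float(r.semi_axis_z_um),
            ),
        )
        for r in df.itertuples()
    ]


def write_tissue(tissue: SyntheticTissue, outdir) -> dict:
    """Write label stacks and tidy tables for a generated tissue.

    Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["cells_csv"] = outdir / "cells.csv"
    tissue_to_cells_df(tissue).to_csv(paths["cells_csv"], index=False)
    if tissue.nuclei:
        paths["nuclei_csv"] = outdir / "nuclei.csv"
        tissue_to_nuclei_df(tissue).to_csv(paths["nuclei_csv"], index=False)
    if tissue.cell_labels is not None:
        paths["cell_labels_tif"] = outdir / "cell_labels.tif"
        write_label_stack(paths["cell_labels_tif"], tissue.cell_labels)
    if tissue.nucleus_labels is not None and tissue.nuclei:
        paths["nucleus_labels_tif"] = outdir / "nucleus_labels.tif"
        write_label_stack(paths["nucleus_labels_tif"], tissue.nucleus_labels)
    return {k: str(v) for k, v in paths.items()}


# --- statistics tables -----------------------------------------------------


def layer_stats_tables(stats_list):
    """Tidy per-class and per-layer summary tables from LayerStats objects.

    Returns ``(per_class_df, summary_df)`` matching the layer_stats.csv /
    layer_summary.csv schemas.
    """
    class_rows, summary_rows = [], []
    for st in stats_list:
        for n in sorted(st.counts):
            m_n, m_sem = st.aw_table[n]
            ratio, l_sem = st.lewis_table[n]
            class_rows.append(
                {
                    "layer": st.layer_index,
                    "z": st.z,
                    "n": n,
                    "count": st.counts[n],
                    "freq": st.freq[n],
                    "m_n": m_n,
                    "m_n_sem": m_sem,
                    "lewis_ratio": ratio,
                    "lewis_ratio_sem": l_sem,
                    "low_count": n in st.low_count,
                }
            )
        summary_rows.append(
            {
                "layer": st.layer_index,
                "z": st.z,
                "n_cells": st.n_cells,
                "n_bar": st.n_bar,
                "area_cv": st.area_cv,
                "hex_fraction": st.hex_fraction,
            }
        )
    return pd.DataFrame(class_rows), pd.DataFrame(summary_rows)


def events_to_df(events) -> pd.DataFrame:
    rows = [
        {
            "cell_id": e.cell_id,
            "interface_index": e.interface_index,
            "rel_position": e.rel_position,
            "delta_n": e.delta_n,
            "gained": _join_ids(e.gained_ids),
            "lost": _join_ids(e.lost_ids),
            "delta_area": e.delta_area,
            "delta_nuclear_area": (
                e.delta_nuclear_area
                if e.delta_nuclear_area is not None
                else np.nan
            ),
        }
        for e in events
    ]
    return pd.DataFrame(rows)


def transition_stats_to_dict(ts) -> dict:
    return {
        "total": ts.total,
        "n_cells": ts.n_cells,
        "mean": ts.mean,
        "variance": ts.variance,
        "dispersion_index": ts.dispersion_index,
        "mean_rel_position": ts.mean_rel_position,
        "rel_position_ci95": list(ts.rel_position_ci95),
        "n_inter_transition_distances": len(ts.inter_transition_distances),
        "mean_inter_transition_distance_um": (
            float(np.mean(ts.inter_transition_distances))
            if ts.inter_transition_distances
            else None
        ),
        "chi2": ts.chi2,
        "dof": ts.dof,
        "p_value": ts.p_value,
    }


# --- geometry and configs --------------------------------------------------


def read_boundaries(path) -> pd.DataFrame:
    """Read boundaries.csv: surface ∈ {apical, basal}, section_index, x, y."""
    df = pd.read_csv(path)
    required = {"surface", "section_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"boundaries table missing columns: {sorted(missing)}")
    bad = set(df["surface"].unique()) - {"apical", "basal"}
    if bad:
        raise ValueError(f"unknown surface values: {sorted(bad)}")
    return df


def read_geometry(path) -> TubeGeometry:
    with open(path) as fh:
        d = json.load(fh)
    return TubeGeometry(
        a_apical=d["a_apical"],
        b_apical=d["b_apical"],
        a_basal=d["a_basal"],
        b_basal=d["b_basal"],
    )


def write_geometry(geom: TubeGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(geom), fh, indent=2)


def load_simulation_config(path, **overrides) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON (field names 1:1)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    data.update(overrides)
    return SimulationConfig(**data)
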