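"""End-to-end pipeline: simulate / load → layer stats → T1 → curvature → nuclei.

The pipeline consumes either a synthetic-tissue configuration or
pre-existing inputs (label stacks or tidy tables), runs every applicable
analysis stage, writes the stage tables under the output directory and
returns a single ``report.json``-style dict of headline statistics.  Given
a fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from epi3d import io
from epi3d.curvature import event_fold_changes, fold_change_summary
from epi3d.datatypes import SimulationConfig, TubeGeometry
from epi3d.layers import build_layer, layer_stats
from epi3d.synthetic import generate_tissue
from epi3d.t1 import detect_t1, transition_stats
from epi3d.theory import theory_curves

log = logging.getLogger("epi3d")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "epi3d_out"
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    cells_csv: Optional[str] = None
    label_stack: Optional[str] = None
    axis_order: str = "apical_to_basal"
    pixel_size: float = 1.0  # µm, for label-stack input
    tissue_height: float = 25.0  # µm
    periodic: bool = False
    min_contact: int = 2
    interior_only: bool = True
    law: str = "lewis_linear"
    geometry: Optional[TubeGeometry] = None
    theory_cv_grid: int = 25

    def __post_init__(self):
        if self.pixel_size <= 0 or self.tissue_height <= 0:
            raise ValueError("pixel and tissue sizes must be positive")
        sources = [self.simulate, self.cells_csv, self.label_stack]
        if all(s is None for s in sources):
            raise ValueError(
                "RunConfig needs one input: simulate, cells_csv or label_stack"
            )
        for path in (self.cells_csv, self.label_stack):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; return the report dict.

    Raises a ``RuntimeError`` naming the failing stage on any error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    stage = "input"
    try:
        layers, columns, nuclei = None, None, []
        if config.simulate is not None:
            stage = "simulate"
            _stage(stage)
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            tissue = generate_tissue(sim)
            io.write_tissue(tissue, outdir)
            layers, columns, nuclei = tissue.layers, tissue.columns, tissue.nuclei
            height = sim.tissue_height
            periodic = sim.periodic
        elif config.cells_csv is not None:
            stage = "load_tables"
            _stage(stage)
            df = pd.read_csv(config.cells_csv)
            columns = io.columns_from_cells_df(df, height=config.tissue_height)
            height = config.tissue_height
            periodic = config.periodic
        else:
            stage = "load_labels"
            _stage(stage)
            stack = io.read_label_stack(config.label_stack, config.axis_order)
            n_layers = stack.shape[0]
            zs = (
                np.arange(n_layers) / (n_layers - 1)
                if n_layers > 1
                else np.zeros(1)
            )
            layers = [
                build_layer(
                    stack[i],
                    pixel_size=config.pixel_size,
                    z=float(zs[i]),
                    layer_index=i,
                    min_contact=config.min_contact,
                    periodic=config.periodic,
                )
                for i in range(n_layers)
            ]
            height = config.tissue_height
            periodic = config.periodic

        if layers is not None:
            stage = "layer_morphometrics"
            _stage(stage)
            stats_list = [layer_stats(layer) for layer in layers]
            per_class, summary = io.layer_stats_tables(stats_list)
            per_class.to_csv(outdir / "layer_stats.csv", index=False)
            summary.to_csv(outdir / "layer_summary.csv", index=False)
            report["layers"] = {
                "n_layers": len(stats_list),
                "n_bar": [s.n_bar for s in stats_list],
                "area_cv": [s.area_cv for s in stats_list],
                "hex_fraction": [s.hex_fraction for s in stats_list],
            }

        if columns is not None:
            stage = "t1_dynamics"
            _stage(stage)
            events = [e for col in columns for e in detect_t1(col)]
            io.events_to_df(events).to_csv(outdir / "t1_events.csv", index=False)
            ts = transition_stats(columns, interior_only=config.interior_only)
            stats_dict = io.transition_stats_to_dict(ts)
            with open(outdir / "t1_stats.json", "w") as fh:
                json.dump(stats_dict, fh, indent=2)
            report["t1"] = stats_dict

            if config.geometry is not None:
                stage = "curvature_model"
                _stage(stage)
                folds = event_fold_changes(
                    columns, config.geometry, interior_only=config.interior_only
                )
                pd.DataFrame(folds).to_csv(
                    outdir / "fold_changes.csv", index=False
                )
                io.write_geometry(config.geometry, outdir / "geometry.json")
                report["curvature"] = {
                    "n_segments": len(folds),
                    "by_n": fold_change_summary(folds),
                }

        if nuclei:
            stage = "nuclear_ikm"
            _stage(stage)
            from epi3d.nuclear import (
                cell_nucleus_correlation,
                ellipticity_from_semi_axes,
                ellipticity_position_test,
            )
            from epi3d.datatypes import NuclearMorphometry

            morph = [
                NuclearMorphometry(
                    cell_id=nuc.cell_id,
                    volume=nuc.volume,
                    ellipticity=ellipticity_from_semi_axes(nuc.semi_axes),
                    centre_z=nuc.centre_z,
                    semi_axes=nuc.semi_axes,
                )
                for nuc in nuclei
            ]
            r_vol, r_area, n_vol, n_area = cell_nucleus_correlation(
                columns, morph
            )
            nuc_report = {
                "n_nuclei": len(morph),
                "r_volume": r_vol,
                "r_area": r_area,
                "n_volume_pairs": n_vol,
                "n_area_pairs": n_area,
            }
            try:
                t, dof, p = ellipticity_position_test(morph)
                nuc_report["ellipticity_position_test"] = {
                    "t": t,
                    "dof": dof,
                    "p_one_sided": p,
                }
            except ValueError:
                pass  # not enough nuclei in a position group
            report["nuclei"] = nuc_report

        stage = "theory"
        _stage(stage)
        cvs = np.linspace(0.0, 0.8, config.theory_cv_grid)
        rows = theory_curves(cvs)
        pd.DataFrame(rows).to_csv(outdir / "theory_curves.csv", index=False)
        report["theory"] = {
            "laws": ["lewis_linear", "quadratic"],
            "cv_grid": [float(c) for c in cvs],
        }

        stage = "report"
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return report
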