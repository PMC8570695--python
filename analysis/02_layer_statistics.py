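#!/usr/bin/env python
"""Per-layer polygonal lattice statistics of the synthetic tissue.

Checks the classic organisation laws layer by layer: the toroidal Euler
requirement (mean neighbour number 6), the Aboav-Weaire law
m(n) = 5 + 8/n, the Lewis area-class relations, and the hexagon fraction
against its theoretical dependence on the per-layer area CV.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epi3d import io
from epi3d.datatypes import SimulationConfig
from epi3d.layers import layer_stats
from epi3d.synthetic import generate_tissue
from epi3d.theory import aw_prediction, predict_class_distribution

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    tissue = generate_tissue(SimulationConfig(seed=SEED))
    stats_list = [layer_stats(layer) for layer in tissue.layers]
    per_class, summary = io.layer_stats_tables(stats_list)
    RESULTS.mkdir(parents=True, exist_ok=True)
    per_class.to_csv(RESULTS / "layer_stats.csv", index=False)
    summary.to_csv(RESULTS / "layer_summary.csv", index=False)

    print("layer  z      n̄      CV     hex")
    for st in stats_list:
        print(f"{st.layer_index:>5}  {st.z:.2f}  {st.n_bar:.3f}  "
              f"{st.area_cv:.3f}  {st.hex_fraction:.3f}")

    # Aboav-Weaire deviation per class, pooled over layers
    aw = per_class.groupby("n").apply(
        lambda g: np.average(g["m_n"], weights=g["count"]),
        include_groups=False,
    )
    print("\nAboav-Weaire law, pooled over layers:")
    for n, m in aw.items():
        if 4 <= n <= 8:
            print(f"  m({n}) = {m:.3f}   law: {aw_prediction(n):.3f}")

    # hexagon fraction vs CV against the theoretical curves
    rows = []
    for st in stats_list:
        for law in ("lewis_linear", "quadratic"):
            pred = predict_class_distribution(st.area_cv, law=law)
            rows.append(
                {
                    "layer": st.layer_index,
                    "cv": st.area_cv,
                    "hex_observed": st.hex_fraction,
                    "law": law,
                    "hex_predicted": pred.hex_fraction,
                }
            )
    pd.DataFrame(rows).to_csv(RESULTS / "hex_fraction_vs_cv.csv", index=False)
    obs = summary["hex_fraction"].mean()
    print(f"\nmean observed hexagon fraction {obs:.3f}; "
          "per-layer theory comparison → results/hex_fraction_vs_cv.csv")


if __name__ == "__main__":
    main()
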