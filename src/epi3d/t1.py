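"""Lateral T1 transition detection and statistics.

A lateral T1 transition (T1L) is any change in a cell's neighbour-ID set
between adjacent cross-sections along the apical-basal axis — including
partner exchanges that conserve the neighbour count (scutoid-type swaps).
The exchange point is unresolved between the two sections, so each event is
placed at the midpoint of the bounding z values.  Counts per cell are
compared against a Poisson law via the dispersion index (variance/mean,
unity under Poisson) and a Pearson chi-squared goodness-of-fit test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from epi3d.datatypes import CellColumn, T1Event, TransitionStats

__all__ = [
    "detect_t1",
    "transition_stats",
    "poisson_gof",
    "area_change_profile",
    "position_histogram",
]


def detect_t1(column: CellColumn) -> list:
    """Detect lateral T1 transitions in one cell column.

    Returns one :class:`T1Event` per adjacent-entry pair whose neighbour
    sets differ, ordered apically → basally.
    """
    if len(column.entries) < 2:
        raise ValueError(f"column {column.cell_id}: need >= 2 entries")
    events = []
    for i, (lo, hi) in enumerate(zip(column.entries, column.entries[1:])):
        if lo.neighbour_ids == hi.neighbour_ids:
            continue
        gained = frozenset(hi.neighbour_ids - lo.neighbour_ids)
        lost = frozenset(lo.neighbour_ids - hi.neighbour_ids)
        dna = None
        if lo.nuclear_area is not None or hi.nuclear_area is not None:
            dna = (hi.nuclear_area or 0.0) - (lo.nuclear_area or 0.0)
        events.append(
            T1Event(
                cell_id=column.cell_id,
                interface_index=i,
                rel_position=0.5 * (lo.z + hi.z),
                delta_n=len(hi.neighbour_ids) - len(lo.neighbour_ids),
                gained_ids=gained,
                lost_ids=lost,
                delta_area=hi.area - lo.area,
                delta_nuclear_area=dna,
            )
        )
    return events


def transition_stats(
    columns: list,
    interior_only: bool = True,
    gof: bool = True,
) -> TransitionStats:
    """Per-cell T1 counts, Poisson statistics and transition positions.

    Parameters
    ----------
    columns
        Cell columns to analyse.
    interior_only
        When computing inter-transition distances, drop the first and last
        segment of each cell (apical end → first transition and last
        transition → basal end), keeping only interior segments between
        transitions.
    gof
        Attach the chi-squared Poisson goodness of fit when at least 20
        cells are available.
    """
    if not columns:
        raise ValueError("transition_stats requires at least one column")
    counts = {}
    positions = []
    distances = []
    for col in columns:
        events = detect_t1(col)
        counts[col.cell_id] = len(events)
        positions.extend(e.rel_position for e in events)
        zs = [e.rel_position for e in events]
        bounds = [0.0] + zs + [1.0]
        gaps = np.diff(bounds) * col.height
        if interior_only:
            gaps = gaps[1:-1]  # interior segments between transitions only
        distances.extend(float(g) for g in gaps)

    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean())
    var = float(values.var(ddof=1)) if values.size > 1 else 0.0
    dispersion = var / mean if mean > 0 else 0.0

    if positions:
        pos = np.array(positions)
        mp = float(pos.mean())
        se = float(pos.std(ddof=1) / math.sqrt(pos.size)) if pos.size > 1 else 0.0
        ci = (mp - 1.96 * se, mp + 1.96 * se)
    else:
        mp, ci = float("nan"), (float("nan"), float("nan"))

    chi2 = dof = p = None
    if gof and values.size >= 20:
        try:
            chi2, dof, p = poisson_gof(counts)
        except ValueError:
            pass  # too few classes after merging; leave the fit fields empty

    return TransitionStats(
        counts_per_cell=counts,
        total=int(values.sum()),
        n_cells=len(counts),
        mean=mean,
        variance=var,
        dispersion_index=dispersion,
        mean_rel_position=mp,
        rel_position_ci95=ci,
        inter_transition_distances=distances,
        chi2=chi2,
        dof=dof,
        p_value=p,
    )


def poisson_gof(counts_per_cell) -> tuple:
    """Pearson chi-squared test of per-cell counts against Poisson(µ̂).

    µ̂ is the sample mean; tail bins are merged until every expected count
    is at least 5; degrees of freedom = bins − 2 (one for the total, one
    for the estimated mean).  Returns ``(chi2, dof, p_value)``.
    """
    values = np.asarray(
        list(counts_per_cell.values())
        if isinstance(counts_per_cell, dict)
        else counts_per_cell,
        dtype=int,
    )
    if values.size < 20:
        raise ValueError("poisson_gof requires at least 20 cells")
    mu = values.mean()
    kmax = values.max()
    ks = np.arange(kmax + 1)
    expected = stats.poisson.pmf(ks, mu) * values.size
    expected = np.append(expected, values.size - expected.sum())  # tail > kmax
    observed = np.append(np.bincount(values, minlength=kmax + 1), 0)

    # merge adjacent bins from both tails until all expected >= 5
    obs, exp = list(observed), list(expected)
    while len(exp) > 1 and exp[-1] < 5:
        e, o = exp.pop(), obs.pop()
        exp[-1] += e
        obs[-1] += o
    while len(exp) > 1 and exp[0] < 5:
        e, o = exp.pop(0), obs.pop(0)
        exp[0] += e
        obs[0] += o
    if len(exp) < 3:
        raise ValueError("fewer than 3 bins after merging; test undefined")
    obs, exp = np.array(obs, dtype=float), np.array(exp, dtype=float)
    exp *= obs.sum() / exp.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 2
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


def _interfaces(columns):
    """All adjacent-section interfaces (event or not) with their deltas."""
    rows = []
    for col in columns:
        for i, (lo, hi) in enumerate(zip(col.entries, col.entries[1:])):
            dna = None
            if lo.nuclear_area is not None or hi.nuclear_area is not None:
                dna = (hi.nuclear_area or 0.0) - (lo.nuclear_area or 0.0)
            rows.append(
                {
                    "cell_id": col.cell_id,
                    "interface_index": i,
                    "delta_area": hi.area - lo.area,
                    "delta_nuclear_area": dna,
                    "changed": lo.neighbour_ids != hi.neighbour_ids,
                    "delta_n": len(hi.neighbour_ids) - len(lo.neighbour_ids),
                }
            )
    return rows


def area_change_profile(
    columns: list,
    bins,
    source: str = "cell",
) -> list:
    """Neighbour-gain/loss frequency as a function of the area change.

    For each Δarea bin, reports the fraction of T1 events with rising,
    constant and falling neighbour number, and the same fractions computed
    over ALL adjacent-section interfaces so that they read as
    per-interface rates.  ``source`` selects the cell ('cell') or nuclear
    ('nucleus') cross-sectional area change.

    Returns a list of row dicts (bin_lo, bin_hi, bin_mid, n_interfaces,
    n_events, gain_fraction, same_fraction, loss_fraction, gain_rate,
    loss_rate, empty).
    """
    if source not in ("cell", "nucleus"):
        raise ValueError("source must be 'cell' or 'nucleus'")
    key = "delta_area" if source == "cell" else "delta_nuclear_area"
    rows = _interfaces(columns)
    if source == "nucleus":
        rows = [r for r in rows if r[key] is not None]
        if not rows:
            raise ValueError("no interfaces carry a nuclear area change")
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("bins must be a 1D array of edges with >= 2 entries")

    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [r for r in rows if lo <= r[key] < hi]
        ev = [r for r in in_bin if r["changed"]]
        n_ev = len(ev)
        gains = sum(1 for r in ev if r["delta_n"] > 0)
        same = sum(1 for r in ev if r["delta_n"] == 0)
        losses = sum(1 for r in ev if r["delta_n"] < 0)
        out.append(
            {
                "bin_lo": float(lo),
                "bin_hi": float(hi),
                "bin_mid": float(0.5 * (lo + hi)),
                "n_interfaces": len(in_bin),
                "n_events": n_ev,
                "gain_fraction": gains / n_ev if n_ev else float("nan"),
                "same_fraction": same / n_ev if n_ev else float("nan"),
                "loss_fraction": losses / n_ev if n_ev else float("nan"),
                "gain_rate": gains / len(in_bin) if in_bin else float("nan"),
                "loss_rate": losses / len(in_bin) if in_bin else float("nan"),
                "empty": not in_bin,
            }
        )
    return out


def position_histogram(events: list, n_bins: int = 10):
    """Normalised histogram of event positions along the apical-basal axis."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not events:
        raise ValueError("no events to histogram")
    pos = np.array([e.rel_position for e in events])
    hist, edges = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    frac = hist / hist.sum()
    return [
        {
            "bin_lo": float(lo),
            "bin_hi": float(hi),
            "fraction": float(f),
            "count": int(c),
        }
        for lo, hi, f, c in zip(edges[:-1], edges[1:], frac, hist)
    ]
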