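"""Lateral T1 detection, Poisson statistics and area-change profiles."""

import numpy as np
import pytest
from scipy import stats as sps

from epi3d.datatypes import CellColumn, ColumnEntry
from epi3d.synthetic import generate_poisson_columns
from epi3d.t1 import (
    area_change_profile,
    detect_t1,
    poisson_gof,
    position_histogram,
    transition_stats,
)
from conftest import make_column


class TestDetectT1:
    def test_single_exchange(self):
        col = make_column([{"A", "B", "C"}, {"A", "B", "C"}, {"A", "B", "D"}])
        events = detect_t1(col)
        assert len(events) == 1
        e = events[0]
        assert e.interface_index == 1
        assert e.gained_ids == frozenset({"D"})
        assert e.lost_ids == frozenset({"C"})
        assert e.delta_n == 0
        assert e.rel_position == pytest.approx(0.75)

    def test_constant_sets_no_events(self):
        col = make_column([{"A", "B", "C"}] * 5)
        assert detect_t1(col) == []

    def test_pure_gain(self):
        col = make_column([{"A", "B", "C"}, {"A", "B", "C", "D"}])
        events = detect_t1(col)
        assert len(events) == 1
        assert events[0].delta_n == 1
        assert events[0].gained_ids == frozenset({"D"})
        assert events[0].lost_ids == frozenset()

    def test_event_count_is_number_of_set_inequalities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sets = []
            current = {1, 2, 3}
            for _ in range(12):
                if rng.random() < 0.4:
                    current = set(current)
                    current.add(int(rng.integers(10, 1000)))
                sets.append(set(current))
            col = make_column(sets)
            expected = sum(a != b for a, b in zip(sets, sets[1:]))
            assert len(detect_t1(col)) == expected

    def test_single_entry_rejected(self):
        col = make_column([{"A", "B", "C"}])
        with pytest.raises(ValueError):
            detect_t1(col)

    def test_unsorted_entries_rejected(self):
        entries = [
            ColumnEntry(1, 0.5, 10.0, frozenset({1, 2, 3})),
            ColumnEntry(0, 0.0, 10.0, frozenset({1, 2, 3})),
        ]
        with pytest.raises(ValueError, match="sorted"):
            CellColumn(cell_id=1, entries=entries, height=25.0)


def columns_with_counts(counts, n_layers=20):
    """Columns engineered to show an exact number of transitions each."""
    cols = []
    for cid, k in enumerate(counts, start=1):
        assert k <= n_layers - 1
        sets = []
        current = {10, 11, 12}
        nxt = 1000 * cid
        for li in range(n_layers):
            if 0 < li <= k:
                current = set(current)
                current.add(nxt)
                nxt += 1
            sets.append(set(current))
        cols.append(make_column(sets, cell_id=cid))
    return cols


class TestTransitionStats:
    def test_tip_scale_mean(self):
        # printed totals of the tip dataset: 169 transitions over 59 cells
        rng = np.random.default_rng(0)
        counts = rng.multinomial(169, np.ones(59) / 59)
        counts = np.minimum(counts, 19)
        while counts.sum() < 169:  # redistribute clipped excess
            counts[np.argmin(counts)] += 1
        ts = transition_stats(columns_with_counts(counts.tolist()))
        assert ts.total == 169
        assert ts.n_cells == 59
        assert round(ts.mean, 2) == 2.86

    def test_identical_counts_zero_dispersion(self):
        ts = transition_stats(columns_with_counts([5] * 30))
        assert ts.dispersion_index == 0.0
        assert ts.variance == 0.0

    def test_poisson_columns_dispersion(self):
        cols = generate_poisson_columns(500, rate=3.0, n_layers=30, seed=3)
        ts = transition_stats(cols)
        assert 0.8 <= ts.dispersion_index <= 1.2

    def test_interior_only_never_increases_distances(self):
        cols = generate_poisson_columns(100, rate=3.0, n_layers=20, seed=9)
        interior = transition_stats(cols, interior_only=True)
        full = transition_stats(cols, interior_only=False)
        assert len(interior.inter_transition_distances) <= len(
            full.inter_transition_distances
        )

    def test_interior_distances_drop_boundary_segments(self):
        col = columns_with_counts([2], n_layers=21)[0]
        ts = transition_stats([col], interior_only=True)
        # two transitions leave exactly one interior segment
        assert len(ts.inter_transition_distances) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            transition_stats([])


class TestPoissonGof:
    def test_null_true_not_rejected(self):
        rng = np.random.default_rng(0)
        counts = {i: int(k) for i, k in enumerate(rng.poisson(5.0, 1000))}
        _, _, p = poisson_gof(counts)
        assert p > 0.01

    def test_constant_counts_rejected_as_underdispersed(self):
        counts = {i: 5 for i in range(100)}
        _, _, p = poisson_gof(counts)
        assert p < 0.01

    def test_tip_scale_size(self):
        # at n=59, rate 2.86, the test should retain a true null almost always
        rng = np.random.default_rng(42)
        retained = 0
        n_trials = 100
        for _ in range(n_trials):
            counts = {i: int(k) for i, k in enumerate(rng.poisson(2.86, 59))}
            try:
                _, _, p = poisson_gof(counts)
            except ValueError:
                continue
            retained += p > 0.05
        assert retained >= 0.9 * n_trials

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            poisson_gof({i: 3 for i in range(10)})


class TestAreaChangeProfile:
    def test_deterministic_gain_loss_fixture(self):
        sets_up = [{1, 2, 3}, {1, 2, 3, 4}, {1, 2, 3, 4, 5}]
        sets_down = [{1, 2, 3, 4, 5}, {1, 2, 3, 4}, {1, 2, 3}]
        up = make_column(sets_up, areas=[10, 20, 30], cell_id=1)
        down = make_column(sets_down, areas=[30, 20, 10], cell_id=2)
        table = area_change_profile([up, down], bins=[-100, 0, 100])
        neg = next(r for r in table if r["bin_hi"] == 0)
        pos = next(r for r in table if r["bin_lo"] == 0)
        assert pos["gain_fraction"] == 1.0
        assert neg["loss_fraction"] == 1.0
        assert neg["gain_fraction"] == 0.0

    def test_symmetric_churn_is_direction_neutral(self):
        rng = np.random.default_rng(4)
        cols = []
        for cid in range(1, 201):
            sets = []
            current = {1, 2, 3, 4, 5}
            nxt = cid * 1000
            for li in range(6):
                if li > 0:
                    current = set(current)
                    if rng.random() < 0.5:
                        current.add(nxt)
                    else:
                        current.discard(sorted(current)[0])
                    nxt += 1
                sets.append(set(current))
            areas = 50 + rng.normal(0, 5, 6)  # independent of the churn
            cols.append(make_column(sets, areas=areas.tolist(), cell_id=cid))
        table = area_change_profile(cols, bins=[-30, -5, 5, 30])
        for row in table:
            if row["n_events"] >= 200:
                assert abs(row["gain_fraction"] - row["loss_fraction"]) < 0.1

    def test_area_coupled_tissue_shows_positive_trend(self, default_tissue):
        deltas = [
            b.area - a.area
            for col in default_tissue.columns
            for a, b in zip(col.entries, col.entries[1:])
        ]
        edges = np.percentile(deltas, [0, 20, 40, 60, 80, 100])
        edges[-1] += 1e-9
        table = area_change_profile(default_tissue.columns, bins=edges)
        rows = [r for r in table if not r["empty"] and r["n_events"] >= 5]
        rho, p = sps.spearmanr(
            [r["bin_mid"] for r in rows], [r["gain_fraction"] for r in rows]
        )
        assert rho > 0
        assert p / 2 < 0.05  # one-sided

    def test_empty_bins_flagged_not_dropped(self):
        col = make_column([{1, 2, 3}, {1, 2, 4}], areas=[10, 11])
        table = area_change_profile([col], bins=[-10, -5, 0, 5, 10])
        assert len(table) == 4
        assert any(r["empty"] for r in table)

    def test_nuclear_source_requires_nuclear_deltas(self):
        col = make_column([{1, 2, 3}, {1, 2, 4}])
        with pytest.raises(ValueError):
            area_change_profile([col], bins=[-1, 0, 1], source="nucleus")


class TestPositionHistogram:
    def test_uniform_events_flat(self):
        cols = generate_poisson_columns(800, rate=4.0, n_layers=40, seed=2)
        events = [e for c in cols for e in detect_t1(c)]
        table = position_histogram(events, n_bins=5)
        for row in table:
            assert row["fraction"] == pytest.approx(0.2, abs=0.05)
        mean_pos = np.mean([e.rel_position for e in events])
        assert 0.45 <= mean_pos <= 0.55

    def test_central_events_single_bin(self):
        col = make_column([{1, 2, 3}, {1, 2, 4}, {1, 2, 3}])
        events = detect_t1(col)  # both interfaces change: 0.25 and 0.75
        central = make_column([{1, 2, 3}] * 2 + [{1, 2, 5}] + [{1, 2, 5}])
        ev = [e for e in detect_t1(central)]
        table = position_histogram(ev, n_bins=3)
        occupied = [r for r in table if r["fraction"] > 0]
        assert len(occupied) == 1
        assert occupied[0]["fraction"] == 1.0

    def test_requires_events_and_bins(self):
        with pytest.raises(ValueError):
            position_histogram([], n_bins=4)
        col = make_column([{1, 2, 3}, {1, 2, 4}])
        with pytest.raises(ValueError):
            position_histogram(detect_t1(col), n_bins=1)
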