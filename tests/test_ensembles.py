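"""Basins, transition paths, separatrix, partition, K_eq."""

import numpy as np
import pandas as pd
import pytest

from gohinge import (
    BasinDefinition, OneDDoubleWell, Separatrix, brownian_1d, find_basins,
    keq_from_rates, optimize_separatrix, partition, predict_keq_shift,
    transition_paths, UnimodalDistributionError,
)
from gohinge.coords import CoordinateTable
from gohinge.ensembles import on_path_mask


def _table(q_open, q_closed):
    return CoordinateTable(data=pd.DataFrame(
        {"q_open": q_open, "q_closed": q_closed}))


def oracle_table(h=5.0, n_steps=300_000, seed=21):
    """Project the 1-D Brownian oracle into (Q_O, Q_C)-like coordinates."""
    x = brownian_1d(OneDDoubleWell(barrier_height=h, n_steps=n_steps,
                                   seed=seed))
    qc = np.clip((x + 1.5) / 3.0, 0.0, 1.0)
    return _table(1.0 - qc, qc)


class TestFindBasins:
    def test_known_gaussian_mixture_modes_recovered(self, rng):
        qc = np.concatenate([
            np.clip(rng.normal(0.15, 0.03, 4000), 0, 1),
            np.clip(rng.normal(0.85, 0.03, 6000), 0, 1),
        ])
        table = _table(1.0 - qc, qc)
        basins = find_basins(table, n_bins=20)
        bin_w = 1.0 / 20  # modes recovered within one bin
        assert abs(basins.center_open[1] - 0.15) <= 1.5 * bin_w
        assert abs(basins.center_closed[1] - 0.85) <= 1.5 * bin_w

    def test_unimodal_distribution_errors_with_advice(self, rng):
        qc = np.clip(rng.normal(0.5, 0.05, 5000), 0, 1)
        with pytest.raises(UnimodalDistributionError, match="recalibrate"):
            find_basins(_table(1.0 - qc, qc))

    def test_oracle_trajectory_visits_both_cores(self):
        table = oracle_table()
        basins = find_basins(table)
        core = basins.core_labels(table["q_open"], table["q_closed"])
        assert (core == "O").sum() > 0 and (core == "C").sum() > 0

    def test_overlapping_cores_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BasinDefinition(center_open=np.array([0.5, 0.3]),
                            center_closed=np.array([0.5, 0.4]),
                            radius_open=0.1, radius_closed=0.1)


class TestTransitionPaths:
    def test_hand_traceable_closing_path(self):
        labels = np.array(["O", "O", "", "", "C"], dtype=object)
        paths = transition_paths(labels)
        assert len(paths) == 1
        p = paths[0]
        assert (p.start, p.stop, p.direction) == (2, 3, "closing")

    def test_reentry_yields_no_path(self):
        labels = np.array(["O", "", "O"], dtype=object)
        assert transition_paths(labels) == ()

    def test_round_trip_gives_two_paths(self):
        labels = np.array(["O", "", "C", "", "", "O"], dtype=object)
        paths = transition_paths(labels)
        assert [p.direction for p in paths] == ["closing", "opening"]

    def test_adjacent_cores_give_empty_segment(self):
        labels = np.array(["O", "C"], dtype=object)
        paths = transition_paths(labels)
        assert len(paths) == 1 and paths[0].n_frames == 0

    def test_oracle_segments_match_two_pointer_scan(self):
        """Path boundaries equal an independent brute-force scan."""
        table = oracle_table(n_steps=100_000, seed=4)
        basins = find_basins(table)
        core = basins.core_labels(table["q_open"], table["q_closed"])
        paths = transition_paths(core)

        # independent scan: walk core indices pairwise
        idx = [(t, lab) for t, lab in enumerate(core) if lab in ("O", "C")]
        expected = []
        for (t0, l0), (t1, l1) in zip(idx, idx[1:]):
            if l0 != l1:
                expected.append((t0 + 1, t1 - 1,
                                 "closing" if l1 == "C" else "opening"))
        got = [(p.start, p.stop, p.direction) for p in paths]
        assert got == expected
        assert len(paths) > 0

    def test_time_reversal_swaps_directions(self):
        table = oracle_table(n_steps=50_000, seed=8)
        basins = find_basins(table)
        core = basins.core_labels(table["q_open"], table["q_closed"])
        fwd = transition_paths(core)
        rev = transition_paths(core[::-1])
        assert len(fwd) == len(rev)
        assert ([p.direction for p in fwd] ==
                [{"closing": "opening", "opening": "closing"}[p.direction]
                 for p in reversed(rev)])


class TestSeparatrix:
    def test_single_basin_p_tp_zero(self, rng):
        qc = np.clip(np.concatenate([rng.normal(0.15, 0.03, 3000),
                                     rng.normal(0.85, 0.02, 40)]), 0, 1)
        table = _table(1.0 - qc, qc)
        basins = find_basins(table, n_bins=20)
        sep = optimize_separatrix(table, (), basins)
        assert sep.p_tp == 0.0

    def test_hand_built_band_membership(self):
        """10-frame series with hand-counted band membership and p_TP."""
        q_open = np.array([0.9, 0.8, 0.6, 0.52, 0.48, 0.5, 0.4, 0.2, 0.1, 0.0])
        q_closed = 1.0 - q_open
        table = _table(q_open, q_closed)
        basins = BasinDefinition(center_open=np.array([0.9, 0.1]),
                                 center_closed=np.array([0.1, 0.9]),
                                 radius_open=0.15, radius_closed=0.15)
        core = basins.core_labels(q_open, q_closed)
        paths = transition_paths(core)
        # horizontal line q_closed = 0.5, band halfwidth 0.05:
        # frames with q_closed in [0.45, 0.55] -> indices 3, 4, 5
        sep = optimize_separatrix(table, paths, basins,
                                  slopes=np.array([0.0]), n_intercepts=201,
                                  band_halfwidth=0.05, min_band_frames=1)
        in_band = np.nonzero(sep.in_band)[0]
        tp = on_path_mask(10, paths)
        hand = tp[in_band].mean()
        assert sep.p_tp == pytest.approx(hand)

    def test_returned_line_maximizes_band_score(self):
        """The selected line attains the maximal shrinkage-regularized p_TP
        over an independently re-evaluated grid, and the reported p_TP is
        the raw transition-path fraction of its band."""
        from gohinge.ensembles import (
            SHRINKAGE_PRIOR_COUNT as K, SHRINKAGE_PRIOR_P as P0,
        )
        table = oracle_table(n_steps=100_000, seed=4)
        basins = find_basins(table)
        core = basins.core_labels(table["q_open"], table["q_closed"])
        paths = transition_paths(core)
        sep = optimize_separatrix(table, paths, basins)
        tp = on_path_mask(len(table), paths)
        qo, qc = table["q_open"], table["q_closed"]
        co, cc = basins.center_open, basins.center_closed
        lo_edge = co[1] + basins.radius_open
        hi_edge = cc[1] - basins.radius_closed
        gap = hi_edge - lo_edge
        corr_lo, corr_hi = lo_edge + 0.25 * gap, hi_edge - 0.25 * gap
        qo_lo, qo_hi = np.percentile(qo, [10.0, 90.0])
        min_band = min(10, max(1, len(qo) // 10))
        best = 0.0
        for m in np.linspace(-3, 3, 61):
            s = qc - m * qo
            for b in np.linspace(s.min(), s.max(), 41):
                if (cc[1] - m * cc[0] - b) * (co[1] - m * co[0] - b) >= 0:
                    continue
                if not (corr_lo <= m * qo_lo + b <= corr_hi
                        and corr_lo <= m * qo_hi + b <= corr_hi):
                    continue
                band = np.abs(s - b) / np.sqrt(1 + m * m) <= sep.band_halfwidth
                if band.sum() >= min_band:
                    best = max(best,
                               (tp[band].sum() + K * P0) / (band.sum() + K))
        chosen_score = (tp[sep.in_band].sum() + K * P0) / (
            sep.in_band.sum() + K)
        assert chosen_score == pytest.approx(best)
        assert sep.p_tp == pytest.approx(tp[sep.in_band].mean())

    def test_p_tp_within_unit_interval_enforced(self):
        with pytest.raises(ValueError):
            Separatrix(slope=0.0, intercept=0.5, band_halfwidth=0.02,
                       p_tp=1.5, closed_side_sign=1.0,
                       in_band=np.zeros(2, bool),
                       side=np.array(["O", "C"], dtype=object))


class TestPartition:
    def test_all_frames_closed_keq_undefined(self):
        q_open = np.full(20, 0.1)
        q_closed = np.full(20, 0.9)
        side = np.full(20, "C", dtype=object)
        sep = Separatrix(slope=0.0, intercept=0.5, band_halfwidth=0.02,
                         p_tp=0.0, closed_side_sign=1.0,
                         in_band=np.zeros(20, bool), side=side)
        part = partition(_table(q_open, q_closed), sep, ())
        assert not part.keq_defined

    def test_keq_is_count_ratio(self):
        side = np.array(["C"] * 400 + ["O"] * 100, dtype=object)
        sep = Separatrix(slope=0.0, intercept=0.5, band_halfwidth=0.02,
                         p_tp=0.0, closed_side_sign=1.0,
                         in_band=np.zeros(500, bool), side=side)
        table = _table(np.zeros(500), np.zeros(500))
        part = partition(table, sep, ())
        assert part.keq == pytest.approx(4.0)

    def test_hand_labelled_twenty_frames(self):
        """Label-by-label equality with a manual assignment."""
        q_open = np.array([0.9] * 4 + [0.7, 0.55, 0.5, 0.45, 0.3] +
                          [0.1] * 7 + [0.5, 0.9, 0.9, 0.9])
        q_closed = 1.0 - q_open
        table = _table(q_open, q_closed)
        basins = BasinDefinition(center_open=np.array([0.9, 0.1]),
                                 center_closed=np.array([0.1, 0.9]),
                                 radius_open=0.1, radius_closed=0.1)
        core = basins.core_labels(q_open, q_closed)
        paths = transition_paths(core)
        sep = optimize_separatrix(table, paths, basins,
                                  slopes=np.array([0.0]), n_intercepts=101,
                                  band_halfwidth=0.06, min_band_frames=1)
        part = partition(table, sep, paths)
        # manual: frames 4-8 form the closing path (between cores);
        # frame 16 is between cores but re-enters O (no path)
        tp = on_path_mask(20, paths)
        manual = []
        for t in range(20):
            if sep.in_band[t] and tp[t]:
                manual.append("TS")
            else:
                manual.append(sep.side[t])
        assert list(part.labels) == manual
        assert set(part.direction[part.labels == "TS"]) <= {"closing",
                                                            "opening"}

    def test_every_frame_labelled_and_ts_on_paths(self):
        table = oracle_table(n_steps=100_000, seed=4)
        basins = find_basins(table)
        core = basins.core_labels(table["q_open"], table["q_closed"])
        paths = transition_paths(core)
        sep = optimize_separatrix(table, paths, basins)
        part = partition(table, sep, paths)
        assert set(part.labels) <= {"O", "C", "TS"}
        tp = on_path_mask(len(table), paths)
        assert np.all(tp[part.labels == "TS"])
        assert np.all(sep.in_band[part.labels == "TS"])


class TestKeqFromRates:
    def test_reported_rate_ratios(self):
        # thermophile: 1571/44 s^-1; mesophile: 1374/286 s^-1
        assert keq_from_rates(1571.0, 44.0) == pytest.approx(35.7, abs=0.05)
        assert keq_from_rates(1374.0, 286.0) == pytest.approx(4.8, abs=0.05)

    def test_equal_rates_unity(self):
        assert keq_from_rates(7.0, 7.0) == 1.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            keq_from_rates(0.0, 5.0)
        with pytest.raises(ValueError):
            keq_from_rates(5.0, -1.0)


class TestReweighting:
    def test_strong_mixing_shift_prediction(self):
        """K_eq multiplier exp(+delta/kT) against a direct Boltzmann
        reweighting of a synthetic two-level system."""
        kt = 0.0019872041 * 300.0
        # two sharply separated wells: populations follow raw Boltzmann
        # factors, so the closed/open ratio reweights exactly
        e_open, e_closed = -10.0, -11.0
        keq0 = np.exp(-(e_closed - e_open) / kt)
        delta = 0.35
        keq1 = np.exp(-(e_closed - (e_open + delta)) / kt)
        assert predict_keq_shift(keq0, delta, 300.0) == pytest.approx(
            keq1, rel=1e-12)
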