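"""p_folded/p_rigid, contact probabilities, classification, comparisons."""

import numpy as np
import pandas as pd
import pytest

from gohinge import Contact, DihedralReference, classify, compare, p_folded
from gohinge.localstats import (
    compare_residues, contact_probabilities, p_rigid, paintable_contact_list,
)


class FakePartition:
    def __init__(self, labels, direction=None):
        self.labels = np.asarray(labels, dtype=object)
        self.direction = (np.asarray(direction, dtype=object)
                          if direction is not None
                          else np.full(len(labels), "", dtype=object))


def refs_from_angles(alpha_open, alpha_closed):
    from gohinge.structures import angular_difference
    a_o = np.asarray(alpha_open, dtype=float)
    a_c = np.asarray(alpha_closed, dtype=float)
    delta = angular_difference(a_c, a_o)
    rule = np.where(np.isnan(delta), "undefined",
                    np.where(np.abs(delta) < 20.0, "single-average",
                             "three-candidate")).astype(object)
    return DihedralReference(alpha_open=a_o, alpha_closed=a_c, delta=delta,
                             rule=rule)


class TestPFolded:
    def test_frames_at_reference_give_one(self):
        refs = refs_from_angles([10.0], [20.0])  # avg ref 15
        angles = np.full((6, 1), 15.0)
        part = FakePartition(["O"] * 3 + ["C"] * 3)
        table = p_folded(angles, refs, part)
        assert table.loc[0, "O"] == 1.0 and table.loc[0, "C"] == 1.0

    def test_frames_at_reference_plus_90_give_zero(self):
        refs = refs_from_angles([0.0], [10.0])  # avg ref 5
        angles = np.full((4, 1), 95.0)
        part = FakePartition(["O"] * 4)
        table = p_folded(angles, refs, part, window=60.0)
        assert table.loc[0, "O"] == 0.0

    def test_rule_tags_follow_delta_threshold(self):
        refs = refs_from_angles([0.0, 0.0], [15.0, 25.0])
        assert refs.rule[0] == "single-average"
        assert refs.rule[1] == "three-candidate"

    def test_three_candidate_takes_best(self):
        # delta = 100: candidates are O=0, C=100, midpoint=50.
        # frames sit at 100, so the C candidate wins with window 20.
        refs = refs_from_angles([0.0], [100.0])
        angles = np.full((5, 1), 100.0)
        part = FakePartition(["O"] * 5)
        table = p_folded(angles, refs, part, window=20.0)
        assert table.loc[0, "O"] == 1.0

    def test_seven_of_ten_within_window_oracle(self):
        refs = refs_from_angles([0.0], [10.0])  # single-average ref = 5
        vals = [5, 10, 60, 64.9, -50, 70, 100, -80, 5, 30]
        angles = np.array(vals, dtype=float).reshape(-1, 1)
        part = FakePartition(["O"] * 10)
        # per-frame listing: within 60 of ref=5 <=> value in [-55, 65]
        manual = sum(1 for v in vals if abs(v - 5) <= 60) / 10
        assert manual == 0.7
        table = p_folded(angles, refs, part, window=60.0)
        assert table.loc[0, "O"] == pytest.approx(0.7)

    def test_ts_is_mean_of_directions(self):
        refs = refs_from_angles([0.0], [10.0])
        angles = np.array([[5.0], [5.0], [100.0], [100.0]])
        part = FakePartition(["TS", "TS", "TS", "TS"],
                             ["closing", "closing", "opening", "opening"])
        table = p_folded(angles, refs, part, window=60.0)
        assert table.loc[0, "TS_closing"] == 1.0
        assert table.loc[0, "TS_opening"] == 0.0
        assert table.loc[0, "TS"] == 0.5

    def test_empty_ensemble_is_missing_not_zero(self):
        refs = refs_from_angles([0.0], [10.0])
        angles = np.full((3, 1), 5.0)
        part = FakePartition(["O"] * 3)
        table = p_folded(angles, refs, part)
        assert np.isnan(table.loc[0, "C"])

    def test_wrap_safe_window(self):
        refs = refs_from_angles([175.0], [-175.0])  # delta=10, ref=180
        angles = np.array([[-170.0], [150.0], [90.0]])
        part = FakePartition(["O"] * 3)
        table = p_folded(angles, refs, part, window=20.0)
        # -170 is 10 deg from 180; 150 is 30; 90 is 90
        assert table.loc[0, "O"] == pytest.approx(1 / 3)

    def test_window_nesting_60_dominates_20(self, toy, rng):
        from gohinge.structures import pseudodihedrals
        refs = DihedralReference.from_structures(toy.open_structure,
                                                 toy.closed_structure)
        frames = toy.open_structure.coords[None] + \
            0.4 * rng.standard_normal((30, 44, 3))
        angles = pseudodihedrals(frames)
        part = FakePartition(["O"] * 15 + ["C"] * 15)
        wide = p_folded(angles, refs, part)
        narrow = p_rigid(angles, refs, part)
        for ens in ("O", "C"):
            w = wide[ens].to_numpy()
            n = narrow[ens].to_numpy()
            ok = ~(np.isnan(w) | np.isnan(n))
            assert np.all(w[ok] >= n[ok])


class TestContactProbabilities:
    def test_native_contact_always_formed(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * 3.8
        frames = np.repeat(coords[None], 6, axis=0)
        contacts = [Contact(0, 4, float(np.linalg.norm(coords[4] - coords[0])),
                            0.5)]
        part = FakePartition(["O", "O", "C", "C", "TS", "TS"],
                             ["", "", "", "", "closing", "opening"])
        table = contact_probabilities(frames, contacts, part)
        assert table.loc[0, ["p_O", "p_C", "p_TS"]].tolist() == [1.0, 1.0, 1.0]

    def test_never_formed_contact_zero(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * 3.8
        frames = np.repeat(coords[None], 4, axis=0)
        contacts = [Contact(0, 7, 5.0, 0.5)]  # actual 26.6 >> 5.5
        part = FakePartition(["O", "O", "C", "C"])
        table = contact_probabilities(frames, contacts, part)
        assert table.loc[0, "p_O"] == 0.0 and table.loc[0, "p_C"] == 0.0

    def test_hand_counts_on_ten_frames(self):
        base = np.zeros((6, 3))
        base[:, 0] = np.arange(6) * 3.8
        contact = Contact(0, 3, 11.4, 0.5)
        frames = np.repeat(base[None], 10, axis=0)
        # stretch the pair beyond 1.1x native in chosen frames
        for k in (1, 4, 7, 8):
            frames[k, 3, 0] += 3.0
        labels = ["O", "O", "O", "C", "C", "C", "TS", "TS", "TS", "TS"]
        dirs = ["", "", "", "", "", "", "closing", "closing", "opening",
                "opening"]
        part = FakePartition(labels, dirs)
        table = contact_probabilities(frames, [contact], part)
        # hand counts: O frames 0,1,2 -> broken in 1 -> 2/3
        assert table.loc[0, "p_O"] == pytest.approx(2 / 3)
        # C frames 3,4,5 -> broken in 4 -> 2/3
        assert table.loc[0, "p_C"] == pytest.approx(2 / 3)
        # closing 6,7 -> 1/2 ; opening 8,9 -> 1/2 ; TS = mean = 1/2
        assert table.loc[0, "p_TS"] == pytest.approx(0.5)


class TestClassify:
    def test_equal_probabilities_neither(self):
        t = pd.DataFrame({"i": [0], "j": [5], "p_O": [0.5], "p_C": [0.5],
                          "p_TS": [0.5]})
        out = classify(t)
        assert out.loc[0, "class"] == "neither"

    def test_rule_application(self):
        t = pd.DataFrame({"i": [0], "j": [5], "p_O": [0.9], "p_C": [0.1],
                          "p_TS": [0.6]})
        out = classify(t)
        assert out.loc[0, "class"] == "O-characteristic"
        assert bool(out.loc[0, "display"])
        assert out.loc[0, "p_TS_bin"] == "0.5<=p_TS<0.7"

    def test_randomized_table_matches_rule_oracle(self, rng):
        n = 200
        t = pd.DataFrame({
            "i": np.arange(n), "j": np.arange(n) + 5,
            "p_O": rng.uniform(0, 1, n), "p_C": rng.uniform(0, 1, n),
            "p_TS": rng.uniform(0, 1, n),
        })
        out = classify(t)
        for _, row in out.iterrows():
            if row.p_O - row.p_C >= 0.2:
                expected = "O-characteristic"
            elif row.p_C - row.p_O >= 0.2:
                expected = "C-characteristic"
            else:
                expected = "neither"
            assert row["class"] == expected
            assert row["display"] == (max(row.p_O, row.p_C) >= 0.5)
            if row.p_TS >= 0.7:
                assert row.p_TS_bin == "p_TS>=0.7"
            elif row.p_TS >= 0.5:
                assert row.p_TS_bin == "0.5<=p_TS<0.7"
            else:
                assert row.p_TS_bin == "p_TS<0.5"

    def test_boundary_delta_inclusive(self):
        t = pd.DataFrame({"i": [0], "j": [5], "p_O": [0.7], "p_C": [0.5],
                          "p_TS": [0.2]})
        assert classify(t).loc[0, "class"] == "O-characteristic"


class TestCompare:
    def _classified(self, p_o, p_c, p_ts=None):
        n = len(p_o)
        t = pd.DataFrame({
            "i": np.arange(n), "j": np.arange(n) + 4,
            "p_O": p_o, "p_C": p_c,
            "p_TS": p_ts if p_ts is not None else np.full(n, 0.5),
        })
        return classify(t)

    def test_identical_tables_zero_delta_empty_display(self):
        a = self._classified([0.9, 0.2], [0.1, 0.9])
        out = compare(a, a.copy())
        assert np.allclose(out[["dp_O", "dp_TS", "dp_C"]].to_numpy(), 0.0)
        assert not out[["display_O", "display_TS", "display_C"]].any().any()

    def test_exact_threshold_retained(self):
        a = self._classified([0.9], [0.1])
        b = self._classified([0.8], [0.1])
        out = compare(a, b, min_delta=0.1)
        assert out.loc[0, "dp_O"] == pytest.approx(0.1)
        assert bool(out.loc[0, "display_O"])  # inclusive threshold

    def test_element_wise_subtraction_oracle(self, rng):
        n = 50
        a = self._classified(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                             rng.uniform(0, 1, n))
        b = self._classified(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                             rng.uniform(0, 1, n))
        out = compare(a, b).set_index(["i", "j"])
        for idx in out.index:
            row_a = a.set_index(["i", "j"]).loc[idx]
            row_b = b.set_index(["i", "j"]).loc[idx]
            for ens in ("O", "TS", "C"):
                assert out.loc[idx, f"dp_{ens}"] == pytest.approx(
                    row_a[f"p_{ens}"] - row_b[f"p_{ens}"])

    def test_disjoint_keys_error(self):
        a = self._classified([0.9], [0.1])
        b = self._classified([0.9], [0.1])
        b["i"] += 100
        with pytest.raises(ValueError, match="no .* keys"):
            compare(a, b)

    def test_order_invariance_of_classify_then_compare(self, rng):
        n = 30
        a = self._classified(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
        b = self._classified(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
        shuffled = a.sample(frac=1.0, random_state=3)
        out1 = compare(a, b).sort_values(["i", "j"]).reset_index(drop=True)
        out2 = compare(shuffled, b).sort_values(["i", "j"]).reset_index(
            drop=True)
        pd.testing.assert_frame_equal(out1, out2)

    def test_residue_delta_table(self):
        a = pd.DataFrame({"residue": [1, 2], "O": [0.9, 0.5],
                          "TS": [0.8, 0.4], "C": [0.7, 0.3]})
        b = pd.DataFrame({"residue": [1, 2], "O": [0.5, 0.5],
                          "TS": [0.9, 0.4], "C": [0.7, 0.2]})
        out = compare_residues(a, b).set_index("residue")
        assert out.loc[1, "dp_O"] == pytest.approx(0.4)
        assert out.loc[1, "dp_TS"] == pytest.approx(-0.1)
        assert out.loc[2, "dp_C"] == pytest.approx(0.1)

    def test_paintable_list_contains_displayed_only(self):
        a = self._classified([0.9, 0.6], [0.1, 0.55])
        b = self._classified([0.5, 0.6], [0.1, 0.55])
        out = compare(a, b)
        text = paintable_contact_list(out)
        lines = text.strip().splitlines()
        assert lines[0] == "i\tj\tensemble\tdp"
        assert any("\tO\t" in ln for ln in lines[1:])
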