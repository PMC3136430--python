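"""Per-residue local-unfolding statistics and per-contact probabilities.

p_folded is the fraction of an ensemble's frames in which a residue's
backbone pseudodihedral stays in the same rotamer as its native reference —
"same rotamer" meaning within a 60° window (a 20° window gives the stricter
p_rigid). The reference is the average of the O and C native values when the
two states agree to within 20°; otherwise three candidate references are
used (the O value, the C value, and their midpoint) and the highest
probability among the three is reported. The TS value is the unweighted mean
of the closing- and opening-direction values, not a pooled count.

Contact probabilities use the same ensemble partition: p_E is the fraction
of E-frames with the pair distance within 1.1x its native contact distance.
Contacts with p_O - p_C >= 0.2 (resp. p_C - p_O >= 0.2) are O- (C-)
characteristic; display filters keep contacts with max(p_O, p_C) >= 0.5 and,
in comparisons, |Δp| >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords import CONTACT_RATIO, contact_distance_series
from .gomodel import Contact
from .structures import CalphaStructure, angular_difference, pseudodihedrals

WINDOW_FOLDED = 60.0
WINDOW_RIGID = 20.0
SINGLE_AVERAGE_CUTOFF = 20.0
CHARACTERISTIC_DELTA = 0.2
DISPLAY_FLOOR = 0.5
COMPARE_MIN_DELTA = 0.1
PTS_BINS = (0.5, 0.7)


@dataclass(frozen=True)
class DihedralReference:
    """Native pseudodihedral references for every residue.

    ``delta`` is the wrapped signed difference alpha_C - alpha_O; the rule
    tag records whether a residue uses the single averaged reference
    (|delta| < 20°) or the three-candidate rule.
    """

    alpha_open: np.ndarray
    alpha_closed: np.ndarray
    delta: np.ndarray
    rule: np.ndarray  # 'single-average' | 'three-candidate' | 'undefined'

    @classmethod
    def from_structures(
        cls, open_structure: CalphaStructure, closed_structure: CalphaStructure
    ) -> "DihedralReference":
        a_o = pseudodihedrals(open_structure.coords)
        a_c = pseudodihedrals(closed_structure.coords)
        delta = angular_difference(a_c, a_o)
        rule = np.where(
            np.isnan(delta), "undefined",
            np.where(np.abs(delta) < SINGLE_AVERAGE_CUTOFF,
                     "single-average", "three-candidate"),
        ).astype(object)
        return cls(alpha_open=a_o, alpha_closed=a_c, delta=delta, rule=rule)

    def midpoint(self) -> np.ndarray:
        """Circular midpoint of the O and C references (shorter arc)."""
        from .structures import wrap_angle
        return wrap_angle(self.alpha_open + 0.5 * self.delta)


def _ensemble_masks(partition) -> dict[str, np.ndarray]:
    labels = np.asarray(partition.labels, dtype=object)
    direction = np.asarray(partition.direction, dtype=object)
    return {
        "O": labels == "O",
        "C": labels == "C",
        "TS_closing": (labels == "TS") & (direction == "closing"),
        "TS_opening": (labels == "TS") & (direction == "opening"),
    }


def _directional_average(closing: float, opening: float) -> float:
    vals = [v for v in (closing, opening) if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def p_folded(
    angles: np.ndarray,
    refs: DihedralReference,
    partition,
    window: float = WINDOW_FOLDED,
    residue_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue rotamer-retention probability in each ensemble.

    ``angles`` is the (n_frames, n_res) pseudodihedral series aligned to the
    partition's frames. Empty ensembles yield nan (missing), never zero.
    Returns a table with columns O, TS, C plus the directional TS values and
    the reference rule per residue.
    """
    angles = np.asarray(angles, dtype=float)
    n_frames, n_res = angles.shape
    if len(partition.labels) != n_frames:
        raise ValueError("angle series not aligned to partition")
    masks = _ensemble_masks(partition)

    def frac_within(mask: np.ndarray, res: int, ref: float) -> float:
        if not mask.any() or not np.isfinite(ref):
            return float("nan")
        diffs = np.abs(angular_difference(angles[mask, res], ref))
        return float(np.mean(diffs <= window))

    rows = []
    for r in range(n_res):
        if refs.rule[r] == "undefined":
            vals = {k: float("nan") for k in masks}
        elif refs.rule[r] == "single-average":
            ref = refs.midpoint()[r]
            vals = {k: frac_within(m, r, ref) for k, m in masks.items()}
        else:
            candidates = (refs.alpha_open[r], refs.alpha_closed[r],
                          refs.midpoint()[r])
            vals = {}
            for k, m in masks.items():
                per_cand = [frac_within(m, r, c) for c in candidates]
                finite = [v for v in per_cand if np.isfinite(v)]
                vals[k] = max(finite) if finite else float("nan")
        rows.append({
            "residue": int(residue_ids[r]) if residue_ids is not None else r + 1,
            "O": vals["O"],
            "TS": _directional_average(vals["TS_closing"], vals["TS_opening"]),
            "C": vals["C"],
            "TS_closing": vals["TS_closing"],
            "TS_opening": vals["TS_opening"],
            "rule": refs.rule[r],
        })
    return pd.DataFrame(rows)


def p_rigid(angles, refs, partition, residue_ids=None) -> pd.DataFrame:
    """p_folded with the stricter 20° rotamer window."""
    return p_folded(angles, refs, partition, WINDOW_RIGID, residue_ids)


def contact_probabilities(
    frames: np.ndarray,
    contacts: list[Contact],
    partition,
    ratio: float = CONTACT_RATIO,
) -> pd.DataFrame:
    """Per-contact formation probabilities p_O, p_TS, p_C.

    Each contact is scored against its own native distance; p_TS averages
    the closing and opening directional values. Empty ensembles give nan.
    """
    if len(partition.labels) != frames.shape[0]:
        raise ValueError("frames not aligned to partition")
    d, r0 = contact_distance_series(frames, contacts)
    formed = d <= ratio * r0
    masks = _ensemble_masks(partition)
    cols = {}
    for k, m in masks.items():
        cols[k] = formed[m].mean(axis=0) if m.any() else np.full(len(contacts), np.nan)
    rows = []
    for idx, c in enumerate(contacts):
        ts = _directional_average(cols["TS_closing"][idx], cols["TS_opening"][idx])
        rows.append({
            "i": c.i, "j": c.j, "provenance": c.provenance,
            "native_distance": c.native_distance,
            "p_O": float(cols["O"][idx]),
            "p_TS": ts,
            "p_C": float(cols["C"][idx]),
            "p_TS_closing": float(cols["TS_closing"][idx]),
            "p_TS_opening": float(cols["TS_opening"][idx]),
        })
    return pd.DataFrame(rows)


def classify(
    table: pd.DataFrame,
    delta: float = CHARACTERISTIC_DELTA,
    display_floor: float = DISPLAY_FLOOR,
) -> pd.DataFrame:
    """Tag contacts as O-/C-characteristic and bin their TS probability.

    O-characteristic iff p_O - p_C >= delta, C-characteristic iff
    p_C - p_O >= delta; the display flag keeps contacts with
    max(p_O, p_C) >= display_floor; p_TS bins split at 0.5 and 0.7.
    """
    out = table.copy()
    p_o = out["p_O"].to_numpy(dtype=float)
    p_c = out["p_C"].to_numpy(dtype=float)
    cls = np.full(len(out), "neither", dtype=object)
    eps = 1e-9  # inclusive thresholds must survive float roundoff
    with np.errstate(invalid="ignore"):
        cls[(p_o - p_c) >= delta - eps] = "O-characteristic"
        cls[(p_c - p_o) >= delta - eps] = "C-characteristic"
        out["class"] = cls
        out["display"] = np.fmax(p_o, p_c) >= display_floor
    p_ts = out["p_TS"].to_numpy(dtype=float)
    bins = np.full(len(out), "missing", dtype=object)
    lo, hi = PTS_BINS
    with np.errstate(invalid="ignore"):
        bins[p_ts < lo] = f"p_TS<{lo}"
        bins[(p_ts >= lo) & (p_ts < hi)] = f"{lo}<=p_TS<{hi}"
        bins[p_ts >= hi] = f"p_TS>={hi}"
    out["p_TS_bin"] = bins
    return out


def compare(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    min_delta: float = COMPARE_MIN_DELTA,
) -> pd.DataFrame:
    """Per-contact probability differences Δp = A - B per ensemble.

    Both tables must be classified (outer join on the (i, j) key; contacts
    present in only one table keep nan on the other side). The display flag
    marks contacts that are O- or C-characteristic in either table and have
    |Δp| >= min_delta (inclusive) in that ensemble; all rows are retained in
    the data either way.
    """
    for t in (table_a, table_b):
        if "class" not in t.columns:
            raise ValueError("tables must be classified first (see classify)")
    a = table_a.set_index(["i", "j"])
    b = table_b.set_index(["i", "j"])
    if not a.index.intersection(b.index).size:
        raise ValueError("contact tables share no (i, j) keys")
    merged = a.join(b, how="outer", lsuffix="_a", rsuffix="_b")
    out = pd.DataFrame(index=merged.index)
    char = np.zeros(len(merged), dtype=bool)
    for side in ("a", "b"):
        col = merged.get(f"class_{side}")
        if col is not None:
            char |= col.fillna("neither").str.endswith("characteristic").to_numpy()
    out["characteristic_either"] = char
    for ens in ("O", "TS", "C"):
        dp = merged[f"p_{ens}_a"] - merged[f"p_{ens}_b"]
        out[f"dp_{ens}"] = dp
        with np.errstate(invalid="ignore"):
            out[f"display_{ens}"] = char & (
                np.abs(dp.to_numpy()) >= min_delta - 1e-9)
    return out.reset_index()


def compare_residues(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-residue Δp_folded = A - B for the O, TS, and C ensembles."""
    a = table_a.set_index("residue")
    b = table_b.set_index("residue")
    if not a.index.intersection(b.index).size:
        raise ValueError("residue tables share no keys")
    out = pd.DataFrame(index=a.index.union(b.index))
    for ens in ("O", "TS", "C"):
        out[f"dp_{ens}"] = a[ens].reindex(out.index) - b[ens].reindex(out.index)
    return out.reset_index().rename(columns={"index": "residue"})


def paintable_contact_list(delta_table: pd.DataFrame) -> str:
    """Flat per-contact TSV (i, j, ensemble, dp) for molecular-graphics use."""
    lines = ["i\tj\tensemble\tdp"]
    for _, row in delta_table.iterrows():
        for ens in ("O", "TS", "C"):
            if row.get(f"display_{ens}", False):
                lines.append(f"{int(row['i'])}\t{int(row['j'])}\t{ens}\t"
                             f"{row[f'dp_{ens}']:.4f}")
    return "\n".join(lines) + "\n"
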