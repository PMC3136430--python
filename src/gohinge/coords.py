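"""Projection of trajectories onto reaction coordinates.

The coordinates mirror the standard two-state contact analysis: Q_O and Q_C
are fractions of contacts *unique* to the open/closed reference structure
that are formed in a frame (formed = instantaneous distance within 1.1x the
native contact distance); Q_O,all / Q_C,all include the contacts shared
between the two references; rms_O / rms_C are Cα rmsds to each reference
after optimal superposition; r_CM coordinates are center-of-mass distances
between mapped domains, with configured connector ranges excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gomodel import Contact, DoubleWellModel, partition_contacts
from .structures import CalphaStructure, rmsd_after_superposition

CONTACT_RATIO = 1.1


@dataclass(frozen=True)
class CoordinateTable:
    """Per-frame reaction-coordinate values plus provenance of definitions."""

    data: pd.DataFrame
    definitions: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in self.data.columns:
            if col.startswith("q_") and len(self.data):
                vals = self.data[col].to_numpy()
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise ValueError(f"column {col} outside [0, 1]")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self) -> str:
        header = "# " + "; ".join(
            f"{k}={v}" for k, v in sorted(self.definitions.items())
        )
        return header + "\n" + self.data.to_csv(sep="\t", index=False)


def contact_arrays(contacts: list[Contact], which: str = "own"):
    ci = np.array([c.i for c in contacts], dtype=int)
    cj = np.array([c.j for c in contacts], dtype=int)
    r0 = np.array([c.native_distance for c in contacts])
    return ci, cj, r0


def fraction_contacts(
    frame: np.ndarray, contacts: list[Contact], ratio: float = CONTACT_RATIO
) -> float:
    """Fraction of listed contacts formed in one frame (d <= ratio x native)."""
    if not contacts:
        raise ValueError("contact list is empty")
    ci, cj, r0 = contact_arrays(contacts)
    d = np.linalg.norm(frame[cj] - frame[ci], axis=1)
    return float(np.mean(d <= ratio * r0))


def fraction_contacts_series(
    frames: np.ndarray, contacts: list[Contact], ratio: float = CONTACT_RATIO
) -> np.ndarray:
    """Vectorized :func:`fraction_contacts` over a frame stack."""
    if not contacts:
        raise ValueError("contact list is empty")
    ci, cj, r0 = contact_arrays(contacts)
    d = np.linalg.norm(frames[:, cj] - frames[:, ci], axis=2)
    return np.mean(d <= ratio * r0, axis=1)


def contact_distance_series(frames: np.ndarray, contacts: list[Contact]):
    """(n_frames, n_contacts) instantaneous distances for a contact list."""
    ci, cj, r0 = contact_arrays(contacts)
    return np.linalg.norm(frames[:, cj] - frames[:, ci], axis=2), r0


def project(
    frames: np.ndarray,
    model: DoubleWellModel,
    open_structure: CalphaStructure,
    closed_structure: CalphaStructure,
    domain_pairs: list[tuple[str, str]] | None = None,
    ratio: float = CONTACT_RATIO,
    shared_distance_rule: str = "own",
    rms_selection: np.ndarray | None = None,
) -> CoordinateTable:
    """Compute all named reaction coordinates for every frame.

    ``domain_pairs`` names the center-of-mass distance coordinates to emit
    (column ``r_cm_<a>_<b>``); exclusion ranges configured on the open
    structure apply to every frame. ``shared_distance_rule`` selects which
    native distance anchors the formed-contact criterion for contacts shared
    between O and C inside Q_*,all: each well's own distance (``"own"``) or
    the other well's (``"other"``).
    """
    if shared_distance_rule not in ("own", "other"):
        raise ValueError("shared_distance_rule must be 'own' or 'other'")
    contacts_o = list(model.potential_open.contacts)
    contacts_c = list(model.potential_closed.contacts)
    o_unique, c_unique, shared = partition_contacts(contacts_o, contacts_c)

    def q_all(unique, shared_own, shared_other):
        shared_scored = shared_own if shared_distance_rule == "own" else shared_other
        return unique + shared_scored

    shared_o = [s[0] for s in shared]
    shared_c = [s[1] for s in shared]
    # ligand contacts live only in the closed potential and count in Q_C,all
    cols: dict[str, np.ndarray] = {}
    if o_unique:
        cols["q_open"] = fraction_contacts_series(frames, o_unique, ratio)
    if c_unique:
        cols["q_closed"] = fraction_contacts_series(frames, c_unique, ratio)
    cols["q_open_all"] = fraction_contacts_series(
        frames, q_all(o_unique, shared_o, shared_c), ratio)
    cols["q_closed_all"] = fraction_contacts_series(
        frames, q_all(c_unique, shared_c, shared_o), ratio)
    cols["rms_open"] = np.array([
        rmsd_after_superposition(f, open_structure.coords, rms_selection)
        for f in frames
    ])
    cols["rms_closed"] = np.array([
        rmsd_after_superposition(f, closed_structure.coords, rms_selection)
        for f in frames
    ])
    for a, b in domain_pairs or []:
        for name in (a, b):
            if name not in open_structure.domain_map:
                raise KeyError(f"domain {name!r} missing from domain map")
        ia = open_structure.domain_indices(a)
        ib = open_structure.domain_indices(b)
        if ia.size == 0 or ib.size == 0:
            raise ValueError("empty domain after exclusions")
        coms_a = frames[:, ia].mean(axis=1)
        coms_b = frames[:, ib].mean(axis=1)
        cols[f"r_cm_{a}_{b}"] = np.linalg.norm(coms_a - coms_b, axis=1)
    defs = {
        "ratio": ratio,
        "shared_distance_rule": shared_distance_rule,
        "n_o_unique": len(o_unique),
        "n_c_unique": len(c_unique),
        "n_shared": len(shared),
    }
    return CoordinateTable(data=pd.DataFrame(cols), definitions=defs)


def dispersion(
    series: np.ndarray, labels: np.ndarray, which: str
) -> tuple[float, float]:
    """Mean and population standard deviation over frames labelled *which*.

    This is the rigid-body flexibility statistic: e.g. the standard
    deviation of the CORE-LID center-of-mass distance restricted to the
    open ensemble (σ_lid).
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(labels) == which
    if not mask.any():
        raise ValueError(f"ensemble {which!r} is empty")
    vals = series[mask]
    return float(vals.mean()), float(vals.std(ddof=0))
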