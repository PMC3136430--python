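"""Cα-resolution structure container and geometric primitives.

A :class:`CalphaStructure` is an ordered list of Cα positions with residue
numbers, an optional domain map (named inclusive residue ranges) and optional
per-domain exclusion ranges (residues omitted from that structure's
center-of-mass calculations, e.g. interdomain connector helices).

All geometry here is plain Cα geometry: Kabsch superposition, domain
center-of-mass distances, and backbone pseudodihedral angles defined over
four consecutive Cα atoms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class CalphaStructure:
    """Ordered Cα trace of a single chain.

    Parameters
    ----------
    residue_ids
        Strictly increasing 1-based residue numbers, one per Cα.
    coords
        ``(n, 3)`` float array of Cα positions in Å.
    chain_id
        Single-character chain identifier.
    domain_map
        Mapping of domain name to a list of inclusive ``(start, stop)``
        residue-number ranges.
    exclusions
        Mapping of domain name to residue ranges excluded from that
        domain's center of mass (connector helices and the like).
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    domain_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    exclusions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)
        if rid.ndim != 1 or xyz.shape != (rid.size, 3):
            raise ValueError("residue_ids and coords shapes are inconsistent")
        if rid.size and np.any(np.diff(rid) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        for name, ranges in self.domain_map.items():
            for lo, hi in ranges:
                if lo > hi or lo < rid.min() or hi > rid.max():
                    raise ValueError(
                        f"domain {name!r} range ({lo}, {hi}) outside residue ids"
                    )

    @property
    def n_residues(self) -> int:
        return int(self.residue_ids.size)

    def index_of(self, residue_id: int) -> int:
        idx = np.searchsorted(self.residue_ids, residue_id)
        if idx >= self.residue_ids.size or self.residue_ids[idx] != residue_id:
            raise KeyError(f"residue {residue_id} not in structure")
        return int(idx)

    def domain_indices(self, domain: str, apply_exclusions: bool = True) -> np.ndarray:
        """Array positions of the residues belonging to *domain*."""
        if domain not in self.domain_map:
            raise KeyError(f"domain {domain!r} not in domain map")
        mask = np.zeros(self.n_residues, dtype=bool)
        for lo, hi in self.domain_map[domain]:
            mask |= (self.residue_ids >= lo) & (self.residue_ids <= hi)
        if apply_exclusions:
            for lo, hi in self.exclusions.get(domain, []):
                mask &= ~((self.residue_ids >= lo) & (self.residue_ids <= hi))
        return np.nonzero(mask)[0]

    def with_coords(self, coords: np.ndarray) -> "CalphaStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed; Cα only, single chain)
# ---------------------------------------------------------------------------

def read_calpha(pdb_text: str, chain: str = "A") -> CalphaStructure:
    """Parse the Cα trace of one chain from PDB-format text.

    Alternate locations resolve to the first occurrence; insertion codes are
    rejected; a residue in the chain without a CA atom is an error that lists
    the offending residues.
    """
    pdb_file = pdb_io.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain!r} is empty or absent")
    if np.any(atoms.ins_code != ""):
        raise ValueError("insertion codes are not supported")
    ca = atoms[atoms.atom_name == "CA"]
    missing = sorted(set(atoms.res_id.tolist()) - set(ca.res_id.tolist()))
    if missing:
        raise ValueError(f"residues missing a CA atom: {missing}")
    order = np.argsort(ca.res_id, kind="stable")
    ca = ca[order]
    res_id, first = np.unique(ca.res_id, return_index=True)
    return CalphaStructure(
        residue_ids=res_id, coords=ca.coord[first], chain_id=chain
    )


def write_calpha(structure: CalphaStructure) -> str:
    """Render a minimal single-chain, CA-only PDB text."""
    n = structure.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords
    atoms.chain_id[:] = structure.chain_id
    atoms.res_id = structure.residue_ids
    atoms.res_name[:] = "GLY"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(atoms)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Superposition and center-of-mass geometry
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray | CalphaStructure,
    reference: np.ndarray | CalphaStructure,
    selection: np.ndarray | None = None,
) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Parameters
    ----------
    mobile, reference
        ``(n, 3)`` coordinate arrays or structures with matching residue
        ordering.
    selection
        Array positions used for the fit (and for the reported rmsd);
        defaults to all residues.

    Returns
    -------
    rotation, translation, rmsd
        ``x_fit = rotation.apply(x - mobile_centroid) + reference_centroid``;
        rmsd is over the selection after superposition, in Å.
    """
    xm = mobile.coords if isinstance(mobile, CalphaStructure) else np.asarray(mobile)
    xr = reference.coords if isinstance(reference, CalphaStructure) else np.asarray(reference)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        xm, xr = xm[sel], xr[sel]
    if xm.shape != xr.shape:
        raise ValueError("mobile and reference selections differ in size")
    if xm.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    a, b = xm - cm, xr - cr
    # collinear selections have a rank-deficient covariance -> no unique fit
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    rot, rssd = Rotation.align_vectors(b, a)
    rmsd = float(rssd / np.sqrt(xm.shape[0]))
    return rot, cr - rot.apply(cm), rmsd


def apply_superposition(
    coords: np.ndarray, rotation: Rotation, mobile_centroid: np.ndarray,
    reference_centroid: np.ndarray
) -> np.ndarray:
    return rotation.apply(coords - mobile_centroid) + reference_centroid


def rmsd_after_superposition(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """Convenience wrapper returning only the optimal rmsd."""
    return superpose(mobile, reference, selection)[2]


def com_distance(
    structure: CalphaStructure,
    domain_a: str,
    domain_b: str,
    coords: np.ndarray | None = None,
) -> float:
    """Unweighted Cα center-of-mass distance between two mapped domains.

    Residues listed in the structure's exclusion map for a domain are left
    out of that domain's center of mass. ``coords`` overrides the structure's
    own coordinates (e.g. a trajectory frame sharing its residue ordering).
    """
    xyz = structure.coords if coords is None else np.asarray(coords)
    out = []
    for name in (domain_a, domain_b):
        idx = structure.domain_indices(name)
        if idx.size == 0:
            raise ValueError(f"domain {name!r} is empty after exclusions")
        out.append(xyz[idx].mean(axis=0))
    return float(np.linalg.norm(out[0] - out[1]))


# ---------------------------------------------------------------------------
# Pseudodihedrals
# ---------------------------------------------------------------------------

def wrap_angle(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into (-180, 180]."""
    wrapped = -((-np.asarray(angle_deg) + 180.0) % 360.0 - 180.0)
    return wrapped if np.ndim(angle_deg) else float(wrapped)


def angular_difference(a_deg, b_deg):
    """Minimal-image angular difference a - b, wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def pseudodihedrals(coords: np.ndarray) -> np.ndarray:
    """Backbone pseudodihedral angle per residue, in degrees.

    The angle assigned to residue index ``i`` is the torsion about the
    virtual bond between residues ``i-1`` and ``i``, defined over the Cα
    atoms ``(i-2, i-1, i, i+1)``. Termini without four atoms get ``nan``,
    as do degenerate (collinear) quadruples. For a trajectory pass a
    ``(n_frames, n_res, 3)`` array; a ``(n_res, n_frames_like)`` output
    becomes ``(n_frames, n_res)``.
    """
    xyz = np.asarray(coords, dtype=float)
    single = xyz.ndim == 2
    if single:
        xyz = xyz[None]
    n = xyz.shape[1]
    if n < 4:
        raise ValueError("pseudodihedrals need at least 4 residues")
    p0, p1, p2, p3 = xyz[:, :-3], xyz[:, 1:-2], xyz[:, 2:-1], xyz[:, 3:]
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # collinear triples give a zero normal -> undefined torsion
    bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    ang[bad] = np.nan
    out = np.full((xyz.shape[0], n), np.nan)
    out[:, 2:-1] = wrap_angle(ang)
    return out[0] if single else out
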