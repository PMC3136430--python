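"""Single-well Cα Gō potentials and their exponential double-well mixture.

Each reference conformation defines a single-well structure-based potential:
harmonic virtual bonds at native lengths, a generic double-basin pseudo-bond
angle term (permitting both helix-like and extended angles), per-well cosine
dihedrals with minima at the native torsions, a 12-10-6 attractive well for
every native contact, and r^-12 excluded volume for all other long-range
pairs. Two such potentials, V_O and V_C, combine into a smooth double well by
exponential averaging:

    E = -(1/beta_mix) * ln[ exp(-beta_mix (E_O + eps_O)) + exp(-beta_mix E_C) ]

where ``eps_O`` shifts the relative stability of the open state and
``beta_mix`` controls how sharply the mixture interpolates between wells
(large beta_mix approaches min(E_O + eps_O, E_C) and raises the barrier).

The contact builder is a deliberately simple Cα-distance rule (cutoff 8 Å,
sequence separation >= 3, uniform depths) rather than an all-atom
contact/energy assignment; a per-contact energy override table can restore
arbitrary depths. Contact energies are multiplied by ``contact_scale``
(default 2.5) identically in both wells to compensate for the conformational
entropy introduced by the generic angle term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .structures import CalphaStructure

# ---------------------------------------------------------------------------
# Defaults (all exposed through the builders / config)
# ---------------------------------------------------------------------------

CONTACT_CUTOFF = 8.0          # Å, Cα–Cα native-contact threshold
MIN_SEPARATION = 3            # minimum |i-j| for a contact
BASE_WELL_DEPTH = 0.9         # kcal/mol per contact before scaling
CONTACT_SCALE = 2.5           # uniform contact-energy multiplier
BOND_K = 100.0                # kcal/mol/Å^2
ANGLE_THETA = (92.0, 130.0)   # degrees, generic double-basin angle minima
ANGLE_WIDTH = 20.0            # degrees, Gaussian basin width
ANGLE_HEIGHT = 4.0            # kcal/mol, basin depth scale
DIHEDRAL_K = 3.0              # kcal/mol
EV_RADIUS = 4.0               # Å, excluded-volume radius
EV_EPSILON = 1.0              # kcal/mol at r = EV_RADIUS
KB_KCAL = 0.0019872041        # kcal/mol/K


@dataclass(frozen=True)
class Contact:
    """A native contact between residues *i* and *j* (array positions)."""

    i: int
    j: int
    native_distance: float
    well_depth: float
    provenance: str = "shared"  # O | C | shared | ligand

    def __post_init__(self):
        if self.native_distance <= 0:
            raise ValueError("native_distance must be positive")
        if self.well_depth <= 0:
            raise ValueError("well_depth must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class GoPotential:
    """A single-well Cα Gō potential anchored at one reference conformation."""

    reference: CalphaStructure
    contacts: tuple[Contact, ...]
    contact_scale: float = CONTACT_SCALE
    bond_k: float = BOND_K
    angle_theta: tuple[float, float] = ANGLE_THETA
    angle_width: float = ANGLE_WIDTH
    angle_height: float = ANGLE_HEIGHT
    dihedral_k: float = DIHEDRAL_K
    dihedral_multipliers: dict[int, float] = field(default_factory=dict)
    ev_radius: float = EV_RADIUS
    ev_epsilon: float = EV_EPSILON
    min_separation: int = MIN_SEPARATION

    def __post_init__(self):
        if self.contact_scale <= 0:
            raise ValueError("contact_scale must be positive")
        seen = set()
        for c in self.contacts:
            if c.pair in seen:
                raise ValueError(f"duplicate contact pair {c.pair}")
            seen.add(c.pair)

    @property
    def n_residues(self) -> int:
        return self.reference.n_residues

    def _arrays(self):
        """Pack parameters into the flat arrays the numba kernel consumes."""
        x0 = self.reference.coords
        n = x0.shape[0]
        bond_r0 = np.linalg.norm(np.diff(x0, axis=0), axis=1)
        phi0 = _native_torsions(x0)
        dk = np.full(max(n - 3, 0), self.dihedral_k)
        # a residue-level stiffness multiplier softens/stiffens every torsion
        # whose quadruple contains that residue (0-based array position)
        for pos, mult in self.dihedral_multipliers.items():
            lo, hi = max(0, pos - 3), min(n - 3, pos + 1)
            dk[lo:hi] *= mult
        ci = np.array([c.i for c in self.contacts], dtype=np.int64)
        cj = np.array([c.j for c in self.contacts], dtype=np.int64)
        cr0 = np.array([c.native_distance for c in self.contacts])
        ceps = np.array([c.well_depth * self.contact_scale for c in self.contacts])
        pairset = {c.pair for c in self.contacts}
        evi, evj = [], []
        for i in range(n):
            for j in range(i + self.min_separation, n):
                if (i, j) not in pairset:
                    evi.append(i)
                    evj.append(j)
        return dict(
            bond_r0=bond_r0, bond_k=self.bond_k,
            theta1=np.radians(self.angle_theta[0]),
            theta2=np.radians(self.angle_theta[1]),
            angle_w=np.radians(self.angle_width), angle_h=self.angle_height,
            phi0=phi0, dihedral_k=dk,
            ci=ci, cj=cj, cr0=cr0, ceps=ceps,
            evi=np.array(evi, dtype=np.int64), evj=np.array(evj, dtype=np.int64),
            ev_sigma=self.ev_radius, ev_eps=self.ev_epsilon,
        )

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Potential energy (kcal/mol) and forces (kcal/mol/Å)."""
        coords = np.ascontiguousarray(coords, dtype=np.float64)
        if coords.shape != (self.n_residues, 3):
            raise ValueError("conformation size does not match the model")
        p = self._packed
        e, f = _single_well_energy_forces(
            coords, p["bond_r0"], p["bond_k"], p["theta1"], p["theta2"],
            p["angle_w"], p["angle_h"], p["phi0"], p["dihedral_k"],
            p["ci"], p["cj"], p["cr0"], p["ceps"],
            p["evi"], p["evj"], p["ev_sigma"], p["ev_eps"],
        )
        return float(e), f

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords)[0]

    @property
    def _packed(self):
        cached = self.__dict__.get("_packed_cache")
        if cached is None:
            cached = self._arrays()
            object.__setattr__(self, "_packed_cache", cached)
        return cached


@dataclass(frozen=True)
class DoubleWellModel:
    """Exponential mixture of open- and closed-state Gō potentials."""

    potential_open: GoPotential
    potential_closed: GoPotential
    eps_open: float = 0.0
    beta_mix: float = 0.1  # 1/(kcal/mol)

    def __post_init__(self):
        if self.beta_mix <= 0:
            raise ValueError("beta_mix must be positive")
        if self.potential_open.n_residues != self.potential_closed.n_residues:
            raise ValueError("wells differ in residue count")

    @property
    def n_residues(self) -> int:
        return self.potential_open.n_residues

    def with_eps_open(self, eps_open: float) -> "DoubleWellModel":
        return replace(self, eps_open=eps_open)

    def mixed_energy_forces(self, coords):
        e_o, f_o = self.potential_open.energy_forces(coords)
        e_c, f_c = self.potential_closed.energy_forces(coords)
        if not (np.isfinite(e_o) and np.isfinite(e_c)):
            raise FloatingPointError(
                f"non-finite single-well energy (E_O={e_o}, E_C={e_c})"
            )
        e, w_o = _mix(e_o + self.eps_open, e_c, self.beta_mix)
        return e, w_o * f_o + (1.0 - w_o) * f_c, e_o, e_c

    def mixed_energy(self, coords) -> float:
        return self.mixed_energy_forces(coords)[0]

    def energy_breakdown(self, coords) -> dict:
        e, _, e_o, e_c = self.mixed_energy_forces(coords)
        shifted_o = e_o + self.eps_open
        return {
            "E": e,
            "E_O": e_o,
            "E_C": e_c,
            "E_O_shifted": shifted_o,
            "dominant_well": "O" if shifted_o < e_c else "C",
        }


def _mix(e_o_shifted: float, e_c: float, beta: float) -> tuple[float, float]:
    """Overflow-safe two-term logsumexp mix; returns (energy, weight of O)."""
    lo = min(e_o_shifted, e_c)
    z_o = np.exp(-beta * (e_o_shifted - lo))
    z_c = np.exp(-beta * (e_c - lo))
    e = lo - np.log(z_o + z_c) / beta
    return float(e), float(z_o / (z_o + z_c))


def mixed_energy(model: DoubleWellModel, coords) -> float:
    """Functional alias for :meth:`DoubleWellModel.mixed_energy`."""
    return model.mixed_energy(coords)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_contacts(
    structure: CalphaStructure,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
    well_depth: float = BASE_WELL_DEPTH,
    provenance: str = "shared",
    depth_overrides: dict[tuple[int, int], float] | None = None,
) -> list[Contact]:
    """All residue pairs with |i-j| >= min_separation within *cutoff* Å.

    ``depth_overrides`` maps ``(i, j)`` array-position pairs to per-contact
    well depths, replacing the uniform default.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = structure.coords
    n = xyz.shape[0]
    out = []
    for i in range(n):
        d = np.linalg.norm(xyz[i + min_separation:] - xyz[i], axis=1)
        for k in np.nonzero(d <= cutoff)[0]:
            j = i + min_separation + int(k)
            depth = well_depth
            if depth_overrides and (i, j) in depth_overrides:
                depth = depth_overrides[(i, j)]
            out.append(Contact(i, j, float(d[k]), depth, provenance))
    return out


def read_depth_overrides(tsv_text: str) -> dict[tuple[int, int], float]:
    """Parse a per-contact energy table: three columns ``i  j  depth``."""
    out = {}
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j, depth = line.split()
        out[(int(i), int(j))] = float(depth)
    return out


def partition_contacts(
    contacts_open: list[Contact], contacts_closed: list[Contact]
) -> tuple[list[Contact], list[Contact], list[tuple[Contact, Contact]]]:
    """Split two contact lists into (O-unique, C-unique, shared) by pair.

    Shared contacts keep both native distances, returned as ``(O, C)`` pairs.
    """
    by_pair_c = {c.pair: c for c in contacts_closed}
    pairs_o = {c.pair for c in contacts_open}
    o_unique = [replace(c, provenance="O") for c in contacts_open
                if c.pair not in by_pair_c]
    c_unique = [replace(c, provenance="C") for c in contacts_closed
                if c.pair not in pairs_o]
    shared = [(replace(c, provenance="shared"),
               replace(by_pair_c[c.pair], provenance="shared"))
              for c in contacts_open if c.pair in by_pair_c]
    return o_unique, c_unique, shared


def add_ligand_contacts(
    potential_closed: GoPotential,
    pairs: list[tuple[int, int]],
    closed_structure: CalphaStructure | None = None,
    well_depth: float = BASE_WELL_DEPTH,
) -> GoPotential:
    """Augment the closed-state potential with ligand-mediated contacts.

    Native distances come from the closed structure (defaults to the
    potential's own reference); the open potential is never touched. Pairs
    already present as native contacts are an error.
    """
    ref = closed_structure or potential_closed.reference
    existing = {c.pair for c in potential_closed.contacts}
    extra = []
    for i, j in pairs:
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        if (i, j) in existing:
            raise ValueError(f"pair ({i}, {j}) is already a native contact")
        d = float(np.linalg.norm(ref.coords[i] - ref.coords[j]))
        extra.append(Contact(i, j, d, well_depth, "ligand"))
    return replace(potential_closed,
                   contacts=potential_closed.contacts + tuple(extra))


INTERFACE_WELL_DEPTH = 0.45   # kcal/mol, interdomain (state-unique) contacts


def build_double_well(
    open_structure: CalphaStructure,
    closed_structure: CalphaStructure,
    ligand_pairs: list[tuple[int, int]] | None = None,
    eps_open: float = 0.0,
    beta_mix: float = 0.1,
    contact_scale: float = CONTACT_SCALE,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
    well_depth: float = BASE_WELL_DEPTH,
    interface_depth: float | None = INTERFACE_WELL_DEPTH,
    depth_overrides: dict[tuple[int, int], float] | None = None,
    dihedral_multipliers: dict[int, float] | None = None,
) -> DoubleWellModel:
    """Build the full double-well model from two reference conformations.

    Ligand pairs are given as 1-based residue-number pairs and augment the
    closed well only. ``interface_depth`` is the well depth given to
    state-unique (interdomain) and ligand contacts; intradomain contacts
    shared by both states keep ``well_depth``. Pass ``interface_depth=None``
    for fully uniform depths. ``dihedral_multipliers`` maps residue numbers
    to local backbone-stiffness factors (e.g. 0.2 for glycine-like
    softening, 5 for proline-like stiffening), applied identically in both
    wells.
    """
    contacts_o = build_contacts(open_structure, cutoff, min_separation,
                                well_depth, "O", depth_overrides)
    contacts_c = build_contacts(closed_structure, cutoff, min_separation,
                                well_depth, "C", depth_overrides)
    if interface_depth is not None:
        pairs_o = {c.pair for c in contacts_o}
        pairs_c = {c.pair for c in contacts_c}
        shared = pairs_o & pairs_c
        override = depth_overrides or {}
        contacts_o = [c if c.pair in shared or c.pair in override
                      else replace(c, well_depth=interface_depth)
                      for c in contacts_o]
        contacts_c = [c if c.pair in shared or c.pair in override
                      else replace(c, well_depth=interface_depth)
                      for c in contacts_c]
    mult = {}
    for res_num, m in (dihedral_multipliers or {}).items():
        mult[open_structure.index_of(int(res_num))] = float(m)
    mk = lambda ref, cts: GoPotential(
        reference=ref, contacts=tuple(cts), contact_scale=contact_scale,
        dihedral_multipliers=mult, min_separation=min_separation,
    )
    pot_o = mk(open_structure, contacts_o)
    pot_c = mk(closed_structure, contacts_c)
    if ligand_pairs:
        idx_pairs = [
            (closed_structure.index_of(a), closed_structure.index_of(b))
            for a, b in ligand_pairs
        ]
        pot_c = add_ligand_contacts(
            pot_c, idx_pairs,
            well_depth=(interface_depth if interface_depth is not None
                        else well_depth))
    return DoubleWellModel(pot_o, pot_c, eps_open=eps_open, beta_mix=beta_mix)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON)
# ---------------------------------------------------------------------------

def model_to_json(model: DoubleWellModel) -> str:
    def pot(p: GoPotential):
        return {
            "residue_ids": p.reference.residue_ids.tolist(),
            "coords": p.reference.coords.tolist(),
            "chain_id": p.reference.chain_id,
            "domain_map": {k: [list(r) for r in v]
                           for k, v in p.reference.domain_map.items()},
            "exclusions": {k: [list(r) for r in v]
                           for k, v in p.reference.exclusions.items()},
            "contacts": [[c.i, c.j, c.native_distance, c.well_depth,
                          c.provenance] for c in p.contacts],
            "contact_scale": p.contact_scale,
            "bond_k": p.bond_k,
            "angle_theta": list(p.angle_theta),
            "angle_width": p.angle_width,
            "angle_height": p.angle_height,
            "dihedral_k": p.dihedral_k,
            "dihedral_multipliers": {str(k): v
                                     for k, v in p.dihedral_multipliers.items()},
            "ev_radius": p.ev_radius,
            "ev_epsilon": p.ev_epsilon,
            "min_separation": p.min_separation,
        }

    return json.dumps({
        "format": "gohinge-double-well",
        "version": 1,
        "eps_open": model.eps_open,
        "beta_mix": model.beta_mix,
        "potential_open": pot(model.potential_open),
        "potential_closed": pot(model.potential_closed),
    })


def model_from_json(text: str) -> DoubleWellModel:
    doc = json.loads(text)
    if doc.get("format") != "gohinge-double-well" or doc.get("version") != 1:
        raise ValueError("unrecognized model file format/version")

    def pot(d):
        ref = CalphaStructure(
            residue_ids=np.array(d["residue_ids"]),
            coords=np.array(d["coords"]),
            chain_id=d["chain_id"],
            domain_map={k: [tuple(r) for r in v]
                        for k, v in d["domain_map"].items()},
            exclusions={k: [tuple(r) for r in v]
                        for k, v in d["exclusions"].items()},
        )
        contacts = tuple(Contact(int(i), int(j), r0, depth, prov)
                         for i, j, r0, depth, prov in d["contacts"])
        return GoPotential(
            reference=ref, contacts=contacts,
            contact_scale=d["contact_scale"], bond_k=d["bond_k"],
            angle_theta=tuple(d["angle_theta"]), angle_width=d["angle_width"],
            angle_height=d["angle_height"], dihedral_k=d["dihedral_k"],
            dihedral_multipliers={int(k): v
                                  for k, v in d["dihedral_multipliers"].items()},
            ev_radius=d["ev_radius"], ev_epsilon=d["ev_epsilon"],
            min_separation=d["min_separation"],
        )

    return DoubleWellModel(pot(doc["potential_open"]), pot(doc["potential_closed"]),
                           eps_open=doc["eps_open"], beta_mix=doc["beta_mix"])


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

def _native_torsions(x0: np.ndarray) -> np.ndarray:
    """Torsion (radians) for each consecutive Cα quadruple of the reference."""
    n = x0.shape[0]
    out = np.empty(max(n - 3, 0))
    for q in range(n - 3):
        out[q] = _torsion(x0[q], x0[q + 1], x0[q + 2], x0[q + 3])
    return out


@njit(cache=True)
def _torsion(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    x = np.dot(n1, n2)
    return np.arctan2(y, x)


@njit(cache=True)
def _single_well_ef(
    x, bond_r0, bond_k, theta1, theta2, angle_w, angle_h, phi0, dihedral_k,
    ci, cj, cr0, ceps, evi, evj, ev_sigma, ev_eps, f,
):
    """Energy of one well; forces accumulated into preallocated *f* (zeroed).

    All vector algebra is written out in scalars to avoid per-call
    allocations — this function runs once per integrator step per well.
    """
    n = x.shape[0]
    f[:] = 0.0
    energy = 0.0

    # --- harmonic virtual bonds
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[i]
        energy += 0.5 * bond_k * dr * dr
        coef = bond_k * dr / r
        f[i, 0] += coef * dx
        f[i, 1] += coef * dy
        f[i, 2] += coef * dz
        f[i + 1, 0] -= coef * dx
        f[i + 1, 1] -= coef * dy
        f[i + 1, 2] -= coef * dz

    # --- generic double-basin pseudo-bond angles (stable two-term logsumexp)
    inv_w2 = 1.0 / (angle_w * angle_w)
    for j in range(1, n - 1):
        ax = x[j - 1, 0] - x[j, 0]
        ay = x[j - 1, 1] - x[j, 1]
        az = x[j - 1, 2] - x[j, 2]
        bx = x[j + 1, 0] - x[j, 0]
        by = x[j + 1, 1] - x[j, 1]
        bz = x[j + 1, 2] - x[j, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        cos_t = (ax * bx + ay * by + az * bz) / (na * nb)
        if cos_t > 1.0 - 1e-10:
            cos_t = 1.0 - 1e-10
        elif cos_t < -1.0 + 1e-10:
            cos_t = -1.0 + 1e-10
        theta = np.arccos(cos_t)
        u1 = 0.5 * (theta - theta1) ** 2 * inv_w2
        u2 = 0.5 * (theta - theta2) ** 2 * inv_w2
        umin = min(u1, u2)
        g1 = np.exp(-(u1 - umin))
        g2 = np.exp(-(u2 - umin))
        energy += angle_h * (umin - np.log(g1 + g2))
        dv_dtheta = angle_h * inv_w2 * (
            g1 * (theta - theta1) + g2 * (theta - theta2)
        ) / (g1 + g2)
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        coef = dv_dtheta / sin_t
        inab = 1.0 / (na * nb)
        inaa = cos_t / (na * na)
        inbb = cos_t / (nb * nb)
        fix = coef * (bx * inab - ax * inaa)
        fiy = coef * (by * inab - ay * inaa)
        fiz = coef * (bz * inab - az * inaa)
        fkx = coef * (ax * inab - bx * inbb)
        fky = coef * (ay * inab - by * inbb)
        fkz = coef * (az * inab - bz * inbb)
        f[j - 1, 0] += fix
        f[j - 1, 1] += fiy
        f[j - 1, 2] += fiz
        f[j + 1, 0] += fkx
        f[j + 1, 1] += fky
        f[j + 1, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # --- per-well cosine dihedrals
    for q in range(n - 3):
        b1x = x[q + 1, 0] - x[q, 0]
        b1y = x[q + 1, 1] - x[q, 1]
        b1z = x[q + 1, 2] - x[q, 2]
        b2x = x[q + 2, 0] - x[q + 1, 0]
        b2y = x[q + 2, 1] - x[q + 1, 1]
        b2z = x[q + 2, 2] - x[q + 1, 2]
        b3x = x[q + 3, 0] - x[q + 2, 0]
        b3y = x[q + 3, 1] - x[q + 2, 1]
        b3z = x[q + 3, 2] - x[q + 2, 2]
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx = b2y * b3z - b2z * b3y
        ny = b2z * b3x - b2x * b3z
        nz = b2x * b3y - b2y * b3x
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        if m2 < 1e-18 or n2 < 1e-18:
            continue
        # (m x n) . b2
        cxx = my * nz - mz * ny
        cyy = mz * nx - mx * nz
        czz = mx * ny - my * nx
        y = (cxx * b2x + cyy * b2y + czz * b2z) / b2n
        xx = mx * nx + my * ny + mz * nz
        phi = np.arctan2(y, xx)
        k = dihedral_k[q]
        energy += k * (1.0 - np.cos(phi - phi0[q]))
        dv_dphi = k * np.sin(phi - phi0[q])
        ci_ = dv_dphi * b2n / m2
        cl_ = -dv_dphi * b2n / n2
        fix = ci_ * mx
        fiy = ci_ * my
        fiz = ci_ * mz
        flx = cl_ * nx
        fly = cl_ * ny
        flz = cl_ * nz
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        f[q, 0] += fix
        f[q, 1] += fiy
        f[q, 2] += fiz
        f[q + 1, 0] += -(1.0 + s12) * fix + s32 * flx
        f[q + 1, 1] += -(1.0 + s12) * fiy + s32 * fly
        f[q + 1, 2] += -(1.0 + s12) * fiz + s32 * flz
        f[q + 2, 0] += s12 * fix - (1.0 + s32) * flx
        f[q + 2, 1] += s12 * fiy - (1.0 + s32) * fly
        f[q + 2, 2] += s12 * fiz - (1.0 + s32) * flz
        f[q + 3, 0] += flx
        f[q + 3, 1] += fly
        f[q + 3, 2] += flz

    # --- 12-10-6 native contacts
    for c in range(ci.shape[0]):
        i = ci[c]
        j = cj[c]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = cr0[c] / r
        s6 = s ** 6
        s10 = s6 * s ** 4
        s12 = s6 * s6
        energy += ceps[c] * (13.0 * s12 - 18.0 * s10 + 4.0 * s6)
        dv_dr = ceps[c] * (-156.0 * s12 + 180.0 * s10 - 24.0 * s6) / r
        coef = -dv_dr / r
        f[i, 0] -= coef * dx
        f[i, 1] -= coef * dy
        f[i, 2] -= coef * dz
        f[j, 0] += coef * dx
        f[j, 1] += coef * dy
        f[j, 2] += coef * dz

    # --- excluded volume for non-native long-range pairs
    sig2 = ev_sigma * ev_sigma
    for c in range(evi.shape[0]):
        i = evi[c]
        j = evj[c]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = sig2 / r2
        if s2 < 0.04:  # r > 5 sigma: negligible
            continue
        s12 = s2 ** 6
        energy += ev_eps * s12
        coef = 12.0 * ev_eps * s12 / r2
        f[i, 0] -= coef * dx
        f[i, 1] -= coef * dy
        f[i, 2] -= coef * dz
        f[j, 0] += coef * dx
        f[j, 1] += coef * dy
        f[j, 2] += coef * dz

    return energy


def _single_well_energy_forces(
    x, bond_r0, bond_k, theta1, theta2, angle_w, angle_h, phi0, dihedral_k,
    ci, cj, cr0, ceps, evi, evj, ev_sigma, ev_eps,
):
    """Allocating wrapper around the in-place kernel (convenience API)."""
    f = np.zeros_like(x)
    e = _single_well_ef(
        x, bond_r0, bond_k, theta1, theta2, angle_w, angle_h, phi0,
        dihedral_k, ci, cj, cr0, ceps, evi, evj, ev_sigma, ev_eps, f,
    )
    return e, f
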