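"""Synthetic two-state hinge proteins and a 1-D diffusive double-well oracle.

The toy generator builds a single Cα chain of two locally rigid helical
lobes joined by a short hinge. Open and closed conformations share all
lobe-internal geometry and differ only by a rigid rotation of the second
lobe about the hinge pivot, so lobe-internal contacts are exactly shared
while the interdomain interface differs — the minimal geometry needed to
exercise a double-well structure-based model: shared contacts, O-unique and
C-unique contact sets, and a closed interface that a handful of ligand
pseudo-contacts can bridge.

The 1-D oracle is overdamped Brownian motion on the quartic double well
``V(x) = h ((x/a)^2 - 1)^2``, whose transition-path statistics are known
(in particular the diffusive bound p_TP <= 1/2), giving the downstream
separatrix machinery an independent testbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import pdist, squareform

from .structures import CalphaStructure

#: ideal helix-like spiral parameters: 1.5 Å rise, ~100 degrees per residue
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
#: radius chosen so consecutive Calpha atoms sit 3.8 Å apart
CA_CA_DISTANCE = 3.8
HINGE_LENGTH = 4
MIN_RESIDUES = 12  # two 4-residue lobes + 4 hinge residues
DEFAULT_JITTER = 0.05


@dataclass(frozen=True)
class ToySystem:
    """A generated two-conformation hinge protein."""

    open_structure: CalphaStructure
    closed_structure: CalphaStructure
    domain_map: dict[str, list[tuple[int, int]]]
    ligand_contacts: list[tuple[int, int]]
    seed: int

    @property
    def n_residues(self) -> int:
        return self.open_structure.n_residues


@dataclass(frozen=True)
class OneDDoubleWell:
    """Parameters of the quartic double-well Brownian oracle.

    Energies are in units of k_B T; lengths and time are dimensionless.
    """

    barrier_height: float = 5.0
    well_separation: float = 1.0
    diffusion_coefficient: float = 1.0
    timestep: float = 1e-3
    n_steps: int = 1_000_000
    seed: int = 0
    x0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("barrier_height", "well_separation",
                     "diffusion_coefficient", "timestep"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.timestep <= 0 or self.diffusion_coefficient < 0:
            raise ValueError("timestep must be > 0 and diffusion >= 0")
        if self.x0 is None:
            object.__setattr__(self, "x0", -self.well_separation)


def _helix_spiral(n: int) -> np.ndarray:
    """Ideal Cα spiral along +z with 3.8 Å consecutive spacing."""
    twist = np.radians(HELIX_TWIST_DEG)
    chord = np.sqrt(CA_CA_DISTANCE**2 - HELIX_RISE**2)
    radius = chord / (2.0 * np.sin(twist / 2.0))
    k = np.arange(n)
    return np.column_stack([
        radius * np.cos(k * twist),
        radius * np.sin(k * twist),
        HELIX_RISE * k,
    ])


def _renormalize_bonds(coords: np.ndarray) -> np.ndarray:
    """Rescale each virtual bond to exactly 3.8 Å, keeping jittered directions."""
    out = coords.copy()
    for i in range(len(coords) - 1):
        u = coords[i + 1] - coords[i]
        out[i + 1] = out[i] + CA_CA_DISTANCE * u / np.linalg.norm(u)
    return out


def _bend_at_pivot(coords: np.ndarray, pivot: int, bend_deg: float) -> np.ndarray:
    """Rigidly rotate residues after *pivot* about an axis through the pivot Cα.

    Rotation about an axis through the pivot atom preserves the pivot-to-next
    bond length, so the chain connectivity survives arbitrary hinge angles.
    """
    out = coords.copy()
    axis = np.array([0.0, 1.0, 0.0])
    rot = Rotation.from_rotvec(np.radians(bend_deg) * axis)
    p = coords[pivot]
    out[pivot + 1:] = rot.apply(coords[pivot + 1:] - p) + p
    return out


def make_toy_two_state(
    n_res: int = 44,
    hinge_angle_open: float = 150.0,
    hinge_angle_closed: float = 80.0,
    seed: int = 1,
    jitter: float = DEFAULT_JITTER,
    contact_cutoff: float = 8.0,
    min_separation: int = 3,
    n_ligand_contacts: int = 3,
) -> ToySystem:
    """Generate a deterministic two-lobe hinge protein in open and closed forms.

    The hinge angle is the interlobe angle: 180° is a straight chain and
    smaller angles fold lobe B back toward lobe A. Both conformations are
    built from one jittered base chain, so the construction is bitwise
    deterministic for fixed inputs and lobe-internal geometry is identical
    between the two states.
    """
    if n_res < MIN_RESIDUES:
        raise ValueError(
            f"n_res={n_res} too small to form two lobes; minimum is {MIN_RESIDUES}"
        )
    for name, ang in (("hinge_angle_open", hinge_angle_open),
                      ("hinge_angle_closed", hinge_angle_closed)):
        if not 0.0 < ang <= 180.0:
            raise ValueError(f"{name} must lie in (0, 180] degrees, got {ang}")

    n_lobe_a = (n_res - HINGE_LENGTH) // 2
    n_lobe_b = n_res - HINGE_LENGTH - n_lobe_a
    pivot = n_lobe_a + HINGE_LENGTH // 2  # middle of the hinge

    base = _helix_spiral(n_res)
    rng = np.random.default_rng(seed)
    base = base + jitter * rng.standard_normal(base.shape)
    base = _renormalize_bonds(base)

    open_xyz = _bend_at_pivot(base, pivot, 180.0 - hinge_angle_open)
    closed_xyz = _bend_at_pivot(base, pivot, 180.0 - hinge_angle_closed)

    res_ids = np.arange(1, n_res + 1)
    domain_map = {
        "core": [(1, n_lobe_a)],
        "hinge": [(n_lobe_a + 1, n_lobe_a + HINGE_LENGTH)],
        "lid": [(n_lobe_a + HINGE_LENGTH + 1, n_res)],
    }
    mk = lambda xyz: CalphaStructure(
        residue_ids=res_ids, coords=xyz, chain_id="A", domain_map=domain_map
    )
    open_s, closed_s = mk(open_xyz), mk(closed_xyz)

    ligand = _ligand_pseudo_contacts(
        closed_s, domain_map, contact_cutoff, min_separation, n_ligand_contacts
    )
    return ToySystem(
        open_structure=open_s,
        closed_structure=closed_s,
        domain_map=domain_map,
        ligand_contacts=ligand,
        seed=seed,
    )


def _ligand_pseudo_contacts(
    closed: CalphaStructure,
    domain_map: dict,
    cutoff: float,
    min_separation: int,
    k: int,
) -> list[tuple[int, int]]:
    """The k shortest closed-state inter-lobe pairs that are not native contacts.

    Mimics a ligand bridging the closed interface with a deterministic rule.
    """
    d = squareform(pdist(closed.coords))
    core = set(closed.domain_indices("core").tolist())
    lid = set(closed.domain_indices("lid").tolist())
    candidates = []
    n = closed.n_residues
    for i in range(n):
        for j in range(i + 1, n):
            if {i, j} & core and {i, j} & lid and j - i >= min_separation:
                if d[i, j] > cutoff:  # native contacts are excluded
                    candidates.append((d[i, j], i, j))
    candidates.sort()
    rid = closed.residue_ids
    return [(int(rid[i]), int(rid[j])) for _, i, j in candidates[:k]]


def brownian_1d(params: OneDDoubleWell) -> np.ndarray:
    """Overdamped Euler–Maruyama trajectory on ``V(x) = h ((x/a)^2 - 1)^2``.

    With k_B T = 1 the update is
    ``x += -D dV/dx dt + sqrt(2 D dt) xi``; the returned array includes the
    initial position, so its length is ``n_steps + 1``.
    """
    h, a = params.barrier_height, params.well_separation
    d_coef, dt = params.diffusion_coefficient, params.timestep
    rng = np.random.default_rng(params.seed)
    noise = np.sqrt(2.0 * d_coef * dt) * rng.standard_normal(params.n_steps)
    x = np.empty(params.n_steps + 1)
    x[0] = params.x0
    c = 4.0 * h / a**2
    xt = x[0]
    for t in range(params.n_steps):
        grad = c * xt * ((xt / a) ** 2 - 1.0)
        xt = xt - d_coef * grad * dt + noise[t]
        x[t + 1] = xt
    return x
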