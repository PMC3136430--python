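"""Langevin sampling of the double-well model.

The integrator is BAOAB-split Langevin dynamics: two half kicks (B) and two
half drifts (A) around an exact Ornstein-Uhlenbeck step (O). BAOAB gives
very accurate configurational averages at large timesteps, which is what the
ensemble statistics downstream consume. Units: kcal/mol, Å, ps; bead masses
are 1 in reduced units (kcal/mol ps^2/Å^2), so the nominal femtosecond
timestep sets the clock only through the friction coefficient.

Trajectories are bit-reproducible for a fixed seed (single-threaded kernel;
the noise stream is drawn inside one jitted loop).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .gomodel import DoubleWellModel, GoPotential, KB_KCAL, _single_well_ef

DIVERGENCE_THRESHOLD = 1.0e6  # kcal/mol; abort when |E| exceeds this


@dataclass(frozen=True)
class SimulationConfig:
    """Langevin run parameters.

    ``timestep`` is in femtoseconds (default 15), ``temperature`` in kelvin,
    ``friction`` in 1/ps; ``save_stride`` frames are kept every that many
    steps.
    """

    timestep: float = 15.0
    n_steps: int = 1_000_000
    temperature: float = 300.0
    friction: float = 0.2
    save_stride: int = 100
    seed: int = 0
    mass: float = 1.0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction < 0 or self.mass <= 0:
            raise ValueError("friction must be >= 0 and mass > 0")


@dataclass(frozen=True)
class Trajectory:
    """Strided frames plus per-frame energies of one Langevin run."""

    frames: np.ndarray          # (n_frames, n_res, 3)
    energy: np.ndarray          # mixed E per frame
    energy_open: np.ndarray     # E_O (unshifted)
    energy_closed: np.ndarray   # E_C
    config: SimulationConfig
    model_hash: str = ""
    seed: int = 0

    def __post_init__(self):
        expected = self.config.n_steps // self.config.save_stride
        if self.frames.shape[0] != expected:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != "
                f"floor(n_steps/save_stride) = {expected}"
            )
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("non-finite energies in trajectory")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def save(self, path) -> None:
        np.savez_compressed(
            path, frames=self.frames, energy=self.energy,
            energy_open=self.energy_open, energy_closed=self.energy_closed,
            config=np.array([self.config.timestep, self.config.n_steps,
                             self.config.temperature, self.config.friction,
                             self.config.save_stride, self.config.seed,
                             self.config.mass]),
            model_hash=np.array(self.model_hash), seed=np.array(self.seed),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        z = np.load(path, allow_pickle=False)
        c = z["config"]
        cfg = SimulationConfig(
            timestep=float(c[0]), n_steps=int(c[1]), temperature=float(c[2]),
            friction=float(c[3]), save_stride=int(c[4]), seed=int(c[5]),
            mass=float(c[6]),
        )
        return cls(frames=z["frames"], energy=z["energy"],
                   energy_open=z["energy_open"], energy_closed=z["energy_closed"],
                   config=cfg, model_hash=str(z["model_hash"]),
                   seed=int(z["seed"]))

    def energies_tsv(self) -> str:
        lines = ["frame\tE\tE_O\tE_C"]
        for k in range(self.n_frames):
            lines.append(f"{k}\t{self.energy[k]:.6f}\t"
                         f"{self.energy_open[k]:.6f}\t{self.energy_closed[k]:.6f}")
        return "\n".join(lines) + "\n"


class EnergyDivergenceError(RuntimeError):
    def __init__(self, step: int, energy: float):
        super().__init__(
            f"energy diverged at step {step} (|E| = {energy:.3g} exceeds "
            f"{DIVERGENCE_THRESHOLD:.0g}); check timestep/beta_mix/eps_open"
        )
        self.step = step


def total_time(config: SimulationConfig) -> float:
    """Total simulated time in nanoseconds (n_steps x timestep)."""
    return config.n_steps * config.timestep * 1.0e-6


def _as_double_well(model) -> DoubleWellModel:
    if isinstance(model, GoPotential):
        # single-well sampling: mix a well with itself (constant -ln2/beta
        # offset; identical forces)
        return DoubleWellModel(model, model, eps_open=0.0, beta_mix=1.0)
    return model


def run_langevin(
    model: DoubleWellModel | GoPotential,
    start: np.ndarray,
    config: SimulationConfig,
) -> Trajectory:
    """Sample the model with BAOAB Langevin dynamics from *start*.

    Raises :class:`EnergyDivergenceError` (with the failing step) if the
    mixed energy leaves ±10^6 kcal/mol.
    """
    dw = _as_double_well(model)
    x0 = np.ascontiguousarray(start, dtype=np.float64)
    if x0.shape != (dw.n_residues, 3):
        raise ValueError("start conformation does not match model size")
    e0 = dw.mixed_energy(x0)
    if not np.isfinite(e0):
        raise ValueError("non-finite initial energy")

    po, pc = dw.potential_open._packed, dw.potential_closed._packed
    dt_ps = config.timestep * 1.0e-3
    kbt = KB_KCAL * config.temperature
    frames, energies, fail_step, fail_e = _baoab_loop(
        x0, config.n_steps, config.save_stride, dt_ps, config.friction,
        kbt, config.mass, int(config.seed) & 0x7FFFFFFF,
        dw.eps_open, dw.beta_mix,
        po["bond_r0"], po["bond_k"], po["theta1"], po["theta2"],
        po["angle_w"], po["angle_h"], po["phi0"], po["dihedral_k"],
        po["ci"], po["cj"], po["cr0"], po["ceps"], po["evi"], po["evj"],
        po["ev_sigma"], po["ev_eps"],
        pc["bond_r0"], pc["bond_k"], pc["theta1"], pc["theta2"],
        pc["angle_w"], pc["angle_h"], pc["phi0"], pc["dihedral_k"],
        pc["ci"], pc["cj"], pc["cr0"], pc["ceps"], pc["evi"], pc["evj"],
        pc["ev_sigma"], pc["ev_eps"],
        DIVERGENCE_THRESHOLD,
    )
    if fail_step >= 0:
        raise EnergyDivergenceError(int(fail_step), float(fail_e))
    from .gomodel import model_to_json
    model_hash = ""
    if isinstance(model, DoubleWellModel):
        model_hash = hashlib.sha256(model_to_json(model).encode()).hexdigest()[:16]
    return Trajectory(
        frames=frames, energy=energies[:, 0], energy_open=energies[:, 1],
        energy_closed=energies[:, 2], config=config, model_hash=model_hash,
        seed=config.seed,
    )


@njit(cache=True)
def _baoab_loop(
    x0, n_steps, save_stride, dt, friction, kbt, mass, seed, eps_o, beta,
    o_bond_r0, o_bond_k, o_t1, o_t2, o_aw, o_ah, o_phi0, o_dk,
    o_ci, o_cj, o_cr0, o_ceps, o_evi, o_evj, o_evs, o_eve,
    c_bond_r0, c_bond_k, c_t1, c_t2, c_aw, c_ah, c_phi0, c_dk,
    c_ci, c_cj, c_cr0, c_ceps, c_evi, c_evj, c_evs, c_eve,
    divergence_threshold,
):
    np.random.seed(seed)
    n = x0.shape[0]
    n_frames = n_steps // save_stride
    frames = np.empty((n_frames, n, 3))
    energies = np.empty((n_frames, 3))
    x = x0.copy()
    v = np.zeros((n, 3))
    f_o = np.zeros((n, 3))
    f_c = np.zeros((n, 3))
    f = np.zeros((n, 3))
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kbt / mass)
    half = 0.5 * dt
    inv_m = 1.0 / mass

    e = 0.0
    e_o = 0.0
    e_c = 0.0
    for step in range(-1, n_steps):
        if step >= 0:
            for i in range(n):
                for d in range(3):
                    v[i, d] += half * f[i, d] * inv_m          # B
                    x[i, d] += half * v[i, d]                  # A
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * np.random.standard_normal()  # O
                    x[i, d] += half * v[i, d]                  # A
        e_o = _single_well_ef(
            x, o_bond_r0, o_bond_k, o_t1, o_t2, o_aw, o_ah, o_phi0, o_dk,
            o_ci, o_cj, o_cr0, o_ceps, o_evi, o_evj, o_evs, o_eve, f_o)
        e_c = _single_well_ef(
            x, c_bond_r0, c_bond_k, c_t1, c_t2, c_aw, c_ah, c_phi0, c_dk,
            c_ci, c_cj, c_cr0, c_ceps, c_evi, c_evj, c_evs, c_eve, f_c)
        a = e_o + eps_o
        lo = min(a, e_c)
        z_o = np.exp(-beta * (a - lo))
        z_c = np.exp(-beta * (e_c - lo))
        e = lo - np.log(z_o + z_c) / beta
        w_o = z_o / (z_o + z_c)
        w_c = 1.0 - w_o
        for i in range(n):
            for d in range(3):
                f[i, d] = w_o * f_o[i, d] + w_c * f_c[i, d]
        if step >= 0:
            for i in range(n):
                for d in range(3):
                    v[i, d] += half * f[i, d] * inv_m          # B
            if not np.isfinite(e) or abs(e) > divergence_threshold:
                k = step // save_stride
                return frames[:k], energies[:k], step, e
            if (step + 1) % save_stride == 0:
                k = step // save_stride
                frames[k] = x
                energies[k, 0] = e
                energies[k, 1] = e_o
                energies[k, 2] = e_c
    return frames, energies, -1, 0.0


def match_temperature(
    potential: GoPotential,
    contacts_all,
    target_q: float,
    t_range: tuple[float, float],
    config: SimulationConfig | None = None,
    tol: float = 0.01,
    max_iter: int = 12,
) -> tuple[float, float]:
    """Find the temperature at which a single-well run attains a target Q.

    Runs short single-well simulations started from the reference and
    bisects on temperature until the mean fraction of formed contacts
    (over ``contacts_all``, the well's full native set) matches ``target_q``.
    Returns ``(temperature, achieved_q)``.
    """
    from .coords import fraction_contacts_series

    if not 0.0 < target_q < 1.0:
        raise ValueError("target_q must lie in (0, 1)")
    t_lo, t_hi = t_range
    if not t_lo < t_hi:
        raise ValueError("temperature range bounds must be ordered")
    base = config or SimulationConfig(n_steps=50_000, save_stride=50)

    def mean_q(temp: float) -> float:
        cfg = SimulationConfig(
            timestep=base.timestep, n_steps=base.n_steps, temperature=temp,
            friction=base.friction, save_stride=base.save_stride,
            seed=base.seed, mass=base.mass,
        )
        traj = run_langevin(potential, potential.reference.coords, cfg)
        warm = traj.n_frames // 5
        return float(np.mean(
            fraction_contacts_series(traj.frames[warm:], contacts_all)))

    q_lo, q_hi = mean_q(t_lo), mean_q(t_hi)
    # Q decreases with temperature: Q(t_lo) >= Q(t_hi)
    if abs(q_lo - target_q) <= tol:
        return t_lo, q_lo
    if abs(q_hi - target_q) <= tol:
        return t_hi, q_hi
    if not (q_hi <= target_q <= q_lo):
        raise ValueError(
            f"target Q={target_q} not bracketed: Q({t_lo}K)={q_lo:.3f}, "
            f"Q({t_hi}K)={q_hi:.3f}"
        )
    t_mid, q_mid = t_lo, q_lo
    for _ in range(max_iter):
        t_mid = 0.5 * (t_lo + t_hi)
        q_mid = mean_q(t_mid)
        if abs(q_mid - target_q) <= tol:
            break
        if q_mid > target_q:
            t_lo = t_mid
        else:
            t_hi = t_mid
    return t_mid, q_mid
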