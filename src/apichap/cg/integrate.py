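"""Public simulation API: forces, single steps, full replica runs."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .system import CGSystem

ENERGY_TERMS = ("bond", "angle", "dihedral", "native", "repulsion",
                "debye_huckel", "hydrophobic")


@dataclass
class SimParams:
    """Run parameters in reduced units (lengths in Å).

    The source model's nominal "2 fs" step maps to dt = 0.005 reduced time
    units here; production scale is 1e8 steps x 10 replicas, desk scale is
    1e5-1e6 steps.
    """

    T_reduced: float = 0.4
    dt: float = 0.005
    friction: float = 0.1
    n_steps: int = 100_000
    save_interval: int = 100
    box: float = 250.0
    n_replicas: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.T_reduced < 0 or self.friction < 0:
            raise ValueError("T_reduced and friction must be >= 0")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")


@dataclass
class Trajectory:
    """Saved frames and per-frame energy breakdown for one replica."""

    frames: np.ndarray            # (n_frames, n_beads, 3)
    energies: dict                # term -> (n_frames,) incl. "kinetic"
    replica_id: int
    seed: int
    save_interval: int = 1
    dt: float = 0.005

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        for term, arr in self.energies.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {term} energy in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _kernel_args(system: CGSystem, ff: ForceField):
    return (system.box, system.pbc,
            system.bonds, system.bond_r0, ff.k_bond,
            system.angles, system.angle_th0, ff.k_angle,
            system.dihedrals, system.dihedral_phi0, ff.k_dihedral,
            system.native_pairs, system.native_r0, system.native_qq,
            ff.eps_native,
            system.nb_pairs, system.nb_qq, system.nb_hh,
            ff.eps_rep, ff.sigma_rep,
            ff.dh_prefactor, ff.debye_len, ff.lambda_hp, ff.sigma_hp)


def compute_forces(system: CGSystem, ff: ForceField,
                   positions: np.ndarray | None = None):
    """Forces (exact negative gradient) and the energy breakdown dict."""
    pos = system.positions if positions is None else \
        np.ascontiguousarray(positions, dtype=float)
    forces, energies, bad_i, bad_j = _kernels.forces_energies(
        pos, *_kernel_args(system, ff))
    if bad_i >= 0:
        raise RuntimeError(f"bead overlap (r < {_kernels.OVERLAP_R} Å) "
                           f"between beads {bad_i} and {bad_j}")
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0][0])
        raise RuntimeError(f"non-finite force on bead {bad}")
    breakdown = dict(zip(ENERGY_TERMS, energies))
    breakdown["potential"] = float(energies.sum())
    return forces, breakdown


def total_energy(system: CGSystem, ff: ForceField,
                 positions: np.ndarray | None = None) -> float:
    return compute_forces(system, ff, positions)[1]["potential"]


def _ou_coeffs(params: SimParams) -> tuple[float, float]:
    c1 = math.exp(-params.friction * params.dt)
    c2 = math.sqrt((1.0 - c1 * c1) * params.T_reduced)
    return c1, c2


def langevin_step(state, system: CGSystem, ff: ForceField,
                  params: SimParams, rng: np.random.Generator):
    """One BAOAB Langevin step; ``state`` is (positions, velocities).

    Returns the new (positions, velocities) pair.  With friction = 0 the
    step reduces to plain velocity Verlet (no thermostat).
    """
    pos, vel = state
    pos = np.ascontiguousarray(pos, dtype=float).copy()
    vel = np.ascontiguousarray(vel, dtype=float).copy()
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
        raise ValueError("non-finite positions or velocities")
    forces, _ = compute_forces(system, ff, pos)
    c1, c2 = _ou_coeffs(params)
    noise = rng.standard_normal((1, *pos.shape))
    status, bad_i, bad_j = _kernels.run_block(
        pos, vel, forces, noise, params.dt, c1, c2,
        *_kernel_args(system, ff))
    _raise_for_status(status, bad_i, bad_j, params)
    return pos, vel


def _raise_for_status(status, bad_i, bad_j, params):
    if status == 1:
        raise RuntimeError(f"bead overlap between {bad_i} and {bad_j} "
                           "during integration")
    if status == 2:
        raise RuntimeError("integration blew up (per-step displacement > "
                           f"{_kernels.MAX_STEP_DISP} Å); try a smaller dt "
                           f"than {params.dt}")


def _frame_energies(system, ff, pos, vel) -> dict:
    _, breakdown = compute_forces(system, ff, pos)
    breakdown["kinetic"] = float(0.5 * np.sum(vel * vel))
    return breakdown


def run_replica(system: CGSystem, ff: ForceField, params: SimParams,
                replica_id: int, seed: int) -> Trajectory:
    rng = np.random.default_rng(seed)
    pos = system.positions.copy()
    vel = rng.standard_normal(pos.shape) * math.sqrt(params.T_reduced)
    forces, _ = compute_forces(system, ff, pos)
    c1, c2 = _ou_coeffs(params)
    args = _kernel_args(system, ff)

    frames = [pos.copy()]
    energy_rows = [_frame_energies(system, ff, pos, vel)]
    n_blocks, rem = divmod(params.n_steps, params.save_interval)
    sizes = [params.save_interval] * n_blocks + ([rem] if rem else [])
    for size in sizes:
        noise = rng.standard_normal((size, *pos.shape))
        status, bad_i, bad_j = _kernels.run_block(
            pos, vel, forces, noise, params.dt, c1, c2, *args)
        _raise_for_status(status, bad_i, bad_j, params)
        frames.append(pos.copy())
        energy_rows.append(_frame_energies(system, ff, pos, vel))
    energies = {key: np.array([row[key] for row in energy_rows])
                for key in energy_rows[0]}
    return Trajectory(frames=np.array(frames), energies=energies,
                      replica_id=replica_id, seed=seed,
                      save_interval=params.save_interval, dt=params.dt)


def run_simulation(system: CGSystem, ff: ForceField,
                   params: SimParams) -> list[Trajectory]:
    """Run ``n_replicas`` independent trajectories.

    Replica seeds are spawned deterministically from the master seed, so a
    given (seed, configuration) pair always yields identical trajectories.
    """
    if system.extent() > params.box:
        raise ValueError("initial system does not fit in the box")
    children = np.random.SeedSequence(params.seed).spawn(params.n_replicas)
    out = []
    for rid, child in enumerate(children):
        seed = int(child.generate_state(1)[0])
        out.append(run_replica(system, ff, params, rid, seed))
    return out


def native_contact_fraction(system: CGSystem, positions: np.ndarray,
                            tolerance: float = 1.2) -> float:
    """Q: fraction of native pairs within tolerance * native distance."""
    if len(system.native_pairs) == 0:
        raise ValueError("system has no native contacts")
    d = positions[system.native_pairs[:, 0]] \
        - positions[system.native_pairs[:, 1]]
    if system.pbc:
        d -= system.box * np.round(d / system.box)
    r = np.linalg.norm(d, axis=1)
    return float(np.mean(r <= tolerance * system.native_r0))
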