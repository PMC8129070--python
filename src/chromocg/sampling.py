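"""Langevin dynamics and Debye-length Hamiltonian replica exchange.

The integrator is a BAOAB-splitting Langevin scheme at fixed temperature.
Point beads translate; each DNA base-pair body (ellipsoid centre plus two
phosphate virtual sites) moves as one rigid body with an isotropic-inertia
quaternion rotation.  Replica exchange swaps configurations between
replicas that differ only in the Debye length of the screened-Coulomb
term, with the standard Hamiltonian-exchange Metropolis rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from chromocg import constants
from chromocg.energetics import EnergyModel
from chromocg.geometry import quat_multiply, quat_normalize, rotvec_to_quat

__all__ = [
    "LangevinParams",
    "ChromatinDynamics",
    "GenericLangevinDynamics",
    "ReplicaLadder",
    "RemdResult",
    "exchange_probability",
    "run_debye_remd",
    "langevin_step",
]

#: isotropic moment of inertia of one base-pair body, g/mol A^2
BODY_INERTIA = 2.3e4


class SamplingError(RuntimeError):
    pass


@dataclass
class LangevinParams:
    dt_fs: float = 10.0
    friction: float = 0.5       # 1 / internal time unit
    temperature: float = constants.T_REF

    @property
    def dt(self) -> float:
        """Time step in internal units."""
        return self.dt_fs / constants.TIME_UNIT_FS


def _ou_coefficients(friction: float, dt: float) -> tuple[float, float]:
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    return c1, c2


class ChromatinDynamics:
    """Langevin sampler for one chemically specific system.

    ``bias`` may be a callable ``(prot, bpos, bquat) -> (energy, f_prot,
    f_body)`` adding e.g. an umbrella restraint; its torque contribution is
    assumed zero (restraints act on positions).
    """

    def __init__(self, model: EnergyModel, params: LangevinParams | None = None,
                 seed: int = 0, bias=None, initial_coords=None):
        self.model = model
        self.params = params or LangevinParams()
        self.rng = np.random.default_rng(seed)
        self.bias = bias
        if initial_coords is not None:
            self.prot, self.bpos, self.bquat = [np.array(a) for a in initial_coords]
        else:
            self.prot, self.bpos, self.bquat = model.coords_from_system()
        self.prot_mass = np.array([b.mass for b in model.system.protein_beads]).reshape(-1, 1)
        self.n_bodies = model.n_bodies
        self.v_prot = np.zeros_like(self.prot)
        self.v_body = np.zeros((self.n_bodies, 3))
        self.w_body = np.zeros((self.n_bodies, 3))
        self.step_count = 0
        self._forces = None

    # -- coordinate/velocity bundles for replica swaps ---------------------
    def get_state(self):
        return (self.prot.copy(), self.bpos.copy(), self.bquat.copy(),
                self.v_prot.copy(), self.v_body.copy(), self.w_body.copy())

    def set_state(self, state):
        (self.prot, self.bpos, self.bquat,
         self.v_prot, self.v_body, self.w_body) = [np.array(a) for a in state]
        self._forces = None

    def energy_at(self, debye_length: float) -> float:
        """Total potential energy of the current configuration at some
        Debye length (the only replica-dependent part of the Hamiltonian)."""
        e = self.model.energy(self.prot, self.bpos, self.bquat,
                              debye_length=debye_length).total
        if self.bias is not None:
            e += self.bias(self.prot, self.bpos, self.bquat)[0]
        return e

    def energy(self) -> float:
        return self.energy_at(self.model.dh.debye_length)

    def _compute_forces(self):
        fp, fb, tb = self.model.forces(self.prot, self.bpos, self.bquat)
        if self.bias is not None:
            _, bfp, bfb = self.bias(self.prot, self.bpos, self.bquat)
            fp = fp + bfp
            fb = fb + bfb
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fb)) and np.all(np.isfinite(tb))):
            raise SamplingError(self._diagnose_nonfinite())
        return fp, fb, tb

    def _diagnose_nonfinite(self) -> str:
        x = self.model.site_positions(self.prot, self.bpos, self.bquat)
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        d[~self.model.pair_mask] = np.inf
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return (f"non-finite forces at step {self.step_count}; "
                f"closest interacting site pair ({i}, {j}) at {d[i, j]:.3g} A")

    def step(self, n_steps: int = 1):
        """Advance by BAOAB Langevin steps (deterministic given the seed)."""
        p = self.params
        dt = p.dt
        kbt = constants.KB * p.temperature
        c1, c2 = _ou_coefficients(p.friction, dt)
        sp = np.sqrt(kbt / self.prot_mass)
        sb = math.sqrt(kbt / constants.BP_MASS)
        sw = math.sqrt(kbt / BODY_INERTIA)
        if self._forces is None:
            self._forces = self._compute_forces()
        for _ in range(n_steps):
            fp, fb, tb = self._forces
            # B
            self.v_prot += 0.5 * dt * fp / self.prot_mass
            self.v_body += 0.5 * dt * fb / constants.BP_MASS
            self.w_body += 0.5 * dt * tb / BODY_INERTIA
            # A
            self._drift(0.5 * dt)
            # O
            self.v_prot = c1 * self.v_prot + c2 * sp * self.rng.standard_normal(self.v_prot.shape)
            self.v_body = c1 * self.v_body + c2 * sb * self.rng.standard_normal(self.v_body.shape)
            self.w_body = c1 * self.w_body + c2 * sw * self.rng.standard_normal(self.w_body.shape)
            # A
            self._drift(0.5 * dt)
            # B
            fp, fb, tb = self._compute_forces()
            self.v_prot += 0.5 * dt * fp / self.prot_mass
            self.v_body += 0.5 * dt * fb / constants.BP_MASS
            self.w_body += 0.5 * dt * tb / BODY_INERTIA
            self._forces = (fp, fb, tb)
            self.step_count += 1

    def _drift(self, h: float):
        self.prot += h * self.v_prot
        if self.n_bodies:
            self.bpos += h * self.v_body
            rotvec = self.w_body * h
            dq = rotvec_to_quat(rotvec)
            self.bquat = quat_normalize(quat_multiply(dq, self.bquat))


def langevin_step(dynamics: ChromatinDynamics, n_steps: int = 1) -> ChromatinDynamics:
    """Functional wrapper around :meth:`ChromatinDynamics.step`."""
    dynamics.step(n_steps)
    return dynamics


class GenericLangevinDynamics:
    """BAOAB Langevin for an arbitrary point system with a family of
    potentials parameterised by the Debye length (used for toy replica
    ladders and unit tests; the chromatin sampler shares the same update).

    ``force_fn(x, lam)`` and ``energy_fn(x, lam)`` define the family.
    """

    def __init__(self, x0, mass, energy_fn, force_fn, debye_length: float,
                 params: LangevinParams | None = None, seed: int = 0):
        self.x = np.array(x0, dtype=float)
        self.v = np.zeros_like(self.x)
        self.mass = float(mass)
        self.energy_fn = energy_fn
        self.force_fn = force_fn
        self.debye_length = float(debye_length)
        self.params = params or LangevinParams()
        self.rng = np.random.default_rng(seed)
        self.step_count = 0

    def get_state(self):
        return (self.x.copy(), self.v.copy())

    def set_state(self, state):
        self.x, self.v = np.array(state[0]), np.array(state[1])

    def energy_at(self, lam: float) -> float:
        return float(self.energy_fn(self.x, lam))

    def energy(self) -> float:
        return self.energy_at(self.debye_length)

    def step(self, n_steps: int = 1):
        p = self.params
        dt = p.dt
        kbt = constants.KB * p.temperature
        c1, c2 = _ou_coefficients(p.friction, dt)
        s = math.sqrt(kbt / self.mass)
        f = self.force_fn(self.x, self.debye_length)
        for _ in range(n_steps):
            self.v += 0.5 * dt * f / self.mass
            self.x += 0.5 * dt * self.v
            self.v = c1 * self.v + c2 * s * self.rng.standard_normal(self.v.shape)
            self.x += 0.5 * dt * self.v
            f = self.force_fn(self.x, self.debye_length)
            self.v += 0.5 * dt * f / self.mass
            self.step_count += 1


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLadder:
    """Ordered Debye lengths with exchange bookkeeping."""

    debye_lengths: np.ndarray
    temperature: float = constants.T_REF
    attempts: np.ndarray = field(init=False)
    accepts: np.ndarray = field(init=False)

    def __post_init__(self):
        lam = np.asarray(self.debye_lengths, dtype=float)
        if len(lam) >= 2 and not (np.all(np.diff(lam) > 0) or np.all(np.diff(lam) < 0)):
            raise ValueError("ladder Debye lengths must be strictly monotone")
        self.debye_lengths = lam
        self.attempts = np.zeros(max(len(lam) - 1, 0), dtype=int)
        self.accepts = np.zeros(max(len(lam) - 1, 0), dtype=int)

    @classmethod
    def geometric(cls, lo: float = 8.0, hi: float = 15.0, n: int = 16,
                  temperature: float = constants.T_REF) -> "ReplicaLadder":
        """Default production ladder: geometric spacing over 8-15 A."""
        return cls(np.geomspace(lo, hi, n), temperature=temperature)

    @property
    def n_replicas(self) -> int:
        return len(self.debye_lengths)

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / np.maximum(self.attempts, 1), np.nan)


def exchange_probability(u_i_of_xi: float, u_i_of_xj: float,
                         u_j_of_xj: float, u_j_of_xi: float,
                         temperature: float = constants.T_REF) -> float:
    """Hamiltonian-exchange acceptance probability.

    ``min(1, exp[(U_i(x_i) - U_i(x_j) + U_j(x_j) - U_j(x_i)) / k_B T])``.
    """
    vals = (u_i_of_xi, u_i_of_xj, u_j_of_xj, u_j_of_xi)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite energy passed to exchange_probability")
    arg = (u_i_of_xi - u_i_of_xj + u_j_of_xj - u_j_of_xi) / (constants.KB * temperature)
    if arg >= 0:
        return 1.0
    return math.exp(arg)


@dataclass
class RemdResult:
    ladder: ReplicaLadder
    trajectories: list          # per-slot list of recorded coordinate states
    energies: np.ndarray        # (n_sweeps, n_replicas) slot energies
    replica_ids: np.ndarray     # (n_sweeps, n_replicas) which walker is in each slot

    def mean_acceptance(self) -> float:
        total = self.ladder.attempts.sum()
        return float(self.ladder.accepts.sum() / total) if total else float("nan")


def run_debye_remd(ladder: ReplicaLadder, replicas: list, n_sweeps: int,
                   steps_per_sweep: int, exchange: bool = True,
                   record: bool = True, rng_seed: int = 0) -> RemdResult:
    """Debye-length Hamiltonian replica exchange.

    ``replicas`` holds one dynamics object per ladder slot, in ladder order;
    each must expose ``step / get_state / set_state / energy_at``.  Slot
    ``k`` always samples the Hamiltonian at ``ladder.debye_lengths[k]``; on
    an accepted exchange the *configurations* of neighbouring slots are
    switched.  Attempts alternate between even and odd neighbour pairs.
    """
    n = ladder.n_replicas
    if len(replicas) != n:
        raise ValueError("one dynamics object required per ladder slot")
    if n == 1:
        warnings.warn("ladder of one replica: running plain MD without exchanges")
        exchange = False
    ex_rng = np.random.default_rng(rng_seed)
    trajectories = [[] for _ in range(n)]
    energies = np.empty((n_sweeps, n))
    walker = np.arange(n)
    replica_ids = np.empty((n_sweeps, n), dtype=int)
    for sweep in range(n_sweeps):
        for rep in replicas:
            rep.step(steps_per_sweep)
        if exchange and n > 1:
            start = sweep % 2
            for i in range(start, n - 1, 2):
                lam_i = ladder.debye_lengths[i]
                lam_j = ladder.debye_lengths[i + 1]
                u_i_xi = replicas[i].energy_at(lam_i)
                u_i_xj = replicas[i + 1].energy_at(lam_i)
                u_j_xj = replicas[i + 1].energy_at(lam_j)
                u_j_xi = replicas[i].energy_at(lam_j)
                p = exchange_probability(u_i_xi, u_i_xj, u_j_xj, u_j_xi,
                                         ladder.temperature)
                ladder.attempts[i] += 1
                if ex_rng.random() < p:
                    ladder.accepts[i] += 1
                    si = replicas[i].get_state()
                    sj = replicas[i + 1].get_state()
                    replicas[i].set_state(sj)
                    replicas[i + 1].set_state(si)
                    walker[i], walker[i + 1] = walker[i + 1], walker[i]
        for k, rep in enumerate(replicas):
            energies[sweep, k] = rep.energy_at(ladder.debye_lengths[k])
            if record:
                trajectories[k].append(rep.get_state())
        replica_ids[sweep] = walker
    return RemdResult(ladder=ladder, trajectories=trajectories,
                      energies=energies, replica_ids=replica_ids)
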