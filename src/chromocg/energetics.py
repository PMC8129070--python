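"""Potential-energy terms of the chemically specific model.

Terms: flexible harmonic bonds, elastic-network springs, rigid-base-pair
DNA step elasticity (six helical parameters per step), Debye-Hueckel
screened electrostatics, and pairwise residue contact interactions of the
Kim-Hummer form (which also carries the excluded volume of the DNA sites
through purely repulsive entries).

Harmonic convention: ``E = k (r - r0)^2`` for bonds and springs.
The total energy decomposes exactly as bonds + gnm + rbp + dh + kh.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from chromocg import constants
from chromocg.geometry import (quat_conj, quat_multiply, quat_rotate_vec,
                               quat_to_rotvec, rotvec_to_quat)
from chromocg.model_build import ChromatinSystem

__all__ = [
    "HelicalStepParams",
    "StepStiffness",
    "DebyeHuckelParams",
    "KHPairTable",
    "EnergyBreakdown",
    "EnergyModel",
    "debye_length_from_salt",
    "salt_from_debye_length",
    "dh_pair_energy",
    "kh_pair_energy",
    "step_params_from_frames",
    "apply_step_params",
    "step_params_batch",
    "rbp_step_energy",
    "step_stiffness_table",
    "total_energy",
]

HELICAL_ORDER = ("shift", "slide", "rise", "tilt", "roll", "twist")

#: default well prefactor for the purely repulsive DNA-site entries, kcal/mol
DNA_REPULSION_EPS = 0.2

#: Kim-Hummer scaling defaults (applied to the packaged contact matrix)
KH_LAMBDA = 0.159
KH_E0 = -1.36  # kcal/mol

QUAT_TOL = 1e-6


class EnergeticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HelicalStepParams:
    """Six helical parameters of one base-pair step.

    Distances in Angstroms (shift, slide, rise), angles in degrees
    (tilt, roll, twist)."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist])

    @classmethod
    def from_vector(cls, v) -> "HelicalStepParams":
        return cls(*np.asarray(v, dtype=float))


@dataclass
class StepStiffness:
    """Equilibrium 6-vector and symmetric PSD 6x6 force-constant matrix."""

    equilibrium: np.ndarray
    force_constants: np.ndarray

    def __post_init__(self):
        self.equilibrium = np.asarray(self.equilibrium, dtype=float).reshape(6)
        f = np.asarray(self.force_constants, dtype=float).reshape(6, 6)
        if np.max(np.abs(f - f.T)) >= 1e-12:
            raise EnergeticsError("force-constant matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(f)) < -1e-10:
            raise EnergeticsError("force-constant matrix must be positive semi-definite")
        self.force_constants = 0.5 * (f + f.T)


@dataclass
class DebyeHuckelParams:
    """Screened-Coulomb (Yukawa) parameters; energy shifted to 0 at cutoff."""

    debye_length: float
    relative_permittivity: float = constants.EPS_R
    cutoff: float | None = None
    coulomb_constant: float = constants.COULOMB_KCAL

    def __post_init__(self):
        if self.debye_length <= 0:
            raise EnergeticsError("debye_length must be positive")
        if self.cutoff is None:
            # cutoffs must grow with the screening length at low salt
            self.cutoff = max(35.0, 4.0 * self.debye_length)
        if self.cutoff < 3.0 * self.debye_length:
            raise EnergeticsError("cutoff must be at least 3 Debye lengths")

    @classmethod
    def from_salt(cls, concentration: float, temperature: float = constants.T_REF, **kw) -> "DebyeHuckelParams":
        eps_r = kw.pop("relative_permittivity", constants.EPS_R)
        lam = debye_length_from_salt(concentration, temperature, eps_r)
        return cls(debye_length=lam, relative_permittivity=eps_r, **kw)


class KHPairTable:
    """Pairwise contact well depths and contact distances per species pair.

    Protein-protein entries come from the packaged additive contact matrix
    scaled as ``eps_ij = lambda_kh * (e_ij - e0)``; any pair involving a DNA
    site ('bp' ellipsoid centre or 'ph' phosphate) gets a purely repulsive
    entry so the same functional form carries the DNA excluded volume.
    Contact distances are arithmetic means of the species diameters.
    """

    DNA_SPECIES = {"bp": 12.0, "ph": 4.0}

    def __init__(self, lambda_kh: float = KH_LAMBDA, e0: float = KH_E0,
                 dna_repulsion: float = DNA_REPULSION_EPS,
                 cutoff_factor: float = 3.0,
                 residue_table: pd.DataFrame | None = None):
        from chromocg.model_build import residue_table as _restab

        tab = residue_table if residue_table is not None else _restab()
        self.species = list(tab.index) + list(self.DNA_SPECIES)
        self._index = {s: i for i, s in enumerate(self.species)}
        n = len(self.species)
        diam = np.array(
            [float(tab.loc[s, "diameter"]) for s in tab.index]
            + [self.DNA_SPECIES[s] for s in self.DNA_SPECIES]
        )
        h = np.array([float(tab.loc[s, "contact_h"]) for s in tab.index])
        self.sigma = 0.5 * (diam[:, None] + diam[None, :])
        eps = np.full((n, n), dna_repulsion)
        naa = len(tab.index)
        contact = -(h[:, None] + h[None, :])  # e_ij, additive contact matrix
        eps[:naa, :naa] = lambda_kh * (contact - e0)
        self.epsilon = eps
        self.cutoff_factor = cutoff_factor
        self.lambda_kh = lambda_kh
        self.e0 = e0

    def index_of(self, species: str) -> int:
        try:
            return self._index[species]
        except KeyError:
            raise EnergeticsError(f"unknown residue/species code {species!r}") from None

    def pair(self, a: str, b: str) -> tuple[float, float, float]:
        """(epsilon, sigma, cutoff) for a species pair."""
        i, j = self.index_of(a), self.index_of(b)
        return float(self.epsilon[i, j]), float(self.sigma[i, j]), float(self.cutoff_factor * self.sigma[i, j])


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def debye_length_from_salt(concentration: float,
                           temperature: float = constants.T_REF,
                           relative_permittivity: float = constants.EPS_R) -> float:
    """Debye screening length in Angstroms for a 1:1 electrolyte.

    ``lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I))`` with the ionic
    strength I equal to the molar concentration for a monovalent salt.
    """
    import scipy.constants as sc

    if concentration <= 0:
        raise EnergeticsError("concentration must be positive")
    ionic = concentration * 1000.0 * sc.N_A  # ions/m^3 per species
    lam2 = relative_permittivity * sc.epsilon_0 * sc.k * temperature / (2.0 * sc.e**2 * ionic)
    return math.sqrt(lam2) * 1e10


def salt_from_debye_length(debye_length: float,
                           temperature: float = constants.T_REF,
                           relative_permittivity: float = constants.EPS_R) -> float:
    """Inverse of :func:`debye_length_from_salt` (mol/L)."""
    if debye_length <= 0:
        raise EnergeticsError("debye_length must be positive")
    ref = debye_length_from_salt(1.0, temperature, relative_permittivity)
    return (ref / debye_length) ** 2


def dh_pair_energy(q_i: float, q_j: float, r: float, params: DebyeHuckelParams) -> float:
    """Shifted-truncated Yukawa pair energy, kcal/mol."""
    if r <= 0:
        raise EnergeticsError("r must be positive")
    if r >= params.cutoff:
        return 0.0
    k = params.coulomb_constant / params.relative_permittivity * q_i * q_j
    lam, rc = params.debye_length, params.cutoff
    return k * (math.exp(-r / lam) / r - math.exp(-rc / lam) / rc)


def _kh_unshifted(eps: float, sigma: float, r: np.ndarray) -> np.ndarray:
    """Kim-Hummer pair form without the cutoff shift (vectorised in r)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    lj = 4.0 * (sr6 * sr6 - sr6)
    if eps < 0.0:
        return -eps * lj  # plain LJ with depth |eps|
    if eps == 0.0:
        return np.zeros_like(r)
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    return np.where(r <= rmin, eps * lj + 2.0 * eps, -eps * lj)


def kh_pair_energy(aa_i: str, aa_j: str, r: float, table: KHPairTable) -> float:
    """Contact pair energy for two species at separation r, kcal/mol."""
    if r <= 0:
        raise EnergeticsError("r must be positive")
    eps, sigma, rc = table.pair(aa_i, aa_j)
    if r >= rc:
        return 0.0
    return float(_kh_unshifted(eps, sigma, np.array(r)) - _kh_unshifted(eps, sigma, np.array(rc)))


# ---------------------------------------------------------------------------
# helical-step geometry (mid-frame decomposition)
# ---------------------------------------------------------------------------

def _check_unit(q: np.ndarray):
    norm = np.linalg.norm(np.asarray(q, dtype=float), axis=-1)
    if np.any(np.abs(norm - 1.0) > QUAT_TOL):
        raise EnergeticsError("orientation quaternion is not unit norm")


def step_params_batch(pos1: np.ndarray, quat1: np.ndarray,
                      pos2: np.ndarray, quat2: np.ndarray) -> np.ndarray:
    """Mid-frame helical parameters for batches of frame pairs -> (n, 6).

    The relative rotation's rotation vector (expressed in the mid frame,
    where it is invariant) gives (tilt, roll, twist); the displacement
    expressed in the mid frame gives (shift, slide, rise).
    """
    q1 = np.atleast_2d(quat1)
    q2 = np.atleast_2d(quat2)
    rel = quat_multiply(quat_conj(q1), q2)
    rotvec = quat_to_rotvec(rel)
    mid = quat_multiply(q1, rotvec_to_quat(0.5 * rotvec))
    disp = np.atleast_2d(pos2) - np.atleast_2d(pos1)
    trans = quat_rotate_vec(quat_conj(mid), disp)
    return np.hstack([trans, np.degrees(rotvec)])


def step_params_from_frames(upstream, downstream) -> HelicalStepParams:
    """Helical parameters taking ``upstream`` onto ``downstream``."""
    _check_unit(upstream.orientation)
    _check_unit(downstream.orientation)
    v = step_params_batch(upstream.position, upstream.orientation,
                          downstream.position, downstream.orientation)[0]
    return HelicalStepParams.from_vector(v)


def apply_step_params(upstream, params: HelicalStepParams):
    """Rebuild the downstream frame from the upstream frame plus parameters.

    Exact inverse of :func:`step_params_from_frames`.  Returns a
    (position, quaternion) tuple.
    """
    _check_unit(upstream.orientation)
    v = params.as_vector()
    rotvec = np.radians(v[3:])
    r1 = Rotation.from_quat(np.roll(upstream.orientation, -1))
    mid = r1 * Rotation.from_rotvec(0.5 * rotvec)
    pos2 = np.asarray(upstream.position, dtype=float) + mid.apply(v[:3])
    r2 = r1 * Rotation.from_rotvec(rotvec)
    quat2 = np.roll(r2.as_quat(), 1)
    return pos2, quat2


def rbp_step_energy(params: HelicalStepParams, stiffness: StepStiffness) -> float:
    """Harmonic step-distortion energy ``1/2 d^T F d``, kcal/mol."""
    d = params.as_vector() - stiffness.equilibrium
    return float(0.5 * d @ stiffness.force_constants @ d)


_STEP_TABLE: dict[str, StepStiffness] | None = None


def step_stiffness_table() -> dict[str, StepStiffness]:
    """Packaged per-dinucleotide step stiffness (diagonal force constants)."""
    global _STEP_TABLE
    if _STEP_TABLE is None:
        with importlib.resources.as_file(
            importlib.resources.files("chromocg") / "data" / "rbp_steps.tsv"
        ) as p:
            tab = pd.read_csv(p, sep="\t", comment="#").set_index("step")
        out = {}
        for step, row in tab.iterrows():
            eq = np.array([row[f"{k}0"] for k in HELICAL_ORDER])
            fc = np.diag([row[f"k_{k}"] for k in HELICAL_ORDER])
            out[step] = StepStiffness(eq, fc)
        _STEP_TABLE = out
    return _STEP_TABLE


# ---------------------------------------------------------------------------
# full-system energies and forces
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    bonds: float = 0.0
    gnm: float = 0.0
    rbp: float = 0.0
    dh: float = 0.0
    kh: float = 0.0

    @property
    def total(self) -> float:
        return self.bonds + self.gnm + self.rbp + self.dh + self.kh

    def as_dict(self) -> dict:
        return {"bonds": self.bonds, "gnm": self.gnm, "rbp": self.rbp,
                "dh": self.dh, "kh": self.kh, "total": self.total}


class EnergyModel:
    """Precomputed evaluator for energies and forces of one topology.

    Intended for desk-scale systems: pair quantities are dense ``(n, n)``
    matrices, so memory grows as ``n_sites^2``.

    Coordinates are passed as ``(protein_positions, body_positions,
    body_quaternions)``; phosphate site positions are derived from the rigid
    bodies.  ``forces`` returns per-protein-bead forces plus net force and
    torque on each DNA body (internal rigid constraints carry the rest).
    """

    def __init__(self, system: ChromatinSystem, dh: DebyeHuckelParams,
                 kh: KHPairTable | None = None):
        self.system = system
        self.dh = dh
        self.kh = kh if kh is not None else KHPairTable()
        self._validate_topology()
        n = system.n_sites
        species = system.site_species()
        idx = np.array([self.kh.index_of(s) for s in species])
        self.eps = self.kh.epsilon[np.ix_(idx, idx)].copy()
        self.sigma = self.kh.sigma[np.ix_(idx, idx)].copy()
        self.kh_cut = self.kh.cutoff_factor * self.sigma
        self.kh_shift = _kh_vec(self.eps, self.sigma, self.kh_cut)
        q = system.site_charges()
        self.qq = np.outer(q, q)
        mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(mask, False)
        excl = system.exclusion_pairs()
        if len(excl):
            mask[excl[:, 0], excl[:, 1]] = False
            mask[excl[:, 1], excl[:, 0]] = False
        self.pair_mask = mask
        self.bonds = np.asarray(system.flexible_bonds, dtype=int).reshape(-1, 2)
        gnm_pairs, gnm_rest, gnm_k = [], [], []
        for g in system.gnm:
            if g.n_springs:
                gnm_pairs.append(g.pairs)
                gnm_rest.append(g.rest_lengths)
                gnm_k.append(np.full(g.n_springs, g.spring_constant))
        self.gnm_pairs = np.vstack(gnm_pairs) if gnm_pairs else np.empty((0, 2), dtype=int)
        self.gnm_rest = np.concatenate(gnm_rest) if gnm_rest else np.empty(0)
        self.gnm_k = np.concatenate(gnm_k) if gnm_k else np.empty(0)
        steps = system._bonded_bp_steps()
        self.step_pairs = np.asarray(steps, dtype=int).reshape(-1, 2)
        table = step_stiffness_table()
        self.step_eq = np.array(
            [table[system.dna_frames[a].step_sequence].equilibrium for a, b in steps]
        ).reshape(-1, 6)
        self.step_fc = np.array(
            [table[system.dna_frames[a].step_sequence].force_constants for a, b in steps]
        ).reshape(-1, 6, 6)
        self.phos_offsets = np.array([f.phosphate_offsets for f in system.dna_frames]).reshape(-1, 2, 3)
        self.n_protein = system.n_protein
        self.n_bodies = system.n_bp

    def _validate_topology(self):
        n = self.system.n_sites
        for name, arr in (("bond", self.system.flexible_bonds),):
            arr = np.asarray(arr)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise EnergeticsError(f"dangling {name} index")
        for g in self.system.gnm:
            if g.n_springs and (g.pairs.min() < 0 or g.pairs.max() >= n):
                raise EnergeticsError("dangling GNM spring index")

    # -- coordinate handling ------------------------------------------------
    def coords_from_system(self):
        s = self.system
        prot = np.array([b.position for b in s.protein_beads], dtype=float).reshape(-1, 3)
        bpos = np.array([f.position for f in s.dna_frames], dtype=float).reshape(-1, 3)
        bq = np.array([f.orientation for f in s.dna_frames], dtype=float).reshape(-1, 4)
        return prot, bpos, bq

    def site_positions(self, prot, bpos, bquat) -> np.ndarray:
        n = self.n_protein + 3 * self.n_bodies
        out = np.empty((n, 3))
        out[: self.n_protein] = prot
        if self.n_bodies:
            ph1 = bpos + quat_rotate_vec(bquat, self.phos_offsets[:, 0])
            ph2 = bpos + quat_rotate_vec(bquat, self.phos_offsets[:, 1])
            out[self.n_protein + 0 :: 3] = bpos
            out[self.n_protein + 1 :: 3] = ph1
            out[self.n_protein + 2 :: 3] = ph2
        return out

    # -- energies -----------------------------------------------------------
    def energy(self, prot=None, bpos=None, bquat=None,
               debye_length: float | None = None) -> EnergyBreakdown:
        """Per-term breakdown; ``debye_length`` overrides the screening
        length of the electrostatic term (used by replica exchange)."""
        if prot is None:
            prot, bpos, bquat = self.coords_from_system()
        x = self.site_positions(prot, bpos, bquat)
        out = EnergyBreakdown()
        out.bonds = self._harmonic_energy(x, self.bonds,
                                          np.full(len(self.bonds), self.system.bond_rest_length),
                                          np.full(len(self.bonds), self.system.bond_spring_constant))
        out.gnm = self._harmonic_energy(x, self.gnm_pairs, self.gnm_rest, self.gnm_k)
        out.rbp = self._rbp_energy(bpos, bquat)
        dh_e, kh_e = self._nonbonded_energy(x, debye_length=debye_length)
        out.dh, out.kh = dh_e, kh_e
        return out

    def _harmonic_energy(self, x, pairs, rest, k):
        if len(pairs) == 0:
            return 0.0
        d = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
        return float(np.sum(k * (d - rest) ** 2))

    def _rbp_energy(self, bpos, bquat) -> float:
        if len(self.step_pairs) == 0:
            return 0.0
        a, b = self.step_pairs[:, 0], self.step_pairs[:, 1]
        xi = step_params_batch(bpos[a], bquat[a], bpos[b], bquat[b])
        d = xi - self.step_eq
        return float(0.5 * np.einsum("ni,nij,nj->", d, self.step_fc, d))

    def _pair_distances(self, x):
        diff = x[:, None, :] - x[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        return diff, r

    def _nonbonded_energy(self, x, debye_length: float | None = None):
        diff, r = self._pair_distances(x)
        rs = np.where(r > 0, r, np.inf)
        if debye_length is None:
            lam, rc = self.dh.debye_length, self.dh.cutoff
        else:
            lam = debye_length
            rc = max(35.0, 4.0 * lam)
        kc = self.dh.coulomb_constant / self.dh.relative_permittivity
        dh_mask = self.pair_mask & (self.qq != 0) & (rs < rc)
        dh_mat = np.where(dh_mask, kc * self.qq * (np.exp(-rs / lam) / rs - math.exp(-rc / lam) / rc), 0.0)
        kh_mask = self.pair_mask & (rs < self.kh_cut)
        kh_mat = np.where(kh_mask, _kh_vec(self.eps, self.sigma, rs) - self.kh_shift, 0.0)
        return 0.5 * float(dh_mat.sum()), 0.5 * float(kh_mat.sum())

    # -- forces -------------------------------------------------------------
    def forces(self, prot, bpos, bquat):
        """(protein forces, body forces, body torques) in kcal/mol/A.

        Site-based terms are analytic; the step-elasticity contribution is
        obtained by central differences on the twelve rigid-body degrees of
        freedom of each step (the quadratic form itself is analytic in the
        helical parameters).
        """
        x = self.site_positions(prot, bpos, bquat)
        f_sites = np.zeros_like(x)
        # pair terms: dU/dr summed into site forces
        diff, r = self._pair_distances(x)
        rs = np.where(r > 0, r, np.inf)
        lam, rc = self.dh.debye_length, self.dh.cutoff
        kc = self.dh.coulomb_constant / self.dh.relative_permittivity
        dh_mask = self.pair_mask & (self.qq != 0) & (rs < rc)
        dUdr = np.where(dh_mask,
                        kc * self.qq * (-np.exp(-rs / lam) * (1.0 / (lam * rs) + 1.0 / rs**2)),
                        0.0)
        kh_mask = self.pair_mask & (rs < self.kh_cut)
        dUdr = dUdr + np.where(kh_mask, _kh_dvec(self.eps, self.sigma, rs), 0.0)
        w = -dUdr / rs
        f_sites += np.einsum("ij,ijk->ik", w, diff)
        # harmonic terms
        for pairs, rest, k in (
            (self.bonds, np.full(len(self.bonds), self.system.bond_rest_length),
             np.full(len(self.bonds), self.system.bond_spring_constant)),
            (self.gnm_pairs, self.gnm_rest, self.gnm_k),
        ):
            if len(pairs) == 0:
                continue
            d = x[pairs[:, 0]] - x[pairs[:, 1]]
            dist = np.linalg.norm(d, axis=1)
            mag = 2.0 * k * (dist - rest) / np.where(dist > 0, dist, np.inf)
            fv = -mag[:, None] * d
            np.add.at(f_sites, pairs[:, 0], fv)
            np.add.at(f_sites, pairs[:, 1], -fv)

        f_prot = f_sites[: self.n_protein]
        f_body = np.zeros((self.n_bodies, 3))
        t_body = np.zeros((self.n_bodies, 3))
        if self.n_bodies:
            centers = f_sites[self.n_protein + 0 :: 3]
            ph1 = f_sites[self.n_protein + 1 :: 3]
            ph2 = f_sites[self.n_protein + 2 :: 3]
            f_body = centers + ph1 + ph2
            x_ph1 = x[self.n_protein + 1 :: 3]
            x_ph2 = x[self.n_protein + 2 :: 3]
            t_body = np.cross(x_ph1 - bpos, ph1) + np.cross(x_ph2 - bpos, ph2)
            fb, tb = self._rbp_forces(bpos, bquat)
            f_body += fb
            t_body += tb
        return f_prot, f_body, t_body

    def _rbp_forces(self, bpos, bquat, h_t=1e-5, h_r=1e-6):
        """Central-difference step-elasticity forces/torques per body.

        All 24 perturbed evaluations (+-x/y/z translation and lab-frame
        rotation of either body of each step) are batched into one call.
        """
        nb = self.n_bodies
        f = np.zeros((nb, 3))
        t = np.zeros((nb, 3))
        ns = len(self.step_pairs)
        if ns == 0:
            return f, t
        a, b = self.step_pairs[:, 0], self.step_pairs[:, 1]
        pa, qa, pb, qb = bpos[a], bquat[a], bpos[b], bquat[b]

        K = 24  # perturbation slots: (body a/b) x (trans/rot) x (axis) x (+/-)
        PA = np.broadcast_to(pa, (K, ns, 3)).copy()
        QA = np.broadcast_to(qa, (K, ns, 4)).copy()
        PB = np.broadcast_to(pb, (K, ns, 3)).copy()
        QB = np.broadcast_to(qb, (K, ns, 4)).copy()
        slot = 0
        slots = []
        for axis in range(3):
            for which in ("pa", "pb", "qa", "qb"):
                for sign in (+1.0, -1.0):
                    if which == "pa":
                        PA[slot, :, axis] += sign * h_t
                    elif which == "pb":
                        PB[slot, :, axis] += sign * h_t
                    elif which == "qa":
                        QA[slot] = _rotate_quats(qa, axis, sign * h_r)
                    else:
                        QB[slot] = _rotate_quats(qb, axis, sign * h_r)
                    slot += 1
                kind = "f" if which in ("pa", "pb") else "t"
                idx = a if which in ("pa", "qa") else b
                h = h_t if kind == "f" else h_r
                slots.append((kind, idx, axis, +1.0, h))
        xi = step_params_batch(PA.reshape(-1, 3), QA.reshape(-1, 4),
                               PB.reshape(-1, 3), QB.reshape(-1, 4))
        d = xi.reshape(K, ns, 6) - self.step_eq
        e = 0.5 * np.einsum("kni,nij,knj->kn", d, self.step_fc, d)
        for m, (kind, idx, axis, _, h) in enumerate(slots):
            grad = -(e[2 * m] - e[2 * m + 1]) / (2.0 * h)
            target = f if kind == "f" else t
            np.add.at(target[:, axis], idx, grad)
        return f, t


def _rotate_quats(q: np.ndarray, axis: int, angle: float) -> np.ndarray:
    """Left-multiply each quaternion by a small lab-frame rotation."""
    rv = np.zeros(3)
    rv[axis] = angle
    dq = rotvec_to_quat(rv)
    return quat_multiply(dq, q)


def _kh_vec(eps: np.ndarray, sigma: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorised Kim-Hummer form over matching-shape arrays."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        sr6 = (sigma / r) ** 6
        lj = 4.0 * (sr6 * sr6 - sr6)
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        att = np.abs(eps) * lj
        rep = np.where(r <= rmin, eps * lj + 2.0 * eps, -eps * lj)
        out = np.where(eps < 0, att, rep)
        return np.where(eps == 0, 0.0, out)


def _kh_dvec(eps: np.ndarray, sigma: np.ndarray, r: np.ndarray) -> np.ndarray:
    """d/dr of the (unshifted) Kim-Hummer form; the shift has zero slope."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        sr6 = (sigma / r) ** 6
        dlj = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        att = np.abs(eps) * dlj
        rep = np.where(r <= rmin, eps * dlj, -eps * dlj)
        out = np.where(eps < 0, att, rep)
        return np.where(eps == 0, 0.0, out)


def total_energy(system: ChromatinSystem, dh: DebyeHuckelParams,
                 kh: KHPairTable | None = None) -> EnergyBreakdown:
    """Per-term energy breakdown of a full system (kcal/mol)."""
    return EnergyModel(system, dh, kh).energy()
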