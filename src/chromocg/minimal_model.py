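"""Minimal (nucleosome-resolution) chromatin model.

DNA is reduced to one oriented bead per 5 bp; the histone core to a single
ellipsoid.  Mapping from chemically specific snapshots keeps the bound
fraction of the nucleosomal DNA attached to the core; 5-bp block helical
parameters are fitted from ensembles of the higher-resolution model; and
nucleosome-nucleosome / nucleosome-DNA interactions use an
orientation-modulated well fitted to potential-of-mean-force tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from chromocg import constants
from chromocg.energetics import (DebyeHuckelParams, StepStiffness,
                                 step_params_batch, step_stiffness_table)
from chromocg.geometry import quat_normalize
from chromocg.model_build import ChromatinSystem

__all__ = [
    "MinimalDNABead",
    "MinimalNucleosome",
    "MinimalStepStiffness",
    "MinimalSystem",
    "AnisoParams",
    "map_cs_to_minimal",
    "fit_minimal_helix_params",
    "fit_aniso_nucleosome_potential",
    "minimal_total_energy",
    "default_minimal_stiffness",
    "build_minimal_array",
]

#: DNA bead: sphere-equivalent ellipsoid radii, A
DNA_BEAD_RADII = (12.0, 12.0, 12.0)
#: histone core ellipsoid radii (a, a, c), A
CORE_RADII = (28.0, 28.0, 20.0)
#: base pairs per minimal DNA bead
BP_PER_BEAD = 5
#: charge per DNA bead: two phosphates per bp
DNA_BEAD_CHARGE = -2.0 * BP_PER_BEAD
#: effective core charge (histone octamer net charge, coarse)
CORE_CHARGE = 52.0

DETACH_THRESHOLD = 18.0  # A, same rule as the unwrapping counter


class MinimalModelError(ValueError):
    pass


@dataclass
class MinimalDNABead:
    position: np.ndarray
    orientation: np.ndarray
    span_bp: int = BP_PER_BEAD
    is_nucleosomal: bool = False
    charge: float = DNA_BEAD_CHARGE


@dataclass
class MinimalNucleosome:
    position: np.ndarray
    orientation: np.ndarray
    attached_beads: list[int] = field(default_factory=list)
    breathing_variant: int = 0
    charge: float = CORE_CHARGE


@dataclass
class MinimalStepStiffness:
    equilibrium: np.ndarray
    force_constants: np.ndarray

    def __post_init__(self):
        base = StepStiffness(self.equilibrium, self.force_constants)
        self.equilibrium = base.equilibrium
        self.force_constants = base.force_constants


@dataclass
class AnisoParams:
    """Orientation-modulated pair well.

    ``U(r, ci, cj) = 4 eps(ci, cj) [ (s/r)^12 - (s/r)^6 ]`` with
    ``s = sigma_side + (sigma_face - sigma_side) * (ci^2 + cj^2)/2`` and
    ``eps = eps_side + (eps_face - eps_side) * ci^2 cj^2``, where ci/cj are
    the cosines between each body's symmetry axis and the separation unit
    vector.  Face-on approach therefore sees a shorter contact distance and
    (typically) a deeper well.
    """

    eps_face: float
    eps_side: float
    sigma_face: float
    sigma_side: float
    core_exposure: float = 0.0   # extra depth scale for breathing cores

    def evaluate(self, r, ci, cj):
        r = np.asarray(r, dtype=float)
        ci2 = np.asarray(ci, dtype=float) ** 2
        cj2 = np.asarray(cj, dtype=float) ** 2
        sig = self.sigma_side + (self.sigma_face - self.sigma_side) * 0.5 * (ci2 + cj2)
        eps = self.eps_side + (self.eps_face - self.eps_side) * ci2 * cj2
        sr6 = (sig / r) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)


@dataclass
class MinimalSystem:
    dna_beads: list[MinimalDNABead]
    nucleosomes: list[MinimalNucleosome]
    stiffness: MinimalStepStiffness
    aniso: AnisoParams
    breathing: bool = True
    bonds: list[tuple[int, int, float]] = field(default_factory=list)  # (core, bead, rest)

    @property
    def n_beads(self) -> int:
        return len(self.dna_beads)


# ---------------------------------------------------------------------------
# mapping from the chemically specific model
# ---------------------------------------------------------------------------

def map_cs_to_minimal(system: ChromatinSystem, stiffness: "MinimalStepStiffness | None" = None,
                      aniso: "AnisoParams | None" = None,
                      detach_threshold: float = DETACH_THRESHOLD,
                      bound_fraction_rule: float = 0.5) -> MinimalSystem:
    """Map a chemically specific snapshot onto the minimal representation.

    Each 5-bp block becomes one bead at the block centroid with the middle
    base pair's orientation (a trailing block of <5 bp is merged into the
    final bead).  A block of nucleosomal DNA stays attached to its core
    only if more than ``bound_fraction_rule`` of its base pairs are bound
    (within ``detach_threshold`` of a globular core bead); detached blocks
    become linker beads, which is how breathing states are inherited.
    """
    bp_pos = np.array([f.position for f in system.dna_frames]).reshape(-1, 3)
    bp_quat = np.array([f.orientation for f in system.dna_frames]).reshape(-1, 4)
    n_bp = len(bp_pos)
    bound = np.zeros(n_bp, dtype=bool)
    glob = np.array(
        [b.position for b in system.protein_beads if b.region == "globular"]
    ).reshape(-1, 3)
    if len(glob):
        from scipy.spatial import cKDTree

        tree = cKDTree(glob)
        sites = system.site_positions()[system.n_protein :].reshape(n_bp, 3, 3)
        for j in range(n_bp):
            d, _ = tree.query(sites[j])
            bound[j] = d.min() <= detach_threshold
    else:
        # DNA-only input (no resolved histones): geometry-only mapping, the
        # wrapped spans of the records define the bound DNA
        bound[:] = True

    # block boundaries: trailing remainder merges into the final block
    n_blocks = max(n_bp // BP_PER_BEAD, 1 if n_bp else 0)
    beads: list[MinimalDNABead] = []
    block_of_bp = np.zeros(n_bp, dtype=int)
    for b in range(n_blocks):
        lo = b * BP_PER_BEAD
        hi = (b + 1) * BP_PER_BEAD if b < n_blocks - 1 else n_bp
        block_of_bp[lo:hi] = b
        span = hi - lo
        centroid = bp_pos[lo:hi].mean(axis=0)
        mid = (lo + hi) // 2
        beads.append(
            MinimalDNABead(
                position=centroid,
                orientation=quat_normalize(bp_quat[min(mid, n_bp - 1)]),
                span_bp=span,
                charge=DNA_BEAD_CHARGE * span / BP_PER_BEAD,
            )
        )

    nucleosomes: list[MinimalNucleosome] = []
    bonds: list[tuple[int, int, float]] = []
    for rec_idx, rec in enumerate(system.nucleosome_records):
        core_beads = [
            b for i, b in enumerate(system.protein_beads)
            if rec.histone_range[0] <= i < rec.histone_range[1] and b.region == "globular"
        ]
        lo, hi = rec.dna_span
        if core_beads:
            core_pos = np.mean([b.position for b in core_beads], axis=0)
        elif hi > lo:
            core_pos = bp_pos[lo:hi].mean(axis=0)
        else:
            core_pos = np.zeros(3)
        attached = []
        for b in sorted(set(block_of_bp[lo:hi])) if hi > lo else []:
            blo = b * BP_PER_BEAD
            bhi = (b + 1) * BP_PER_BEAD if b < n_blocks - 1 else n_bp
            in_span = max(blo, lo), min(bhi, hi)
            span_bps = np.arange(*in_span)
            if len(span_bps) == 0:
                continue
            # non-breathing nucleosomes keep the full wrapped-span definition
            frac = 1.0 if not rec.breathing else bound[span_bps].mean()
            if frac > bound_fraction_rule:
                attached.append(int(b))
                beads[b].is_nucleosomal = True
        nuc = MinimalNucleosome(
            position=np.asarray(core_pos, dtype=float),
            orientation=_plane_orientation(bp_pos[lo:hi]),
            attached_beads=attached,
            breathing_variant=rec_idx,
        )
        nucleosomes.append(nuc)
        for b in attached:
            bonds.append((rec_idx, b, float(np.linalg.norm(beads[b].position - nuc.position))))

    return MinimalSystem(
        dna_beads=beads,
        nucleosomes=nucleosomes,
        stiffness=stiffness or default_minimal_stiffness(),
        aniso=aniso or default_aniso_params(),
        breathing=any(rec.breathing for rec in system.nucleosome_records),
        bonds=bonds,
    )


def _plane_orientation(points: np.ndarray) -> np.ndarray:
    """Quaternion whose body z-axis is the best-fit plane normal of points."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 3:
        return np.array([1.0, 0.0, 0.0, 0.0])
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    x = vt[0]
    y = np.cross(normal, x)
    from chromocg.geometry import matrix_to_quat

    return matrix_to_quat(np.column_stack([x, y, normal]))


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def fit_minimal_helix_params(samples: np.ndarray,
                             temperature: float = constants.T_REF) -> MinimalStepStiffness:
    """Gaussian fit of 5-bp block helical-parameter samples.

    Mean vector -> equilibrium; stiffness = k_B T * inverse covariance.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 6:
        raise MinimalModelError("samples must be (n, 6)")
    if len(samples) < 2:
        raise MinimalModelError("need at least 2 samples")
    mean = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise MinimalModelError(f"singular covariance (condition number {cond:.3g})")
    kbt = constants.KB * temperature
    return MinimalStepStiffness(mean, kbt * np.linalg.inv(cov))


def default_minimal_stiffness() -> MinimalStepStiffness:
    """Fallback 5-bp stiffness derived from the packaged single-bp table.

    Gaussian composition of 5 independent average steps: the equilibrium
    6-vector scales by 5 and the covariance (inverse stiffness) adds.
    """
    avg = step_stiffness_table()["AVG"]
    eq = avg.equilibrium * BP_PER_BEAD
    fc = avg.force_constants / BP_PER_BEAD
    return MinimalStepStiffness(eq, fc)


def fit_aniso_nucleosome_potential(pmf_table: np.ndarray,
                                   x0: "AnisoParams | None" = None) -> tuple[AnisoParams, float]:
    """Least-squares fit of the orientation-modulated well to a PMF table.

    ``pmf_table`` rows are ``(r, cos_i, cos_j, free_energy)`` (energies in
    kcal/mol).  The table must cover both a face-to-face approach
    (|cos| > 0.8 for both bodies) and a side-to-side approach (|cos| < 0.2);
    otherwise the missing coverage is reported.  Returns the fitted
    parameters and the residual RMS.
    """
    tab = np.asarray(pmf_table, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 4:
        raise MinimalModelError("pmf table must be (n, 4): r, cos_i, cos_j, energy")
    ff = (np.abs(tab[:, 1]) > 0.8) & (np.abs(tab[:, 2]) > 0.8)
    ss = (np.abs(tab[:, 1]) < 0.2) & (np.abs(tab[:, 2]) < 0.2)
    missing = [name for name, m in (("face-to-face", ff), ("side-to-side", ss)) if not m.any()]
    if missing:
        raise MinimalModelError(f"pmf table lacks orientation coverage: {', '.join(missing)}")

    r, ci, cj, g = tab.T
    p0 = x0 or AnisoParams(eps_face=1.0, eps_side=0.5,
                           sigma_face=2.0 * CORE_RADII[2], sigma_side=2.0 * CORE_RADII[0])

    def resid(v):
        pars = AnisoParams(*v)
        return pars.evaluate(r, ci, cj) - g

    fit = least_squares(
        resid,
        [p0.eps_face, p0.eps_side, p0.sigma_face, p0.sigma_side],
        bounds=([0.0, 0.0, 5.0, 5.0], [np.inf, np.inf, 200.0, 200.0]),
    )
    pars = AnisoParams(*fit.x)
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    return pars, rms


def default_aniso_params() -> AnisoParams:
    """Documented default well: face-to-face contact at the short core axis
    and a deeper face-on well, side contact at the long axes."""
    return AnisoParams(
        eps_face=1.2, eps_side=0.4,
        sigma_face=2.0 * CORE_RADII[2] * 2 ** (-1.0 / 6.0),
        sigma_side=2.0 * CORE_RADII[0] * 2 ** (-1.0 / 6.0),
        core_exposure=0.6,
    )


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@dataclass
class MinimalEnergyBreakdown:
    bonds: float = 0.0
    rbp: float = 0.0
    dh: float = 0.0
    aniso: float = 0.0
    exposure: float = 0.0

    @property
    def total(self) -> float:
        return self.bonds + self.rbp + self.dh + self.aniso + self.exposure

    def as_dict(self):
        return {"bonds": self.bonds, "rbp": self.rbp, "dh": self.dh,
                "aniso": self.aniso, "exposure": self.exposure, "total": self.total}


BOND_K = 5.0  # kcal/mol/A^2, permanent core-DNA attachments
ANISO_CUTOFF_FACTOR = 2.5


def _axis_of(quat: np.ndarray) -> np.ndarray:
    """Body symmetry axis (body z) in the lab frame."""
    from chromocg.geometry import quat_rotate_vec

    return quat_rotate_vec(np.atleast_2d(quat), np.array([0.0, 0.0, 1.0]))


def minimal_total_energy(system: MinimalSystem,
                         dh: DebyeHuckelParams | None = None) -> MinimalEnergyBreakdown:
    """Per-term energy of a minimal configuration, kcal/mol.

    Terms: permanent core-DNA bonds, 5-bp step elasticity along the DNA,
    screened electrostatics between bead charges, anisotropic
    core-core/core-DNA wells, and (breathing variants only) the
    core-exposure term proportional to the unbound fraction of nucleosomal
    DNA.
    """
    dh = dh or DebyeHuckelParams(debye_length=8.0)
    out = MinimalEnergyBreakdown()
    beads = system.dna_beads
    cores = system.nucleosomes
    nb = len(beads)
    nc = len(cores)
    for ci, bi, _ in system.bonds:
        if ci >= nc or bi >= nb:
            raise MinimalModelError("dangling bond in minimal topology")
    bead_pos = np.array([b.position for b in beads]).reshape(-1, 3)
    bead_q = np.array([b.orientation for b in beads]).reshape(-1, 4)
    core_pos = np.array([c.position for c in cores]).reshape(-1, 3)
    return _minimal_energy_arrays(system, dh, bead_pos, bead_q, core_pos)


def _minimal_energy_arrays(system: MinimalSystem, dh: DebyeHuckelParams,
                           bead_pos: np.ndarray, bead_q: np.ndarray,
                           core_pos: np.ndarray,
                           core_axes: np.ndarray | None = None) -> MinimalEnergyBreakdown:
    """Vectorised energy on explicit coordinate arrays (used by the Monte
    Carlo sampler, which moves coordinates without rebuilding objects)."""
    out = MinimalEnergyBreakdown()
    beads = system.dna_beads
    cores = system.nucleosomes
    nb = len(beads)
    nc = len(cores)
    if system.bonds:
        ci = np.array([b[0] for b in system.bonds], dtype=int)
        bi = np.array([b[1] for b in system.bonds], dtype=int)
        rest = np.array([b[2] for b in system.bonds])
        d = np.linalg.norm(core_pos[ci] - bead_pos[bi], axis=1)
        out.bonds = float(np.sum(BOND_K * (d - rest) ** 2))
    # step elasticity between consecutive DNA beads
    if nb >= 2:
        xi = step_params_batch(bead_pos[:-1], bead_q[:-1], bead_pos[1:], bead_q[1:])
        d = xi - system.stiffness.equilibrium
        out.rbp = float(0.5 * np.einsum("ni,ij,nj->", d, system.stiffness.force_constants, d))
    # electrostatics between all charge carriers, excluding bonded/adjacent
    pos = np.vstack([bead_pos, core_pos]) if nc else bead_pos
    chg = np.array([b.charge for b in beads] + [c.charge for c in cores])
    n = len(pos)
    if n >= 2:
        r = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        for i in range(nb - 1):
            mask[i, i + 1] = False
        for ci_, bi_, _ in system.bonds:
            a, b = sorted((bi_, nb + ci_))
            mask[a, b] = False
        lam, rc = dh.debye_length, dh.cutoff
        kc = dh.coulomb_constant / dh.relative_permittivity
        rs = np.where(r > 0, r, np.inf)
        sel = mask & (rs < rc)
        qq = np.outer(chg, chg)
        out.dh = float(np.sum(np.where(
            sel, kc * qq * (np.exp(-rs / lam) / rs - math.exp(-rc / lam) / rc), 0.0)))
    # anisotropic wells: core-core and core-(non-attached DNA)
    pars = system.aniso
    if nc:
        if core_axes is None:
            core_axes = _axis_of(np.array([c.orientation for c in cores])).reshape(-1, 3)
        sig_max = max(pars.sigma_face, pars.sigma_side)
        rc_a = ANISO_CUTOFF_FACTOR * sig_max
        # core-core
        dvec = core_pos[None, :, :] - core_pos[:, None, :]
        rcc = np.linalg.norm(dvec, axis=-1)
        iu = np.triu_indices(nc, k=1)
        rr = rcc[iu]
        near = (rr > 0) & (rr < rc_a)
        if near.any():
            u = dvec[iu][near] / rr[near][:, None]
            ci_ = np.einsum("nk,nk->n", np.repeat(core_axes, nc, axis=0).reshape(nc, nc, 3)[iu][near], u)
            cj_ = np.einsum("nk,nk->n", np.tile(core_axes, (nc, 1)).reshape(nc, nc, 3)[iu][near], u)
            out.aniso += float(np.sum(pars.evaluate(rr[near], ci_, cj_)))
        # core - non-attached DNA
        attached = np.zeros((nc, nb), dtype=bool)
        for a, core in enumerate(cores):
            attached[a, list(core.attached_beads)] = True
        dvec = bead_pos[None, :, :] - core_pos[:, None, :]
        rcb = np.linalg.norm(dvec, axis=-1)
        sel = (~attached) & (rcb > 0) & (rcb < rc_a)
        if sel.any():
            u = dvec[sel] / rcb[sel][:, None]
            axes_rep = np.repeat(core_axes[:, None, :], nb, axis=1)[sel]
            ci_ = np.einsum("nk,nk->n", axes_rep, u)
            out.aniso += float(np.sum(pars.evaluate(rcb[sel], ci_, np.zeros_like(ci_))))
        # core exposure: breathing variants expose part of the histone core
        if system.breathing and pars.core_exposure != 0.0:
            full_blocks = constants.NUCLEOSOME_WRAP_BP // BP_PER_BEAD
            exposure = np.array([
                max(0.0, 1.0 - len(c.attached_beads) / full_blocks) for c in cores
            ])
            if np.any(exposure > 0) and nc >= 2:
                sig = pars.sigma_face
                sel = (rcc > 0) & (rcc < ANISO_CUTOFF_FACTOR * sig)
                sr6 = np.where(sel, (sig / np.where(rcc > 0, rcc, np.inf)) ** 6, 0.0)
                # per ordered pair (a, b): a's exposure attracts b
                out.exposure = float(np.sum(-4.0 * pars.core_exposure * exposure[:, None] * sr6))
    return out


def _aniso_pair(p1, ax1, p2, ax2, pars: AnisoParams) -> float:
    d = np.asarray(p2) - np.asarray(p1)
    r = np.linalg.norm(d)
    if r <= 0:
        return 0.0
    u = d / r
    ci = float(np.dot(np.ravel(ax1), u)) if ax1 is not None else 0.0
    cj = float(np.dot(np.ravel(ax2), u)) if ax2 is not None else 0.0
    sig_max = max(pars.sigma_face, pars.sigma_side)
    if r >= ANISO_CUTOFF_FACTOR * sig_max:
        return 0.0
    return float(pars.evaluate(r, ci, cj))


def minimal_monte_carlo(system: MinimalSystem, dh: DebyeHuckelParams | None = None,
                        n_moves: int = 1000, seed: int = 0,
                        max_angle_deg: float = 25.0,
                        temperature: float = constants.T_REF,
                        record_every: int = 20):
    """Metropolis pivot Monte Carlo on a minimal array.

    Pivot moves rotate everything downstream of a randomly chosen linker
    bead (nucleosome units move rigidly with their attached DNA), which
    folds/unfolds the array efficiently at desk scale.  Returns recorded
    ``(bead_positions, core_positions)`` snapshots.
    """
    from chromocg.geometry import quat_multiply, quat_to_matrix, rotvec_to_quat

    dh = dh or DebyeHuckelParams(debye_length=8.0)
    rng = np.random.default_rng(seed)
    kbt = constants.KB * temperature
    nb = len(system.dna_beads)
    nc = len(system.nucleosomes)
    bead_pos = np.array([b.position for b in system.dna_beads]).reshape(-1, 3)
    bead_q = np.array([b.orientation for b in system.dna_beads]).reshape(-1, 4)
    core_pos = np.array([c.position for c in system.nucleosomes]).reshape(-1, 3)
    core_axes = _axis_of(np.array([c.orientation for c in system.nucleosomes])).reshape(-1, 3)
    linker_idx = [i for i, b in enumerate(system.dna_beads)
                  if not b.is_nucleosomal and 0 < i < nb - 1]
    if not linker_idx:
        linker_idx = list(range(1, max(nb - 1, 2)))
    core_first_bead = np.array([
        min(c.attached_beads) if c.attached_beads else nb for c in system.nucleosomes
    ])
    e_old = _minimal_energy_arrays(system, dh, bead_pos, bead_q, core_pos, core_axes).total
    recorded = []
    for move in range(n_moves):
        p = int(rng.choice(linker_idx))
        rotvec = rng.normal(size=3)
        rotvec *= np.radians(max_angle_deg) * rng.random() / np.linalg.norm(rotvec)
        rot = quat_to_matrix(rotvec_to_quat(rotvec))
        pivot = bead_pos[p]
        new_bead_pos = bead_pos.copy()
        new_bead_q = bead_q.copy()
        new_core_pos = core_pos.copy()
        new_core_axes = core_axes.copy()
        dq = rotvec_to_quat(rotvec)
        sel = np.arange(nb) > p
        new_bead_pos[sel] = (bead_pos[sel] - pivot) @ rot.T + pivot
        new_bead_q[sel] = quat_multiply(dq, bead_q[sel])
        csel = core_first_bead > p
        new_core_pos[csel] = (core_pos[csel] - pivot) @ rot.T + pivot
        new_core_axes[csel] = core_axes[csel] @ rot.T
        e_new = _minimal_energy_arrays(system, dh, new_bead_pos, new_bead_q,
                                       new_core_pos, new_core_axes).total
        if e_new <= e_old or rng.random() < math.exp(-(e_new - e_old) / kbt):
            bead_pos, bead_q = new_bead_pos, new_bead_q
            core_pos, core_axes = new_core_pos, new_core_axes
            e_old = e_new
        if move % record_every == 0:
            recorded.append((bead_pos.copy(), core_pos.copy()))
    return recorded


# ---------------------------------------------------------------------------
# direct construction of minimal arrays (used by the phase module)
# ---------------------------------------------------------------------------

def build_minimal_array(n_nucleosomes: int = 12, nrl: int = 165,
                        breathing: bool = True, unwrapped_blocks: int = 0,
                        seed: int = 0) -> MinimalSystem:
    """Build a minimal-model array directly on an idealized path.

    For breathing variants, each nucleosome's bound span is drawn from a
    library of breathing states realised geometrically: up to
    ``unwrapped_blocks`` 5-bp blocks per end are unwrapped, which shortens
    that nucleosome's wrap, lengthens its linker and rotates everything
    downstream (the linker-twist diversification mechanism).  Non-breathing
    arrays keep the full wrapped span everywhere.
    """
    if nrl < constants.NUCLEOSOME_WRAP_BP:
        raise MinimalModelError("nrl below the wrapped span")
    from chromocg.model_build import build_array

    if breathing and unwrapped_blocks > 0:
        rng = np.random.default_rng(seed)
        wraps = [
            int(constants.NUCLEOSOME_WRAP_BP
                - 2 * BP_PER_BEAD * rng.integers(0, unwrapped_blocks + 1))
            for _ in range(n_nucleosomes)
        ]
    else:
        wraps = constants.NUCLEOSOME_WRAP_BP
    cs = build_array(n_nucleosomes, nrl, wrap_bp=wraps, histones={})  # DNA-only path
    minimal = map_cs_to_minimal(cs)
    minimal.breathing = breathing
    return minimal
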