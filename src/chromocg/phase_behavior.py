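"""Direct-coexistence phase behaviour of minimal-model chromatin arrays.

A slab of arrays in an elongated periodic box is evolved (at desk scale,
with rigid-array Monte Carlo moves over nucleosome-level interactions);
axial density profiles give the coexisting densities, and critical points
are fitted with the 3-D Ising scaling law (beta = 0.325) plus the
rectilinear-diameter rule.  Densities are arrays per nm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from chromocg.energetics import debye_length_from_salt

__all__ = [
    "SlabSystem",
    "DensityProfile",
    "CoexistenceResult",
    "PhaseDiagram",
    "ConnectivityResult",
    "build_slab",
    "density_profile",
    "coexistence_densities",
    "estimate_critical_point",
    "condensate_connectivity",
    "slab_monte_carlo",
]

ISING_BETA = 0.325
CONTACT_CUTOFF = 110.0  # A, nucleosome centre-to-centre

#: minimum nucleosome-nucleosome distance between different arrays at build
OVERLAP_THRESHOLD = 60.0


class PhaseBehaviorError(ValueError):
    pass


@dataclass
class SlabSystem:
    """Nucleosome centre coordinates of ``n_arrays`` rigid arrays in a
    periodic box (lengths in A, long axis = z)."""

    positions: np.ndarray        # (n_arrays, n_per_array, 3)
    box: np.ndarray              # (3,)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.box[2] < 3.0 * max(self.box[0], self.box[1]):
            raise PhaseBehaviorError("box long axis must be at least 3x the short axes")

    @property
    def n_arrays(self) -> int:
        return self.positions.shape[0]

    def array_coms(self) -> np.ndarray:
        return self.positions.mean(axis=1)


@dataclass
class DensityProfile:
    z: np.ndarray                # bin centres, A
    density: np.ndarray          # arrays / nm^3, frame-averaged
    per_frame: np.ndarray        # (n_frames, n_bins)
    bin_volume_nm3: float
    n_arrays: int


@dataclass
class CoexistenceResult:
    dilute: float
    dense: float
    dilute_err: float
    dense_err: float
    one_phase: bool = False


@dataclass
class PhaseDiagram:
    """Per-salt coexistence rows plus the fitted critical point."""

    rows: list = field(default_factory=list)  # (salt, CoexistenceResult)
    c_crit: float | None = None
    c_crit_err: float | None = None
    rho_crit: float | None = None


@dataclass
class ConnectivityResult:
    mean_connections: float      # distinct partner arrays per condensate member
    condensed_density: float     # arrays / nm^3 (0 if not supplied/derivable)
    connectivity: float          # mean_connections * condensed_density
    n_condensate: int
    empty: bool = False


# ---------------------------------------------------------------------------
# slab construction
# ---------------------------------------------------------------------------

def build_slab(template_positions: np.ndarray, n_arrays: int, box,
               seed: int = 0, slab_fraction: float = 0.3,
               overlap_threshold: float = OVERLAP_THRESHOLD,
               max_tries: int = 2000) -> SlabSystem:
    """Pack rigid copies of a template array into a central slab.

    ``template_positions`` is the (n_per_array, 3) nucleosome-centre layout
    of one array.  Copies are randomly rotated and placed in the central
    ``slab_fraction`` of the box's long axis, rejecting placements whose
    inter-array nucleosome distance falls below ``overlap_threshold``.
    Raises (reporting the feasible count) if packing fails.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float).reshape(3)
    template = np.asarray(template_positions, dtype=float)
    template = template - template.mean(axis=0)
    placed = []
    for k in range(n_arrays):
        ok = False
        for _ in range(max_tries):
            # uniform random rotation via quaternion
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            rot = _quat_matrix(q)
            centre = np.array([
                rng.uniform(0, box[0]),
                rng.uniform(0, box[1]),
                box[2] / 2 + rng.uniform(-0.5, 0.5) * slab_fraction * box[2],
            ])
            cand = template @ rot.T + centre
            if all(_min_pbc_distance(cand, other, box) > overlap_threshold for other in placed):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise PhaseBehaviorError(
                f"cannot pack {n_arrays} arrays without overlap; managed {k}"
            )
    return SlabSystem(positions=np.array(placed), box=box)


def _quat_matrix(q):
    from chromocg.geometry import quat_to_matrix

    return quat_to_matrix(q)


def _min_pbc_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return float(np.sqrt((d**2).sum(axis=-1)).min())


# ---------------------------------------------------------------------------
# profiles and coexistence densities
# ---------------------------------------------------------------------------

def density_profile(trajectory, box, n_bins: int = 50, axis: int = 2) -> DensityProfile:
    """Centre-of-mass-recentred axial density profile, arrays per nm^3.

    ``trajectory`` is an iterable of (n_arrays, n_per, 3) configurations.
    Each frame is recentred so the periodic centre of mass of the array
    COMs sits at the box middle, then histogrammed along ``axis``.  The
    profile integrates to the number of arrays.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    frames = [np.asarray(f, dtype=float) for f in trajectory]
    if not frames:
        raise PhaseBehaviorError("empty trajectory selection")
    L = box[axis]
    edges = np.linspace(0, L, n_bins + 1)
    cross = np.prod(np.delete(box, axis)) / 1e2  # A^2 -> nm^2
    bin_vol = cross * (L / n_bins) / 10.0        # nm^3
    per_frame = []
    for f in frames:
        coms = f.mean(axis=1)
        zc = coms[:, axis] % L
        # periodic (circular) centre of mass
        theta = 2 * math.pi * zc / L
        centre = (math.atan2(np.sin(theta).mean(), np.cos(theta).mean()) / (2 * math.pi)) * L
        z = (zc - centre + L / 2) % L
        counts, _ = np.histogram(z, bins=edges)
        per_frame.append(counts / bin_vol)
    per_frame = np.array(per_frame)
    return DensityProfile(
        z=0.5 * (edges[:-1] + edges[1:]),
        density=per_frame.mean(axis=0),
        per_frame=per_frame,
        bin_volume_nm3=bin_vol,
        n_arrays=frames[0].shape[0],
    )


def coexistence_densities(profile: DensityProfile, plateau_fraction: float = 0.6,
                          n_samples: int = 100, seed: int = 0) -> CoexistenceResult:
    """Plateau densities of the dense slab and the surrounding dilute phase.

    The dense region is the contiguous run of bins above the half-maximum
    around the profile peak; the central ``plateau_fraction`` of each region
    is averaged.  Errors are standard deviations over ``n_samples`` plateau
    values drawn from the per-frame profiles.
    """
    rho = profile.density
    n = len(rho)
    lo, hi = rho.min(), rho.max()
    if hi - lo < 1e-12 or hi < 2.0 * max(lo, 1e-12):
        mean = float(rho.mean())
        return CoexistenceResult(mean, mean, 0.0, 0.0, one_phase=True)
    half = 0.5 * (hi + lo)
    peak = int(np.argmax(rho))
    dense_idx = [peak]
    i = peak
    while rho[(i - 1) % n] > half and len(dense_idx) < n:
        i -= 1
        dense_idx.insert(0, i % n)
    i = peak
    while rho[(i + 1) % n] > half and len(dense_idx) < n:
        i += 1
        dense_idx.append(i % n)
    dense_idx = np.array(dense_idx)
    keep = int(max(1, round(len(dense_idx) * plateau_fraction)))
    trim = (len(dense_idx) - keep) // 2
    dense_core = dense_idx[trim : trim + keep]
    dilute_all = np.setdiff1d(np.arange(n), dense_idx)
    # stay clear of the interfaces: drop the dilute bins adjacent to the slab
    margin = max(1, len(dense_idx) // 4)
    near = set()
    for m in range(1, margin + 1):
        near.add((dense_idx[0] - m) % n)
        near.add((dense_idx[-1] + m) % n)
    dilute_core = np.array([i for i in dilute_all if i not in near])
    if len(dilute_core) == 0:
        dilute_core = dilute_all
    rng = np.random.default_rng(seed)
    dense_vals = profile.per_frame[:, dense_core].ravel()
    dilute_vals = profile.per_frame[:, dilute_core].ravel()
    ds = rng.choice(dense_vals, size=min(n_samples, len(dense_vals)), replace=False)
    dl = rng.choice(dilute_vals, size=min(n_samples, len(dilute_vals)), replace=False)
    return CoexistenceResult(
        dilute=float(dl.mean()), dense=float(ds.mean()),
        dilute_err=float(dl.std(ddof=1)) if len(dl) > 1 else 0.0,
        dense_err=float(ds.std(ddof=1)) if len(ds) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# critical point
# ---------------------------------------------------------------------------

def estimate_critical_point(rows, beta: float = ISING_BETA):
    """Critical salt concentration from two-phase coexistence rows.

    ``rows`` is a sequence of ``(salt, dilute, dense)``; LLPS occurs above
    the critical salt, so the density gap closes as C -> C_crit from above:
    ``dense - dilute = A (C - C_crit)^beta`` together with the rectilinear
    diameter ``(dense + dilute)/2 = rho_c + B (C - C_crit)``.  Returns
    ``(c_crit, c_crit_err, rho_crit)``.
    """
    rows = [(float(c), float(dl), float(dn)) for c, dl, dn in rows]
    if len(rows) < 3:
        raise PhaseBehaviorError("need at least 3 two-phase rows")
    c = np.array([r[0] for r in rows])
    gap = np.array([r[2] - r[1] for r in rows])
    mid = np.array([0.5 * (r[1] + r[2]) for r in rows])
    if np.any(gap <= 0):
        raise PhaseBehaviorError("rows must be two-phase (dense > dilute)")
    c_min = c.min()

    def resid(p):
        cc, loga, rhoc, b = p
        dc = np.maximum(c - cc, 1e-12)
        r1 = np.exp(loga) * dc**beta - gap
        r2 = rhoc + b * dc - mid
        return np.concatenate([r1, r2])

    p0 = np.array([c_min - 0.1 * (c.max() - c_min) - 1e-4,
                   math.log(max(gap.max(), 1e-6)), mid.mean(), 0.0])
    fit = least_squares(resid, p0, bounds=([-np.inf, -np.inf, -np.inf, -np.inf],
                                           [c_min - 1e-9, np.inf, np.inf, np.inf]))
    cc = float(fit.x[0])
    # 1-sigma from the Gauss-Newton covariance
    try:
        jtj = fit.jac.T @ fit.jac
        dof = max(len(fit.fun) - len(fit.x), 1)
        cov = np.linalg.inv(jtj) * 2.0 * fit.cost / dof
        err = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        err = float("nan")
    return cc, err, float(fit.x[2])


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def condensate_connectivity(positions: np.ndarray, box=None,
                            cutoff: float = CONTACT_CUTOFF,
                            condensed_density: float | None = None) -> ConnectivityResult:
    """Mean distinct-array contacts within the condensate, times density.

    Two arrays are in contact when any nucleosome pair sits within
    ``cutoff`` (minimum-image if ``box`` given).  Phase membership uses
    single-linkage clustering on that contact graph; the largest cluster is
    the condensate.  If ``condensed_density`` (arrays/nm^3) is omitted it is
    estimated from the condensate's bounding volume.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i][:, None, :] - pos[j][None, :, :]
            if box is not None:
                b = np.asarray(box, dtype=float)
                d -= b * np.round(d / b)
            if np.sqrt((d**2).sum(axis=-1)).min() <= cutoff:
                adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    largest = int(np.argmax(sizes))
    members = np.where(labels == largest)[0]
    if sizes[largest] < 2:
        return ConnectivityResult(0.0, 0.0, 0.0, int(sizes[largest]), empty=True)
    mean_conn = float(adj[np.ix_(members, members)].sum(axis=1).mean())
    if condensed_density is None:
        coms = pos[members].mean(axis=1)
        span = np.maximum(coms.max(axis=0) - coms.min(axis=0), cutoff)
        vol_nm3 = float(np.prod(span)) / 1e3
        condensed_density = len(members) / vol_nm3
    return ConnectivityResult(
        mean_connections=mean_conn,
        condensed_density=float(condensed_density),
        connectivity=mean_conn * float(condensed_density),
        n_condensate=len(members),
    )


# ---------------------------------------------------------------------------
# desk-scale slab dynamics (rigid-array Monte Carlo)
# ---------------------------------------------------------------------------

def array_pair_energy(a: np.ndarray, b: np.ndarray, debye_length: float,
                      eps: float, sigma: float = 80.0, q_eff: float = 600.0,
                      box=None) -> float:
    """Nucleosome-level interaction energy between two rigid arrays.

    Lennard-Jones-like nucleosome attraction of depth ``eps`` plus a
    screened electrostatic repulsion whose range follows the Debye length:
    the salt dependence of array-array binding, and hence of condensation.
    """
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        d -= box * np.round(d / box)
    r = np.sqrt((d**2).sum(axis=-1))
    r = np.maximum(r, 30.0)
    near = r < 3.0 * sigma
    if not near.any():
        return 0.0
    rr = r[near]
    sr6 = (sigma / rr) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    el = q_eff * np.exp(-rr / debye_length) / (rr / sigma)
    return float((lj + el).sum())


def dimer_binding_curve(template: np.ndarray, salt: float, breathing: bool,
                        separations=None, eps0: float = 0.5,
                        exposure_bonus: float = 0.4, sigma: float = 80.0,
                        q_eff: float = 600.0):
    """Binding-energy curve of two parallel array copies vs separation.

    Returns ``(separations, energies)``; the minimum over separation is the
    dimer well depth.  Condensation onsets once this well out-competes the
    thermal scale, which happens at lower salt for breathing arrays (their
    exposure term deepens the well).
    """
    template = np.asarray(template, dtype=float)
    template = template - template.mean(axis=0)
    if separations is None:
        separations = np.linspace(0.8 * sigma, 2.5 * sigma, 40)
    lam = debye_length_from_salt(salt)
    eps = eps0 + (exposure_bonus if breathing else 0.0)
    energies = [
        array_pair_energy(template, template + np.array([s, 0.0, 0.0]),
                          lam, eps, sigma, q_eff)
        for s in separations
    ]
    return np.asarray(separations), np.asarray(energies)


def condensation_onset_salt(template: np.ndarray, breathing: bool,
                            salts=None, threshold_kt: float = -0.5,
                            temperature_kt: float = 0.6, **kw) -> float:
    """Lowest salt on the grid where the dimer well is deep enough to bind.

    The binding criterion is ``min-well <= threshold_kt * kT``; above the
    returned concentration, array-array attraction out-competes the screened
    repulsion and condensation proceeds.  Returns ``nan`` if no salt on the
    grid binds.
    """
    salts = np.asarray(salts if salts is not None else np.linspace(0.03, 0.20, 35))
    for c in np.sort(salts):
        _, e = dimer_binding_curve(template, float(c), breathing, **kw)
        if e.min() <= threshold_kt * temperature_kt:
            return float(c)
    return float("nan")

def slab_monte_carlo(slab: SlabSystem, salt: float, breathing: bool,
                     n_sweeps: int = 200, seed: int = 0,
                     eps0: float = 0.5, exposure_bonus: float = 0.4,
                     sigma: float = 80.0, q_eff: float = 150.0,
                     temperature_kt: float = 0.6,
                     max_translation: float = 30.0,
                     record_every: int = 10) -> list[np.ndarray]:
    """Metropolis Monte Carlo over rigid-array translations/rotations.

    Nucleosome-level pair energy between different arrays combines a
    Lennard-Jones-like attraction (depth raised by ``exposure_bonus`` for
    breathing nucleosomes, mirroring the minimal model's core-exposure
    term) with a screened electrostatic repulsion whose range follows the
    Debye length at the given salt.  Returns recorded configurations.
    """
    rng = np.random.default_rng(seed)
    lam = debye_length_from_salt(salt)
    eps = eps0 + (exposure_bonus if breathing else 0.0)
    pos = slab.positions.copy()
    box = slab.box

    def array_energy(k, coords):
        e = 0.0
        for m in range(slab.n_arrays):
            if m != k:
                e += array_pair_energy(coords, pos[m], lam, eps, sigma, q_eff, box)
        return e

    recorded = []
    for sweep in range(n_sweeps):
        for k in range(slab.n_arrays):
            old = pos[k]
            e_old = array_energy(k, old)
            new = old + rng.uniform(-max_translation, max_translation, size=3)
            if rng.random() < 0.5:
                q = rng.normal(size=4)
                q /= np.linalg.norm(q)
                rot = _quat_matrix(q)
                com = new.mean(axis=0)
                new = (new - com) @ rot.T + com
            e_new = array_energy(k, new)
            if e_new <= e_old or rng.random() < math.exp(-(e_new - e_old) / temperature_kt):
                pos[k] = new
        if sweep % record_every == 0:
            recorded.append(pos.copy())
    return recorded
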