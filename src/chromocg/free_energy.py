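"""Umbrella sampling over the DNA end-to-end distance, WHAM, and barrier
readouts.

The umbrella bias is ``U_bias = 1/2 k (r - c)^2`` on the distance between
the first and last base-pair bodies.  PMFs are reported in units of k_B T
with the minimum shifted to zero; forces derive from the PMF by numerical
differentiation (1 k_B T / A at 300 K = 41.4 pN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from chromocg import constants
from chromocg.energetics import EnergyModel
from chromocg.sampling import ChromatinDynamics, LangevinParams

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "BarrierSummary",
    "end_to_end_distance",
    "end_to_end_bias",
    "run_umbrella_series",
    "wham",
    "force_extension_from_pmf",
    "extract_barriers",
    "write_wham_input",
    "read_wham_input",
]


class FreeEnergyError(ValueError):
    pass


@dataclass
class UmbrellaWindow:
    center: float                 # A
    spring_constant: float        # kcal/mol/A^2
    samples: np.ndarray           # end-to-end distances, A
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class PMFProfile:
    grid: np.ndarray              # bin centres, A
    free_energy: np.ndarray       # k_B T, minimum at 0
    uncertainty: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)


@dataclass
class BarrierSummary:
    dg1: float                    # k_B T, state 1 -> 2
    dg2: float                    # k_B T, state 2 -> 3
    f1: float                     # pN, max force during 1 -> 2
    f2: float                     # pN, max force during 2 -> 3
    state_boundaries: tuple
    no_rupture_1: bool = False
    no_rupture_2: bool = False


# ---------------------------------------------------------------------------
# umbrella machinery
# ---------------------------------------------------------------------------

def end_to_end_distance(bpos: np.ndarray) -> float:
    """Distance between the first and last DNA body centres."""
    return float(np.linalg.norm(bpos[-1] - bpos[0]))


def end_to_end_bias(center: float, spring_constant: float):
    """Bias callable for :class:`ChromatinDynamics`.

    Returns ``(energy, protein forces, body forces)`` with equal and
    opposite restraint forces on the two terminal DNA bodies.
    """

    def bias(prot, bpos, bquat):
        fb = np.zeros_like(bpos)
        d = bpos[-1] - bpos[0]
        r = np.linalg.norm(d)
        e = 0.5 * spring_constant * (r - center) ** 2
        if r > 1e-12:
            mag = spring_constant * (r - center)
            u = d / r
            fb[-1] = -mag * u
            fb[0] = mag * u
        return e, np.zeros_like(prot), fb

    return bias


def unwrap_ends_configuration(system, n_end_bp: int):
    """Configuration with ``n_end_bp`` base pairs peeled straight from each
    end of the DNA, continuing the local tangent outward.

    Used to seed umbrella windows along the unwrapping coordinate so each
    window equilibrates locally instead of having to nucleate the peel.
    Returns ``(prot, bpos, bquat)``.
    """
    from chromocg.geometry import quat_multiply, quat_rotate_vec, rotvec_to_quat

    prot = np.array([b.position for b in system.protein_beads]).reshape(-1, 3)
    bpos = np.array([f.position for f in system.dna_frames]).reshape(-1, 3)
    bquat = np.array([f.orientation for f in system.dna_frames]).reshape(-1, 4)
    n_bp = len(bpos)
    n = int(min(n_end_bp, max(n_bp // 2 - 1, 0)))
    if n > 0:
        twist = np.radians(constants.BDNA_TWIST)
        for anchor, idxs, sign in ((n, range(n - 1, -1, -1), -1.0),
                                   (n_bp - 1 - n, range(n_bp - n, n_bp), +1.0)):
            tangent = quat_rotate_vec(bquat[anchor][None], np.array([0.0, 0, 1]))[0]
            for step, j in enumerate(idxs, start=1):
                bpos[j] = bpos[anchor] + sign * constants.BDNA_RISE * step * tangent
                # keep canonical twist about the local helix axis
                dq = rotvec_to_quat(np.array([0.0, 0.0, sign * twist * step]))
                bquat[j] = quat_multiply(bquat[anchor], dq)
    return prot, bpos, bquat


def unwrapping_window_seeds(system, n_max_peel: int, n_interp: int = 3):
    """Window seeds along the unwrapping coordinate.

    Generates peeled-end configurations for 0..n_max_peel base pairs per
    end plus ``n_interp`` geometric interpolants between consecutive peel
    states (unwrapping is quantised into per-bp basins; the interpolants
    let neighbouring umbrella windows overlap).  Returns a list of
    ``(end_to_end, state)`` sorted by the coordinate value.
    """
    anchors = [unwrap_ends_configuration(system, n) for n in range(n_max_peel + 1)]
    out = []
    for idx, state in enumerate(anchors):
        out.append(state)
        if idx + 1 < len(anchors):
            nxt = anchors[idx + 1]
            for t in np.linspace(0, 1, n_interp + 2)[1:-1]:
                prot = (1 - t) * state[0] + t * nxt[0]
                bpos = (1 - t) * state[1] + t * nxt[1]
                bq = (1 - t) * state[2] + t * nxt[2]
                bq = bq / np.linalg.norm(bq, axis=1, keepdims=True)
                out.append((prot, bpos, bq))
    tagged = [(end_to_end_distance(st[1]), st) for st in out]
    tagged.sort(key=lambda p: p[0])
    return tagged


def unwrapping_pmf(model: EnergyModel, n_max_peel: int = 10,
                   spring_constant: float = 2.0, n_steps: int = 400,
                   equilibration: int = 150, stride: int = 5,
                   n_interp: int = 3, seed: int = 0,
                   params: LangevinParams | None = None,
                   bin_width: float = 1.0,
                   estimator: str = "wham") -> PMFProfile:
    """Desk-scale unwrapping PMF over the DNA end-to-end distance.

    Seeds one umbrella window per (interpolated) peel state, centred at the
    seed's own end-to-end distance, and runs the biased series.  With
    ``estimator='wham'`` the profile is reconstructed by WHAM (requires
    histogram overlap); ``estimator='integration'`` uses mean-force
    integration, which is the appropriate choice for the quantised
    sub-Angstrom peel basins of miniaturised fixtures.
    """
    seeds = unwrapping_window_seeds(model.system, n_max_peel, n_interp)
    windows, states = [], []
    last = -np.inf
    for r, st in seeds:
        if r - last < 1e-6:   # strictly monotone centres
            continue
        windows.append((r, spring_constant))
        states.append(st)
        last = r
    wins = run_umbrella_series(model, windows, n_steps=n_steps,
                               equilibration=equilibration, stride=stride,
                               params=params, seed=seed, initial_states=states)
    if estimator == "integration":
        return umbrella_integration(wins)
    return wham(wins, bin_width=bin_width)


def run_umbrella_series(
    model: EnergyModel,
    windows: list[tuple[float, float]],
    n_steps: int = 3000,
    equilibration: int = 500,
    stride: int = 10,
    params: LangevinParams | None = None,
    seed: int = 0,
    initial_states: list | None = None,
) -> list[UmbrellaWindow]:
    """Run one biased Langevin trajectory per (center, k) window.

    Windows must have strictly monotone centres.  Each window is seeded
    independently and decorrelated by ``stride``; a window whose histogram
    overlaps neither neighbour is flagged with ``overlap_warning``.
    ``initial_states`` optionally supplies one (prot, bpos, bquat) starting
    configuration per window (e.g. from
    :func:`unwrap_ends_configuration`).
    """
    centers = [c for c, _ in windows]
    if np.any(np.diff(centers) <= 0):
        raise FreeEnergyError("window centers must be strictly monotone")
    if initial_states is not None and len(initial_states) != len(windows):
        raise FreeEnergyError("need one initial state per window")
    out = []
    for w_idx, (center, k) in enumerate(windows):
        dyn = ChromatinDynamics(model, params=params, seed=seed + 1000 * w_idx,
                                bias=end_to_end_bias(center, k),
                                initial_coords=None if initial_states is None
                                else initial_states[w_idx])
        dyn.step(equilibration)
        samples = []
        for _ in range(max((n_steps - equilibration) // stride, 1)):
            dyn.step(stride)
            samples.append(end_to_end_distance(dyn.bpos))
        out.append(
            UmbrellaWindow(
                center=center, spring_constant=k, samples=np.array(samples),
                metadata={
                    "debye_length": model.dh.debye_length,
                    "seed": seed + 1000 * w_idx,
                    "stride": stride,
                },
            )
        )
    _flag_overlaps(out)
    return out


def _flag_overlaps(windows: list[UmbrellaWindow]):
    for i, w in enumerate(windows):
        neighbours = [n for n in (i - 1, i + 1) if 0 <= n < len(windows)]
        if not neighbours:
            continue
        lo, hi = w.samples.min(), w.samples.max()
        overlap = any(
            (windows[n].samples.max() >= lo) and (windows[n].samples.min() <= hi)
            for n in neighbours
        )
        if not overlap:
            w.metadata["overlap_warning"] = True
            warnings.warn(f"umbrella window at {w.center:.1f} A overlaps no neighbour")


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham(windows: list[UmbrellaWindow], bin_width: float = 2.0,
         tolerance: float = 1e-6, max_iterations: int = 100000,
         temperature: float = constants.T_REF) -> PMFProfile:
    """Weighted-histogram reconstruction of the unbiased PMF.

    Standard self-consistent iteration on the per-window free-energy shifts
    until the largest change is below ``tolerance`` (k_B T).  Raises if the
    window-overlap graph is disconnected (listing the components).
    """
    if not windows:
        raise FreeEnergyError("need at least one window")
    kbt = constants.KB * temperature
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows])
    _check_overlap_graph(windows, counts)
    n_tot = counts.sum(axis=1).astype(float)          # samples per window
    bias = np.array([w.bias_energy(grid) for w in windows]) / kbt  # (W, B)
    cexp = np.exp(-bias)

    f = np.zeros(len(windows))                         # window shifts, kBT
    numer = counts.sum(axis=0).astype(float)
    for _ in range(max_iterations):
        denom = (n_tot[:, None] * np.exp(f)[:, None] * cexp).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        norm = p.sum()
        if norm > 0:
            p = p / norm
        with np.errstate(divide="ignore"):
            f_new = -np.log(np.maximum((cexp * p[None, :]).sum(axis=1), 1e-300))
        f_new -= f_new[0]
        shift = np.max(np.abs(f_new - f))
        f = f_new
        if shift < tolerance:
            break
    with np.errstate(divide="ignore"):
        g = -np.log(np.where(p > 0, p, np.nan))
    g = g - np.nanmin(g)
    # Poisson-style per-bin uncertainty from the effective counts
    eff = numer.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        unc = np.where(eff > 0, 1.0 / np.sqrt(eff), np.nan)
    return PMFProfile(grid=grid, free_energy=g, uncertainty=unc)


def _check_overlap_graph(windows, counts):
    """Windows overlapping in at least one bin form a graph; it must be
    connected for WHAM to stitch a single profile."""
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    occupied = counts > 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(occupied[i] & occupied[j]):
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    if len(comps) > 1:
        desc = "; ".join(
            "{" + ", ".join(f"{windows[i].center:.1f}" for i in c) + "}"
            for c in comps.values()
        )
        raise FreeEnergyError(f"window overlap graph is disconnected: components {desc}")


# ---------------------------------------------------------------------------
# derived readouts
# ---------------------------------------------------------------------------

def umbrella_integration(windows: list[UmbrellaWindow],
                         temperature: float = constants.T_REF) -> PMFProfile:
    """Mean-force integration of umbrella windows (no histogram overlap
    needed).

    At each window the unbiased mean force is estimated from the bias
    balance ``dA/dr ~ k (c - <r>)`` at the window's sample mean, and the
    profile is reconstructed by trapezoidal integration over the sorted
    sample means.  Used when the landscape is too stiff/quantised for
    WHAM's histogram overlap (e.g. desk-scale unwrapping, where peel states
    form sub-Angstrom basins); WHAM remains the primary estimator.
    """
    if not windows:
        raise FreeEnergyError("need at least one window")
    kbt = constants.KB * temperature
    means = np.array([w.samples.mean() for w in windows])
    dadr = np.array([w.spring_constant * (w.center - w.samples.mean()) for w in windows])
    order = np.argsort(means)
    r = means[order]
    f = dadr[order]
    g = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(r))]) / kbt
    g = g - g.min()
    sem = np.array([w.samples.std(ddof=1) / np.sqrt(len(w.samples)) for w in windows])[order]
    unc = np.abs(sem * np.array([w.spring_constant for w in windows])[order]) / kbt
    return PMFProfile(grid=r, free_energy=g, uncertainty=unc)


def force_extension_from_pmf(pmf: PMFProfile) -> np.ndarray:
    """Force curve (pN) by numerical derivative of the PMF.

    Central differences in the interior, one-sided at the endpoints.
    """
    g = pmf.free_energy
    x = pmf.grid
    if len(x) < 3:
        raise FreeEnergyError("need at least 3 grid points")
    dx = np.diff(x)
    if np.max(np.abs(dx - dx[0])) > 1e-9 * max(abs(dx[0]), 1.0):
        raise FreeEnergyError("grid spacing must be uniform")
    dgdx = np.gradient(g, x[1] - x[0])
    return dgdx * constants.KBT_PER_ANGSTROM_IN_PN


def extract_barriers(pmf: PMFProfile, state_boundaries) -> BarrierSummary:
    """Barrier heights and rupture forces from a 3-state partition.

    ``state_boundaries`` is ``(b1, b2)``: grid values splitting the profile
    into state 1 (< b1), state 2 (b1..b2) and state 3 (> b2).  Barriers are
    differences of per-state minima; forces are the maximum derived force
    within each transition region (between consecutive state minima),
    clamped at zero.  A transition whose free-energy difference is <= 0 is
    flagged ``no_rupture``.
    """
    b1, b2 = state_boundaries
    x, g = pmf.grid, pmf.free_energy
    masks = [x < b1, (x >= b1) & (x <= b2), x > b2]
    for k, m in enumerate(masks, start=1):
        if not np.any(m & np.isfinite(g)):
            raise FreeEnergyError(f"state {k} region is empty")
    mins = []
    argmins = []
    for m in masks:
        gm = np.where(m, g, np.nan)
        idx = int(np.nanargmin(gm))
        argmins.append(idx)
        mins.append(float(g[idx]))
    dg1 = mins[1] - mins[0]
    dg2 = mins[2] - mins[1]
    # np.gradient handles non-uniform grids (umbrella-integration profiles)
    force = (np.gradient(g, x) * constants.KBT_PER_ANGSTROM_IN_PN
             if len(x) >= 3 else np.zeros_like(g))
    f1 = _max_force(force, argmins[0], argmins[1])
    f2 = _max_force(force, argmins[1], argmins[2])
    return BarrierSummary(
        dg1=dg1, dg2=dg2, f1=f1, f2=f2,
        state_boundaries=(b1, b2),
        no_rupture_1=dg1 <= 0.0,
        no_rupture_2=dg2 <= 0.0,
    )


def _max_force(force: np.ndarray, i0: int, i1: int) -> float:
    lo, hi = min(i0, i1), max(i0, i1)
    seg = force[lo : hi + 1]
    seg = seg[np.isfinite(seg)]
    return float(max(seg.max(), 0.0)) if len(seg) else 0.0


# ---------------------------------------------------------------------------
# grossfield-style text layout
# ---------------------------------------------------------------------------

def write_wham_input(windows: list[UmbrellaWindow], directory):
    """Write one time-series file per window plus a metadata index."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, w in enumerate(windows):
        fname = d / f"window_{i:03d}.dat"
        with open(fname, "w") as fh:
            for t, x in enumerate(w.samples):
                fh.write(f"{t}\t{x:.6f}\n")
        lines.append(f"{fname.name}\t{w.center:.6f}\t{w.spring_constant:.6f}")
    (d / "metadata.dat").write_text("\n".join(lines) + "\n")


def read_wham_input(directory) -> list[UmbrellaWindow]:
    """Read the layout produced by :func:`write_wham_input` (also accepts
    the common grossfield metadata format ``file center k``)."""
    from pathlib import Path

    d = Path(directory)
    windows = []
    for line in (d / "metadata.dat").read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        fname, center, k = parts[0], float(parts[1]), float(parts[2])
        data = np.loadtxt(d / fname)
        samples = data[:, 1] if data.ndim == 2 else data
        windows.append(UmbrellaWindow(center=center, spring_constant=k, samples=samples))
    return windows
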