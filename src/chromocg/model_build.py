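"""Construction of chemically specific chromatin systems.

Builds histone chains (one bead per residue), elastic networks for the
globular cores, idealized wrapped nucleosomes on a left-handed superhelix,
regular oligonucleosome arrays, and the non-breathing constraint that ties
nucleosomal DNA into the core elastic network.

Site indexing convention used throughout the package: protein beads occupy
global site indices ``0 .. n_protein-1``; base pair ``j`` contributes three
sites ``n_protein + 3j`` (ellipsoid centre) and ``n_protein + 3j + 1/2``
(the two phosphate charge sites).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from chromocg import constants
from chromocg.geometry import matrix_to_quat, quat_rotate, quat_to_matrix

__all__ = [
    "ResidueBead",
    "BasePairFrame",
    "GNMTopology",
    "NucleosomeRecord",
    "ChromatinSystem",
    "residue_table",
    "packaged_histones",
    "build_histone_chain",
    "build_gnm",
    "build_ideal_nucleosome",
    "build_array",
    "apply_non_breathing",
]

# Body-frame phosphate virtual sites: canonical B-DNA backbone positions,
# radial distance ~9.4 A at +-154 degrees azimuth from the major-groove axis.
PHOSPHATE_RADIUS = 9.4
PHOSPHATE_AZIMUTH_DEG = 154.0

#: effective excluded-volume diameters of the DNA sites, A
BP_CENTER_DIAMETER = 12.0
PHOSPHATE_DIAMETER = 4.0

#: DNA bodies within this index separation have all site-site non-bonded
#: pairs excluded: at B-DNA rise a 12 A isotropic excluded volume would
#: otherwise clash with its own chain (local structure is carried by the
#: step elasticity instead)
DNA_EXCLUSION_SPAN = 4

GNM_CUTOFF = 7.5          # A
GNM_SPRING_CONSTANT = 20.0  # kcal/mol/A^2
BOND_SPRING_CONSTANT = 20.0  # kcal/mol/A^2
BOND_REST_LENGTH = 3.5       # A

SUPERHELIX_RADIUS = 41.9  # A, canonical nucleosome crystallography value
SUPERHELIX_PITCH = 25.9   # A per superhelical turn


class ModelBuildError(ValueError):
    """Raised on invalid build inputs."""


@dataclass
class ResidueBead:
    chain_id: str
    residue_index: int
    amino_acid: str
    position: np.ndarray
    charge: float
    diameter: float
    region: str  # "tail" | "globular"
    mass: float = 110.0


@dataclass
class BasePairFrame:
    index: int
    position: np.ndarray
    orientation: np.ndarray  # unit quaternion (w, x, y, z)
    step_sequence: str = "AVG"
    phosphate_offsets: np.ndarray = field(default_factory=lambda: default_phosphate_offsets())
    phosphate_charge: float = -1.0

    def phosphate_positions(self) -> np.ndarray:
        """Lab-frame positions of the two phosphate sites."""
        return self.position[None, :] + quat_rotate(self.orientation, self.phosphate_offsets)


def default_phosphate_offsets() -> np.ndarray:
    a = math.radians(PHOSPHATE_AZIMUTH_DEG)
    r = PHOSPHATE_RADIUS
    return np.array(
        [
            [r * math.cos(a), r * math.sin(a), 0.0],
            [r * math.cos(-a), r * math.sin(-a), 0.0],
        ]
    )


@dataclass
class GNMTopology:
    """Elastic network: unique (i, j) site pairs with reference rest lengths."""

    pairs: np.ndarray            # (n, 2) int, i < j, global site indices
    rest_lengths: np.ndarray     # (n,) A
    spring_constant: float = GNM_SPRING_CONSTANT
    cutoff: float = GNM_CUTOFF

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float).reshape(-1)
        if len(self.pairs) != len(self.rest_lengths):
            raise ModelBuildError("GNM pairs and rest lengths must align")

    @property
    def n_springs(self) -> int:
        return len(self.pairs)


@dataclass
class NucleosomeRecord:
    histone_range: tuple[int, int]   # protein bead index span [start, stop)
    dna_span: tuple[int, int]        # bp index span [start, stop)
    dyad_bp: int                     # 0-based internally
    breathing: bool = True

    @property
    def dyad_bp_report(self) -> int:
        """1-based dyad index for reports."""
        return self.dyad_bp + 1


@dataclass
class ChromatinSystem:
    protein_beads: list[ResidueBead]
    dna_frames: list[BasePairFrame]
    flexible_bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    gnm: list[GNMTopology] = field(default_factory=list)
    nucleosome_records: list[NucleosomeRecord] = field(default_factory=list)
    bond_spring_constant: float = BOND_SPRING_CONSTANT
    bond_rest_length: float = BOND_REST_LENGTH

    # ---- site bookkeeping -------------------------------------------------
    @property
    def n_protein(self) -> int:
        return len(self.protein_beads)

    @property
    def n_bp(self) -> int:
        return len(self.dna_frames)

    @property
    def n_sites(self) -> int:
        return self.n_protein + 3 * self.n_bp

    def bp_center_site(self, j: int) -> int:
        return self.n_protein + 3 * j

    def bp_phosphate_sites(self, j: int) -> tuple[int, int]:
        base = self.n_protein + 3 * j
        return base + 1, base + 2

    def site_positions(self) -> np.ndarray:
        """(n_sites, 3) lab-frame positions of every interaction site."""
        out = np.empty((self.n_sites, 3))
        for i, b in enumerate(self.protein_beads):
            out[i] = b.position
        p = self.n_protein
        for j, f in enumerate(self.dna_frames):
            out[p + 3 * j] = f.position
            out[p + 3 * j + 1 : p + 3 * j + 3] = f.phosphate_positions()
        return out

    def site_charges(self) -> np.ndarray:
        q = np.zeros(self.n_sites)
        for i, b in enumerate(self.protein_beads):
            q[i] = b.charge
        p = self.n_protein
        for j, f in enumerate(self.dna_frames):
            q[p + 3 * j + 1] = f.phosphate_charge
            q[p + 3 * j + 2] = f.phosphate_charge
        return q

    def site_diameters(self) -> np.ndarray:
        d = np.empty(self.n_sites)
        for i, b in enumerate(self.protein_beads):
            d[i] = b.diameter
        p = self.n_protein
        for j in range(self.n_bp):
            d[p + 3 * j] = BP_CENTER_DIAMETER
            d[p + 3 * j + 1] = PHOSPHATE_DIAMETER
            d[p + 3 * j + 2] = PHOSPHATE_DIAMETER
        return d

    def site_species(self) -> np.ndarray:
        """Per-site species code: the amino-acid letter, 'bp' or 'ph'."""
        s = np.empty(self.n_sites, dtype=object)
        for i, b in enumerate(self.protein_beads):
            s[i] = b.amino_acid
        p = self.n_protein
        for j in range(self.n_bp):
            s[p + 3 * j] = "bp"
            s[p + 3 * j + 1] = "ph"
            s[p + 3 * j + 2] = "ph"
        return np.asarray(s)

    # ---- topology ---------------------------------------------------------
    def exclusion_pairs(self) -> np.ndarray:
        """Unique (i, j) site pairs excluded from non-bonded interactions.

        Covers flexible bonds, elastic-network springs, the three sites of
        one rigid base-pair body, and all site pairs between base-pair
        bodies within ``DNA_EXCLUSION_SPAN`` along the chain (consecutive
        bodies are directly bonded through the step elasticity; the next few
        are excluded because B-DNA rise is far below the bead excluded
        volume).
        """
        pairs = []
        if len(self.flexible_bonds):
            pairs.append(np.asarray(self.flexible_bonds, dtype=int))
        for g in self.gnm:
            if g.n_springs:
                pairs.append(g.pairs)
        p = self.n_protein
        intra = []
        for j in range(self.n_bp):
            base = p + 3 * j
            intra.extend([(base, base + 1), (base, base + 2), (base + 1, base + 2)])
        for a in range(self.n_bp):
            for b in range(a + 1, min(a + DNA_EXCLUSION_SPAN + 1, self.n_bp)):
                sa = [p + 3 * a + k for k in range(3)]
                sb = [p + 3 * b + k for k in range(3)]
                intra.extend((i, j) for i in sa for j in sb)
        if intra:
            pairs.append(np.asarray(intra, dtype=int))
        if not pairs:
            return np.empty((0, 2), dtype=int)
        allp = np.vstack(pairs)
        allp = np.sort(allp, axis=1)
        return np.unique(allp, axis=0)

    def _bonded_bp_steps(self) -> list[tuple[int, int]]:
        """Consecutive bp body pairs that interact through the step potential.

        Consecutive bp indices are bonded except across a gap between
        independent DNA molecules (not used by the regular builders, where
        the whole array is one DNA molecule).
        """
        return [(j, j + 1) for j in range(self.n_bp - 1)]

    def copy(self) -> "ChromatinSystem":
        return ChromatinSystem(
            protein_beads=[replace(b, position=np.array(b.position, dtype=float)) for b in self.protein_beads],
            dna_frames=[
                replace(
                    f,
                    position=np.array(f.position, dtype=float),
                    orientation=np.array(f.orientation, dtype=float),
                    phosphate_offsets=np.array(f.phosphate_offsets, dtype=float),
                )
                for f in self.dna_frames
            ],
            flexible_bonds=np.array(self.flexible_bonds, dtype=int),
            gnm=[
                GNMTopology(np.array(g.pairs), np.array(g.rest_lengths), g.spring_constant, g.cutoff)
                for g in self.gnm
            ],
            nucleosome_records=[replace(r) for r in self.nucleosome_records],
            bond_spring_constant=self.bond_spring_constant,
            bond_rest_length=self.bond_rest_length,
        )


# ---------------------------------------------------------------------------
# residue parameter table and packaged histones
# ---------------------------------------------------------------------------

_RESIDUE_TABLE: pd.DataFrame | None = None


def _data_path(name: str):
    return importlib.resources.files("chromocg") / "data" / name


def residue_table(histidine_charge: float = 0.0) -> pd.DataFrame:
    """Packaged per-residue charge/diameter/mass table, indexed by code.

    ``histidine_charge`` overrides the histidine default of 0 (set to e.g.
    +0.5 to model partial protonation).
    """
    global _RESIDUE_TABLE
    if _RESIDUE_TABLE is None:
        with importlib.resources.as_file(_data_path("residues.tsv")) as p:
            tab = pd.read_csv(p, sep="\t", comment="#").set_index("code")
        tab["charge"] = tab["charge"].astype(float)
        _RESIDUE_TABLE = tab
    tab = _RESIDUE_TABLE.copy()
    tab.loc["H", "charge"] = histidine_charge
    return tab


def packaged_histones() -> dict[str, tuple[str, list[str]]]:
    """Packaged canonical histone sequences with disorder annotations.

    Returns ``{name: (sequence, regions)}`` where ``regions`` is a
    per-residue list of ``"tail"``/``"globular"`` flags.
    """
    from Bio import SeqIO

    with importlib.resources.as_file(_data_path("histone_tails.yaml")) as p:
        tails = yaml.safe_load(p.read_text())
    out = {}
    with importlib.resources.as_file(_data_path("histones.fasta")) as p:
        for rec in SeqIO.parse(str(p), "fasta"):
            seq = str(rec.seq)
            regions = ["globular"] * len(seq)
            for lo, hi in tails.get(rec.id, {}).values():
                for i in range(lo - 1, hi):
                    regions[i] = "tail"
            out[rec.id] = (seq, regions)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_histone_chain(
    sequence: str,
    disorder_annotation: list[str],
    chain_id: str = "A",
    histidine_charge: float = 0.0,
) -> list[ResidueBead]:
    """One bead per residue, charge/diameter/mass from the packaged table.

    ``disorder_annotation`` holds one ``"tail"``/``"globular"`` flag per
    residue and must match the sequence length.
    """
    if not sequence:
        raise ModelBuildError("empty sequence")
    if len(disorder_annotation) != len(sequence):
        raise ModelBuildError(
            f"annotation length {len(disorder_annotation)} != sequence length {len(sequence)}"
        )
    tab = residue_table(histidine_charge=histidine_charge)
    beads = []
    for i, aa in enumerate(sequence):
        if aa not in tab.index:
            raise ModelBuildError(f"invalid residue code {aa!r} at position {i + 1}")
        region = disorder_annotation[i]
        if region not in ("tail", "globular"):
            raise ModelBuildError(f"invalid region flag {region!r} at position {i + 1}")
        row = tab.loc[aa]
        beads.append(
            ResidueBead(
                chain_id=chain_id,
                residue_index=i,
                amino_acid=aa,
                position=np.zeros(3),
                charge=float(row["charge"]),
                diameter=float(row["diameter"]),
                region=region,
                mass=float(row["mass"]),
            )
        )
    return beads


def build_gnm(
    reference_positions: np.ndarray,
    cutoff: float = GNM_CUTOFF,
    k: float = GNM_SPRING_CONSTANT,
    site_indices: np.ndarray | None = None,
) -> GNMTopology:
    """Elastic network over all position pairs within ``cutoff``.

    ``site_indices`` maps local row numbers to global site indices (defaults
    to ``0..n-1``).  Rest lengths are the reference distances.
    """
    pos = np.asarray(reference_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ModelBuildError("need at least 2 reference positions")
    tree = cKDTree(pos)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw):
        raw = raw[np.lexsort((raw[:, 1], raw[:, 0]))]
        rest = np.linalg.norm(pos[raw[:, 0]] - pos[raw[:, 1]], axis=1)
    else:
        rest = np.empty(0)
    if site_indices is not None:
        site_indices = np.asarray(site_indices, dtype=int)
        raw = np.sort(site_indices[raw], axis=1) if len(raw) else raw
    return GNMTopology(pairs=raw, rest_lengths=rest, spring_constant=k, cutoff=cutoff)


#: default core scaffold shell, as fractions of the superhelix radius:
#: (inner radius, outer radius, half height)
CORE_SHELL = (0.36, 0.68, 0.55)


def _core_scaffold_positions(n_globular: int, radius: float,
                             shell: tuple[float, float, float] = CORE_SHELL) -> np.ndarray:
    """Deterministic quasi-random filling of a cylindrical shell.

    With the default shell the scaffold reaches close enough to the wrapped
    DNA (whose inner phosphate envelope sits at ``radius - 9.4``) for the
    non-breathing elastic network to form, while keeping ~4 A of
    excluded-volume clearance.
    """
    rin, rout, zhalf = shell
    i = np.arange(n_globular)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = (-zhalf + 2.0 * zhalf * (i + 0.5) / n_globular) * radius
    theta = i * golden
    frac = np.mod(i * math.sqrt(2.0), 1.0)
    r = (rin + (rout - rin) * frac) * radius
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _superhelix_frames(
    wrap_bp: int,
    radius: float,
    pitch: float,
    handedness: str,
    twist_per_bp: float = constants.BDNA_TWIST,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Base-pair frames (position, quaternion) on an ideal superhelix.

    The frame z-axis follows the local tangent, the x-axis starts radially
    outward, and an intrinsic B-DNA twist accumulates about the tangent.
    """
    if wrap_bp == 0:
        return []
    total_angle = wrap_bp * (constants.NUCLEOSOME_WRAP_TURNS * 2.0 * math.pi / constants.NUCLEOSOME_WRAP_BP)
    sign = -1.0 if handedness == "left" else 1.0
    # arc parameter u: z rises with u, azimuth falls with u for a left wrap
    us = total_angle * (np.arange(wrap_bp) / max(wrap_bp - 1, 1) - 0.5)
    climb = pitch / (2.0 * math.pi)
    frames = []
    for i, u in enumerate(us):
        th = sign * u
        pos = np.array([radius * math.cos(th), radius * math.sin(th), climb * u])
        # tangent of the helix curve dP/du
        t = np.array([-radius * math.sin(th) * sign, radius * math.cos(th) * sign, climb])
        t /= np.linalg.norm(t)
        radial = np.array([math.cos(th), math.sin(th), 0.0])
        x = radial - np.dot(radial, t) * t
        x /= np.linalg.norm(x)
        y = np.cross(t, x)
        m = np.column_stack([x, y, t])
        # accumulate intrinsic twist about the local z-axis
        phi = math.radians(twist_per_bp) * i
        c, s = math.cos(phi), math.sin(phi)
        twist = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        frames.append((pos, matrix_to_quat(m @ twist)))
    return frames


def _step_codes(sequence: str | None, n_bp: int) -> list[str]:
    """Dinucleotide step code for each bp (the step towards the next bp)."""
    if sequence is None:
        return ["AVG"] * n_bp
    sequence = sequence.upper()
    codes = []
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    canonical = {"AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA"}
    for j in range(n_bp):
        if j + 1 >= len(sequence):
            codes.append("AVG")
            continue
        step = sequence[j : j + 2]
        if any(b not in complement for b in step):
            raise ModelBuildError(f"invalid DNA base in step {step!r} at position {j + 1}")
        if step not in canonical:
            step = complement[step[1]] + complement[step[0]]
        codes.append(step)
    return codes


def build_ideal_nucleosome(
    wrap_bp: int = constants.NUCLEOSOME_WRAP_BP,
    superhelix_radius: float = SUPERHELIX_RADIUS,
    superhelix_pitch: float = SUPERHELIX_PITCH,
    handedness: str = "left",
    histones: dict[str, tuple[str, list[str]]] | None = None,
    dna_sequence: str | None = None,
    histidine_charge: float = 0.0,
    core_shell: tuple[float, float, float] = CORE_SHELL,
) -> ChromatinSystem:
    """Idealized wrapped nucleosome: core scaffold plus superhelical DNA.

    The DNA wraps ``wrap_bp * 1.7 / 147`` turns on a left-handed superhelix.
    ``histones`` maps chain names to (sequence, per-residue regions); the
    packaged octamer (two copies each of H3/H4/H2A/H2B) is used by default.
    A custom dict allows miniaturized fixtures for fast tests.
    """
    if wrap_bp < 0:
        raise ModelBuildError("wrap_bp must be >= 0")
    if handedness not in ("left", "right"):
        raise ModelBuildError("handedness must be 'left' or 'right'")
    if histones is None:
        base = packaged_histones()
        histones = {}
        for copy in (1, 2):
            for name in ("H3", "H4", "H2A", "H2B"):
                seq, regions = base[name]
                histones[f"{name}.{copy}"] = (seq, regions)

    beads: list[ResidueBead] = []
    for chain_id, (seq, regions) in histones.items():
        beads.extend(build_histone_chain(seq, regions, chain_id=chain_id, histidine_charge=histidine_charge))

    glob_idx = [i for i, b in enumerate(beads) if b.region == "globular"]
    scaffold = _core_scaffold_positions(max(len(glob_idx), 1), superhelix_radius, core_shell)
    for row, i in enumerate(glob_idx):
        beads[i].position = scaffold[row]

    # tails walk outward from the nearest globular bead of their chain
    bonds = []
    by_chain: dict[str, list[int]] = {}
    for i, b in enumerate(beads):
        by_chain.setdefault(b.chain_id, []).append(i)
    rng = np.random.default_rng(1234)  # deterministic fixture layout
    for chain in by_chain.values():
        for a, b in zip(chain[:-1], chain[1:]):
            if beads[a].region == "tail" or beads[b].region == "tail":
                bonds.append((a, b))
        # tails walk out of the core mostly axially (through the superhelix
        # crown, clear of the DNA ring), in the azimuthal plane of the anchor
        for run_start, run_stop, anchor, direction in _tail_runs(beads, chain):
            if anchor is None:
                origin = np.zeros(3)
                u = _random_unit(rng)
            else:
                origin = beads[anchor].position
                rad = np.array([origin[0], origin[1], 0.0])
                n = np.linalg.norm(rad)
                rad = rad / n if n > 1e-9 else _random_unit(rng)
                axial = 1.0 if origin[2] >= 0 else -1.0
                u = 0.15 * rad + np.array([0.0, 0.0, axial])
                u /= np.linalg.norm(u)
            seq_idx = range(run_start, run_stop) if direction > 0 else range(run_stop - 1, run_start - 1, -1)
            for step, i in enumerate(seq_idx, start=1):
                jitter = 0.3 * _random_unit(rng)
                beads[chain[i]].position = origin + (BOND_REST_LENGTH * step) * u + jitter

    frames = [
        BasePairFrame(index=j, position=pos, orientation=q, step_sequence=code)
        for j, ((pos, q), code) in enumerate(
            zip(
                _superhelix_frames(wrap_bp, superhelix_radius, superhelix_pitch, handedness),
                _step_codes(dna_sequence, wrap_bp),
            )
        )
    ]

    _resolve_tail_overlaps(beads, frames)

    system = ChromatinSystem(
        protein_beads=beads,
        dna_frames=frames,
        flexible_bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
    )
    if glob_idx:
        gnm = build_gnm(
            np.array([beads[i].position for i in glob_idx]),
            site_indices=np.asarray(glob_idx),
        )
    else:
        gnm = GNMTopology(np.empty((0, 2), dtype=int), np.empty(0))
    system.gnm = [gnm]
    system.nucleosome_records = [
        NucleosomeRecord(
            histone_range=(0, len(beads)),
            dna_span=(0, wrap_bp),
            dyad_bp=wrap_bp // 2,
            breathing=True,
        )
    ]
    return system


MINI_CHAIN_SEQ = "GKRKS" + "AKRGSKAGLKVAKRG"
MINI_CHAIN_REGIONS = ["tail"] * 5 + ["globular"] * 15


#: weak-binding variant: most cationic residues live in the tails, the
#: globular scaffold is nearly neutral -- per-bp detachment barriers are a
#: few k_B T, so unwrapping equilibrates in short desk-scale runs
MINI_WEAK_CHAIN_SEQ = "GKRKS" + "ASGLSKAGLVSAGLS"

#: strongly cationic variant: maximises the electrostatic share of the
#: DNA-core binding, used for salt-dependence sign checks
MINI_CHARGED_CHAIN_SEQ = "GKRKS" + "KKRKSKRKLKVKKRG"

_MINI_CHAIN_SETS = {
    "standard": MINI_CHAIN_SEQ,
    "weak": MINI_WEAK_CHAIN_SEQ,
    "charged": MINI_CHARGED_CHAIN_SEQ,
}


def mini_histones(n_chains: int = 4, chain_set: str = "standard") -> dict[str, tuple[str, list[str]]]:
    """Synthetic miniature 'histone' set for fast desk-scale fixtures."""
    seq = _MINI_CHAIN_SETS[chain_set]
    return {f"C{k}": (seq, list(MINI_CHAIN_REGIONS)) for k in range(n_chains)}


def build_mini_nucleosome(
    wrap_bp: int = 24,
    n_chains: int = 4,
    core_shell: tuple[float, float, float] = (0.55, 0.68, 0.12),
    chain_set: str = "standard",
    clip_tails: bool = False,
    **kw,
) -> ChromatinSystem:
    """Miniaturized synthetic nucleosome fixture (~100-200 sites).

    Same construction as :func:`build_ideal_nucleosome` but with short
    lysine/arginine-rich synthetic chains and a compact core shell, sized so
    that short Langevin/umbrella runs are desk-cheap while keeping the
    wrapped-DNA-on-charged-core physics.  ``chain_set='weak'`` concentrates
    the cationic residues in the tails; ``clip_tails`` removes the tail
    segments entirely (the tail-less control).
    """
    histones = mini_histones(n_chains, chain_set)
    if clip_tails:
        histones = {
            name: ("".join(a for a, reg in zip(seq, regions) if reg != "tail"),
                   [r for r in regions if r != "tail"])
            for name, (seq, regions) in histones.items()
        }
    return build_ideal_nucleosome(
        wrap_bp=wrap_bp,
        histones=histones,
        core_shell=core_shell,
        **kw,
    )


def _tail_runs(beads, chain):
    """Contiguous tail runs of one chain: (start, stop, anchor_bead, direction)."""
    runs = []
    i = 0
    n = len(chain)
    while i < n:
        if beads[chain[i]].region != "tail":
            i += 1
            continue
        j = i
        while j < n and beads[chain[j]].region == "tail":
            j += 1
        if j < n:  # N-terminal-style run anchored downstream
            runs.append((i, j, chain[j], -1))
        elif i > 0:  # C-terminal run anchored upstream
            runs.append((i, j, chain[i - 1], +1))
        else:  # whole chain is a tail
            runs.append((i, j, None, +1))
        i = j
    return runs


def _resolve_tail_overlaps(beads, frames, clearance_fixed: float = 5.0,
                           clearance_tail: float = 4.5, n_iter: int = 80):
    """Geometric repair pass pushing tail beads out of hard overlaps.

    Fixed obstacles are the globular beads and all DNA sites; tail-tail
    overlaps are resolved symmetrically.  Keeps the initial configuration
    free of catastrophic excluded-volume clashes so short Langevin runs
    start stably (soft residual strain is fine).
    """
    tail_idx = [i for i, b in enumerate(beads) if b.region == "tail"]
    if not tail_idx:
        return
    fixed = [b.position for b in beads if b.region == "globular"]
    for f in frames:
        fixed.append(f.position)
        fixed.extend(f.phosphate_positions())
    if not fixed:
        return
    fixed = np.asarray(fixed)
    tree = cKDTree(fixed)
    pos = np.array([beads[i].position for i in tail_idx])
    for _ in range(n_iter):
        moved = False
        d, nn = tree.query(pos)
        bad = d < clearance_fixed
        if np.any(bad):
            away = pos[bad] - fixed[nn[bad]]
            norm = np.linalg.norm(away, axis=1, keepdims=True)
            norm[norm < 1e-9] = 1.0
            pos[bad] += (clearance_fixed - d[bad])[:, None] * (away / norm)
            moved = True
        ttree = cKDTree(pos)
        for a, b in ttree.query_pairs(clearance_tail):
            delta = pos[a] - pos[b]
            dist = np.linalg.norm(delta)
            if dist < 1e-9:
                delta, dist = np.array([0.0, 0.0, 1.0]), 1.0
            shift = 0.5 * (clearance_tail - dist) * delta / dist
            pos[a] += shift
            pos[b] -= shift
            moved = True
        if not moved:
            break
    for i, p in zip(tail_idx, pos):
        beads[i].position = p


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_straight_dna(
    n_bp: int,
    dna_sequence: str | None = None,
    rise: float = constants.BDNA_RISE,
    twist: float = constants.BDNA_TWIST,
) -> ChromatinSystem:
    """Bare straight B-DNA along the z-axis (no histones, no records)."""
    if n_bp < 1:
        raise ModelBuildError("need at least one base pair")
    codes = _step_codes(dna_sequence, n_bp)
    frames = []
    pos = np.zeros(3)
    rot = np.eye(3)
    tw = _twist_matrix(twist)
    for j in range(n_bp):
        frames.append(
            BasePairFrame(index=j, position=np.array(pos),
                          orientation=matrix_to_quat(rot), step_sequence=codes[j])
        )
        pos = pos + rot[:, 2] * rise
        rot = rot @ tw
    return ChromatinSystem(protein_beads=[], dna_frames=frames)


def build_array(
    n_nucleosomes: int,
    nrl: int,
    dna_sequence: str | None = None,
    wrap_bp=constants.NUCLEOSOME_WRAP_BP,
    superhelix_radius: float = SUPERHELIX_RADIUS,
    superhelix_pitch: float = SUPERHELIX_PITCH,
    histones: dict[str, tuple[str, list[str]]] | None = None,
    linker_rise: float = constants.BDNA_RISE,
    linker_twist: float = constants.BDNA_TWIST,
    core_shell: tuple[float, float, float] = CORE_SHELL,
) -> ChromatinSystem:
    """Oligonucleosome array with straight B-DNA linkers.

    ``wrap_bp`` may be a single value (regular array: every linker is
    ``nrl - wrap_bp`` bp and dyad-to-dyad separation is exactly ``nrl``) or
    one value per nucleosome, which realises breathing states geometrically:
    a shorter wrap lengthens that nucleosome's linker and rotates everything
    downstream through the accumulated linker twist.
    """
    if n_nucleosomes < 1:
        raise ModelBuildError("need at least one nucleosome")
    wraps = ([int(wrap_bp)] * n_nucleosomes if np.isscalar(wrap_bp)
             else [int(w) for w in wrap_bp])
    if len(wraps) != n_nucleosomes:
        raise ModelBuildError("need one wrap_bp per nucleosome")
    if min(wraps) < 1:
        raise ModelBuildError("wrap_bp must be >= 1 (use build_straight_dna for bare DNA)")
    if nrl < max(wraps):
        raise ModelBuildError(f"nrl {nrl} < wrap {max(wraps)}: linker would be negative")
    total_bp = n_nucleosomes * nrl
    if dna_sequence is not None and len(dna_sequence) != total_bp:
        raise ModelBuildError(
            f"sequence length {len(dna_sequence)} != n_nucleosomes * nrl = {total_bp}"
        )

    templates = {}
    for w in set(wraps):
        t = build_ideal_nucleosome(
            wrap_bp=w,
            superhelix_radius=superhelix_radius,
            superhelix_pitch=superhelix_pitch,
            histones=histones,
            core_shell=core_shell,
        )
        templates[w] = (
            t,
            np.array([b.position for b in t.protein_beads]),
            np.array([f.position for f in t.dna_frames]),
            np.array([quat_to_matrix(f.orientation) for f in t.dna_frames]),
        )

    step_codes = _step_codes(dna_sequence, total_bp)

    beads: list[ResidueBead] = []
    frames: list[BasePairFrame] = []
    bonds_all: list[tuple[int, int]] = []
    gnms: list[GNMTopology] = []
    records: list[NucleosomeRecord] = []

    # current frame of the next bp to place (position, rotation matrix)
    cur_pos = np.zeros(3)
    cur_rot = np.eye(3)
    twist_mat = _twist_matrix(linker_twist)

    for k in range(n_nucleosomes):
        wrap_k = wraps[k]
        template, t_bead_pos, t_frame_pos, t_frame_rot = templates[wrap_k]
        # rigid placement mapping template frame 0 onto the current frame
        rot = cur_rot @ t_frame_rot[0].T
        trans = cur_pos - rot @ t_frame_pos[0]

        bead_offset = len(beads)
        placed_beads = (rot @ t_bead_pos.T).T + trans if len(t_bead_pos) else np.empty((0, 3))
        for b, pos in zip(template.protein_beads, placed_beads):
            beads.append(replace(b, position=np.array(pos)))
        bonds_all.extend(
            (int(a) + bead_offset, int(b) + bead_offset) for a, b in template.flexible_bonds
        )

        bp_offset = len(frames)
        for j in range(wrap_k):
            m = rot @ t_frame_rot[j]
            frames.append(
                BasePairFrame(
                    index=bp_offset + j,
                    position=rot @ t_frame_pos[j] + trans,
                    orientation=matrix_to_quat(m),
                    step_sequence=step_codes[bp_offset + j],
                )
            )
        for g in template.gnm:
            remapped = _remap_template_sites(np.array(g.pairs), template.n_protein, bead_offset)
            gnms.append(
                GNMTopology(remapped, np.array(g.rest_lengths), g.spring_constant, g.cutoff)
            )
        records.append(
            NucleosomeRecord(
                histone_range=(bead_offset, len(beads)),
                dna_span=(bp_offset, bp_offset + wrap_k),
                dyad_bp=bp_offset + wrap_k // 2,
                breathing=True,
            )
        )

        # advance the running frame: end of this wrap, then the linker
        cur_rot = rot @ t_frame_rot[-1]
        cur_pos = rot @ t_frame_pos[-1] + trans
        n_linker = (nrl - wrap_k) if k < n_nucleosomes - 1 else 0
        for j in range(n_linker):
            cur_pos = cur_pos + cur_rot[:, 2] * linker_rise
            cur_rot = cur_rot @ twist_mat
            idx = len(frames)
            frames.append(
                BasePairFrame(
                    index=idx,
                    position=np.array(cur_pos),
                    orientation=matrix_to_quat(cur_rot),
                    step_sequence=step_codes[idx],
                )
            )
        # step from the last placed bp to where the next bp will go
        cur_pos = cur_pos + cur_rot[:, 2] * linker_rise
        cur_rot = cur_rot @ twist_mat

    system = ChromatinSystem(
        protein_beads=beads,
        dna_frames=frames,
        flexible_bonds=np.asarray(bonds_all, dtype=int).reshape(-1, 2),
        gnm=gnms,
        nucleosome_records=records,
    )
    return system


def _remap_template_sites(pairs: np.ndarray, template_n_protein: int, bead_offset: int) -> np.ndarray:
    """Remap template-local site indices into array-global site indices.

    Works on protein-bead indices only at build time (the template GNM is
    core-only); DNA sites are remapped by `apply_non_breathing` later.
    """
    if len(pairs) == 0:
        return pairs
    if np.any(pairs >= template_n_protein):
        raise ModelBuildError("template GNM unexpectedly references DNA sites")
    return pairs + bead_offset


def _twist_matrix(twist_deg: float) -> np.ndarray:
    phi = math.radians(twist_deg)
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def apply_non_breathing(system: ChromatinSystem, cutoff: float = GNM_CUTOFF, k: float = GNM_SPRING_CONSTANT) -> ChromatinSystem:
    """Tie nucleosomal DNA into each core's elastic network.

    Per nucleosome, the core network is rebuilt over the globular beads plus
    every DNA site (bp centres and phosphates) of the wrapped span, with the
    same cutoff and spring constant; intra-body and consecutive-body DNA
    pairs are dropped (those degrees of freedom are already rigid/bonded).
    The result is a strict superset of the core-only network, idempotent on
    unchanged coordinates, and flags every nucleosome non-breathing.
    """
    if not any(rec.breathing for rec in system.nucleosome_records):
        raise ModelBuildError("no breathing nucleosome to constrain")
    out = system.copy()
    positions = out.site_positions()
    new_gnms = []
    for rec, core_gnm in zip(out.nucleosome_records, out.gnm):
        glob_sites = [
            i
            for i in range(*rec.histone_range)
            if out.protein_beads[i].region == "globular"
        ]
        dna_sites = []
        for j in range(*rec.dna_span):
            base = out.n_protein + 3 * j
            dna_sites.extend([base, base + 1, base + 2])
        sites = np.asarray(glob_sites + dna_sites, dtype=int)
        gnm = build_gnm(positions[sites], cutoff=cutoff, k=k, site_indices=sites)
        keep = _filter_rigid_pairs(gnm.pairs, out.n_protein)
        new_gnms.append(
            GNMTopology(gnm.pairs[keep], gnm.rest_lengths[keep], k, cutoff)
        )
        rec.breathing = False
    out.gnm = new_gnms
    return out


def _filter_rigid_pairs(pairs: np.ndarray, n_protein: int) -> np.ndarray:
    """Mask dropping DNA-DNA spring pairs within one body or between bonded bodies."""
    if len(pairs) == 0:
        return np.zeros(0, dtype=bool)
    body = np.where(pairs >= n_protein, (pairs - n_protein) // 3, -1)
    both_dna = np.all(pairs >= n_protein, axis=1)
    near = np.abs(body[:, 0] - body[:, 1]) <= 1
    return ~(both_dna & near)
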