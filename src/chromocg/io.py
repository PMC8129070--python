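"""File formats: topology text files, reference PDB ingestion, FASTA,
trajectory containers (HDF5 + extended-XYZ export), run configs, manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chromocg import __version__
from chromocg.model_build import (BasePairFrame, ChromatinSystem, GNMTopology,
                                  NucleosomeRecord, ResidueBead)

__all__ = [
    "RunConfig",
    "write_topology",
    "read_topology",
    "read_fasta",
    "read_reference_pdb",
    "write_reference_pdb",
    "write_trajectory",
    "read_trajectory",
    "export_extended_xyz",
    "write_manifest",
]


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Single structured config driving the CLI pipelines."""

    model_level: str = "chemically_specific"   # or "minimal"
    n_nucleosomes: int = 1
    nrl: int = 165
    wrap_bp: int = 147
    salt: float = 0.15                          # mol/L
    debye_lengths: list = field(default_factory=lambda: [8.0, 15.0])
    n_replicas: int = 16
    n_steps: int = 1000
    steps_per_sweep: int = 100
    dt_fs: float = 10.0
    friction: float = 0.5
    temperature: float = 300.0
    seed: int = 1
    mini_fixture: bool = False
    output_dir: str = "runs"
    analyses: list = field(default_factory=lambda: ["unwrapped_bp", "valency"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path):
        Path(path).write_text(self.to_yaml())


# ---------------------------------------------------------------------------
# topology text format
# ---------------------------------------------------------------------------

def write_topology(system: ChromatinSystem, path):
    """Sectioned tab-separated topology file (documented, versioned)."""
    lines = ["# chromocg topology v1"]
    lines.append("[beads]")
    lines.append("# chain residue_index amino_acid x y z charge diameter region mass")
    for b in system.protein_beads:
        x, y, z = b.position
        lines.append(
            f"{b.chain_id}\t{b.residue_index}\t{b.amino_acid}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
            f"\t{b.charge:g}\t{b.diameter:g}\t{b.region}\t{b.mass:g}"
        )
    lines.append("[dna]")
    lines.append("# index x y z qw qx qy qz step phosphate_charge")
    for f in system.dna_frames:
        x, y, z = f.position
        qw, qx, qy, qz = f.orientation
        lines.append(
            f"{f.index}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{qw:.9f}\t{qx:.9f}\t{qy:.9f}\t{qz:.9f}"
            f"\t{f.step_sequence}\t{f.phosphate_charge:g}"
        )
    lines.append("[bonds]")
    for a, b in np.asarray(system.flexible_bonds).reshape(-1, 2):
        lines.append(f"{a}\t{b}")
    lines.append("[gnm]")
    lines.append("# network_id site_a site_b rest_length spring_constant cutoff")
    for g_id, g in enumerate(system.gnm):
        for (a, b), r0 in zip(g.pairs, g.rest_lengths):
            lines.append(f"{g_id}\t{a}\t{b}\t{r0:.6f}\t{g.spring_constant:g}\t{g.cutoff:g}")
    lines.append("[nucleosomes]")
    lines.append("# histone_start histone_stop dna_start dna_stop dyad breathing")
    for r in system.nucleosome_records:
        lines.append(
            f"{r.histone_range[0]}\t{r.histone_range[1]}\t{r.dna_span[0]}\t{r.dna_span[1]}"
            f"\t{r.dyad_bp}\t{int(r.breathing)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> ChromatinSystem:
    section = None
    beads, frames, bonds = [], [], []
    gnm_rows: dict[int, list] = {}
    records = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        parts = line.split("\t")
        if section == "beads":
            beads.append(
                ResidueBead(
                    chain_id=parts[0], residue_index=int(parts[1]), amino_acid=parts[2],
                    position=np.array([float(v) for v in parts[3:6]]),
                    charge=float(parts[6]), diameter=float(parts[7]),
                    region=parts[8], mass=float(parts[9]),
                )
            )
        elif section == "dna":
            frames.append(
                BasePairFrame(
                    index=int(parts[0]),
                    position=np.array([float(v) for v in parts[1:4]]),
                    orientation=np.array([float(v) for v in parts[4:8]]),
                    step_sequence=parts[8], phosphate_charge=float(parts[9]),
                )
            )
        elif section == "bonds":
            bonds.append((int(parts[0]), int(parts[1])))
        elif section == "gnm":
            gnm_rows.setdefault(int(parts[0]), []).append(
                (int(parts[1]), int(parts[2]), float(parts[3]), float(parts[4]), float(parts[5]))
            )
        elif section == "nucleosomes":
            records.append(
                NucleosomeRecord(
                    histone_range=(int(parts[0]), int(parts[1])),
                    dna_span=(int(parts[2]), int(parts[3])),
                    dyad_bp=int(parts[4]), breathing=bool(int(parts[5])),
                )
            )
    gnms = []
    for g_id in sorted(gnm_rows):
        rows = gnm_rows[g_id]
        gnms.append(
            GNMTopology(
                pairs=np.array([(a, b) for a, b, *_ in rows], dtype=int),
                rest_lengths=np.array([r for _, _, r, _, _ in rows]),
                spring_constant=rows[0][3], cutoff=rows[0][4],
            )
        )
    return ChromatinSystem(
        protein_beads=beads, dna_frames=frames,
        flexible_bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        gnm=gnms, nucleosome_records=records,
    )


# ---------------------------------------------------------------------------
# sequences / structures
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_NUC_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}


def read_reference_pdb(path, expected_sequences: dict[str, str] | None = None):
    """C-alpha and phosphate reference coordinates from a PDB file.

    Returns ``(protein, dna)``: ``protein`` maps chain id to a list of
    ``(residue_name_1letter, position)`` in chain order; ``dna`` maps chain
    id to phosphate positions.  Optionally validates residue identities
    against expected one-letter sequences.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    from Bio.SeqUtils import seq1

    try:
        structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        raise IOError_(f"cannot parse PDB file {path}: {exc}") from exc
    if structure.array_length() == 0:
        raise IOError_(f"empty PDB file: {path}")
    protein: dict[str, list] = {}
    dna: dict[str, list] = {}
    for chain_id in np.unique(structure.chain_id):
        chain = structure[structure.chain_id == chain_id]
        is_nuc = np.isin(chain.res_name, list(_NUC_RESNAMES))
        if is_nuc.any():
            p = chain[(chain.atom_name == "P")]
            dna[str(chain_id)] = [np.array(c) for c in p.coord]
        else:
            res_ids = np.unique(chain.res_id)
            entries = []
            missing = []
            for rid in res_ids:
                res = chain[chain.res_id == rid]
                ca = res[res.atom_name == "CA"]
                if ca.array_length() == 0:
                    missing.append(int(rid))
                    continue
                entries.append((seq1(str(res.res_name[0])), np.array(ca.coord[0])))
            if missing:
                raise IOError_(
                    f"chain {chain_id}: missing CA records for residues {missing}"
                )
            protein[str(chain_id)] = entries
    if expected_sequences:
        for cid, seq in expected_sequences.items():
            if cid not in protein:
                raise IOError_(f"expected protein chain {cid} not found")
            got = "".join(aa for aa, _ in protein[cid])
            if got != seq:
                raise IOError_(f"chain {cid}: sequence mismatch ({got[:10]}... vs {seq[:10]}...)")
    return protein, dna


def write_reference_pdb(system: ChromatinSystem, path):
    """Minimal PDB export: protein beads as CA atoms, phosphates as P."""
    lines = []
    serial = 1
    chain_letters = {}
    next_letter = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    aa3 = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    for b in system.protein_beads:
        if b.chain_id not in chain_letters:
            chain_letters[b.chain_id] = next(next_letter)
        ch = chain_letters[b.chain_id]
        x, y, z = b.position
        lines.append(
            f"ATOM  {serial:5d}  CA  {aa3[b.amino_acid]:>3s} {ch}{b.residue_index + 1:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    dna_chain = next(next_letter, "Z")
    for f in system.dna_frames:
        for px, py, pz in f.phosphate_positions():
            lines.append(
                f"ATOM  {serial:5d}  P    DA {dna_chain}{f.index + 1:4d}"
                f"    {px:8.3f}{py:8.3f}{pz:8.3f}  1.00  0.00           P"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(path, frames: list, metadata: dict | None = None):
    """Chunked HDF5 container: per-frame protein positions, body positions
    and quaternions, plus optional metadata attributes."""
    import h5py

    with h5py.File(path, "w") as h5:
        n = len(frames)
        if n:
            prot0, bpos0, bq0 = frames[0][:3]
            h5.create_dataset("protein", data=np.array([f[0] for f in frames]),
                              chunks=(1, *np.shape(prot0)) if np.size(prot0) else None)
            h5.create_dataset("body_pos", data=np.array([f[1] for f in frames]))
            h5.create_dataset("body_quat", data=np.array([f[2] for f in frames]))
        for k, v in (metadata or {}).items():
            h5.attrs[k] = v


def read_trajectory(path):
    import h5py

    with h5py.File(path, "r") as h5:
        prot = h5["protein"][...] if "protein" in h5 else np.empty((0, 0, 3))
        bpos = h5["body_pos"][...] if "body_pos" in h5 else np.empty((0, 0, 3))
        bq = h5["body_quat"][...] if "body_quat" in h5 else np.empty((0, 0, 4))
        meta = dict(h5.attrs)
    return prot, bpos, bq, meta


def export_extended_xyz(path, system: ChromatinSystem, frames: list):
    """Extended-XYZ text export of site positions for visualisation."""
    species = system.site_species()
    with open(path, "w") as fh:
        for prot, bpos, bquat, *_ in frames:
            pos = _site_positions(system, prot, bpos, bquat)
            fh.write(f"{len(pos)}\n")
            fh.write('Properties=species:S:1:pos:R:3\n')
            for s, (x, y, z) in zip(species, pos):
                fh.write(f"{s}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")


def _site_positions(system, prot, bpos, bquat):
    from chromocg.geometry import quat_rotate_vec

    n = system.n_sites
    out = np.empty((n, 3))
    out[: system.n_protein] = prot
    offs = np.array([f.phosphate_offsets for f in system.dna_frames])
    if len(offs):
        out[system.n_protein + 0 :: 3] = bpos
        out[system.n_protein + 1 :: 3] = bpos + quat_rotate_vec(bquat, offs[:, 0])
        out[system.n_protein + 2 :: 3] = bpos + quat_rotate_vec(bquat, offs[:, 1])
    return out


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, inputs: dict, seed: int | None = None, extra: dict | None = None):
    """Manifest with input hashes, seed and code version, enough to re-run."""
    digest = {}
    for name, value in inputs.items():
        src = None
        if isinstance(value, (str, Path)):
            try:
                candidate = Path(value)
                if candidate.is_file():
                    src = candidate
            except (OSError, ValueError):
                src = None
        if src is not None:
            digest[name] = hashlib.sha256(src.read_bytes()).hexdigest()[:16]
        else:
            digest[name] = hashlib.sha256(repr(value).encode()).hexdigest()[:16]
    manifest = {"version": __version__, "seed": seed, "inputs": digest}
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
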