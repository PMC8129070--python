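import numpy as np
import pytest

from chromocg import energetics as en
from chromocg import model_build as mb


@pytest.fixture(scope="session")
def full_nucleosome():
    """Canonical 147-bp idealized nucleosome with the packaged octamer."""
    return mb.build_ideal_nucleosome()


@pytest.fixture(scope="session")
def mini_nucleosome():
    """Miniature synthetic fixture (~150 sites) for dynamics tests."""
    return mb.build_mini_nucleosome()


@pytest.fixture(scope="session")
def mini_model(mini_nucleosome):
    return en.EnergyModel(mini_nucleosome, en.DebyeHuckelParams(debye_length=8.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dilute_system(rng, n_protein=30, n_bp=6, spread=80.0):
    """Random, hard-overlap-free system for brute-force energy oracles.

    Hard overlaps make the Lennard-Jones-type terms so large that float64
    cannot resolve a 1e-9 kcal/mol comparison, so protein beads keep >= 4 A
    between themselves, DNA body centres >= 25 A between themselves (their
    phosphate sites reach 9.4 A out of the centre) and >= 16 A to any
    protein bead."""
    # placement radii: protein-protein, dna-dna, protein-dna
    pp, dd, pd = 4.0, 25.0, 16.0
    prot_pos = np.empty((n_protein, 3))
    dna_pos = np.empty((n_bp, 3))

    def ok(p, placed, min_d):
        return len(placed) == 0 or np.linalg.norm(np.asarray(placed) - p, axis=1).min() >= min_d

    placed_p, placed_d = [], []
    for _ in range(n_protein):
        for _ in range(2000):
            p = rng.uniform(-spread, spread, 3)
            if ok(p, placed_p, pp):
                placed_p.append(p)
                break
        else:
            raise RuntimeError("could not place protein beads without overlap")
    for _ in range(n_bp):
        for _ in range(2000):
            p = rng.uniform(-spread, spread, 3)
            if ok(p, placed_d, dd) and ok(p, placed_p, pd):
                placed_d.append(p)
                break
        else:
            raise RuntimeError("could not place DNA bodies without overlap")
    prot_pos[:] = placed_p
    if n_bp:
        dna_pos[:] = placed_d

    table = mb.residue_table()
    codes = list(table.index)
    beads = []
    for i in range(n_protein):
        aa = codes[int(rng.integers(len(codes)))]
        row = table.loc[aa]
        beads.append(
            mb.ResidueBead(
                chain_id="X", residue_index=i, amino_acid=aa,
                position=prot_pos[i],
                charge=float(row["charge"]), diameter=float(row["diameter"]),
                region="tail", mass=float(row["mass"]),
            )
        )
    frames = []
    for j in range(n_bp):
        q = rng.normal(size=4)
        frames.append(
            mb.BasePairFrame(
                index=j, position=dna_pos[j],
                orientation=q / np.linalg.norm(q),
            )
        )
    bonds = np.array([[i, i + 1] for i in range(0, n_protein - 1, 7)], dtype=int)
    return mb.ChromatinSystem(protein_beads=beads, dna_frames=frames, flexible_bonds=bonds)
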