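import numpy as np
import pytest

from stabscore import (
    Atom,
    Residue,
    SequenceRecord,
    StructureRecord,
    generate_helix_structure,
)


@pytest.fixture
def helix():
    return generate_helix_structure(12, sequence="MKVLINSGAEDK")


@pytest.fixture
def random_structure_factory():
    """Structures with random side-chain atoms in a compact box, for oracles."""

    def make(seed: int, n_res: int = 12, max_sc_atoms: int = 3) -> StructureRecord:
        rng = np.random.default_rng(seed)
        letters = "ADEFHIKLMNPQRSTVWY"  # gly excluded: every residue has a side chain
        residues = []
        for i in range(n_res):
            base = rng.uniform(0, 15, size=3)
            atoms = [
                Atom("N", "N", base + rng.normal(0, 0.5, 3)),
                Atom("CA", "C", base),
                Atom("C", "C", base + rng.normal(0, 0.5, 3)),
            ]
            for k in range(rng.integers(1, max_sc_atoms + 1)):
                name = "CB" if k == 0 else f"CG{k}"
                atoms.append(Atom(name, "C", base + rng.normal(0, 1.5, 3)))
            residues.append(
                Residue(residue_index=i + 1, aa=rng.choice(list(letters)), atoms=atoms)
            )
        return StructureRecord(id=f"rand{seed}", residues=residues)

    return make


@pytest.fixture
def seq_factory():
    def make(sid: str, length: int, seed: int = 0) -> SequenceRecord:
        rng = np.random.default_rng(seed)
        from stabscore import AA_ALPHABET

        return SequenceRecord(sid, "".join(rng.choice(list(AA_ALPHABET), size=length)))

    return make
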