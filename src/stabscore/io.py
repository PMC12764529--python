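"""Core record types and readers/writers for FASTA, PDB and tabular score files.

Sequences are designed mini-proteins tagged with the backbone ("fold") they
were designed for and the generative model that produced them.  Structures are
single protein chains with per-residue heavy-atom coordinates.  Score tables
join sequences with stability measurements (ΔG_unfold, kcal/mol; higher = more
stable) and computed metrics.

Residue indices are 1-based as in PDB files; every pairwise matrix produced
elsewhere in the package is 0-based over the residue order of the record, with
``StructureRecord.residue_index`` providing the mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20, alphabetical 1-letter
MODEL_TAGS = ("TrROS", "TrMRF", "ProteinMPNN", "Joint", "other")

AA_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


class StabscoreError(Exception):
    """Base class for domain errors (CLI maps these to exit code 1)."""


class ParseError(StabscoreError):
    pass


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One designed sequence with its fold identifier and generating model."""

    id: str
    sequence: str
    fold_id: str | None = None
    model_tag: str = "other"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().rstrip("*")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains non-canonical letters {sorted(bad)}"
            )
        if self.model_tag not in MODEL_TAGS:
            self.model_tag = "other"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def check_no_cysteine(self) -> None:
        """Designed sets exclude cysteine to avoid disulfide formation."""
        if "C" in self.sequence:
            raise StabscoreError(f"sequence {self.id!r} contains cysteine")

    def indices(self, alphabet: str = AA_ALPHABET) -> np.ndarray:
        """0-based alphabet index per position."""
        lookup = {a: i for i, a in enumerate(alphabet)}
        try:
            return np.array([lookup[c] for c in self.sequence], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - guarded in __post_init__
            raise StabscoreError(f"letter {exc} not in alphabet") from exc


def _parse_header_fields(description: str) -> dict[str, str]:
    fields = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            fields[key] = value
    return fields


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``fold=`` and ``model=`` tokens in the header description are parsed into
    ``fold_id`` and ``model_tag``.  Order is preserved; sequences are
    upper-cased and trailing ``*`` terminators stripped.
    """
    path = Path(path)
    _check_fasta_wellformed(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header_fields(rec.description)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                fold_id=fields.get("fold"),
                model_tag=fields.get("model", "other"),
            )
        )
    return records


def _check_fasta_wellformed(path: Path) -> None:
    """Reject headers with no sequence line, naming the offending line."""
    last_header_line = None
    has_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if not has_seq:
                    raise ParseError(
                        f"{path}:{last_header_line}: header without sequence"
                    )
                last_header_line = lineno
                has_seq = False
            else:
                has_seq = True
    if last_header_line is not None and not has_seq:
        raise ParseError(f"{path}:{last_header_line}: header without sequence")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.fold_id is not None:
                header += f" fold={rec.fold_id}"
            if rec.model_tag != "other":
                header += f" model={rec.model_tag}"
            fh.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# Structure records
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    atom_name: str
    element: str
    xyz: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StabscoreError(f"atom {self.atom_name}: bad coordinates")


@dataclass
class Residue:
    residue_index: int  # 1-based, as in PDB
    aa: str  # 1-letter code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.xyz


@dataclass
class StructureRecord:
    """Single-chain protein structure: ordered residues with heavy atoms."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.residue_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StabscoreError("residue indices must be strictly increasing")
        for r in self.residues:
            names = {a.atom_name for a in r.atoms}
            if not {"N", "CA", "C"} <= names:
                raise StabscoreError(
                    f"residue {r.residue_index} lacks backbone atoms N/CA/C"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def cb_coords(self, virtual: bool = False) -> np.ndarray:
        """(L, 3) Cβ coordinates; Cα substitutes for glycine.

        With ``virtual=True`` an ideal-geometry Cβ is built from N/CA/C for
        every residue missing one.
        """
        coords = np.empty((len(self.residues), 3))
        for i, r in enumerate(self.residues):
            cb = r.coord("CB")
            if cb is None:
                if virtual:
                    cb = _virtual_cb(r.coord("N"), r.coord("CA"), r.coord("C"))
                else:
                    cb = r.coord("CA")
            coords[i] = cb
        return coords


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # ideal tetrahedral Cβ from backbone frame (standard 1.522 Å construction)
    b = ca - n
    c_vec = c - ca
    a = np.cross(b, c_vec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_vec + ca


def read_structure(
    path: str | Path,
    chain: str | None = None,
    skip_unknown: bool = False,
    allow_insertion_codes: bool = False,
) -> StructureRecord:
    """Read a single chain from a PDB file.

    Only ATOM records are kept; alternate locations are resolved to the
    highest-occupancy conformer; insertion codes are rejected by default.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=1, altloc="occupancy")
    array = array[~array.hetero]
    if array.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    if chain is None:
        chain = array.chain_id[0]
    array = array[array.chain_id == chain]
    if array.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records in chain {chain!r}")
    if not allow_insertion_codes and np.any(array.ins_code != ""):
        raise ParseError(f"{path}: insertion codes present; pass allow_insertion_codes")

    residues: list[Residue] = []
    for res_id in np.unique(array.res_id):
        sub = array[array.res_id == res_id]
        res_name = sub.res_name[0]
        aa = AA_3TO1.get(res_name.upper())
        if aa is None:
            if skip_unknown:
                logger.warning("skipping unknown residue %s %d", res_name, res_id)
                continue
            raise ParseError(f"{path}: unknown residue name {res_name!r}")
        atoms = [
            Atom(atom_name=sub.atom_name[k], element=sub.element[k], xyz=sub.coord[k])
            for k in range(sub.array_length())
        ]
        residues.append(Residue(residue_index=int(res_id), aa=aa, atoms=atoms))
    return StructureRecord(id=path.stem, residues=residues)


AA_1TO3 = {v: k.upper() for k, v in protein_letters_3to1.items()}


def write_structure(record: StructureRecord, path: str | Path) -> None:
    """Write a StructureRecord as a minimal single-chain PDB file."""
    n_atoms = sum(len(r.atoms) for r in record.residues)
    array = struc.AtomArray(n_atoms)
    k = 0
    for res in record.residues:
        for atom in res.atoms:
            array.chain_id[k] = "A"
            array.res_id[k] = res.residue_index
            array.res_name[k] = AA_1TO3[res.aa]
            array.atom_name[k] = atom.atom_name
            array.element[k] = atom.element
            array.coord[k] = atom.xyz
            array.hetero[k] = False
            k += 1
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

#: canonical metric column names used throughout the package
CANONICAL_COLUMNS = (
    "dG_unfold",
    "plddt_af2_3rec",
    "plddt_af2_maskedmsa",
    "plddt_esmfold_halfmask",
    "mpnn_cce",
    "mpnn_uce",
    "esm2_pll",
    "esmif_sl",
    "inter_pae",
    "fold_id",
    "model_tag",
)

#: best-guess mapping from commonly seen file headers to canonical names
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "deltaG": "dG_unfold",
    "dG": "dG_unfold",
    "dg": "dG_unfold",
    "dG_unfold": "dG_unfold",
    "deltaG_unfold": "dG_unfold",
    "stability": "dG_unfold",
    "plddt": "plddt_af2_3rec",
    "af2_plddt": "plddt_af2_3rec",
    "pae_interaction": "inter_pae",
    "inter_pae": "inter_pae",
    "fold": "fold_id",
    "fold_id": "fold_id",
    "model": "model_tag",
    "model_tag": "model_tag",
    "name": "id",
    "seq_id": "id",
}


@dataclass
class ScoreTable:
    """Tabular join of sequences × named metrics, keyed by ``id``.

    Thin wrapper around a pandas DataFrame: missing values stay NaN (never
    silently zero), column names are unique, and a declared key column is
    guaranteed present.
    """

    df: pd.DataFrame
    key: str = "id"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            dupes = self.df.columns[self.df.columns.duplicated()].tolist()
            raise StabscoreError(f"duplicate columns: {dupes}")
        if self.key not in self.df.columns:
            raise StabscoreError(
                f"key column {self.key!r} missing; available: {list(self.df.columns)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise StabscoreError(
                f"metric {name!r} not in table; available: {list(self.df.columns)}"
            )
        return self.df[name]

    def with_column(self, name: str, values) -> "ScoreTable":
        df = self.df.copy()
        df[name] = values
        return ScoreTable(df, key=self.key, metadata=dict(self.metadata))


def read_score_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    key: str = "id",
    dg_reducer: str = "mean",
) -> ScoreTable:
    """Load a CSV/TSV score table, renaming columns to canonical names.

    ``column_map`` maps file headers to canonical names and overrides the
    shipped default-guess map.  If two protease-specific stability columns
    (``dG_trypsin``/``dG_chymotrypsin``) are present and no consensus column
    is, a reducer (default arithmetic mean) builds ``dG_unfold`` and the
    choice is recorded in the table metadata.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    renames = {c: cmap[c] for c in df.columns if c in cmap and cmap[c] not in df.columns}
    df = df.rename(columns=renames)

    metadata: dict = {}
    if "dG_unfold" not in df.columns:
        protease_cols = [c for c in ("dG_trypsin", "dG_chymotrypsin") if c in df.columns]
        if len(protease_cols) == 2:
            if dg_reducer == "mean":
                df["dG_unfold"] = df[protease_cols].mean(axis=1)
            elif dg_reducer == "min":
                df["dG_unfold"] = df[protease_cols].min(axis=1)
            else:
                raise StabscoreError(f"unknown dG reducer {dg_reducer!r}")
            metadata["dG_consensus"] = dg_reducer

    if key not in df.columns:
        raise StabscoreError(
            f"key column {key!r} missing; available columns: {list(df.columns)}"
        )
    # drop rows with an unusable key rather than imputing
    bad = df[key].isna()
    if bad.any():
        logger.warning("dropping %d rows with missing key", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return ScoreTable(df, key=key, metadata=metadata)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.df.to_csv(path, sep=sep, index=False)
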