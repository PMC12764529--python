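"""Side-chain contact extraction and 20×20 pairwise log-odds potentials.

A residue pair (i, j) is *in contact* when some pair of side-chain heavy
atoms lies closer than a cutoff (default 5 Å) and the residues are separated
by more than ``min_separation`` positions in sequence (default 5, i.e.
j − i ≥ 6).  Side-chain heavy atoms are all non-hydrogen atoms beyond Cα
(Cβ included, OXT excluded); glycine has no side chain and cannot form a
contact under the strict rule unless ``gly_cb`` substitutes a (virtual) Cβ.

The pairwise potential over amino-acid types is the log-odds

    V(a, b) = ln [ P({a, b} | contact) / (P(a) · P(b)) ]

where P({a, b} | contact) is the probability of the *unordered* residue-type
pair among observed contacts and P(a) is a background composition.  Positive
values mark enriched interactions, negative values depleted ones.  Compared
across design models, enrichment of hydrophilic (charged/polar) pairs
distinguishes jointly optimized sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import AA_ALPHABET, StabscoreError, StructureRecord, _virtual_cb

__all__ = [
    "ContactPair",
    "PairwisePotential",
    "extract_contacts",
    "pairwise_potential",
    "contact_aa_frequencies",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ContactPair:
    """One residue-residue contact (i < j, 1-based residue indices)."""

    i: int
    j: int
    aa_i: str
    aa_j: str
    min_dist: float


def _side_chain_coords(residue, gly_cb: bool) -> np.ndarray:
    coords = [
        a.xyz
        for a in residue.atoms
        if a.atom_name not in BACKBONE_ATOMS and not a.element.upper().startswith("H")
    ]
    if not coords and residue.aa == "G" and gly_cb:
        cb = residue.coord("CB")
        if cb is None:
            cb = _virtual_cb(residue.coord("N"), residue.coord("CA"), residue.coord("C"))
        coords = [cb]
    if not coords:
        return np.empty((0, 3))
    return np.asarray(coords)


def extract_contacts(
    structure: StructureRecord,
    cutoff: float = 5.0,
    min_separation: int = 5,
    gly_cb: bool = False,
) -> list[ContactPair]:
    """All residue pairs whose closest side-chain heavy atoms are within
    ``cutoff`` Å at sequence separation > ``min_separation``.

    Separation is measured on the 1-based residue numbering; each qualifying
    pair is reported once with its minimal atom-atom distance.
    """
    import warnings

    residues = structure.residues
    side_chains = [_side_chain_coords(r, gly_cb) for r in residues]
    if all(len(c) == 0 for c in side_chains):
        warnings.warn(
            f"structure {structure.id!r} has no side-chain heavy atoms", stacklevel=2
        )
        return []
    contacts = []
    for a in range(len(residues)):
        if len(side_chains[a]) == 0:
            continue
        for b in range(a + 1, len(residues)):
            if residues[b].residue_index - residues[a].residue_index <= min_separation:
                continue
            if len(side_chains[b]) == 0:
                continue
            d = cdist(side_chains[a], side_chains[b]).min()
            if d < cutoff:
                contacts.append(
                    ContactPair(
                        i=residues[a].residue_index,
                        j=residues[b].residue_index,
                        aa_i=residues[a].aa,
                        aa_j=residues[b].aa,
                        min_dist=float(d),
                    )
                )
    return contacts


@dataclass
class PairwisePotential:
    """Symmetric 20×20 log-odds matrix with raw counts and background.

    ``pair_probs`` are probabilities of unordered amino-acid pairs (their sum
    over unordered pairs — upper triangle plus diagonal — is 1).  ``matrix``
    stores V(a,b) at both (a,b) and (b,a); cells with zero raw count are NaN
    in ``masked_matrix``.
    """

    matrix: np.ndarray  # (20, 20) log-odds, nats
    counts: np.ndarray  # (20, 20) symmetric integer counts
    background: np.ndarray  # (20,) P(a), sums to 1
    pair_probs: np.ndarray  # (20, 20) symmetric, unordered-pair normalized
    alphabet: str = AA_ALPHABET

    @property
    def masked_matrix(self) -> np.ndarray:
        out = self.matrix.copy()
        out[self.counts == 0] = np.nan
        return out


def _endpoint_counts(counts: np.ndarray) -> np.ndarray:
    """Per-residue-type participation counts from a symmetric pair-count matrix."""
    # each unordered {a,b} contact contributes one a and one b endpoint;
    # an (a,a) contact contributes two a endpoints
    return counts.sum(axis=1) + np.diag(counts)


def _count_matrix(contacts: Iterable[ContactPair]) -> np.ndarray:
    counts = np.zeros((20, 20), dtype=np.int64)
    n = 0
    for c in contacts:
        a, b = _AA_INDEX[c.aa_i], _AA_INDEX[c.aa_j]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
        n += 1
    if n == 0:
        raise StabscoreError("empty contact list")
    return counts


def pairwise_potential(
    contacts: Sequence[ContactPair],
    background: Literal["uniform", "contact_marginal"] | np.ndarray = "contact_marginal",
    alpha: float = 0.5,
) -> PairwisePotential:
    """Log-odds contact potential from pooled contacts over many structures.

    ``alpha`` is a pseudocount added to every unordered amino-acid pair
    (Jeffreys-style 0.5 by default) so no cell is −∞; zero-raw-count cells are
    additionally exposed as NaN through ``masked_matrix``.  The background
    P(a) defaults to the contact-participant marginal; ``"uniform"`` or a
    supplied 20-vector are alternatives.
    """
    if alpha < 0:
        raise StabscoreError("pseudocount must be >= 0")
    counts = _count_matrix(contacts)

    # unordered-pair probabilities with pseudocounts
    upper = np.triu(counts).astype(float)  # one entry per unordered pair
    upper[np.triu_indices(20)] += alpha
    total = upper.sum()
    probs_upper = upper / total
    pair_probs = probs_upper + np.triu(probs_upper, 1).T  # mirror to symmetric

    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(20, 1 / 20)
        elif background == "contact_marginal":
            endpoint = _endpoint_counts(counts).astype(float)
            bg = endpoint / endpoint.sum()
        else:
            raise StabscoreError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise StabscoreError("supplied background must be a 20-vector summing to 1")

    with np.errstate(divide="ignore", invalid="ignore"):
        matrix = np.log(pair_probs) - np.log(np.outer(bg, bg))
    matrix[~np.isfinite(matrix)] = np.nan
    return PairwisePotential(
        matrix=matrix, counts=counts, background=bg, pair_probs=pair_probs
    )


def contact_aa_frequencies(contacts: Sequence[ContactPair]) -> np.ndarray:
    """P(a in contact): endpoint frequency over all counted pairs (sums to 1).

    Each contact contributes both endpoints, so a single (K, E) contact gives
    P(K) = P(E) = 0.5.
    """
    counts = _count_matrix(contacts)
    endpoint = _endpoint_counts(counts).astype(float)
    return endpoint / endpoint.sum()
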