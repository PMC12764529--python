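"""Zero-shot stability score formulas on plain numeric inputs.

The scores here quantify, without any supervised stability training, how
plausible a designed sequence/structure pair looks to a generative protein
model:

* **pseudo-likelihood** — mean log-probability a masked language model assigns
  to each true residue given all others (per-residue, nats);
* **distogram cross-entropy** — cross-entropy between a structure-prediction
  model's binned Cβ–Cβ distance distribution and the digitized true structure;
* **sequence cross-entropy** — cross-entropy between a sequence (one-hot) and
  inverse-folding logits; the same formula serves conditional (CCE) and
  unconditional (UCE) logits, the caller chooses which logits to pass;
* **summed likelihood** — sum over positions of the softmax probability of the
  native residue (an absolute-stability proxy in [0, L]);
* **aggregated pLDDT** — mean structure-prediction confidence over replicate
  predictions under input-masking protocols.

No neural network lives in this module: logits arrive as plain arrays or
through the :mod:`stabscore.backends` contract.  Natural logarithms
throughout; every entropy is in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import log_softmax, softmax

from .io import AA_ALPHABET, SequenceRecord, StabscoreError, StructureRecord

__all__ = [
    "PositionLogits",
    "DistogramSpec",
    "DistogramLogits",
    "DigitizedDistances",
    "pseudo_likelihood",
    "digitize_distances",
    "distogram_cross_entropy",
    "sequence_cross_entropy",
    "summed_likelihood",
    "aggregate_plddt",
]


@dataclass
class PositionLogits:
    """L×A matrix of logits or log-probabilities over an amino-acid alphabet."""

    values: np.ndarray
    alphabet: str = AA_ALPHABET
    kind: Literal["logits", "log_probs"] = "logits"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.alphabet):
            raise StabscoreError(
                f"logits shape {self.values.shape} inconsistent with "
                f"alphabet of size {len(self.alphabet)}"
            )
        if self.kind == "log_probs":
            row_sums = np.exp(self.values).sum(axis=1)
            if not np.allclose(row_sums, 1.0, atol=1e-6):
                raise StabscoreError("log_probs rows do not normalize to 1")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def log_probs(self) -> np.ndarray:
        """Row-normalized log-probabilities (log-softmax applied if needed)."""
        if self.kind == "log_probs":
            return self.values
        return log_softmax(self.values, axis=1)


@dataclass
class DistogramSpec:
    """Uniform distance binning: edges ``b[0]..b[M]`` (Å), width ``h``."""

    b: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim != 1 or len(self.b) < 2:
            raise StabscoreError("need at least two bin edges")
        if np.any(np.diff(self.b) <= 0):
            raise StabscoreError("bin edges must be strictly increasing")
        m_implied = (self.b[-1] - self.b[0]) / self.h
        if abs(m_implied - self.M) > 1e-9:
            raise StabscoreError(
                f"edge span / width gives {m_implied} bins, edges imply {self.M}"
            )

    @property
    def M(self) -> int:
        return len(self.b) - 1

    @classmethod
    def uniform(cls, b_min: float = 2.0, b_max: float = 22.0, h: float = 0.5) -> "DistogramSpec":
        n = round((b_max - b_min) / h)
        return cls(b=np.linspace(b_min, b_max, n + 1), h=h)


@dataclass
class DistogramLogits:
    """L×L×M structural-bin logits from a structure-prediction model."""

    values: np.ndarray
    spec: DistogramSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != self.spec.M:
            raise StabscoreError(
                f"distogram shape {self.values.shape} inconsistent with M={self.spec.M}"
            )
        if self.values.shape[0] != self.values.shape[1]:
            raise StabscoreError("distogram must be square over residue pairs")
        if not np.all(np.isfinite(self.values)):
            raise StabscoreError("distogram logits must be finite")


@dataclass
class DigitizedDistances:
    """One-hot binned true distances F_ijk plus an out-of-range pair mask."""

    F: np.ndarray  # (L, L, M) one-hot over bins for in-range pairs
    out_of_range_mask: np.ndarray  # (L, L) bool, True where no bin applies

    def __post_init__(self) -> None:
        sums = self.F.sum(axis=2)
        if not np.array_equal(sums[~self.out_of_range_mask], np.ones((~self.out_of_range_mask).sum())):
            raise StabscoreError("in-range pairs must be exactly one-hot over bins")
        if np.any(sums[self.out_of_range_mask] != 0):
            raise StabscoreError("out-of-range pairs must have all-zero bins")


def pseudo_likelihood(masked_log_probs: PositionLogits, seq: SequenceRecord) -> float:
    """Mean masked log-probability of the true residues, (1/L)·Σ log P(s_i|S_\\i).

    Row *i* of ``masked_log_probs`` must be the model's distribution at
    position *i* computed with position *i* masked.  Returns nats.
    """
    if masked_log_probs.kind != "log_probs":
        raise StabscoreError("pseudo_likelihood requires kind='log_probs'")
    if masked_log_probs.L != seq.length:
        raise StabscoreError(
            f"length mismatch: logits L={masked_log_probs.L}, sequence L={seq.length}"
        )
    idx = seq.indices(masked_log_probs.alphabet)
    return float(masked_log_probs.values[np.arange(seq.length), idx].mean())


def _distance_matrix(structure: StructureRecord, atom_rule: str) -> np.ndarray:
    if atom_rule == "cb":
        coords = structure.cb_coords(virtual=False)
    elif atom_rule == "virtual_cb":
        coords = structure.cb_coords(virtual=True)
    elif atom_rule == "ca":
        coords = np.array([r.coord("CA") for r in structure.residues])
    else:
        raise StabscoreError(f"unknown atom rule {atom_rule!r}")
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def digitize_distances(
    structure,
    spec: DistogramSpec,
    atom_rule: str = "cb",
    include_diagonal: bool = False,
    clamp: bool = False,
) -> DigitizedDistances:
    """Digitize true pairwise distances into one-hot bins F_ijk.

    Bins are half-open ``[b_{k-1}, b_k)``.  Accepts a :class:`StructureRecord`
    (Cβ distances, Cα for glycine) or a ready L×L distance matrix.  By default
    the i==j diagonal is mapped to out-of-range (d_ii carries no structural
    information); ``include_diagonal=True`` digitizes it literally.
    Out-of-range distances are excluded via the mask unless ``clamp=True``,
    which assigns them to the nearest edge bin.
    """
    if isinstance(structure, StructureRecord):
        d = _distance_matrix(structure, atom_rule)
    else:
        d = np.asarray(structure, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise StabscoreError("distance matrix must be square")
    L, M = d.shape[0], spec.M

    bin_idx = np.searchsorted(spec.b, d, side="right") - 1
    in_range = (d >= spec.b[0]) & (d < spec.b[-1])
    if clamp:
        bin_idx = np.clip(bin_idx, 0, M - 1)
        in_range = np.ones_like(in_range)
    if not include_diagonal:
        np.fill_diagonal(in_range, False)

    F = np.zeros((L, L, M))
    ii, jj = np.nonzero(in_range)
    F[ii, jj, bin_idx[ii, jj]] = 1.0
    return DigitizedDistances(F=F, out_of_range_mask=~in_range)


def distogram_cross_entropy(F: DigitizedDistances, g: DistogramLogits) -> float:
    """H(F, g) = Σ_ij Σ_k −F_ijk · LogSoftmax(g_ijk), softmax over the bin axis.

    Pairs masked out-of-range contribute 0.  Always ≥ 0 (nats).
    """
    if F.F.shape != g.values.shape:
        raise StabscoreError(
            f"shape mismatch: F {F.F.shape} vs distogram {g.values.shape}"
        )
    log_probs = log_softmax(g.values, axis=2)
    return float(-(F.F * log_probs).sum())


def sequence_cross_entropy(
    seq: SequenceRecord, logits: PositionLogits
) -> dict[str, float]:
    """Cross-entropy between a one-hot sequence and per-position logits.

    H(X, f(X)) = Σ_l Σ_a −X_la · log f(X)_la.  Pass conditional inverse-folding
    logits for CCE, unconditional ones for UCE.  Returns ``{"total", "per_residue"}``
    in nats with ``total == per_residue · L``.
    """
    if logits.L != seq.length:
        raise StabscoreError(
            f"length mismatch: logits L={logits.L}, sequence L={seq.length}"
        )
    lp = logits.log_probs()
    idx = seq.indices(logits.alphabet)
    total = float(-lp[np.arange(seq.length), idx].sum())
    return {"total": total, "per_residue": total / seq.length}


def summed_likelihood(logits: PositionLogits, seq: SequenceRecord) -> float:
    """Σ_i softmax(logits_i)[s_i] — summed native-residue probability in [0, L]."""
    if logits.L != seq.length:
        raise StabscoreError(
            f"length mismatch: logits L={logits.L}, sequence L={seq.length}"
        )
    probs = np.exp(logits.log_probs())
    idx = seq.indices(logits.alphabet)
    return float(probs[np.arange(seq.length), idx].sum())


def plddt_mask_stream(seed: int, rep: int, L: int, n_hidden: int) -> np.ndarray:
    """Visible-position mask for replicate ``rep`` from a named counter stream.

    Bit-reproducible given (seed, rep, L): each replicate gets its own child
    generator, and exactly ``n_hidden`` positions are hidden without
    replacement.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, rep, L, 0x6D61736B]))
    hidden = rng.choice(L, size=n_hidden, replace=False)
    visible = np.ones(L, dtype=bool)
    visible[hidden] = False
    return visible


def aggregate_plddt(
    backend,
    seq: SequenceRecord,
    protocol: Literal["half_mask", "masked_msa", "plain"] = "half_mask",
    n_reps: int = 8,
    mask_frac: float = 0.5,
    recycles: int = 3,
    seed: int = 0,
) -> float:
    """Mean pLDDT over replicate predictions under a masking protocol (0–100).

    Protocols:

    * ``half_mask`` — each replicate hides ``⌊mask_frac·L⌋`` randomly chosen
      sequence positions (default 8 replicates at 50% masking);
    * ``masked_msa`` — the MSA input is fully masked and replicates differ
      only by seed (default 8 replicates);
    * ``plain`` — no masking, replicates differ by seed.

    The arithmetic mean of the per-replicate scalar pLDDT values is returned.
    """
    if n_reps < 1:
        raise StabscoreError("n_reps must be >= 1")
    L = seq.length
    values = np.empty(n_reps)
    for rep in range(n_reps):
        if protocol == "half_mask":
            visible = plddt_mask_stream(seed, rep, L, int(mask_frac * L))
            values[rep] = backend.predict_plddt(
                seq, visible_mask=visible, recycles=recycles, seed=seed + rep
            )
        elif protocol == "masked_msa":
            values[rep] = backend.predict_plddt(
                seq, msa_masked=True, recycles=recycles, seed=seed + rep
            )
        elif protocol == "plain":
            values[rep] = backend.predict_plddt(
                seq, recycles=recycles, seed=seed + rep
            )
        else:
            raise StabscoreError(f"unknown protocol {protocol!r}")
    return float(values.mean())
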