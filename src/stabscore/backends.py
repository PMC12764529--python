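"""Backend contract separating score math from neural models.

Real structure/sequence models (AlphaFold2, ESMFold, ESM-2, ProteinMPNN,
ESM-IF) are reached only through the :class:`ScoreBackend` contract; the
library itself never imports them.  :class:`MockBackend` is a deterministic
stand-in whose outputs rank-correlate with a configurable latent stability,
so the whole scoring/evaluation pipeline can be exercised and tested offline.

Determinism contract: identical inputs plus seed give identical outputs.  The
mock derives every random draw from a hash of (sequence id, visible mask,
seed), never from global random state, so results are reproducible across
platforms and call orders.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from scipy.special import log_softmax

from .io import AA_ALPHABET, SequenceRecord, StabscoreError
from .scores import PositionLogits

CAPABILITIES = frozenset(
    {
        "plddt",
        "masked_log_probs",
        "sequence_logits_conditional",
        "sequence_logits_unconditional",
        "distogram",
        "inter_pae",
    }
)


@runtime_checkable
class ScoreBackend(Protocol):
    """What a model adapter must provide to drive the scoring layer."""

    capabilities: frozenset[str]
    max_len: int

    def predict_plddt(
        self,
        seq: SequenceRecord,
        visible_mask: np.ndarray | None = None,
        msa_masked: bool = False,
        recycles: int = 3,
        seed: int = 0,
    ) -> float: ...

    def masked_log_probs(self, seq: SequenceRecord, seed: int = 0) -> PositionLogits: ...


def _hash_stream(*parts) -> np.random.Generator:
    """Generator keyed by a SHA-256 hash of the given parts (no global state)."""
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, np.ndarray):
            h.update(part.tobytes())
        else:
            h.update(repr(part).encode())
        h.update(b"\x1f")
    digest = int.from_bytes(h.digest()[:8], "little")
    return np.random.default_rng(digest)


@dataclass
class MockBackend:
    """Deterministic surrogate backend with an optional latent-stability link.

    If ``latent_stability`` maps a sequence id to a real latent value, mock
    pLDDT is ``clip(50 + 8·latent + noise, 0, 100)`` and the masked
    log-probability of the true residue is tilted upward with the latent, so
    pLDDT and pseudo-likelihood both rank-correlate with the latent — the
    structure the evaluation pipeline assumes of real models.
    """

    seed: int = 0
    latent_stability: Mapping[str, float] | None = None
    noise_sd: float = 2.0
    capabilities: frozenset[str] = field(
        default=frozenset({"plddt", "masked_log_probs"})
    )
    max_len: int = 1024

    def _latent(self, seq: SequenceRecord) -> float:
        if self.latent_stability is not None and seq.id in self.latent_stability:
            return float(self.latent_stability[seq.id])
        return 0.0

    def predict_plddt(
        self,
        seq: SequenceRecord,
        visible_mask: np.ndarray | None = None,
        msa_masked: bool = False,
        recycles: int = 3,
        seed: int = 0,
    ) -> float:
        if seq.length > self.max_len:
            raise StabscoreError(f"sequence longer than max_len={self.max_len}")
        if visible_mask is None:
            visible_mask = np.ones(seq.length, dtype=bool)
        if len(visible_mask) != seq.length:
            raise StabscoreError("visible_mask length must equal sequence length")
        rng = _hash_stream("plddt", seq.id, visible_mask, msa_masked, recycles, self.seed, seed)
        noise = rng.normal(0.0, self.noise_sd) if self.noise_sd > 0 else 0.0
        return float(np.clip(50.0 + 8.0 * self._latent(seq) + noise, 0.0, 100.0))

    def masked_log_probs(self, seq: SequenceRecord, seed: int = 0) -> PositionLogits:
        rng = _hash_stream("mlm", seq.id, seq.sequence, self.seed, seed)
        logits = rng.normal(0.0, 1.0, size=(seq.length, len(AA_ALPHABET)))
        idx = seq.indices(AA_ALPHABET)
        # tilt true-letter logits with the latent so PLL tracks stability
        logits[np.arange(seq.length), idx] += self._latent(seq)
        if self.noise_sd > 0:
            logits[np.arange(seq.length), idx] += rng.normal(
                0.0, self.noise_sd / 8.0, size=seq.length
            )
        return PositionLogits(
            values=log_softmax(logits, axis=1), alphabet=AA_ALPHABET, kind="log_probs"
        )
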