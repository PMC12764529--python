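"""Score formulas: closed forms, brute-force oracles and invariances."""

import numpy as np
import pytest

from stabscore import (
    DistogramLogits,
    DistogramSpec,
    MockBackend,
    PositionLogits,
    SequenceRecord,
    StabscoreError,
    aggregate_plddt,
    digitize_distances,
    distogram_cross_entropy,
    pseudo_likelihood,
    sequence_cross_entropy,
    summed_likelihood,
)
from stabscore.scores import plddt_mask_stream

LN20 = np.log(20.0)


def uniform_log_probs(L: int) -> PositionLogits:
    return PositionLogits(np.full((L, 20), -LN20), kind="log_probs")


def true_letter_log_probs(seq: SequenceRecord, probs: list[float]) -> PositionLogits:
    """Rows placing the given probability on the true letter, rest spread evenly."""
    values = np.empty((seq.length, 20))
    idx = seq.indices()
    for i, p in enumerate(probs):
        values[i] = np.log((1.0 - p) / 19.0) if p < 1.0 else -np.inf
        values[i, idx[i]] = np.log(p)
    # replace -inf rows (p == 1) with a huge margin so rows still normalize
    if np.isinf(values).any():
        values = np.where(np.isinf(values), -745.0, values)
    return PositionLogits(values, kind="log_probs")


class TestPseudoLikelihood:
    def test_uniform_rows_closed_form(self):
        seq = SequenceRecord("s", "MKVLINSGAE")
        assert pseudo_likelihood(uniform_log_probs(10), seq) == pytest.approx(
            -LN20, abs=1e-12
        )

    def test_certain_prediction_is_zero(self):
        seq = SequenceRecord("s", "MK")
        lp = true_letter_log_probs(seq, [1.0, 1.0])
        assert pseudo_likelihood(lp, seq) == pytest.approx(0.0, abs=1e-6)

    def test_hand_summed_two_positions(self):
        # (ln 0.5 + ln 0.25) / 2 = -1.0397207...
        seq = SequenceRecord("s", "MK")
        lp = true_letter_log_probs(seq, [0.5, 0.25])
        expected = (np.log(0.5) + np.log(0.25)) / 2
        assert pseudo_likelihood(lp, seq) == pytest.approx(expected, abs=1e-12)

    def test_requires_log_probs(self):
        seq = SequenceRecord("s", "MK")
        logits = PositionLogits(np.zeros((2, 20)), kind="logits")
        with pytest.raises(StabscoreError, match="log_probs"):
            pseudo_likelihood(logits, seq)

    def test_length_mismatch(self):
        with pytest.raises(StabscoreError, match="mismatch"):
            pseudo_likelihood(uniform_log_probs(3), SequenceRecord("s", "MK"))

    def test_equals_negative_per_residue_cross_entropy(self):
        rng = np.random.default_rng(0)
        seq = SequenceRecord("s", "MKVLINSG")
        from scipy.special import log_softmax

        lp = PositionLogits(
            log_softmax(rng.normal(size=(8, 20)), axis=1), kind="log_probs"
        )
        pll = pseudo_likelihood(lp, seq)
        ce = sequence_cross_entropy(seq, lp)
        assert pll == pytest.approx(-ce["per_residue"], abs=1e-12)


class TestDigitize:
    def test_lower_edge_bin(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        d = np.full((2, 2), 3.0)
        F = digitize_distances(d, spec, include_diagonal=True)
        assert F.F[0, 1].tolist() == [1.0, 0.0]

    def test_half_open_lower_inclusive(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        d = np.full((2, 2), 4.0)
        F = digitize_distances(d, spec, include_diagonal=True)
        assert F.F[0, 1].tolist() == [0.0, 1.0]

    def test_diagonal_masked_by_default(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        F = digitize_distances(np.full((3, 3), 3.0), spec)
        assert F.out_of_range_mask.diagonal().all()
        assert not F.out_of_range_mask[0, 1]

    def test_out_of_range_masked_vs_clamped(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        d = np.array([[3.0, 9.0], [9.0, 3.0]])
        masked = digitize_distances(d, spec, include_diagonal=True)
        assert masked.out_of_range_mask[0, 1]
        clamped = digitize_distances(d, spec, include_diagonal=True, clamp=True)
        assert clamped.F[0, 1, 1] == 1.0  # last bin

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_interval_search_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        spec = DistogramSpec.uniform(2.0, 10.0, 2.0)
        raw = rng.uniform(0.0, 12.0, size=(4, 4))
        d = (raw + raw.T) / 2
        F = digitize_distances(d, spec, include_diagonal=True)
        for i in range(4):
            for j in range(4):
                expected = np.zeros(spec.M)
                for k in range(spec.M):
                    if spec.b[k] <= d[i, j] < spec.b[k + 1]:
                        expected[k] = 1.0
                np.testing.assert_array_equal(F.F[i, j], expected)
                assert F.out_of_range_mask[i, j] == (expected.sum() == 0)


class TestDistogramCrossEntropy:
    def test_huge_true_bin_margin_gives_zero(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        d = np.full((3, 3), 3.0)
        F = digitize_distances(d, spec, include_diagonal=True)
        logits = np.zeros((3, 3, 2))
        logits[:, :, 0] = 1e4  # true bin everywhere
        H = distogram_cross_entropy(F, DistogramLogits(logits, spec))
        assert 0.0 <= H <= 1e-3

    def test_uniform_logits_closed_form(self):
        # L=2, M=10, all pairs in range incl. diagonal -> 4 * ln 10
        spec = DistogramSpec.uniform(0.0, 10.0, 1.0)
        F = digitize_distances(np.full((2, 2), 5.0), spec, include_diagonal=True)
        H = distogram_cross_entropy(F, DistogramLogits(np.zeros((2, 2, 10)), spec))
        assert H == pytest.approx(4 * np.log(10), abs=1e-9)

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_elementwise_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        spec = DistogramSpec.uniform(2.0, 8.0, 1.0)
        raw = rng.uniform(1.0, 9.0, size=(3, 3))
        d = (raw + raw.T) / 2
        F = digitize_distances(d, spec, include_diagonal=True)
        logits = rng.normal(size=(3, 3, spec.M))
        H = distogram_cross_entropy(F, DistogramLogits(logits, spec))
        # independent -log-softmax summation
        expected = 0.0
        for i in range(3):
            for j in range(3):
                if F.out_of_range_mask[i, j]:
                    continue
                k = int(np.argmax(F.F[i, j]))
                log_z = np.log(np.exp(logits[i, j]).sum())
                expected += -(logits[i, j, k] - log_z)
        assert H == pytest.approx(expected, abs=1e-9)

    def test_single_bin_entropy_is_zero_for_any_logits(self):
        spec = DistogramSpec(b=[0.0, 100.0], h=100.0)
        rng = np.random.default_rng(3)
        d = rng.uniform(1, 99, size=(4, 4))
        F = digitize_distances((d + d.T) / 2, spec, include_diagonal=True)
        logits = rng.normal(size=(4, 4, 1))
        assert distogram_cross_entropy(F, DistogramLogits(logits, spec)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_decreases_with_true_bin_margin(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        d = np.full((2, 2), 3.0)
        np.fill_diagonal(d, 0.0)
        F = digitize_distances(d, spec)  # single off-diagonal pair (both orders)
        values = []
        for margin in (0.0, 1.0, 2.0, 5.0):
            logits = np.zeros((2, 2, 2))
            logits[:, :, 0] = margin
            values.append(distogram_cross_entropy(F, DistogramLogits(logits, spec)))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_shape_mismatch(self):
        spec = DistogramSpec(b=[2.0, 4.0, 6.0], h=2.0)
        F = digitize_distances(np.full((2, 2), 3.0), spec)
        with pytest.raises(StabscoreError, match="mismatch"):
            distogram_cross_entropy(F, DistogramLogits(np.zeros((3, 3, 2)), spec))


class TestSequenceCrossEntropy:
    def test_uniform_closed_form(self, seq_factory):
        seq = seq_factory("s", 10)
        result = sequence_cross_entropy(seq, PositionLogits(np.zeros((10, 20))))
        assert result["total"] == pytest.approx(10 * LN20, abs=1e-9)
        assert result["per_residue"] == pytest.approx(LN20, abs=1e-9)

    def test_certain_prediction_is_zero(self):
        seq = SequenceRecord("s", "MKV")
        lp = true_letter_log_probs(seq, [1.0, 1.0, 1.0])
        assert sequence_cross_entropy(seq, lp)["total"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_per_position_oracle(self, trial, seq_factory):
        rng = np.random.default_rng(4000 + trial)
        seq = seq_factory("s", 5, seed=trial)
        logits = PositionLogits(rng.normal(size=(5, 20)))
        total = sequence_cross_entropy(seq, logits)["total"]
        idx = seq.indices()
        expected = 0.0
        for i in range(5):
            row = logits.values[i]
            expected += -(row[idx[i]] - np.log(np.exp(row).sum()))
        assert total == pytest.approx(expected, abs=1e-9)

    def test_logit_shift_invariance(self, seq_factory):
        rng = np.random.default_rng(5)
        seq = seq_factory("s", 6)
        raw = rng.normal(size=(6, 20))
        base = sequence_cross_entropy(seq, PositionLogits(raw))["total"]
        shifted = sequence_cross_entropy(
            seq, PositionLogits(raw + rng.normal(size=(6, 1)))
        )["total"]
        assert shifted == pytest.approx(base, abs=1e-9)


class TestSummedLikelihood:
    def test_uniform_gives_L_over_20(self, seq_factory):
        seq = seq_factory("s", 7)
        assert summed_likelihood(PositionLogits(np.zeros((7, 20))), seq) == pytest.approx(
            7 / 20, abs=1e-12
        )

    def test_certain_gives_L(self):
        seq = SequenceRecord("s", "MKVL")
        lp = true_letter_log_probs(seq, [1.0] * 4)
        assert summed_likelihood(lp, seq) == pytest.approx(4.0, abs=1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_softmax_then_index_oracle(self, trial, seq_factory):
        rng = np.random.default_rng(6000 + trial)
        seq = seq_factory("s", 6, seed=trial)
        logits = PositionLogits(rng.normal(size=(6, 20)))
        value = summed_likelihood(logits, seq)
        idx = seq.indices()
        expected = sum(
            np.exp(logits.values[i][idx[i]]) / np.exp(logits.values[i]).sum()
            for i in range(6)
        )
        assert value == pytest.approx(expected, abs=1e-9)


class _ConstantBackend:
    capabilities = frozenset({"plddt"})
    max_len = 10_000

    def __init__(self, value: float):
        self.value = value
        self.calls = []

    def predict_plddt(self, seq, visible_mask=None, msa_masked=False, recycles=3, seed=0):
        self.calls.append((None if visible_mask is None else visible_mask.copy(),
                           msa_masked, recycles, seed))
        return self.value


class TestAggregatePlddt:
    @pytest.mark.parametrize("protocol", ["half_mask", "masked_msa", "plain"])
    def test_constant_backend(self, protocol, seq_factory):
        seq = seq_factory("s", 20)
        value = aggregate_plddt(_ConstantBackend(77.0), seq, protocol=protocol, seed=3)
        assert value == pytest.approx(77.0)

    def test_single_plain_rep_equals_direct_call(self, seq_factory):
        seq = seq_factory("s", 15)
        backend = MockBackend(seed=5)
        agg = aggregate_plddt(backend, seq, protocol="plain", n_reps=1, seed=9)
        direct = backend.predict_plddt(seq, recycles=3, seed=9)
        assert agg == pytest.approx(direct, abs=1e-12)

    def test_half_mask_matches_explicit_loop(self, seq_factory):
        """Re-execution oracle: aggregate == explicit loop on the same seed stream."""
        seq = seq_factory("s", 24)
        backend = MockBackend(seed=1)
        agg = aggregate_plddt(backend, seq, protocol="half_mask", n_reps=8, seed=42)
        values = []
        for rep in range(8):
            visible = plddt_mask_stream(42, rep, 24, 12)
            values.append(backend.predict_plddt(seq, visible_mask=visible, seed=42 + rep))
        assert agg == pytest.approx(np.mean(values), abs=1e-12)

    def test_mask_hides_exact_fraction(self):
        visible = plddt_mask_stream(0, 0, 21, int(0.5 * 21))
        assert (~visible).sum() == 10  # floor(0.5 * 21)

    def test_n_reps_validation(self, seq_factory):
        with pytest.raises(StabscoreError, match="n_reps"):
            aggregate_plddt(_ConstantBackend(50.0), seq_factory("s", 5), n_reps=0)


class TestSpecValidation:
    def test_inconsistent_width(self):
        with pytest.raises(StabscoreError, match="bins"):
            DistogramSpec(b=[0.0, 1.0, 2.0], h=0.7)

    def test_nonmonotone_edges(self):
        with pytest.raises(StabscoreError, match="increasing"):
            DistogramSpec(b=[0.0, 2.0, 1.0], h=1.0)

    def test_log_prob_rows_must_normalize(self):
        with pytest.raises(StabscoreError, match="normalize"):
            PositionLogits(np.zeros((2, 20)), kind="log_probs")
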