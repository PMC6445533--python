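"""Energy matrices, PWM estimation, K-L distortion, background sequences."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chipsim.motif import (
    ALPHABET,
    EnergyMatrix,
    default_dinuc_model,
    DinucModel,
    dinucleotide_sequences,
    estimate_pwm,
    infer_motif_from_simulation,
    kl_distance,
    nearest_energy_sequence,
    read_energy_matrix,
    sequence_energy,
    single_mutation_energy_quantiles,
)


class TestEnergyMatrix:
    def test_column_normalisation(self):
        m = EnergyMatrix(np.array([[1.0, 0.3], [1.5, 0.0], [1.0, 1.2], [2.0, 0.8]]))
        assert m.values[:, 0] == pytest.approx([0.0, 0.5, 0.0, 1.0])
        assert m.values[:, 1] == pytest.approx([0.3, 0.0, 1.2, 0.8])

    def test_packaged_matrix(self, matrix):
        assert matrix.length == 10
        assert np.all(matrix.values.min(axis=0) == 0)
        assert sequence_energy(matrix.consensus, matrix) == 0.0

    def test_loader_rejects_malformed(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("A 1 2\nC 1 x\nG 0 0\nT 1 1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_energy_matrix(bad)

    def test_sequence_energy_single_mismatch(self, matrix):
        cons = matrix.consensus
        mutant = "T" + cons[1:]
        expected = matrix.values[ALPHABET.index("T"), 0]
        assert sequence_energy(mutant, matrix) == pytest.approx(expected)

    def test_sequence_energy_validation(self, matrix):
        with pytest.raises(ValueError):
            sequence_energy("ACGT", matrix)
        with pytest.raises(ValueError):
            sequence_energy("ACGTACGTXN"[: matrix.length], matrix)


class TestNearestEnergySequence:
    def test_target_zero_is_consensus(self, matrix):
        seq, e = nearest_energy_sequence(0.0, matrix)
        assert seq == matrix.consensus and e == 0.0

    def test_target_above_maximum(self, matrix):
        seq, e = nearest_energy_sequence(1e6, matrix)
        assert e == pytest.approx(matrix.max_energy())

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        m = EnergyMatrix(r.uniform(0, 3, size=(4, 5)))
        targets = r.uniform(0, m.max_energy(), size=4)
        # independent brute force over all 4^5 sequences
        table = {
            "".join(s): sum(m.values[ALPHABET.index(b), j] for j, b in enumerate(s))
            for s in itertools.product(ALPHABET, repeat=5)
        }
        for t in targets:
            _, e = nearest_energy_sequence(float(t), m)
            best = min(abs(v - t) for v in table.values())
            assert abs(e - t) == pytest.approx(best, abs=1e-12)


class TestPWM:
    def test_hand_computed_weights(self):
        pwm = estimate_pwm(["AA", "AC", "AA"])
        assert pwm.weights[0, 0] == pytest.approx(np.log2(3.25))
        assert pwm.weights[1, 0] == pytest.approx(-2.0)
        assert pwm.weights[0, 1] == pytest.approx(np.log2(2.25))
        assert pwm.weights[1, 1] == pytest.approx(np.log2(1.25))
        assert pwm.probs.sum(axis=0) == pytest.approx([1.0, 1.0])

    def test_single_sequence(self):
        pwm = estimate_pwm(["A"])
        assert pwm.weights[0, 0] == pytest.approx(np.log2(1.25 / 0.5))
        assert pwm.weights[1, 0] == pytest.approx(-1.0)

    def test_counts_at_background_give_zero_weights(self):
        # 4 sequences, one of each base: N_ij = N * b_i at every position
        pwm = estimate_pwm(["A", "C", "G", "T"])
        assert pwm.weights == pytest.approx(np.zeros((4, 1)), abs=1e-12)

    def test_permutation_invariance(self, rng):
        seqs = ["ACGTA", "AAGTC", "TCGGA", "ACGTT"]
        a = estimate_pwm(seqs)
        b = estimate_pwm(seqs[::-1])
        assert a.weights == pytest.approx(b.weights)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_pwm([])


class TestKLDistance:
    def test_zero_on_identical(self):
        p = estimate_pwm(["ACGT", "ACGA"])
        assert kl_distance(p, p) == 0.0

    def test_symmetry(self):
        p = estimate_pwm(["AAAA", "AACA"])
        q = estimate_pwm(["TTTT", "TGTT"])
        assert kl_distance(p, q) == pytest.approx(kl_distance(q, p))

    def test_hand_value_single_position(self):
        p = estimate_pwm(["A", "A", "A"])  # probs (3.25, .25, .25, .25)/4
        q = estimate_pwm(["A", "C", "G", "T"])  # uniform
        pp, qq = p.probs[:, 0], q.probs[:, 0]
        expected = 0.5 * (
            np.sum(pp * np.log2(pp / qq)) + np.sum(qq * np.log2(qq / pp))
        )
        assert kl_distance(p, q) == pytest.approx(expected)
        assert kl_distance(p, q, "forward") == pytest.approx(np.sum(pp * np.log2(pp / qq)))

    def test_grows_with_concentration(self):
        base = estimate_pwm(["A", "C", "G", "T"])
        mild = estimate_pwm(["A", "A", "C", "G", "T"])
        strong = estimate_pwm(["A"] * 8 + ["C", "G", "T"])
        assert kl_distance(base, strong) > kl_distance(base, mild) > 0


class TestDinucleotideModel:
    def test_uniform_transitions_give_uniform_bases(self):
        model = DinucModel(np.full(4, 0.25), np.full((4, 4), 0.25))
        seqs = dinucleotide_sequences(model, 10, 10_000, 0)
        counts = np.zeros(4)
        for s in seqs:
            for b in s:
                counts[ALPHABET.index(b)] += 1
        assert counts / counts.sum() == pytest.approx([0.25] * 4, abs=0.01)

    def test_absorbing_chain(self):
        tr = np.zeros((4, 4))
        tr[:, 0] = 1.0
        model = DinucModel(np.array([0, 0, 0, 1.0]), tr)
        assert dinucleotide_sequences(model, 6, 3, 1) == ["TAAAAA"] * 3

    def test_transition_recovery(self):
        model = default_dinuc_model()
        seqs = dinucleotide_sequences(model, 50, 2500, 2)
        counts = np.zeros((4, 4))
        for s in seqs:
            for a, b in zip(s, s[1:]):
                counts[ALPHABET.index(a), ALPHABET.index(b)] += 1
        est = counts / counts.sum(axis=1, keepdims=True)
        assert est == pytest.approx(model.transitions, abs=0.02)


class TestMotifInference:
    def _table(self, ratios):
        return pd.DataFrame({"ratio": ratios})

    def test_noiseless_ranking_recovers_lowest_energy_sites(self, matrix, rng):
        energies = np.linspace(0, 6, 50)
        sites = [nearest_energy_sequence(e, matrix)[0] for e in energies]
        ratios = 10 - energies  # strictly decreasing in energy
        pwm = infer_motif_from_simulation(self._table(ratios), sites, top_fraction=0.2)
        expected = estimate_pwm(sites[:10])
        assert kl_distance(pwm, expected) == 0.0

    def test_top_fraction_one_uses_all(self, matrix):
        sites = [matrix.consensus] * 10
        pwm = infer_motif_from_simulation(self._table(np.arange(10)), sites, 1.0)
        assert pwm.n_sequences == 10

    def test_nan_ratios_excluded(self, matrix):
        sites = [matrix.consensus] * 10
        ratios = [np.nan] * 9 + [1.0]
        with pytest.raises(ValueError):
            infer_motif_from_simulation(self._table(ratios), sites, 0.5)


class TestSingleMutationQuantiles:
    def test_uniform_matrix_all_mutants_differ_by_one(self):
        vals = np.ones((4, 6))
        vals[0] = 0.0  # consensus AAAAAA, every mutation adds exactly 1
        m = EnergyMatrix(vals)
        out = single_mutation_energy_quantiles([m], baseline_energies=(0,))
        assert out["q0.25"].iloc[0] == 1.0 and out["q0.5"].iloc[0] == 1.0

    def test_two_position_matrix_brute_force(self):
        m = EnergyMatrix(np.array([[0.0, 0.0], [0.5, 1.0], [1.5, 2.0], [2.5, 3.0]]))
        out = single_mutation_energy_quantiles([m], baseline_energies=(0,))
        diffs = sorted([0.5, 1.5, 2.5, 1.0, 2.0, 3.0])
        assert out["q0.25"].iloc[0] == pytest.approx(np.quantile(diffs, 0.25))
        assert out["q0.5"].iloc[0] == pytest.approx(np.quantile(diffs, 0.5))

    def test_quantiles_ordered(self, matrix):
        out = single_mutation_energy_quantiles([matrix])
        assert np.all(out["q0.25"] <= out["q0.5"])
        assert np.all(out["n_mutants"] == 30)
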