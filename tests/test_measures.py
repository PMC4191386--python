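import math

import numpy as np
import pytest

import _oracle as oracle
from ribodesign.engine import BasePairProbabilityMatrix, ToyEngine
from ribodesign.iofmt import RnaSequence, parse_dotbracket
from ribodesign.measures import (
    CONSERVED_SITE,
    discrepancy,
    ebpd_profile,
    ensemble_defect,
    ensemble_profile,
    expected_bp_distance,
    measure_suite,
    normalized_ensemble_defect,
    positional_entropy,
    structural_diversity,
)


def bppm_from_structures(structures: list[str], weights: list[float]):
    """Build an exact probability matrix from an explicit tiny ensemble."""
    n = len(structures[0])
    total = sum(weights)
    m = np.zeros((n + 1, n + 1))
    for text, w in zip(structures, weights):
        db = parse_dotbracket(text)
        paired = set()
        for i, j in db.pairs:
            m[i, j] += w / total
            m[j, i] += w / total
            paired.update((i, j))
        for i in range(1, n + 1):
            if i not in paired:
                m[i, i] += w / total
    return BasePairProbabilityMatrix(m)


class TestPositionalEntropy:
    def test_deterministic_ensemble_has_zero_entropy(self):
        bppm = bppm_from_structures(["((...))"], [1.0])
        assert np.allclose(positional_entropy(bppm, "full"), 0.0)
        assert np.allclose(positional_entropy(bppm, "binary"), 0.0)

    def test_half_paired_position_has_one_bit_binary_entropy(self):
        bppm = bppm_from_structures(["((...))", "......."], [1.0, 1.0])
        hb = positional_entropy(bppm, "binary")
        assert hb[0] == pytest.approx(1.0)
        assert hb[3] == pytest.approx(0.0)  # loop position unpaired in both

    def test_log_base_conversion(self):
        bppm = bppm_from_structures(["((...))", "......."], [1.0, 1.0])
        bits = positional_entropy(bppm, "full", base=2.0)
        nats = positional_entropy(bppm, "full", base=math.e)
        assert np.allclose(nats, bits * math.log(2.0))

    def test_matches_enumerated_state_distribution(self, rng):
        eng = ToyEngine()
        for _ in range(4):
            seq = oracle.random_rna(rng, 12)
            _, bppm = eng.partition(RnaSequence("x", seq))
            expected = oracle.state_entropy(seq, eng.config.rt)
            assert np.allclose(positional_entropy(bppm, "full"), expected, atol=1e-9)


class TestEnsembleDefect:
    def test_zero_when_ensemble_is_the_target(self):
        bppm = bppm_from_structures(["((...))"], [1.0])
        assert ensemble_defect(bppm, parse_dotbracket("((...))")) == pytest.approx(0.0)

    def test_matches_boltzmann_weighted_mismatch_count(self, rng):
        eng = ToyEngine()
        for _ in range(4):
            seq = oracle.random_rna(rng, 12)
            rs = RnaSequence("x", seq)
            target, _ = eng.mfe(rs)
            _, bppm = eng.partition(rs)
            expected = oracle.boltzmann_ensemble_defect(
                seq, frozenset(target.pairs), eng.config.rt
            )
            assert ensemble_defect(bppm, target) == pytest.approx(expected, abs=1e-9)

    def test_normalized_value_in_unit_interval(self):
        bppm = bppm_from_structures(["((...))", "......."], [1.0, 3.0])
        nd = normalized_ensemble_defect(bppm, parse_dotbracket("((...))"))
        assert 0.0 <= nd <= 1.0

    def test_site_restriction_never_exceeds_whole(self):
        bppm = bppm_from_structures(["((...))", "......."], [1.0, 1.0])
        t = parse_dotbracket("((...))")
        assert ensemble_defect(bppm, t, [1, 2]) <= ensemble_defect(bppm, t)


class TestExpectedBpDistance:
    def test_zero_for_single_structure_ensemble(self):
        bppm = bppm_from_structures(["((...))"], [1.0])
        assert expected_bp_distance(bppm, parse_dotbracket("((...))")) == 0.0

    def test_matches_boltzmann_average_distance(self, rng):
        eng = ToyEngine()
        for _ in range(4):
            seq = oracle.random_rna(rng, 12)
            rs = RnaSequence("x", seq)
            target, _ = eng.mfe(rs)
            _, bppm = eng.partition(rs)
            expected = oracle.boltzmann_bp_distance(
                seq, frozenset(target.pairs), eng.config.rt
            )
            assert expected_bp_distance(bppm, target) == pytest.approx(expected, abs=1e-9)

    def test_per_position_profile_sums_to_twice_the_whole(self):
        bppm = bppm_from_structures(["((...))", ".(...)."], [1.0, 2.0])
        t = parse_dotbracket("((...))")
        d = ebpd_profile(bppm, t)
        assert d.sum() == pytest.approx(2.0 * expected_bp_distance(bppm, t))

    def test_site_restriction_never_exceeds_position_sum(self):
        bppm = bppm_from_structures(["((...))", ".(...)."], [1.0, 1.0])
        t = parse_dotbracket("((...))")
        assert expected_bp_distance(bppm, t, [1, 7]) <= ebpd_profile(bppm, t).sum()


class TestDiversity:
    def test_single_structure_has_zero_vienna_diversity(self):
        bppm = bppm_from_structures(["((...))"], [1.0])
        assert structural_diversity(bppm, "vienna") == pytest.approx(0.0)

    def test_two_state_swap_gives_unit_vienna_diversity(self):
        # equiprobable ensembles whose pair sets are disjoint singletons
        bppm = bppm_from_structures(["(...)..", "..(...)"], [1.0, 1.0])
        assert structural_diversity(bppm, "vienna") == pytest.approx(1.0)

    def test_vienna_diversity_matches_pairwise_expectation(self, rng):
        eng = ToyEngine()
        seq = oracle.random_rna(rng, 11)
        _, bppm = eng.partition(RnaSequence("x", seq))
        expected = oracle.pairwise_diversity(seq, eng.config.rt)
        assert structural_diversity(bppm, "vienna") == pytest.approx(expected, abs=1e-9)

    def test_morgan_higgs_uniform_row(self):
        # p*(i,j) = 1/n across each row -> per-position value 1 - 1/n
        n = 4
        m = np.full((n + 1, n + 1), 1.0 / n)
        m[0, :] = m[:, 0] = 0.0
        bppm = BasePairProbabilityMatrix(m)
        assert structural_diversity(bppm, "morgan_higgs") == pytest.approx(
            n * (1.0 - 1.0 / n)
        )


class TestDiscrepancy:
    def test_identical_profiles_have_zero_discrepancy(self):
        assert discrepancy([0.1, 0.4], [0.1, 0.4]) == 0.0

    def test_site_restricted_max_abs_difference(self):
        a = [0.0] * 10
        b = [0.0] * 10
        b[5] = 0.3  # position 6
        assert discrepancy(a, b, positions=[6]) == pytest.approx(0.3)
        assert discrepancy(a, b, positions=[1, 2]) == 0.0

    def test_self_discrepancy_after_engine_round_trip(self):
        eng = ToyEngine()
        rs = RnaSequence("x", "GGGAAACCCAAA")
        target, _ = eng.mfe(rs)
        _, bppm1 = eng.partition(rs)
        _, bppm2 = eng.partition(rs)
        p1 = ensemble_profile(bppm1, target)
        p2 = ensemble_profile(bppm2, target)
        assert discrepancy(p1.entropy_full, p2.entropy_full) <= 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discrepancy([0.1], [0.1, 0.2])


class TestMeasureSuite:
    def test_all_fields_match_enumeration_on_toy_ensemble(self):
        eng = ToyEngine()
        seq = "GGCGAAACGCCA"
        rs = RnaSequence("x", seq)
        target, _ = eng.mfe(rs)
        rec = measure_suite(rs, target, conserved_site=(1, 2, 3), engine_config=eng.config)
        rt = eng.config.rt
        assert rec.ensemble_defect == pytest.approx(
            oracle.boltzmann_ensemble_defect(seq, frozenset(target.pairs), rt), abs=1e-9
        )
        assert rec.ebpd == pytest.approx(
            oracle.boltzmann_bp_distance(seq, frozenset(target.pairs), rt), abs=1e-9
        )
        assert rec.pos_entropy == pytest.approx(
            float(np.mean(oracle.state_entropy(seq, rt))), abs=1e-9
        )
        assert rec.vienna_diversity == pytest.approx(
            oracle.pairwise_diversity(seq, rt), abs=1e-9
        )
        probs = oracle.structure_probabilities(seq, rt)
        assert rec.prob_target == pytest.approx(probs[target.text], rel=1e-9)

    def test_conserved_site_constant(self):
        assert len(CONSERVED_SITE) == 16
        assert CONSERVED_SITE[0] == 6 and CONSERVED_SITE[-1] == 49
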