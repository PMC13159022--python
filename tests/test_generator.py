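from collections import Counter

import numpy as np
import pytest

from algocp.alphabet import AA_INDEX
from algocp.generator import (
    GeneratedSet,
    GenerationConfig,
    ProfileSequenceGenerator,
    generate_chimeras,
    generate_sequences,
    sample_unique,
)
from algocp.msa import AlignmentColumn
from algocp.profiles import ScoringConfig, build_profiles

from conftest import make_column


def single_position_profiles(counts: str):
    return build_profiles([make_column(counts)], cfg=ScoringConfig(r=0.0))


class TestSampling:
    def test_fully_conserved_profiles_yield_consensus(self):
        cols = [make_column("S" * 20, 0), make_column("A" * 20, 1)]
        profiles = build_profiles(cols)
        batch = generate_sequences(profiles, GenerationConfig(n_sequences=1, seed=0))
        assert batch.sequences == ("SA",)

    def test_seeded_reproducibility(self, fitted_generator):
        a = fitted_generator.sample(50, seed=123)
        b = fitted_generator.sample(50, seed=123)
        assert a.sequences == b.sequences
        c = fitted_generator.sample(50, seed=124)
        assert a.sequences != c.sequences

    def test_sequence_i_independent_of_set_size(self, fitted_generator):
        # substreams keyed by (seed, index): the first 10 of a 50-sequence
        # run equal the 10-sequence run (no duplicates rejected here)
        small = fitted_generator.sample(10, seed=5)
        large = fitted_generator.sample(50, seed=5)
        assert large.sequences[:10] == small.sequences

    def test_single_position_binomial_frequency(self):
        # oracle: 10^4 independent single draws from P(A)=0.8, P(V)=0.2
        # fall within 3 sigma of the binomial expectation
        profiles = single_position_profiles("A" * 8 + "V" * 2)
        n = 10_000
        draws = [
            generate_sequences(
                profiles, GenerationConfig(n_sequences=1, seed=s, r=0.0)
            ).sequences[0]
            for s in range(n)
        ]
        frac_a = Counter(draws)["A"] / n
        assert abs(frac_a - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / n)

    def test_duplicate_budget_exhaustion_reports_diversity(self):
        profiles = build_profiles([make_column("S" * 20)])
        with pytest.raises(RuntimeError, match="1 unique"):
            generate_sequences(profiles, GenerationConfig(n_sequences=2, seed=0))

    def test_generated_set_invariants(self, fitted_generator):
        batch = fitted_generator.sample(200, seed=9)
        assert len(set(batch.sequences)) == 200
        assert batch.length == fitted_generator.n_positions_
        assert batch.provenance["r"] == 0.60

    def test_conserved_override_positions_fixed_in_every_sequence(self, fitted_generator):
        overrides = [
            (i, p.modal_residue)
            for i, p in enumerate(fitted_generator.profiles_)
            if p.conserved_override
        ]
        assert overrides  # fixture has at least the invariant serine
        for r in (0.0, 0.6, 1.0):
            batch = fitted_generator.sample(100, seed=3, r=r)
            for seq in batch:
                assert all(seq[i] == aa for i, aa in overrides)

    def test_r_zero_support_limited_to_observed_residues(
        self, fitted_generator, synthetic_columns
    ):
        batch = fitted_generator.sample(500, seed=21, r=0.0)
        for seq in batch:
            for pos, col in enumerate(synthetic_columns):
                assert seq[pos] in col.residues

    def test_empirical_frequencies_match_profile(self, fitted_generator):
        # multinomial oracle at every (position, residue) over 10^4 draws
        n = 10_000
        batch = fitted_generator.sample(n, seed=2, r=0.6)
        probs = np.stack([p.a_u for p in fitted_generator.profiles_])
        counts = np.zeros_like(probs)
        for seq in batch:
            for pos, aa in enumerate(seq):
                counts[pos, AA_INDEX[aa]] += 1
        freqs = counts / n
        sigma = np.sqrt(probs * (1 - probs) / n)
        z = np.abs(freqs - probs) / np.where(sigma > 0, sigma, np.inf)
        # simultaneous check over 1560 cells: ~0.27% are expected beyond
        # 3 sigma by chance alone, so assert the envelope collectively
        assert (z <= 3).mean() >= 0.99
        assert z.max() < 6
        # exact-support sanity: impossible residues are never drawn
        assert np.all(counts[probs == 0] == 0)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        gen = ProfileSequenceGenerator(r=0.25, min_residues=10)
        params = gen.get_params()
        assert params["r"] == 0.25
        clone = ProfileSequenceGenerator().set_params(**params)
        assert clone.get_params() == params

    def test_unfitted_sample_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            ProfileSequenceGenerator().sample(1, seed=0)

    def test_fit_on_alignment_and_columns_agree(self, synthetic_alignment, synthetic_columns):
        a = ProfileSequenceGenerator().fit(synthetic_alignment)
        b = ProfileSequenceGenerator().fit(synthetic_columns)
        assert a.n_positions_ == b.n_positions_
        assert np.allclose(
            np.stack([p.a_u for p in a.profiles_]),
            np.stack([p.a_u for p in b.profiles_]),
        )


class TestChimeras:
    def test_identical_parents_single_outcome(self):
        batch = generate_chimeras("ACDE", "ACDE", 1, seed=0)
        assert batch.sequences == ("ACDE",)

    def test_identical_parents_cannot_yield_two(self):
        with pytest.raises(ValueError, match="single chimera"):
            generate_chimeras("ACDE", "ACDE", 2, seed=0)

    def test_two_outcome_space_enumerated(self):
        batch = generate_chimeras("AC", "AD", 2, seed=1)
        assert sorted(batch.sequences) == ["AC", "AD"]

    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_uniqueness_forces_exact_enumeration(self, d):
        # parents differing at d positions span exactly 2^d chimeras
        a = "A" * (d + 2)
        b = "C" * d + "A" * 2
        batch = generate_chimeras(a, b, 2**d, seed=3)
        expected = set()
        for mask in range(2**d):
            seq = list(a)
            for bit in range(d):
                if mask >> bit & 1:
                    seq[bit] = "C"
            expected.add("".join(seq))
        assert set(batch.sequences) == expected

    def test_request_beyond_outcome_space_rejected(self):
        with pytest.raises(ValueError, match="2\\^1"):
            generate_chimeras("AC", "AD", 3, seed=0)

    def test_every_position_inherited_from_a_parent(self):
        a, b = "ACDEFGHIKL", "ACDWFGHYKV"
        batch = generate_chimeras(a, b, 6, seed=4)
        for seq in batch:
            assert all(s in (x, y) for s, x, y in zip(seq, a, b))

    def test_gapped_or_unequal_parents_rejected(self):
        with pytest.raises(ValueError, match="gapped"):
            generate_chimeras("A-C", "AAC", 1, seed=0)
        with pytest.raises(ValueError, match="equal length"):
            generate_chimeras("AC", "ACD", 1, seed=0)
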