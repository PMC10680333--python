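"""Vocabulary, sample derivation, encoding, splitting and balanced batches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flowrec as fr
from flowrec.dataset import (
    N_BINS,
    compute_bin_eligibility,
    load_dataset,
    save_dataset,
)


def seqs(*lists):
    return [fr.ToolSequence(tools=tuple(t), source_workflow_id="w") for t in lists]


def brute_force_samples(sequences, n):
    """Independent oracle: scan every sequence, every prefix, accumulate
    successors after truncating the prefix to its last n tools."""
    successors = {}
    for s in sequences:
        for i in range(1, len(s.tools)):
            key = s.tools[max(0, i - n):i]
            successors.setdefault(key, set()).add(s.tools[i])
    return successors


class TestVocabulary:
    def test_frequency_order_with_lexicographic_ties(self):
        vocab = fr.build_vocabulary(seqs("AB", "AC"))
        assert vocab.index_of == {"A": 1, "B": 2, "C": 3}

    def test_single_sequence_size(self):
        assert fr.build_vocabulary(seqs("AB")).size == 2

    def test_vocabulary_of_generated_corpus_is_subset_of_grammar_tools(
        self, small_grammar, small_vocab
    ):
        assert set(small_vocab.index_of) <= set(small_grammar.tools)

    def test_index_zero_reserved(self, small_vocab):
        assert 0 not in small_vocab.tool_of
        assert sorted(small_vocab.index_of.values()) == list(
            range(1, small_vocab.size + 1)
        )

    def test_unknown_tool_error_names_tool(self, small_vocab):
        with pytest.raises(fr.UnknownToolError, match="no-such-tool"):
            small_vocab["no-such-tool"]


class TestEncoding:
    VOCAB = fr.ToolVocabulary(index_of={"A": 1, "B": 2, "C": 3})

    def test_left_padding(self):
        np.testing.assert_array_equal(
            fr.encode_and_pad(["A", "B", "C"], self.VOCAB, 5), [0, 0, 1, 2, 3]
        )

    def test_exact_length_no_padding(self):
        ids = fr.encode_and_pad(["A", "B", "C"], self.VOCAB, 3)
        assert (ids != 0).all()

    def test_overlong_prefix_keeps_last_n(self):
        prefix = ["A", "B", "C"] * 10  # 30 tools, n=25 keeps the last 25
        ids = fr.encode_and_pad(prefix, self.VOCAB, 25)
        assert len(ids) == 25 and (ids != 0).all()
        assert fr.decode(ids, self.VOCAB) == tuple(prefix[-25:])

    @given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=1, max_size=12),
           st.integers(min_value=2, max_value=8))
    @settings(max_examples=60, deadline=None)
    def test_decode_inverts_encode_after_truncation(self, prefix, n):
        ids = fr.encode_and_pad(prefix, self.VOCAB, n)
        assert fr.decode(ids, self.VOCAB) == tuple(prefix[-n:])
        nz = np.flatnonzero(ids)
        if nz.size:  # non-zero block is contiguous and right-aligned
            assert nz[-1] == n - 1 and nz.size == nz[-1] - nz[0] + 1

    def test_multi_hot_positions_and_sum(self):
        vec = fr.to_multi_hot({"B"}, self.VOCAB)
        np.testing.assert_array_equal(vec, [0, 0, 1, 0])
        assert fr.to_multi_hot({"A", "C"}, self.VOCAB).sum() == 2

    def test_multi_hot_empty_set_error(self):
        with pytest.raises(ValueError):
            fr.to_multi_hot(set(), self.VOCAB)


class TestDeriveSamples:
    def test_linear_corpus_prefix_labels(self):
        sequences = seqs("ABC")
        vocab = fr.build_vocabulary(sequences)
        samples = fr.derive_labeled_samples(sequences, vocab, n=5)
        got = {s.raw_prefix: {vocab.name(int(i)) for i in s.label_indices}
               for s in samples}
        assert got == {("A",): {"B"}, ("A", "B"): {"C"}}

    def test_branching_corpus_merges_labels(self):
        sequences = seqs("ABC", "ABD")
        vocab = fr.build_vocabulary(sequences)
        samples = fr.derive_labeled_samples(sequences, vocab, n=5)
        got = {s.raw_prefix: {vocab.name(int(i)) for i in s.label_indices}
               for s in samples}
        assert got[("A", "B")] == {"C", "D"}
        assert len([p for p in got if p == ("A", "B")]) == 1

    def test_two_tool_sequence_yields_one_sample(self):
        sequences = seqs("AB")
        vocab = fr.build_vocabulary(sequences)
        assert len(fr.derive_labeled_samples(sequences, vocab, n=25)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_corpora(self, seed):
        grammar = fr.generate_grammar(10, 2, 1.0, seed=seed, n_layers=5)
        corpus = fr.generate_workflow_corpus(
            grammar, 15, length_range=(2, 5), target_median=3,
            branch_prob=0.5, seed=seed,
        )
        sequences = [s for g in corpus for s in fr.enumerate_linear_sequences(g)]
        n = 3  # short cap exercises truncation-before-uniquing
        vocab = fr.build_vocabulary(sequences)
        samples = fr.derive_labeled_samples(sequences, vocab, n=n)
        oracle = brute_force_samples(sequences, n)
        got = {s.raw_prefix: {vocab.name(int(i)) for i in s.label_indices}
               for s in samples}
        assert got == oracle

    def test_label_vector_sum_equals_label_count(self, small_samples):
        for s in small_samples:
            assert s.label_vector.sum() == len(s.label_indices) >= 1
            assert s.label_vector[0] == 0


class TestSplit:
    def test_eighty_twenty_counts(self, small_samples):
        split = fr.split_train_test(small_samples[:10], fraction=0.8, seed=1)
        assert len(split.train) == 8 and len(split.test) == 2

    def test_disjoint_and_reproducible(self, small_samples):
        a = fr.split_train_test(small_samples, fraction=0.8, seed=5)
        b = fr.split_train_test(small_samples, fraction=0.8, seed=5)
        assert [s.raw_prefix for s in a.train] == [s.raw_prefix for s in b.train]
        assert not ({s.raw_prefix for s in a.train}
                    & {s.raw_prefix for s in a.test})

    def test_different_seeds_differ(self, small_samples):
        a = fr.split_train_test(small_samples, fraction=0.8, seed=1)
        b = fr.split_train_test(small_samples, fraction=0.8, seed=2)
        assert {s.raw_prefix for s in a.train} != {s.raw_prefix for s in b.train}

    def test_too_few_samples_error(self, small_samples):
        with pytest.raises(ValueError):
            fr.split_train_test(small_samples[:1], fraction=0.8, seed=0)


class TestFrequencyBins:
    def _samples_with_frequencies(self, freqs):
        """Build a corpus whose per-tool label frequencies equal ``freqs``."""
        tools = [f"t{i}" for i in range(len(freqs))]
        vocab = fr.ToolVocabulary(
            index_of={t: i + 1 for i, t in enumerate(sorted(tools))}
        )
        samples = []
        counter = 0
        for tool, freq in zip(tools, freqs):
            for _ in range(freq):
                prefix = (f"p{counter}",)
                counter += 1
                vec = np.zeros(vocab.size + 1, dtype=np.uint8)
                vec[vocab[tool]] = 1
                samples.append(fr.LabeledSample(
                    input_ids=np.array([vocab[tool]], dtype=np.int32),
                    label_vector=vec, raw_prefix=prefix))
        return samples, vocab, tools

    def test_quartile_example_two_per_bin(self):
        freqs = [1, 1, 10, 10, 100, 100, 1000, 1000]
        samples, vocab, tools = self._samples_with_frequencies(freqs)
        bins = fr.assign_frequency_bins(samples, vocab)
        got = [bins.bin_of[t] for t in tools]
        assert got == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_every_tool_gets_exactly_one_bin(self, small_split, small_vocab,
                                             small_bins):
        assert set(small_bins.bin_of) == set(small_vocab.index_of)
        assert set(small_bins.bin_of.values()) <= set(range(1, N_BINS + 1))

    def test_rare_bin_contains_lowest_frequency_tools(self, small_split,
                                                      small_vocab, small_bins):
        counts = np.zeros(small_vocab.size + 1, dtype=int)
        for s in small_split.train:
            counts += s.label_vector
        rare = small_bins.tools_in_bin(1)
        assert rare
        max_rare = max(counts[small_vocab[t]] for t in rare)
        others = [counts[small_vocab[t]] for t in small_bins.bin_of
                  if small_bins.bin_of[t] > 1]
        assert all(max_rare <= c for c in others) or max_rare <= np.percentile(
            counts[1:], 25
        )


class TestBalancedBatches:
    def test_exact_batch_size(self, small_split, small_bins, small_vocab):
        batch = fr.sample_balanced_batch(
            small_split.train, small_bins, 64, rng=0, vocab=small_vocab
        )
        assert len(batch) == 64

    def test_batch_members_come_from_train_only(self, small_split, small_bins,
                                                small_vocab):
        train_ids = {id(s) for s in small_split.train}
        batch = fr.sample_balanced_batch(
            small_split.train, small_bins, 32, rng=3, vocab=small_vocab
        )
        assert all(id(s) in train_ids for s in batch)

    def test_bins_selected_uniformly_within_three_standard_errors(
        self, small_split, small_bins, small_vocab
    ):
        eligible = compute_bin_eligibility(
            small_split.train, small_bins, small_vocab
        )
        usable = [b for b in eligible if len(eligible[b]) > 0]
        n_draws = 10000
        rng = np.random.default_rng(9)
        batch = fr.sample_balanced_batch(
            small_split.train, small_bins, n_draws, rng=rng, vocab=small_vocab
        )
        # recover the bin of each draw via eligibility membership counts
        per_bin = {b: 0 for b in usable}
        member_sets = {b: {id(small_split.train[i]) for i in eligible[b]}
                       for b in usable}
        for s in batch:
            hits = [b for b in usable if id(s) in member_sets[b]]
            for b in hits:
                per_bin[b] += 1 / len(hits)  # sample may be eligible in 2 bins
        p = 1 / len(usable)
        se = np.sqrt(p * (1 - p) / n_draws)
        for b in usable:
            assert abs(per_bin[b] / n_draws - p) < 5 * se + 0.02

    def test_batch_smaller_than_bin_count_rejected(self, small_split, small_bins,
                                                   small_vocab):
        with pytest.raises(ValueError):
            fr.sample_balanced_batch(
                small_split.train, small_bins, N_BINS - 1, rng=0,
                vocab=small_vocab,
            )

    def test_single_populated_bin_degenerates_to_uniform(self):
        vocab = fr.ToolVocabulary(index_of={"A": 1, "B": 2})
        vec = np.array([0, 1, 0], dtype=np.uint8)
        train = [
            fr.LabeledSample(np.array([1], np.int32), vec, (f"p{i}",))
            for i in range(5)
        ]
        bins = fr.FrequencyBins(bin_of={"A": 1, "B": 1}, boundaries=(1, 1, 1))
        batch = fr.sample_balanced_batch(train, bins, 16, rng=0, vocab=vocab)
        assert len(batch) == 16


class TestContainer:
    def test_round_trip(self, small_samples, small_vocab, small_split, tmp_path):
        path = tmp_path / "ds.h5"
        save_dataset(path, small_samples, small_vocab, small_split, n=10)
        samples, vocab, split, n = load_dataset(path)
        assert n == 10
        assert vocab.index_of == small_vocab.index_of
        assert len(split.train) == len(small_split.train)
        for a, b in zip(samples, small_samples):
            np.testing.assert_array_equal(a.input_ids, b.input_ids)
            np.testing.assert_array_equal(a.label_vector, b.label_vector)

    def test_rewrite_is_byte_identical(self, small_samples, small_vocab,
                                       small_split, tmp_path):
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        save_dataset(p1, small_samples, small_vocab, small_split, n=10)
        save_dataset(p2, small_samples, small_vocab, small_split, n=10)
        assert p1.read_bytes() == p2.read_bytes()
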