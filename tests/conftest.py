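import numpy as np
import pytest

import flowrec as fr


@pytest.fixture(scope="session")
def diamond_graph():
    """4-node diamond DAG: A→B→D, A→C→D."""
    return fr.WorkflowGraph.from_parts(
        "diamond", ["A", "B", "C", "D"], [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    )


@pytest.fixture(scope="session")
def small_grammar():
    return fr.generate_grammar(
        16, branching_factor=2, skew_exponent=1.5, seed=7, n_layers=6
    )


@pytest.fixture(scope="session")
def small_corpus(small_grammar):
    return fr.generate_workflow_corpus(
        small_grammar, 80, length_range=(2, 6), target_median=4,
        branch_prob=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def small_sequences(small_corpus):
    return [s for g in small_corpus for s in fr.enumerate_linear_sequences(g)]


@pytest.fixture(scope="session")
def small_vocab(small_sequences):
    return fr.build_vocabulary(small_sequences)


@pytest.fixture(scope="session")
def small_samples(small_sequences, small_vocab):
    return fr.derive_labeled_samples(small_sequences, small_vocab, n=10)


@pytest.fixture(scope="session")
def small_split(small_samples):
    return fr.split_train_test(small_samples, fraction=0.8, seed=7)


@pytest.fixture(scope="session")
def small_bins(small_split, small_vocab):
    return fr.assign_frequency_bins(small_split.train, small_vocab)


def tiny_transformer_config(n_tools=6, **over):
    defaults = dict(
        d_model=8, n_heads=2, head_dim=4, ffn_dims=(6, 8), hidden_dense_dim=5,
        max_len=6, dropout_rate=0.0,
    )
    defaults.update(over)
    return fr.config_for_vocabulary("transformer", n_tools, **defaults)


@pytest.fixture(scope="session")
def tiny_transformer():
    cfg = tiny_transformer_config()
    return fr.build_transformer(cfg, seed=3)


@pytest.fixture(scope="session")
def tiny_bundle_path(tiny_transformer, tmp_path_factory):
    vocab = fr.ToolVocabulary(
        index_of={f"t{i}": i for i in range(1, 7)}
    )
    path = tmp_path_factory.mktemp("bundle") / "tiny.h5"
    fr.save_bundle(tiny_transformer, vocab, path)
    return path
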