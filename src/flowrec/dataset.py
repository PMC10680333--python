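"""Vocabulary building, multi-label sample derivation, encoding and batching.

Each proper prefix of every tool sequence becomes one training sample; its
label set is the union, over the whole corpus, of tools observed to follow
that prefix.  Prefixes are integer-encoded against a frequency-ordered
vocabulary (index 0 reserved for padding), left-padded to a fixed length,
and labels stored as multi-hot vectors.  Because tool frequencies in real
workflow corpora are heavily skewed, training batches are drawn
frequency-balanced: label-frequency quartile bins are sampled uniformly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import h5py
import numpy as np

from .workflow_corpus import ToolSequence

logger = logging.getLogger(__name__)

__all__ = [
    "ToolVocabulary",
    "LabeledSample",
    "DatasetSplit",
    "FrequencyBins",
    "UnknownToolError",
    "build_vocabulary",
    "derive_labeled_samples",
    "encode_and_pad",
    "decode",
    "to_multi_hot",
    "split_train_test",
    "assign_frequency_bins",
    "sample_balanced_batch",
    "save_dataset",
    "load_dataset",
    "write_samples_tsv",
]

PAD_INDEX = 0
N_BINS = 4


class UnknownToolError(KeyError):
    pass


@dataclass(frozen=True)
class ToolVocabulary:
    """Bijective tool-name <-> integer mapping; index 0 is padding."""

    index_of: dict[str, int]
    tool_of: dict[int, str] = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "tool_of", {i: t for t, i in self.index_of.items()}
        )
        if PAD_INDEX in self.tool_of:
            raise ValueError("index 0 is reserved for padding")
        if sorted(self.index_of.values()) != list(range(1, len(self.index_of) + 1)):
            raise ValueError("vocabulary indices must be a bijection onto 1..V")

    @property
    def size(self) -> int:
        return len(self.index_of)

    def __contains__(self, tool: str) -> bool:
        return tool in self.index_of

    def __getitem__(self, tool: str) -> int:
        try:
            return self.index_of[tool]
        except KeyError:
            raise UnknownToolError(f"tool not in vocabulary: {tool!r}") from None

    def name(self, index: int) -> str:
        return self.tool_of[index]


@dataclass(frozen=True)
class LabeledSample:
    """One encoded prefix with its multi-hot next-tool label vector."""

    input_ids: np.ndarray  # int32, length N, left-padded with 0
    label_vector: np.ndarray  # uint8, length V_out
    raw_prefix: tuple[str, ...]

    @property
    def label_indices(self) -> np.ndarray:
        return np.flatnonzero(self.label_vector)


@dataclass
class DatasetSplit:
    train: list[LabeledSample]
    test: list[LabeledSample]
    seed: int


@dataclass
class FrequencyBins:
    """Quartile partition of tools by how often they occur as labels."""

    bin_of: dict[str, int]  # tool -> bin in 1..N_BINS (1 = rarest)
    boundaries: tuple[float, ...]  # the 25/50/75 percentiles

    def tools_in_bin(self, b: int) -> list[str]:
        return sorted(t for t, v in self.bin_of.items() if v == b)


# -- vocabulary ------------------------------------------------------------


def build_vocabulary(sequences: list[ToolSequence]) -> ToolVocabulary:
    """Indices 1..V by descending total frequency, ties lexicographic."""
    if not sequences:
        raise ValueError("cannot build a vocabulary from no sequences")
    freq: Counter[str] = Counter()
    for s in sequences:
        freq.update(s.tools)
    ordered = sorted(freq, key=lambda t: (-freq[t], t))
    return ToolVocabulary(index_of={t: i + 1 for i, t in enumerate(ordered)})


# -- encoding --------------------------------------------------------------


def encode_and_pad(prefix, vocab: ToolVocabulary, n: int) -> np.ndarray:
    """Map the last min(len, n) tools to indices, left-padded with zeros."""
    prefix = list(prefix)
    if not prefix:
        raise ValueError("prefix must contain at least one tool")
    kept = prefix[-n:]
    out = np.zeros(n, dtype=np.int32)
    for i, tool in enumerate(kept):
        out[n - len(kept) + i] = vocab[tool]
    return out


def decode(input_ids: np.ndarray, vocab: ToolVocabulary) -> tuple[str, ...]:
    """Strip padding and map indices back to tool names."""
    return tuple(vocab.name(int(i)) for i in input_ids if i != PAD_INDEX)


def to_multi_hot(labels, vocab: ToolVocabulary) -> np.ndarray:
    """Binary vector of length V+1 with ones at the 1-based label indices."""
    labels = set(labels)
    if not labels:
        raise ValueError("label set must be non-empty")
    vec = np.zeros(vocab.size + 1, dtype=np.uint8)
    for tool in labels:
        vec[vocab[tool]] = 1
    return vec


# -- sample derivation -----------------------------------------------------


def derive_labeled_samples(
    sequences: list[ToolSequence], vocab: ToolVocabulary, n: int = 25
) -> list[LabeledSample]:
    """One sample per distinct (truncated) proper prefix.

    For every proper prefix P of every sequence, the label set is the union
    over the corpus of tools immediately following P.  Prefixes longer than
    ``n`` keep their most recent ``n`` tools before uniquing, so two long
    prefixes sharing a recent context merge into one sample.
    """
    if n < 2:
        raise ValueError("maximum sequence length must be at least 2")
    successors: dict[tuple[str, ...], set[str]] = {}
    for seq in sequences:
        tools = seq.tools
        for plen in range(1, len(tools)):
            key = tools[max(0, plen - n) : plen]
            successors.setdefault(key, set()).add(tools[plen])
    samples = []
    for prefix in sorted(successors):
        samples.append(
            LabeledSample(
                input_ids=encode_and_pad(prefix, vocab, n),
                label_vector=to_multi_hot(successors[prefix], vocab),
                raw_prefix=prefix,
            )
        )
    return samples


# -- splitting & balanced batching ----------------------------------------


def split_train_test(
    samples: list[LabeledSample], fraction: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Uniform random split by sample, reproducible under ``seed``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(len(samples) * fraction))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return DatasetSplit(
        train=[samples[i] for i in train_idx],
        test=[samples[i] for i in test_idx],
        seed=seed,
    )


def assign_frequency_bins(
    samples: list[LabeledSample], vocab: ToolVocabulary
) -> FrequencyBins:
    """Partition tools into quartile bins of empirical label frequency.

    A tool's label frequency is the number of samples whose label set
    contains it.  Bin 1 holds the rarest quartile.
    """
    if not samples:
        raise ValueError("cannot bin label frequencies of no samples")
    counts = np.zeros(vocab.size + 1, dtype=np.int64)
    for s in samples:
        counts += s.label_vector
    freqs = {tool: int(counts[idx]) for tool, idx in vocab.index_of.items()}
    values = np.array(list(freqs.values()), dtype=float)
    boundaries = tuple(np.percentile(values, [25, 50, 75]))
    # side="left": a tool sitting exactly on a percentile boundary stays in
    # the lower bin, so the rarest quartile is never empty
    bin_of = {
        tool: int(np.searchsorted(boundaries, f, side="left")) + 1
        for tool, f in freqs.items()
    }
    return FrequencyBins(bin_of=bin_of, boundaries=boundaries)


def sample_balanced_batch(
    train: list[LabeledSample],
    bins: FrequencyBins,
    batch_size: int,
    rng: np.random.Generator | int,
    vocab: ToolVocabulary | None = None,
    _eligible_cache: dict | None = None,
) -> list[LabeledSample]:
    """Draw a batch with label-frequency bins represented uniformly.

    For each slot a bin is chosen uniformly among bins that have at least
    one eligible sample (a sample whose label set intersects the bin's
    tools); within the bin a sample is drawn uniformly with replacement.
    Bins with no eligible sample are skipped with a logged warning.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if batch_size < N_BINS:
        raise ValueError(f"batch size must be at least the bin count ({N_BINS})")
    eligible = _eligible_cache if _eligible_cache is not None else {}
    if not eligible:
        eligible.update(compute_bin_eligibility(train, bins, vocab))
        for b in range(1, N_BINS + 1):
            if len(eligible.get(b, ())) == 0:
                logger.warning("frequency bin %d has no eligible samples; skipped", b)
    usable = [b for b in range(1, N_BINS + 1) if len(eligible.get(b, ())) > 0]
    if not usable:
        raise ValueError("no frequency bin has any eligible training sample")
    batch = []
    bin_choices = rng.integers(0, len(usable), size=batch_size)
    for c in bin_choices:
        members = eligible[usable[c]]
        batch.append(train[members[rng.integers(0, len(members))]])
    return batch


def compute_bin_eligibility(
    train: list[LabeledSample], bins: FrequencyBins, vocab: ToolVocabulary
) -> dict[int, np.ndarray]:
    """Per-bin arrays of train-sample indices whose labels touch the bin."""
    if vocab is None:
        raise ValueError("vocab is required to compute bin eligibility")
    bin_of_index = np.zeros(vocab.size + 1, dtype=np.int8)
    for tool, b in bins.bin_of.items():
        bin_of_index[vocab[tool]] = b
    out: dict[int, list[int]] = {b: [] for b in range(1, N_BINS + 1)}
    for i, s in enumerate(train):
        for b in np.unique(bin_of_index[s.label_indices]):
            out[int(b)].append(i)
    return {b: np.asarray(v, dtype=np.int64) for b, v in out.items()}


# -- container I/O ---------------------------------------------------------


def save_dataset(
    path,
    samples: list[LabeledSample],
    vocab: ToolVocabulary,
    split: DatasetSplit,
    n: int,
) -> None:
    """Single HDF5 container: input matrix, CSR labels, vocabulary, split."""
    x = np.stack([s.input_ids for s in samples])
    indptr = [0]
    indices: list[int] = []
    for s in samples:
        idx = s.label_indices
        indices.extend(int(i) for i in idx)
        indptr.append(len(indices))
    train_prefixes = {s.raw_prefix for s in split.train}
    train_idx = [i for i, s in enumerate(samples) if s.raw_prefix in train_prefixes]
    test_idx = [i for i, s in enumerate(samples) if s.raw_prefix not in train_prefixes]
    names = [vocab.name(i) for i in range(1, vocab.size + 1)]
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = "1"
        f.attrs["max_len"] = n
        f.attrs["seed"] = split.seed
        f.create_dataset("inputs", data=x.astype(np.int32))
        f.create_dataset("label_indptr", data=np.asarray(indptr, dtype=np.int64))
        f.create_dataset("label_indices", data=np.asarray(indices, dtype=np.int64))
        f.create_dataset("train_idx", data=np.asarray(train_idx, dtype=np.int64))
        f.create_dataset("test_idx", data=np.asarray(test_idx, dtype=np.int64))
        f.create_dataset(
            "vocabulary", data=np.array(names, dtype=h5py.string_dtype("utf-8"))
        )


def load_dataset(path):
    """Inverse of :func:`save_dataset`.

    Returns (samples, vocab, split, n).
    """
    with h5py.File(path, "r") as f:
        n = int(f.attrs["max_len"])
        seed = int(f.attrs["seed"])
        x = f["inputs"][:]
        indptr = f["label_indptr"][:]
        indices = f["label_indices"][:]
        train_idx = f["train_idx"][:]
        test_idx = f["test_idx"][:]
        names = [s.decode() if isinstance(s, bytes) else s for s in f["vocabulary"][:]]
    vocab = ToolVocabulary(index_of={t: i + 1 for i, t in enumerate(names)})
    samples = []
    for i in range(x.shape[0]):
        vec = np.zeros(vocab.size + 1, dtype=np.uint8)
        vec[indices[indptr[i] : indptr[i + 1]]] = 1
        samples.append(
            LabeledSample(
                input_ids=x[i],
                label_vector=vec,
                raw_prefix=decode(x[i], vocab),
            )
        )
    split = DatasetSplit(
        train=[samples[i] for i in train_idx],
        test=[samples[i] for i in test_idx],
        seed=seed,
    )
    return samples, vocab, split, n


def write_samples_tsv(samples: list[LabeledSample], vocab: ToolVocabulary, path):
    """Human-inspectable TSV of (prefix, labels) pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("prefix\tlabels\n")
        for s in samples:
            labels = ",".join(vocab.name(int(i)) for i in s.label_indices)
            fh.write(f"{','.join(s.raw_prefix)}\t{labels}\n")
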