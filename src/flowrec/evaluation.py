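"""Evaluation: precision@k, infrequent-tool breakdown, model usage time.

Precision@k is the fraction of the k highest-scoring recommendations that
are true labels; by default k equals the size of the sample's label set,
and a fixed-k mode is available.  The infrequent-tool report restricts the
test set to samples whose labels touch the rarest label-frequency quartile.
Model usage time is the cost a user of the recommender actually pays: the
wall time to reconstruct a saved bundle plus one forward pass.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .architectures import ModelBundle, load_bundle
from .dataset import FrequencyBins, LabeledSample, encode_and_pad

__all__ = [
    "EvalReport",
    "UsageTime",
    "precision_at_k",
    "evaluate_model",
    "evaluate_infrequent_tools",
    "measure_usage_time",
]


@dataclass
class EvalReport:
    mean_precision: float
    per_sample_precision: list[float]
    n_samples: int
    subset_label: str = "all"


@dataclass
class UsageTime:
    """Median wall times in seconds; total = reconstruction + prediction."""

    reconstruction: float
    prediction: float
    total: float
    raw: list[tuple[float, float]] = field(default_factory=list)


def precision_at_k(scores: np.ndarray, true_labels, k: int | None = None) -> float:
    """|top-k(scores) ∩ true_labels| / k.

    Ranking is by descending score with ties broken by ascending index.
    Default policy: k = |true_labels|.
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = set(int(i) for i in true_labels)
    if not true_labels:
        raise ValueError("true label set must be non-empty")
    if k is None:
        k = len(true_labels)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds the score vector length {scores.shape[0]}")
    order = np.argsort(-scores, kind="stable")  # stable => ascending-index ties
    top = set(int(i) for i in order[:k])
    return len(top & true_labels) / k


def evaluate_model(
    bundle: ModelBundle,
    test: list[LabeledSample],
    k: int | None = None,
    subset_label: str = "all",
) -> EvalReport:
    """Per-sample precision@k over a test set, mean reported."""
    if not test:
        raise ValueError("test set is empty")
    v_out = bundle.config.vocab_out
    if test[0].label_vector.shape[0] != v_out:
        raise ValueError(
            f"bundle vocabulary ({v_out - 1} tools) does not match the "
            f"sample label dimension {test[0].label_vector.shape[0]}"
        )
    x = np.stack([s.input_ids for s in test])
    per_sample = []
    for start in range(0, len(test), 512):
        scores = bundle.predict(x[start : start + 512])
        scores[:, 0] = 0.0  # padding slot is never a recommendation
        for row, sample in zip(scores, test[start : start + 512]):
            labels = set(int(i) for i in sample.label_indices)
            per_sample.append(precision_at_k(row, labels, k))
    return EvalReport(
        mean_precision=float(np.mean(per_sample)),
        per_sample_precision=per_sample,
        n_samples=len(per_sample),
        subset_label=subset_label,
    )


def evaluate_infrequent_tools(
    bundle: ModelBundle,
    test: list[LabeledSample],
    bins: FrequencyBins,
    k: int | None = None,
    mode: str = "any",
) -> EvalReport:
    """Precision@k restricted to samples with rare-bin labels.

    ``mode='any'`` keeps samples whose label set intersects the lowest
    frequency quartile (bin 1); ``mode='all'`` requires every label to be
    rare.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    rare = {bundle.vocabulary[t] for t in bins.tools_in_bin(1)}
    picker = any if mode == "any" else all
    subset = [
        s for s in test
        if picker(int(i) in rare for i in s.label_indices)
    ]
    if not subset:
        raise ValueError("no test sample has labels in the lowest-frequency bin")
    report = evaluate_model(bundle, subset, k=k, subset_label="lowest-25%")
    return report


def measure_usage_time(
    bundle_path, prefix, repeats: int = 5
) -> UsageTime:
    """Median model reconstruction + prediction wall time.

    Reconstruction is one :func:`load_bundle` call; prediction is one
    forward pass on the encoded prefix.  Components are medians over
    ``repeats``; the total is their sum.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    raw = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        bundle = load_bundle(bundle_path)
        t1 = time.perf_counter()
        ids = encode_and_pad(prefix, bundle.vocabulary, bundle.config.max_len)
        t2 = time.perf_counter()
        bundle.predict(ids)
        t3 = time.perf_counter()
        raw.append((t1 - t0, t3 - t2))
    recon = float(np.median([r for r, _ in raw]))
    pred = float(np.median([p for _, p in raw]))
    return UsageTime(
        reconstruction=recon, prediction=pred, total=recon + pred, raw=raw
    )
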