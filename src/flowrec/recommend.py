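"""Inference and post-processing of next-tool recommendations.

Scores come straight from a model bundle's sigmoid outputs.  Post-processing
mirrors what a production recommender in a workflow platform does before
showing results: drop tools that are deprecated or otherwise unavailable,
then re-rank the survivors by how much each tool was actually used in the
last year, so the recommendations a user sees favour well-maintained,
popular tools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .architectures import ModelBundle
from .dataset import PAD_INDEX, UnknownToolError, encode_and_pad

__all__ = [
    "Recommendation",
    "ToolUsageTable",
    "predict_scores",
    "recommend_top_n",
    "postprocess",
    "read_usage_table",
    "read_deprecated_list",
    "recommendations_to_tsv",
]


@dataclass(frozen=True)
class Recommendation:
    tool: str
    score: float
    rank: int
    usage_count: int | None = None


class ToolUsageTable(dict):
    """Mapping tool -> usage count in the last year (missing tools count 0)."""

    def count(self, tool: str) -> int:
        return int(self.get(tool, 0))


def predict_scores(bundle: ModelBundle, prefix) -> np.ndarray:
    """Sigmoid score vector (length vocab_out) for a tool-name prefix."""
    prefix = list(prefix)
    unknown = [t for t in prefix if t not in bundle.vocabulary]
    if unknown:
        raise UnknownToolError(f"tools not in vocabulary: {unknown}")
    ids = encode_and_pad(prefix, bundle.vocabulary, bundle.config.max_len)
    return bundle.predict(ids)[0]


def recommend_top_n(
    scores: np.ndarray, n: int, bundle: ModelBundle
) -> list[Recommendation]:
    """The n highest-scoring real tools, descending score, index tie-break.

    The padding slot (index 0) is never recommended.
    """
    scores = np.asarray(scores, dtype=float)
    n_real = bundle.vocabulary.size
    if not 1 <= n <= scores.shape[0]:
        raise ValueError(f"n must be in [1, {scores.shape[0]}]")
    order = np.argsort(-scores, kind="stable")
    out = []
    for idx in order:
        idx = int(idx)
        if idx == PAD_INDEX or idx > n_real:
            continue
        out.append(
            Recommendation(
                tool=bundle.vocabulary.name(idx),
                score=float(scores[idx]),
                rank=len(out) + 1,
            )
        )
        if len(out) == min(n, n_real):
            break
    return out


def postprocess(
    recs: list[Recommendation],
    deprecated: set[str] | None = None,
    usage: ToolUsageTable | None = None,
) -> list[Recommendation]:
    """Deprecation filtering and usage-based re-ranking.

    Deprecated tools are removed; survivors are sorted by usage count
    descending, ties by model score descending, then by tool name; ranks
    are reassigned 1..m.  An empty or missing usage table degrades to
    score ordering.
    """
    deprecated = deprecated or set()
    usage = usage if usage is not None else ToolUsageTable()
    survivors = [r for r in recs if r.tool not in deprecated]
    survivors.sort(key=lambda r: (-usage.count(r.tool), -r.score, r.tool))
    return [
        replace(r, rank=i + 1, usage_count=usage.count(r.tool))
        for i, r in enumerate(survivors)
    ]


# -- file dialects ---------------------------------------------------------


def read_usage_table(path) -> ToolUsageTable:
    """TSV dialect ``tool<TAB>count``; an optional header line is skipped."""
    table = ToolUsageTable()
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            tool, count = cols
            if ln == 1 and not count.strip().lstrip("-").isdigit():
                continue  # header
            table[tool.strip()] = int(count)
    return table


def read_deprecated_list(path) -> set[str]:
    """One tool name per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def recommendations_to_tsv(recs: list[Recommendation]) -> str:
    lines = ["rank\ttool\tscore\tusage"]
    for r in recs:
        usage = "" if r.usage_count is None else str(r.usage_count)
        lines.append(f"{r.rank}\t{r.tool}\t{r.score:.6f}\t{usage}")
    return "\n".join(lines) + "\n"
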