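"""Synthetic workflow corpora with known ground truth.

Real workflow corpora have three structural features the models must cope
with: DAG-shaped workflows over a tool vocabulary, heavily skewed tool
frequencies (the most common text-manipulation tools appear orders of
magnitude more often than specialist tools), and branching, so that one
tool sequence maps to several next-tool labels.  The generator emulates
all three from a *tool grammar*: a layered DAG of tools with power-law
frequency weights.  Layering makes acyclicity true by construction, and
the grammar's successor map is the exact ground truth for every prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .workflow_corpus import WorkflowGraph

__all__ = [
    "ToolGrammar",
    "generate_grammar",
    "generate_workflow_corpus",
    "ground_truth_labels",
    "corpus_to_edge_tsv",
    "grammar_to_table",
]

#: corpus profile defaults: sequence lengths span 2..28 with median 15,
#: mirroring the published Galaxy Europe corpus shape
DEFAULT_LENGTH_RANGE = (2, 28)
DEFAULT_MEDIAN_LENGTH = 15
DEFAULT_BRANCH_PROB = 0.25
DEFAULT_SKEW = 1.5


@dataclass(frozen=True)
class ToolGrammar:
    """Ground-truth successor structure for simulating workflows."""

    tools: tuple[str, ...]
    successor_map: dict[str, tuple[str, ...]]
    start_tools: tuple[str, ...]
    frequency_weights: dict[str, float]
    max_depth: int
    layer_of: dict[str, int]

    def successors(self, tool: str) -> tuple[str, ...]:
        if tool not in self.successor_map:
            raise KeyError(f"tool not in grammar: {tool!r}")
        return self.successor_map[tool]


def generate_grammar(
    n_tools: int,
    branching_factor: int = 2,
    skew_exponent: float = DEFAULT_SKEW,
    seed: int = 0,
    n_layers: int = 28,
) -> ToolGrammar:
    """Layered-DAG grammar with power-law tool weights.

    Tools are spread over ``n_layers`` layers; every non-terminal tool gets
    up to ``branching_factor`` successors in the next layer.  Frequency
    weights follow ``rank**-skew_exponent`` over a random rank permutation,
    so the max/min weight ratio is ``n_tools**skew_exponent``.
    """
    if n_tools < 4:
        raise ValueError("grammar needs at least 4 tools")
    if branching_factor < 1:
        raise ValueError("branching factor must be at least 1")
    rng = np.random.default_rng(seed)
    n_layers = min(n_layers, n_tools)
    if n_layers < 2:
        raise ValueError("grammar needs at least 2 layers")
    tools = tuple(f"tool_{i:04d}" for i in range(n_tools))
    order = rng.permutation(n_tools)
    layer_of = {}
    # one tool per layer first (every layer non-empty), rest at random
    for layer, idx in enumerate(order[:n_layers]):
        layer_of[tools[idx]] = layer
    for idx in order[n_layers:]:
        layer_of[tools[idx]] = int(rng.integers(0, n_layers))
    layers = [sorted(t for t in tools if layer_of[t] == l) for l in range(n_layers)]

    ranks = rng.permutation(n_tools) + 1
    weights = {t: float(r) ** (-skew_exponent) for t, r in zip(tools, ranks)}

    successor_map: dict[str, tuple[str, ...]] = {}
    for l, layer in enumerate(layers):
        nxt = layers[l + 1] if l + 1 < n_layers else []
        for tool in layer:
            if not nxt:
                successor_map[tool] = ()
                continue
            k = min(branching_factor, len(nxt))
            chosen = rng.choice(len(nxt), size=k, replace=False)
            successor_map[tool] = tuple(sorted(nxt[i] for i in chosen))
    return ToolGrammar(
        tools=tools,
        successor_map=successor_map,
        start_tools=tuple(layers[0]),
        frequency_weights=weights,
        max_depth=n_layers,
        layer_of=layer_of,
    )


@lru_cache(maxsize=32)
def _length_pmf(lo: int, hi: int, median: int, r: int = 8) -> tuple[float, ...]:
    """Truncated, shifted negative-binomial length pmf calibrated so the
    distribution's median equals ``median``."""
    if not lo <= median <= hi:
        raise ValueError("target median must lie inside the length range")
    support = np.arange(lo, hi + 1)

    def pmf_for(p):
        raw = stats.nbinom.pmf(support - lo, r, p)
        s = raw.sum()
        if s <= 0:
            return None
        return raw / s

    best, best_gap = None, None
    for p in np.linspace(0.02, 0.98, 481):
        pmf = pmf_for(p)
        if pmf is None:
            continue
        med = support[np.searchsorted(np.cumsum(pmf), 0.5)]
        gap = abs(int(med) - median)
        if best_gap is None or gap < best_gap:
            best, best_gap = pmf, gap
        if gap == 0:
            break
    return tuple(float(x) for x in best)


def generate_workflow_corpus(
    grammar: ToolGrammar,
    n_workflows: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    target_median: int | None = None,
    branch_prob: float = DEFAULT_BRANCH_PROB,
    seed: int = 0,
) -> list[WorkflowGraph]:
    """Simulate workflows as weighted random walks through the grammar.

    Each workflow is a chain of the drawn length (truncated if the walk
    reaches a terminal tool).  Branch duplication then makes workflows
    DAG-shaped rather than purely linear: independently with probability
    ``branch_prob``, each unused grammar successor of each interior chain
    node is attached as an extra leaf edge, creating multi-successor
    prefixes exactly as real branched workflows do.  At ``branch_prob=1``
    every workflow exposes the full successor set of each of its interior
    tools, so corpus-derived label sets equal the grammar's ground truth.
    """
    lo, hi = length_range
    if lo < 2 or hi > grammar.max_depth:
        raise ValueError(
            f"length range must lie within [2, {grammar.max_depth}] for this grammar"
        )
    if target_median is None:
        target_median = int(np.clip(DEFAULT_MEDIAN_LENGTH, lo, hi))
    pmf = np.array(_length_pmf(lo, hi, target_median))
    support = np.arange(lo, hi + 1)
    rng = np.random.default_rng(seed)
    w = grammar.frequency_weights

    def weighted_choice(options):
        probs = np.array([w[t] for t in options])
        return options[rng.choice(len(options), p=probs / probs.sum())]

    corpus = []
    for i in range(n_workflows):
        target_len = int(rng.choice(support, p=pmf))
        chain = [weighted_choice(list(grammar.start_tools))]
        while len(chain) < target_len:
            succ = grammar.successor_map[chain[-1]]
            if not succ:
                break
            chain.append(weighted_choice(list(succ)))
        edges = list(zip(chain[:-1], chain[1:]))
        nodes = list(chain)
        for pos in range(len(chain) - 1):
            for extra in grammar.successor_map[chain[pos]]:
                if extra != chain[pos + 1] and rng.random() < branch_prob:
                    nodes.append(extra)
                    edges.append((chain[pos], extra))
        corpus.append(WorkflowGraph.from_parts(f"wf_{i:05d}", nodes, edges))
    return corpus


def ground_truth_labels(grammar: ToolGrammar, prefix) -> set[str]:
    """Exact successor set of the prefix's final tool under the grammar."""
    prefix = list(prefix)
    if not prefix:
        raise ValueError("prefix must contain at least one tool")
    for tool in prefix:
        if tool not in grammar.successor_map:
            raise KeyError(f"tool not in grammar: {tool!r}")
    return set(grammar.successor_map[prefix[-1]])


# -- export ----------------------------------------------------------------


def corpus_to_edge_tsv(corpus: list[WorkflowGraph], header: bool = True) -> str:
    """3-column dialect ``workflow_id<TAB>source_tool<TAB>target_tool``."""
    lines = ["workflow_id\tsource_tool\ttarget_tool"] if header else []
    for wf in corpus:
        connected = {n for e in wf.edges for n in e}
        for s, t in wf.edges:
            lines.append(f"{wf.workflow_id}\t{s}\t{t}")
        for n in wf.nodes:
            if n not in connected:
                lines.append(f"{wf.workflow_id}\t{n}\t")
    return "\n".join(lines) + "\n"


def grammar_to_table(grammar: ToolGrammar) -> str:
    """Plain-text successor table for inspection."""
    lines = ["tool\tlayer\tweight\tsuccessors"]
    for t in grammar.tools:
        succ = ",".join(grammar.successor_map[t])
        lines.append(
            f"{t}\t{grammar.layer_of[t]}\t{grammar.frequency_weights[t]:.6g}\t{succ}"
        )
    return "\n".join(lines) + "\n"
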