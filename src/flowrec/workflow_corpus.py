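"""Workflow parsing, linear-sequence extraction and corpus statistics.

Galaxy-style workflows are directed acyclic graphs whose nodes are
scientific tools.  This module reads the native workflow-export dialect
(a JSON document of steps and input connections) and two tabular edge-list
dialects, contracts non-tool steps (data inputs), and decomposes each DAG
into the maximal source-to-sink linear tool sequences that downstream
modules learn from.
"""

from __future__ import annotations

import json
import statistics
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "WorkflowGraph",
    "ToolSequence",
    "CorpusStats",
    "WorkflowParseError",
    "WorkflowValidationError",
    "parse_workflow",
    "parse_edge_list_corpus",
    "read_workflow_file",
    "enumerate_linear_sequences",
    "compute_corpus_stats",
    "serialize_edge_list",
    "serialize_native",
    "write_sequences_tsv",
    "read_sequences_tsv",
]


class WorkflowParseError(ValueError):
    """Malformed workflow content; the message names the offending record."""


class WorkflowValidationError(ValueError):
    """Structurally invalid workflow (e.g. a directed cycle)."""


@dataclass(frozen=True)
class WorkflowGraph:
    """A parsed workflow: tool-labelled nodes plus directed edges.

    Nodes are tool names; duplicate edges are collapsed.  Construction
    validates acyclicity and edge-endpoint membership.
    """

    workflow_id: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        node_set = set(self.nodes)
        if any(not n for n in self.nodes):
            raise WorkflowValidationError(
                f"workflow {self.workflow_id!r}: empty tool name among nodes"
            )
        for s, t in self.edges:
            if s not in node_set or t not in node_set:
                raise WorkflowValidationError(
                    f"workflow {self.workflow_id!r}: edge ({s!r}, {t!r}) "
                    "references a tool not in nodes"
                )
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise WorkflowValidationError(
                f"workflow {self.workflow_id!r} contains a directed cycle: {cycle}"
            )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_parts(cls, workflow_id: str, nodes, edges) -> "WorkflowGraph":
        """Normalise: deduplicate, deterministic (sorted) node/edge order."""
        return cls(
            workflow_id=str(workflow_id),
            nodes=tuple(sorted(set(nodes))),
            edges=tuple(sorted(set(tuple(e) for e in edges))),
        )


@dataclass(frozen=True)
class ToolSequence:
    """A linear ordering of tools along one path through a workflow DAG."""

    tools: tuple[str, ...]
    source_workflow_id: str = ""

    def __post_init__(self):
        if len(self.tools) < 2:
            raise WorkflowValidationError(
                f"tool sequence from {self.source_workflow_id!r} has fewer "
                "than two tools"
            )

    def __len__(self):
        return len(self.tools)


@dataclass
class CorpusStats:
    n_workflows: int
    n_sequences: int
    n_unique_sequences: int
    n_unique_tools: int
    max_length: int
    min_length: int
    median_length: float
    per_tool_frequency: dict[str, int] = field(default_factory=dict)


# -- parsing ---------------------------------------------------------------


def parse_workflow(content: str, workflow_id: str = "") -> WorkflowGraph:
    """Parse one workflow from native JSON export or 2-column edge TSV.

    Non-tool steps (data inputs etc.) are dropped and their in/out edges
    contracted, so the returned graph contains tools only.
    """
    stripped = content.lstrip()
    if stripped.startswith("{"):
        return _parse_native(content, workflow_id)
    return _parse_edge_tsv(content, workflow_id)


def _parse_native(content: str, workflow_id: str) -> WorkflowGraph:
    try:
        doc = json.loads(content)
    except json.JSONDecodeError as exc:
        raise WorkflowParseError(f"invalid workflow JSON: {exc}") from exc
    if not isinstance(doc, dict) or "steps" not in doc:
        raise WorkflowParseError("workflow JSON lacks a 'steps' mapping")
    wf_id = workflow_id or str(doc.get("name", "") or doc.get("uuid", "") or "workflow")
    steps = doc["steps"]
    tool_of_step: dict[str, str | None] = {}
    preds: dict[str, set[str]] = {}
    for key, step in steps.items():
        if not isinstance(step, dict):
            raise WorkflowParseError(f"step {key!r} is not a mapping")
        sid = str(step.get("id", key))
        step_type = step.get("type", "tool")
        tool_id = step.get("tool_id")
        tool_of_step[sid] = str(tool_id) if (step_type == "tool" and tool_id) else None
        inputs = step.get("input_connections", {}) or {}
        src_ids: set[str] = set()
        for conn in inputs.values():
            conns = conn if isinstance(conn, list) else [conn]
            for c in conns:
                if not isinstance(c, dict) or "id" not in c:
                    raise WorkflowParseError(
                        f"step {sid!r}: malformed input connection {c!r}"
                    )
                src_ids.add(str(c["id"]))
        preds[sid] = src_ids

    # contract non-tool steps: predecessors of a dropped step become
    # predecessors of its successors (fixed-point over chains of inputs)
    def tool_ancestors(sid: str, seen: frozenset = frozenset()) -> set[str]:
        out: set[str] = set()
        for p in preds.get(sid, ()):  # may reference a missing step
            if p not in tool_of_step:
                raise WorkflowParseError(
                    f"step {sid!r}: connection references unknown step {p!r}"
                )
            if p in seen:
                continue
            if tool_of_step[p] is not None:
                out.add(p)
            else:
                out |= tool_ancestors(p, seen | {sid})
        return out

    nodes = [t for t in tool_of_step.values() if t is not None]
    edges = []
    for sid, tool in tool_of_step.items():
        if tool is None:
            continue
        for p in tool_ancestors(sid):
            src_tool = tool_of_step[p]
            if src_tool != tool:  # self-edges from duplicate tool steps dropped
                edges.append((src_tool, tool))
    return WorkflowGraph.from_parts(wf_id, nodes, edges)


def _split_tsv_rows(content: str) -> list[list[str]]:
    rows = []
    for ln, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        rows.append([ln, line.rstrip("\n").split("\t")])
    return rows


_HEADER_TOKENS = {"source_tool", "target_tool", "workflow_id", "source", "target"}


def _parse_edge_tsv(content: str, workflow_id: str) -> WorkflowGraph:
    rows = _split_tsv_rows(content)
    if not rows:
        raise WorkflowParseError("empty edge list")
    if set(map(str.lower, rows[0][1])) & _HEADER_TOKENS:
        rows = rows[1:]
    edges = []
    nodes = []
    for ln, cols in rows:
        if len(cols) != 2:
            raise WorkflowParseError(
                f"line {ln}: expected 2 tab-separated columns, got {len(cols)}"
            )
        s, t = (c.strip() for c in cols)
        if not s:
            raise WorkflowParseError(f"line {ln}: empty source tool")
        nodes.append(s)
        if t:  # "tool<TAB>" row records an isolated node
            nodes.append(t)
            edges.append((s, t))
    return WorkflowGraph.from_parts(workflow_id or "workflow", nodes, edges)


def parse_edge_list_corpus(content: str) -> list[WorkflowGraph]:
    """Parse the 3-column dialect ``workflow_id<TAB>source<TAB>target``.

    Returns one graph per distinct workflow id, in sorted id order.
    """
    rows = _split_tsv_rows(content)
    if not rows:
        raise WorkflowParseError("empty corpus edge list")
    if set(map(str.lower, rows[0][1])) & _HEADER_TOKENS:
        rows = rows[1:]
    per_wf: dict[str, list[tuple[str, str]]] = {}
    per_wf_nodes: dict[str, list[str]] = {}
    for ln, cols in rows:
        if len(cols) != 3:
            raise WorkflowParseError(
                f"line {ln}: expected 3 tab-separated columns, got {len(cols)}"
            )
        wf, s, t = (c.strip() for c in cols)
        if not wf or not s:
            raise WorkflowParseError(f"line {ln}: empty workflow id or source tool")
        per_wf.setdefault(wf, [])
        per_wf_nodes.setdefault(wf, []).append(s)
        if t:
            per_wf_nodes[wf].append(t)
            per_wf[wf].append((s, t))
    return [
        WorkflowGraph.from_parts(wf, per_wf_nodes[wf], per_wf[wf])
        for wf in sorted(per_wf)
    ]


def read_workflow_file(path) -> WorkflowGraph:
    with open(path, encoding="utf-8") as fh:
        return parse_workflow(fh.read())


# -- sequence extraction ---------------------------------------------------


def enumerate_linear_sequences(graph: WorkflowGraph) -> list[ToolSequence]:
    """All maximal simple paths from an in-degree-0 to an out-degree-0 node.

    Only paths with at least two tools qualify; output is sorted
    lexicographically by the tool names along the path.
    """
    g = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(g):  # defensive; constructor validates
        raise WorkflowValidationError("cannot enumerate sequences of a cyclic graph")
    sources = [n for n in g.nodes if g.in_degree(n) == 0]
    sinks = {n for n in g.nodes if g.out_degree(n) == 0}
    paths: list[tuple[str, ...]] = []
    for s in sources:
        if s in sinks:
            continue  # isolated node: no length-2 path through it
        for path in nx.all_simple_paths(g, s, sinks):
            if len(path) >= 2:
                paths.append(tuple(path))
    paths.sort()
    return [ToolSequence(tools=p, source_workflow_id=graph.workflow_id) for p in paths]


def compute_corpus_stats(sequences: list[ToolSequence]) -> CorpusStats:
    """Length and frequency statistics over extracted tool sequences."""
    if not sequences:
        raise ValueError("cannot compute statistics of an empty sequence list")
    lengths = [len(s) for s in sequences]
    freq: Counter[str] = Counter()
    for s in sequences:
        freq.update(s.tools)
    return CorpusStats(
        n_workflows=len({s.source_workflow_id for s in sequences}),
        n_sequences=len(sequences),
        n_unique_sequences=len({s.tools for s in sequences}),
        n_unique_tools=len(freq),
        max_length=max(lengths),
        min_length=min(lengths),
        median_length=float(statistics.median(lengths)),
        per_tool_frequency=dict(sorted(freq.items())),
    )


# -- serialisation ---------------------------------------------------------


def serialize_edge_list(graph: WorkflowGraph, header: bool = True) -> str:
    """2-column TSV dialect; isolated nodes written as ``tool<TAB>`` rows."""
    lines = ["source_tool\ttarget_tool"] if header else []
    connected = {n for e in graph.edges for n in e}
    for s, t in graph.edges:
        lines.append(f"{s}\t{t}")
    for n in graph.nodes:
        if n not in connected:
            lines.append(f"{n}\t")
    return "\n".join(lines) + "\n"


def serialize_native(graph: WorkflowGraph) -> str:
    """Emit the native JSON dialect (steps with tool_id / input_connections)."""
    step_of = {tool: i for i, tool in enumerate(graph.nodes)}
    steps = {}
    for tool, i in step_of.items():
        inputs = {
            f"input{j}": {"id": step_of[s], "output_name": "output"}
            for j, (s, t) in enumerate(graph.edges)
            if t == tool
        }
        steps[str(i)] = {
            "id": i,
            "type": "tool",
            "tool_id": tool,
            "input_connections": inputs,
        }
    return json.dumps(
        {"a_galaxy_workflow": "true", "name": graph.workflow_id, "steps": steps},
        indent=1,
        sort_keys=True,
    )


def write_sequences_tsv(sequences: list[ToolSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sequences:
            fh.write(f"{s.source_workflow_id}\t{','.join(s.tools)}\n")


def read_sequences_tsv(path) -> list[ToolSequence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                wf, tools = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise WorkflowParseError(f"line {ln}: expected 2 columns") from exc
            out.append(ToolSequence(tools=tuple(tools.split(",")), source_workflow_id=wf))
    return out
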