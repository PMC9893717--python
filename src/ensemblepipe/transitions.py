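"""Ensemble activation sequences and directed transition graphs.

A transition happens when one ensemble's significant coactivity ends and
another's begins. Runs of consecutive flagged frames of one ensemble
collapse to a single activation event anchored at the run's first frame
(onset convention); the merged, frame-ordered event list defines a
directed graph whose edge weights count how often each ordered ensemble
pair occurred consecutively. Consecutive events of the same ensemble are
recorded as self-loops but excluded from transition totals and drawings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import networkx as nx
import numpy as np

from .coactivity import PeakSet

__all__ = [
    "ActivationSequence",
    "TransitionGraph",
    "activation_sequence",
    "build_transition_graph",
    "graph_metrics",
    "export_graph",
    "load_edge_list",
]


@dataclass(frozen=True)
class ActivationSequence:
    """Frame-ordered (frame, ensemble_id) activation onsets."""

    events: Tuple[Tuple[int, int], ...]
    n_ensembles: int

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.events]
        if any(b < a for a, b in zip(frames, frames[1:])):
            raise ValueError("event frames must be non-decreasing")
        for _, e in self.events:
            if not 0 <= e < self.n_ensembles:
                raise ValueError(f"ensemble id {e} out of range")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class TransitionGraph:
    """Directed, count-weighted graph of ensemble transitions."""

    edges: Mapping[Tuple[int, int], int]
    self_loop_counts: Mapping[int, int]
    n_ensembles: int

    @property
    def total_transitions(self) -> int:
        """Sum of edge counts; self-loops excluded."""
        return int(sum(self.edges.values()))

    @property
    def total_self_loops(self) -> int:
        return int(sum(self.self_loop_counts.values()))

    @property
    def max_edge_share(self) -> float:
        """Largest single edge count as a fraction of all transitions."""
        total = self.total_transitions
        if total == 0:
            return 0.0
        return max(self.edges.values()) / total

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_ensembles))
        for (a, b), count in sorted(self.edges.items()):
            g.add_edge(a, b, count=int(count))
        return g


def activation_sequence(peaksets: Mapping[int, PeakSet]) -> ActivationSequence:
    """Merge per-ensemble peak flags into one ordered activation sequence.

    Consecutive flagged frames of the same ensemble form one event at the
    run's first frame. Simultaneous onsets of distinct ensembles are
    ordered by ensemble id and reported via a warning.
    """
    if not peaksets:
        raise ValueError("need at least one PeakSet")
    n_ensembles = max(peaksets.keys()) + 1
    events: List[Tuple[int, int]] = []
    for cid in sorted(peaksets):
        flags = peaksets[cid].flags
        if flags.any():
            onsets = np.flatnonzero(flags & ~np.concatenate(([False], flags[:-1])))
            events.extend((int(t), int(cid)) for t in onsets)
    if not events:
        warnings.warn("all peak sets empty: empty activation sequence",
                      stacklevel=2)
        return ActivationSequence((), n_ensembles)
    events.sort()  # frame, then ensemble id
    frames = [f for f, _ in events]
    ties = len(frames) - len(set(frames))
    if ties:
        warnings.warn(
            f"{ties} simultaneous-onset tie(s) broken by ensemble id",
            stacklevel=2,
        )
    return ActivationSequence(tuple(events), n_ensembles)


def build_transition_graph(sequence: ActivationSequence) -> TransitionGraph:
    """Count consecutive ordered pairs of the activation sequence."""
    edges: Dict[Tuple[int, int], int] = {}
    loops: Dict[int, int] = {}
    labels = [e for _, e in sequence.events]
    for a, b in zip(labels[:-1], labels[1:]):
        if a == b:
            loops[a] = loops.get(a, 0) + 1
        else:
            edges[(a, b)] = edges.get((a, b), 0) + 1
    return TransitionGraph(edges, loops, sequence.n_ensembles)


def graph_metrics(graph: TransitionGraph) -> dict:
    """Summary: node/edge counts, total transitions, max-edge share."""
    return {
        "n_nodes": graph.n_ensembles,
        "n_distinct_edges": len(graph.edges),
        "total_transitions": graph.total_transitions,
        "total_self_loops": graph.total_self_loops,
        "max_edge_share": graph.max_edge_share,
    }


def export_graph(graph: TransitionGraph, format: str, path) -> None:
    """Write the transition graph as edge-list, DOT, or GraphML."""
    if format == "edge-list":
        # self-loops appear as from==to rows so the file round-trips fully
        lines = ["# from\tto\tcount"]
        for (a, b), count in sorted(graph.edges.items()):
            lines.append(f"{a}\t{b}\t{count}")
        for a, count in sorted(graph.self_loop_counts.items()):
            lines.append(f"{a}\t{a}\t{count}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "DOT":
        lines = ["digraph transitions {"]
        for node in range(graph.n_ensembles):
            lines.append(f'  e{node} [label="ensemble {node}"];')
        for (a, b), count in sorted(graph.edges.items()):
            lines.append(f"  e{a} -> e{b} [count={count}, penwidth={count}];")
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "GraphML":
        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def load_edge_list(path, n_ensembles: int) -> TransitionGraph:
    """Re-import an edge-list file written by :func:`export_graph`."""
    edges: Dict[Tuple[int, int], int] = {}
    loops: Dict[int, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, count = (int(x) for x in line.split("\t"))
            if a == b:
                loops[a] = count
            else:
                edges[(a, b)] = count
    return TransitionGraph(edges, loops, n_ensembles)
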