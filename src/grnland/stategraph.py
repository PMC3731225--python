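"""Discretised cell-state dynamics: binarised trajectories and state graphs.

A stochastic trajectory is reduced to bit patterns: each gene is called
high (1) or low (0) against the cutoff ``(max - min)/2 + min`` of its own
trace.  Projecting onto the marker genes turns every snapshot into a cell
state code; occupancy fractions of the codes and the fractions of
consecutive code changes give a probability-weighted transition graph of
the differentiation/reprogramming dynamics, which can be exported for
Cytoscape-style rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .langevin import Trajectory

__all__ = [
    "BinaryTrajectory",
    "StateGraph",
    "binarize",
    "project_markers",
    "build_state_graph",
    "export_graph",
]


@dataclass
class BinaryTrajectory:
    cutoffs: np.ndarray
    codes: np.ndarray  # (n_records, n_genes) of uint8
    gene_ids: list[int] | None = None  # 1-based ids of the columns

    def code_strings(self) -> list[str]:
        return ["".join(str(int(b)) for b in row) for row in self.codes]


@dataclass
class StateGraph:
    states: dict[str, float]
    transitions: dict[tuple[str, str], float]
    hamming_stem: dict[str, int] = field(default_factory=dict)
    hamming_diff: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def binarize(traj: Trajectory, cutoffs: np.ndarray | None = None) -> BinaryTrajectory:
    """Binarise each gene trace against ``(max - min)/2 + min``.

    Values exactly at the cutoff are called high.  A constant gene (its
    trace never moves) is flagged with a warning and coded 0 throughout.
    """
    states = traj.states
    if states.size == 0:
        raise ValueError("empty trajectory")
    if cutoffs is None:
        mx = states.max(axis=0)
        mn = states.min(axis=0)
        cutoffs = (mx - mn) / 2.0 + mn
        constant = mx == mn
    else:
        cutoffs = np.asarray(cutoffs, dtype=float)
        constant = np.zeros(states.shape[1], dtype=bool)
    codes = (states >= cutoffs).astype(np.uint8)
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) coded low", RuntimeWarning
        )
        codes[:, constant] = 0
    return BinaryTrajectory(
        cutoffs=cutoffs, codes=codes, gene_ids=list(range(1, states.shape[1] + 1))
    )


def project_markers(btraj: BinaryTrajectory, marker_ids: list[int]) -> BinaryTrajectory:
    """Keep only the marker-gene columns, in the given (1-based id) order."""
    if not marker_ids:
        raise ValueError("marker id list is empty")
    ids = btraj.gene_ids or list(range(1, btraj.codes.shape[1] + 1))
    pos = {g: i for i, g in enumerate(ids)}
    try:
        cols = [pos[m] for m in marker_ids]
    except KeyError as exc:
        raise KeyError(f"marker id {exc.args[0]} not in trajectory") from exc
    return BinaryTrajectory(
        cutoffs=btraj.cutoffs[cols],
        codes=btraj.codes[:, cols],
        gene_ids=list(marker_ids),
    )


def build_state_graph(
    btraj: BinaryTrajectory,
    prob_cutoff: float = 0.0002,
    stem_code: str | None = None,
    diff_code: str | None = None,
    conditional: bool = False,
) -> StateGraph:
    """Occupancy-weighted cell-state transition graph.

    State probability is the occupancy fraction of each code.  Transition
    probability is, by default, the joint fraction of consecutive snapshot
    pairs with differing codes (self-loops excluded from the edge
    statistics); with ``conditional=True`` it is normalised per source
    state instead.  States below ``prob_cutoff`` are dropped, and
    transitions are kept only between kept states and if above the cutoff
    themselves.  Each kept state is annotated with its Hamming distance to
    the stem and differentiated reference codes when given.
    """
    if not 0 <= prob_cutoff < 1:
        raise ValueError("prob_cutoff must lie in [0, 1)")
    codes = btraj.code_strings()
    if not codes:
        raise ValueError("empty trajectory")
    n = len(codes)
    occ: dict[str, int] = {}
    for c in codes:
        occ[c] = occ.get(c, 0) + 1
    probs = {c: cnt / n for c, cnt in occ.items()}

    pair_counts: dict[tuple[str, str], int] = {}
    n_moves = 0
    for a, b in zip(codes[:-1], codes[1:]):
        if a == b:
            continue
        pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        n_moves += 1
    if conditional:
        src_tot: dict[str, int] = {}
        for (a, _), cnt in pair_counts.items():
            src_tot[a] = src_tot.get(a, 0) + cnt
        trans = {k: cnt / src_tot[k[0]] for k, cnt in pair_counts.items()}
    else:
        trans = (
            {k: cnt / n_moves for k, cnt in pair_counts.items()} if n_moves else {}
        )

    kept = {c: p for c, p in probs.items() if p >= prob_cutoff}
    kept_trans = {
        (a, b): p
        for (a, b), p in trans.items()
        if a in kept and b in kept and p >= prob_cutoff
    }

    def ham(c, ref):
        return sum(1 for x, y in zip(c, ref) if x != y)

    return StateGraph(
        states=kept,
        transitions=kept_trans,
        hamming_stem={c: ham(c, stem_code) for c in kept} if stem_code else {},
        hamming_diff={c: ham(c, diff_code) for c in kept} if diff_code else {},
        meta={
            "prob_cutoff": prob_cutoff,
            "edge_statistic": "conditional" if conditional else "joint",
            "self_transitions": "excluded",
            "n_snapshots": n,
        },
    )


def export_graph(g: StateGraph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML (lossless), SIF or TSV (lossy)."""
    if not g.states:
        raise ValueError("empty state graph")
    if format == "graphml":
        G = nx.DiGraph()
        for c, p in g.states.items():
            G.add_node(
                c,
                probability=float(p),
                hamming_stem=int(g.hamming_stem.get(c, -1)),
                hamming_diff=int(g.hamming_diff.get(c, -1)),
            )
        for (a, b), p in g.transitions.items():
            G.add_edge(a, b, weight=float(p))
        nx.write_graphml(G, path)
    elif format == "sif":
        lines = [f"{a}\ttransition\t{b}" for (a, b) in g.transitions]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "tsv":
        from pathlib import Path

        lines = ["# kind\tsource\ttarget\tprobability"]
        for c, p in g.states.items():
            lines.append(f"state\t{c}\t\t{p:.8g}")
        for (a, b), p in g.transitions.items():
            lines.append(f"transition\t{a}\t{b}\t{p:.8g}")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (graphml, sif, tsv)")
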