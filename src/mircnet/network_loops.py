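"""Signed directed regulatory network assembly and loop-motif analysis.

Sign conventions: miRNAs repress their targets (−1) and TFs activate
theirs (+1), unless a curated regulation record says otherwise.  A feedback
loop (FBL) is a simple directed cycle, positive when its repression-edge
count is even; a feed-forward loop (FFL) is a triple X→Y, Y→Z, X→Z,
coherent when sign(X→Z) equals sign(X→Y)·sign(Y→Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

ACTIVATION, REPRESSION = 1, -1

CATEGORIES = ("mirna_target", "tf_mirna", "tf_gene")
EVIDENCE_LEVELS = ("predicted", "validated", "both")

# roles implied by an edge's category, as (src role, dst role)
_CATEGORY_ROLES = {
    "mirna_target": ("mirna", "target"),
    "tf_mirna": ("tf", "mirna"),
    "tf_gene": ("tf", "target"),
}


@dataclass(frozen=True)
class SignedEdge:
    """A directed regulation with sign (+1 activation / −1 repression)."""

    src: str
    dst: str
    sign: int
    category: str
    evidence: str = "validated"

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"self-loop {self.src} -> {self.dst} not allowed")
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence {self.evidence!r}")


@dataclass
class RegNetwork:
    """Node roles plus a set of signed edges, one per ordered (src, dst)."""

    nodes: dict[str, frozenset[str]] = field(default_factory=dict)
    edges: list[SignedEdge] = field(default_factory=list)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node, roles in self.nodes.items():
            g.add_node(node, roles=roles)
        for e in self.edges:
            g.add_edge(
                e.src, e.dst, sign=e.sign, category=e.category, evidence=e.evidence
            )
        return g

    def edge_dict(self) -> dict[tuple[str, str], SignedEdge]:
        return {(e.src, e.dst): e for e in self.edges}

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, roles in self.nodes.items() if role in roles}


@dataclass
class FeedbackLoop:
    cycle: tuple[str, ...]  # node order; edge i goes cycle[i] -> cycle[i+1 mod L]
    sign: str  # "positive" | "negative"


@dataclass
class FeedForwardLoop:
    regulator: str  # X
    intermediate: str  # Y
    target: str  # Z
    coherent: bool
    contains_mirna: bool


class SignConflictError(ValueError):
    """Contradictory explicit signs were supplied for one (src, dst) pair."""


# ---------------------------------------------------------------------------
# assembly


def _merge_evidence(a: str, b: str) -> str:
    if a == b:
        return a
    return "both"


def assemble_network(
    edge_sets: Sequence[Iterable[SignedEdge]],
    overrides: Iterable | None = None,
) -> RegNetwork:
    """Merge edge lists into one network, applying sign overrides.

    Default signs (mirna_target → −1, tf_* → +1) are assumed already set on
    the incoming edges by their producers; ``overrides`` (records with
    ``tf``, ``mirna`` and ``sign`` attributes, e.g. curated TF–miRNA
    regulations) replace the sign of matching (tf → mirna) edges.
    Duplicate (src, dst) pairs merge: category must agree (a pair cannot be
    both a miRNA-target and a TF edge), evidence combines
    validated+predicted → both.  Contradictory explicit signs raise
    :class:`SignConflictError`.
    """
    explicit: dict[tuple[str, str], int] = {}
    for rec in overrides or []:
        tf = rec.tf if hasattr(rec, "tf") else rec["tf"]
        mirna = rec.mirna if hasattr(rec, "mirna") else rec["mirna"]
        sign = rec.sign if hasattr(rec, "sign") else rec["sign"]
        sign = _coerce_sign(sign)
        key = (tf, mirna)
        if key in explicit and explicit[key] != sign:
            raise SignConflictError(
                f"contradictory explicit signs for edge {key}"
            )
        explicit[key] = sign

    merged: dict[tuple[str, str], SignedEdge] = {}
    for edges in edge_sets:
        for e in edges:
            key = (e.src, e.dst)
            if key in explicit:
                e = replace(e, sign=explicit[key])
            if key in merged:
                prev = merged[key]
                if prev.category != e.category:
                    raise ValueError(
                        f"edge {key} arises under two categories "
                        f"({prev.category}, {e.category})"
                    )
                if prev.sign != e.sign:
                    raise SignConflictError(
                        f"contradictory signs for edge {key}: "
                        f"{prev.sign:+d} vs {e.sign:+d}"
                    )
                merged[key] = replace(
                    prev, evidence=_merge_evidence(prev.evidence, e.evidence)
                )
            else:
                merged[key] = e

    nodes: dict[str, set[str]] = {}
    for e in merged.values():
        src_role, dst_role = _CATEGORY_ROLES[e.category]
        nodes.setdefault(e.src, set()).add(src_role)
        nodes.setdefault(e.dst, set()).add(dst_role)
    return RegNetwork(
        nodes={n: frozenset(r) for n, r in nodes.items()},
        edges=sorted(merged.values(), key=lambda e: (e.src, e.dst)),
    )


def _coerce_sign(sign) -> int:
    if isinstance(sign, str):
        s = sign.strip().lower()
        if s in ("activation", "+1", "+"):
            return ACTIVATION
        if s in ("repression", "-1", "-"):
            return REPRESSION
        raise ValueError(f"unknown sign {sign!r}")
    if sign in (ACTIVATION, REPRESSION):
        return int(sign)
    raise ValueError(f"unknown sign {sign!r}")


def network_summary(net: RegNetwork) -> dict:
    """Node totals (by role, dual-role nodes counted once in the total)
    and edge counts by category."""
    by_role = {
        role: len(net.nodes_with_role(role)) for role in ("mirna", "tf", "target")
    }
    dual = len(net.nodes_with_role("tf") & net.nodes_with_role("target"))
    by_cat = {c: 0 for c in CATEGORIES}
    for e in net.edges:
        by_cat[e.category] += 1
    return {
        "n_nodes": len(net.nodes),
        "nodes_by_role": by_role,
        "n_tf_also_target": dual,
        "n_edges": len(net.edges),
        "edges_by_category": by_cat,
    }


# ---------------------------------------------------------------------------
# loop motifs


def find_feedback_loops(net: RegNetwork, max_len: int = 2) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= max_len, sign by parity.

    The default length 2 targets mutual-regulation loops (TF activates or
    represses a miRNA which represses the TF back); longer cycles are
    enumerated with networkx's bounded simple-cycle search.
    """
    g = net.graph()
    ed = net.edge_dict()
    loops = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        if len(cycle) < 2:
            continue
        n_repress = sum(
            ed[(cycle[i], cycle[(i + 1) % len(cycle)])].sign == REPRESSION
            for i in range(len(cycle))
        )
        # canonical rotation so output order is stable
        k = min(range(len(cycle)), key=lambda i: cycle[i])
        canon = tuple(cycle[k:] + cycle[:k])
        loops.append(
            FeedbackLoop(
                cycle=canon, sign="positive" if n_repress % 2 == 0 else "negative"
            )
        )
    loops.sort(key=lambda l: l.cycle)
    return loops


def find_feedforward_loops(net: RegNetwork) -> list[FeedForwardLoop]:
    """Every ordered distinct triple (X, Y, Z) with X→Y, Y→Z and X→Z.

    Coherent iff the direct edge's sign equals the product of the indirect
    path's signs; ``contains_mirna`` is true when any participant carries
    the mirna role.
    """
    ed = net.edge_dict()
    succ: dict[str, list[str]] = {}
    for (src, dst) in ed:
        succ.setdefault(src, []).append(dst)
    out = []
    for x, ys in succ.items():
        for y in ys:
            for z in succ.get(y, ()):
                if z == x or (x, z) not in ed:
                    continue
                direct = ed[(x, z)].sign
                indirect = ed[(x, y)].sign * ed[(y, z)].sign
                out.append(
                    FeedForwardLoop(
                        regulator=x,
                        intermediate=y,
                        target=z,
                        coherent=direct == indirect,
                        contains_mirna=any(
                            "mirna" in net.nodes.get(n, frozenset())
                            for n in (x, y, z)
                        ),
                    )
                )
    out.sort(key=lambda f: (f.regulator, f.intermediate, f.target))
    return out
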