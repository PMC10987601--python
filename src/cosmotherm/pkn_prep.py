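"""Prior-knowledge-network filtering before optimization.

Four removal-only filters applied in sequence: keep only expressed nodes,
prune nodes more than a fixed number of directed steps from any input,
remove activity/abundance sign-incoherent edges, and drop inputs that no
longer appear in the network.  Each filter is idempotent and only ever
shrinks the edge set.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable

import pandas as pd

from .core_io import InputNodeSet, PKN

log = logging.getLogger("cosmotherm")


def filter_by_expression(pkn: PKN, expressed: set[str]) -> PKN:
    """Keep edges whose endpoints are both in the expressed-node set."""
    if not expressed:
        raise ValueError("expressed set is empty")
    kept = frozenset(e for e in pkn.edges
                     if e[0] in expressed and e[2] in expressed)
    out = PKN(kept)
    log.info("filter_by_expression: %d -> %d edges, %d -> %d nodes",
             len(pkn), len(out), len(pkn.nodes), len(out.nodes))
    return out


def _bfs_within(adj: dict[str, set[str]], sources: Iterable[str],
                max_steps: int) -> set[str]:
    seen = {s: 0 for s in sources}
    queue = deque(seen)
    while queue:
        v = queue.popleft()
        if seen[v] >= max_steps:
            continue
        for w in adj.get(v, ()):
            if w not in seen:
                seen[w] = seen[v] + 1
                queue.append(w)
    return set(seen)


def prune_by_distance(pkn: PKN, inputs: InputNodeSet,
                      max_steps: int = 7) -> PKN:
    """Remove nodes more than ``max_steps`` directed edges away from any input.

    A node survives if it lies within ``max_steps`` steps downstream of an
    upstream-role input (kinase or TPP) or within ``max_steps`` steps upstream
    of a downstream-role input (TF or TPP); the induced subgraph is returned.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    nodes = pkn.nodes
    upstream = [e.node for e in inputs if e.role in ("kinase", "tpp")
                and e.node in nodes]
    downstream = [e.node for e in inputs if e.role in ("tf", "tpp")
                  and e.node in nodes]
    if not upstream and not downstream:
        raise ValueError("no input node present in the PKN")

    fwd: dict[str, set[str]] = {}
    rev: dict[str, set[str]] = {}
    for s, _, t in pkn.edges:
        fwd.setdefault(s, set()).add(t)
        rev.setdefault(t, set()).add(s)
    keep = _bfs_within(fwd, upstream, max_steps) \
        | _bfs_within(rev, downstream, max_steps)
    kept = frozenset(e for e in pkn.edges if e[0] in keep and e[2] in keep)
    out = PKN(kept)
    log.info("prune_by_distance(%d): %d -> %d edges, %d -> %d nodes",
             max_steps, len(pkn), len(out), len(pkn.nodes), len(out.nodes))
    return out


def coherence_filter(pkn: PKN, regulators: InputNodeSet,
                     de: pd.DataFrame) -> PKN:
    """Remove edges from signed regulators to significantly changed targets
    whose fold-change sign contradicts the propagated sign.

    For an edge ``r -> g`` with regulator sign ``a`` and edge sign ``b``, the
    edge is dropped iff ``g`` has a significant differential result and
    ``a * b * sign(log2fc_g) == -1``.  Unsigned regulators and
    unmeasured/non-significant targets are out of the rule's scope.
    """
    rsign = {e.node: e.sign for e in regulators if e.sign is not None}
    sig = de[de["significant"] & (de["log2fc"] != 0)]
    tsign = {str(r.feature): (1 if r.log2fc > 0 else -1)
             for r in sig.itertuples()}
    removed = {e for e in pkn.edges
               if e[0] in rsign and e[2] in tsign
               and rsign[e[0]] * e[1] * tsign[e[2]] == -1}
    out = PKN(frozenset(pkn.edges - removed))
    log.info("coherence_filter: removed %d incoherent edge(s)", len(removed))
    return out


def drop_missing_inputs(inputs: InputNodeSet, pkn: PKN) -> InputNodeSet:
    """Drop inputs that appear in no PKN edge (logged per role)."""
    nodes = pkn.nodes
    kept = [e for e in inputs if e.node in nodes]
    for role in ("kinase", "tf", "tpp"):
        n_drop = sum(1 for e in inputs
                     if e.role == role and e.node not in nodes)
        if n_drop:
            log.info("drop_missing_inputs: dropped %d %s input(s) absent "
                     "from the PKN", n_drop, role)
    if not kept:
        raise ValueError("all input nodes are absent from the PKN; "
                         "nothing to optimize")
    return InputNodeSet.build(kept)
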