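"""Sign-consistent subnetwork extraction by integer linear programming.

The optimizer selects a small, acyclic, sign-consistent subnetwork of the
prior knowledge network that connects upstream perturbed nodes (kinases and
thermally shifted proteins with a known direction) to downstream measurements
(transcription-factor activities, and in the second round also signed TPP
proteins).  Each node ``v`` has binary up/down state variables ``x+_v, x-_v``;
each edge ``e = (s, sigma, t)`` has binary signal carriers ``y+_e, y-_e``
gated by the source state and the edge sign; integer node depths enforce
acyclicity of the carrier subgraph.  The objective trades measurement
mismatches against a node-sparsity penalty ``beta``, minus inclusion bonuses
for sign-unknown TPP nodes:

    min  sum_{v in M} w_v * mismatch_v
         + beta * sum_v (x+_v + x-_v)
         - sum_{v in B} b_v * (x+_v + x-_v)

The MILP is solved with HiGHS through :func:`scipy.optimize.milp`; a
brute-force enumerator over node-state assignments serves as an exact oracle
on small instances.  ``run_cosmos_tpp`` orchestrates the two optimization
rounds, the between-round incoherent-edge filter, and the final merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .config import Config
from .core_io import CausalNetwork, InputNodeSet, PKN

log = logging.getLogger("cosmotherm")


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

@dataclass
class IlpProblem:
    """A sign-consistent subnetwork selection problem.

    ``upstream_signs`` maps upstream nodes to their locked sign (``None`` for
    sign-unknown upstream TPP nodes, which need no support but have no lock);
    ``measured`` maps downstream nodes to ``(target_sign, weight)``; ``bonus``
    maps sign-unknown TPP nodes to their inclusion bonus.
    """

    nodes: list[str]
    edges: list[tuple[str, int, str]]
    upstream_signs: dict[str, int | None]
    measured: dict[str, tuple[int, float]]
    bonus: dict[str, float]
    beta: float = 0.2

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        overlap = set(self.upstream_signs) & set(self.measured)
        if overlap:
            raise ValueError("a node cannot be upstream and measured in the "
                             f"same problem: {sorted(overlap)}")
        for v, b in self.bonus.items():
            if b >= self.beta:
                log.warning("bonus %.3g for %s >= beta %.3g: node is free to "
                            "include", b, v, self.beta)

    @property
    def empty_objective(self) -> float:
        """Objective of the all-inactive solution."""
        return float(sum(w for _, w in self.measured.values()))


def build_ilp(pkn: PKN, upstream: InputNodeSet, downstream: InputNodeSet,
              beta: float = 0.2) -> IlpProblem:
    """Assemble an :class:`IlpProblem` from a PKN and input node sets.

    Signed upstream entries get a sign lock; sign-unknown (TPP) upstream
    entries enter the upstream set without a lock and receive their weight as
    an inclusion bonus.  Signed downstream entries become weighted
    measurements; sign-unknown downstream entries become bonus nodes only.
    """
    if not len(upstream) or not len(downstream):
        raise ValueError("upstream and downstream sets must be non-empty")
    nodes = sorted(pkn.nodes)
    node_set = set(nodes)
    upstream_signs: dict[str, int | None] = {}
    bonus: dict[str, float] = {}
    measured: dict[str, tuple[int, float]] = {}
    for e in upstream:
        if e.node not in node_set:
            continue
        upstream_signs[e.node] = e.sign
        if e.sign is None:
            bonus[e.node] = e.weight
    for e in downstream:
        if e.node not in node_set or e.node in upstream_signs:
            continue
        if e.sign is None:
            bonus[e.node] = e.weight
        else:
            measured[e.node] = (e.sign, e.weight)
    return IlpProblem(nodes=nodes, edges=sorted(pkn.edges),
                      upstream_signs=upstream_signs, measured=measured,
                      bonus=bonus, beta=beta)


# ---------------------------------------------------------------------------
# MILP solve
# ---------------------------------------------------------------------------

def _objective_terms(problem: IlpProblem) -> tuple[np.ndarray, float]:
    """Linear objective coefficients over (x+, x-) per node, plus constant."""
    n = len(problem.nodes)
    c = np.zeros(2 * n)
    const = 0.0
    for i, v in enumerate(problem.nodes):
        c[2 * i] += problem.beta
        c[2 * i + 1] += problem.beta
        if v in problem.measured:
            m_hat, w = problem.measured[v]
            const += w
            if m_hat == 1:
                c[2 * i] -= w
                c[2 * i + 1] += w
            else:
                c[2 * i] += w
                c[2 * i + 1] -= w
        if v in problem.bonus:
            c[2 * i] -= problem.bonus[v]
            c[2 * i + 1] -= problem.bonus[v]
    return c, const


def solve(problem: IlpProblem, mip_gap: float = 0.0,
          time_limit: float | None = None) -> CausalNetwork:
    """Solve the MILP with HiGHS and extract the active subnetwork."""
    nodes, edges = problem.nodes, problem.edges
    n, m = len(nodes), len(edges)
    N = max(n, 1)
    idx = {v: i for i, v in enumerate(nodes)}
    # variable layout: [x+_v, x-_v]*n, [y+_e, y-_e]*m, [d_v]*n
    nx_, ny = 2 * n, 2 * m
    nvar = nx_ + ny + n

    def xp(v):
        return 2 * idx[v]

    def xm(v):
        return 2 * idx[v] + 1

    def yp(j):
        return nx_ + 2 * j

    def ym(j):
        return nx_ + 2 * j + 1

    def dv(v):
        return nx_ + ny + idx[v]

    rows, cols, vals, ub = [], [], [], []

    def add_row(entries, upper):
        r = len(ub)
        for c_, v_ in entries:
            rows.append(r)
            cols.append(c_)
            vals.append(v_)
        ub.append(upper)

    for v in nodes:                                   # x+ + x- <= 1
        add_row([(xp(v), 1.0), (xm(v), 1.0)], 1.0)
    incoming: dict[str, list[int]] = {v: [] for v in nodes}
    for j, (s, sign, t) in enumerate(edges):
        incoming[t].append(j)
        if sign == 1:                                 # carrier gating
            add_row([(yp(j), 1.0), (xp(s), -1.0)], 0.0)
            add_row([(ym(j), 1.0), (xm(s), -1.0)], 0.0)
        else:
            add_row([(yp(j), 1.0), (xm(s), -1.0)], 0.0)
            add_row([(ym(j), 1.0), (xp(s), -1.0)], 0.0)
        add_row([(yp(j), 1.0), (ym(j), 1.0)], 1.0)    # y+ + y- <= 1
        # acyclicity: d_s - d_t + N*(y+ + y-) <= N - 1
        add_row([(dv(s), 1.0), (dv(t), -1.0), (yp(j), float(N)),
                 (ym(j), float(N))], float(N - 1))
    for t in nodes:                                   # activation support
        if t in problem.upstream_signs:
            continue
        add_row([(xp(t), 1.0)] + [(yp(j), -1.0) for j in incoming[t]], 0.0)
        add_row([(xm(t), 1.0)] + [(ym(j), -1.0) for j in incoming[t]], 0.0)

    lb_var = np.zeros(nvar)
    ub_var = np.ones(nvar)
    ub_var[nx_ + ny:] = float(N)                      # depths in [0, N]
    for v, sign in problem.upstream_signs.items():    # sign locks
        if sign == 1:
            ub_var[xm(v)] = 0.0
        elif sign == -1:
            ub_var[xp(v)] = 0.0

    c = np.zeros(nvar)
    c_x, const = _objective_terms(problem)
    c[:nx_] = c_x

    A = sparse.csc_matrix((vals, (rows, cols)), shape=(len(ub), nvar))
    constraints = LinearConstraint(A, -np.inf, np.asarray(ub))
    integrality = np.ones(nvar)
    options: dict[str, object] = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c=c, constraints=constraints,
               bounds=Bounds(lb_var, ub_var), integrality=integrality,
               options=options)
    if res.x is None:
        raise RuntimeError("MILP solver returned no incumbent; try a larger "
                           "time_limit")
    x = np.round(res.x).astype(int)

    node_state: dict[str, int] = {}
    for v in nodes:
        if x[xp(v)] == 1:
            node_state[v] = 1
        elif x[xm(v)] == 1:
            node_state[v] = -1
    net_edges: set[tuple[str, int, str, str]] = set()
    for j, (s, sign, t) in enumerate(edges):
        if s not in node_state or t not in node_state:
            continue
        carrier = (x[yp(j)] == 1 and node_state[t] == 1) or \
                  (x[ym(j)] == 1 and node_state[t] == -1)
        if carrier and node_state[s] * sign == node_state[t]:
            net_edges.add((s, sign, t, "run1"))
    used = {v for e in net_edges for v in (e[0], e[2])}
    # keep isolated active inputs/measurements out of the edge list but in the
    # state map only if they touch an edge
    node_state = {v: st for v, st in node_state.items()
                  if v in used or not net_edges}
    if not net_edges:
        node_state = {}
    objective = float(c @ x + const)
    return CausalNetwork(edges=net_edges, node_state=node_state,
                         objective_value=objective)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _assignment_objective(problem: IlpProblem,
                          state: dict[str, int]) -> float:
    obj = problem.beta * sum(1 for s in state.values() if s != 0)
    for v, (m_hat, w) in problem.measured.items():
        obj += w * (1 - m_hat * state.get(v, 0))
    for v, b in problem.bonus.items():
        if state.get(v, 0) != 0:
            obj -= b
    return obj


def _support_closure(problem: IlpProblem, state: dict[str, int]
                     ) -> tuple[bool, list[tuple[str, int, str]]]:
    """Check that every active non-upstream node can be supported through an
    acyclic cascade; returns (feasible, supporting edge list)."""
    active = {v for v, s in state.items() if s != 0}
    supported = {v for v in active if v in problem.upstream_signs}
    pending = active - supported
    support_edges: list[tuple[str, int, str]] = []
    changed = True
    while changed and pending:
        changed = False
        for t in sorted(pending):
            for (s, sign, tt) in problem.edges:
                if tt != t or s not in supported:
                    continue
                if state[s] * sign == state[t]:
                    supported.add(t)
                    support_edges.append((s, sign, t))
                    changed = True
                    break
            pending = active - supported
    return not pending, support_edges


def brute_force_solve(problem: IlpProblem) -> CausalNetwork:
    """Exhaustive enumeration over node-state assignments (|V| <= 14)."""
    nodes = problem.nodes
    if len(nodes) > 14:
        raise ValueError("brute force is limited to 14 nodes")
    domains = []
    for v in nodes:
        if v in problem.upstream_signs and problem.upstream_signs[v] is not None:
            domains.append((0, problem.upstream_signs[v]))
        else:
            domains.append((0, 1, -1))

    best_obj = np.inf
    best_state: dict[str, int] = {}
    best_edges: list[tuple[str, int, str]] = []

    def rec(i: int, state: dict[str, int]) -> None:
        nonlocal best_obj, best_state, best_edges
        if i == len(nodes):
            feasible, edges = _support_closure(problem, state)
            if not feasible:
                return
            obj = _assignment_objective(problem, state)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_state = {v: s for v, s in state.items() if s != 0}
                best_edges = edges
            return
        for s in domains[i]:
            state[nodes[i]] = s
            rec(i + 1, state)
        del state[nodes[i]]

    rec(0, {})
    edges = {(s, g, t, "run1") for s, g, t in best_edges}
    used = {v for e in edges for v in (e[0], e[2])}
    state = {v: s for v, s in best_state.items() if v in used} if edges else {}
    return CausalNetwork(edges=edges, node_state=state,
                         objective_value=float(best_obj))


# ---------------------------------------------------------------------------
# invariant checker
# ---------------------------------------------------------------------------

def verify_causal_network(net: CausalNetwork,
                          upstream_nodes: set[str]) -> None:
    """Assert sign consistency, support, and acyclicity of a solution network.

    Every edge must propagate its source state to its target's state; every
    active node outside ``upstream_nodes`` must be supported through an
    acyclic cascade rooted in active upstream nodes.  Raises ``AssertionError``
    on violation.
    """
    import networkx as nx

    for s, sign, t, _ in net.edges:
        assert net.node_state[s] * sign == net.node_state[t], \
            f"sign-inconsistent edge {s}({net.node_state[s]})-{sign}->{t}"
    g = nx.DiGraph()
    g.add_nodes_from(net.node_state)
    g.add_edges_from((s, t) for s, _, t, _ in net.edges)
    assert nx.is_directed_acyclic_graph(g), "active-edge subgraph has a cycle"
    supported = {v for v in net.node_state if v in upstream_nodes}
    pending = set(net.node_state) - supported
    changed = True
    while changed and pending:
        changed = False
        for t in sorted(pending):
            for s, sign, tt, _ in net.edges:
                if tt == t and s in supported \
                        and net.node_state[s] * sign == net.node_state[t]:
                    supported.add(t)
                    changed = True
                    break
        pending = set(net.node_state) - supported
    assert not pending, f"unsupported active nodes: {sorted(pending)}"


# ---------------------------------------------------------------------------
# two-round orchestration
# ---------------------------------------------------------------------------

def _split_tpp(tpp_inputs: InputNodeSet) -> tuple[list, list]:
    signed = [e for e in tpp_inputs if e.sign is not None]
    unknown = [e for e in tpp_inputs if e.sign is None]
    return signed, unknown


def _one_run(pkn: PKN, upstream: InputNodeSet, downstream: InputNodeSet,
             cfg: Config) -> CausalNetwork | None:
    try:
        problem = build_ilp(pkn, upstream, downstream, beta=cfg.beta)
        return solve(problem, mip_gap=cfg.mip_gap, time_limit=cfg.time_limit)
    except (ValueError, RuntimeError) as err:
        log.warning("optimization round failed (%s); continuing", err)
        return None


def _incoherent_solution_edges(nets: list[CausalNetwork],
                               measured_signs: dict[str, int]
                               ) -> set[tuple[str, int, str]]:
    """Solution edges whose propagated sign contradicts the measured sign of
    their target (the between-round PKN filter)."""
    bad = set()
    for net in nets:
        for s, sign, t, _ in net.edges:
            if t in measured_signs \
                    and net.node_state[s] * sign != measured_signs[t]:
                bad.add((s, sign, t))
    return bad


def _merge_runs(net1: CausalNetwork | None,
                net2: CausalNetwork | None) -> CausalNetwork:
    """Union of the two final runs with duplicate edges collapsed.

    State conflicts are resolved toward the run with the lower objective;
    edges inconsistent with the resolved states are dropped, cycles introduced
    by the union are broken by removing edges of the higher-objective run, and
    unsupported remnants are pruned (all logged).
    """
    runs = [(n, lbl) for n, lbl in ((net1, "run1"), (net2, "run2"))
            if n is not None]
    if not runs:
        return CausalNetwork(edges=set(), node_state={},
                             objective_value=float("nan"))
    runs.sort(key=lambda t: t[0].objective_value)
    state: dict[str, int] = {}
    for net, _ in runs:                # preferred (lower-objective) run first
        for v, s in net.node_state.items():
            if v in state and state[v] != s:
                log.info("merge: node-state conflict at %s resolved to %+d",
                         v, state[v])
            state.setdefault(v, s)
    merged: dict[tuple[str, int, str], list[str]] = {}
    preferred_label = runs[0][1]
    for net, lbl in runs:
        for s, sign, t, _ in net.edges:
            if state[s] * sign != state[t]:
                log.info("merge: dropping edge %s-%+d->%s inconsistent with "
                         "resolved states", s, sign, t)
                continue
            merged.setdefault((s, sign, t), [])
            if lbl not in merged[(s, sign, t)]:
                merged[(s, sign, t)].append(lbl)

    import networkx as nx
    g = nx.DiGraph((s, t) for s, _, t in merged)
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        drop = None
        for a, b in cycle:
            for (s, sign, t), labels in merged.items():
                if s == a and t == b and preferred_label not in labels:
                    drop = (s, sign, t)
                    break
            if drop:
                break
        if drop is None:  # cycle lies within one run's DAG plus merged dupes
            drop = next(k for k in sorted(merged) if k[0] == cycle[0][0]
                        and k[2] == cycle[0][1])
        log.info("merge: breaking cycle by dropping %s->%s", drop[0], drop[2])
        del merged[drop]
        g = nx.DiGraph((s, t) for s, _, t in merged)

    edges = {(s, sign, t, ";".join(sorted(lbls)))
             for (s, sign, t), lbls in merged.items()}
    used = {v for e in edges for v in (e[0], e[2])}
    state = {v: s for v, s in state.items() if v in used}
    total_obj = float(sum(n.objective_value for n, _ in runs))
    return CausalNetwork(edges=edges, node_state=state,
                         objective_value=total_obj)


def _prune_unsupported(net: CausalNetwork, upstream: set[str]) -> CausalNetwork:
    """Iteratively drop active nodes (and their edges) that lost support."""
    state = dict(net.node_state)
    edges = set(net.edges)
    while True:
        supported = {v for v in state if v in upstream}
        changed = True
        while changed:
            changed = False
            for s, sign, t, _ in edges:
                if s in supported and t not in supported \
                        and state[s] * sign == state[t]:
                    supported.add(t)
                    changed = True
        bad = set(state) - supported
        if not bad:
            break
        log.info("merge: pruning %d unsupported node(s)", len(bad))
        edges = {e for e in edges if e[0] not in bad and e[2] not in bad}
        state = {v: s for v, s in state.items() if v not in bad}
    used = {v for e in edges for v in (e[0], e[2])}
    state = {v: s for v, s in state.items() if v in used} if edges else {}
    if not edges:
        state = {}
    return CausalNetwork(edges=edges, node_state=state,
                         objective_value=net.objective_value)


def run_cosmos_tpp(pkn: PKN, kinases: InputNodeSet, tfs: InputNodeSet,
                   tpp_inputs: InputNodeSet,
                   config: Config | None = None) -> CausalNetwork:
    """Two-round optimization with between-round incoherence filtering.

    Round A uses kinases plus signed TPP proteins as upstream nodes and TFs as
    downstream measurements; round B uses kinases upstream and TFs plus signed
    TPP proteins downstream.  Sign-unknown TPP proteins participate as bonus
    nodes in both rounds (upstream, without a sign lock, in round A).  After
    both rounds, solution edges whose propagated sign contradicts the measured
    sign of their target are removed from the PKN and both rounds are
    repeated; the final network is the union of the repeated runs.
    """
    cfg = config or Config()
    signed_tpp, unknown_tpp = _split_tpp(tpp_inputs)
    kin_ids = kinases.node_ids

    def upstream_a() -> InputNodeSet:
        extra = [e for e in signed_tpp + unknown_tpp if e.node not in kin_ids]
        return InputNodeSet.build(list(kinases) + extra)

    def downstream_a() -> InputNodeSet:
        return InputNodeSet.build([e for e in tfs])

    def upstream_b() -> InputNodeSet:
        return kinases

    def downstream_b() -> InputNodeSet:
        extra = [e for e in signed_tpp + unknown_tpp if e.node not in kin_ids]
        return InputNodeSet.build(list(tfs) + extra)

    net_a = _one_run(pkn, upstream_a(), downstream_a(), cfg)
    net_b = _one_run(pkn, upstream_b(), downstream_b(), cfg)

    measured_signs = {e.node: e.sign for e in list(kinases) + list(tfs)
                      + signed_tpp if e.sign is not None}
    bad = _incoherent_solution_edges([n for n in (net_a, net_b) if n],
                                     measured_signs)
    if bad:
        log.info("between-round filter removed %d edge(s) from the PKN",
                 len(bad))
    pkn2 = PKN(frozenset(pkn.edges - bad))

    net_a2 = _one_run(pkn2, upstream_a(), downstream_a(), cfg)
    net_b2 = _one_run(pkn2, upstream_b(), downstream_b(), cfg)
    merged = _merge_runs(net_a2, net_b2)
    upstream_nodes = kin_ids | {e.node for e in tpp_inputs}
    final = _prune_unsupported(merged, upstream_nodes)
    verify_causal_network(final, upstream_nodes)
    return final
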