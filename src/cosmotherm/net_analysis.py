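"""Network-level enrichment, clustering and comparison.

Over-representation analysis (ORA) is a one-tailed Fisher exact test
(hypergeometric upper tail) of a query node set against a background, with
Haldane-corrected odds ratios and BH adjustment.  Communities come from
Clauset-Newman-Moore greedy modularity maximization on the sign- and
direction-collapsed simple graph; clusterings are compared with pairwise
Jaccard indices, and enrichment profiles of two networks are compared through
per-pathway log-odds-ratio differences with a rank-sum (or t) test between
pathway groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CausalNetwork
from .diffstats import bh_adjust

log = logging.getLogger("cosmotherm")

ENRICH_COLUMNS = ("pathway", "description", "k", "n", "K", "N",
                  "odds_ratio", "pvalue", "qvalue")


def _haldane_or(k: int, n: int, K: int, N: int) -> float:
    """Odds ratio of the 2x2 table with a 0.5 correction when any cell is 0."""
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def ora(query: set[str], background: set[str],
        db: Mapping[str, tuple[str, frozenset[str]]],
        min_size: int = 5, max_size: int = 500,
        alpha: float = 0.05) -> pd.DataFrame:
    """One-tailed Fisher exact over-representation of ``query`` in each
    pathway, against ``background``.

    Pathways are restricted to their background members; those with restricted
    size outside ``[min_size, max_size]`` are excluded.  Returns a dataframe
    with the ``ENRICH_COLUMNS`` schema sorted by p-value.
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not db:
        raise ValueError("empty pathway database")
    N = len(background)
    n = len(query)
    rows = []
    for pid in sorted(db):
        desc, members = db[pid]
        in_bg = members & background
        K = len(in_bg)
        if not min_size <= K <= max_size:
            continue
        k = len(in_bg & query)
        # upper tail: P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, desc, k, n, K, N, _haldane_or(k, n, K, N), p))
    df = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS
                                     if c != "qvalue"])
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    df["significant"] = df["qvalue"] < alpha if len(df) else []
    return df.sort_values(["pvalue", "pathway"], ignore_index=True)


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    modularity: float

    def members(self, cluster: int) -> set[str]:
        return {v for v, c in self.assignment.items() if c == cluster}

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))


def cluster_fast_greedy(net: CausalNetwork) -> ClusterAssignment:
    """Greedy modularity (Clauset-Newman-Moore) communities of the collapsed
    undirected simple graph (signs, directions, parallel edges dropped)."""
    if not net.edges:
        raise ValueError("cannot cluster an empty network")
    g = nx.Graph()
    for v in sorted(net.node_state):
        g.add_node(v)
    for s, _, t, _ in sorted(net.edges):
        if s != t:
            g.add_edge(s, t)
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges after collapsing")
    comms = nx.community.greedy_modularity_communities(g)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    assignment = {v: i + 1 for i, comm in enumerate(comms) for v in comm}
    q = nx.community.modularity(g, [set(c) for c in comms])
    return ClusterAssignment(assignment=assignment, modularity=float(q))


def jaccard_compare(a: ClusterAssignment,
                    b: ClusterAssignment) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B|/|A∪B| between the clusters of two
    assignments (rows = clusters of ``a``, columns = clusters of ``b``)."""
    mat = pd.DataFrame(index=a.cluster_ids, columns=b.cluster_ids,
                       dtype=float)
    for ca in a.cluster_ids:
        ma = a.members(ca)
        for cb in b.cluster_ids:
            mb = b.members(cb)
            union = ma | mb
            mat.loc[ca, cb] = len(ma & mb) / len(union) if union else 0.0
    return mat


def compare_network_enrichments(enr_a: pd.DataFrame, enr_b: pd.DataFrame,
                                pathway_groups: Mapping[str, str],
                                min_nodes: int = 4,
                                test: str = "wilcoxon"
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare two enrichment profiles through per-pathway log-odds-ratio
    differences.

    Pathways significant (q < 0.05) in either network and with at least
    ``min_nodes`` query nodes in one of them are retained; per pathway the
    difference ``delta = log(OR_A) - log(OR_B)`` is computed from the
    Haldane-corrected odds ratios, and each pair of pathway groups is compared
    with a two-sided Wilcoxon rank-sum test (``test="ttest"`` switches to
    Welch's t).  Returns ``(per-pathway table, per-group-pair test table)``.
    """
    a = enr_a.set_index("pathway")
    b = enr_b.set_index("pathway")
    shared = a.index.union(b.index)
    rows = []
    for pid in shared:
        in_a, in_b = pid in a.index, pid in b.index
        if not (in_a or in_b):
            continue
        sig = (in_a and bool(a.loc[pid, "significant"])) or \
              (in_b and bool(b.loc[pid, "significant"]))
        big = max(a.loc[pid, "k"] if in_a else 0,
                  b.loc[pid, "k"] if in_b else 0)
        if not sig or big < min_nodes:
            continue
        or_a = float(a.loc[pid, "odds_ratio"]) if in_a else np.nan
        or_b = float(b.loc[pid, "odds_ratio"]) if in_b else np.nan
        delta = np.log(or_a) - np.log(or_b)
        rows.append((pid, pathway_groups.get(pid, "other"),
                     np.log(or_a), np.log(or_b), delta))
    table = pd.DataFrame(rows, columns=["pathway", "group", "log_or_a",
                                        "log_or_b", "delta"])

    tests = []
    groups = sorted(table["group"].unique())
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            d1 = table.loc[table["group"] == g1, "delta"].dropna()
            d2 = table.loc[table["group"] == g2, "delta"].dropna()
            if len(d1) == 0 or len(d2) == 0:
                continue
            if d1.nunique() <= 1 and d2.nunique() <= 1 \
                    and set(d1.unique()) == set(d2.unique()):
                p = np.nan
            elif test == "wilcoxon":
                p = float(stats.ranksums(d1, d2).pvalue)
            elif test == "ttest":
                p = float(stats.ttest_ind(d1, d2, equal_var=False).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            tests.append((g1, g2, len(d1), len(d2),
                          float(d1.median() - d2.median()), p))
    test_table = pd.DataFrame(tests, columns=["group_a", "group_b", "n_a",
                                              "n_b", "median_delta_diff",
                                              "pvalue"])
    return table, test_table
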