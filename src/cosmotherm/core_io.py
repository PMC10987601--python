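"""Domain types and readers/writers for every file format the pipeline touches.

In-memory containers
--------------------
``OmicsMatrix``    features × samples measurement table with condition labels.
``PKN``            signed directed prior-knowledge interaction graph.
``Regulon``        a regulator with its signed, optionally weighted target set.
``TppProfile``     one protein's 2D thermal profile (temperature × dose).
``InputNodeSet``   upstream/downstream optimization inputs with signs/weights.
``CausalNetwork``  an optimized signed subnetwork with node activity states.

Differential results and activity scores are plain :class:`pandas.DataFrame`
objects with fixed column schemas (see ``DE_COLUMNS`` / the footprint module);
a dataframe is the natural lingua franca for tabular statistics here.

All files are TSV, UTF-8, decimal point, no quoting.  Gene-level node
identifiers are case-sensitive symbols; phosphosites use ``SYMBOL_S473``-style
identifiers whose protein is recovered by splitting at the last underscore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import DEFAULT_SIGN_ALIASES

log = logging.getLogger("cosmotherm")

MATRIX_KINDS = ("transcript_counts", "protein_log2", "phospho_log2")
DE_COLUMNS = ("feature", "log2fc", "stat", "pvalue", "qvalue", "significant")

#: 2D-TPP default axes: the twelve heat-challenge temperatures (deg C) and the
#: four drug doses (uM) plus the vehicle (0) of the assay design.
DEFAULT_TEMPERATURES = (42.1, 44.1, 46.2, 48.1, 50.4, 51.9,
                        54.0, 56.1, 58.2, 60.1, 62.4, 63.9)
DEFAULT_CONCENTRATIONS = (0.0, 0.4, 1.0, 4.0, 10.0)


def site_protein(site_id: str) -> str:
    """Protein symbol of a ``SYMBOL_S473``-style phosphosite id (identity for
    ids without an underscore)."""
    return site_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Features × samples numeric matrix with a condition label per sample."""

    values: pd.DataFrame
    sample_condition: dict[str, str]
    kind: str
    notes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_condition]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.sample_condition.values()) - {"treatment", "control"}
        if bad:
            raise ValueError(f"conditions must be treatment/control, got {bad}")
        if self.kind == "transcript_counts":
            vals = self.values.to_numpy()
            if np.isnan(vals).any() or (vals < 0).any():
                raise ValueError("transcript counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("transcript counts must be integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns
                if self.sample_condition[s] == condition]

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return replace(self, values=values)


@dataclass(frozen=True)
class PKN:
    """Signed directed interaction network; edges are (source, sign, target)."""

    edges: frozenset[tuple[str, int, str]]

    def __post_init__(self) -> None:
        for s, sign, t in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"invalid edge sign {sign!r} on {s}->{t}")
            if not s or not t:
                raise ValueError("node ids must be non-empty")
        loops = [e for e in self.edges if e[0] == e[2]]
        if loops:
            log.warning("PKN contains %d self-loop(s)", len(loops))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, int, str]]) -> "PKN":
        return cls(frozenset((str(s), int(g), str(t)) for s, g, t in edges))

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, _, t in self.edges:
            out.add(s)
            out.add(t)
        return out

    def to_digraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for s, sign, t in sorted(self.edges):
            g.add_edge(s, t, sign=sign)
        return g

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Regulon:
    """A regulator with its (target, mode, weight) triples."""

    regulator: str
    targets: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        ids = [t for t, _, _ in self.targets]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate targets in regulon {self.regulator}")
        for t, mode, w in self.targets:
            if mode not in (1, -1):
                raise ValueError(f"invalid mode {mode!r} for {self.regulator}->{t}")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"invalid weight {w!r} for {self.regulator}->{t}")


ROLES = ("kinase", "tf", "tpp")


@dataclass(frozen=True)
class InputNode:
    node: str
    role: str          # kinase | tf | tpp
    sign: int | None   # +1 / -1 / None (unknown; tpp only)
    weight: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.sign is None and self.role != "tpp":
            raise ValueError(f"sign=unknown only allowed for tpp ({self.node})")
        if self.sign is not None and self.sign not in (1, -1):
            raise ValueError(f"invalid sign {self.sign!r} for {self.node}")
        if not np.isfinite(self.weight) or not 0 <= self.weight <= 1:
            raise ValueError(f"weight must be in [0,1], got {self.weight!r}")


@dataclass(frozen=True)
class InputNodeSet:
    entries: tuple[InputNode, ...]

    def __post_init__(self) -> None:
        for role in ROLES:
            ids = [e.node for e in self.entries if e.role == role]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate node ids within role {role}")

    @classmethod
    def build(cls, entries: Iterable[InputNode]) -> "InputNodeSet":
        return cls(tuple(entries))

    def of_role(self, role: str) -> tuple[InputNode, ...]:
        return tuple(e for e in self.entries if e.role == role)

    @property
    def node_ids(self) -> set[str]:
        return {e.node for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class TppProfile:
    """Relative soluble abundance (treatment/vehicle ratio) of one protein on a
    temperature × concentration grid; the vehicle column (dose 0) is the
    normalisation reference and is identically 1 by construction."""

    protein: str
    temperatures: np.ndarray
    concentrations: np.ndarray
    rel_abundance: np.ndarray   # shape (T, C), linear-scale ratios

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if 0.0 not in self.concentrations:
            raise ValueError(f"{self.protein}: vehicle (dose 0) column missing")
        if self.rel_abundance.shape != (len(self.temperatures),
                                        len(self.concentrations)):
            raise ValueError(f"{self.protein}: matrix shape does not match axes")

    @property
    def vehicle_index(self) -> int:
        return int(np.where(self.concentrations == 0.0)[0][0])

    def log2_matrix(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.rel_abundance)


@dataclass
class CausalNetwork:
    """Optimized sign-consistent subnetwork.

    ``edges`` carry a round label (``run1``/``run2``; merged duplicates get
    ``"run1;run2"``); every edge endpoint has an activity state in
    ``node_state``.
    """

    edges: set[tuple[str, int, str, str]]
    node_state: dict[str, int]
    objective_value: float

    def __post_init__(self) -> None:
        for s, sign, t, _ in self.edges:
            if s not in self.node_state or t not in self.node_state:
                raise ValueError(f"edge {s}->{t} endpoint lacks a node state")
            if sign not in (1, -1):
                raise ValueError("edge signs must be +1/-1")
        for v, st in self.node_state.items():
            if st not in (1, -1):
                raise ValueError(f"node state must be +1/-1, got {st!r} for {v}")

    @property
    def nodes(self) -> set[str]:
        return set(self.node_state)

    def edge_triples(self) -> set[tuple[str, int, str]]:
        return {(s, g, t) for s, g, t, _ in self.edges}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_sign(token: str, aliases: Mapping[str, int]) -> int | None:
    return aliases.get(token.strip())


def read_pkn(path: str, sign_aliases: Mapping[str, int] | None = None) -> PKN:
    """Read a signed directed network from a 3-column TSV (source, sign, target).

    Extra columns (e.g. a round label written by :func:`write_network`) are
    ignored.  Duplicate triples are collapsed with a warning.
    """
    aliases = dict(DEFAULT_SIGN_ALIASES if sign_aliases is None else sign_aliases)
    edges: list[tuple[str, int, str]] = []
    n_dup = 0
    seen: set[tuple[str, int, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # optional header: first line whose sign column does not parse
    start = 0
    if lines and len(lines[0].split("\t")) >= 3 \
            and _parse_sign(lines[0].split("\t")[1], aliases) is None:
        start = 1
    body = [(i, ln) for i, ln in enumerate(lines[start:], start=start + 1)
            if ln.strip()]
    if not body:
        raise ValueError(f"{path}: no interaction rows")
    for lineno, line in body:
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: expected >=3 columns at line {lineno}")
        src, sign_tok, tgt = parts[0].strip(), parts[1], parts[2].strip()
        sign = _parse_sign(sign_tok, aliases)
        if sign is None:
            raise ValueError(f"{path}: invalid sign at line {lineno}: {sign_tok!r}")
        edge = (src, sign, tgt)
        if edge in seen:
            n_dup += 1
            continue
        seen.add(edge)
        edges.append(edge)
    if n_dup:
        log.warning("read_pkn(%s): dropped %d duplicate edge(s)", path, n_dup)
    pkn = PKN.from_edges(edges)
    log.info("read_pkn(%s): %d edges, %d nodes", path, len(pkn), len(pkn.nodes))
    return pkn


def read_matrix(path: str, kind: str,
                condition_map: Mapping[str, str]) -> OmicsMatrix:
    """Read a features × samples TSV (header = sample ids, first column =
    feature ids) into an :class:`OmicsMatrix` of the declared kind."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature ids {dups[:5]}")
    missing = [s for s in df.columns if s not in condition_map]
    if missing:
        raise ValueError(f"{path}: samples missing from condition map: {missing}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            where = f"feature {bad.index[0]!r}, sample {col!r}" if len(bad) else col
            raise ValueError(f"{path}: non-numeric cell at {where}")
    cond = {s: condition_map[s] for s in df.columns}
    return OmicsMatrix(values=df.astype(float), sample_condition=cond, kind=kind)


def read_gmt(path: str) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set collection into ``{id: (description, members)}``.

    Members are deduplicated; empty sets are dropped with a warning.
    """
    db: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} has <3 fields")
            name, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m.strip())
            if not members:
                log.warning("read_gmt(%s): dropping empty set %s", path, name)
                continue
            db[name] = (desc, members)
    return db


def read_regulons(path: str,
                  sign_aliases: Mapping[str, int] | None = None) -> list[Regulon]:
    """Read regulons from a TSV: regulator, target, mode, [weight]."""
    aliases = dict(DEFAULT_SIGN_ALIASES if sign_aliases is None else sign_aliases)
    groups: dict[str, dict[str, tuple[int, float]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and len(lines[0].split("\t")) >= 3 \
            and _parse_sign(lines[0].split("\t")[2], aliases) is None:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: expected >=3 columns at line {lineno}")
        reg, tgt = parts[0].strip(), parts[1].strip()
        mode = _parse_sign(parts[2], aliases)
        if mode is None:
            raise ValueError(f"{path}: invalid mode at line {lineno}: {parts[2]!r}")
        weight = float(parts[3]) if len(parts) > 3 and parts[3].strip() else 1.0
        groups.setdefault(reg, {})[tgt] = (mode, weight)
    return [Regulon(regulator=r,
                    targets=tuple((t, m, w) for t, (m, w) in sorted(tg.items())))
            for r, tg in sorted(groups.items())]


def read_tpp_table(path: str) -> list[TppProfile]:
    """Read a long-format 2D-TPP table (protein, temperature, concentration,
    rel_abundance) into per-protein profiles."""
    df = pd.read_csv(path, sep="\t")
    need = {"protein", "temperature", "concentration", "rel_abundance"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(need)}")
    profiles = []
    for prot, sub in df.groupby("protein", sort=True):
        piv = sub.pivot_table(index="temperature", columns="concentration",
                              values="rel_abundance")
        profiles.append(TppProfile(
            protein=str(prot),
            temperatures=piv.index.to_numpy(float),
            concentrations=piv.columns.to_numpy(float),
            rel_abundance=piv.to_numpy(float)))
    return profiles


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_network(net: CausalNetwork, edge_path: str, node_path: str) -> None:
    """Write a causal network as a SIF-like edge TSV plus a node-attribute TSV.

    Edges duplicated across optimization rounds collapse to one row whose
    round label joins the rounds with ``;``.  The edge file round-trips
    through :func:`read_pkn` (which ignores the extra round column).
    """
    rounds: dict[tuple[str, int, str], list[str]] = {}
    for s, sign, t, rnd in sorted(net.edges):
        rounds.setdefault((s, sign, t), [])
        for r in rnd.split(";"):
            if r not in rounds[(s, sign, t)]:
                rounds[(s, sign, t)].append(r)
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\tsign\ttarget\tround\n")
        for (s, sign, t), rl in sorted(rounds.items()):
            fh.write(f"{s}\t{sign}\t{t}\t{';'.join(sorted(rl))}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("node\tstate\n")
        for v, st in sorted(net.node_state.items()):
            fh.write(f"{v}\t{st}\n")


def write_de_table(de: pd.DataFrame, path: str) -> None:
    de.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)


def make_de_frame(feature: Sequence[str], log2fc, stat, pvalue, qvalue,
                  significant=None) -> pd.DataFrame:
    """Assemble the canonical differential-result dataframe."""
    df = pd.DataFrame({
        "feature": list(feature),
        "log2fc": np.asarray(log2fc, float),
        "stat": np.asarray(stat, float),
        "pvalue": np.asarray(pvalue, float),
        "qvalue": np.asarray(qvalue, float),
        "significant": (np.zeros(len(feature), bool) if significant is None
                        else np.asarray(significant, bool)),
    })
    if ((df["pvalue"].dropna() < 0).any() or (df["pvalue"].dropna() > 1).any()
            or (df["qvalue"].dropna() < 0).any()
            or (df["qvalue"].dropna() > 1).any()):
        raise ValueError("p/q values must lie in [0,1]")
    return df
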