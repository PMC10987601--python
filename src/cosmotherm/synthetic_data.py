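"""Synthetic multi-omics data with a planted ground-truth active subnetwork.

The generator emulates the statistical structure the analysis assumes: a
layered signed PKN in which kinases sit upstream, thermally responsive (TPP)
proteins are intermediates, and transcription factors are sinks; a
sign-consistent, acyclic path system from >=2 kinases through >=2 TPP proteins
to >=2 TFs is planted and recorded.  Planted TPP proteins come in three
flavours mirroring how such proteins enter the optimization: reached through
an intermediate, directly phosphorylated by a kinase (so their activity sign
is recoverable from kinase consistency), and terminal (no route onward to a
TF, so only the TPP layer can recover them).

Downstream data are drawn from the generative models the statistics assume:
transcripts are negative binomial with target genes of planted-active TFs
shifted by ``mode * sign(TF) * effect_lfc``; phosphosites are Gaussian with
substrate sites of planted-active kinases shifted likewise; a fraction of
sites is confounded with protein-abundance changes (to exercise the
protein-level correction); TPP profiles follow the dose-response alternative
model with the planted direction.  Everything is bit-reproducible under a
seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (InputNode, InputNodeSet, OmicsMatrix, PKN, Regulon,
                      TppProfile, DEFAULT_TEMPERATURES,
                      DEFAULT_CONCENTRATIONS, CausalNetwork)

log = logging.getLogger("cosmotherm")


@dataclass
class SyntheticTruth:
    pkn: PKN
    true_active: dict[str, int]
    roles: dict[str, str]               # node -> kinase|tf|tpp|other
    tf_regulons: list[Regulon]
    kinase_regulons: list[Regulon]
    params: dict[str, object] = field(default_factory=dict)

    def nodes_of_role(self, role: str) -> list[str]:
        return sorted(v for v, r in self.roles.items() if r == role)


# ---------------------------------------------------------------------------
# PKN with planted truth
# ---------------------------------------------------------------------------

def generate_pkn(n_nodes: int = 60, n_edges: int = 150, n_kinases: int = 3,
                 n_tfs: int = 3, n_tpp: int = 4,
                 seed: int = 0) -> SyntheticTruth:
    """Random layered signed digraph with a planted active path system.

    Nodes are arranged in five layers (kinases, intermediates, TPP proteins,
    intermediates, TFs) and edges only point forward, so the PKN is acyclic.
    Edge signs are Bernoulli(0.7) activating.  The planted subnetwork runs
    from two kinases through three TPP proteins (one via an intermediate, one
    direct, one terminal) to two TFs and is sign-consistent by construction.
    """
    if n_edges < n_nodes - 1:
        raise ValueError("n_edges must be at least n_nodes - 1")
    if n_kinases + n_tfs + n_tpp > n_nodes:
        raise ValueError("role counts exceed n_nodes")
    if n_kinases < 2 or n_tfs < 2 or n_tpp < 3:
        raise ValueError("need >=2 kinases, >=2 TFs and >=3 TPP nodes")
    rng = np.random.default_rng(seed)

    kinases = [f"KIN{i+1}" for i in range(n_kinases)]
    tpps = [f"TPP{i+1}" for i in range(n_tpp)]
    tfs = [f"TF{i+1}" for i in range(n_tfs)]
    n_other = n_nodes - n_kinases - n_tfs - n_tpp
    others = [f"P{i+1}" for i in range(n_other)]
    half = n_other // 2
    layer: dict[str, int] = {}
    for v in kinases:
        layer[v] = 0
    for v in others[:half]:
        layer[v] = 1
    for v in tpps:
        layer[v] = 2
    for v in others[half:]:
        layer[v] = 3
    for v in tfs:
        layer[v] = 4
    roles = {v: "kinase" for v in kinases}
    roles |= {v: "tpp" for v in tpps}
    roles |= {v: "tf" for v in tfs}
    roles |= {v: "other" for v in others}
    nodes = kinases + others[:half] + tpps + others[half:] + tfs

    # ---- planted path system ------------------------------------------------
    true_active: dict[str, int] = {}
    edges: set[tuple[str, int, str]] = set()

    planted_edges: list[tuple[str, int, str]] = []

    def plant_edge(s: str, t: str) -> None:
        sign = true_active[s] * true_active[t]
        edges.add((s, sign, t))
        planted_edges.append((s, sign, t))

    k1, k2 = kinases[0], kinases[1]
    t1, t2, t3 = tpps[0], tpps[1], tpps[2]
    f1, f2 = tfs[0], tfs[1]
    mid1 = others[0] if half >= 1 else None
    mid3 = others[half] if n_other > half else None
    mid1b = others[1] if half >= 2 else mid1
    mid3b = others[half + 1] if n_other > half + 1 else mid3
    for v in (k1, k2, t1, t2, t3, f1, f2, mid1, mid1b, mid3, mid3b):
        if v is not None:
            true_active[v] = int(rng.choice([1, -1]))
    # kinase -> intermediate -> TPP1; kinase2 -> TPP2 (direct);
    # kinase -> intermediate -> TPP3 (terminal); TPP1/TPP2 -> (mid) -> TFs
    if mid1 is not None:
        plant_edge(k1, mid1)
        plant_edge(mid1, t1)
    else:
        plant_edge(k1, t1)
    plant_edge(k2, t2)
    if mid1b is not None and mid1b != mid1:
        plant_edge(k2, mid1b)
        plant_edge(mid1b, t3)
    else:
        plant_edge(k2, t3)
    if mid3 is not None:
        plant_edge(t1, mid3)
        plant_edge(mid3, f1)
    else:
        plant_edge(t1, f1)
    if mid3b is not None and mid3b != mid3:
        plant_edge(t2, mid3b)
        plant_edge(mid3b, f2)
    else:
        plant_edge(t2, f2)

    # ---- random forward filler edges ---------------------------------------
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        s, t = rng.choice(nodes, size=2, replace=False)
        if layer[s] >= layer[t]:
            continue
        sign = 1 if rng.random() < 0.7 else -1
        if (s, sign, t) in edges or (s, -sign, t) in edges:
            continue
        edges.add((s, sign, t))
    pkn = PKN.from_edges(edges)

    # ---- regulons -----------------------------------------------------------
    tf_regulons = []
    for tf in tfs:
        targets = []
        for i in range(30):
            mode = 1 if rng.random() < 0.8 else -1
            targets.append((f"G_{tf}_{i+1}", mode, 1.0))
        tf_regulons.append(Regulon(regulator=tf, targets=tuple(targets)))
    kinase_regulons = []
    succ = {k: sorted({t for s, _, t in edges if s == k}) for k in kinases}
    sign_of = {(s, t): g for s, g, t in edges}
    site_counter: dict[str, int] = {}   # unique residue numbers per substrate
    for k in kinases:
        targets = []
        for t in succ[k][:4]:
            site_counter[t] = site_counter.get(t, 100) + 1
            targets.append((f"{t}_S{site_counter[t]}", sign_of[(k, t)], 1.0))
        i = 0
        while len(targets) < 6:
            i += 1
            mode = 1 if rng.random() < 0.8 else -1
            targets.append((f"SUB_{k}_{i}_S1", mode, 1.0))
        kinase_regulons.append(Regulon(regulator=k, targets=tuple(targets)))

    truth = SyntheticTruth(
        pkn=pkn, true_active=true_active, roles=roles,
        tf_regulons=tf_regulons, kinase_regulons=kinase_regulons,
        params={"n_nodes": n_nodes, "n_edges": n_edges, "seed": seed,
                "planted_tpp": [t1, t2, t3],
                "planted_kinases": [k1, k2], "planted_tfs": [f1, f2],
                "planted_edges": planted_edges})
    _check_planted_consistency(truth)
    return truth


def _check_planted_consistency(truth: SyntheticTruth) -> None:
    """The planted subnetwork must be sign-consistent within the PKN."""
    for s, g, t in truth.params["planted_edges"]:
        assert (s, g, t) in truth.pkn.edges
        assert truth.true_active[s] * g == truth.true_active[t], \
            f"planted edge {s}->{t} is sign-inconsistent"


# ---------------------------------------------------------------------------
# omics simulation
# ---------------------------------------------------------------------------

def _sample_names(n_reps: int) -> tuple[list[str], dict[str, str]]:
    treat = [f"T{i+1}" for i in range(n_reps)]
    ctrl = [f"C{i+1}" for i in range(n_reps)]
    cond = {s: "treatment" for s in treat} | {s: "control" for s in ctrl}
    return treat + ctrl, cond


def simulate_omics(truth: SyntheticTruth, n_reps: int = 3,
                   effect_lfc: float = 1.0, noise_sd: float = 0.2,
                   nb_dispersion: float = 0.05, seed: int = 0,
                   n_background_genes: int = 100,
                   n_background_sites: int = 50,
                   confound_frac: float = 0.2,
                   protein_sample_sd: float = 0.5,
                   ) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix]:
    """Simulate (transcript counts, phosphosite log2, protein log2) matrices.

    Transcript genes comprise all TF-regulon targets, every PKN node (so the
    expression filter is meaningful) and background genes.  Phosphosite
    intensities are protein abundance plus phosphorylation signal: each
    protein has a per-sample abundance component (sd ``protein_sample_sd``)
    shared with all of its sites, so the site-on-protein regression of the
    correction step has a true unit slope.  A ``confound_frac`` fraction of
    site-bearing proteins additionally receives a treatment abundance shift
    mirrored in its sites, which the protein-level correction must remove.
    """
    if effect_lfc <= 0:
        raise ValueError("effect_lfc must be positive")
    if n_reps < 2:
        raise ValueError("need >=2 replicates per condition")
    rng = np.random.default_rng(seed)
    samples, cond = _sample_names(n_reps)
    n_t = n_reps

    # --- transcripts ---------------------------------------------------------
    genes: list[str] = []
    shift: dict[str, float] = {}
    for reg in truth.tf_regulons:
        tf_state = truth.true_active.get(reg.regulator, 0)
        for g, mode, _ in reg.targets:
            genes.append(g)
            if tf_state != 0:
                shift[g] = mode * tf_state * effect_lfc
    genes += sorted(truth.pkn.nodes)
    genes += [f"BGG{i+1}" for i in range(n_background_genes)]
    base = np.exp(rng.normal(np.log(200.0), 1.0, size=len(genes)))
    counts = np.zeros((len(genes), 2 * n_reps))
    r = 1.0 / nb_dispersion
    for i, g in enumerate(genes):
        mu_c = base[i]
        mu_t = base[i] * 2.0 ** shift.get(g, 0.0)
        mu = np.array([mu_t] * n_t + [mu_c] * n_reps)
        counts[i] = rng.negative_binomial(r, r / (r + mu))
    transcripts = OmicsMatrix(
        values=pd.DataFrame(counts.astype(int), index=genes, columns=samples),
        sample_condition=dict(cond), kind="transcript_counts")

    # --- phosphosites + proteins --------------------------------------------
    sites: list[str] = []
    site_shift: dict[str, float] = {}
    for reg in truth.kinase_regulons:
        k_state = truth.true_active.get(reg.regulator, 0)
        for s, mode, _ in reg.targets:
            sites.append(s)
            if k_state != 0:
                site_shift[s] = mode * k_state * effect_lfc
    sites += [f"BGP{i+1}_S1" for i in range(n_background_sites)]
    proteins = sorted({s.rsplit("_", 1)[0] for s in sites})
    confounded = set(
        rng.choice(proteins, size=int(confound_frac * len(proteins)),
                   replace=False))

    prot_base = rng.normal(25.0, 1.0, size=len(proteins))
    prot_shift = {p: 0.6 for p in confounded}
    # per-(protein, sample) abundance deviation shared with the protein's sites
    abund_dev = rng.normal(0.0, protein_sample_sd,
                           size=(len(proteins), 2 * n_reps))
    prot_idx = {p: i for i, p in enumerate(proteins)}
    prot_vals = np.zeros((len(proteins), 2 * n_reps))
    for i, p in enumerate(proteins):
        mu = np.array([prot_base[i] + prot_shift.get(p, 0.0)] * n_t
                      + [prot_base[i]] * n_reps)
        prot_vals[i] = mu + abund_dev[i] \
            + rng.normal(0.0, noise_sd, size=2 * n_reps)
    protein = OmicsMatrix(
        values=pd.DataFrame(prot_vals, index=proteins, columns=samples),
        sample_condition=dict(cond), kind="protein_log2")

    site_base = rng.normal(20.0, 1.0, size=len(sites))
    phospho_vals = np.zeros((len(sites), 2 * n_reps))
    for i, s in enumerate(sites):
        p = s.rsplit("_", 1)[0]
        abund = prot_shift.get(p, 0.0)
        mu = np.array([site_base[i] + site_shift.get(s, 0.0) + abund] * n_t
                      + [site_base[i]] * n_reps)
        phospho_vals[i] = mu + abund_dev[prot_idx[p]] \
            + rng.normal(0.0, noise_sd, size=2 * n_reps)
    phospho = OmicsMatrix(
        values=pd.DataFrame(phospho_vals, index=sites, columns=samples),
        sample_condition=dict(cond), kind="phospho_log2")
    return transcripts, phospho, protein


def simulate_tpp(truth: SyntheticTruth, amplitude: float = 0.5,
                 noise_sd: float = 0.05, seed: int = 0,
                 n_background: int = 50) -> list[TppProfile]:
    """Simulate 2D-TPP profiles on the default 12-temperature x 4-dose grid.

    Planted TPP nodes follow the dose-response alternative model with
    temperature-specific amplitude ``amplitude * state`` over the upper half
    of the temperature range (stabilized when the planted state is +1);
    everything else is flat at 1 plus Gaussian noise.  The vehicle column is
    identically 1.
    """
    planted = set(truth.params.get("planted_tpp", []))
    if amplitude == 0 and planted:
        log.warning("simulate_tpp: amplitude 0 leaves planted nodes null")
    rng = np.random.default_rng(seed)
    temps = np.array(DEFAULT_TEMPERATURES)
    concs = np.array(DEFAULT_CONCENTRATIONS)
    nonveh = concs != 0.0
    s_curve = np.zeros_like(concs)
    s_curve[nonveh] = 1.0 / (1.0 + np.exp(-2.0 * (np.log10(concs[nonveh])
                                                  - 0.0)))
    profiles = []
    proteins = truth.nodes_of_role("tpp") + [f"BGT{i+1}"
                                             for i in range(n_background)]
    T = len(temps)
    for prot in proteins:
        r = np.ones((T, len(concs)))
        if prot in planted and amplitude != 0:
            direction = truth.true_active.get(prot, 1)
            A = np.zeros(T)
            A[T // 2:] = amplitude * direction
            r = r + A[:, None] * s_curve[None, :]
        noise = rng.normal(0.0, noise_sd, size=(T, len(concs)))
        noise[:, ~nonveh] = 0.0          # vehicle is the reference
        profiles.append(TppProfile(protein=prot, temperatures=temps,
                                   concentrations=concs,
                                   rel_abundance=r + noise))
    return profiles


def simulate_tpp_population(n_null: int = 200, n_planted: int = 20,
                            amplitude: float = 0.5, noise_sd: float = 0.05,
                            seed: int = 0
                            ) -> tuple[list[TppProfile], set[str]]:
    """A standalone TPP population for calibration studies: ``n_null`` flat
    proteins plus ``n_planted`` stabilized proteins (amplitude over the upper
    half of the temperature range), on the default design.  Returns the
    profiles and the planted protein ids."""
    rng = np.random.default_rng(seed)
    temps = np.array(DEFAULT_TEMPERATURES)
    concs = np.array(DEFAULT_CONCENTRATIONS)
    nonveh = concs != 0.0
    s_curve = np.zeros_like(concs)
    s_curve[nonveh] = 1.0 / (1.0 + np.exp(-2.0 * np.log10(concs[nonveh])))
    T = len(temps)
    profiles = []
    planted: set[str] = set()
    for i in range(n_null + n_planted):
        is_hit = i >= n_null
        name = f"HIT{i - n_null + 1}" if is_hit else f"NULL{i + 1}"
        r = np.ones((T, len(concs)))
        if is_hit:
            planted.add(name)
            A = np.zeros(T)
            A[T // 2:] = amplitude
            r = r + A[:, None] * s_curve[None, :]
        noise = rng.normal(0.0, noise_sd, size=r.shape)
        noise[:, ~nonveh] = 0.0
        profiles.append(TppProfile(protein=name, temperatures=temps,
                                   concentrations=concs,
                                   rel_abundance=r + noise))
    return profiles, planted


def generate_pathways(truth: SyntheticTruth, n_random: int = 20,
                      set_size: int = 8, seed: int = 0
                      ) -> dict[str, tuple[str, frozenset[str]]]:
    """A small pathway collection over PKN nodes: the planted process plus
    random sets (for enrichment analyses on synthetic networks)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.pkn.nodes)
    db = {"PLANTED": ("planted active process",
                      frozenset(truth.true_active))}
    for i in range(n_random):
        members = rng.choice(nodes, size=min(set_size, len(nodes)),
                             replace=False)
        db[f"RANDOM{i+1}"] = (f"random set {i+1}", frozenset(members))
    return db


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(result: CausalNetwork,
                   truth: SyntheticTruth) -> dict[str, float]:
    """Node precision/recall/F1 against the planted subnetwork, plus sign
    accuracy among true positives."""
    true_nodes = set(truth.true_active)
    found = set(result.node_state)
    tp = found & true_nodes
    precision = len(tp) / len(found) if found else 0.0
    recall = len(tp) / len(true_nodes) if true_nodes else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    sign_acc = (sum(1 for v in tp
                    if result.node_state[v] == truth.true_active[v]) / len(tp)
                if tp else float("nan"))
    return {"precision": precision, "recall": recall, "f1": f1,
            "sign_accuracy": sign_acc, "n_found": float(len(found)),
            "empty_result": float(not found)}


# ---------------------------------------------------------------------------
# file emission (for the CLI)
# ---------------------------------------------------------------------------

def write_synthetic_dataset(outdir: str, truth: SyntheticTruth,
                            transcripts: OmicsMatrix, phospho: OmicsMatrix,
                            protein: OmicsMatrix,
                            profiles: list[TppProfile]) -> None:
    """Emit every pipeline input file plus the ground-truth JSON."""
    os.makedirs(outdir, exist_ok=True)

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    with open(p("pkn.tsv"), "w", encoding="utf-8") as fh:
        fh.write("source\tsign\ttarget\n")
        for s, g, t in sorted(truth.pkn.edges):
            fh.write(f"{s}\t{g}\t{t}\n")
    for m, name in ((transcripts, "transcripts.tsv"),
                    (phospho, "phospho.tsv"), (protein, "protein.tsv")):
        m.values.to_csv(p(name), sep="\t")
    with open(p("conditions.yaml"), "w", encoding="utf-8") as fh:
        for s, c in transcripts.sample_condition.items():
            fh.write(f"{s}: {c}\n")
    with open(p("tpp.tsv"), "w", encoding="utf-8") as fh:
        fh.write("protein\ttemperature\tconcentration\trel_abundance\n")
        for prof in profiles:
            for i, t in enumerate(prof.temperatures):
                for j, c in enumerate(prof.concentrations):
                    fh.write(f"{prof.protein}\t{t}\t{c}\t"
                             f"{prof.rel_abundance[i, j]:.6g}\n")
    for regs, name in ((truth.tf_regulons, "tf_regulons.tsv"),
                       (truth.kinase_regulons, "kinase_regulons.tsv")):
        with open(p(name), "w", encoding="utf-8") as fh:
            fh.write("regulator\ttarget\tmode\tweight\n")
            for reg in regs:
                for t, mode, w in reg.targets:
                    fh.write(f"{reg.regulator}\t{t}\t{mode}\t{w:g}\n")
    db = generate_pathways(truth, seed=int(truth.params.get("seed", 0)))
    with open(p("pathways.gmt"), "w", encoding="utf-8") as fh:
        for pid, (desc, members) in sorted(db.items()):
            fh.write("\t".join([pid, desc] + sorted(members)) + "\n")
    with open(p("truth.json"), "w", encoding="utf-8") as fh:
        json.dump({"true_active": truth.true_active, "roles": truth.roles,
                   "params": {k: v for k, v in truth.params.items()}},
                  fh, indent=1)
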