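"""End-to-end orchestration: from omics matrices to the merged causal network.

``run_pipeline`` executes the full workflow on in-memory inputs;
``run_synthetic_benchmark`` wraps it around the synthetic generator and scores
recovery of the planted truth.  The command-line interface is a thin file-IO
wrapper around these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import (causal_ilp, diffstats, footprint, net_analysis, pkn_prep,
               synthetic_data, tpp_analysis)
from .config import Config
from .core_io import (CausalNetwork, InputNodeSet, OmicsMatrix, PKN, Regulon,
                      TppProfile, site_protein)

log = logging.getLogger("cosmotherm")


@dataclass
class PipelineResult:
    network: CausalNetwork
    transcript_de: pd.DataFrame
    phospho_de: pd.DataFrame
    tf_scores: pd.DataFrame
    kinase_scores: pd.DataFrame
    tf_inputs: InputNodeSet
    kinase_inputs: InputNodeSet
    tpp_hits: list[tpp_analysis.TppHit]
    tpp_inputs: InputNodeSet
    pkn_final: PKN
    extras: dict = field(default_factory=dict)


def run_pipeline(pkn: PKN, transcripts: OmicsMatrix, phospho: OmicsMatrix,
                 protein: OmicsMatrix, tpp_profiles: list[TppProfile],
                 tf_regulons: list[Regulon], kinase_regulons: list[Regulon],
                 config: Config | None = None,
                 with_tpp: bool = True) -> PipelineResult:
    """Run the complete workflow.

    Steps: differential statistics per layer; footprint scoring and top-
    regulator selection; TPP hit calling, activity estimation and the
    kinase-sign PKN filter; PKN preprocessing (expression filter, distance
    pruning, coherence filter, input pruning); two-round sign-consistent ILP
    with between-round filtering and merging.  ``with_tpp=False`` runs the
    kinase-to-TF-only variant for comparison.
    """
    cfg = config or Config()

    # 1. differential statistics
    transcript_de = diffstats.nb_wald_test(transcripts, cfg)
    phospho_n = diffstats.quantile_normalize(phospho)
    protein_n = diffstats.quantile_normalize(protein)
    phospho_c = diffstats.correct_phospho_for_protein(phospho_n, protein_n)
    phospho_de = diffstats.moderated_ttest(phospho_c, config=cfg)

    # 2. footprint activities
    t_stats = dict(zip(transcript_de["feature"], transcript_de["log2fc"]))
    tf_scores = footprint.score_activities(t_stats, tf_regulons,
                                           cfg.tf_min_targets, role="tf")
    tf_inputs = footprint.select_top_regulators(
        tf_scores, cfg.n_top_regulators, cfg.tf_nes_floor)
    p_stats = dict(zip(phospho_de["feature"], phospho_de["log2fc"]))
    kin_scores = footprint.score_activities(p_stats, kinase_regulons,
                                            cfg.kinase_min_targets,
                                            role="kinase")
    kinase_inputs = footprint.select_top_regulators(
        kin_scores, cfg.n_top_regulators, cfg.kinase_nes_floor)

    # 3. TPP hit calling and activity estimation
    hits: list[tpp_analysis.TppHit] = []
    tpp_inputs = InputNodeSet(entries=())
    pkn_work = pkn
    if with_tpp and tpp_profiles:
        hits = tpp_analysis.bootstrap_fdr(tpp_profiles, B=cfg.tpp_bootstrap_B,
                                          cutoff=cfg.tpp_fdr_cutoff,
                                          seed=cfg.seed)
        tpp_inputs, pkn_work = tpp_analysis.estimate_tpp_activities(
            hits, pkn, kinase_inputs, phospho_de)

    # 4. PKN preprocessing
    expressed = (set(transcript_de["feature"])
                 | set(protein.feature_ids)
                 | {site_protein(s) for s in phospho.feature_ids})
    pkn_work = pkn_prep.filter_by_expression(pkn_work, expressed)
    all_inputs = InputNodeSet.build(list(kinase_inputs) + list(tf_inputs)
                                    + list(tpp_inputs))
    pkn_work = pkn_prep.prune_by_distance(pkn_work, all_inputs,
                                          cfg.pkn_max_steps)
    regs = InputNodeSet.build(list(kinase_inputs) + list(tf_inputs)
                              + [e for e in tpp_inputs if e.sign is not None])
    pkn_work = pkn_prep.coherence_filter(pkn_work, regs, transcript_de)
    all_inputs = pkn_prep.drop_missing_inputs(all_inputs, pkn_work)
    kept = all_inputs.node_ids
    kinase_kept = InputNodeSet.build([e for e in kinase_inputs
                                      if e.node in kept])
    tf_kept = InputNodeSet.build([e for e in tf_inputs if e.node in kept])
    tpp_kept = InputNodeSet.build([e for e in tpp_inputs if e.node in kept])

    # 5. two-round optimization
    network = causal_ilp.run_cosmos_tpp(pkn_work, kinase_kept, tf_kept,
                                        tpp_kept, cfg)
    return PipelineResult(network=network, transcript_de=transcript_de,
                          phospho_de=phospho_de, tf_scores=tf_scores,
                          kinase_scores=kin_scores, tf_inputs=tf_kept,
                          kinase_inputs=kinase_kept, tpp_hits=hits,
                          tpp_inputs=tpp_kept, pkn_final=pkn_work)


def run_synthetic_benchmark(seed: int = 0, config: Config | None = None,
                            with_tpp: bool = True,
                            tpp_bootstrap_B: int = 50,
                            **generator_kwargs) -> dict:
    """Generate a synthetic dataset, run the pipeline, score recovery.

    Returns a dict with the truth, the pipeline result, and the recovery
    metrics of :func:`synthetic_data.score_recovery`.
    """
    cfg = config or Config()
    cfg.seed = seed
    cfg.tpp_bootstrap_B = tpp_bootstrap_B
    truth = synthetic_data.generate_pkn(seed=seed, **generator_kwargs)
    transcripts, phospho, protein = synthetic_data.simulate_omics(
        truth, seed=seed + 1)
    profiles = synthetic_data.simulate_tpp(truth, seed=seed + 2)
    result = run_pipeline(truth.pkn, transcripts, phospho, protein, profiles,
                          truth.tf_regulons, truth.kinase_regulons,
                          config=cfg, with_tpp=with_tpp)
    metrics = synthetic_data.score_recovery(result.network, truth)
    planted_tpp = set(truth.params["planted_tpp"])
    metrics["planted_tpp_recovered"] = float(
        len(planted_tpp & set(result.network.node_state)))
    return {"truth": truth, "result": result, "metrics": metrics}
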