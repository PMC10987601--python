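"""Run configuration.

All tunable thresholds of the workflow live in a single :class:`Config`
dataclass so that a YAML file can override any of them.  Defaults follow the
study design the package models: a treatment-vs-control contrast with three
replicates per arm, footprint-based regulator selection, 2D thermal proteome
profiling hit calling at 10% FDR, and a two-round sign-consistent ILP.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

log = logging.getLogger("cosmotherm")

#: accepted spellings for edge signs in PKN / regulon files (strict {1,-1}
#: unless ``Config.sign_aliases`` widens this)
DEFAULT_SIGN_ALIASES: dict[str, int] = {"1": 1, "-1": -1}
EXTENDED_SIGN_ALIASES: dict[str, int] = {
    "1": 1, "-1": -1, "+": 1, "-": -1, "+1": 1, "A": 1, "I": -1,
}


@dataclass
class Config:
    """All workflow parameters with their defaults.

    Differential-abundance thresholds default to an absolute log2 fold change
    above ``log2(1.2)`` with BH-adjusted p below 0.05; an alternative, stricter
    transcript threshold (1.5 on the log2 scale) is kept available because the
    two are both in circulation for this kind of contrast.
    """

    # --- differential statistics -------------------------------------------
    lfc_min: float = math.log2(1.2)
    alpha: float = 0.05
    #: alternative transcript log2FC threshold (set e.g. to 1.5 or log2(1.5))
    transcript_lfc_min: float | None = None
    nb_prefilter_min_total: int = 10        # keep genes with total count > this
    nb_dispersion_shrink_weight: float = 0.5  # weight toward the fitted trend
    moderated_d0_tol: float = 1e-6

    # --- footprinting -------------------------------------------------------
    tf_min_targets: int = 25
    kinase_min_targets: int = 3
    tf_nes_floor: float = 4.0
    kinase_nes_floor: float = 2.0
    dereg_abs_nes: float = 1.7
    n_top_regulators: int = 30
    permutation_null: bool = False
    n_permutations: int = 1000

    # --- TPP ----------------------------------------------------------------
    tpp_fdr_cutoff: float = 0.1
    tpp_bootstrap_B: int = 100
    tpp_strict_r2: float = 0.8
    tpp_strict_lfc: float = 1.5
    tpp_score_k_top: int = 100

    # --- PKN preprocessing --------------------------------------------------
    pkn_max_steps: int = 7

    # --- ILP ----------------------------------------------------------------
    beta: float = 0.2
    mip_gap: float = 0.0
    time_limit: float | None = None

    # --- enrichment / network analysis -------------------------------------
    ora_min_size: int = 5
    ora_max_size: int = 500
    ora_alpha: float = 0.05
    network_report_min_nodes: int = 4
    comparison_test: str = "wilcoxon"       # or "ttest"

    # --- misc ---------------------------------------------------------------
    sign_aliases: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIGN_ALIASES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
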