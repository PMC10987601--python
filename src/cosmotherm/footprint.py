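"""Regulon-based footprint activity scoring.

A regulator's activity is inferred from the behaviour of its targets: the
per-feature statistics (log2 fold changes) are rank-transformed to normal
scores over all measured features, and the regulator's normalized enrichment
score (NES) is the mode- and weight-signed average of its targets' scores,

    NES = sum_i w_i * m_i * z_i / sqrt(sum_i w_i^2),

which is standard normal under the null of exchangeable targets.  Transcription
factors are scored on transcript statistics (>=25 measured targets by default)
and kinases/phosphatases on protein-corrected phosphosite statistics (>=3
measured substrate sites).  An optional permutation null (feature-label
shuffling) can replace the analytic null.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import InputNode, InputNodeSet, Regulon

log = logging.getLogger("cosmotherm")

SCORE_COLUMNS = ("regulator", "role", "nes", "n_targets_used")


def rank_normal_scores(stat: Mapping[str, float]) -> dict[str, float]:
    """Inverse-normal transform of (rank - 0.5)/N over all measured features."""
    items = sorted(stat.items())
    vals = np.array([v for _, v in items], dtype=float)
    if len(vals) == 0:
        raise ValueError("empty statistics")
    if np.ptp(vals) == 0:
        raise ValueError("all statistics equal; ranks are degenerate")
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - 0.5) / len(vals))
    return {k: float(zi) for (k, _), zi in zip(items, z)}


def _regulon_nes(z: Mapping[str, float], regulon: Regulon) -> tuple[float, int]:
    num = 0.0
    den = 0.0
    n_used = 0
    for target, mode, weight in regulon.targets:
        if target in z:
            num += weight * mode * z[target]
            den += weight * weight
            n_used += 1
    if n_used == 0 or den == 0:
        return np.nan, n_used
    return num / np.sqrt(den), n_used


def score_activities(stat: Mapping[str, float], regulons: Sequence[Regulon],
                     min_targets: int, role: str = "tf",
                     permutation_null: bool = False, n_permutations: int = 1000,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Score every regulon with >= ``min_targets`` measured targets.

    Returns a dataframe with columns ``regulator, role, nes, n_targets_used``
    sorted by regulator.  With ``permutation_null=True`` the analytic NES is
    replaced by a z-score of the raw enrichment against ``n_permutations``
    feature-label shuffles.
    """
    z = rank_normal_scores(stat)
    rows = []
    if permutation_null:
        rng = rng or np.random.default_rng(0)
        feats = sorted(z)
        feat_idx = {f: i for i, f in enumerate(feats)}
        zvals = np.array([z[f] for f in feats])
        zperm = np.stack([rng.permutation(zvals)
                          for _ in range(n_permutations)])
    for reg in regulons:
        nes, n_used = _regulon_nes(z, reg)
        if n_used < min_targets or not np.isfinite(nes):
            continue
        if permutation_null:
            idx = np.array([feat_idx[t] for t, _, _ in reg.targets
                            if t in feat_idx])
            mw = np.array([m * w for t, m, w in reg.targets if t in feat_idx])
            den = np.sqrt(np.sum([w * w for t, _, w in reg.targets
                                  if t in feat_idx]))
            null = zperm[:, idx] @ mw / den
            sd = null.std(ddof=1)
            nes = (nes - null.mean()) / sd if sd > 0 else np.nan
        rows.append((reg.regulator, role, float(nes), int(n_used)))
    if not rows:
        log.warning("score_activities: no regulon reached min_targets=%d",
                    min_targets)
    df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    return df.sort_values("regulator", ignore_index=True)


def select_top_regulators(scores: pd.DataFrame, n_top: int, nes_floor: float,
                          role: str | None = None) -> InputNodeSet:
    """Keep the strongest regulators as optimization inputs.

    Regulators are sorted by |NES| descending (ties broken lexicographically
    by id); the ``min(n_top, #{|NES| > nes_floor})`` strongest are kept with
    sign = sign(NES) and weight = |NES| / max|NES| among the kept set.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    df = scores.copy()
    if role is not None:
        df = df[df["role"] == role]
    df = df[df["nes"].abs() > nes_floor]
    df = df.sort_values(["nes", "regulator"], key=lambda c: (
        -c.abs() if c.name == "nes" else c), ignore_index=True)
    kept = df.head(n_top)
    if kept.empty:
        return InputNodeSet(entries=())
    max_abs = kept["nes"].abs().max()
    entries = [InputNode(node=r.regulator, role=r.role,
                         sign=1 if r.nes > 0 else -1,
                         weight=float(abs(r.nes) / max_abs))
               for r in kept.itertuples()]
    return InputNodeSet.build(entries)
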