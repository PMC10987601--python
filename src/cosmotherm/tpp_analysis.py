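"""2D thermal-proteome-profiling hit calling and TPP activity estimation.

Hit calling compares, per protein, a no-change null model against a
dose-response alternative on the temperature × concentration grid of relative
soluble abundances:

* null: one constant per temperature (the mean across doses), ``p0 = T``
  parameters;
* alternative: a log-logistic dose response per temperature,
  ``r(c, t) = b_t + A_t / (1 + exp(-h * (log10 c - mu)))``, with the
  log10-EC50 ``mu`` and slope ``h`` shared across temperatures and a
  temperature-specific intercept ``b_t`` and amplitude ``A_t``
  (``p1 = 2T + 2``; the per-temperature coefficients are linear given ``mu``
  and ``h`` and are profiled out).  The per-temperature intercepts make the
  null an exact submodel (``A_t = 0``), so ``rss1 <= rss0`` always, and make
  the F statistic invariant to adding a constant to any temperature row.

Both models are fitted by least squares on the non-vehicle observations (the
vehicle column is the normalisation reference, identically 1, and carries no
information).  Models are compared with an F statistic whose
significance is calibrated by a bootstrap false-discovery-rate procedure
(residual resampling under the null).  A 10% FDR cutoff defines the ``fstat``
hit set; a strict fit-quality/effect-size rule and a stabilization-score
ranking provide alternative hit sets.

TPP activity estimation assigns signs to hits whose upstream kinases agree in
their predicted effect, and removes kinase->hit edges that contradict measured
phosphosite changes (kinase-sign PKN filter).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.optimize import minimize

from .core_io import (InputNode, InputNodeSet, PKN, TppProfile, site_protein)

log = logging.getLogger("cosmotherm")

STABILIZED = "stabilized"
DESTABILIZED = "destabilized"

_MU_GRID = np.linspace(-1.0, 1.5, 5)          # log10 uM around the dose range
_H_GRID = np.array([1e-6, 0.5, 1.5, 4.0, 10.0])  # includes the near-null limit


@dataclass
class TppFit:
    """Null/alternative least-squares fit of one protein's 2D profile."""

    protein: str
    rss0: float
    rss1: float
    p0: int
    p1: int
    n_obs: int
    F: float
    direction: str
    r2: float                 # alternative-model R^2 against the grand mean
    max_abs_log2: float       # effect size over the full profile
    amplitudes: np.ndarray
    mu: float
    h: float

    def __post_init__(self) -> None:
        if self.rss1 > self.rss0 + 1e-9:
            raise ValueError(f"{self.protein}: rss1 > rss0")
        if self.F < 0 or self.p1 <= self.p0:
            raise ValueError(f"{self.protein}: invalid F-test bookkeeping")


@dataclass(frozen=True)
class TppHit:
    """A called (de)stabilization event."""

    protein: str
    direction: str
    F: float
    fdr: float
    hit_set: str              # fstat | strict | score
    magnitude: float          # max |log2 rel abundance| of the profile


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _alt_fit(y: np.ndarray, logc: np.ndarray, mu: float, h: float
             ) -> tuple[float, np.ndarray]:
    """Profiled alternative-model fit given (mu, h).

    The per-temperature intercepts and amplitudes are ordinary least squares
    on the common two-column design ``[1, s(c)]``, solved through the closed-
    form 2x2 normal equations.  In the degenerate case of a flat dose curve
    (collinear design) the fit collapses onto the null model.  Returns
    ``(rss, amplitudes)``.
    """
    s = special.expit(h * (logc - mu))                   # (C-1,)
    c1 = float(len(s))
    ss = float(s @ s)
    sm = float(s.sum())
    det = c1 * ss - sm * sm
    ysum = y.sum(axis=1)                                  # (T,)
    ys = y @ s
    yy = float(np.sum(y * y))
    if det <= 1e-12 * max(c1 * ss, 1e-300):
        return yy - float(ysum @ ysum) / c1, np.zeros(y.shape[0])
    b0 = (ss * ysum - sm * ys) / det
    b1 = (c1 * ys - sm * ysum) / det
    return yy - float(b0 @ ysum + b1 @ ys), b1


def _alt_rss(y: np.ndarray, logc: np.ndarray, mu: float, h: float) -> float:
    return _alt_fit(y, logc, mu, h)[0]


def fit_models(profile: TppProfile) -> TppFit | None:
    """Fit the null and alternative models for one protein.

    The (mu, h) surface is scanned on a 5 x 5 start grid and the best start is
    refined by Nelder-Mead.  Returns ``None`` (with a warning) for profiles
    that cannot support the fit (fewer than 3 temperatures, fewer than 2
    non-vehicle doses, or ``n_obs <= p1``).
    """
    nonveh = profile.concentrations != 0.0
    T = len(profile.temperatures)
    C1 = int(nonveh.sum())
    p0, p1 = T, 2 * T + 2
    n_obs = T * C1
    if T < 3 or C1 < 2 or n_obs <= p1:
        log.warning("fit_models: skipping %s (T=%d, doses=%d)",
                    profile.protein, T, C1)
        return None

    y = profile.rel_abundance[:, nonveh]
    logc = np.log10(profile.concentrations[nonveh])
    row_means = y.mean(axis=1, keepdims=True)
    rss0 = float(np.sum((y - row_means) ** 2))

    best = (np.inf, 0.0, 0.0)
    for mu in _MU_GRID:
        for h in _H_GRID:
            r = _alt_rss(y, logc, mu, h)
            if r < best[0]:
                best = (r, mu, h)
    res = minimize(lambda p: _alt_rss(y, logc, p[0], abs(p[1])),
                   x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 200})
    if res.fun < best[0]:
        best = (float(res.fun), float(res.x[0]), abs(float(res.x[1])))
    rss1, mu, h = best
    rss1 = min(rss1, rss0)   # the null is the A_t = 0 submodel

    denom_df = n_obs - p1
    scale = rss1 / denom_df
    F = 0.0 if scale <= 0 else max(0.0, (rss0 - rss1) / (p1 - p0) / scale)
    _, A = _alt_fit(y, logc, mu, h)
    order = np.argsort(profile.temperatures)
    upper = order[T // 2:]
    direction = STABILIZED if A[upper].sum() >= 0 else DESTABILIZED

    grand = y.mean()
    tss = float(np.sum((y - grand) ** 2))
    r2 = 1.0 - rss1 / tss if tss > 0 else 0.0
    max_abs_log2 = float(np.nanmax(np.abs(profile.log2_matrix())))
    return TppFit(protein=profile.protein, rss0=rss0, rss1=rss1, p0=p0, p1=p1,
                  n_obs=n_obs, F=F, direction=direction, r2=r2,
                  max_abs_log2=max_abs_log2, amplitudes=A, mu=mu, h=h)


# ---------------------------------------------------------------------------
# bootstrap FDR
# ---------------------------------------------------------------------------

def _protein_rng(seed: int, protein: str) -> np.random.Generator:
    """Deterministic per-protein substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(protein.encode("utf-8"))]))


def _refit_F(y: np.ndarray, logc: np.ndarray) -> float:
    """F statistic of a (resampled) non-vehicle data block."""
    T, C1 = y.shape
    n_obs = T * C1
    p0, p1 = T, 2 * T + 2
    row_means = y.mean(axis=1, keepdims=True)
    rss0 = float(np.sum((y - row_means) ** 2))
    best = np.inf
    bmu = bh = 0.0
    for mu in _MU_GRID:
        for h in _H_GRID:
            r = _alt_rss(y, logc, mu, h)
            if r < best:
                best, bmu, bh = r, mu, h
    res = minimize(lambda p: _alt_rss(y, logc, p[0], abs(p[1])),
                   x0=[bmu, bh], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 200})
    rss1 = min(float(res.fun), best, rss0)
    scale = rss1 / (n_obs - p1)
    if scale <= 0:
        return 0.0
    return max(0.0, (rss0 - rss1) / (p1 - p0) / scale)


def bootstrap_fdr(profiles: list[TppProfile], B: int = 100,
                  cutoff: float = 0.1, seed: int = 0,
                  fits: dict[str, TppFit] | None = None) -> list[TppHit]:
    """Call F-statistic hits with a bootstrap plug-in FDR.

    For every protein, ``B`` null datasets are generated by resampling the
    null-model residuals with replacement and adding them back onto the
    null-model fit; both models are refitted on each to obtain null F values.
    For a threshold theta, ``FDR(theta)`` is the average null exceedance count
    divided by the observed exceedance count; monotonicity is enforced by a
    running minimum from the largest theta down.  Hits are the proteins whose
    F reaches the smallest theta with ``FDR(theta) < cutoff``.
    """
    if B <= 0:
        raise ValueError("B must be >= 1")
    if fits is None:
        fits = {}
        for p in profiles:
            f = fit_models(p)
            if f is not None:
                fits[p.protein] = f
    prof_by_id = {p.protein: p for p in profiles}
    proteins = sorted(fits)
    if not proteins:
        return []
    F_obs = np.array([fits[p].F for p in proteins])

    null_F: list[float] = []
    for prot in proteins:
        profile = prof_by_id[prot]
        nonveh = profile.concentrations != 0.0
        y = profile.rel_abundance[:, nonveh]
        logc = np.log10(profile.concentrations[nonveh])
        fit0 = y.mean(axis=1, keepdims=True)
        resid = (y - fit0).ravel()
        rng = _protein_rng(seed, prot)
        for _ in range(B):
            e = rng.choice(resid, size=y.shape, replace=True)
            null_F.append(_refit_F(fit0 + e, logc))
    null_F_arr = np.sort(np.asarray(null_F))

    # plug-in FDR over observed thresholds; the expected null exceedance
    # count is averaged over proteins as well as bootstrap draws
    order = np.argsort(-F_obs)
    thetas = F_obs[order]
    n_null_ge = len(null_F_arr) - np.searchsorted(null_F_arr, thetas,
                                                  side="left")
    n_obs_ge = np.arange(1, len(thetas) + 1)
    fdr = np.minimum(1.0, (n_null_ge / B) / np.maximum(1, n_obs_ge))
    # q-value enforcement: FDR(theta) non-increasing in theta (suffix minimum
    # over the descending thresholds)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]

    hits: list[TppHit] = []
    passing = fdr < cutoff
    if passing.any():
        k_max = int(np.max(np.where(passing)[0]))   # smallest passing theta
        for rank in range(k_max + 1):
            idx = order[rank]
            prot = proteins[idx]
            fit = fits[prot]
            hits.append(TppHit(protein=prot, direction=fit.direction,
                               F=fit.F, fdr=float(fdr[rank]), hit_set="fstat",
                               magnitude=fit.max_abs_log2))
    log.info("bootstrap_fdr: %d/%d proteins called at FDR < %.2g",
             len(hits), len(proteins), cutoff)
    return sorted(hits, key=lambda h: (-h.F, h.protein))


# ---------------------------------------------------------------------------
# alternative hit sets
# ---------------------------------------------------------------------------

def strict_hits(profiles: list[TppProfile], r2_min: float = 0.8,
                lfc_min: float = 1.5,
                fits: dict[str, TppFit] | None = None) -> list[TppHit]:
    """Strict hit set: sigmoidal fit quality R^2 > ``r2_min`` and effect size
    max |log2 rel abundance| > ``lfc_min``."""
    out = []
    for p in profiles:
        fit = (fits or {}).get(p.protein) or fit_models(p)
        if fit is None:
            continue
        if fit.r2 > r2_min and fit.max_abs_log2 > lfc_min:
            out.append(TppHit(protein=p.protein, direction=fit.direction,
                              F=fit.F, fdr=float("nan"), hit_set="strict",
                              magnitude=fit.max_abs_log2))
    return sorted(out, key=lambda h: (-h.F, h.protein))


def stabilization_score(profiles: list[TppProfile],
                        k_top: int = 100) -> list[TppHit]:
    """Rank proteins by a dose-weighted stabilization score.

    The score sums, over the upper half of the temperature range, the
    dose-rank-weighted mean of the log2 relative abundances across non-vehicle
    concentrations (higher doses weigh more); the top ``k_top`` proteins by
    absolute score are returned with direction = sign(score).
    """
    scored = []
    for p in profiles:
        nonveh = p.concentrations != 0.0
        w = np.argsort(np.argsort(p.concentrations[nonveh])) + 1.0  # dose ranks
        l2 = p.log2_matrix()[:, nonveh]
        order = np.argsort(p.temperatures)
        upper = order[len(p.temperatures) // 2:]
        score = float(np.sum((l2[upper] * w).sum(axis=1) / w.sum()))
        scored.append((p, score))
    if k_top > len(scored):
        log.warning("stabilization_score: k_top=%d > %d proteins; returning all",
                    k_top, len(scored))
    scored.sort(key=lambda t: (-abs(t[1]), t[0].protein))
    out = []
    for p, score in scored[:k_top]:
        nonveh = p.concentrations != 0.0
        mag = float(np.nanmax(np.abs(p.log2_matrix())))
        out.append(TppHit(protein=p.protein,
                          direction=STABILIZED if score >= 0 else DESTABILIZED,
                          F=float("nan"), fdr=float("nan"), hit_set="score",
                          magnitude=mag))
    return out


# ---------------------------------------------------------------------------
# TPP activity estimation and the kinase-sign PKN filter
# ---------------------------------------------------------------------------

def estimate_tpp_activities(hits: list[TppHit], pkn: PKN,
                            kinases: InputNodeSet,
                            phospho_de: pd.DataFrame | None = None,
                            ) -> tuple[InputNodeSet, PKN]:
    """Infer TPP activities from upstream-kinase consistency.

    For every hit, the edges from selected kinases into the hit predict a sign
    (kinase sign x edge sign); when at least one such edge exists and all
    predictions agree, the hit enters the input set with that sign and weight
    1.  Otherwise it enters sign-unknown with a weight equal to its
    (de)stabilization magnitude normalized to [0, 1] across hits.

    Separately, every kinase->hit edge whose predicted sign contradicts the
    direction of a significantly changed phosphosite on the hit protein is
    removed from the PKN (kinase-sign filter).  ``phospho_de`` supplies the
    phosphosite differential results; with ``None`` the edge filter is a
    no-op.
    """
    ksign = {e.node: e.sign for e in kinases.of_role("kinase")
             if e.sign is not None}
    hit_ids = {h.protein for h in hits}
    max_mag = max((h.magnitude for h in hits), default=0.0)

    entries: list[InputNode] = []
    for h in sorted(hits, key=lambda x: x.protein):
        preds = {ksign[s] * sign for s, sign, t in pkn.edges
                 if t == h.protein and s in ksign}
        if len(preds) == 1:
            entries.append(InputNode(node=h.protein, role="tpp",
                                     sign=preds.pop(), weight=1.0))
        else:
            w = h.magnitude / max_mag if max_mag > 0 else 0.0
            entries.append(InputNode(node=h.protein, role="tpp", sign=None,
                                     weight=float(min(1.0, w))))

    removed = set()
    if phospho_de is not None:
        sig = phospho_de[phospho_de["significant"]]
        site_signs: dict[str, set[int]] = {}
        for r in sig.itertuples():
            prot = site_protein(str(r.feature))
            if prot in hit_ids and r.log2fc != 0:
                site_signs.setdefault(prot, set()).add(1 if r.log2fc > 0 else -1)
        for s, sign, t in pkn.edges:
            if s in ksign and t in site_signs:
                pred = ksign[s] * sign
                if any(pred != ms for ms in site_signs[t]):
                    removed.add((s, sign, t))
    if removed:
        log.info("kinase-sign filter removed %d incoherent edge(s)", len(removed))
    return (InputNodeSet.build(entries),
            PKN(frozenset(pkn.edges - removed)))
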