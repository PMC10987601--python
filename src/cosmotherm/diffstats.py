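"""Differential statistics for the three omics layers.

* quantile normalization of log2 intensity matrices (proteomics/phospho),
* an empirical-Bayes moderated t-test (variance shrinkage toward a scaled
  inverse-chi-square prior estimated by method of moments on log s^2),
* a simplified negative-binomial Wald test for transcript counts
  (median-of-ratios size factors, moment dispersions shrunk toward a fitted
  mean-dispersion trend, Wald statistic with a normal reference),
* protein-abundance correction of phosphosites by per-site OLS,
* Benjamini-Hochberg adjustment and significance calling.

Differential results are dataframes with the ``core_io.DE_COLUMNS`` schema.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import Config
from .core_io import OmicsMatrix, make_de_frame, site_protein

log = logging.getLogger("cosmotherm")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force identical column distributions (reference = row means of the
    column-sorted values).  Missing values stay missing and are ignored when
    ranking; columns with missing entries are mapped through interpolated
    quantiles of the reference curve."""
    if m.kind not in ("phospho_log2", "protein_log2"):
        raise ValueError("quantile normalization applies to log2 intensity data")
    X = m.values.to_numpy(float)
    n, p = X.shape
    if n == 1:
        log.warning("quantile_normalize: single-row matrix returned unchanged")
        return m
    if np.all(np.isnan(X), axis=0).any():
        raise ValueError("matrix has an all-missing column")

    # reference distribution on a common grid of n quantiles
    grid = (np.arange(n) + 0.5) / n
    ref = np.zeros(n)
    for j in range(p):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        k = len(col)
        if k == n:
            ref += col
        else:
            ref += np.interp(grid, (np.arange(k) + 0.5) / k, col)
    ref /= p

    out = np.full_like(X, np.nan)
    for j in range(p):
        obs = ~np.isnan(X[:, j])
        k = obs.sum()
        ranks = stats.rankdata(X[obs, j], method="average")
        out[obs, j] = np.interp((ranks - 0.5) / k, grid, ref)
    return m.with_values(pd.DataFrame(out, index=m.values.index,
                                      columns=m.values.columns))


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray,
               tol: float = 1e-6) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F distribution to sample variances.

    Returns ``(d0, s0_sq)``: the prior degrees of freedom and prior variance of
    the empirical-Bayes hierarchy (``d0 = inf`` when the variances are no more
    dispersed than chi-square sampling alone explains).
    """
    ok = np.isfinite(s2) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) == 0:
        raise ValueError("no features with positive residual df")
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return math.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (n - 1)
                 - np.mean(special.polygamma(1, df / 2.0)))
    if evar <= tol:
        return math.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(m: OmicsMatrix, prior_df: float | str = "auto",
                    config: Config | None = None) -> pd.DataFrame:
    """Two-group moderated t-test (treatment minus control).

    Per feature the pooled residual variance is shrunk toward a common prior:
    ``s_tilde^2 = (d0*s0^2 + d*s^2)/(d0 + d)``; the moderated t statistic is
    referred to a t distribution on ``d0 + d`` degrees of freedom.  Means are
    pairwise-complete; features with fewer than two complete values in either
    group are skipped.

    ``prior_df`` may be ``"auto"`` (estimate ``d0`` and ``s0^2`` by method of
    moments), ``0`` (ordinary t-test) or ``inf``.
    """
    cfg = config or Config()
    t_samples = m.samples_of("treatment")
    c_samples = m.samples_of("control")
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("moderated_ttest requires >=2 replicates per condition; "
                         f"got {len(t_samples)} treatment / {len(c_samples)} control")
    Xt = m.values[t_samples].to_numpy(float)
    Xc = m.values[c_samples].to_numpy(float)

    nt = np.sum(~np.isnan(Xt), axis=1)
    nc = np.sum(~np.isnan(Xc), axis=1)
    usable = (nt >= 2) & (nc >= 2)
    if not usable.any():
        raise ValueError("no feature has >=2 complete values per group")
    n_skip = int((~usable).sum())
    if n_skip:
        log.warning("moderated_ttest: skipping %d feature(s) with <2 complete "
                    "values per group", n_skip)

    with np.errstate(invalid="ignore"):
        mt = np.nanmean(Xt, axis=1)
        mc = np.nanmean(Xc, axis=1)
        vt = np.nanvar(Xt, axis=1, ddof=1)
        vc = np.nanvar(Xc, axis=1, ddof=1)
    d = nt + nc - 2.0
    s2 = ((nt - 1) * np.where(np.isnan(vt), 0, vt)
          + (nc - 1) * np.where(np.isnan(vc), 0, vc)) / d
    log2fc = mt - mc
    v_coef = 1.0 / nt + 1.0 / nc

    idx = np.where(usable)[0]
    if prior_df == "auto":
        d0, s0_sq = fit_f_dist(s2[idx], d[idx], tol=cfg.moderated_d0_tol)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[idx])) if d0 > 0 else 1.0
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / np.sqrt(s2_post * v_coef)
    pvals = np.where(np.isinf(df_total),
                     2.0 * stats.norm.sf(np.abs(tstat)),
                     2.0 * stats.t.sf(np.abs(tstat), np.maximum(df_total, 1e-9)))

    feats = np.asarray(m.feature_ids, dtype=object)[idx]
    q = bh_adjust(pvals[idx])
    de = make_de_frame(feats, log2fc[idx], tstat[idx], pvals[idx], q)
    return call_significant(de, cfg.lfc_min, cfg.alpha)


# ---------------------------------------------------------------------------
# negative-binomial Wald test for counts
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (reference = per-gene geometric mean over
    samples, computed on genes with all-positive counts)."""
    pos = np.all(counts > 0, axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(counts[pos])
    loggeo = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - loggeo, axis=0))


def _fit_dispersion_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by non-negative least squares and evaluate
    it at the given means."""
    from scipy.optimize import nnls
    ok = (mu > 0) & (alpha_raw > 1e-8)
    if ok.sum() < 10:
        return np.full_like(mu, max(float(np.median(alpha_raw[mu > 0])), 1e-8))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, _ = nnls(A, alpha_raw[ok])
    trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.maximum(trend, 1e-8)


def nb_wald_test(m: OmicsMatrix, config: Config | None = None) -> pd.DataFrame:
    """Simplified negative-binomial Wald test on raw transcript counts.

    Genes with total count <= the prefilter threshold (default 10) are removed
    before testing.  Per-gene dispersions are moment estimates shrunk toward a
    fitted mean-dispersion trend; group means come from size-factor-weighted
    count sums; the Wald statistic on the log2 fold change uses the NB Fisher
    information and a standard-normal reference.
    """
    cfg = config or Config()
    if m.kind != "transcript_counts":
        raise ValueError("nb_wald_test requires transcript counts")
    t_samples = m.samples_of("treatment")
    c_samples = m.samples_of("control")
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("nb_wald_test requires >=2 samples per condition")

    counts = m.values.to_numpy(float)
    keep = counts.sum(axis=1) > cfg.nb_prefilter_min_total
    if not keep.any():
        raise ValueError("no gene passes the total-count prefilter")
    counts = counts[keep]
    feats = np.asarray(m.feature_ids, dtype=object)[keep]

    sf = size_factors(counts)
    samp = list(m.values.columns)
    it = np.array([samp.index(s) for s in t_samples])
    ic = np.array([samp.index(s) for s in c_samples])
    norm = counts / sf[None, :]

    # moment dispersion from within-group variability of normalized counts
    mu_all = norm.mean(axis=1)
    var_w = (norm[:, it].var(axis=1, ddof=1) * (len(it) - 1)
             + norm[:, ic].var(axis=1, ddof=1) * (len(ic) - 1)) \
        / (len(it) + len(ic) - 2)
    # subtract the Poisson component on the normalized scale
    xim = float(np.mean(1.0 / sf))
    alpha_raw = np.clip((var_w - xim * mu_all) / np.maximum(mu_all, 1e-8) ** 2,
                        1e-8, 10.0)
    alpha_trend = _fit_dispersion_trend(mu_all, alpha_raw)
    w = cfg.nb_dispersion_shrink_weight
    alpha = np.clip(w * alpha_trend + (1.0 - w) * alpha_raw, 1e-8, 10.0)

    # group means (size-factor-weighted; small continuity offset guards zeros)
    mu_t = (counts[:, it].sum(axis=1) + 0.25) / sf[it].sum()
    mu_c = (counts[:, ic].sum(axis=1) + 0.25) / sf[ic].sum()
    log2fc = np.log2(mu_t / mu_c)

    # Fisher information of the log-mean within each group
    info_t = (sf[None, it] * mu_t[:, None]
              / (1.0 + alpha[:, None] * sf[None, it] * mu_t[:, None])).sum(axis=1)
    info_c = (sf[None, ic] * mu_c[:, None]
              / (1.0 + alpha[:, None] * sf[None, ic] * mu_c[:, None])).sum(axis=1)
    se_ln = np.sqrt(1.0 / info_t + 1.0 / info_c)
    wald = (log2fc * math.log(2.0)) / se_ln
    pvals = 2.0 * stats.norm.sf(np.abs(wald))

    q = bh_adjust(pvals)
    lfc_min = (cfg.transcript_lfc_min if cfg.transcript_lfc_min is not None
               else cfg.lfc_min)
    de = make_de_frame(feats, log2fc, wald, pvals, q)
    return call_significant(de, lfc_min, cfg.alpha)


# ---------------------------------------------------------------------------
# phosphosite correction for protein abundance
# ---------------------------------------------------------------------------

def correct_phospho_for_protein(phospho: OmicsMatrix,
                                protein: OmicsMatrix) -> OmicsMatrix:
    """Remove the protein-abundance component from phosphosite intensities.

    For every site with a matched measured protein, the site trace is replaced
    by ``intercept + residuals`` of the per-site OLS fit of site on protein
    across samples; what remains is the phosphorylation signal net of protein
    abundance.  Sites without a matched protein (or a degenerate fit) pass
    through unchanged and are flagged in ``notes['uncorrected_sites']``.
    """
    if phospho.kind != "phospho_log2" or protein.kind != "protein_log2":
        raise ValueError("expected phospho_log2 and protein_log2 matrices")
    common = [s for s in phospho.sample_ids if s in set(protein.sample_ids)]
    if len(common) < 3:
        raise ValueError("need >=3 shared samples to correct phosphosites")

    out = phospho.values.copy()
    uncorrected: list[str] = []
    prot_vals = protein.values
    for site in phospho.feature_ids:
        prot = site_protein(site)
        if prot not in prot_vals.index:
            uncorrected.append(site)
            continue
        y = phospho.values.loc[site, common].to_numpy(float)
        x = prot_vals.loc[prot, common].to_numpy(float)
        ok = ~(np.isnan(y) | np.isnan(x))
        if ok.sum() < 3:
            log.warning("correct_phospho_for_protein: <3 paired samples for "
                        "%s; passing through", site)
            uncorrected.append(site)
            continue
        xo, yo = x[ok], y[ok]
        if np.ptp(xo) == 0:  # zero-variance regressor: nothing to remove
            uncorrected.append(site)
            continue
        slope, intercept = np.polyfit(xo, yo, 1)
        resid = yo - (intercept + slope * xo)
        corrected = np.full_like(y, np.nan)
        corrected[ok] = intercept + resid
        out.loc[site, common] = corrected
    res = phospho.with_values(out)
    res.notes = dict(phospho.notes, uncorrected_sites=tuple(uncorrected))
    return res


# ---------------------------------------------------------------------------
# multiple testing and significance calling
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0,1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_significant(de: pd.DataFrame, lfc_min: float | None = None,
                     alpha: float | None = None) -> pd.DataFrame:
    """Flag features with ``|log2fc| > lfc_min`` and ``q < alpha`` (both
    strict).  Defaults: ``log2(1.2)`` and 0.05."""
    lfc_min = math.log2(1.2) if lfc_min is None else lfc_min
    alpha = 0.05 if alpha is None else alpha
    de = de.copy()
    de["significant"] = ((de["log2fc"].abs() > lfc_min)
                         & (de["qvalue"] < alpha)).fillna(False)
    return de
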