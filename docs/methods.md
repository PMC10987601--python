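# Methods

`cosmotherm` infers a signed causal subnetwork that connects perturbed
kinases, proteins with altered thermal stability, and deregulated
transcription factors, from three omics layers measured in a
treatment-versus-control contrast.  This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not show.

## Differential statistics

**Transcripts.** Raw counts are prefiltered to genes with a total count above
10 across all samples.  Size factors are median-of-ratios (reference = the
per-gene geometric mean over samples, computed on genes with all-positive
counts).  Per-gene dispersions are moment estimates from the within-group
variance of normalized counts, shrunk toward a fitted `a0 + a1/mu` trend
(non-negative least squares) with weight 0.5 — a deliberate simplification of
a full negative-binomial GLM pipeline; outlier handling and fold-change
shrinkage are out of scope.  Group means are size-factor-weighted count sums
(continuity offset 0.25), and the Wald statistic on the log2 fold change uses
the NB Fisher information with a standard-normal reference.  The unit suite
verifies type-I error within [0.03, 0.08] at nominal 0.05 on NB-simulated
nulls (2000 genes, 3 vs 3).

**Proteins and phosphosites.** Log2 intensities are quantile normalized
(reference = row means of the column-sorted values; missing entries are
ignored in ranking and mapped through interpolated quantiles).  Phosphosites
are corrected for protein abundance by per-site OLS of site on matched
protein across samples, keeping `intercept + residuals`; sites without a
matched protein, with fewer than 3 complete pairs, or with a zero-variance
regressor pass through unchanged and are flagged.  Note one honest caveat of
this standard correction: with three replicates per arm, regressing on an
uninformative (flat) protein trace absorbs a random share of the treatment
signal; the correction helps exactly when protein traces carry real shared
abundance variation, which is what the synthetic generator emulates.

Differential testing uses an empirical-Bayes moderated t-test: the pooled
per-feature variance is shrunk toward a prior, `s~2 = (d0 s0^2 + d s^2) /
(d0 + d)`, with `(d0, s0^2)` estimated by method of moments on `log s^2`
(digamma/trigamma moment matching; the trigamma inverse is solved by Newton
iteration to 1e-8 relative precision).  At `d0 = 0` the statistic reduces to
the ordinary two-sample t (verified to machine precision); at `d0 = inf` all
features are tested against the common prior variance.  P-values are
BH-adjusted; significance requires `|log2FC| > log2(1.2)` and `q < 0.05`
(both strict; both configurable, including the stricter transcript threshold
of 1.5 on the log2 scale that is also in circulation for such contrasts).

## Footprint activity scoring

Per-feature statistics (log2 fold changes) are rank-transformed to normal
scores, `z = Phi^-1((rank - 0.5)/N)` over all measured features.  A regulator
with target modes `m_i` and weights `w_i` scores

    NES = sum_i w_i m_i z_i / sqrt(sum_i w_i^2),

standard normal under the null of exchangeable targets (checked by
simulation: 500 random regulons on N(0,1) statistics give NES mean within
±0.1 and sd within [0.9, 1.1]).  This deliberately replaces the three-tailed,
mode-weighted aREA statistic of the VIPER family: the workflow uses regulator
activities only as a ranking and sign source, and the rank-normal statistic
has an exact analytic null, is invariant to monotone rescaling of the input,
and exactly negates under mode flips.  An optional permutation null
(feature-label shuffling) is provided and agrees with the analytic null
within |ΔNES| < 0.25 at 5000 permutations.

Regulators require 25 measured targets (TFs) or 3 measured substrate sites
(kinases/phosphatases).  The top 30 regulators by |NES| above a floor (4 for
TFs, 2 for kinases; ties broken lexicographically) become optimization
inputs with sign = sign(NES) and weight = |NES| / max|NES| among the kept
set.  An absolute-NES threshold of 1.7 defines the reported "deregulated"
counts only, not input selection.

## TPP hit calling

Each protein's 2D profile (12 temperatures × 4 doses plus vehicle, relative
to vehicle) is tested by comparing

* null: one constant per temperature (`p0 = T`), against
* alternative: `r(c, t) = b_t + A_t / (1 + exp(-h (log10 c - mu)))` with the
  log10-EC50 `mu` and slope `h` shared across temperatures and
  per-temperature intercepts and amplitudes (`p1 = 2T + 2`).

Both are least-squares fits on the non-vehicle observations (the vehicle
column is the normalisation reference, identically 1, and carries no
information).  The per-temperature coefficients are linear given `(mu, h)`
and are profiled through closed-form 2×2 normal equations; the `(mu, h)`
surface is scanned on a 5×5 grid (`mu` in [-1, 1.5] log10 µM, `h` in
[1e-6, 10]) and refined by Nelder-Mead.  Because the null is the `A_t = 0`
submodel, `rss1 <= rss0` holds structurally and F is invariant to adding a
constant to any temperature row.  An earlier design with the baseline fixed
at 1 (amplitudes only) lacked both properties, and its residual-bootstrap
null was demonstrably miscalibrated — the null-model fit contributes row
means on top of the resampled residual row means, doubling the
ones-direction energy and deflating bootstrap F (observed flat-profile
median ≈ 1.5 vs bootstrap ≈ 0.1); the intercept family removes this failure
mode by construction.

Significance: for each protein, B (default 100) null datasets are built by
resampling null-fit residuals with replacement onto the null fit; both
models are refitted per replicate with the same procedure.  The plug-in FDR
at threshold θ is the average null exceedance count over the observed
exceedance count, made monotone non-increasing in θ by a running minimum
from the smallest θ (the q-value convention); hits are proteins reaching the
smallest θ with FDR < 0.1.  Per-protein RNG substreams derive
deterministically from the global seed and a CRC32 of the protein id.
Direction (stabilized/destabilized) is the sign of the summed amplitudes
over the upper half of the temperature range.

Two alternative hit sets support robustness comparisons: a strict rule
(alternative-model R² > 0.8 and max |log2 relative abundance| > 1.5, read as
an absolute log2 threshold) and the top 100 proteins by a dose-weighted
stabilization score (dose-rank-weighted mean of log2 relative abundance over
the upper half of the temperature range; the score is a stand-in
formulation, as the original is not fully specified in the sources this
design follows).

**TPP activity estimation.** A hit whose selected upstream kinases, through
their PKN edges, all predict the same sign (kinase sign × edge sign) enters
the optimization signed with weight 1.  All other hits enter sign-unknown
with weight = their stabilization magnitude normalized to [0, 1] across
hits.  Separately, kinase→hit edges whose prediction contradicts a
significantly changed phosphosite on the hit protein are removed from the
PKN (kinase-sign filter; only significant sites are used, as non-significant
fold-change signs are noise).

## PKN preprocessing

Four removal-only, idempotent filters: (1) keep edges with both endpoints
expressed (expressed = detected in transcripts after the count prefilter, or
detected in the protein/phospho layers); (2) remove nodes more than 7
directed steps from any input (downstream of kinases/TPP, upstream of
TFs/TPP; distance counted in edges — the directedness of this rule is a
design choice documented here); (3) remove regulator→target edges whose
propagated sign contradicts a significant target abundance change;
(4) drop inputs absent from the filtered network.

## The ILP

Binary up/down states `x+_v, x-_v` per node, binary carriers `y+_e, y-_e`
per edge gated by the source state and edge sign, integer depths enforcing
acyclic carriers, upstream sign locks (none for sign-unknown TPP upstream
nodes), and support constraints for every non-upstream node.  Objective:

    min  sum_{v in M} w_v mismatch_v + beta sum_v (x+_v + x-_v)
         - sum_{v in B} b_v (x+_v + x-_v),

with node-sparsity penalty `beta = 0.2` by default (no edge penalty) and
inclusion bonuses `b_v` for sign-unknown TPP nodes; `b_v >= beta` makes a
node free to include and is warned about.  Upstream nodes may stay inactive;
their sign is locked only when active.  The MILP is solved with HiGHS via
`scipy.optimize.milp` at `mip_gap = 0` by default; only the objective value
is contract-bound (edge sets among ties are solver-dependent).  A
brute-force enumerator over node-state assignments with an iterative
support-closure feasibility check serves as the exact oracle on instances of
up to 14 nodes and agrees with the MILP objective to 1e-9 on random
instances.

**Two rounds and merging.** Round A: kinases ∪ signed TPP upstream, TFs
downstream (sign-unknown TPP upstream without lock, with bonus).  Round B:
kinases upstream, TFs ∪ signed TPP downstream.  Solution edges whose
propagated sign contradicts the measured sign of their target are removed
from the PKN, both rounds repeat, and the final network is the union with
duplicate edges collapsed (round provenance recorded).  Node-state conflicts
resolve toward the lower-objective run; edges inconsistent with resolved
states are dropped, union-induced cycles are broken by removing
higher-objective-run edges, and unsupported remnants are pruned — these
merge repairs are this package's design choices for an under-specified step,
and the final network always passes the structural checker (sign-consistent
support, acyclic).

## Network analysis

Over-representation is a one-tailed Fisher exact test (hypergeometric upper
tail) against the preprocessed-PKN background (network level) or the
measured features (single-omics level), gene sets restricted to the
background with size window [5, 500], Haldane-corrected odds ratios, BH
adjustment at q < 0.05.  Communities come from Clauset-Newman-Moore greedy
modularity on the sign/direction-collapsed simple graph (deterministic under
lexicographic node insertion); clusterings are compared by pairwise Jaccard
index.  Two networks' enrichment profiles are compared through per-pathway
`log OR` differences restricted to pathways significant in either network
with at least 4 query nodes, testing pathway groups against each other with
a two-sided Wilcoxon rank-sum test by default (Welch's t available, as both
appear in practice for this comparison).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw mass spectrometry.  A layered signed digraph (kinases → intermediates →
TPP proteins → intermediates → TFs, edges only forward, so the PKN is
acyclic; signs Bernoulli(0.7) activating) carries a planted sign-consistent
path system from 2 kinases through 3 TPP proteins (one via an intermediate,
one directly phosphorylated, one terminal without a route to any TF) to
2 TFs.  Defaults: 60 nodes, 150 edges, 3/4/3 kinase/TPP/TF roles; these
sizes keep a full ten-seed recovery study within minutes while leaving
enough random edges for non-trivial shortcut structure.

Downstream data follow the generative models the statistics assume: 3+3
replicates; transcripts NB with dispersion 0.05 and target genes of
planted-active TFs shifted by `mode × sign(TF) × 1.0` log2 units (30 targets
per TF, 80% activating modes); phosphosites Gaussian (sd 0.2) with substrate
sites of planted-active kinases shifted likewise (≥6 sites per kinase,
including sites on actual PKN successors so the kinase-sign filter is
exercised); each protein carries a per-sample abundance component (sd 0.5)
shared with its sites — the signal the protein-level correction removes —
plus a 0.6 abundance confound on 20% of proteins; TPP profiles follow the
dose-response model with amplitude 0.5 over the upper temperature half
(sign = planted direction) and noise sd 0.05 against 50 flat background
proteins.  Effect sizes and noise levels follow the simulation conditions
the calibration studies state; they are strong, clean signals.

What passing the benchmark shows: the statistics are calibrated on their
own generative models, the ILP is exactly optimal, and the full pipeline
recovers a planted truth (median node F1 ≥ 0.7 over ten seeds) with the TPP
layer contributing strictly more recovered TPP proteins than the no-TPP
variant.  What it does not show: robustness to missing-value mechanisms, TMT
ratio compression, regulon misannotation, identifier mismatches, or
genome-scale prior networks — none of which the generator emulates.

## Known limitations

* The NB test is a simplification; borderline transcript calls can differ
  from a full GLM pipeline with outlier handling.
* The bootstrap FDR is a plug-in estimate; at very small protein counts its
  tail estimates are noisy (mitigated by pooling nulls across proteins).
* The phosphosite correction attenuates site signal when the matched protein
  trace is uninformative (see above).
* Merge repairs (conflict resolution, cycle breaking) are tie-breaking
  policies; alternative optima with equal objective may yield different edge
  sets across solver versions.
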