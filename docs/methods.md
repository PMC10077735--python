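# Methods

`scpa` infers protein activity from sparse single-cell UMI counts and links
cell states to bulk disease signatures.  This note documents the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
want to know.

## Pipeline overview

1. **QC** — keep cells with ≥ 1000 UMIs, 300–8000 expressed genes, ≤ 5%
   mitochondrial UMIs (genes prefixed `MT-`), and library complexity
   log10(n_gene)/log10(n_umi) ≥ 0.8, all boundaries inclusive on the keep
   side.
2. **Normalization** — regularized negative-binomial Pearson residuals
   (below), top-3000 genes by residual variance flagged highly variable.
3. **Expression clustering** — PCA on HVG residuals (default 30 PCs, signs
   fixed by making each component's largest loading positive), a shared
   nearest-neighbor graph (Jaccard weights over Euclidean k=20 KNN lists),
   Louvain modularity optimization, and resolution selection by mean
   silhouette (correlation distance, 1 − Pearson r over PC coordinates)
   over 100 random subsamples of up to 500 cells on a 25-point grid in
   [0.01, 1.0]; ties go to the smaller resolution.
4. **metaCells** — per cluster, up to 250 seed cells drawn without
   replacement; each pools the raw counts of its k = 10 nearest same-cluster
   neighbors in PC space (seed included), renormalized to log2(CPM + 1).
   k = 1 reduces to pass-through.
5. **Network inference (ARACNe-style)** — pairwise mutual information
   between each regulator and every gene by adaptive partitioning of the
   rank plane; significance threshold from a permutation null; per-bootstrap
   DPI pruning; Poisson consensus over 100 bootstraps.  Regulator classes
   (TFs, co-TFs, signaling, surface) are plain-text lists run separately
   and unioned.
6. **Activity (aREA / metaVIPER)** — per-gene z-score signatures against
   the all-cell reference; regulon enrichment NES per cell; multi-network
   integration with confidence weights NES².
7. **Activity re-clustering and master regulators** — the activity matrix
   is re-embedded and re-clustered with the same silhouette-optimized
   Louvain; per cluster, a bootstrapped Welch t (100 bootstraps) ranks
   proteins.
8. **Bulk arm** — TMM + log2 CPM, a voom/eBayes-style moderated two-group
   contrast, DEG calls at |log2FC| > 1 and BH-adjusted p < 0.05, genes
   ranked by log2FC for GSEA of each cluster's top master regulators, with
   leading-edge extraction and cross-dataset intersection.
9. **GSVA** — per-cell pathway scores on the activity matrix (switchable to
   expression).

## Normalization model

Per gene g and cell c the NB model is `mu_gc = exp(beta0_g) * n_umi_c`
(intercept plus log-depth offset; the intercept has the closed-form Poisson
MLE `log(sum_c x_gc / sum_c n_umi_c)`).  The dispersion theta_g is
moment-estimated from `E[(x − mu)²] = mu + mu²/theta` and then regularized
by Nadaraya–Watson Gaussian-kernel regression of log10 theta on log10 gene
mean (bandwidth 0.3 dex).  Residuals `(x − mu)/sqrt(mu + mu²/theta)` are
clipped to ±sqrt(n_cells).  The regularization presumes a smooth
mean–dispersion trend; per-gene dispersion that is independent of the mean
is deliberately shrunk toward the trend.  This is a from-scratch scheme in
the spirit of regularized-NB normalization, validated by parameter recovery
on synthetic NB data, not by byte equality with any external tool.

## Mutual information and network inference

MI is estimated on ranks by recursive quadrant partitioning: a region is
split at its midpoints when the chi-square of quadrant occupancy exceeds the
5% critical value (df 3); the root split is unconditional so independent
data yields a small positive estimate rather than a degenerate 0.  Leaves
contribute `n/N · log(nN / (n_row · n_col))`.  Ties are broken by a
deterministic seeded jitter of 1e-9 × SD before ranking.  An equal-frequency
binned estimator is kept solely as an independent test oracle.  Exact
mirror symmetry under rank reflection holds when region widths stay even
(e.g. n a power of two); for general n the estimates agree to a few
percent.

The significance threshold comes from a permutation null (default 1000
decoupled gene pairs): within the empirical range it is the (1 − p)
quantile; deeper tails are extrapolated by a linear fit of log p on MI over
the top 20% of the null, floored at the largest observed null value so the
threshold is monotone in p.  The default p = 1e-8 follows ARACNe
convention; the desk-scale studies run per-cluster networks at p = 1e-4
because ~250 metacells from 200-cell clusters carry far fewer effective
observations than the tool's usual operating point.

Each bootstrap resamples metacells with replacement and adds Gaussian noise
of 0.1 × per-gene SD before ranking: duplicated observations would
otherwise register as spurious fine-scale dependence under any rank-based
estimator.  DPI (tolerance 0) removes, simultaneously against the
thresholded edge set of that bootstrap, every edge (a,c) with
`MI(a,c) < min(MI(a,b), MI(b,c))` over common neighbors b.  Consensus keeps
edges whose occurrence count exceeds the Bonferroni-corrected (α = 0.05)
Poisson upper tail with mean = total occurrences / candidate pairs tested.

Note that the *consensus* edge count is not monotone in the MI p-threshold:
a lenient threshold floods each bootstrap with noise edges, which raises
the Poisson bar and intensifies DPI pruning.  Monotonicity is exact at the
thresholding level and is tested there.

Regulons attach `tfmode` = Spearman correlation of regulator and target
across metacells and `likelihood` = edge MI / max MI in the regulon,
truncated to 50 targets, dropped below 25 (relaxed to 10 in the desk-scale
studies).

## aREA, metaVIPER, master regulators

Signatures are per-gene z-scores of log2 CPM against the all-cell mean/SD
(a rank-normal variant is available).  For a cell's signature, genes are
rank-transformed to r ∈ (0,1); the directional quantile is Φ⁻¹(r) and the
magnitude quantile Φ⁻¹(0.5 + |r − 0.5|).  Target i contributes
`m_i·q1 + (1 − |m_i|)·q2` with m_i = tfmode; the likelihood-normalized
weighted sum divided by sqrt(Σ w²) gives an NES whose null is approximately
standard normal (verified against a 10,000-shuffle permutation null).  The
regulon-size floor is 25 targets, lowered to 10 when the gene universe has
fewer than 2000 genes.

metaVIPER integrates per-network NES with weights w_n = NES_n²
(`Σ w·NES / sqrt(Σ w²)`); a protein carried by one network passes through
unchanged, and integration is order-invariant.

Master regulators: per cluster, 100 bootstrap resamples (cluster and rest
resampled separately) each yield a Welch t across proteins; the summary is
the studentized bootstrap mean z = mean(t)/sd(t) with a two-sided normal p.
A naive Stouffer accumulation over bootstrap t-values (×sqrt(100)) treats
strongly dependent resamples as independent tests and inflates |z| roughly
tenfold; the studentized form holds the null false-positive rate at ~5%,
which is the binding contract here.  "Top MRs" of a cluster are its top-n
proteins by z among those with z > 0: on a small protein universe an
uncapped top-100 would dip into anti-activated proteins, which the
genome-scale top-100 extraction never reaches.

## Bulk arm

TMM uses a 30% M-trim, 5% A-trim, inverse-asymptotic-variance weights, the
reference sample whose upper-quartile count fraction is nearest the mean,
and factors scaled to geometric mean 1.  The moderated contrast fits
per-gene weighted least squares with precision weights from a lowess trend
of sqrt(residual SD) on average log2 count, then shrinks variances with a
moment-matched scaled-inverse-chi-square prior (trigamma inversion, as in
empirical-Bayes moderation).  Acceptance is statistical calibration
(uniform null p, FPR in band, sensitivity on planted effects), not
numerical equality with any external package.  `differential_expression`
takes an explicit `baseline` label; the contrast is group-minus-baseline.

GSEA uses the weighted KS running sum (hit increments ∝ |log2FC|^p, p = 1;
miss decrements 1/(N − n)) against a gene-set permutation null of
size-matched random sets; NES = ES / mean(|null ES| of matching sign); the
p-value is estimated within the sign-matched null subset.  Sample
permutation is unavailable by design: the unit is a protein set against one
fixed ranked list.  The full ranked list is the default universe, with a
DEG-only switch.  Leading-edge overlap is reported against each input set
and against the union, since either denominator is defensible.

GSVA: per gene, a Gaussian-kernel ECDF across cells (bandwidth SD/4) gives
the expression-level statistic; per cell, genes are ranked by it and a
KS-like walk with centered-rank weights (tau = 1) is scored as max positive
plus min negative deviation (`max_diff`) or the signed extremum
(`classic`).  Constant rows are excluded.

## Synthetic data: what it emulates and what it does not

The generator plants a `TruthNetwork` (regulators, signed weighted targets)
and drives per-cell gene means log-linearly: a cell's latent activity for
regulator p is its cluster's activity a_{p,k} plus N(0, activity_sd)
jitter; the regulator's own gene moves with coefficient 1 and each target
by sign × strength × activity.  Without the within-cluster jitter,
regulator and target expression would not co-vary inside a cluster and
per-cluster network recovery would be impossible; the cluster-level mean
behavior is unchanged.  Counts are Gamma–Poisson (shared dispersion, NB
marginals) thinned multinomially to an exactly controlled LogNormal library
size, so column sums equal the drawn libraries.  The first 20 genes are a
mitochondrial block receiving a requested per-cell share in expectation.
Cells can be forced to violate named QC rules for boundary testing.
Targets exclude other regulators by default: cascaded regulation creates
indirect dependence through shared upstream drivers that no pairwise-MI
method fully separates from direct edges, and the recovery studies are
meant to measure estimator performance, not that identifiability limit
(`allow_regulator_targets=True` plants cascades deliberately).

Defaults are tuned once to emulate 10x-like chondrocyte data at desk scale:
library sizes LogNormal(log 1600, 0.12) and base log2-abundance SD 0.8 give
per-gene depth and QC-metric distributions (complexity ≈ 0.83, ~500
expressed genes per cell on a 1000-gene universe) such that normal cells
pass every QC rule, as real retained cells do.  The bulk cohort mirrors an
18-healthy vs 20-disease design; disease shifts are
`Σ sign·strength·Δa_p` in log2, recorded exactly as the planted truth.

Not emulated: batch effects beyond library-size variation, doublets,
ambient RNA, cell-cycle structure, and regulator cascades (off by default,
above).  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated generative model, not robustness to
those artifacts.

## Study scales

Chosen so the full suite and the validation script run comfortably on one
CPU:

- **Regulon recovery** — 4000 genes, 25 regulators × 40 targets (strengths
  1–2, signs balanced), one population of 4000 cells with activity SD 1.5
  and library sizes scaled with the universe (LogNormal(log 3200, 0.12)) so
  per-gene depth matches the standard scale; 800 metacells (k = 5); 100
  bootstraps.  Keeping the planted targets a modest fraction of the
  transcriptome matters: log-CPM normalization couples every gene through
  the library denominator, and when half the universe is regulated this
  compositional common mode becomes a dominant false-edge source that no
  real transcriptome exhibits.
- **Standard five-cluster study** — 1000 genes, 25 regulators, 5 clusters ×
  200 cells, activity magnitude 1.8, activity SD 0.8; per-cluster networks
  at 250 metacells (k = 10), 100 bootstraps, MI p = 1e-4; both cluster
  optimizations at 100 silhouette repeats.
- **Calibration nulls** — 1000 genes/proteins × 150–200 cells; 18 vs 20
  bulk samples; 500 GSEA draws at 200 permutations.

## Known limitations

- The MI estimator's conservative chi-square splitting underestimates MI by
  ~5–15% for moderate dependence at n ≤ 500; the permutation-calibrated
  threshold absorbs this for edge calling.
- Metacell pooling with large k relative to cluster size (overlap of member
  sets) inflates all pairwise MI; network precision degrades when
  k × n_meta approaches several times the cluster size.  Defaults keep the
  overlap moderate.
- The voom/eBayes-lite chain uses per-observation weights from a single
  lowess pass and moment-matched moderation; exact agreement with
  limma-voom is out of scope.
- Resolution optimization scores a single-cluster partition as silhouette 0
  (no separation evidence), which is a convention, not a statistic.
- `estimate_mi` rank-reflection symmetry is exact only for power-of-two
  sample sizes (midpoint parity); see above.
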