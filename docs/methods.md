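# Methods note

This note documents the statistical model, the design choices and their
rationale, the synthetic-data generators and their limitations, and the
numerical conventions used throughout `screenkit`.

## 1. Dropout-screen arc

### Normalization and fold change

Hairpin counts are converted to within-sample proportions; the
per-replicate log2 fold change is

  log2FC = log2((c10/N10 + q) / (c0/N0 + q)),  q = pseudocount / mean depth.

The pseudocount (default 0.5 reads at mean depth) lives on the proportion
scale so that the offset is depth-invariant. T0 replicate r is paired with
T10 replicate r when both exist; unpaired T10 replicates fall back to the
T0 mean proportion. A log2FC of −1 corresponds exactly to an abundance
fraction of 0.5 in the limit of a vanishing pseudocount.

### Moderated t-test

With n = 3 replicates, per-hairpin variances are unstable. We use the
standard empirical-Bayes treatment: the replicate variances s² are assumed
to follow a scaled inverse-χ² prior (d0, s0²), estimated by matching the
mean and variance of log s² through digamma/trigamma equations (the
trigamma inverse is solved by Newton iteration). The posterior variance
s̃² = (d0·s0² + d·s²)/(d0 + d) feeds t = mean/ (s̃/√n) with d0 + d degrees
of freedom; d0 = ∞ (no excess spread in log s²) reduces to full pooling
with a normal reference. On a null screen of 5,001 hairpins the p-values
are uniform (KS) with type-I error ≈ 0.05 at α = 0.05.

### z-scores, meta-analysis, candidate filters

Per line, hairpin mean log2FCs are z-scored against a Gaussian fitted
robustly (median and 1.4826·MAD) because dropout screens have heavy
negative tails; a moment fit is available as an option. Within a group of
lines the Stouffer statistic Z = Σz/√k preserves the standard normal null;
two groups are contrasted with z_comp = (Z_a − Z_b)/√2, so |z_comp| ≥ 1.96
corresponds to a two-tailed p < 0.05. Candidate hairpins must satisfy three
clauses: (1) comparative p < 0.05 with z_comp < 0 (depletion direction),
(2) log2FC ≤ −1 in every line of the target group, (3) no strong
significant depletion (p < 0.05 and log2FC < −1) in any non-transformed
line. Genes qualify via at least `min_hairpins` passing hairpins (default
1) and are ranked by the most negative z_comp.

### QC and line classification

Replicate agreement is summarized per line by Pearson and Spearman
correlation of replicate log2FC profiles. "Common essentials" are genes
depleted (p < 0.05, negative log2FC, any hairpin) in ≥ 3 lines; their
overlap with a reference list uses Fisher's exact test (scipy), with the
Haldane 0.5 correction applied only to the reported odds ratio. Lines are
clustered on hairpins depleted in ≥ `min_lines_cluster` lines whose IQR of
z across lines is strictly above the 70th percentile (numpy linear
interpolation; with all-distinct IQRs exactly the top 30% is retained),
using 1 − Pearson distance and complete linkage. The default
`min_lines_cluster = 2` is one third of the default panel's six cancer
lines, the desk-scale analog of a "recurrent over one third of lines"
rule; with only 2 lines per planted subtype, requiring more recurrence
would empty the feature set.

### Enrichment

Over-representation uses the one-sided hypergeometric tail per gene set
with Benjamini–Hochberg correction across sets (statsmodels); an optional
EASE variant subtracts one from the overlap. The ranked test is a weighted
Kolmogorov–Smirnov running sum (hits weighted by |stat|^w, misses uniform)
with a gene-label permutation null, same-sign NES normalization and
add-one-corrected p-values.

## 2. Activity arc

### Preprocessing

Quantile normalization maps each column's ranks onto the mean sorted
profile (average ranks for ties); duplicate gene rows keep the highest-IQR
copy; rows with IQR < 0.5 are dropped.

### Mutual information and network

MI is estimated on the rank-rank plane by adaptive partitioning: a quadrant
is split at its rank midpoints while a χ²(3 df) uniformity test rejects at
α_split = 0.05 and at least 8 points remain; MI is the plug-in sum over the
leaf cells. The estimator is implemented with numba and matches the
Gaussian closed form −½ln(1−ρ²) within a few percent at n = 5,000. A
fixed-grid rank-bin estimator is available as a fallback.

The significance threshold maps a target p to an MI cutoff via a
permutation null (10,000 permuted pairs) with an exponential mean-excess
tail fit above the 90th percentile — necessary because desk-scale nulls
cannot resolve p = 1e−4 empirically. Per bootstrap (sample resampling with
replacement), regulator–gene MI is computed and thresholded; MI among that
bootstrap's candidate neighbor genes is then computed so indirect chains
(regulator → target → downstream gene) form complete triangles, and DPI
removes every triangle's weakest edge when its MI < min(other two)·(1−ε),
ε = 0 by default. Neighbor–neighbor edges only mediate pruning; the
consensus counts regulator-incident edges. Without the triangle-completing
step a single-regulator network has no triangles at all and DPI cannot
remove indirect edges — planted chain genes then enter the regulon.

**Consensus support (deviation from the reference tool's majority
Poisson consensus).** The consensus keeps edges present in ≥ 20% of the 25
bootstraps. This is an explicit design choice: zero-tolerance DPI is
unstable under resampling (a true edge loses its triangle contest in a
minority of bootstraps), so a majority vote discards true edges, while
false edges recur rarely. With a per-bootstrap false-inclusion rate near
the 5% level for locally correlated pairs, P(Binomial(25, 0.05) ≥ 5) ≈
2.6e−3, so support 0.2 still controls false consensus edges. Measured on
planted networks, true edges have support 0.16–1.0 and false edges ≤ 0.08.

### Regulon, scoring, tests

The regulon is the hub's first network neighbors; the mode is the signed
Pearson correlation of hub and target on the full matrix and the
confidence is the bootstrap support. Activity per sample is the maxmean of
mode-sign-adjusted row z-scores: s⁺ = mean positive part over all regulon
genes, s⁻ = mean negative part, score = s⁺ if s⁺ ≥ s⁻ else −s⁻. The
master-regulator test computes per-gene pooled two-sample t statistics
between groups (vectorized over label permutations via indicator-matrix
algebra), summarizes them with the mode-adjusted maxmean, and compares the
observed statistic with a sample-permutation null (add-one two-sided p,
NES standardized against the null). Covariate adjustment uses a
nested-model OLS ANOVA (statsmodels) with rank-aware degrees of freedom so
aliased covariates contribute nothing rather than crashing.

## 3. Synthetic generators

All generators are pure functions of (config, seed); child streams are
derived with `numpy.random.SeedSequence([seed, k])`, so different
components never share a stream and reruns are byte-identical.

**Screen generator.** Hairpin baseline abundances are lognormal; planted
effects (default −2 log2 units) apply to general essentials (all lines),
subtype essentials (their subtype's lines), and IBC-specific essentials
(IBC lines). T10 proportions are p0·2^effect renormalized; counts are
negative binomial (var = m + φm², φ = 0.01; φ = 0 gives Poisson). FASTQ
export embeds guides between fixed flanks with per-base substitution
errors, and deconvolution inverts it by exact substring match with a
sliding-window mismatch fallback (exact hits outrank mismatched ones;
cross-hairpin ties are ambiguous).

**Expression generator.** A latent activity a = shift·group + e drives the
planted targets (signed coefficients drawn from ±[0.6, 1.4]); chain genes
follow 0.8·parent + noise to create the indirect correlations DPI must
prune; decoys are pure noise. The hub's own mRNA is modeled as a faithful
readout of within-group activity fluctuation (hub = mRNA-shift·group + e +
0.3·noise) with zero group shift by default: the hub transcript must
correlate with its targets (otherwise no MI edge, hence no regulon exists
to find) while carrying no group signal — activity, not expression,
separates the groups. The observation-noise level 0.3 is a generator
design parameter: appreciably larger values make the hub transcript an
unfaithful reporter of its own activity and the inference problem
ill-posed by construction. Structure (signs, coefficients) is drawn from a
structure-only stream so that independent draws (`draw_id`) share the
regulon while resampling noise — this provides the inference compendium /
scoring cohort split used by the pipeline (network inferred on 300
shift-free samples, activity scored on a separate 80-sample cohort).

**Limitations.** Counts are independent across hairpins (no guide-level
off-target structure, no GC bias); expression is Gaussian and linear (no
saturation, no multi-hub overlap); group sizes are balanced; the panel is
8 lines at desk scale rather than a genome-scale screen. These choices keep
runtimes in seconds while preserving the statistical structure each method
is meant to exploit.

## 4. Numerical conventions

- Two-sided p-values are clipped to [tiny, 1]; permutation p-values are
  add-one corrected and never 0.
- Quantiles use numpy's default linear interpolation; the feature filter
  keeps IQRs strictly above the cutoff.
- Ranks are dense 0..n−1 with deterministic tie-breaking by position;
  GSEA ranking breaks statistic ties by gene id ascending.
- Dendrograms order labels lexicographically before clustering so results
  do not depend on input order; Newick export encodes merge heights as
  branch lengths.
- All tables are written as TSV with fixed column order; JSON artifacts are
  sorted by key — reruns with the same config are byte-identical.

## 5. Default parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| pseudocount | 0.5 | half-read offset at mean depth, depth-invariant |
| p_cut / log2fc_cut | 0.05 / −1 | two-tailed 5%; abundance at most halved |
| min_lines_essential | 3 | recurrence across ≥ 3 of 8 lines |
| min_lines_cluster | 2 | one third of the 6 cancer lines |
| iqr_quantile | 0.70 | keep the top 30% most variable features |
| MI p_threshold | 1e−4 | desk-scale analog of the reference 1e−7 |
| dpi_tolerance | 0 | strict DPI |
| n_bootstraps | 25 | desk-scale analog of the reference 100 |
| consensus_min_support | 0.2 | binomial-null bound, see §2 |
| nb_dispersion | 0.01 | mild overdispersion typical of count data |
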