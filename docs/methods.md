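# Methods

## Model and procedure

The pipeline treats "which pathways tell cell types apart" as a three-stage
problem on a log2 expression matrix with K ≥ 2 sample classes.

**Per-gene ANOVA.** Each gene is fit with the one-way fixed-effects model
y_jk = μ + μ_k + ε_jk, ε ~ N(0, σ²). The F-statistic is the ratio of the
treatment mean square (between-class sum of squares over K−1) to the
residual mean square (within-class sum of squares over N−K), so that under
the null F ~ F(K−1, N−K). Both terms are scaled as mean squares — this is
the only scaling under which the reference F(K−1, N−K) distribution is the
null, and the implementation is verified against `scipy.stats.f_oneway` to
1e-10 relative. Genes constant across all samples have no defined F and are
excluded; genes with zero residual variance but real class differences get
F = ∞ and are likewise excluded from log-F pools (counts are logged).

**Pathway-level Welch T.** A pathway's detected members (those present with
finite positive F) contribute their log2 F values; the comparison pool is
the union of detected genes over all tested pathways, *including* the
pathway's own members — the statistic compares a pathway to the annotated
background, not to its complement. The log transform is what makes a
t-test defensible here: F is heavily right-skewed, log2 F is approximately
symmetric. The T uses unbiased sample variances and Welch–Satterthwaite
degrees of freedom, and is two-sided by default with the direction (sign of
the mean difference) reported separately; a one-sided "greater" option
exists because enrichment in discriminative genes is a right-tail
alternative. p-values are Benjamini–Hochberg adjusted once across all
tested pathways per run (delegated to statsmodels; the textbook step-up is
kept as an independent oracle in the tests). Ranking ties on adjusted p are
broken by |T| descending, then pathway ID, for full determinism.

**Flat genes.** A gene is "flat" when its differential-expression p exceeds
a threshold (default 0.05). The default statistic is the ordinary ANOVA p.
An optional empirical-Bayes variant shrinks each gene's residual variance
toward a pooled prior fitted by moment matching under the scaled-F sampling
model s² ~ s0²·F(d, d0) and refers the moderated F to F(K−1, N−K+d0); it
stabilises calls at small replicate counts. The threshold rule is strict
(p > t), with one documented special case: a threshold ≥ 1 flags every gene
(the strict rule alone can never do so, since p ≤ 1).

**Synexpression decomposition.** Within a significant pathway, flat and
F-undefined genes are removed, and the rest are clustered by average-linkage
(UPGMA) agglomeration on Pearson correlation distance d = 1 − r computed on
the raw sample vectors. Average linkage is the conventional pairing with
correlation distance in expression work and is deterministic; determinism
*including tie cases* and invariance to input gene order are obtained by
sorting genes lexicographically before building the linkage, rather than by
a custom agglomeration loop.

**Informativeness.** Candidate cluster counts c = 1..c_max are scored by
averaging, over groups, the log2 F obtained by running the same one-way
ANOVA on each group's mean profile (the profile is treated as a single
gene); an optional penalty λ per group (default 0) is subtracted. The
chosen c is the smallest whose score is within a relative plateau tolerance
(default 0.01) of the maximum — "the most clusters that stay consistently
informative" read conservatively. The per-group *mean* (not sum) is
deliberate: summing grows roughly linearly in c whenever signal is strong
(splitting a coherent group of m genes yields two profiles whose F is about
halved, a net gain in summed log2 F), which would always drive the choice
to c_max. With the mean, splitting a homogeneous pathway dilutes each
profile (fewer genes averaged, noisier profile, lower F), so homogeneous
pathways settle at c = 1 while genuinely opposed patterns (which cancel in
the pooled mean profile) reward splitting sharply. Known limitation: if a
pathway contains ≥ 2 blocks whose patterns are mutually orthogonal *without*
cancelling (the pooled profile keeps 1/B of the pattern variance while
pooling B× more genes), the expected score is nearly flat in c and the
plateau rule conservatively returns c = 1. A group whose mean profile is
constant contributes the minimum log2 F observed among the other groups
(logged). The score is isolated behind one function so an alternative
criterion can be substituted.

**Expansion.** The correlation target is the group's *mean profile* — the
group's discriminating pattern — not all pairwise member correlations; an
optional `min_pairwise` mode additionally demands the cutoff against every
member. The cutoff (default 0.85) is signed: anti-correlated genes are
biologically a distinct (repressed) program and are reported separately,
with an `absolute` flag to attach on |r|. Candidates may be all non-member
genes or only unannotated ones. Attached correlations match brute-force
Pearson to 1e-12. Overlap validation against reference lists uses the
hypergeometric upper tail (one-sided Fisher exact).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_size` | 5 | minimum detected members for a pathway to be tested; guards the variance estimate s²_P. No field-standard value exists; configurable. |
| `fdr` | 0.05 | BH-adjusted significance threshold across pathways |
| `flat_p` | 0.05 | differential-expression p above which a gene is "flat" |
| `c_max` | 10 | largest synexpression cluster count evaluated |
| `plateau_tol` | 0.01 | relative tolerance defining the informativeness plateau |
| `cutoff` | 0.85 | Pearson r for attaching genes to a group |
| `score_min`, `sample_frac` | 0.99, 0.75 | detection filter: keep a gene iff some class has ≥ 75% of samples with detection score ≥ 0.99 (both comparisons inclusive; the fraction is exact, not rounded). Optional — only applied when a detection matrix is supplied. |

Expression values are assumed log2-transformed and normalised upstream; the
tool performs no normalisation and treats gene identifiers as opaque
strings (pathway membership comes solely from the GMT file).

## Synthetic data generator

`SimulationSpec`/`generate` draw data from exactly the ANOVA model above:
baseline 8.0 (a typical log2 intensity midpoint), residual σ = 0.5 (a
realistic log2-scale residual spread for replicated expression data), K = 4
classes with 6 replicates each, one planted pathway among 50 null pathways
of 10–30 genes, planted class-mean patterns with SD `effect_size`·σ
(default 1.5), two blocks per planted pathway whose patterns sum to zero
across blocks (for two blocks: opposite up/down programs — the
configuration the decomposition step exists to resolve; a user-supplied
K × B pattern matrix overrides this), 30 unannotated partner genes per
block at partner noise σ_p = 0.05, a 5% flat fraction inside planted
pathways, and 500 unannotated flat filler genes. Planted and null pathways
draw genes from disjoint pools so ground truth is unambiguous; an
overlapping-membership mode shares null genes across null pathways to mimic
annotation redundancy, and a heavy-tailed option (t with 5 df residuals)
probes robustness. Output is fully deterministic given the integer seed.

What the generator does *not* emulate: probe-level artifacts, correlated
residuals between genes outside planted blocks, class-size imbalance beyond
what the spec requests, batch effects, count-based mean–variance coupling.
Passing tests therefore demonstrate correctness of the statistics and
recovery under the model's own assumptions, not robustness to everything
real data can do.

## Numerical choices

- Constant-gene detection uses a scale-aware tolerance on the raw sums of
  squares (machine epsilon scaled by the squared data magnitude), and exact
  max−min = 0 checks where exact constancy is the question (correlation
  distance, expansion candidates).
- The correlation-distance matrix is symmetrised ((d + dᵀ)/2), clipped to
  [0, 2], with the diagonal forced to 0.
- Welch p-values are capped at 1; pathways with fewer than two usable
  log2 F values or zero pooled variance are skipped with a logged reason.
- BH adjustment is applied once per run over all tested pathways.
- The plateau threshold is `best − tol·|best|`, which behaves sensibly when
  the best score is negative (all-noise pathways).

## Known limitations

- The pathway T-test is slightly liberal at small pathway sizes: with
  10–30 members, log2 F values are left-skewed (the normal approximation
  the t-test relies on is imperfect), and the realised type-I rate under an
  all-null simulation is ≈ 0.055–0.059 at nominal 0.05, shrinking toward
  nominal as g_p grows. Both component statistics are oracle-equivalent to
  scipy, so this is a property of the method, not the implementation; the
  BH step and the 0.05 FDR threshold absorb it in practice.
- The informativeness score's flat-in-c regime for non-cancelling
  orthogonal blocks (above) means c can be under-estimated for pathways
  with ≥ 3 genuinely independent programs of equal strength.
- Welch df and the F-null both presume within-class normality; grossly
  heavy-tailed data (the generator's t(5) mode) inflate variance estimates
  and cost power rather than type-I control.
- Pathways are tested against a shared annotated universe; strongly
  co-expressed genes *within* a pathway violate the t-test's independence
  assumption and can inflate |T| in either direction — the classic
  inter-gene-correlation caveat of self-contained gene-set tests.
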