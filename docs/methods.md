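# Methods

This note documents the models, numerical choices and limitations of the
`ailqtl` pipeline in the order data flows through it.

## Simulated study populations

`synthetic_data` generates the cohorts on which everything downstream is
tested. The design mirrors an advanced intercross line (AIL) bred from two
fully inbred, opposite-homozygous founders (S1 and S2): an F1 cross
followed by rounds of random mating. `n_generations` is the AIL generation
number — 1 is the F1 itself, 10 (the default) means nine rounds of random
mating, matching the generation used for mapping.

**Gamete model.** Per meiosis and chromosome, the crossover count is
Poisson in the physical length (`recombination_rate` crossovers per 100 Mb,
default 0.5 — a mouse-like genome-wide average of ≈0.5 cM/Mb), crossover
positions are uniform, and there is no interference. Genetic maps,
crossover hotspots and sex-specific recombination are deliberately not
modeled: the only property downstream methods rely on is that linkage
disequilibrium decays with physical distance and generation number, which
this minimal model produces. All chromosomes are treated as autosomes (the
emulated study mapped autosomal QTL in males only), and each offspring
draws two distinct parents uniformly per generation, which makes the
variance-effective population size approximately the census size.

Consequences worth knowing: allele frequencies drift — after t generations
in N diploids a marker's frequency has variance `pq(1 − (1 − 1/2N)^t)`
around 0.5, and linked markers drift together, so a single simulated cohort
can have a whole chromosome displaced from 0.5. Tests of frequency behavior
use this Wright–Fisher expression, not the smaller drift-free binomial
error. Within a cohort, random mating keeps genotype proportions at
Hardy–Weinberg given the realized frequency.

**Defaults as study conditions.** `evenly_spaced_design()` defaults to 397
individuals at generation 10 with 1,000 markers over five 150-Mb
chromosomes (≈0.75 Mb spacing). The real array yielded ~5,000 informative
SNPs over the full genome; a thousand markers preserve the marker density
relevant for mapping resolution while keeping simulation-heavy tests fast.
Sub-megabase localization effects are the only thing this down-scaling
sacrifices.

**Trait architecture.** Each `QtlSpec` contributes
`additive_effect × code + dominance_effect × [code == 1]` to its target
trait plus optional mediated input `slope × mediator`; traits are evaluated
in topological order of the mediation graph (cycles are rejected), then
i.i.d. Gaussian noise is added. This makes "the QTL affects T2 only through
T1" a generative statement the causal-modeling stage can be validated
against. Litter size is a uniform integer covariate in 4–12 pups with a
purely additive effect on designated traits (liver weight in the emulated
study).

**Selective genotyping.** `select_tails` standardizes each selection trait
and takes the union of upper and lower extremes, round-robin over
(trait, tail) pairs, until the requested count is reached; ties break on id
order so the selection is reproducible. The emulated study selected 200 of
397 males from the tails of adipose and liver weight but did not state how
the two traits were combined; the union-of-tails rule is this package's
choice, and it guarantees that the k = n_select/(2·n_traits) most extreme
animals of every tail are always included.

**Expression.** Probe baselines are N(8, 1.5) on the log2 scale, a
configurable fraction of probes receives a between-line shift of
`effect_size_log2` (alternating sign), plus N(0, noise_sd) per sample;
values are exported as raw intensities so the normalization stage sees
realistic input. Probe-level variance heterogeneity, background and batch
structure of real arrays are not emulated — passing tests show the testing
and FDR machinery is correct, not that it is robust to array artifacts.

## Phenotype QC

Outliers are single measurements more than k = 4 sample SDs from the trait
mean and are masked per trait rather than deleting the animal (the emulated
protocol's wording refers to individual measurements; either reading is
defensible and this one preserves data). The rule is single-pass: mean and
SD include the outlier itself. Re-running the cleaned table can flag new
values as the estimates tighten; the removal log makes the pass auditable.
Traits with < 3 values or zero SD are skipped.

Glucose/insulin tolerance tests are summarized by the trapezoidal AUC over
the measured interval (mg/dl·min). Trait-pair correlations are
normality-gated: Shapiro–Wilk per trait at α = 0.05 (the split into
Pearson vs Spearman is prescribed by the emulated analysis; the test and
level are this package's choice), Pearson iff both traits pass, on
pairwise-complete observations.

## QTL scan

Genotype enters as an unordered 3-level factor (2 df), not an additive
dosage, because the reported allele effects are three class means and
dominance at metabolic loci is plausible; an additive 1-df scan is
available via `ScanConfig(additive=True)`. Covariates are screened per
trait (slope t-test for numeric, one-way F for categorical, include iff
p < 0.05). Each marker is fit on its complete cases; missing genotypes are
never imputed. No kinship or polygenic term is included — the emulated
study tested subfamily structure and found no influence; for populations
with stronger structure this is a known limitation.

Numerics: p-values come from the exact F distribution; a numerically
perfect fit (RSS below 1e-12 of the total SS) is reported at the LOD cap
(default 300), which also caps all `-log10(p)` values. Markers with fewer
than two observed classes or zero residual df get missing LOD. LOD is
invariant to affine rescaling of the trait.

**simpleM.** Windows of ≤ 820 consecutive markers per chromosome (the
published window size); per window the pairwise-complete correlation
matrix is eigen-decomposed and the smallest k with top-k eigenvalue mass
≥ C = 0.995 is the window's Meff. C is the method's published default; the
emulated study printed window and Meff but not C. Pairwise-complete
correlation matrices can be slightly non-PSD, so eigenvalues are clipped at
zero before cumulating; constant markers contribute zero correlation.
Thresholds are `-log10(α/Meff)` at α = 0.05 ("significant") and 0.01
("highly significant"), which reproduces the published 4.2/4.9 for
Meff = 849.

**Support intervals.** The 1.5-LOD-drop rule: the peak (ties toward the
lower position), the maximal contiguous run of markers around it within
1.5 LOD of the peak (missing LOD breaks the run), extended outward by one
marker and clamped at chromosome ends. Tests show ≥ 90% coverage of the
causal marker for high-LOD (≥ 6) peaks.

**Two stages.** Stage 1 scans the selectively genotyped subset and applies
the genome-wide threshold to per-chromosome peaks; stage 2 refits each peak
marker on all phenotyped animals (array- plus targeted-genotyped) for LOD
and effect estimates, because tail selection biases effect sizes upward —
the refit demonstrably shrinks that bias. Stage-1 significance uses the
same thresholds as a full scan; whether the emulated study did exactly this
is implied but unstated. Peaks missing from the stage-2 genotypes keep
stage-1 estimates flagged `unconfirmed`. Model validity at a top marker can
be checked with `nonparametric_check`: Shapiro–Wilk on residuals, and if
non-normal, Kruskal–Wallis across genotype classes.

## Causal modeling

The three structures (independent, causal, reactive) are factorizations of
the joint Gaussian likelihood of the trait pair given the genotype factor;
each factor is an OLS component whose log-likelihoods add. Models are
compared by AICc — they are non-nested, so a likelihood-ratio test does not
apply, and the small-sample correction matters at n ≈ 400 with up to eight
parameters. The winner must beat the runner-up by a configurable gap
(default 2.0, a conventional "positive evidence" AICc difference);
otherwise the verdict is `undetermined`, as it also is when the winning
model's residuals fail Shapiro–Wilk at α = 0.01 (the implementation of
"no model fits satisfactorily") or when two models fit exactly
(e.g. duplicated traits, where causal and reactive are symmetric).
Verdicts are invariant to affine rescaling of either trait and swap
causal↔reactive under trait exchange. The reference analysis described its
model set but not its selection statistic; the AICc contract here is this
package's versioned choice. Per-trait labels follow: independent → both
direct; causal → T1 direct, T2 indirect; conflicting labels across pairs
of the same QTL are reported, never silently resolved.

## Expression analysis

Log2 then quantile normalization within tissue (columns share the mean
sorted profile; ties receive the mean of their tied ranks' reference
values, so exact multiset equality across samples holds for tie-free
data). Zeros are offset by ε = 1e-6 before the log; a single-sample tissue
is only log-transformed. DE uses Welch's unequal-variance t-test per probe
(the reference analysis said "t-tests" without a variant; Welch is the
safer default), fold change is the log2-scale difference of line means
(S1 − S2), and BH adjustment is applied across probes within tissue with
significance at adjusted p < 0.05. A probe with zero variance in both
groups and equal means gets p = 1. For prioritization, a gene is "DE" if
significant in at least one tissue. `cluster_by_line` reports whether
2-cluster average-linkage clustering of 1 − r between samples separates
the lines perfectly, plus a cohesion score (mean within-line minus
between-line correlation).

## Prioritization

Candidate genes are protein-coding models whose span, padded by 1000 bp on
each flank (to catch promoters), overlaps the QTL interval; overlap is
1-based inclusive and padded abutment counts. Genes without any
founder-line variant in the padded span are removed as monomorphic. Scoring
is category-once by default: each variant category contributes its points
once regardless of variant count, a domain missense contributes domain
points plus the SIFT points of the gene's most severe missense class, and
DE/KEGG always count once. The published per-gene scores are only
reproduced jointly by this category-once rule with additive domain+SIFT
missense points, which is why it is the default; a per-variant mode
(points × qualifying-variant counts) is kept behind `ScoringScheme(mode=
"per_variant")` since the source prose reads per-variant. KEGG relevance is
a per-gene input flag, never fetched live. Ranking is per QTL, descending
score, alphabetical tie-break (logged), top two flagged.

The shipped reference flags (`data/bfmi_candidates.tsv`) are a synthetic
reconstruction: per-gene KEGG membership is not published, so the flags are
derived to be consistent with the published per-gene variant descriptions
and scores (KEGG set for all eight genes except Zfat; DE unset only for
Plg). They pin the scoring arithmetic, not the underlying annotation data.

## Pipeline

`ailqtl run` executes simulate → qc → scan → causal → de → prioritize from
one YAML config; a single root seed deterministically spawns per-stage
seeds (all below 2^31), so reruns are byte-identical. The manifest records
versions, seeds, thresholds and the filter cascade (markers in →
informative → scanned; genes candidate → scored), which must be monotone.
The causal stage runs automatically on overlapping same-chromosome
intervals of different traits, using the higher-LOD peak marker.

## Problem sizes in tests

Simulation-based tests use cohorts of 397 individuals at generation 10
with 100–1,000 markers, replicated 20–100 times depending on the property;
these sizes give the binomial assertion bounds (e.g. ≥ 18/20, ≥ 40/50,
≥ 90/100) comfortable margins under the planted effect sizes (0.5–1
trait-SD per allele copy) while keeping the whole suite under a minute of
simulation time.

## Known limitations

* No X/Y or mitochondrial inheritance; no crossover interference; no
  genotyping error model.
* Single-QTL scan only: no multi-QTL models, interactions, or kinship
  correction.
* Causal modeling is limited to trait pairs with Gaussian errors; no
  latent-variable or measurement-error structure, no networks over > 3
  traits.
* The expression generator does not emulate probe-level artifacts, so DE
  results on real arrays additionally depend on upstream array QC that is
  out of scope here.
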