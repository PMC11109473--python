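# Methods

## Data model

A targeted tracing experiment is represented by up to three aligned
tables over a common sample set: corrected isotopologue measurements
(absolute intensities or MDV proportions, rows indexed by metabolite and
isotopologue index 0…n), per-metabolite total abundances, and
per-metabolite fractional contributions, plus a sample sheet mapping each
sample to (condition, timepoint, replicate). Carbon counts are inferred
as (number of isotopologue rows − 1); an explicitly supplied count that
disagrees is a structural error, not a warning.

Validation enforces the MDV algebra: contiguous isotopologue indices
0…n, non-negative absolute intensities, proportions in [0, 1 + ε] with
per-(metabolite, sample) sums in 1 ± ε. The sum tolerance ε defaults to
0.02 — upstream correction tools routinely leave percent-level
non-closure — and is configurable everywhere it is used. Negative
corrected intensities (a known artifact of natural-abundance correction)
are rejected and reported, never silently clipped. Proportion tables
whose per-cell sums cluster around 100 are auto-detected as percentages
and rescaled by 1/100 (logged), since both conventions circulate.

## Derived quantities

- m = Σⱼ Mⱼ (total abundance), cᵢ = Mᵢ/Σⱼ Mⱼ (MDV), φ = Σⱼ(cⱼ·j)/n
  (fractional contribution / mean enrichment).
- A zero-total (metabolite, sample) cell makes the MDV a 0/0; it is
  recorded as missing and excluded pairwise from tests. Missing values
  are never imputed.
- When a user supplies a table that is also derivable from the
  isotopologues, the supplied table wins; a relative discrepancy above
  1e-6 is reported in the dataset log so upstream inconsistencies surface
  instead of disappearing.

## Univariate testing

Six tests are offered: Student t (equal-variance by default; Welch via
option), Mann–Whitney, Wilcoxon rank-sum, Wilcoxon signed-rank (paired,
aligned by replicate index), Kruskal–Wallis (the multi-group default and
requirement), and a two-group permutation test. All p-values are
two-sided; statistics are oriented so positive means group A above group
B (rank statistics are centered at their null means). Rank tests use
exact null distributions when both groups have ≤ 25 observations and no
ties, otherwise the normal approximation with continuity and midrank tie
correction; Kruskal–Wallis uses the χ²(k−1) reference with tie
correction.

The permutation test permutes group labels. Default statistic:
difference of means (options: absolute mean difference, centered rank
sum); default budget 10 000 permutations; p follows the add-one rule
p = (1 + #{|T*| ≥ |T|})/(1 + N), so p > 0 always. When the number of
distinct labelings C(n_A+n_B, n_A) is within the budget the engine
switches to exhaustive enumeration and the p-value is exact (flagged as
such). Comparisons of |T*| against |T| use a 1e-12 relative guard so
analytically tied labelings are never lost to floating-point noise.

**The small-sample resolution floor.** With triplicates, the exhaustive
two-sided permutation p over C(6,3) = 20 labelings cannot fall below
2/20 = 0.1, and the exact two-sided rank-sum p has the same floor; BH
adjustment only raises p-values. Consequently *no* feature can clear an
α = 0.05 FDR threshold from a 3-vs-3 exact nonparametric test: at n = 3,
ranked effects and raw p-values carry the signal, and only the t-test
(continuous p) can produce adjusted significance. This is a mathematical
property of exact tests, not an implementation limit; it is asserted by
the test suite and stated here so users do not misread empty DAM lists
at n = 3.

Effect sizes: log2 ratio of group geometric means for abundances
(strictly positive, spanning decades); difference of group means for
fractional contributions and isotopologue proportions (bounded in
[0, 1], where ratios mislead). FDR families are one
(comparison × quantity type): abundance results never share a family
with isotopologue results, and each isotopologue feature
(`metabolite_m+i`) is adjusted independently. Per-quantity default
tests: permutation for abundances and fractional contributions, Wilcoxon
rank-sum for isotopologue proportions; both overridable per quantity.
Features with too few non-missing observations are reported with a
reason code and excluded from the family size — never a silent NaN.

Randomness: one top-level seed; each feature's permutation stream is
seeded by (seed, CRC32 of the feature id), so feature order, subsetting,
or parallel evaluation can never change a result.

## Time-course analysis

For T timepoints ordered by their numeric hour, exactly T−1 families
t_{i+1} vs t_i are generated (labels like `4vs2`, `24vs6`), each with its
own FDR adjustment per quantity type. A feature is *time-responsive* if
significant in at least one interval. Note that with triplicate groups
the resolution floor above applies per interval; the t-test is the
appropriate choice for n = 3 kinetics designs.

## Bivariate MDV comparison

Whole labeling profiles are compared as group means of per-sample
proportions (not pooled samples: the profile is a group-level object).
Spearman ρ uses midranks; for profiles with ≤ 8 isotopologues the
p-value comes from the exact permutation distribution of ρ (all (n+1)!
rank permutations), otherwise the t approximation. Metabolites with
n ≤ 1 carbons (2-point profiles) are excluded with a reason; constant
profiles have no rank variance and are reported as undefined rather than
assigned a value. Per comparison, the ρ p-values form one FDR family.

## PCA

Samples in metabolite space, via full-SVD PCA. Defaults by quantity:
abundances are log10(x + δ)-transformed (δ = half the smallest positive
value) and unit-variance scaled, because metabolite pools span orders of
magnitude; fractional contributions enter centered but unscaled (already
bounded). Zero-variance features are dropped and reported. Component
signs are fixed by making each component's largest-magnitude loading
positive, so results are bit-reproducible.

## Metabolograms and network projection

For one pathway and one comparison, the metabologram pairs metabolite
segments (inner ring, alphabetical) with gene segments (outer ring) —
raw signed differential values on a color domain symmetric about zero
(the max |effect| across both omics), and additionally rescaled to
[−1, 1] within each ring so neither omics' dynamic range swamps the
other. Members absent from the results enter as neutral grey segments
flagged "not measured"; non-significant segments render muted. Which
metabolite quantity is shown (abundance effect or enrichment effect) is
a configuration choice — both are supported.

On a user-supplied reaction graph (metabolite nodes as ovals, gene nodes
as rectangles), an edge into metabolite v is styled *hypothesized slow*
when v's fractional contribution decreased significantly while its
abundance is non-decreasing: the signature of a pool that accumulates
while labeling slows, consistent with either a slower producing flux or
an unlabeled alternative source. The rule is an interpretive aid, is
labeled as such in the output metadata, and is not a flux inference.

## Synthetic data generator

Each (metabolite, sample) cell is (total pool) × (replicate MDV). Pools
are lognormal around a condition mean with CV 0.2 (typical targeted
LC-MS replicate scatter); replicate MDVs are Dirichlet around the
condition/timepoint MDV with concentration 500 (component SD ≈ 0.02 —
tight, instrument-like noise on the simplex, which is the natural noise
model for compositions). Time courses start fully unlabeled (all mass in
m+0 at t = 0) and relax toward a randomly drawn steady-state MDV with a
per-metabolite half-time around 2 h, so 0–24 h spans the pre-steady-state
window. Injected effects: abundance shifts in units of the log-scale
replicate SD (2.0 ⇒ a 2σ effect), enrichment shifts as absolute Δφ
implemented by mixing the MDV toward the fully (un)labeled corner. Two
presets: `ldh_ko_48h` (2 conditions × 3 replicates at 48 h, ten
metabolites including 5-carbon α-ketoglutarate/glutamate analogs with an
abundance increase plus enrichment drops) and `timecourse_p3`
(1 condition × 6 timepoints × 3 replicates, including one never-labeled
control metabolite). Identical seeds give byte-identical tables.

What the generator does *not* emulate: batch effects and drift,
missing-at-random peak dropouts, correlated metabolite pools,
natural-abundance correction artifacts (negative intensities), and
heteroscedasticity beyond the lognormal model. Passing recovery tests on
these fixtures therefore demonstrates correctness of the statistical
machinery under clean, known conditions — not robustness to every
real-data pathology.

## Numerical and testing choices

Problem sizes used by the self-checks: type-I error simulations run
10 000 replicates per test per group size (3, 5, 10); effect recovery
uses 200 replicates of the knockout preset; time-course recovery 100
replicates; BH agreement 1000 random vectors. Type-I calibration is
asserted against each test's *attainable* size at α = 0.05 — computed by
enumerating the exact null distribution of the discrete rank/permutation
p-values — rather than against α itself, because at n ∈ {3, 5} a correct
exact test rejects strictly less often than α (see the resolution floor
above). Output tables are UTF-8, Unix newlines, `%.12g` floats; figures
are SVG (deterministic: fixed font, fixed hash salt, no timestamp
metadata) plus PNG.

## Known limitations

- No longitudinal modeling: time courses are compared interval by
  interval, not fit with splines or mixed models.
- No flux estimation; the slow-flux edge style is interpretive.
- DEG tables are consumed, not computed; differential expression must
  come from a dedicated RNA-seq pipeline.
- Pathway definitions and reaction graphs are user-supplied; there is no
  KEGG/Reactome retrieval.
- At n = 3, exact nonparametric tests cannot reach adjusted significance
  at α = 0.05 (resolution floor); study designs needing DAM calls from
  triplicates must either use the t-test or accept ranked-effect
  readouts.
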