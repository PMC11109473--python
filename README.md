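# isodiff

Differential analysis of targeted **stable-isotope-resolved metabolomics
(SIRM)** data: experiments in which cells or organisms are fed a labeled
substrate (typically ¹³C₆-glucose) and the incorporation of heavy atoms
into downstream metabolites is quantified by mass spectrometry. `isodiff`
takes *corrected* isotopologue measurements (natural-abundance correction
is an upstream concern, e.g. IsoCor or PolyMID) and provides the
downstream statistics a tracing study needs: derived quantities,
exploratory figures, rigorous small-sample differential testing with FDR
control, time-course and labeling-profile analysis, PCA, and pathway
integration with transcriptomics.

## The quantities

For a metabolite with *n* carbons, the corrected isotopologue intensities
are M₀…Mₙ (m+0 = unlabeled, m+n = fully labeled). From these, `isodiff`
derives:

- **total abundance** m = Σⱼ Mⱼ — the pool size;
- **isotopologue proportions** cᵢ = Mᵢ / Σⱼ Mⱼ — the mass distribution
  vector (MDV), summing to 1;
- **fractional contribution** (mean enrichment)
  φ = Σⱼ (cⱼ · j) / n ∈ [0, 1] — the carbon-weighted mean of the MDV, a
  proxy for labeling speed.

## The statistics

- **Pairwise tests** (two conditions, or consecutive timepoints tᵢ₊₁ vs
  tᵢ): Student t, Mann–Whitney, Wilcoxon rank-sum, Wilcoxon signed-rank
  (paired), Kruskal–Wallis, and a permutation test with the add-one rule
  p = (1 + #{|T*| ≥ |T|}) / (1 + N) that switches automatically to exact
  exhaustive enumeration when all C(n_A+n_B, n_A) labelings fit the
  permutation budget. Rank tests use exact null distributions at small n.
- **Multi-group**: Kruskal–Wallis across ≥3 groups.
- **FDR**: Benjamini–Hochberg by default (any statsmodels step-up/down
  method by name), applied within one (comparison × quantity type)
  family. Features significant after adjustment are the differentially
  abundant/labeled metabolites (DAMs).
- **Bivariate MDV comparison**: Spearman ρ between whole mean labeling
  profiles of two groups, with exact permutation p-values for short
  profiles.
- **Multivariate**: PCA on total abundances (log10, unit variance) or
  fractional contributions, with deterministic component signs.
- **Metabolograms**: per-pathway paired rings of metabolite differential
  values and gene log2 fold changes from an upstream RNA-seq analysis, on
  a shared symmetric color scale, plus projection onto a reaction graph
  that marks "hypothesized slow flux" edges (enrichment significantly
  down while the pool is non-decreasing).

A deterministic synthetic-data generator (`isodiff.simulate`) emulates
both classic designs — a two-condition knockout comparison in triplicate
and a six-timepoint labeling kinetics experiment — with lognormal
abundance noise, Dirichlet-distributed replicate MDVs, and known injected
effects, so every stage is testable without downloads.

## Worked example

```sh
python examples/01_preprocess_quantities.py
```

```
total abundance (ΣMj):
            sample1  sample2
metabolite
Alanine       100.0    100.0

isotopologue proportions (MDV):
                               sample1  sample2
metabolite isotopologue_index
Alanine    0                       0.1     0.80
           1                       0.3     0.15
           2                       0.6     0.05

fractional contribution φ:
            sample1  sample2
metabolite
Alanine        0.75    0.125
```

Both samples hold the same alanine pool (m = 100), but in sample1 most
mass sits in m+2 so three quarters of its carbons carry the tracer
(φ = 0.75), while sample2 is mostly unlabeled (φ = 0.125) — identical
abundances, completely different labeling speed. The remaining examples
(`examples/02…07`) walk through differential testing, time-course and
MDV-profile analysis, PCA, metabologram integration, and the full
configured pipeline; each prints the tables it computes.

## Command line

The library is also exposed as a thin CLI:

```sh
isodiff simulate --preset ldh_ko_48h --seed 2 --out data/
isodiff diff --isotopologues data/isotopologues_absolute.tsv \
             --samplesheet data/samplesheet.tsv \
             --condition-a KO --condition-b control --out results/
isodiff run --config run.yaml     # full pipeline from a YAML config
```

All inputs and outputs are tab-delimited text; isotopologue rows are
identified either by `metabolite_m+i` ids or by explicit
(metabolite, isotopologue_index) columns.

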