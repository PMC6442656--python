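# Methods

## Problem setting

Multi-region sequencing of an infiltrative tumour yields samples of very
unequal purity: several tumour-mass regions (T) at roughly 45–75% tumour
cells, a sub-ventricular-zone sample (SVZ) around 20%, an infiltrative-margin
sample (M) at 5–10%, and germline blood. Deciding whether the margin/SVZ
clone is a *descendant* of the tumour mass or an *early ancestor* hinges on
whether mutations truncal to the mass are present in those compartments —
precisely the call that low purity makes unreliable. The package separates
"not detected" into "statistically demonstrated absent" and "cannot tell",
and builds phylogenies only on what is demonstrated.

## Cancer cell fractions and truncal selection

For an observation with alt count x at depth n, VAF = x/n, sample purity π,
local tumour total copy number CN_t, normal copy number CN_n (2 for
autosomes) and mutation multiplicity m:

    CCF = VAF · (π·CN_t + (1−π)·CN_n) / (π · m)
    m   = clamp(round(VAF·(π·CN_t + (1−π)·CN_n)/π), 1, major_cn)

Raw CCF > 1 (sampling noise or model misfit) is capped at 1 and flagged
rather than excluded: exclusion would make the selected set non-monotone in
the threshold and would bias against exactly the high-CCF mutations the
truncal set exists to capture.

A SNV is *putatively truncal* when CCF ≥ 0.8 (configurable) in **every** T
sample from the whole-exome counts and its (total, major) copy-number state
is identical across the T samples. Fewer than two T samples make truncality
meaningless and raise an error. Loci outside every copy-number segment fall
back to diploid-heterozygous, are flagged, and are excluded from model
training (still testable).

## Beta-binomial VAF model

Truncal SNVs in one high-purity training sample (the highest-purity T
sample; the deepest assay available there) share an expected VAF per
copy-number state; their counts are modelled beta-binomially with mean μ and
overdispersion ρ (shape parameters α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ; ρ = 0 is
the binomial). ρ absorbs assay noise beyond read sampling: mapping artefacts,
slight CCF/multiplicity heterogeneity within a state.

Fitting is maximum likelihood over (logit μ, logit ρ) by bounded
Nelder–Mead from a method-of-moments start, always compared against the
exact ρ = 0 boundary (per-group binomial MLE); the boundary is returned when
it dominates. Gradient-based optimisation proved numerically fragile next to
the boundary, where the likelihood is flat in log-ρ.

States with fewer than `min_training` (default 10) SNVs are pooled into the
nearest-ploidy large group (total CN first, then major CN) and flagged. The
pooled fit is *joint*: one mean per state — their expected VAFs differ by
construction — and a single shared ρ. Merging raw counts across states would
masquerade between-state mean differences as overdispersion; and since the
test recomputes the null mean from the candidate's own copy-number state,
the concentration is the only trained quantity pooling needs to share. If no
state reaches `min_training`, everything is pooled into one flagged fit
(≥ 3 observations required; a warning notes the shortfall).

## Rescaling and the absence test

The expected VAF of a clonal mutation at purity π is

    f(π) = π·m / (π·CN_t + (1−π)·CN_n).

A trained fit moves to another purity by setting μ′ = f(π\*) and keeping the
concentration α+β (equivalently ρ) unchanged: overdispersion is a property
of assay and locus, not of purity.

For each margin/SVZ sample, candidates are truncal SNVs **not detected by
any assay** there; a mutation counts as detected when
alt ≥ max(2, depth·5×10⁻⁴). Each candidate is tested on its deepest assay.
The null — "truly truncal, present at worst-case purity π\* (default 1%)" —
gives the one-sided p-value p = P(X ≤ x) under the rescaled beta-binomial;
for x = 0 the closed form P(X=0) = B(α, β+n)/B(α, β) is evaluated in
log-space. Using P(X ≤ x) rather than only the zero-read case handles
near-zero observations uniformly.

**Testability and multiplicity correction.** A candidate is testable when
even the largest still-undetected alt count would be significant after
Bonferroni correction over the testable family. Because the family size and
the testable set define each other, the package uses the largest
self-consistent family: k\* = max{k : the k-th smallest bound < α/k}, ties
broken by variant id. Bonferroni runs per target sample within a patient.
Decisions: ABSENT (testable, adjusted p < α), DETECTED (detection rule fired
in some assay), UNDETERMINED (everything else, including loci with no
coverage in the target).

At the study's scales the arithmetic is stark: a diploid truncal SNV with
zero reads at panel depth ~4000 has p ≈ 0.995⁴⁰⁰⁰ ≈ 2×10⁻⁹ under the
1%-purity null, surviving any reasonable correction, while the same zero at
exome depth 150 gives p ≈ 0.47 — never evidence of absence. Overdispersion
erodes this power quickly: the test is only as sharp as ρ is small, which is
why training uses the deepest assay, where excess variance is identifiable.

## Presence matrix and phylogeny

Characters are mutations with states PRESENT/ABSENT/UNKNOWN per sample.
Blood is all ABSENT (germline). T samples take the detection rule on exome
counts. Margin/SVZ cells are PRESENT when detected by any assay, ABSENT when
the absence test rejected, and UNKNOWN otherwise — crucially, an
UNDETERMINED or untested missing mutation contributes *no* signal instead of
a false absence. A sample whose row is entirely UNKNOWN aborts the run.

Trees are rooted on the blood leaf and scored by minimum-change parsimony on
binary characters (two-state Sankoff recursion, exact at any node arity;
UNKNOWN is missing data). The search is exact: taxa are added one at a time
on every edge, and a partial tree whose score already exceeds the incumbent
is pruned — valid because adding taxa never lowers the parsimony score. The
cohort design (≤ 9 samples per patient) keeps this affordable; more than 12
non-blood samples raises an error rather than silently going heuristic.
Ties between equally parsimonious topologies are broken deterministically by
the lexicographically smallest canonical Newick form.

Branch lengths are the mutations assigned to each edge by a minimum-change
traceback with the germline root forced ABSENT and ties resolved toward
change, i.e. placing mutations as close to the root as possible. Internal
edges with zero assigned mutations are collapsed, so indistinguishable
samples appear as a multifurcation rather than an arbitrary resolution.

**Bootstrap.** Columns are resampled with replacement (`n_bootstrap`,
default 1000); each replicate is re-searched exactly, and a clade's support
is the percentage of replicates containing it. Within a replicate,
equally parsimonious trees are resolved *uniformly at random* from the
seeded generator — a deterministic tie-break would funnel all tied mass to
one topology and overstate its support; the whole procedure is still
bit-reproducible given the seed. The full-data tree keeps its canonical
deterministic tie-break.

## Synthetic data generator

The generator encodes the study conditions: 4 T samples (purity uniform
0.45–0.72, median ≈ 0.58), one SVZ (0.18–0.26), one margin (0.05–0.10),
blood; whole-exome depth negative-binomial around ×157 for all samples,
amplicon panel ×4050, capture panel ×1128 on margin and SVZ. Clonal
evolution is a random binary clone tree grown by sequential attachment with
Poisson mutation counts per edge (trunk mean 40, subclonal edges 15). Sample
composition is Dirichlet over clones with mass 200 on a dominant clone and
0.05 elsewhere — residual-disease compartments are modelled as spatially
segregated, near-pure clones. Copy number is clonal and deliberately simple:
one gained chromosome (3,2), one lost (1,1), the rest diploid, so the
per-state machinery is exercised without subclonal CN. Read counts are
beta-binomial around the purity/CN-expected VAF with assay overdispersion
ρ = 5×10⁻⁴ — read-level noise for truncal SNVs in a clonal sample, chosen so
that a zero at panel depth is as informative as the depth arithmetic above
implies; sequencing error is not modelled separately (a truly absent locus
draws zero alt reads). The `ancestral_margin` scenario constrains the tree
to a trunk chain (germline → A → B, tumour clones below B) and pins the
margin's dominant clone to A: the edge A→B mutations are putatively truncal
yet genuinely absent from the margin — the configuration the test exists to
detect. Mutation placement can be restricted to chosen chromosomes (e.g.
diploid-only scenarios). All draws flow from one `numpy` generator;
identical seeds give bit-identical datasets.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: subclonal copy number, mutation multiplicity > 1,
sequencing error and strand artefacts, mappability-varying depth, purity
*estimation* error (purities are passed through as known), and spatial
structure beyond clone mixtures.

## Numerical and design choices

* Zero-read p-values use log-Beta differences; ρ ≤ 10⁻¹² is treated as
  exactly binomial. The closed form agrees with numerical integration of the
  binomial kernel against the Beta density to < 10⁻¹⁰ over a broad (α, β, n)
  grid (verified in the acceptance checks).
* Depth 0 always yields p = 1; no data can never support absence.
* CN intervals are 1-based and closed on both ends, matching VCF positions;
  boundary inclusion is tested explicitly.
* Acceptance-scale choices: the end-to-end ancestral-margin property is
  measured over 100 simulated patients with 25 bootstrap replicates each
  (topology, not support, is under test there); the noiseless tree-recovery
  check uses 1000 replicates on a ~6-taxon tree. Clone-tree shapes for the
  recovery check are drawn from successive seeds until the tree has ≥ 5 leaf
  clones, a structural requirement, not a result filter.
* Per-patient execution: patients are statistically independent throughout;
  batch analysis is a loop over configs.

## Known limitations

* The exact search is factorially bounded; a pathological matrix with no
  phylogenetic signal at the 12-taxon limit can exhaust it. Cohort-scale
  inputs (≤ 9 samples) are far from this regime.
* Overdispersion estimates from few truncal SNVs in a small copy-number
  group carry real uncertainty (roughly factor-2 at ~50 SNVs, panel depth);
  since power at worst-case purity depends sharply on ρ, borderline
  candidates in small CN states can flip between ABSENT and UNDETERMINED.
  The per-state fit sizes are reported in the run log for exactly this
  reason.
* The multiplicity estimator assumes clonal copy number; amplified loci with
  subclonal gains will mis-estimate m and hence the null mean.
* UNKNOWN cells carry no signal: a margin sample whose evidence is entirely
  UNDETERMINED attaches with low support near the root rather than being
  placed confidently.
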