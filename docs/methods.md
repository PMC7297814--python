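# Methods

## Study design and data model

The package targets three-group blood small-RNA-seq designs: an acute-phase
group (RAA, n = 19), a chronic-phase group (RAC, n = 20) and controls
(C, n = 20). The unit of analysis is an annotated sRNA locus with a class
label (piRNA, rRNA_5S/SSU/LSU, miRNA_primary, mir_5p, mir_3p, scRNA, tRNA,
tRF3, tRF5, snoRNA, snRNA, other) and a stranded, 0-based half-open genomic
interval. Raw counts are normalized by per-sample library size only (counts
per million); no TMM or quantile step is applied, because total-count
normalization is the procedure the pipeline is modelled on. Library sizes
are computed once, before gene filtering, and are deliberately not updated
by the detectability filter (an explicit `recompute_lib_sizes` switch
exists). An sRNA is detectable when its CPM exceeds 2 (strict inequality;
configurable) in at least 10 of all samples — "all samples" rather than
per-group, which is the simplest reading of the rule.

## Differential expression

Counts are modelled per sRNA as negative binomial with mean
q_group · lib_size and variance μ + φμ². Fitting is a one-way NB GLM with a
log library-size offset, solved by Fisher scoring on log q per group
(closed-form score equations; vectorized over all sRNAs).

Dispersion estimation follows the Cox–Reid adjusted profile likelihood on a
fixed grid of φ values (1e-6 … 10, 41 points), with group means re-fitted at
every grid value. The common dispersion maximizes the summed APL (with a
parabolic refinement of the grid argmax); genewise estimates are the
per-sRNA argmaxes, shrunk toward the common value by a log-scale weighted
average with prior weight 10 against the residual df. The GLM deviances that
feed the test are computed at the **common** dispersion: gene-level
departures from it are exactly what the quasi-dispersion is meant to absorb,
and using the genewise estimates in the fit as well would count that
variation twice (measurably costing power; the choice was cross-checked
against the reference QL implementation in edgeR, which the test suite uses
as an independent oracle on a small seeded dataset).

The genewise quasi-dispersion s² = residual deviance / residual df is
squeezed by the standard scaled-F empirical-Bayes moment fit (matching mean
and variance of log s² to a s₀²·F(df, d₀) model; trigamma inversion by
Newton iteration). The omnibus statistic for the group factor is
F = (Δdeviance/2)/s²_post, referred to F(2, df_resid + d₀); q-values are
Benjamini–Hochberg. Degenerate inputs: all-zero rows are flagged and
reported as p = 1, fc = 1; single-group designs are an error.

The engine is validated by operating characteristics, not by bit-level
agreement with any package: pooled type-I error on 25 null simulations
(2000 sRNAs, 20/20/20) falls in [0.035, 0.065] at nominal 0.05, power at
2-fold spikes in 10% of sRNAs exceeds 0.95 at q < 0.1, and fold-change
estimates for balanced spikes are median-unbiased within 5%.

Fold-changes are linear-scale ratios of fitted group proportions vs C.
Note that with total-count normalization, a one-sided spike of fraction f at
fold Δ shifts all apparent fold-changes by the compositional factor
1/(1 + f(Δ−1)); estimator-bias checks therefore use balanced up/down spikes.

Pattern classification: an sRNA is significant at q < 0.1 (the Methods-level
threshold; the stricter 0.01 used in parts of the original results is a
config value, not a default), and "passes" a contrast when fc > 1.2 or
fc < 1/1.2. Membership is acute_only / chronic_only / both according to
which contrasts pass; direction is up/down when passing contrasts agree and
mixed_down_up / mixed_up_down when both pass in opposite directions (so a
mixed call requires membership = both by construction).

## Power estimation

Closed form (Hart et al.): power = Φ(√(n(ln Δ)²/(2(1/μ̄+σ²))) − z_{1−α/2}).
Defaults n = 20 per group and α = 0.1 two-sided: neither is stated alongside
the published power quadruple (33.6/85/97.2/99.86% at Δ = 1.2/1.5/1.7/2 with
depth 676 and CV 0.47), but this pairing is the unique natural combination
that reproduces all four printed values (85% computes as 85.9%), and α = 0.1
matches the FDR threshold. At Δ = 2 the formula gives 99.866%, i.e. 99.87%
at two decimals against the printed (truncated) 99.86%.

Shuffle-and-spike: each sRNA's counts are independently permuted across
samples (preserving the per-sRNA count multiset, destroying group
structure), a random 10% of sRNAs is multiplied by Δ in one group (RAA by
default; rounded to integers), and the QL test plus BH is re-run. Reported:
detection fraction among spiked at q < 0.1 and the empirical FDR among
detections. A `--shuffle global` alternative permutes the entire matrix.
The published headline (99.4% detection at Δ = 1.2) is tied to the original
count matrix and is not reproducible from synthetic data; on synthetic
studies the procedure is validated by its properties — detection ≤ FDR level
at Δ = 1, monotone in Δ, ≥ 0.99 by Δ = 8. Within-sRNA permutation does not
collapse between-subject variance, so detection at Δ = 1.2 remains near the
closed-form figure rather than the headline value; the two estimates are
reported side by side and deliberately not reconciled.

## Class composition

Background sets are uniform seeded samples of nonregulated sRNAs at the
requested size (233 for composition figures, 455 for TFBS — two call sites
of one sampler). Composition rows are exact class counts including empty
classes; two rows are compared by Pearson χ² on the 2 × k table with
pooled-margin expected counts, df = k − 1, no continuity correction
(k > 2 in practice). Expected counts below 5 warn rather than error, since
small sRNA classes are the norm.

## Conservation

Per-sRNA conservation is the mean of per-base track scores over the locus,
with uncovered bases scored 0, divided by the full locus length. Tracks are
text bedGraph (bit-exactly testable); scores live in [0, 1]. Summaries per
class × regulation group (regulated_up / regulated_down / mixed /
nonregulated) are descriptive only — count, mean, median, quartiles — with
no attached test, mirroring how such comparisons are reported.

## TFBS overrepresentation

The query is a regulated locus set (downregulated-in-both by default); the
reference is an expression-matched background: query mean log-CPM values are
binned into deciles and the nonregulated pool is sampled without replacement
proportionally to the query's decile occupancy (largest-remainder rounding
to hit the requested size exactly; starved strata warn and reallocate).
The per-locus statistic is mean coverage in a ±1000 bp window centred at the
strand-aware 5′ start (window and a body-mean alternative are
config-exposed; the window default reflects that ChIP signal concentrates
near locus starts). Clipped windows keep the full-window divisor, consistent
with uncovered-equals-zero. Query vs background is compared by Welch's
two-sample t-test (chosen over the pooled-variance form because group sizes
and variances differ), Bonferroni-corrected across TF tracks. A locus is
"bound" when its signal exceeds background mean + 2 SD (falling back to
"above background mean" for degenerate backgrounds); the bound/unbound
partition feeds the composition χ² to test class bias among bound loci.
Coordinate conversion between genome assemblies is out of scope: all
synthetic coordinates live on one chromosome of one assembly.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed at the study conditions: groups 19/20/20, 1766
detectable sRNAs, mean depth 676 counts, biological CV 0.47.

- **Baselines**: per-sRNA means are log-normal with sdlog 1, centred so the
  grand mean equals the target depth. The true abundance distribution of
  the original data is unknown; log-normal is a stand-in giving a realistic
  dynamic range so that CPM filtering has something to do, not an inference
  about the data. An optional undetectable stratum (uniform means in
  [0.05, 0.8] counts) lets filter-recovery tests plant a known detectable
  count.
- **Counts**: NB with variance μ + σ²μ² (Poisson at σ = 0), group means
  multiplied by the planted pattern's fold-change (mixed patterns apply Δ in
  one contrast and 1/Δ in the other), and per-sample depth factors uniform
  in [0.75, 1.25] so that library-size normalization is non-trivial.
  Planted regulation is confined to the detectable stratum.
- **Patterns**: eight timepoint/direction patterns plus null; fractions are
  allocated by largest remainder and assigned to a seeded shuffle of the
  detectable sRNAs. The bundled `study_config` plants all eight with the
  both-timepoints set dominant and mostly downregulated, at Δ = 2.
- **Annotation**: class counts by largest remainder of the class
  proportions (default mix shaped like a nonregulated blood pool);
  class-typical locus lengths; non-overlapping placement on one synthetic
  chromosome (default 3000 bp per locus) with multinomial gaps; random
  strands.
- **ChIP tracks**: exponential background noise in 25 bp bins plus Gaussian
  peaks (height 5, sd = window/4 = 50 bp) centred at the strand-aware 5′
  start of each enriched locus; enriched loci are drawn from a chosen
  pattern (61 of the both-down set at study scale, scaled proportionally for
  smaller studies), optionally biased toward one class. A decoy track with
  no peaks ships in the default config.
- **Conservation**: each locus fully covered at a constant score drawn
  around its class mean (sd 0.08, clipped to [0, 1]); class means follow the
  class-specific ordering reported for real data (tRNA/piRNA/mir-5p high,
  tRF3/tRF5/scRNA low).
- **Determinism**: one config seed fans out to independent per-stage
  child streams via fixed string tags (CRC-based, process-stable); identical
  configs give byte-identical outputs.

What the generator does **not** emulate: read-level error and mapping
artifacts, multi-mapping between homologous loci, class-dependent abundance
(classes are independent of expression), correlated sRNAs (counts are
independent across loci given the design), batch structure, and real ChIP
peak shapes. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the assumed NB model, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Simulation-based checks run at the study scale (≈ 1766–2000 sRNAs, 59–60
samples) with 3–25 replicates per check and 100 replicates for the TFBS
recovery rates; these sizes give the Monte-Carlo precision the asserted
bounds need (e.g. SE ≈ 0.003 on the pooled power estimate over 25
replicates). Dispersion grid 1e-6…10 (41 log-spaced points) with parabolic
refinement; dispersion floor 1e-6 (numerically Poisson); Newton iterations
capped with step clipping ±5 on log-mean scale; BH ties resolved by stable
sort. The trigamma inversion uses the standard Newton scheme started at
0.5 + 1/y.

## Known limitations

- Exact numerical agreement with edgeR is a non-goal; agreement is
  validated at the level of p-value ranking (Spearman ρ > 0.95) and call
  overlap on seeded data.
- Total-count normalization leaves compositional bias in fold-change
  estimates when regulation is strongly one-sided (see above); this is
  faithful to the modelled pipeline rather than a defect of the estimator.
- The published real-data set counts (542 DE sRNAs, 516 after fold-change
  filtering, class tallies) depend on the original count matrix and are not
  targets for synthetic reproduction.
- The mixed-pattern definition is strict (both contrasts pass in opposite
  directions); published mixed-set tallies that disagree internally are not
  arbitrated.
- bigWig input is not supported; convert to bedGraph first.
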