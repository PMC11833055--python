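# Methods

## The concordance statistic

For two studies *a* and *b* with log2 fold-change vectors FC_a, FC_b over
their *n* shared genes, the distance is

S(a, b) = Σ_g |FC_a(g) − FC_b(g)|.

Every shared gene contributes — there is no significance filter,
winsorizing, or weighting before the sum. That makes S sensitive to the
bulk of small coordinated shifts as well as to a few large discordant
genes; `gene_contributions` decomposes S gene by gene to tell the two
apart. S inherits the metric axioms of the L1 norm (non-negativity,
identity of indiscernibles on fold-change vectors, symmetry, triangle
inequality), which the test suite verifies exhaustively on random
panels. Because S is a raw sum, its magnitude scales with the number of
shared genes; the per-gene mean (`s_value / n_genes`) is reported
alongside for cross-panel comparisons, with the raw sum remaining the
primary quantity.

Genes are matched by exact, case-sensitive string equality. "Shared"
means present with finite log2FC and p-value in every study: rows with
missing values are dropped at read time (counted in a warning log), and
a gene absent from any study is excluded from the shared matrix. This is
the operational definition of "consistently detected in all models";
detection at the count or FPKM level is deliberately not modelled, since
the package consumes per-gene result tables, not reads.

## DEG calling

A gene is called differentially expressed when raw p < p_threshold
(default 0.05) and its linear fold change 2^log2FC is strictly > fc_up
(default 1.5) or strictly < fc_down. All inequalities are strict: a gene
sitting exactly on a bound is not called. The compound condition is read
as p AND (up OR down).

Two deliberate choices:

- **fc_down defaults to 1/fc_up** (= 2/3 ≈ 0.6667 for the default band),
  i.e. symmetric in log space, rather than the rounded 0.667 often
  printed in methods sections. The difference matters only for genes
  whose fold change falls in (2/3, 0.667) — roughly a one-gene-scale
  discrepancy on real data. Passing `fc_down=0.667` reproduces the
  rounded bound exactly.
- **Raw p-values by default.** The calling rule is stated on unadjusted
  P; Benjamini–Hochberg adjustment is available (`build_profile(...,
  adjust=True)`, CLI `--adjust`) but off by default.

Venn membership is by gene id regardless of direction: a gene up in one
study and down in another still lands in their shared region. The CLI
`overlap --directional` additionally partitions the up- and down-sets
separately when direction-concordant overlap is wanted.

The heatmap selection restricts to the shared genes and keeps those
calling up or down under the stricter 2-fold band (p < 0.05, FC > 2 or
< 0.5) in at least one study, in lexicographic order.

## The DE engine

`build_profile` maps a gene × sample count matrix plus a two-group design
to a study profile:

- **CPM normalisation** (each sample scaled to 1e6 total) is the only
  library-size correction;
- **log2FC** = log2((mean treated CPM + pc) / (mean control CPM + pc))
  with pseudocount pc = 0.5 by default. The pseudocount is the main
  small-count bias knob: it bounds fold changes for genes with zeros and
  shrinks low-expression estimates toward 0;
- **p-values** from a two-sided Welch t-test on log2(CPM + pc) per gene.
  Genes with zero variance in both groups get p = 1 when the group means
  are equal and p = 0 when they differ (a noiseless shift; the second
  rule is this package's extension of the stated degenerate case).

This engine is intentionally not a negative-binomial shrinkage estimator
(DESeq2-style): its job is to be a *calibrated*, dependency-light
significance source for synthetic counts — the type-I error on null NB
genes at 6 vs 6 is verified to sit near the nominal 0.05 — while real
studies are expected to arrive as precomputed tables from whatever DE
tool produced them. Dispersion shrinkage, size factors beyond CPM, and
covariate designs are out of scope.

## The simulator

The simulator emulates a three-study comparison design with planted
ground truth.

**Effects.** A fraction `f_de` of genes is differential in the
reference, with log2 effects β_ref ~ N(0, σ_β²). A study with
concordance ρ gets, on those same genes,

β_study = ρ·β_ref + √(1 − ρ²)·η,  η ~ N(0, σ_β²),

so corr(β_study, β_ref) = ρ and both marginals have spread σ_β.
Non-differential genes are exactly zero everywhere. The gap
β_study − β_ref is Gaussian with variance 2σ_β²(1 − ρ), hence
E|β_study − β_ref| = 2σ_β√((1 − ρ)/π) — a closed form the tests check by
Monte Carlo (3-SE band at ≥ 500 differential genes). Expected true
distance to the reference is therefore monotone decreasing in ρ, which
is what makes the ranking question well-posed. Study-private
differential genes (differential in a comparison study but not the
reference) are off by default and available via `private_de_frac`.

**Counts.** Counts are negative binomial with mean μ_g·2^(β·x) (x = 1
for treated samples) and variance μ + φμ² — φ is the overdispersion
coefficient on the squared-mean term, the gamma-Poisson parameterisation
(numpy's NB is called with size r = 1/φ, p = r/(r + μ)). Baselines μ_g
are log-normal and drawn per study: the three studies stand for separate
experiments, so sharing baselines across them would be unrealistically
favourable.

**Defaults.** 5000 genes, 6 animals per group, f_de = 0.1, σ_β = 1,
φ = 0.3, concordances FL = 1.0 (reference), CS = 0.8, HU = 0.2. These
are the conditions under which all end-to-end checks run. The baseline
log-normal parameters (natural-log mean 4.0, SD 1.5; median count ≈ 55
with a long right tail) are this package's choice of a typical bulk
RNA-seq gene-level count profile; nothing downstream is sensitive to
them beyond the usual power/precision trade-off.

**Randomness.** One master seed; each study's effect noise, baselines and
counts come from separate substreams keyed by crc32 of (study label,
context), so adding a study to a config never perturbs the studies
already present, and identical (seed, label) pairs reproduce counts
byte-identically.

**What the simulator does not emulate.** Batch effects, library-size
imbalance, gene–gene correlation, count outliers, more than two groups,
and read-level artefacts are all absent. Passing the end-to-end checks
therefore demonstrates that the pipeline recovers a planted concordance
ordering under clean NB sampling noise — not that it is robust to the
confounders of real multi-laboratory data, where normalisation and batch
handling would dominate.

## Behavioral indices

All indices are on the 0–100 percent scale and invariant under a uniform
change of time unit:

- recognition index = 100·TN/(TN + TF); complementarity
  RI(TN,TF) + RI(TF,TN) = 100 holds exactly;
- spontaneous alternation % = 100·alternations/(entries − 2), an
  alternation being three consecutive entries into three different arms.
  Windows **overlap** (ABCABC scores 4 alternations in 6 entries): with
  the conventional (entries − 2) denominator, overlapping counting is
  the only convention under which a perfect alternator scores 100%.
  Consecutive re-entries into the same arm count as entries but can
  never complete an alternation;
- open-arm entry % = 100·open/(open + closed) and open-arm time % =
  100·open_time/total_time for the elevated plus maze. A single combined
  "anxiety index" mixing times and entries is sometimes quoted but is
  ambiguous as usually stated (one pooled ratio vs. an average of two);
  only the two unambiguous components are implemented.

Zero denominators (no exploration, fewer than 3 arm entries, no arm
entries, zero session time) raise `UndefinedIndexError` rather than
returning a sentinel.

## Numerical and interface choices

- Gene order is lexicographic everywhere outputs are ordered; ranking
  ties and contribution ties break lexicographically on gene/study
  label. This makes every output deterministic.
- Distances are accumulated by numpy vector sum on float64; the oracle
  tests compare against scalar loops at 1e-9 absolute tolerance.
- Profile round-trips through TSV preserve finite decimal inputs
  bit-exactly (pandas writes full precision by default).
- The acceptance script derives all replicate seeds by small integer
  offsets from the master `--seed`, keeping every derived seed a valid
  32-bit integer.

## Problem sizes

The verification suite runs the metric-axiom sweep on 200 random panels
(3–5 studies, 10–500 genes), oracle equivalence on 100 random instances
per operation, the closed-form check on 10 000 differential genes, the
end-to-end ranking recovery on 20 replicates of the default 5000-gene
panel, and the type-I calibration on 2000 null genes — sizes chosen so
Monte-Carlo error is small relative to each check's tolerance while the
whole suite completes in seconds.
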