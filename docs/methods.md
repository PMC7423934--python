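# Methods

This note documents the statistical models implemented in `lepinet`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

The primary input is a protein × sample matrix of spectral counts (SpC):
the number of tandem MS/MS spectra assigned to a protein in one LC–MS/MS
run, a label-free proxy for protein abundance.  Counts are non-negative
integers, frequently zero for low-abundance proteins, and compositional:
a run yields a roughly fixed total number of identified spectra, so one
protein's gain is every other protein's (fractional) loss.  Replicate
runs (`sample.rep` columns) are aggregated by summation by default, which
conserves totals and keeps counts integral for the count-based G-test;
`mean_round` (half-up) is available where per-run scale matters.

Subtype labels (e.g. AIS/MIA/LPA) are encoded as one-vs-rest binary trait
vectors, one per subtype — the form consumed by module–trait correlation.

## Characteristic-protein filter

A protein is *characteristic* of a subtype when its aggregated SpC is
positive in at least `min_samples` of the subtype's samples (default 4 =
"more than three").  Strict positivity is the detection criterion;
`include_zero=True` switches to SpC ≥ 0, which trivially admits every
protein and exists only for comparability with workflows that state the
rule that way.  The characteristic set is monotone non-increasing in
`min_samples`, and a group smaller than `min_samples` yields an empty set
with a warning rather than an error.

## Pairwise G-test with Williams' correction

For protein *i* and groups A, B the 2×2 table is

|            | A            | B            |
|------------|--------------|--------------|
| protein i  | f₁₁ = Σ SpC  | f₁₂ = Σ SpC  |
| all others | T_A − f₁₁    | T_B − f₁₂    |

the standard construction for spectral-count likelihood-ratio tests: it
conditions on the groups' total spectrum budgets.  G = 2 Σ O·ln(O/E) with
expected cells from the margins and the convention 0·ln(0/E) = 0.
Williams' divisor q = 1 + (N/R₁ + N/R₂ − 1)(N/C₁ + N/C₂ − 1)/(6N)
corrects the small-count inflation of G; G/q is referred to χ² with 1 df.
A zero row or column margin means the table carries no evidence and
short-circuits to G = 0, p = 1 — this is what makes all-zero and
singleton-count proteins safe to test.  Under a proportional null with
Poisson sampling the corrected test holds its size: the acceptance script
measures the empirical rejection rate at α = 0.05 over 2,000 null
proteins (observed ≈ 0.05, within 3 binomial SEs).

Multiple testing uses Benjamini–Hochberg.  The default family pools all
(protein, pair) p-values — conservative and reproducible; a per-pair
family is available (`bh_family="per_pair"`).

**Group significance** (three-part rule, all required):
presence fraction ≥ 0.6 in the group; relative-abundance share > 0.5,
where share(g) is the group's mean normalized abundance divided by the
sum of all groups' means (so > 0.5 identifies the dominant group among
three); BH q < α in the pairwise test against *every* other group.  The
share is computed on normalized values and flagged undefined for all-zero
proteins.

## Co-expression network analysis

The module-discovery pipeline is the classical weighted co-expression
sequence with one hub-based summary:

1. **Correlation**: Pearson over samples, after dropping numerically
   flat profiles (sd ≤ 1e-12 relative).
2. **Adjacency**: signed transform ((1+r)/2)^β by default, β = 10.  The
   signed transform maps r = 1 → 1 and r = −1 → 0, which is what "power
   the similarity" requires; `unsigned` (|r|^β) and the inverted
   `dissim_literal` ((1−r)/2)^β are retained as options.  Diagonal set
   to 1; connectivity k excludes the self term.
3. **Soft-threshold scan**: for each candidate β, connectivities are
   binned (10 log bins), log₁₀ frequency is regressed on log₁₀ mean
   connectivity, and the signed fit index −sign(slope)·R² is reported.
   The smallest β reaching R² ≥ 0.8 is recommended, else the argmax.
   Degenerate (all-equal-k) networks report NA.
4. **TOM**: TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 −
   a_ij), unit diagonal, 0 on zero denominators.  Closed forms used as
   tests: all-ones adjacency → all-ones TOM; the 0.5/0.5/0 star →
   TOM₁₂ = 0.5.
5. **Clustering**: average linkage (UPGMA) on 1 − TOM via SciPy, whose
   tie handling is deterministic.
6. **Dynamic hybrid tree cut**: the merge tree is walked bottom-up,
   growing branches.  When two branches meet, each is kept as a separate
   module only if it looks like a genuine cluster: ≥ `min_module_size`
   members (default 10), core scatter (mean joining height of the branch
   core, core size ≈ minSize/2 + 1 + √·) at most a deepSplit-dependent
   threshold, and attachment-height gap above the matching minimum.
   Thresholds live on the tree's normalized height scale (reference
   height = 5 % merge quantile, cut height = 99 % of the range):
   maxCoreScatter ∈ {0.64, 0.73, 0.82, 0.91, 0.95} for deepSplit 0–4 and
   minGap = (1 − maxCoreScatter)·3/4.  Remaining objects are assigned to
   the nearest module by average dissimilarity (PAM-like stage, default
   on, capped at the cut height); labels are renumbered by decreasing
   module size with 0 = unassigned.  deepSplit = 4 is deliberately
   aggressive: on unstructured proteins it produces many small modules,
   which mirrors how the reference hybrid cut behaves at its most
   sensitive setting.
7. **Module summary**: the *eigen-protein* — the member with the highest
   intramodular connectivity Σ_{j∈m} a_ij, ties broken lexicographically.
   A first-principal-component eigengene (`module_summary_pca`) is
   provided as an optional alternative; the hub-based summary is the
   default because it is directly interpretable as a protein and is the
   summary the trait statistics use.
8. **Module–trait correlation**: Pearson r between the eigen-protein's
   expression profile and each binary trait; p from the exact t
   transform t = r√((n−2)/(1−r²)); BH per trait across modules (pooled
   optional); screening flags |r| > 0.5 and q < 0.05.

### Normalization for correlation work

The default expression scale for co-expression is `log2_mor`:
total-count fractions divided by per-sample median-of-ratios size
factors (the median, over proteins detected in every sample, of the
sample-to-reference fraction ratio; reference = geometric mean profile),
rescaled to counts-per-1e4 and transformed log2(1 + x).  The median-ratio
step matters for compositional counts: a genuinely up-regulated protein
group inflates its samples' totals, so plain total-count scaling imprints
a shared downward offset on *every other* protein in those samples.  On
synthetic cohorts with one strongly trait-linked module that offset gives
unrelated noise modules spurious trait correlations (|r| ≈ 0.85); the
median ratio is robust to a minority of shifted proteins and removes it,
after which the planted module ranks first essentially always.  Plain
`log2_total` and `total_count` remain available; the G-test never uses
normalized values (it is count-based by construction).

## Hub ranking (MCC)

Maximal cliques are enumerated exactly (Bron–Kerbosch with pivoting, via
networkx) and MCC(v) = Σ_{C∋v}(|C|−1)!.  An isolated node forms a
singleton maximal clique and scores 0! = 1, keeping scores positive.
Ranks sort by MCC, then degree, then node id — fully deterministic.
Exactness is checked against a brute-force subset-enumeration oracle on
hundreds of random ≤10-node graphs and by closed forms (K_n → (n−1)! per
node; path P₃ → 2/1/1).  Graphs beyond 20,000 nodes / 2,000,000 edges are
refused with advice to extract a module subnetwork first.

## Genomic alterations

Copy-number loss is strict CN < 2 (the diploid value 2 is not a loss);
the gain threshold defaults to 2.5 and is explicitly a tunable, since no
canonical cutoff exists for panel CN values.  Gene × sample states
combine mutation and CNV ({none, mutation, gain, loss, mutation+gain,
mutation+loss}).  Group burden (lost genes per sample) is compared with
a two-sided Mann–Whitney test; for groups of ≤ 8 samples the p-value is
computed by exhaustive enumeration of group relabelings (exact and valid
under ties, unlike the closed-form null distribution), larger groups use
the tie-corrected normal approximation; Welch's t is available.  An
all-identical burden vector returns p = 1 with a warning.

## Cohort descriptives

Group summaries report mean ± population SD (divisor n) by default;
the bundled 14-patient reference table reproduces its published summary
lines only under the population form (e.g. the AIS ages give 8.5 with
divisor n and 9.5 with n−1), and `ddof=1` switches to the sample SD.
One-way fixed-effects ANOVA (SciPy) supplies F and p at full precision;
rounding is presentation-layer only.  The degenerate case of zero
within-group variance with unequal means returns F = ∞, p = 0
explicitly.

## Synthetic-data generator

`SimSpec` defaults emulate the reference study design: 3 groups of
5/5/4 samples, 2,000 proteins, triplicate runs, expected depth 1e4
counts per run.  Per-sample protein log-abundance (natural log) is

baseline_i + Σ_m loading_m · factor_m(s) + ln(fold)·[s ∈ target group]

with baseline_i ~ N(0, 1) (about two orders of magnitude of abundance
spread), module factors standard normal per sample, mean-shifted by
`trait_shift` (default 4.0) in the linked group.  The default shift is
set so that a planted trait-linked module's eigen-protein reaches trait
correlations around 0.9 — the magnitude reported for strongly
subtype-associated modules in real early-adenocarcinoma cohorts — rather
than the weak associations a unit shift would produce.  Expected counts
are the per-sample softmax of log-abundance times depth (compositional,
like spectral counting under a fixed spectrum budget); observed counts
are Poisson, or gamma-Poisson with dispersion 0.2 (variance μ + 0.2μ²)
for overdispersed cohorts.  Poisson is the calibration condition: the
2×2 G-test conditions on totals and assumes multinomial sampling, which
negative-binomial replicate noise deliberately violates.

What the generator does **not** emulate: peptide-level identification
and protein inference, run-order or batch effects, missingness beyond
sampling zeros, and correlated baselines between modules.  Passing tests
therefore demonstrate the pipeline's behaviour under its own stated
assumptions, not performance on raw mass-spectrometry output.

Network fixtures (`simulate_network`) embed planted cliques on sparse
Erdős–Rényi backgrounds with the planted members recorded as truth.

## Problem sizes and evaluation conventions

The test-suite and acceptance runs use: 2,000-protein null cohorts for
type-I calibration; 20-seed sweeps of the default-size cohort with three
30-protein modules (loading 0.9) for module recovery; 200 random ≤10-node
graphs for the MCC oracle.  Module recovery is scored as the adjusted
Rand index over *planted-module members*, with planted↔recovered
matching by recall (the recovered module holding the majority of a
planted module's members): the assignment stage intentionally attaches
background proteins to nearby modules, so member-precision would penalise
perfect recoveries of the planted structure.

## Known limitations

- The tree cut is a faithful re-implementation of the hybrid algorithm's
  published logic, not a line-for-line port; branch-by-branch agreement
  with other implementations on arbitrary dendrograms is not guaranteed
  (closed-form and recovery behaviour are what the tests pin down).
- Exact clique enumeration is exponential in the worst case; MCC is
  meant for module-sized subnetworks, not proteome-wide graphs.
- With 14 samples, module–trait correlations have wide sampling error;
  the |r| > 0.5 screen is a screen, not an inference guarantee.
- The G-test's calibration argument assumes independent counts across
  samples; overdispersed (negbin) cohorts inflate its type-I error, which
  is a property of the test, not a bug in the implementation.
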