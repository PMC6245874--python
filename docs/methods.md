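# Methods

## Transforms

Four piecewise desirability functions map a raw gene-level variable Y onto
[0, 1]. `low` and `high` use two cuts A < B with a power-interpolated
middle branch; `extreme` is a four-cut valley B_lo < A_lo ≤ A_hi < B_hi
(1 in the tails, 0 on the inner plateau, `low`/`high`-shaped flanks);
`target` is the peak-shaped complement with cuts A < C < B, maximal at C.
The scale exponent s > 0 bends the interpolating branch; s = 1 gives
straight-line interpolation. Outputs can be affinely rescaled into a
user-chosen [d_min, d_max] ⊆ [0, 1]; this happens at transform time, before
any averaging, so every downstream mean operates on the bounded scores.

Boundary ownership is deterministic: a value exactly at a cut takes the
closed saturated branch (Y = A under `low` gives 1, Y = B gives 0), so ties
at cuts never depend on floating-point direction. A P-value of exactly 0
is simply below A and scores 1 — no epsilon substitution. Non-finite
values (NaN, ±inf) propagate as missing rather than being coerced to 0,
because a silent 0 would penalise the gene in every later mean. Adjacent
cuts must differ strictly wherever they bound an interpolating branch
(equal cuts would divide by zero); the two inner `extreme` cuts may
coincide, since they only delimit the zero plateau.

Two shapes exist for "intermediate vs extreme" because the two conventions
are both used in practice: fold-change-style variables reward tails
(`extreme`), while genuinely target-valued variables reward an interior
optimum (`target`). Both are first-class kinds; the config chooses.

No automatic log detection is attempted for fold changes: the config must
state the cuts on whatever scale the study reports (the numeric preset
ships both raw and log2 cut sets).

## Percentile cuts

Percentile-coded cuts are resolved per variable against its non-missing
values using linear-interpolation empirical quantiles (numpy's default
convention), fixed so percentile runs are exactly reproducible. For a
`low` variable the desirable tail is the smallest-value end: cuts (5, 95)
saturate at 1 at or below the 5th quantile. A three-cut percentile
`extreme` spec (p_lo, m, p_hi) treats m as the width of the central band
zeroed out: (5, 50, 95) becomes valley cuts at the 5th / 25th / 75th /
95th quantiles, so the middle 50% of observations scores 0. Variables with
fewer than two distinct non-missing values cannot anchor quantiles and are
skipped with a warning.

## Integration

Within a study, d_study is the weighted arithmetic mean of the variable
desirabilities — deliberately not the classical Derringer–Suich geometric
form, so that a zero on one variable keeps the gene in the analysis.
Weights are renormalised per gene over the variables actually observed;
with unit weights and complete data this is the plain mean Σ dᵢ/N. A gene
missing a variable is averaged over its remaining variables (missing data
is absence of evidence, not evidence of undesirability); a gene missing
every variable is missing from that study.

Across K studies,

    d_overall = (Σ_present w_j d_study,j / Σ_present w_j) / (n_missing + 1),

i.e. the weighted mean over the studies with data, divided by one plus the
number of studies without data. The per-gene weight renormalisation keeps
scores in [0, 1] for any non-negative user weights and reduces to the
unweighted form when all weights are 1. Two consequences anchor the
scale: a fully observed gene scores its plain (weighted) mean, and a gene
with a perfect score in exactly one of K studies scores 1/K. That second
value is the soft cutoff; genes at or above it are flagged *desirable*
(inclusive ≥).

Two alternative normalisations are retained for comparison. `literal_eq5`
divides the weighted sum by K·(n_missing+1) with K the total study count;
under it the single-study-perfect gene among 10 scores 0.01, which is
inconsistent with the 1/K cutoff semantics, so it is not the default.
`raw_mean` applies no missingness penalty at all.

Ranks are dense over d_overall (ties share a rank, 1 = most desirable) and
listings break ties lexicographically by gene id for byte-reproducible
output. Within-study percentile ranks use the number of unique values:
percentile = 100·(1 − (dense_rank − 1)/n_unique), so the top unique score
maps to 100 in every study regardless of study size.

## Permutation null

The null asks what the mean d_overall would be if study scores were
unrelated to gene identity. Each replicate independently permutes every
study's column of d_study values — missing cells travel with the shuffle,
so each study's score distribution and missingness rate are preserved
exactly while the gene-to-profile pairing is broken. The shuffle unit is
the study column (not individual variables, and not a global pool): it is
the coarsest unit that preserves per-study marginals, and the only one
whose null is non-trivial under the missingness normalisation. With
complete data the mean of d_overall is a grand mean invariant under column
shuffles, so every replicate equals the observed mean — a useful analytic
limit check. A shuffle can leave a gene with no data in any study; such
genes drop from that replicate's mean, mirroring how unobserved genes are
absent from the observed results.

Replicate RNG substreams are spawned deterministically from a single
user seed, so the distribution is reproducible and independent of
evaluation order. The summary reports the replicate mean and the
empirical 2.5–97.5 percentile interval.

## Hard-threshold baseline

Each study is dichotomised at adjusted P < 0.1 where an adjusted P-value
variable is configured, else unadjusted P < 0.05 (both strict). Genes
missing from a study are not significant there. The intersection table
counts genes significant in exactly k studies, with memberships, which is
the information an upset-style comparison needs.

## Input handling

Studies are TSV/CSV with a header and a named gene-identifier column.
Gene ids are matched exactly after whitespace stripping and case folding;
probe-to-gene or cross-annotation mapping belongs upstream. Duplicate gene
rows keep, per variable, the most desirable value under that variable's
orientation (min for `low`, max for `high`, farthest from the valley
centre for `extreme`, closest to the peak for `target`) — conservative
toward candidate retention and deterministic; occurrences are logged.
Genes absent from a study are treated as missing whether they were
unmeasured or filtered; the inputs do not distinguish the two. Unparseable
numeric cells become missing with a logged count. Result floats are
serialised at 12 significant digits so reruns diff cleanly.

## Synthetic data generator

The generator emulates a sparse heterogeneous integration: K studies over
a shared universe of n_genes, each study covering an `overlap` fraction of
it, each reporting a P-value and a log2 fold change. Null genes draw
P ~ Uniform(0,1) and log2FC ~ Normal(0, σ); planted genes draw
P ~ Beta(a, 1) with a < 1 (monotone strength control: smaller a
concentrates P near 0) and a fold change displaced into the tails by a
constant shift with random sign. Defaults — 10 studies, 5000 genes, 70%
overlap, 50 planted genes, a = 0.1, shift = 2, σ = 1 — describe moderate,
consistent evidence: planted genes are rarely the top hit of any single
study but carry signal wherever they are measured. Missingness is
gene-uniform by default; the `signal_correlated` mode keeps planted genes
present in every study, coupling high scores with low missingness — the
regime in which the permutation null separates from the observed mean.

What the generator does not emulate: platform-specific artifacts (probe
effects, batch effects, methylation beta distributions), correlation
between genes, or between-study effect-size heterogeneity beyond presence/
absence. Passing recovery tests on it therefore shows that the ranking
arithmetic surfaces consistent moderate evidence and beats all-studies
intersection under sparsity; it does not certify performance on any real
data set.

## Numerical and design notes

- All transforms are vectorised numpy; tests pin them to pointwise
  evaluation of the piecewise formulas at 1e−12.
- Cross-study integration is validated against a per-gene scalar reference
  on random matrices at 1e−12 in all three modes.
- Acceptance-scale problem sizes: the recovery benchmark runs 20 seeds of
  the default 5000-gene, 10-study generator; the null-regime check uses a
  2000-gene, 10-study signal-correlated matrix with 1000 shuffles. These
  sizes give stable directional results at desk scale.
- Empty matrices, all-zero weight vectors, unknown modes and malformed
  configs raise typed errors naming the offending study or variable.

## Known limitations

- d_overall is a prioritisation score, not a test statistic; no per-gene
  empirical P-values against the null are computed.
- User weights are renormalised per gene; a deliberately unnormalised
  weighting scheme is not supported.
- Gene harmonisation is exact string matching after normalisation; alias
  resolution must happen before input.
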