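# Methods

This note documents the models, conventions and numerical choices behind
`flankpref`, and what the synthetic-data generators do and do not emulate.

## Hairpin-bisulfite reconstitution

A hairpin-ligated molecule is sequenced as one read: converted upper strand
5'→3', the 27-mer linker, then the converted lower strand 5'→3' from the
ligation point. With upper-strand length *n*, the duplex partner of upper
position *i* is lower-read position *n* − 1 − *i*. Bisulfite converts
unmethylated C to T on each strand independently, so each duplex position is
decoded from the (upper, lower) base pair: A/T→A, G/{C,T}→G, C/G→C
(methylated at the central site), T/G→C (unmethylated), T/A→T; any other
pair is inconsistent. Reads with any inconsistent pair inside the analysis
window are discarded whole rather than position-masked — the simplest
defensible rule; the rate is reported in the run log, whose counters satisfy
input = calls + dropped(length) + dropped(quality) + duplicates +
dropped(alignment) + dropped(inconsistent).

Conventions: the central cytosine is position 0 and the second base of the
central dinucleotide is +1, so the variable flank positions are −10..−1 and
+2..+11; analysis restricts to −8..+8 to stay clear of the fixed arms.
Quality filtering trims to 128 nt and by default requires every base of the
trimmed read to reach Phred 20 (`quality_mode="mean"` relaxes this to the
mean); duplicates are identical full read strings after trimming, so reads
differing only in methylation state are *not* duplicates. Both read
orientations are tried during linker search since the sequenced strand is
library-dependent.

The simulator emits the methylation state on the upper-strand central
cytosine only; the lower-strand central C is written unmethylated. Because
the decoder reads the central state from the upper strand, simulation and
reconstitution are exact inverses in the noise-free case — a property the
tests exploit as a round-trip identity at 10 000 reads. CCWGG-context calls
(the E. coli dcm motif, which shares the central C of CpA/CpT sites when the
enzyme is produced in a dcm+ host) are flagged and excluded from CpA/CpT
analyses.

## o/e profiles

For the methylated product pool, per-position base frequencies are divided
by the frequencies in the total analyzed pool. Using the total pool as the
expectation (rather than a theoretical 0.25) makes the profile robust to
library composition bias; a uniform-expectation switch exists. The
normalization identity Σ_b f_total(b,p)·oe(b,p) = 1 holds by construction
and is asserted to 1e-9. Replicates are merged by pooling raw counts, not by
averaging o/e — count-weighted pooling is the statistically coherent
reading of merging — and pairwise Pearson r values of the inputs are
attached as a replicate-consistency diagnostic. Positions absent from both
pools are reported missing, not zero. Extreme-decile composition ranks
contexts by value with lexicographic tie-breaking (determinism over
aesthetics: under exactly tied values the "top" set is the alphabetical
head, which is arbitrary but reproducible).

## Virtual-time kinetics

Each reaction *j* (its own enzyme concentration and incubation time) is
assigned a latent virtual time τ_j ≥ 0; context *i* follows the
monoexponential m_ij = P·(1 − exp(−k_i τ_j)) with plateau P fixed at 1 by
default (a single global fitted plateau in (0,1] handles incomplete
conversion). The model is invariant under k→ck, τ→τ/c; the gauge is fixed by
geometric-mean(k) = 1, so rates are relative to the average context —
symmetric in contexts, unlike pinning one τ. With τ frozen by the caller
(`fix_tau`) no gauge is applied, and the one-reaction fit reduces exactly to
k = −ln(1 − m/P)/τ.

Fitting minimizes Σ w_ij (m_ij − P(1−e^{−k_i τ_j}))² by alternating exact
coordinate updates — all k given τ, then all τ given k (vectorized,
safeguarded Newton with backtracking; single-observation rows solved in
closed form) — until the relative SSE change is below 1e-10. The joint
problem is coordinate-separable, so this "serial fitting" converges to the
same stationary points as a joint nonlinear solver at machine precision;
multiple restarts (closed-form initialization plus log-normal jitter, σ=0.3)
guard against local minima, and the fit is declared converged only when at
least three restarts agree in SSE to 1e-6 relative.

Weights: the first pass uses w_ij = per-context read counts. Counts alone
underweight near-saturated observations, whose binomial variance p(1−p)/n is
tiny, and measurably inflate the spread of the extreme fitted rates; the
default therefore adds one generalized-least-squares refinement pass with
w_ij = n_ij / max(p̂(1−p̂), 10⁻³), where p̂ is the model-predicted level from
the first pass (the floor caps the weight of fully saturated cells).
`weighting="counts"` restores the plain behaviour; on noise-free data the
two are identical because the residuals vanish.

Degenerate contexts are handled outside the optimizer: contexts observed in
fewer than two reactions (one, with fixed τ) are excluded and listed;
all-zero contexts get k = 0 and all-at-plateau contexts k = +inf, both
flagged (`fitted_rates` filters the sentinels). `min_count` (default 10
reads per context per reaction) controls which observations enter. Standard
errors are conditional Gauss–Newton errors (τ held fixed, residual variance
from the weighted SSE over its degrees of freedom) — adequate for ranking
and for flagging poorly determined contexts, not a full covariance.

A caution from simulation: the max/min rate ratio is a heavy-tailed
statistic. A near-extreme context is typically informative in only one
reaction, and a 2–3σ binomial fluctuation there propagates through the
−ln(1−m) nonlinearity into tens of percent of ratio error. Recovery studies
therefore report the median ratio error over three replicate datasets;
rank-based measures (Spearman ≈ 0.998 at 4 reactions × 50 000 reads) are
stable per replicate.

Class-level CpN rates reuse the same machinery at CpG/CpA/CpT/CpC
granularity, optionally with τ frozen to the CpG fit, and are reported
relative to CpG = 1. Initial rates for radioactive progress curves are
ordinary least squares over the initial linear phase (≥ 3 strictly
increasing time points; duplicate times collapse to their mean), and the
hemimethylated-minus-fully-methylated slope difference isolates the central
upper-strand site, with errors propagated in quadrature. Substrate-level
preference averages the rate-table lookups of every CpG strand-site (lower
strand via reverse-complemented context); sites lacking the full −2..+3
context are skipped and counted.

## Genomic methylomes

Call tables are bedGraph-like (chrom, 0-based position, strand, methylated
count, total count; a Bismark-coverage dialect is auto-detected). Each
cytosine of a CpG is kept as its own record with a strand-appropriate
(reverse-complemented on minus) 22-nt context, coverage ≥ 5, and ≥ 10 bp
clearance from contig edges; per-context means are unweighted across sites
(each site's m/t counts once; a coverage-weighted mode exists), and o/e is
the context mean over the overall mean. NNCG granularity aggregates the 16
contexts sharing the −2/−1 bases, site-count-weighted.

The local analysis slides a 22-consecutive-CpG window (step 1) along one
chromosome and computes Pearson r between per-site level and per-site
preference, implemented with cumulative sums so a full chromosome scan is
O(n); windows with a numerically constant vector are skipped and counted.
The randomization test permutes the 256 preference *values* among context
keys (≥ 20 rounds), recomputes the summary statistic (mean window r by
default; the positive-minus-negative window count is the alternative), and
reports Z = (obs − null mean)/null SD with a one-sided normal p. With 20
permutation rounds the null-SD estimate adds ~5% heavy-tailing to Z; at
1 Mb this still left 100/100 shuffled-preference datasets below |Z| = 3 in
calibration runs.

## Repeat motif scanning

Counts are overlapping exact matches; a CCCGGG hexamer deliberately counts
one CCCG and one CGGG (occurrences are defined independently; the combined
o/e is then exactly strand-symmetric, since f_C and f_G swap under reverse
complement). Expectations use the mononucleotide composition of the scanned
region itself: expected(CG) = n_pos·f_C·f_G, expected(CCCG) = n_pos·f_C³·f_G,
expected(CGGG) = n_pos·f_C·f_G³, with n_pos the number of motif start
positions minus windows containing ambiguous bases. The fraction mode,
[(n_CCCG+n_CGGG)/n_CG]/(f_C²+f_G²), asks what share of CpG sites sit in the
double-stranded CCCG/CGGG context, normalized so an i.i.d. sequence scores 1.
Windowed profiles tile the element in non-overlapping 50-bp windows (final
partial tile kept if ≥ 25 bp) against the whole-element expectation. Group
comparisons use the two-sided Welch t-test with Welch–Satterthwaite degrees
of freedom (zero variance in both groups with equal means returns p = 1).
Promoter or sub-element regions must be supplied as explicit coordinates;
the tool does not infer them.

## Synthetic-data generators: what they emulate

The read generator draws uniformly random flanks (a composition-bias option
stresses the o/e normalization), applies the monoexponential model with a
known rate table, and emits converted hairpin reads with optional noise
(incomplete/inappropriate conversion, substitution errors, duplicate reads).
It does not simulate PCR amplification bias, paired ends, or indels, and
flank CpN methylation is off by default — so passing tests demonstrate the
correctness of the decoding and estimation machinery, not robustness to
every artefact of real libraries. `dnmt3c_like_rate_table()` is a
deterministic additive-log-weight table expressing a strong C(−2)/C(−1)
preference with T(−1) disfavor and a DNMT3B-like G(+2) preference, spanning
roughly two decades with geometric mean 1; `loguniform_rate_table()` is the
neutral counterpart for recovery studies.

The methylome generator assigns each CpG cytosine a level proportional to
its own strand's 6-mer preference, scaled so the table-average context sits
at `mean_level` (default 1.46%, the regime of a DNMT3C-only methylome) and
clipped to [0,1]; observation is binomial at Poisson coverage. Modelling the
strands independently reflects pure de novo methylation without maintenance
coupling — appropriate for the DNMT3-only setting, unrealistic for somatic
methylomes with DNMT1. The repeat generator plants non-overlapping motif
copies into an i.i.d. background; 50 planted CCCG per 2 kb produce the ~3×
fraction-mode enrichment used in the group-detection studies.

Recovery-study conditions, chosen once: virtual times {0.3, 1.0, 2.5, 6.0}
to cover the progress curve of a geometric-mean-1, two-decade rate table;
4 reactions × 50 000 reads for rate recovery; 1 Mb at coverage 10 for the
genomic pipeline; 100 kb for motif null behaviour. All generators are
deterministic given their integer seed.

## Known limitations

- Standard errors of the rates ignore k–τ covariance (conditional errors).
- The fitted plateau is global; per-reaction plateaus are not modelled.
- The window-correlation scan treats retained sites as equally spaced in
  "site index"; genomic distance between consecutive CpGs is ignored, as in
  the windowed-site design it implements.
- Welch p-values at n = 3 vs 3 carry only 2–4 degrees of freedom; they are
  reported as computed, and group effects below ~3× should not be expected
  to reach p < 0.01 at that size.
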