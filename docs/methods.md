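# Methods

## The primer-design model

The object being optimized is a degenerate oligonucleotide: a string over
the 15 IUPAC nucleotide codes, standing for the mixture of all its
concrete expansions (its *degeneracy* is the product of per-position code
set sizes). A transcript window *matches* the motif when every window
base is a concrete A/C/G/T contained in the corresponding code set.
Ambiguous bases in target sequences never match: a primer cannot be
guaranteed to anneal to an unknown base, so counts stay conservative and
deterministic. Occurrences are counted at every start position,
overlapping ones included — priming sites are positions, not disjoint
blocks. Primers are reverse complements of mRNA-sense motifs, using the
IUPAC complement (A↔T, C↔G, R↔Y, K↔M, B↔V, D↔H; S, W, N fixed).

The search score is s = m / (m_t · (1 + t + r)). `m` counts mRNAs that
contain the motif at least once (presence), while `t` and `r` count total
occurrences in tRNA/rRNA. This asymmetric reading reconciles the coverage
interpretation of the score (with a clean background, s is the fraction
of mRNAs primed) with occurrence-level counter-selection against
structural RNA, where every additional site matters; an
occurrence-counting mode for `m` is available behind a flag.

The optimizer is a simulated-annealing-style walk at fixed selection
strength: one uniformly chosen position is mutated to one of the 14 other
codes (uniformly), and the mutant is kept when a uniform draw u satisfies
u < (s_new/s_old)^10. Consequences used by the tests: any non-worsening
move is always kept; a mutant at half the current score survives with
probability 2^-10 ≈ 0.00098. A zero previous score always accepts, which
escapes degenerate starts. The exponent (default 10) and iteration count
(default 2·10^6 per restart, the production setting; desk-scale runs use
2·10^4) are configurable, and several random restarts guard against local
optima. Every accepted motif is recorded; the ledger is deduplicated by
motif (scores are deterministic, keeping the first acceptance) and ranked
by score, then degeneracy (more general motifs first), then
lexicographically, for fully reproducible output. One master seed spawns
independent per-restart streams, so results do not depend on how restarts
are scheduled.

Primer selection applies a strong-binding 3'-end rule: scanning the
ranked ledger, the first candidate whose primer ends in `gc_rule_width`
symbols denoting only G/C bases (G, C or S) is returned, along with how
many higher-scoring candidates were skipped. The width defaults to 2; the
exact published form of the rule is unstated, so it is configurable, and
width 0 disables it.

## Occurrence scanning

Sequences of each class are packed once into a byte array (A=1, C=2, G=4,
T=8; anything else 16), with one separator byte between records so
windows cannot straddle transcripts. A motif becomes a vector of inverted
masks, and a window matches iff `bits & inv_mask == 0` everywhere. Two
paths share this definition: a plain early-exit kernel, and an indexed
path that enumerates the concrete 6-mers of the motif's least degenerate
6-symbol half (when fewer than 2048), reads candidate positions from a
precomputed CSR index, and verifies only those. The indexed path is ~20×
faster at search-realistic degeneracies. Both paths are property-tested
against a naive position-by-position scan written independently in the
test suite; the acceptance script repeats that comparison on 1000 random
motif/sequence pairs at run time.

## Tag analytics

Tags are classified by exact substring match on transcript sense strands
(DGE protocols are strand-specific; a both-strands flag exists). "Single"
means one distinct transcript contains the tag, regardless of how many
times within that transcript; two or more distinct transcripts of any
class give "multiple". Library totals N are the single-match mRNA totals.

The per-gene test compares binomial likelihoods with pooled versus
per-sample ML proportions; −2 log Λ → χ²(1), with 0·log 0 = 0 so genes
with zero counts in both samples get statistic 0 and p = 1. Raw p-values
are reported (the historical workflow thresholds raw P ≤ 0.05); a
Benjamini–Hochberg column is available behind a flag. Fold ratios follow
the signed convention (q if q ≥ 1, else −1/q) and are undefined — no
pseudocounts — when either count is zero. Because tag counts are
proportions of a fixed library, the test is compositional: planting 10%
of genes 4-fold up shifts every null gene's proportion down by a common
factor (here 1.3), which a proportion test legitimately detects at large
N. Null calibration is therefore checked on fully null tables, and
sensitivity on the planted DE genes with adequate counts.

## Array preprocessing and power

A spot is well measured when foreground exceeds the background pixel mean
by three background SDs in both channels. The phrase "higher than three
standard deviations of the distribution" admits two readings (3·SD vs
mean + 3·SD); mean + 3·SD is the standard one and is used, with the
multiplier configurable. Normalization subtracts background per channel
and rescales channel 2 so both channels have equal mean net intensity
over well-measured spots; ratios are invariant to any positive rescaling
of either channel.

GEL50 regresses the per-gene significance indicator on x = |log2 fold
change| (logistic MLE via iteratively reweighted least squares, converged
to score norm < 1e-8; perfect separation, one-class outcomes and constant
covariates raise errors) and inverts the curve at probability one half:
GEL50 = 2^(−intercept/slope). Whether the historical analysis regressed
on raw or log fold change is unstated; log2 makes up- and down-regulation
symmetric, and Table-scale GEL50 values (1.27–2.08) are naturally
fold-change-scaled, so the estimate is reported as 2^x50. A non-positive
slope (power not increasing with fold change) is an error rather than an
extrapolation. The binding-sites regression compares intercept-only vs
intercept + n_sites models by a χ²(1) likelihood-ratio test and reports
the slope.

## Synthetic data: what it emulates and what it does not

`make_transcriptome` draws i.i.d. bases at a given GC content (default
0.40, fungal-coding-like) and plants one uniformly chosen concrete
expansion of the motif at a uniform position in a prevalence-chosen
subset of mRNAs (defaults: 300 mRNAs × 500 bp, prevalence 0.8, 5 rRNAs of
1500–1800 nt, 10 tRNAs of 70–90 nt — a realistically sized fungal
structural-RNA complement). In strict mode every sequence is
rejection-resampled (up to 1000 attempts) until its occurrence count
equals its planted count, so the planted motif's components are exactly
(n_planted, 0, 0, m_t). Real transcriptomes are not i.i.d.: codon
structure, repeats and composition gradients create k-mer clustering that
the generator omits, so passing the recovery test demonstrates that the
optimizer finds an identifiable planted optimum, not that any particular
genome admits a high-coverage primer.

The default planted motif is `GCWTACGRTAGC` (degeneracy 4). This is an
identifiability choice: a planted motif of very high degeneracy (such as
the published yeast motif, degeneracy 23328) matches so much random
sequence by composition alone that its planted copies carry no
recoverable signal — the planted motif is then not even a local optimum
of the score, and searches converge instead to generic high-degeneracy
motifs. With a moderate-degeneracy plant the planted sites dominate the
score landscape and recovery is sharp; the recovered optimum is typically
a shifted, N-padded generalization of the plant that also collects chance
hits, scoring slightly above the plant itself, which the recovery check
(best ≥ 0.9 × planted score) accommodates. Its primer also ends in G,C,
exercising the 3'-end rule.

`make_tag_counts` draws log-normal baseline abundances (log-SD 1.0),
multiplies condition-2 abundances of a random DE subset by the fold
change, and draws each sample as one multinomial with the stated library
size (default 10^5) — so column sums are exact and genes are weakly
negatively correlated, as in real tag counting. Overdispersion between
biological replicates is *not* modelled; calibration results apply to the
single-draw sampling model the LRT assumes. `make_power_table` draws
log2 ratios Normal(0, 1) and significance from the logistic model with
slope 3.0 and intercept −3·log2(1.5) by default, i.e. true GEL50 = 1.5.

## Numerical and design choices

- Likelihoods use `xlogy` for the 0·log 0 convention; LRT statistics are
  clamped at 0 against round-off; χ² tails come from scipy.
- Logistic fits use statsmodels' Newton optimizer (tol 1e-12, checked
  score norm < 1e-8); separation is detected both geometrically (for the
  single-covariate case) and from divergent fits.
- Desk-scale problem sizes used by the tests and the acceptance script:
  1000 motif/sequence pairs for scanner equivalence; 5 searches of
  2·10^4 iterations × 4 restarts for planted recovery; 2000 genes at
  N = 10^5 for LRT calibration; 5000 genes for GEL50 recovery. These run
  in about a minute total on one core while leaving the stochastic
  assertions comfortable margins.
- FASTA parsing uses Biopython; U→T mapping and uppercasing accept RNA
  dialects; duplicate ids and empty sequences are hard errors.

## Known limitations

- No thermodynamic model of annealing (Tm, ΔG, mismatch tolerance): a
  "priming site" is an exact combinatorial match.
- Tag classification is transcript-space, not genome-space; tags from
  unannotated transcription are "unmatched" rather than genomic.
- The LRT models sampling only; biological replicate variance would
  require an overdispersed model outside this scope.
- GEL50 assumes a monotone logistic power curve in |log2 ratio|; strongly
  non-monotone power (e.g. saturation artifacts) is reported as a fit
  error, not modelled.
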