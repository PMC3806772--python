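# Methods

## Scope and model

`indeltree` predicts whether an in-frame (3n) coding indel damages gene
function. The classifier operates on indels whose protein consequence is
an amino-acid insertion, amino-acid deletion, or block substitution; 3n
indels that introduce an early stop, and all frameshifting indels, are
excluded and routed to a side channel (they are the province of a
frameshift predictor, which this package deliberately does not
implement).

Two classification routes share one feature schema:

* the **published-rule engine**, an ordered list of mutually exclusive
  rules shipped as plain text (`src/indeltree/data/published_rules.tsv`),
  carrying the training support and correct counts behind each
  confidence (confidence = correct/support, rounded to 3 decimals);
* a **C4.5-style tree inducer** that re-derives trees from any labeled
  feature matrix.

## Coordinates and normalization

External interfaces are 1-based inclusive (VCF convention); internal
span arithmetic is 0-based half-open. `Indel.pos` is the first
inserted/deleted base. Left-normalization rotates the allele one base at
a time while the reference base left of the indel equals the allele's
last base; it is idempotent and preserves the mutant sequence exactly.
Normalization precedes every position-dependent computation — the repeat
call and the 5′ conservation lookup both require it, and
`left_flank_conservation` refuses unnormalized input rather than
silently using an ambiguous coordinate. Repeat status itself is
placement-sensitive for rotated alleles, which is precisely why the
pipeline normalizes first.

## Repeat detection

Candidate units are all substrings of the indel sequence; a unit
qualifies when its exact tandem copies, tiling contiguously across the
indel and its flanking reference sequence, reach at least two copies and
the period-specific minimum total length: 4 bases for period 1, 6 for
period 3, and max(4, 2·period) otherwise (a generalisation consistent
with both stated anchors). Among qualifying candidates the greatest
total length wins; ties prefer the smallest period, so a C-run is
reported as (C)ₙ rather than (CCC)₁. The flank window is 50 bp per side
(configurable); small exact repeats of interest are far shorter.
Matching is case-insensitive and on the reference strand only.
Approximate (mismatched) repeats are out of scope.

## Consequence calling

The mutant CDS is built in plus orientation and reverse-complemented for
minus-strand transcripts; both original and mutant CDS are translated
with the standard nuclear codon table (selenocysteine is not handled).
An in-frame stop before the original terminus ⇒ early stop. Otherwise
the two protein strings are compared after trimming the longest common
prefix, then the longest common suffix of the remainder: an empty
deletion ⇒ amino-acid insertion, an empty insertion ⇒ amino-acid
deletion, both non-empty ⇒ block substitution. The affected span is the
1-based residue interval of deleted/changed residues; a phase-0
insertion anchors to the residue immediately N-terminal of the insertion
point (length-1 span, `pure_insertion` flag, flanking pair recorded) so
that domain/disorder features always have a non-empty residue anchor.
Transcripts whose coding length is not divisible by 3 are rejected as
invalid/incomplete at load time. The GTF dialect this package reads and
writes includes the terminal stop codon in the CDS feature, keeping the
mod-3 invariant and a stop-terminated translation.

## Features

1. `pfam_fraction_affected` ∈ [0,1]: overlapped domain intervals /
   total domain intervals on the protein. Domain *instances* are
   counted, not distinct families. A protein with no annotated domains
   scores 0.0 (not missing), so rules conditioned on "no domain
   affected" fire for domain-less proteins.
2. `in_repeat`: the repeat call on the normalized indel.
3. `in_disorder`: strict majority — more than half of the affected
   residues inside disorder intervals. (The single-residue case is the
   common one; the majority rule is this package's extension to
   multi-residue spans.)
4. `left_base_conservation`: the score at position pos−1 of the
   normalized indel; missing scores propagate as NaN, never as 0. The
   published rules treat a missing score as "not conserved" (the
   ≤ 1.405 branch), and each such event is logged.

Additional features register by name (duplicates rejected) and travel
through extraction, selection and training. The built-in physiochemical
registry uses the Kyte–Doolittle hydropathy scale, average residue
masses, and Zamyatnin residue volumes — these scale choices are this
package's, made because the full 27-feature definitions are not
available; the four core features are first-class and always present.

## Tree induction

Gain-ratio split selection with binary threshold splits at midpoints
between sorted distinct values (booleans split at 0.5); ties in gain
ratio break to the lowest feature index, then the lowest threshold.
Split admissibility requires both children to hold at least `min_leaf`
samples (default 2) after routing missing values to the majority branch
— a simplification of fractional instances, and a documented divergence
from full C4.5. Gain on attributes with missing values is scaled by the
fraction observed. Pruning is pessimistic error-based (upper confidence
bound on the leaf error rate, confidence 0.25 by default), preceded by a
collapse pass that removes subtrees whose splits do not reduce training
error; subtree raising is not implemented. Leaf ties predict neutral
(the conservative call). The ranking score for ROC is the leaf's
damaging fraction.

One deliberate extension: with pruning *disabled*, an impure node where
no split has positive gain takes the first admissible split in tie-break
order. Classical C4.5 stops there and therefore cannot fit, e.g., the
XOR of two flags; the unpruned trainer is meant as an exact
interpolator of consistent data, and exact interpolation additionally
requires `min_leaf=1` (the default 2 cannot isolate singletons). With
pruning enabled the trainer is classical.

## Evaluation

Damaging is the positive class. Sensitivity, specificity, precision and
accuracy are computed as exact rationals (`fractions.Fraction`) and only
rounded for display (percentages to integers, MCC/AUC to 2 decimals).
MCC is reported missing when any confusion marginal is zero; greedy
selection maps a missing MCC to 0.0 so degenerate single-leaf folds
remain comparable. AUC is the tie-averaged Mann–Whitney statistic,
identical to the trapezoidal area under the ROC curve.

Cross-validation is stratified by class (fold assignment: per-class
shuffle, round-robin deal; the seed is recorded in every report); the k
held-out confusions are pooled so each sample is tested exactly once.
Balanced resampling draws |disease| neutrals without replacement per
repetition and aggregates mean and SD (ddof=1) across repetitions; SD is
omitted at reps=1. Greedy forward selection adds, per step, the
candidate with the best cross-validated MCC and stops when no addition
*strictly* improves it (a literal "until performance decreases" can
loop on plateaus); every candidate evaluation shares the same fold seed
so comparisons are paired.

## Synthetic fixtures

The generator emulates a two-class indel study on a toy genome:
single-exon genes (400–900 body codons by default, 40 genes) on one
synthetic chromosome, each protein laid out into a domain zone (two
domain intervals), a disordered zone, and an ordered domain-free zone.
Damaging indels are planted in domains, in repeats, or at conserved
flanking bases; neutral indels in disordered regions, at non-conserved
bases, or — at the neutral repeat rate — in repeats inside the
disordered zone. Default planting rates follow the observed class
contrast (43% of damaging vs 11% of neutral indels in repeats; 474
indels per class; the natural class imbalance of roughly 1:20 can be
requested by raising `n_neutral`). Repeat indels are codon duplications;
non-repeat plants are verified against the repeat caller at the
normalized placement and re-sited on failure, so repeat recall on the
planted truth is exactly 1.

Conservation scores are drawn from class-conditional Gaussians (means
2.3 and 0.6, sd 0.45) that straddle the 1.405 rule threshold, truncated
class-wide to ≥ 1.8 (damaging) and ≤ 1.0 (neutral). The truncation gap
makes the planted label a deterministic function of the four features
with a margin: any data-driven split threshold between observed values
falls inside the gap, so held-out samples always land on the correct
side and noise-free 10-fold CV is exactly perfect, independent of seed.
Observed labels are then flipped symmetrically at the label-noise rate,
giving a closed-form best-achievable accuracy of 1 − noise
(`planted_bayes_accuracy`); the test suite checks the trainer against a
noise rate of 0.18 (best achievable 0.82) at n = 948.

What the fixtures do **not** emulate: multi-exon gene architecture,
splice effects, minus-strand genes (covered by unit tests instead),
overlapping transcripts, realistic conservation autocorrelation along
the chromosome, allele frequencies, or linkage. Passing tests therefore
demonstrate the correctness of the machinery on data whose generative
structure is known, not the field performance of the shipped rules on
real cohorts — the published rule confidences are carried as data, and
real-data performance claims are outside what this package can verify.

## Numerical and procedural choices

* Exact rational metric arithmetic; MCC in floating point via one
  square root of an exact integer product.
* Gain-ratio tie-break: lowest feature index, then lowest threshold;
  float-equal ratios resolve to the earlier candidate.
* Degenerate inputs: single-class training yields a one-leaf tree with
  a warning; empty confusions, empty repeat summaries, single-class AUC
  and undersized neutral pools raise errors.
* One-indel-per-gene dataset thinning keeps the first indel in genomic
  order (the original choice rule is unstated).
* When a VCF record lacks a transcript tag, prediction falls back to
  the longest-CDS transcript overlapping the indel and logs the choice.
* Problem sizes in the test and acceptance suites (948-sample fixtures,
  10-fold CV, 1,000-case oracle sweeps, 10,000 normalization fixtures)
  are chosen to exercise every code path at comfortably interactive
  runtimes.

## Known limitations

* Block substitutions that remove the stop codon ("stop loss") have no
  category of their own and are rejected with a model error.
* The rule file's `default-*` branches for feature combinations not
  covered by the three published rules are this package's assumption
  (damaging at confidence 0.5), chosen so that repeat membership and
  high conservation lean damaging; they are overridable via `--rules`.
* Missing-value routing (majority branch) differs from C4.5's
  fractional instances; with largely complete features the effect is
  confined to rare missing conservation scores.
* The AUC of the published-rule engine ranks on leaf confidences; with
  six distinct confidence levels the ROC curve is coarse.
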