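# Methods

`spaudit` audits "common-feature" secretion predictors — tools that score a
protein's likelihood of secretion from general sequence properties rather
than from the signal peptide (SP) itself. If such a predictor truly relied
on features shared between classically secreted proteins (CSPs) and
leaderless secretory proteins (LSPs), perturbing only the SP of a CSP
should leave its score unchanged. The package generates the perturbations,
scores them through a pluggable predictor, and quantifies how much of the
prediction is attributable to the SP.

## The perturbation protocol

For each input sequence with a resolved SP region `[1..L]`, five derived
datasets are produced:

| kind        | operation                                   | length | replicates |
|-------------|---------------------------------------------|--------|-----------|
| `reverse`   | whole sequence reversed                     | kept   | 1         |
| `sp_remove` | SP region deleted                           | −L     | 1         |
| `sp_cterm`  | SP moved to the C-terminus                  | kept   | 1         |
| `sp_random` | SP residues uniformly shuffled              | kept   | B         |
| `random`    | entire sequence uniformly shuffled          | kept   | B         |

With the default B = 500 bootstrap replicates each input yields
2B + 3 = 1003 derived sequences. Stochastic kinds are aggregated as the
arithmetic mean score over replicates. Each replicate's Fisher–Yates
shuffle is seeded from a SHA-256 hash of `(global seed, origin id, kind,
replicate)`, so any single replicate is reproducible in isolation and two
runs under the same top-level seed are byte-identical.

SP regions come from one of three sources, selected by policy:
`predicted` (parsed from an external SP predictor's short tabular output;
a cleavage site "between L and L+1" maps to region length L),
`annotated` (ground-truth lengths, used for synthetic data), or `fixed`
(a fixed N-terminal length, default 30 residues, the convention for
negative records, which have no SP). Under `predicted_then_drop`,
positives with no SP call are excluded rather than given a fixed region:
assigning them the negative-class convention would conflate the classes.
A region must always leave a non-empty mature sequence.

Records shorter than 40 residues are excluded at admission (the minimum
input length of the reference predictor family). The filter applies to
original sequences only; an `sp_remove` derivative that falls below a
scorer's minimum is still emitted and is skipped-with-a-flag (or raises,
by policy) at scoring time, since the right disposition depends on the
scorer.

## Statistics

* **Paired shift tests.** Scores of modified vs original sequences are
  compared per class with a two-sided paired t-test (the pairs share an
  origin protein, so an unpaired test would be wrong). The five
  modification kinds per class form the multiple-testing family; p-values
  are Bonferroni-adjusted by default (Holm selectable) and significance is
  declared at adjusted p ≤ 0.01. Zero-variance difference vectors are
  resolved explicitly (all-zero → p = 1; constant non-zero → p = 0) and
  flagged.
* **Rank stability.** Spearman correlation (average ranks on ties) between
  original and modified scores, per class and kind; constant inputs yield
  a flagged NaN.
* **Score distributions.** Gaussian-kernel KDE with Scott's-rule bandwidth
  (`n^(-1/5)·sd`), evaluated on a grid spanning [0,1] extended by three
  bandwidths per side so the reported curve integrates to ≈1. The kernel
  sum is computed directly (a constant-score sample with an explicit
  bandwidth is a legitimate degenerate input and is handled exactly); the
  implementation is cross-checked against `scipy.stats.gaussian_kde` in
  the test suite.
* **ROC analysis.** Positive-vs-negative ROC per kind under the rule
  `score ≥ threshold ⇒ positive`, thresholds swept over the distinct
  observed scores plus a +∞ sentinel, AUC by trapezoidal integration —
  numerically identical (≤1e−12, property-tested) to the probability a
  random positive outscores a random negative with ties counted one half.
  Operating points are reported (a) at the discrete point with maximal TPR
  among those with FPR ≤ 0.05, ties broken toward lower FPR then higher
  threshold, and (b) at the discrete points whose thresholds are nearest
  to 0.5 and 0.6, with midway ties resolved toward the higher (more
  conservative) threshold using a 1e−9 relative tolerance so float
  rounding cannot flip the tie.

## The synthetic scorer

A stand-in predictor whose score rises with SP-like N-terminal
hydrophobicity:

    H     = max mean Kyte–Doolittle hydropathy over all 8-residue windows
            within the first 45 residues
    raw   = 0.45 + 0.35 · logistic(2.5 · (H − 1.6))
    score = clamp[0,1](raw + N(0, 0.05))            (noise optional)

Window width 8 and scan depth 45 make the scorer sensitive to any
sufficiently hydrophobic stretch near the N-terminus — a real SP h-region
or a transmembrane-like decoy — which is exactly the failure mode the
audit is designed to expose. Ambiguous residues (B/J/O/U/X/Z) contribute
zero hydropathy and flag the record. Noise draws are keyed on the
sequence's identity hash, so scores are independent of batch order and
splitting. External predictors are wrapped by an adapter that writes a
FASTA batch, runs a shell command template, parses a whitespace-delimited
id/score table, and enforces the [0,1] contract (missing ids, non-numeric
or out-of-range values are hard errors).

## The synthetic data generator

Positives are built as a tripartite SP — an n-region of 1–5 residues
starting with M plus K/R, an h-region of 7–13 residues from
{A,I,L,F,V,M} weighted toward L, and a c-region of 3–7 small/polar
residues (total 11–25, recorded as ground truth) — followed by a mature
region of 80–400 residues drawn from an average database amino-acid
composition. Negatives are mature-only chains starting with M; with
probability 0.2 a negative carries one internal hydrophobic stretch of
8–12 residues. The stretch starts at positions 32–36: inside the scorer's
45-residue scan (so the false-positive channel is active) but past the
fixed 30-residue pseudo-SP region (so SP-targeted perturbations relocate
but never destroy it, and the negative class shows no systematic shift —
the behaviour real non-secretory proteins exhibit).

Under these defaults (200+200 proteins, B = 500, noise on) the synthetic
study reproduces the qualitative audit signature: positive originals score
well above negatives; `sp_remove`, `sp_cterm` and `reverse` shift positive
scores down significantly at adjusted p ≤ 0.01 while SP-targeted kinds
leave negatives non-significant; and the original-score ROC collapses
toward chance once the SP is removed (AUC drop ≳ 0.3 at these settings,
far above the 0.1 the audit treats as decisive).

### What the synthetic conditions do not emulate

* Real score *ranges*: negatives average ≈0.67 here (the max-window
  statistic over a 45-residue background prefix is itself fairly large),
  not the ≈0.48 of real non-secretory proteins; conclusions rest on
  class contrasts and their direction, never on absolute score levels.
* Rank structure: synthetic positives are homogeneous, so original scores
  occupy a narrow band and Spearman correlations between original and
  modified scores are noise-dominated (≈0). Real datasets are
  heterogeneous and show high rank stability for mild perturbations; the
  correlation machinery is exercised and tested, but its magnitudes on
  synthetic data carry no biological meaning.
* Real proteome composition, domain structure, redundancy, or any
  predictor's internal feature set.

## Numerical and design choices

* One top-level seed drives everything: dataset generation, shuffle
  replicates and scorer noise all derive independent streams from it by
  hashing structured keys; derived seeds stay below 2^32.
* Deterministic kinds are emitted once (replicate 0); replicating a
  deterministic transformation would only duplicate rows.
* Bootstrap aggregation is the arithmetic mean, stored with the replicate
  count; per-replicate vectors can be retained on request.
* Problem sizes in the test suite are scaled (30–200 proteins per class,
  25–500 replicates) so the full audit runs end-to-end in minutes on one
  CPU; the protocol is size-independent.
* TSV/JSON outputs use fixed float formatting (`%.12g`, sorted JSON keys)
  so identical seeds produce byte-identical artifacts.

## Known limitations

* The audit quantifies SP-dependence of *one scorer at a time*; it does
  not compare scorers or estimate absolute accuracy on real proteomes.
* `predicted_then_drop` makes the positive set conditional on the external
  SP predictor's recall; the exclusion count is logged but no correction
  is applied.
* The decoy-rate default (0.2) sets the synthetic false-positive channel;
  the ROC's absolute position on negatives is a function of that choice.
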