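# Methods

## The scoring model

The PMC (Policy Modeling Consistency) index treats a policy document as a
vector of binary content features organized in a two-level hierarchy: `M`
main indicators, the *t*-th containing `T_t` sub-indicators
`X_tj ∈ {0, 1}`. All sub-indicators carry equal weight. Scoring proceeds
in two stages, each rounded to two decimals:

1. main-indicator score `X_t = round2( Σ_j X_tj / T_t )`;
2. composite index `PMC = round2( Σ_t X_t )` over **all** main indicators.

The model assumes the binary codings are exhaustive and content-valid for
the policy domain (they come from close reading of the policy texts, here
replaced by bundled reference tables and synthetic generators) and that
equal weighting is appropriate — no weighting variant is implemented.

### Conventions this package fixes

Several conventions are under-determined by the printed record; the
package fixes them as follows and regression-tests each one.

- **Rounding** is decimal half-up at two decimals, at both stages. The
  published score table prints 0.63 for 5/8, which rules out banker's
  rounding (0.62). Implemented with `decimal` arithmetic, not binary-float
  `round`, so exact halves such as 1/8 round up deterministically.
- **The summation covers all main indicators**, including the sub-less
  disclosure indicator: every published composite value equals the sum of
  all ten main scores. (One printed rendering of the formula caps the sum
  at nine; it does not match any published row and is treated as a
  typographical artifact.)
- **Sub-less main indicators** are scored as a single implicit binary
  variable (`T = 1`) contributing one column to the score matrix under the
  main indicator's own id, while `sub_counts` reports 0 declared subs.
- **Depression index** `= M − PMC`. The defining formula is not printed in
  the source record; this reconstruction matches all 13 published rows
  exactly.
- **Levels**: `[7, 10]` Excellent, `[6, 7)` Good, `[5, 6)` Acceptable,
  `[0, 5)` Poor. The intervals partition `[0, 10]`; no published value
  falls on an interior boundary, so the half-open convention is a choice,
  documented rather than inferable.
- **Ranking**: `rank_policies` defaults to competition ranking ("1224").
  The published cohort, however, contains one exact tie (two policies at
  5.79, identical even before rounding) printed with *distinct* ranks in
  table order, so the pipeline entry point `evaluate()` defaults to
  ordinal ranking with ties broken by input (document) order, which
  reproduces the published rank column; pass `rank_method="competition"`
  for shared ranks.
- **Missing cells are errors**, never imputed; the study protocol has no
  missing-data rule.
- `classify_level`/`evaluate` accept a `max_score` other than 10 (e.g.
  scoring out of 9 after dropping the constant disclosure column); the
  level thresholds stay absolute.

## Reference tables and the coding fixture

Four plain-CSV tables ship with the package: policy metadata (ids, titles,
ISO-normalized release dates, issuing agencies), the published main-score
table (twelve policies; the thirteenth has a published total but no
published decomposition and therefore no row), the published results table
(all thirteen), and the published per-variable average codings.

A printed main score `k/T` identifies only the *count* `k` of set
sub-indicators, not which ones. The bundled coding matrix
(`gen_table4_consistent_matrix`) therefore uses a documented convention:
the leading `k` sub-indicators are set, except where the true coding is
inferable from the published record — the release-agency block follows
each policy's issuing agencies (the state TCM administration coded for
every decomposed policy, the health commission added where the printed
score implies two agencies), and the disclosure variable is 1 everywhere.
The matrix is validated at construction against the published table, so it
cannot drift. One inconsistency in the published record is worth noting:
the metadata table lists two issuing agencies for P8 while its printed
agency score implies one; the coding matrix follows the printed score,
the metadata table keeps both agencies as printed.

## Text mining

The original workflow used a proprietary Chinese content-mining
application for word frequencies and the keyword network. The package
replaces it with a documented generic pipeline: Unicode-NFC
normalization and lowercasing (no stemming), a pluggable segmenter
(whitespace default; a per-character segmenter for unsegmented CJK text;
any callable accepted), configurable stopword and minimum-length filters,
frequency-ranked keyword extraction with lexicographic tie-breaks, and a
weighted undirected co-occurrence graph whose default unit is the whole
document (edge weight = number of documents containing both terms), with a
sliding token window available. No claim is made of reproducing the
original network node-for-node — the original tool's dictionary, stopword
list, and thresholds are unpublished; the tests assert the algorithmic
contract (planted-frequency recovery, symmetry, deletion monotonicity,
brute-force pair-count equivalence), not any published figure.

## Synthetic data

The generators emulate the statistical structure the analysis consumes,
under the study's own conditions by default:

- **Score matrices**: independent Bernoulli(p_j) codings per binary
  variable; defaults are a 13-policy cohort with p_j equal to the
  published per-variable average codings, so a generated cohort mimics the
  observed coding rates. Larger cohorts (n = 2000 in the tests) are used
  for parameter-recovery checks.
- **Corpora**: i.i.d. token streams over a keyword profile; the default
  profile is the study's reported top-keyword list with Zipf-decaying
  (1/rank) weights and Poisson document lengths around 300 tokens, a
  realistic order of magnitude for the notice-style policy texts. The
  generators plant ground truth (most-frequent term, token multisets) that
  the mining stage must recover.
- **Metadata**: release dates uniform over the study's 2003–2023 span,
  with a second issuing agency at the observed 3-of-13 rate.

What the generators deliberately do **not** emulate: correlation between
sub-indicators within a policy (real codings are strongly dependent —
e.g. agency variables are determined jointly), temporal clustering of
releases (the real timeline spikes in 2020), and any linguistic structure
beyond marginal token frequencies. Tests passing on synthetic data
therefore validate the arithmetic and algorithmic contracts of the
pipeline, not the content-analytic judgments that produce real codings.

## Numerical and statistical test design

- Scoring tests compare against an independent integer-arithmetic oracle
  (`(200k + T) // (2T)` cents) on exhaustively enumerated and
  property-sampled inputs, so the `decimal`-based implementation and the
  oracle share no code path.
- Conservation (`PMC + depression = M`) is asserted exactly, at two
  decimals, on a 10,000-policy random cohort.
- Parameter recovery uses the per-variable binomial 3-sigma band at
  n = 2000. Because 45 bands are checked simultaneously, a correct
  generator still exceeds one with probability ≈ 2·Φ(−3)·45 ≈ 0.11 per
  cohort; the family-wise form of the check — at most one band exceeded,
  none beyond 4 sigma — follows from that multiplicity arithmetic and has
  a false-failure rate below 1% while still detecting a single
  probability mis-set by ~0.05.
- Degenerate inputs (empty schemas, empty rows, non-binary cells,
  out-of-range indices, unparseable dates) raise typed errors naming the
  offender; nothing is silently coerced.
- Surface smoothing (bilinear upsampling, fixed z-range [0, 1]) is
  presentation-only; the stored artifact is always the exact 3×3 grid.

## Problem sizes

The default test and acceptance runs use the study-sized cohort (12–13
policies), a 2,000-policy cohort for recovery checks, and a
10,000-policy cohort for the conservation sweep; the full suite and the
acceptance script each complete in seconds on one CPU.

## Known limitations

- Equal weighting only; no entropy/TOPSIS-style composite variants.
- No statistical inference on scores (the method is deterministic given
  the codings; the study performs none).
- The text-mining stage makes no attempt at Chinese word segmentation
  beyond the per-character fallback; plug in a dictionary segmenter for
  real Chinese corpora.
- The thirteenth policy's per-indicator decomposition is not published, so
  pipeline-level checks of the composite index cover the twelve decomposed
  policies, with the thirteenth entering only through its published total.
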