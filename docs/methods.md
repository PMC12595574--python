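# Methods

## Model

`dematelkit` implements classical (crisp) DEMATEL. The object of study is
a system of *n* factors whose pairwise direct influences are elicited from
a panel of *m* experts on an integer scale 0 (no influence) to
`scale_max` (very strong influence; default 3), with the diagonal fixed at
zero. The stages are:

- **Aggregation.** The direct-relation matrix *A* is the unweighted
  arithmetic mean of the expert matrices, cell by cell. No per-expert
  weights are offered: the mean is the method's canonical aggregation, and
  weighting schemes would change the estimand. Panels must share one
  factor catalog (same ids in the same order) and one scale.
- **Normalization.** *X* = *A*/s with s = max over rows of the row sums of
  *A*. This is the classical normalizer; it guarantees every entry of *X*
  is in [0, 1] and that the spectral radius of *X* is at most 1, with
  equality only in the degenerate case that every row attains the maximal
  row sum (e.g. a perfectly symmetric constant matrix). In that case
  I − *X* is singular and the package raises a "non-convergent influence
  system" error rather than regularizing silently.
- **Total relation.** *T* = *X*(I − *X*)⁻¹ sums the geometric series
  *X* + *X*² + …: entry (i, j) accumulates the direct influence of i on j
  plus all influence transmitted through chains of intermediaries.
  Computed via a linear solve of (I − *X*)ᵀ*T*ᵀ = *X*ᵀ (LAPACK, through
  scipy) rather than an explicit inverse; the condition number of I − *X*
  is estimated first and values above 10¹² are rejected as
  non-convergent. Magnitudes below 10⁻¹⁵ are snapped to exact zero so
  that influence-free systems produce exact zeros.
- **Prominence/relation.** R = row sums of *T* (dispatched influence),
  C = column sums (received influence); prominence R + C, relation R − C.
  A factor is classified "Cause" iff its relation is strictly positive;
  an exact zero classifies as "Effect" with a logged warning, because the
  cause group is defined by strict positivity. No significance testing is
  attached to the sign: the method is structural, not inferential.
- **Threshold and network.** The network threshold θ is the mean over all
  n² entries of *T*, diagonal included (this convention reproduces the
  packaged study's published threshold). The causal digraph keeps every
  factor as a node — isolated nodes included — at cause–effect-diagram
  coordinates (prominence, relation), and draws edge i → j (i ≠ j)
  wherever t_ij > θ. Strict inequality is the default; an "inclusive"
  (≥) rule is available since published analyses rarely state the
  boundary convention. Self-loops are never drawn, even when t_ii > θ:
  the diagram depicts inter-factor influence, while diagonal entries
  still participate in the threshold mean. Graph layout is deliberately
  not computed; (prominence, relation) are the meaningful coordinates and
  anything else is a renderer's choice.

## Numerical conventions

- All comparisons and stored artifacts are full-precision floats;
  rounding is presentation-only. Display rounding is half away from zero
  (via `decimal`), not banker's rounding, so printed tables are
  platform-stable.
- Matrix CSV files written without a precision round-trip exactly
  (`repr` of the float).
- Tolerances used by the test suite: fixed-point identity
  ‖T − (X + XT)‖_max < 1e−9; conservation ΣR = ΣC = ΣT to 1e−9;
  agreement with the 200-term truncated influence series to 1e−8 on
  systems with spectral radius < 0.9 (the truncation error is ~ρ²⁰¹/(1−ρ),
  so the oracle is only meaningful away from ρ = 1).

## The packaged study matrix

The package ships the 15×15 direct-relation matrix of a published study
of motivators for integrated-care delivery by family-physician teams in
urban China (panel mean of 20 experts, printed at 2 decimals), plus its
factor catalog. Four factor labels were not transcribed in the available
source and carry explicit placeholder labels. Two consequences of the
2-decimal printing are worth knowing:

- Several entries (e.g. 2.26) are not multiples of 1/20, so the original
  per-cell denominators cannot be recovered; the matrix is used as given.
- Recomputing *T* from the rounded input reproduces the published
  total-relation matrix only to about ±0.01 per entry. One visible case:
  the recomputed entry at (F1, F5) is 0.5947, which prints as 0.59 where
  the published table shows 0.60. Profiles (R, C, R+C, R−C) reproduce to
  ±0.02 and all 15 cause/effect labels exactly; the threshold reproduces
  to three decimals (0.566).

## Synthetic expert panels

The generator emulates the elicitation that produced such a matrix: a
latent ground-truth influence matrix G (zero diagonal, entries in
[0, scale_max]), and m experts who each report
clamp(round(G_ij + ε), 0, scale_max) with ε ~ N(0, noise_sd) independent
across experts and cells, rounding half away from zero. A single seed
drives the whole panel through per-expert substreams
(`default_rng([seed, k])`), so enlarging a panel keeps its early experts
unchanged — useful for monotonicity-in-m experiments.

Ground truths with planted structure draw base influences
Uniform(0.8, 2.2) — mid-scale for a 0–3 rating axis and comparable in
magnitude to real panel means — and add a bonus δ to the rows of a chosen
"driver" subset on cells toward non-drivers, clamped to the scale. Drivers
dispatch more than they receive, so with δ large enough they must land in
the cause group; `recovery_experiment` measures how often they do across
seeded replicates, along with the Spearman correlation between true and
recovered prominence orderings. The default experiment scale used in the
tests (n = 8 factors, m = 20 experts, δ = 1.5, noise sd 0.5, 100
replicates) runs in a few seconds.

What the generator does *not* model: correlated experts, rater-specific
bias or leniency, ordinal response curves (an ordinal-logit noise model
would be the natural extension), or missing ratings. Passing recovery
tests therefore demonstrate correctness of the pipeline's mathematics and
its behavior under idealized independent rating noise — not robustness to
panel pathologies. Note also that round-and-clamp is a biased observation
channel for non-integer ground truths (e.g. a true 1.5 maps to 2 more
often than to 1), so aggregated panels converge to the clamp-round
distorted expectation of G, not to G itself, as m grows; with integer
ground truths and small noise the two coincide.

## Known limitations

- Crisp DEMATEL only: no fuzzy/grey variants, no ANP/ISM hybrids,
  no interval ratings.
- No consensus diagnostics (Kendall's W, Delphi loops) and no expert
  reliability weighting.
- The identification of "key" factors beyond the cause/effect split and
  the ranked prominence table is interpretive; the package reproduces the
  tables and groups from which such narratives are built, and stops there.
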