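# Methods

## Scope and coordinate conventions

`phoskit` has two halves: a sequence-only phosphosite classifier
(`io`, `features`, `predictor`, `evaluation`) and an ortholog
conservation analysis (`conservation`), joined by a synthetic-data
generator (`simulate`) and a CLI (`cli`). Site positions are 1-based on
the unaligned protein sequence throughout; `-` is both the window pad
and the alignment gap and is never counted as a residue; ambiguous
residues (B, Z, U, O, J) are mapped to X, which is never a candidate
center and contributes zero to every similarity.

## Feature construction

**Windows.** A candidate is an S/T or Y residue with h = 6 flanking
residues each side (13-mer), padded with `-` past the termini. Separate
models are kept for the S/T and Y classes.

**KNN scores.** Similarity between two equal-length windows is the sum
of BLOSUM62 entries over aligned positions; pad or X positions
contribute 0. For each neighborhood fraction f ∈ {0.0025, 0.005, 0.01,
0.02, 0.04} the feature is the fraction of phosphorylated peptides among
the k = max(1, ⌊f·N + 0.5⌋) most similar training windows. Choices made
where the procedure is conventionally under-specified:

* the score is positives/k rather than a positives/negatives ratio —
  the same information as a monotone transform, without division by
  zero when a neighborhood contains no negatives;
* k uses half-up rounding;
* similarity ties break by training-set input order (deterministic);
* during training-set featurization the query's own window (same
  protein id and position) is excluded from the neighbor pool
  (leave-one-out) to prevent label leakage; at predict time nothing is
  excluded.

**Disorder scores.** Features are the mean per-residue disorder over
centered windows of length 1, 5 and 13, clipped at the sequence bounds.
Per-residue scores come either from an imported TSV (the intended route
when an external disorder predictor is available) or from the built-in
stand-in: the TOP-IDP residue propensity scale, smoothed with a centered
21-residue moving average (truncated at termini) and min-max mapped to
[0, 1] over the scale's attainable range. The stand-in is deliberately
simple; it guarantees only the contract the features need — scores in
[0, 1], high for Ser/Pro/Glu-rich low-complexity stretches, low for
aromatic/hydrophobic ones.

**Amino-acid frequencies.** Counts of the 20 residues among real
(non-pad, non-X) window positions, normalized to sum to 1.

## Ensemble training and calibration

Each of B = 30 (configurable) base classifiers is a linear SVM (C = 1,
features standardized per bootstrap sample) trained on all positives
plus an equal-sized sample of negatives drawn without replacement, with
a fresh seeded draw per classifier (seeded from `(seed, b)`). B = 30 is
a compromise between aggregation stability and desk-scale runtime; a
linear kernel keeps training deterministic and fast, and the features
are already highly engineered, so little is expected from nonlinear
kernels. The aggregated score is the mean decision value.

Specificity calibration uses **out-of-bag** negative scores: each pool
negative is scored by the mean decision value of the classifiers whose
bootstrap sample excluded it (falling back to the full ensemble in the
rare case a negative is in every sample). The stringency-s threshold is
the order statistic at index ⌊s·n⌋ of the sorted calibration scores, so
with 100 stored scores the 0.95 threshold is the 96th smallest and
s → 0 approaches the minimum. Out-of-bag scoring avoids the optimistic
bias of scoring negatives with classifiers that trained on them; the
residual mismatch (calibration negatives are scored leave-one-out in
the KNN features, fresh sites are not) is small, and the realized
specificity on independent synthetic negatives stays within ±0.03 of
the request (tested at 0.90/0.95/0.99 with 5,000 negatives).

## Evaluation

Specificity = TN/(TN+FP) and sensitivity = TP/(TP+FN); both raise on an
empty denominator rather than returning 0. ROC curves sweep descending
unique scores with ties grouped; AUC is trapezoidal and equals the
Mann–Whitney pair statistic, which the tests verify by brute force and
against scikit-learn. Cross-organism evaluation applies one fitted
model to held-out records grouped by organism, never retrains, and
refuses any test window whose (protein, position) also appears among
the model's KNN training neighbors.

## Ortholog conservation statistics

Given aligned quartets and per-site phosphorylation calls, every
alignment column holding at least one S/T/Y is extracted; a column is
S/T-pure when all four residues are S or T, Y-pure when all four are Y,
and excluded otherwise. A gapped member is never phosphorylated at that
column. Quartets with ≥ 1 phosphorylated center are tallied by their
number of phosphorylated centers into n₁..n₄.

The ground probability, binomial-null expectations, χ² test (3 df) and
conditional transfer probabilities follow the formulas in the README.
Numerical choices:

* expected counts are used unrounded in the χ² statistic; rounding to
  integers is display-only;
* p₃ defaults to the "remaining-centers" formula
  (n₃ + 2n₄)/(2(n₂+n₃+n₄)); an alternative "upper" variant with
  denominator 2(n₃+n₄) is available behind `p3_method` because both
  conventions appear in practice — they answer slightly different
  conditional questions and can differ substantially;
* flanking similarity counts a member pair as matching only when the
  symbols are equal and neither is a gap (a gap is a mismatch); offsets
  outside the alignment count as all-mismatch;
* the position-frequency matrix excludes a quartet entirely if any
  member has a gap (or the window overruns the alignment) within the
  ±10 flank.

## Synthetic data

**Proteomes.** A latent disorder process (moving average of i.i.d.
uniform noise, window 15, min-max scaled per protein) drives both the
local residue composition (disorder-prone composition in high-disorder
stretches, order-prone elsewhere) and the phosphosite planting: each
S/T/Y candidate is phosphorylated with probability
σ(b₀ + β_d(d − 0.5) + β_m·motif), where motif indicates D/E at +1..+3
or P at +1, and b₀ is solved per residue type by bisection so the
marginal rate matches the configured fraction. Defaults: 120 proteins,
lengths ~N(300, 100²) clipped to [60, 700], fractions S/T/Y =
0.12/0.08/0.05, β_d = 10, β_m = 2.5. The coupling defaults make the
planted signal strong enough that the 28-feature model recovers
held-out AUC ≥ 0.85, consistent with the near-disjoint disorder
distributions reported for phosphorylated vs non-phosphorylated sites;
weaker couplings are available for null and ablation experiments
(coupling 0 with motif odds 1 gives a label-independent world). The
generator returns the true latent disorder as "imported" profiles, the
stand-in for an external disorder predictor.

What the generator does **not** emulate: kinase-family motif structure
beyond one acidic/proline-directed indicator, protein families and
homology within a proteome, position-dependent composition beyond the
disorder mixture, and any correlation between neighboring candidate
sites. A green predictor test therefore establishes that the pipeline
recovers planted disorder/composition signal — not that it matches any
particular organism's attainable accuracy.

**Ortholog quartets.** An ancestor (STY excluded outside the center, so
the center column's class is unambiguous) is mutated independently
along four branches at the configured per-position rate; substitutions
draw uniformly from the 17 non-STY letters, and an S/T center may
toggle S↔T at the same rate, preserving class purity. No indels are
generated by default, so the trivial alignment is exact; optional gap
injection exists solely to exercise gap handling. One reference center
is always phosphorylated; with probability c the whole quartet is
conserved (all centers phosphorylated), otherwise the other three
centers are i.i.d. Bernoulli(p) — marginal probability c + (1−c)p and
positive inter-center correlation for c > 0, with c = 0 the exact
binomial null.

**Null-uniformity check.** When the χ² machinery is validated against
simulated nulls, expected counts are computed from the generator's true
p, not the per-replicate estimate: estimating p from the same counts
consumes one degree of freedom, so the 3-df reference distribution is
correct only with the true p (with the estimate the p-values pile up
near 1). The ±0.02 recovery check, by contrast, targets the estimator
itself.

## Known limitations

* The built-in disorder stand-in is a smoothed propensity scale, not a
  trained disorder predictor; imported scores should be preferred when
  available.
* The redundancy filter is a deterministic greedy Needleman–Wunsch
  clustering stand-in (identity = exact-match columns / min length,
  match 1 / mismatch 0 / gap −1), quadratic in sequence count and
  intended for desk-scale datasets, not a CD-HIT replacement at
  proteome scale.
* Calibration assumes test-time negatives are drawn from a distribution
  resembling the training negatives; covariate shift between organisms
  degrades the specificity guarantee before it degrades ranking.
* Conditional probabilities treat quartets symmetrically and ignore
  phylogenetic branch structure.
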