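# Methods

## The analysis model

The pipeline treats observer ratings as a classical common-factor measurement
problem with an extra rater layer. Each subject has a latent profile **f**
(k correlated factors, corr(f) = Φ); an item's true value is λ′f plus a
unique part, on the correlation metric (communality h² + uniqueness u² = 1).
Each rater reports the true value plus a rater-specific bias (constant over
subjects) plus independent noise. Averaging raters and correlating items
recovers, up to attenuation, the structure Λ Φ Λ′ + diag(u²).

### Inter-rater reliability

Per item, the subjects × raters matrix is reduced to complete cases (raters
with no ratings dropped first, then subjects not covered by every remaining
rater) and decomposed by a two-way ANOVA without interaction. Consistency
ICCs treat raters as fixed, so constant rater offsets — the bias term above —
do not count against reliability:

- ICC(3,1) = (MS_B − MS_E) / (MS_B + (k−1) MS_E), one rater's reliability;
- ICC(3,k) = (MS_B − MS_E) / MS_B, the k-rater mean's reliability.

The screen retains items with ICC(3,k) strictly above the threshold
(default 0.40; 0.10 and 0.00 are supported for sensitivity sweeps). A
constant item matrix is degenerate and excluded. Under independent ratings
ICC(3,1) is centred at zero but ICC(3,k) is not (it is a monotone transform
with a heavy lower tail), which the tests assert in that form.

### Factor extraction and rotation

Minres/ULS: given uniquenesses ψ, loadings are the scaled top-k eigenvectors
of R − diag(ψ); ψ is optimized by L-BFGS-B (bounds [0.001, 1]) on the sum of
squared **off-diagonal** residuals of R − ΛΛ′. Uniquenesses at the lower
bound are clamped there and flagged (Heywood). Starting values are 1 − SMC.
Rotation is quartimin by oblique gradient projection from the identity; the
line search halves the step up to 60 times and treats step-size exhaustion
as convergence (the criterion is then flat to machine precision). Factors
are ordered by explained variance (sums of squares of Λ·chol(Φ) columns,
descending) and signed so each column sums non-negative. Comparisons
downstream are sign- and permutation-aware, so these conventions are
cosmetic.

### Factor-count vote

- **Parallel analysis**: eigenvalues of R with SMC on the diagonal versus
  eigenvalues of 20 standard-normal datasets of the same shape processed
  identically, compared position-wise from the top. The reference is the
  95th percentile of the simulated eigenvalues (configurable to the mean);
  the percentile reference keeps the false-positive rate on pure-noise data
  near nominal, which a mean reference cannot (the observed top eigenvalue
  exceeds the simulated mean about half the time by construction).
- **Empirical BIC**: eBIC_k = n·Σ_{i<j} r̃²_ij − df_k·ln n with
  df_k = p(p−1)/2 − pk + k(k−1)/2, minimized over k with df_k > 0.
- **Very simple structure (complexity 1)**: the rotated pattern is simplified
  to its largest-|loading| entry per item and scored
  1 − Σ resid² / Σ off-diagonal r²; ties resolve to the smaller k (with
  noise-free data every k ≥ k₀ fits perfectly and parsimony should win).

The chosen k is the median of the three. By default the vote is repeated
after item exclusions; `freeze_k` pins it.

### Item-exclusion loop

Each pass: drop items with MSA < 0.50 → vote k → fit minres + quartimin →
drop items with h² ≤ 0.4 or h² ≥ 0.99 → repeat until a fixed point (cap 10
passes). The final model's per-item MSA ≥ 0.50 and √(Σ r̃²) < 0.10 checks are
assertions that warn rather than fail, since they are confirmations, not
decision rules. Fit statistics: RMSR (mean-square form) and a df-corrected
variant √(Σ r̃²/df); Cronbach's alpha from the correlation matrix; total
omega 1 − Σu²/ΣR.

### Structural comparison

Pairs of loading matrices are restricted to shared items and the source is
orthogonally Procrustes-rotated toward the target (T = UV′ from the SVD of
Λ_s′Λ_t). When factor counts differ, the narrower matrix is padded with zero
columns before rotation and **all** rotated columns are reported — the extra
column is a genuine mixture of the source factors, and empirically carries
reported coefficients. Because rotation puts columns in target order, each
rotated column is relabelled with its most congruent original source factor
(one-to-one optimal assignment); leftover columns are labelled
`unassigned-n`. Congruence magnitudes are binned good ≥ 0.95 /
fair ≥ 0.85 / above-cutoff ≥ 0.80 / poor ≥ 0.70 / incongruent, as labels
only.

### Fuzzy sets and the permutation null

A set mapping assigns, per group, at most one factor (optionally
reverse-scored) to each named construct. An item's intersection value is the
signed minimum absolute loading over the groups whose final model retained
the item ("known information" for partially present items). Ties in
|loading| resolve to the first group in mapping order; sign conflicts after
alignment are flagged and keep the minimum group's sign. The salience null
draws one factor per group per iteration, pools the per-item minima over
1000 iterations (item universe: present in ≥ 1 final model of the family),
and takes the 95th percentile of absolute values — per family and aggregated
across families. Salience itself uses the fixed inclusive |0.40| rule.

### ten Berge scores

With standardized data Z, A = ΛΦ^{1/2}, C = R^{−1/2}A(A′R^{−1}A)^{−1/2},
W = R^{−1/2}CΦ^{1/2}, scores = ZW. Matrix square roots use symmetric
eigendecompositions with a 1e−10 eigenvalue floor; a near-singular R is
flagged. Subjects with any missing item are dropped and listed. The defining
property — corr(scores) = Φ — is asserted in tests at 1e−6 on every fit.
Cross-situation score tables report Pearson r with uncorrected two-sided p
values starred at 0.05/0.01/0.001.

## The synthetic generator

`GeneratorConfig` defaults emulate the motivating study design: three groups
of 150/101/77 subjects with 5/4/5 raters, the 51-item general catalog, five
oblique factors (Φ off-diagonals 0.2), 10% skipped (rater, subject) pairs,
1–7 discretized scores, per-rater mean-centering, and a paired second
situation with latent cross-correlation 0.7 (both factor scores and item
uniques correlate at ρ, so an item's true cross-situation correlation is
exactly ρ). Rater noise sd defaults to 1.4, chosen so the closed-form
single-rater reliability 1/(1 + σ²) ≈ 0.34 matches the reported mean
ICC(3,1), which puts ICC(3,k) near 0.70 at five raters. Loading magnitudes
default to 0.8/0.85/0.9 so that observed (attenuated) communalities land in
the 0.5–0.7 range reported for the real models; weaker loadings would sit on
the 0.4 communality exclusion bound and make recovery tests measure the
screen rather than the estimator. These two targets (printed ICC level,
printed communality level) cannot be hit simultaneously under independent
rater noise — shared rater perspectives in real data inflate apparent
communalities — and the defaults favour the reliability anchor.

The truth record stores generating loadings, Φ, uniquenesses, all latent
scores, the closed-form expected ICC(3,1), and an attenuation factor for the
expected item-level cross-situation correlation (closed form
1/(1 + σ²/k_eff) on the continuous scale; Monte-Carlo under 1–7
discretization, with a fixed internal seed independent of the data seeds).
`expected_score_validity` derives, from the generating parameters alone, the
population correlation between ten Berge scores and the true latents, used
as the analytic band for cross-situation recovery tests.

What the generator does **not** emulate: correlated rater errors (observers
talking to each other), item-specific noise levels, ordinal response styles,
or group-specific loading structure. Passing recovery tests therefore show
the estimator chain is correct under the stated measurement model, not that
real ratings satisfy that model.

## Published-table fixtures

The final rotated pattern matrices for three species in two situations are
packaged as CSVs at the printed two-decimal precision, along with the
item-exclusion annotations ("Low ICC" / "Low MSA" / "Low Communality") and
the cross-species set mappings. Reproduction checks from these fixtures
inherit 2-dp rounding: congruence coefficients are compared at ±0.02,
permutation thresholds at ±0.03, and four intersection cells where two
species tie in |loading| with opposite signs are compared on magnitude only.
Values computing to exactly the 0.40 salience boundary from rounded inputs
are treated as boundary-ambiguous.

## Problem sizes in the test suite

Recovery-style tests use the design scale of the study where it matters
(e.g. 50 seeds of a 150-subject, 45-item, 5-factor pipeline for end-to-end
recovery; 80-subject groups for reliability screening, within the study's
77–150 range) and smaller 12–20-item instances for estimator-level oracle
comparisons, where the statistical question does not depend on p.

## Known limitations

- Orthogonal (not oblique) Procrustes; the published unequal-k comparisons
  are reproduced numerically, but the naming of padded rotated columns in
  those tables was a manual judgment that an assignment algorithm cannot
  fully replicate.
- No confidence intervals on ICCs or loadings; no CFA, ML or WLS extraction;
  no multiple-comparison correction on score correlation tables (reported
  p values are deliberately uncorrected).
- Pairwise-complete correlations carry the minimum pairwise n as the working
  sample size, a conservative simplification that only matters with
  substantial missingness.
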