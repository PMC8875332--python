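# Methods

## Scope and data model

The package analyses semi-quantitative shotgun lipidomics measurements:
counts per second per MRM transition, one value per (cell line,
treatment, biological replicate, technical replicate, lipid species),
plus one row per class internal standard in every injection. Species
are identified by sum-composition shorthand (`PC aa C36:4`,
`SM C34:1`, `TAG C52:3`), except ceramides, which the panel dialect
resolves into sphingoid base and N-acyl chain (`Cer d18:1/16:0`).
Absolute quantification is out of scope; all downstream quantities are
ratios (to the class standard, to the class sum, or to the control
group).

## Structural categories

* **Saturation**: 0 double bonds → SFA, 1 → MUFA, ≥2 → PUFA. For
  base/acyl ceramides the N-acyl double-bond count is used; the
  sphingoid base is analysed separately by the sn1 partition, keeping
  the two views orthogonal.
* **Chain length** (class-specific, on total carbons; N-acyl carbons
  for base/acyl ceramides): PC aa and PC ae short < C32, medium
  C32–C36, long > C36; Lyso-PC and Cer short < C16, medium C16–C20,
  long > C20; SM short < C32, medium C32–C38, long > C38. The
  conventional SM boundaries (< C32 / C34–C38 / > C40) leave C32 and
  C40 unassigned; the default `gap-closed` scheme extends the medium bin so
  the three bins partition every carbon count (which also makes the
  reported SM triple 0.5 + 68.8 + 30.7 close to 100). The `literal`
  scheme keeps the printed boundaries and raises a partition-gap error
  for the orphaned carbons. TAG has no established boundary
  convention; the package splits the C44–C56 range at C48 and C52.
* **Double-bond and carbon bins**: `X:n` and `Cn:X` labels; for
  base/acyl ceramides both refer to the N-acyl chain, which is what
  places `C18:X` ceramides inside the medium C16–C20 bin.
* **sn1 base partition**: ceramides grouped by base label (`C18:1`,
  `C18:2`); requires the base/acyl dialect.

Cholesterol is a single-species class: it is carried through
normalization, totals and fold change but excluded from mol% and
category partitions (a singleton composition is identically 100).

## Quantification

Per injection, each species' counts are divided by the counts of its
class internal standard; the technical-replicate mean is then taken on
that ratio (normalize first, then average). Missing technical
replicates are averaged over whatever is available, with a warning.
Mol% is computed per sample and class as 100·ratio/Σratio. Fold
change of any per-sample parameter (species ratio, class total,
partition bin, ratio index) is 100·value/mean(control group), per
cell line; the control group's own mean is exactly 100 %.

Group-level mol% values are means over biological replicates of
per-sample mol% (not mol% of group means): inference operates on
per-replicate values, so per-sample aggregates must exist first; the
two definitions differ only at second order.

## Ratio indices

`PCae_over_PCaa`, `LysoPC_over_PCaa`, `SM_over_PCaa` and `Cer_over_SM`
are computed per sample as ratios of class sums, optionally restricted
to a saturation stratum applied to numerator and denominator alike.
Ratios are formed per sample first and then related to the control
mean — not as ratios of group means — because each index is itself a
tested parameter. The telescoping identity
(Cer/SM)·(SM/PCaa) = Cer/PCaa holds per sample to machine precision
and is exercised in the tests.

## Dunnett inference

Each parameter family compares the k treatment groups against the
shared solvent control using the pooled within-group variance across
all k+1 groups (df = Σ(n_j − 1)). The statistics are jointly
multivariate-t with the general product correlation
r_ij = b_i b_j, b_i = √(n_i/(n_i + n_0)) — no equicorrelation
shortcut, so unbalanced groups are handled exactly. The two-sided
adjusted p for contrast i is 1 − P(max_j |T_j| ≤ |t_i|), evaluated by
conditioning on the shared control variate (80-node Gauss–Hermite) and
the pooled-SD chi variable (96-node Gauss–Legendre on the probability
scale), which factorises the joint probability into univariate normal
interval probabilities. Agreement with a 10^6-draw Monte-Carlo
evaluation of the same integral is a few 10^-4. For k = 1 the integral
reduces analytically to the classical pooled two-sample t-test, which
is returned exactly.

Dunnett runs on per-replicate fold-change values (not log-transformed),
matching how effects are reported; since fold change is an affine
rescaling of the underlying parameter within a family, the p-values are
identical to those on raw normalized values. Stars follow
p ≤ 0.05/0.01/0.001. Volcano categorisation combines effect direction
(sign of effect − 100), magnitude (|effect − 100| vs an SD threshold)
and significance (adjusted p ≤ 0.05) into eight cells, with a
`no_change` sentinel for an effect of exactly 100 % rather than an
arbitrary direction. The default SD threshold is data-driven: the
standard deviation of all species-level effects in the family (cell
line × treatment × class); a fixed percentage can be configured
(`sd_mode="fixed:<pct>"`). Comparison families never pool cell lines.

## Synthetic-data generator

The generator emulates the study conditions: cell lines SH-SY5Y and
N2a; treatments control, C, TP, P, TB, PPF; 5 biological replicates;
technical triplicates; 188 species over seven classes with one
internal standard per class. Per species and biological sample the
value is `exp(μ_s) · m(treatment, s) · exp(σ_b Z)` with
σ_b = √ln(1 + cv_b²), cv_b = 0.20 by default; per technical replicate
the value is multiplied by (1 + cv_t Z′), cv_t = 0.04 (consistent with
an intra-day variance near 4 %), and by a per-injection matrix factor
(1 ± m) with m drawn uniformly so that the maximum magnitude is 1.12 %
and the mean magnitude 1.05 %. Standards carry technical noise only.
Species-level variances are not knowable a priori for a panel like
this, so the noise defaults are the package's choice and are
config-exposed.
Baseline log-means fan out linearly (range ≈ e³) around per-class
levels so compositions are uneven. Effect multipliers target a
species, a class, or a category selector (e.g. all PUFA plasmalogens)
resolved through the nomenclature module.

What the generator does *not* emulate: per-sample correlated biology
(species draws are independent within a sample apart from the shared
matrix factor), missing values, isobaric interference, detector
saturation and response-factor differences. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated
stochastic model, not robustness to those real-data artefacts.

Counts are floored at 1e-9 to keep the positivity invariant; with
cv_t = 0.04 a negative draw is a ~25σ event, so the floor is
effectively never active.

## Validation experiments and problem sizes

* **Null calibration**: 2000 generated datasets with unit multipliers;
  each runs the real generator + normalization + class-total Dunnett
  family (five treatments, one cell line, the 16-species lyso-PC
  sub-panel) and records whether any treatment is rejected at
  α = 0.05. Classes are generated independently, so the single-class
  sub-panel leaves the tested family's distribution unchanged while
  keeping thousands of replicates cheap. Observed rates sit within
  binomial noise of 0.05.
* **Recovery**: a 0.721 multiplier on all diacyl-PC species under one
  treatment, 200 seeds; the mean estimated class-total effect is
  within a few tenths of 72.1 % at n = 5 and tighter at n = 50.
* **Oracle equivalence**: integrator vs million-draw Monte-Carlo for
  k ∈ {1,3,5}, n ∈ {3,5}, and vs the exact t-test at k = 1.
* **Closure reconstructions**: reported mol% bins rebuilt from their
  printed complements through the real partition code under the
  100-sum invariant (e.g. lyso-PC SFA 30.0 + MUFA 63.9 → PUFA 6.1).

## Known limitations

* Sum-composition shorthand cannot resolve sn-position or individual
  fatty acids; only ceramides get a base/acyl split.
* The volcano SD threshold in its data-driven default depends on the
  family's species set; with very few species per class it becomes
  noisy — the fixed mode is preferable there.
* Dunnett assumes normal within-group errors with common variance;
  fold changes of lognormal data are mildly skewed, which the null
  calibration shows is negligible at the default noise levels but is
  untested for much larger biological CVs (a log-scale option can be
  applied upstream by transforming parameter values).
* The quadrature is accurate to ~1e-6 for moderate k and df; extreme
  tail p-values (< 1e-10) are reported but dominated by quadrature
  error.
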