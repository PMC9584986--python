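# Methods

## Scope and data flow

`bbbrank` implements the dry-lab half of a compound-prioritization study:
descriptor computation → logBB prediction and classification; plate
signals → E/E₀ normalization and group statistics; halo micrographs →
damage ratios; endpoint ratios → weighted-sum ranking. Wet-lab raw data
are replaced by the synthetic generators, which encode the study design
(group structure, effect directions, replication counts) without modelling
any cell biology.

## Descriptors

**McGowan characteristic volume V.** Computed from the standard atomic
increment table (C 16.35, H 8.71, N 14.39, O 12.43, F 10.48, S 22.91,
Cl 20.95, Br 26.21, I 34.53, P 24.87, all cm³/mol) minus 6.56 cm³/mol per
bond, divided by 100 to the Abraham scale. Bonds are counted over the σ
framework — one deduction per connection regardless of bond order — and
hydrogens are made explicit before summing. V is therefore additive over
disconnected components, and each CH₂ unit contributes exactly 0.1409.

**Topological PSA.** The published N/O fragment-contribution sum, via
RDKit's implementation; S/P fragment contributions are off by default
(the common descriptor-software default) and available behind a flag.

**Supplied descriptors.** E, S, A, B, logP and G_solv cannot be recomputed
reproducibly here: they come from trained fragment schemes (different
programs give different values) or DFT solvation calculations. The
pipeline accepts them as a CSV table and records per-field provenance
(`computed` vs `supplied`); a supplied value overrides a computed one so a
user can pin V or PSA to an external source when comparing methods. No
internal logP estimator is provided on purpose — a divergent estimate
would silently change every model-1 prediction.

## logBB models

All four models are affine in their inputs; coefficients are carried to
full precision and rounded only in the output table (two decimals, the
conventional print precision). Classification uses strict inequalities
(readily iff logBB > 0.3, poor iff logBB < −1); boundary values are
intermediate. Missing descriptors degrade per-model — the compound row
reports which models were evaluable and why others were not — rather than
failing the compound.

**The model-4 constant.** The published form of model 4 contains a
−0.605 term with no variable attached, while every other LFER term
carries one of the five descriptors and model 3 has an S term in exactly
that position. The default interpretation takes −0.605 as the S
coefficient; `literal_constant` folds it into the intercept (giving
0.934 − 0.605 = 0.329 at zero input). Both are first-class, and every
result row echoes the interpretation used, so the ambiguity can never be
silent.

**G_solv units.** The solvation model's input is taken in kcal/mol: with
the 0.054 slope, typical drug-like solvation energies (−10…−15 kcal/mol)
land logBB in the −0.1…−0.4 band where such compounds are in fact
reported, which a kJ/mol reading would not.

**Reference fixture.** `data/reference_logbb.csv` holds the published
per-compound logBB values for the TP series under all four models. They
are used solely as classifier inputs in consistency tests (all model-1/2
values intermediate; nothing readily; only TP1 under model 3 poor).
Regenerating the numbers themselves is explicitly out of scope: they
depend on one specific external descriptor program, one logP program and
DFT solvation energies, none of which this package reimplements. For the
same reason the published MCDA percentages and ANOVA F statistics are not
numeric targets — the underlying raw data are not public — and the test
suite instead verifies the machinery on synthetic ground truth.

## Plate-assay statistics

Normalization is per independent experiment: within each experiment every
group mean is divided by that experiment's reference-control mean, and the
resulting ratios are averaged across experiments (the experiment, not the
well, is the replication unit in the figure legends this mirrors). Pooling
all wells first is available behind a flag. The reference defaults to the
negative (insulted) control whenever both controls are present. The
reference group's ratio is exactly 1 by construction.

The statistics contract is deliberately plain: one-way ANOVA with
Shapiro–Wilk (on pooled residuals) and Levene checks, then Tukey HSD
(scipy's studentized-range implementation, which handles unequal n by the
Tukey–Kramer form). Failed assumption checks annotate the report with
warnings but never switch the test family — the report is a contract, not
an expert system. Zero within-group variance with distinct means is
reported as a flagged infinite F rather than an exception, so degenerate
noise-free simulations remain analyzable.

## Halo quantification

The published assay uses operator-assisted measurement; this module is
fully automatic so results are reproducible. Per image:

1. Background mean and SD come from the border frame (outer 5% of each
   dimension).
2. The nucleus is located as the intensity centroid above a global Otsu
   threshold; no pixels above threshold raises "no nucleus detected".
3. The radial profile is the mean intensity in 1-px annuli centered on
   integer radii. Centering annuli (rather than binning `[i, i+1)`)
   roughly halves the systematic edge bias from annuli that straddle the
   core boundary.
4. Core radius: largest radius where the background-subtracted profile is
   ≥ `f_core` (default 0.5) of its peak. Halo radius: largest radius where
   it is ≥ `f_halo` (default 0.05) of peak, or ≥ `k` (default 3) times the
   annulus mean's sampling error, whichever threshold is higher. The noise
   floor is expressed per annulus — border per-pixel SD divided by √(pixels
   in the annulus) — because the quantity being thresholded is an annulus
   mean, not a raw pixel; a per-pixel floor would truncate every halo read
   at realistic noise levels.
5. Threshold crossings are read with sub-pixel linear interpolation
   between annulus centers, capped at the qualifying annulus's outer
   edge: interpolation is unbiased on a gradual falloff, but at a
   step-like edge the next annulus sits just below threshold and an
   uncapped estimate drifts almost a full pixel outward.

Diameters are twice these radii — equivalent-circle diameters, which
coincide with caliper diameters for the circular nuclei the assay
produces. The damage ratio is nucleus/halo ∈ (0, 1] and the halo radius
is clamped to be at least the core radius. QC flags (`touching_border`,
`low_contrast`) exclude a nucleus from slide summaries without discarding
its measurement. Multi-nucleus frames are split by connected-component
labelling with a minimum area (default 100 px) to drop debris; frames
with a single detected nucleus are measured uncropped.

How the per-nucleus ratio becomes a "DNA damage" level in E/E₀ figure
units is not defined by the assay itself, so the slide summary exposes the
mapping explicitly: `ratio` (the assay's own statistic, lower = more
damage) or `inverse_ratio` (halo/nucleus, higher = more damage). Nothing
downstream assumes one of them.

## MCDA

Benefits, weights and scores are as in the README. The percent
normalization (w = base/max|d|, score = 100·Σw·d/Σbase) is the minimal
formula consistent with "standardize significance by the maximum observed
differences": it makes every endpoint's best-observed deviation worth the
same score mass, yields 100 for a compound that attains the columnwise
maximum everywhere and 0 for control-equivalence. A per-endpoint min–max
alternative (`normalization='minmax'`) rescales each benefit column to
[0, 1] instead; it differs in anchoring the worst compound at 0 rather
than the control. Neither variant is validated against published
percentages (inputs only shown graphically); published values are used
solely as a plausibility band in qualitative checks. Ties share the best
(minimum) rank. Scores are scale-invariant per endpoint: multiplying one
endpoint's deviations by any positive constant renormalizes its weight
and leaves every score unchanged.

COX endpoints are routinely assayed only at the top concentration while
the analysis concentration for other endpoints is the lowest dose; the
endpoint matrix carries a per-endpoint concentration annotation and the
assembler reads COX columns at 100 µM and the rest at 10 µM by default.

## Synthetic generators

**Plates.** Positive-control mean fixed at 1 AU. The insult multiplies
each assay's mean by a per-assay factor (defaults: MTT 0.6, DCF-DA 1.8,
Griess 1.7, FHA 1.5, COX_total 1.5, COX1 1.15, COX2 1.7 — a viability
drop and stress/damage/COX elevations of the size such screens report).
A compound's effect is a recovery fraction r ∈ [0, 1] toward the
no-insult control: group mean = m + r·(1 − m), which handles suppressed
and elevated endpoints with one parameter. Default potencies (TP4 0.90,
TP8 0.88, TP9 0.82, TP10 0.76, TP5 0.75, TP1 0.72, TP6 0.55, TP7 0.48)
echo the qualitative ordering reported for this series; the
concentration–response scaling is flat by default because the generator
is phenomenological, not a dose–response model. Well noise is
multiplicative Gaussian (CV, default 0.1) — appropriate for strictly
positive assay signals. Design defaults: 5 experiments × 5 wells per
group, 8 compounds × {10, 50, 100} µM, COX assays at 100 µM only.
`planted_potencies` builds a variant with one clearly dominant compound
(0.9 vs 0.6) for recovery tests.

**Endpoint matrices.** Every endpoint's benefit column is proportional to
the planted per-compound score, so the noise-free weighted-sum ranking
equals the planted order exactly (including ties) by construction; cell
noise is additive Gaussian on the ratio.

**Halo images.** Background + peak inside the core; in the halo the
above-background signal decays linearly from `f_core`·peak at the core
edge to zero at the halo edge; additive Gaussian noise clipped at 0. The
linear falloff is chosen for analytic ground truth — the measurer only
assumes a monotone decay. Image size defaults to 1.3× the halo diameter
(minimum 64 px).

All generators draw from one `numpy` Generator seeded per call;
fixed seed ⇒ byte-identical outputs, and CSV outputs carry the seed in a
header comment.

## What the tests do and do not show

The stochastic suites run at the design's own scale: 100 seeded
full-chain screens for ranking recovery, 500 two-group simulations at
Cohen's d = 2 and n = 25 for the control-contrast power property, and a
400-image halo sweep (nucleus 20–60 px, halo/nucleus 1–3, noise 0–10% of
peak, 20 seeds per cell). Passing them shows the machinery — not the
biology: the generators share the pipeline's structural assumptions
(Gaussian noise, exact group structure, circular nuclei, no illumination
gradients, no dose–response nonlinearity, no correlated endpoint noise),
so real-data performance depends on how well those assumptions hold.

## Known limitations

- logBB models are global linear QSARs with no applicability-domain
  check; extrapolation outside drug-like descriptor space is silent.
- The halo measurer assumes one roughly circular nucleus per (split)
  frame and a monotone radial falloff; overlapping nuclei or strongly
  textured chromatin will bias diameters. With the generator's knife-edge
  case — halo shoulder exactly at `f_core`·peak — the core diameter reads
  ~2–3% high; this is within every stated tolerance but visible in
  noise-free examples (ratio 0.547 for a true 0.50).
- Tukey p-values for the degenerate zero-variance case are reported as
  0/1 indicators, not studentized-range values.
- The MCDA propagates no uncertainty from assay SDs into scores; ranks
  carry no confidence statement.
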