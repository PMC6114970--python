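# Methods

## Panel data model

The core schema lists 186 analytes in fixed order: 40 acylcarnitines,
21 amino acids, 19 biogenic amines, the combined hexoses channel, 38
diacyl + 38 acyl-alkyl phosphatidylcholines, 14
lyso-phosphatidylcholines and 15 sphingomyelins. The exact roster was
reconstructed from the public analyte list of the commercial p180-class
kit this panel follows; the class counts are the binding constraint,
and the roster is exported (with parse fields) by
`PanelSchema.to_json()` so it is fully auditable. Two biogenic amines
of the 21-amine kit version (DOPA, dopamine — the two most frequently
below detection in plasma) are omitted to match the 19-amine panel
composition. The acyl-alkyl PC roster includes PC ae C32:3, a required
leaf of the GCKR ratio.

Five energy metabolites (lactate, the combined pyruvate/oxaloacetate
channel named `Pyr`, alpha-ketoglutarate, fumarate, succinate) form an
optional extension: they were measured in only part of the study
population, so catalog entries that need them simply evaluate to
missing when the extension is absent.

Concentrations are μmol/L throughout; there is no unit-conversion
layer. Missing values are NaN, never zero. Input zeros are treated as
below-LOD and, under the default `half_min` policy, replaced by half
the per-analyte minimum positive value — the common convention in
targeted metabolomics, chosen here because it keeps downstream ratios
finite; `missing` and `keep` policies are available. Column-name
dialects (dotted `PC.aa.C36.6`, underscored `PC_aa_C36_6`, as produced
by vendor exports and R) are normalized to canonical names on load via
a mechanically generated key map.

Reference flagging uses printed clinical anchors: Lac/Pyr > 25.8
(oxidative-phosphorylation deficiency), Phe > 74 μmol/L, and
package-defined policies where only a central value is known:
hypoglutaminemia below half the 800 μmol/L control mean,
hyperglutamatemia above twice the 40 μmol/L normal level,
hyperaspartatemia above the 5 μmol/L upper normal. Pyr = 0 yields an
`indeterminate_lac_pyr` flag rather than a division error.

## Ratio catalog

Ratios are expression trees over analyte symbols with two operators
(sum, divide), so every definition is serializable, auditable and
analyzable. `concentration_degree` computes the net power of
concentration (leaf = 1, sum preserves, divide subtracts): pure ratios
(degree 0, e.g. Gln/Glu, Fischer, Lac/Pyr) are invariant to global
rescaling of all concentrations, while degree-1 features such as the
breast-cancer signature scale linearly — both properties are enforced
by randomized tests.

Evaluation semantics: a missing leaf or a zero denominator produces a
missing value with a recorded reason; no feature is ever ±infinity.

Interpretation choices embedded in the catalog:

- The signature equation's amino-acid term defaults to Val/Phe, with
  an Xle/Phe variant computed from the combined Leu+Ile signal
  (leucine and isoleucine are isobaric in this assay class).
- `C10:2` (decenoylcarnitine) is the signature's denominator carnitine.
- `Phe/[(Gln/Glu)/Asp]` is parsed with the bracketed glutaminolysis
  unit `[(Gln/Glu)/Asp]` as the denominator.
- SFA/MUFA membership is derived mechanically from the name parser:
  acyl-alkyl PCs with more than 36 carbons and 0 (SFA) or 1 (MUFA)
  double bonds. With aspartate up ~10-fold and glutamine down to 1/8,
  the Asp/Gln denominator rises sharply, so `(SFA/MUFA)/(Asp/Gln)`
  falls in cases.
- `AcylC-DC` is the sum of acylcarnitines carrying the dicarboxyl
  (`-DC`) suffix — an interpretation, flagged as such.
- `Hexoses/PHGDH` uses Ser/C2, the first-listed PHGDH proxy;
  murine glucose ratios map onto the hexoses channel (the panel
  quantifies summed hexoses, not glucose specifically).
- Essential/non-essential amino-acid sums follow the standard
  nine-essential convention, with citrulline and ornithine counted in
  the non-essential pool; the membership is recorded in the schema
  JSON.

## Evaluation machinery

- **Log transform**: natural log on all features; nonpositive finite
  values are rejected with a pointer to the LOD policy.
- **Univariate screening**: Welch's t-test for two groups, one-way
  ANOVA for more; Benjamini–Hochberg FDR across tested features (the
  field-default FDR procedure); features with >50% missingness are
  skipped with a note, zero-variance features report p = 1.
- **ROC/AUC**: AUC is the midrank Mann–Whitney statistic (ties count
  half), cross-checked in tests against exhaustive pairwise
  enumeration and against the trapezoidal area of the threshold-sweep
  curve. The operating point maximizes Youden's J, with ties broken
  toward higher specificity; sensitivity, specificity, PPV and NPV
  come from the confusion table at that threshold.
- **MCCV**: each iteration draws, class-stratified and without
  replacement, 2/3 of each class for training; per-feature
  standardization and the classifier (L2-regularized logistic
  regression by default) are fit on the training fold only and scored
  on the held-out third. The linear default preserves the
  interpretability of the two-feature discriminant and is fully
  reproducible; a 2-component PLS-DA option is provided. Per-iteration
  AUC/accuracy and pooled held-out predictions are returned.
- **Permutation test**: the statistic is the mean MCCV accuracy; the
  null re-runs MCCV under label permutations, and
  p = (b+1)/(N+1). With N = 1000 permutations the smallest reachable
  p is 1/1001 ≈ 1e-3; empirical p-values finer than that (as web
  services sometimes report via parametric tail approximations) are
  not produced by this convention.
- **Bootstrap CI**: percentile interval over class-stratified
  resampling with replacement, so no resample is ever one-class.
- **Univariate logistic model**: maximum likelihood via statsmodels;
  under perfect separation a warning is issued and a ridge-penalized
  estimate returned. The packaged reference model is
  logit(P) = −12.24 + 1.80·(Lac/Pyr); its predicted probability is
  0.5 at Lac/Pyr = 12.24/1.80 = 6.8, and odds_ratio = exp(1.80) =
  6.05 (a printed odds of 6.08 would correspond to an unrounded slope
  of ≈1.805).
- **Clustering**: Ward linkage on Euclidean distances of autoscaled
  features (the conventional default where the original distance/
  linkage choice is unspecified); deterministic leaf order.

All stochastic operations take explicit seeds; no global RNG state is
used anywhere.

## Synthetic cohort generator

Marginals are lognormal — concentrations are strictly positive and
right-skewed — parameterized by mean and coefficient of variation
(default CV 0.25, a typical between-subject spread for plasma
metabolites), drawn independently across analytes. Case cohorts
multiply control means by per-analyte fold-changes; continuum grades
interpolate geometrically, mean_g = control_mean · multiplier^λ with
λ ∈ [0, 1] monotone along the grade order (metabolic-syndrome grades
0–5, relative-risk 1.4/1.6/1.8, in situ, invasive), so λ = 0
reproduces controls exactly and λ = 1 cases, and monotone ratios such
as Gln/Glu vary monotonically along the continuum.

Anchored defaults: control Gln 800 μmol/L (case ×1/8), Glu 40 (×10),
Asp 2.5 — the midpoint of the 0–5 reference range — (×10), Phe 57 —
the midpoint of 40–74 — (×89.3/57 so the case mean is 89.3 μmol/L).
Direction-only effects (taurine, Met-SO, SM C18:0, PC ae C38:3,
lysoPC a C26:1, C14:1-OH, PC aa C36:6 up; C10:2 down; PC aa C28:1 and
very-long-chain species up) default to ×2 or ×0.5 and are marked
`invented` in the config's provenance map, as are the ~170 control
means without printed values (set to physiological plasma levels or
class-level defaults). Below-LOD injections appear as zeros at a 1%
rate.

The case lactate fold-change is calibrated in closed form rather than
searched: with independent lognormal Lac and Pyr at equal CV,
log(Lac/Pyr) is normal with sd s = sqrt(2·ln(1+CV²)), so the
multiplier that makes P(Lac/Pyr > 25.8) = 0.76 given control means
Lac = 1100, Pyr = 85 μmol/L is 25.8·exp(Φ⁻¹(0.76)·s)/(1100/85) ≈
2.55; control exceedance stays near 2%. The 1% LOD injections shave
the realized case exceedance to ≈74%.

What the generator does **not** emulate: between-analyte correlation
(lipid-class blocks can be switched on via the config but default to
independence, since only group means and fold-changes are specified),
batch effects, age/BMI covariates, or measurement error distinct from
biological variation. Consequently the synthetic discriminant
performance (AUC ≈ 1.0 at the configured effect sizes) shows that the
pipeline is correct and that the printed effect sizes imply strong
separability under independent lognormal noise — not that real
cohorts, with correlated analytes and weaker marginal effects, would
be classified this well.

## Problem sizes and numerical choices

The test suite and the acceptance script run synthetic cohorts at the
study's printed sizes (31/59 exploratory, 169/154 validation-scale)
with 100 MCCV iterations, averaged over ten seeds in the acceptance
script and three in the test suite; permutation tests in tests use
small N (9–19) since only the counting convention and null behavior
are asserted there. Ties in ranking are handled by midranks; Youden
ties break toward specificity; standardization uses population (ddof
0) standard deviations with zero-variance guards.

## Known limitations

- The exact kit roster beyond the class counts is a reconstruction;
  users with a different export can still load their tables since
  unknown columns are warnings, not errors.
- Independence across analytes makes synthetic multivariate
  performance optimistic (see above).
- The pipeline starts from quantified concentrations; raw spectra
  processing is out of scope.
- SVM and random-forest classifier variants are not implemented; the
  L2-logistic and PLS-DA options cover the linear discriminants the
  feature set was designed around.
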