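# fearsig

**Distributed multivariate brain signatures of subjective fear — a
simulation-backed pipeline for developing, evaluating, interpreting and
stress-testing them.**

Momentary subjective fear can be decoded from volumetric fMRI activity with a
*neural signature*: a fixed voxel weight map **W** plus intercept *b*, applied
to any masked brain image **x** by dot product ("pattern expression"
ŷ = **W**·**x** + *b*).  This package implements the complete life cycle of
such a signature for researchers in affective and cognitive neuroscience:

- **Synthetic cohorts with known ground truth** (`fearsig.synth`): trial- and
  condition-level beta maps on a small 3-D lattice whose encoding pattern is
  distributed over several labeled networks, BOLD time series (boxcar ⋆
  canonical HRF + cosine drift + AR(1) noise), orthogonal-pattern CS+/CS−
  conditioning datasets, and (X, M, Y) mediation triplets.
- **First-level GLMs** (`fearsig.glm`): condition, parametric-modulation and
  single-trial (LSA/LSS) designs with a DCT 128-s high-pass block and the
  24-column motion-nuisance expansion; OLS fitting; variance-inflation-factor
  trial QC (VIF = 1/(1−R²), exclusion at VIF > 3).
- **Signature training and evaluation** (`fearsig.signature`): linear ε-SVR
  (C = 1) on condition-level maps, subject-wise 10×10-fold cross-validation
  with repeat-averaged predictions, and the full metric battery — overall and
  within-subject Pearson r, RMSE, the explained variance score
  EVS = 1 − var(y−ŷ)/var(y), two-alternative forced choice with Cohen's d,
  and within-subject permutation tests.
- **Interpretation** (`fearsig.interpret`): subject-bootstrap Z maps of the
  weights, the Haufe forward-model transform A = cov(X)·W·cov(S)⁻¹ (which
  nulls suppressor voxels), idiographic per-subject models with group t maps,
  Benjamini–Hochberg FDR and sign-aware overlap maps.
- **Regional stress tests** (`fearsig.regional`): searchlight decoding,
  parcel- and network-restricted models with the identical cross-validation,
  and random-voxel-sampling curves with saturating-exponential asymptotes.
- **Specificity** (`fearsig.specificity`): cross-classification of condition
  pairs, spatial weight-map correlation with voxel-shuffle or parcel-block
  permutation nulls, and the octant SSDO analysis of jointly z-scored weights.
- **Multilevel mediation** (`fearsig.mediation`): per-subject OLS paths a, b,
  c, c′ (with the exact single-mediator identity c − c′ = a·b), group-level
  random effects and BCa bootstrap confidence intervals.

The deposited human cohorts behind the original signature are not required:
every analysis here runs on generated data whose ground truth is known, so
each method's recovery, calibration and specificity are directly testable.

## Worked example

`examples/02_train_and_evaluate.py` trains and cross-validates the signature
on the default emulated cohort (67 subjects, ~80 trials each, 5-level
ratings, 2 subjects lacking the top level → 333 condition maps):

```
condition maps: 333 (65 subjects x 5 levels + 2 subjects x 4 levels)
cosine(trained weights, generating pattern) = 0.549
overall prediction-outcome r = 0.635 (333 pairs), EVS = 0.363, RMSE = 1.13
within-subject r = 0.835 +- 0.017 (SE)
forced choice high vs low: 100% (d = 2.59, binomial p = 1.4e-20)
forced choice high vs moderate: 82% (d = 0.93, binomial p = 1e-07)
forced choice moderate vs low: 82% (d = 1.01, binomial p = 1e-07)
```

The overall r pools between- and within-subject variation across all 333
prediction–outcome pairs; the within-subject r averages each subject's 4–5
condition pairs.  High-vs-low forced choice is perfect because the conditions
differ by three rating units of signal, while adjacent contrasts are harder —
the same ordering of difficulty seen in empirical signature studies.  The
cosine measures how well the trained weight map recovers the planted
distributed encoding pattern.

The other examples cover cohort simulation (01), single-trial GLMs with VIF
QC (03), forward/backward model interpretation with a suppressor
demonstration (04), regional restriction and sampling curves (05), signature
specificity against an orthogonal threat pattern (06), multilevel mediation
(07) and the end-to-end artifact pipeline (08).  Each prints the numbers it
computes and a line on what they mean.

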