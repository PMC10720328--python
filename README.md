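# strainpheno

Unsupervised phenogrouping of left-ventricular (LV) longitudinal strain
curves for cardiovascular risk stratification.

Speckle-tracking echocardiography yields a strain curve per subject — the
percentage of long-axis myocardial shortening over one cardiac cycle.
Clinical practice usually keeps a single number from it (peak systolic
strain) and discards the temporal shape: how fast the ventricle contracts,
how fast it relaxes in early diastole, how long and how high the
mid-diastolic plateau (diastasis) is.  `strainpheno` implements a complete,
tested pipeline that mines exactly that temporal information in a
general-population cohort:

1. **Preprocessing** — quality filtering (frame rate ≥ 45 Hz, landmark
   sanity), segmentation of each curve at the ECG landmarks (R-peak, aortic
   valve closure AVC, P-wave), segment-wise resampling onto a cohort-common
   grid, and strain-rate derivation by finite differences.
2. **Feature extraction** — an RSS-optimal piecewise-linear approximation
   (exact dynamic programming over knot placements) splits each curve into
   systole, early diastole, diastasis and late diastole; six features are
   extracted: the three phase slopes (%/s), diastasis duration (s) and
   height (%), and peak strain (%).
3. **Phenogrouping** — a full-covariance Gaussian mixture fitted by EM
   (k-means++ multi-starts, z-scored features) with the number of groups k
   chosen from the BIC curve by an explicit elbow rule.
4. **Interpretation** — permutation-sampling Shapley values of the
   per-cluster posterior probability, random-forest impurity importance,
   and a per-feature-normalized radar profile of the cluster means.
5. **Outcomes** — per-cluster event counts and incidence rates per 1,000
   person-years (first event per subject), Kaplan–Meier cumulative
   incidence with Greenwood variance, and Cox proportional-hazards models
   in which cluster membership is **deviation coded** (sum-to-zero), so
   each exp(β_c) is the hazard of cluster c relative to the cohort-average
   hazard, adjusted for age, sex, BMI, cholesterol, systolic pressure,
   smoking, cardiac history and diabetes (continuous covariates per SD).
6. **Synthetic cohorts** — because the motivating population data are
   access-restricted, a first-class generator produces strain-curve cohorts
   with known four-group structure (systolic rise to peak at AVC,
   early-diastolic release, diastasis plateau, late-diastolic decline),
   subject-specific heart and frame rates, realistic covariates, and
   exponential event times with group-dependent hazards — so every stage is
   validated against known truth.

A frozen fitted model (JSON, including the training standardization and
alignment grid) can be applied unchanged to an external cohort.

## Worked example

```sh
strainpheno simulate --n 300 --seed 7 --out demo/cohort
strainpheno run --input-dir demo/cohort --output-dir demo/run --seed 7
```

prints `chosen k = 4` and writes the artifact directory.  The BIC curve
(`bic_curve.csv`) drops steeply up to four components and rises afterwards,
so the elbow rule selects four phenogroups:

```
k,bic
1,2889.5
2,2199.3
3,1924.6
4,1796.2
5,1898.0
```

`incidence_cv.csv` shows the risk gradient across the canonical clusters
(ordered from fastest to slowest early-diastolic release):

```
cluster,n,events,person_years,rate_per_1000py
1,67,1,530.8,1.9
2,86,3,652.3,4.6
3,100,11,721.9,15.2
4,47,9,293.9,30.6
overall,300,24,2198.8,10.9
```

and `cox_cv.csv` the adjusted deviation-coded hazard ratios versus the
cohort average — cluster 1 is protective (HR 0.17, p = 0.03), cluster 4
carries excess risk (HR 5.25, 95% CI 2.11–13.07):

```
cluster,hr,hr_lo,hr_hi,p
1,0.17,0.03,0.86,0.033
2,0.55,0.19,1.53,0.251
3,2.02,0.90,4.56,0.089
4,5.25,2.11,13.07,0.0004
```

The interpretation reports (`shapley_mean_abs.csv`,
`forest_importance.csv`, `radar_profile.csv`) show that the diastolic
features — early-diastolic slope, diastasis height and duration — drive
the partition more than peak strain does.

Each stage is also available separately (`simulate`, `qc`, `features`,
`cluster`, `explain`, `outcomes`, `apply`), and as library functions:

```python
import strainpheno as sp

cfg = sp.default_config(n_subjects=500, seed=1)
subjects = sp.generate_cohort(cfg)
kept, excluded = sp.qc_filter([s.trace for s in subjects])
aligned, _ = sp.align_and_resample(kept)
features = sp.build_feature_matrix(aligned)
k, bic_curve, models = sp.select_k(features, k_range=range(1, 9), seed=1)
```

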