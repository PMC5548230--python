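# kidsms

Rule-based risk stratification for Marfan syndrome (MFS) in childhood, with
the statistical machinery to evaluate a stratifier against a diagnostic
reference standard.

MFS is an inherited connective-tissue disorder whose organ manifestations
(aortic root dilatation, ectopia lentis, skeletal features) appear
age-dependently, which makes definitive diagnosis in children difficult and
false diagnosis stigmatizing. This package implements, as tested library
code:

- **Kid-SMS** — the Kid-Short Marfan Score, a pediatric *pre-test
  probability* stratifier. Eight manifestation rules map a child's phenotype
  to an ordered category: SV + EL → **very high**; SV + MVP + TVP, SV + PA,
  SV + ≥3 skeletal features, EL + MVP + TVP, EL + PA → **high**; family
  history alone or SV alone → **moderate**; otherwise negative. (SV/PA =
  dilatation of the sinus of Valsalva / pulmonary artery at Z ≥ 2; EL =
  ectopia lentis; MVP/TVP = mitral/tricuspid valve prolapse.)
- **Ghent-2** — the revised Ghent nosology used as the reference standard:
  the 20-point systemic score (positive at ≥ 7) and the six confirmed-MFS
  pathways combining aortic dilatation/dissection, ectopia lentis, systemic
  involvement, FBN1 mutation and family history.
- **Z-score nomograms** — pluggable linear-in-BSA coefficient sets that turn
  echo diameters into Z = (observed − expected)/SD and dilatation flags.
- **Diagnostic performance** — fourfold tables, sensitivity/specificity/
  PPV/NPV with exact (Clopper-Pearson) 95% confidence intervals, the
  positive likelihood ratio sens/(1 − spec), and Fisher's exact test.
- **Survival analysis** — Kaplan-Meier curves and the log-rank test for age
  at risk stratification vs. age at diagnosis (via lifelines).
- **Synthetic cohorts** — a deterministic 106-child fixture cohort that
  reproduces the published validation study's tables cell-for-cell at three
  time points (baseline, follow-up, final contact), plus a seeded random
  generator for property testing.

## Worked example

```
kidsms evaluate src/kidsms/data/fixture_followup.csv
```

prints

```
Fourfold table (index test vs. reference standard)
  TP=24  FP=19
  FN=0  TN=63
Sensitivity: 100% (CI 95% 0.86 to 1.00)
Specificity: 77% (CI 95% 0.66 to 0.85)
PPV:         56% (CI 95% 0.40 to 0.71)
NPV:         100% (CI 95% 0.94 to 1.00)
Positive likelihood ratio: 4.3
Fisher exact p (two-sided): 2.06e-12
```

Of 106 children, Kid-SMS (assessed at first presentation, positive from the
moderate category upward) flagged 43; by the follow-up visit 24 had a
Ghent-2 diagnosis, all of them among the flagged — sensitivity and negative
predictive value are perfect, specificity is 77% because the score
deliberately trades specificity for safety, and a likelihood ratio of 4.3
means a positive stratification shifts the pre-test odds of MFS about
four-fold.

The same pipeline is available as a library:

```python
from kidsms import fixture_cohort, score_record

for rec in fixture_cohort()[:3]:
    s = score_record(rec)
    print(rec.patient_id, s.kidsms.category.label, s.profile, s.ghent2.diagnosis)
```

`kidsms score` writes per-patient scores (systemic points, Ghent-2 pathways,
Kid-SMS category and profile) for any cohort CSV in the documented schema,
and `kidsms simulate` draws seeded random cohorts.

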