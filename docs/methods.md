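# Methods

## Scoring model

**Ghent-2 systemic score.** The 20-point checklist is scored with three
exclusive alternative groups, which is what makes 20 the maximum
reachable total: wrist AND thumb sign scores 3 while exactly one of the
two scores 1 (never 3 + 1); pectus carinatum (2) shadows pectus
excavatum/chest asymmetry (1); hindfoot deformity (2) shadows plain pes
planus (1). All other rows add independently. The published table does
not spell the exclusivities out; we adopt the pairs above because they
are the only reading under which every item present sums to exactly 20.
Systemic involvement is total ≥ 7.

**Confirmed-MFS pathways.** Six conjunctions are evaluated verbatim:
{aorta + EL, aorta + systemic, aorta + FBN1, FH + aorta, FH + EL,
FH + systemic}, where "aorta" is dilatation *or* dissection. This is the
printed pediatric decision rule; the full adult nosology (e.g. the
EL + known-aortic-FBN1-variant pathway, Z-threshold stratification by
age ≥ 20) is deliberately out of scope. `fbn1_status = not_tested` is a
third state that disables, rather than fails, the aorta + FBN1 pathway,
because genetic analysis is typically done only where necessary.

**Kid-SMS.** Eight rules in fixed table order (SV+EL; SV+MVP+TVP; SV+PA;
SV+3Skel; EL+MVP+TVP; EL+PA; FH; SV). A record's category is the maximum
over matched rules; all matches are recorded, and the *primary profile*
(used for cross-tabulation rows) is the first match in table order, so a
moderate-only patient with both family history and isolated SV reports
as FH. "3 skeletal features" counts distinct present items of the
11-item skeletal subset, not systemic points: wrist + thumb sign is two
features even though it scores 3 points once. Aortic dissection does not
enter Kid-SMS; its cardiac criterion is SV dilatation.

**Absent vs. negative.** Unassessed clinical features are absent, not
false. A record with neither a direct dilatation flag nor
diameter + BSA raises an error rather than defaulting to not-dilated;
silently imputed negatives would bias sensitivity estimates.

## Nomograms

Dilatation is Z ≥ 2.0 (inclusive, configurable), with
Z = (observed − expected)/SD. Because published pediatric nomograms
differ in parameterization and the relevant coefficient sets are not
part of this package's claims, nomograms are pluggable JSON coefficient
sets (linear-in-BSA mean and SD). The two bundled defaults use
representative pediatric magnitudes — sinus of Valsalva:
mean = 10.2 + 9.8·BSA mm, SD 2.0 mm; pulmonary artery:
mean = 9.0 + 8.0·BSA mm, SD 1.8 mm; admissible BSA 0.15–2.2 m² — chosen
to give physiologic diameters across childhood, and are *not* validated
against any echo dataset. Users reproducing a specific reference
population must load its published coefficients. BSA from
height/weight is available explicitly via the Du Bois formula; it is
never applied silently.

## Diagnostic performance

Proportions carry exact two-sided Clopper-Pearson intervals (beta
quantiles; lower bound exactly 0 at k = 0, upper exactly 1 at k = n).
The interval method reproduces the published bounds for 24/24 (0.86),
63/63 (0.94), 24/43 (0.40–0.71) and 63/82 (0.66–0.85), which is how it
was identified; that verification is itself a test. The positive
likelihood ratio is sens/(1 − spec), +∞ at perfect specificity. The
two-sided Fisher exact p uses the probability-ordering convention
(sum of hypergeometric probabilities of tables no more probable than
the observed one) — conventions differ between packages, so this is
fixed and cross-checked against exact integer enumeration. Statistics
with an empty margin are flagged undefined, never NaN-propagated.
Report output rounds to whole percents, two-decimal CI bounds and a
one-decimal likelihood ratio; internal values are never pre-rounded.
An unpaired t-test wrapper is provided as a labelled convenience for
cohort summaries only.

## Survival analysis

Kaplan-Meier estimation and the unweighted log-rank test are delegated
to lifelines behind a fixed contract: product-limit steps at event
times only, censorings shrink the risk set without steps, deaths before
censorings at ties, and subjects never reaching an endpoint censored at
age at last contact. The two endpoint series (age at Kid-SMS
stratification, age at Ghent-2 diagnosis) come from the same children,
so the comparison is really paired; the unpaired log-rank is
implemented because that is the analysis convention being mirrored, and
the caveat stands.

## The fixture cohort

The deterministic 106-child cohort realizes the published validation
study's counts from minimal phenotypes: each record carries exactly the
features its profile row requires plus the minimum extras forcing its
assigned diagnosis status (e.g. a Ghent-2-positive SV+3Skel child gets
wrist + thumb + carinatum + hindfoot = 7 systemic points; a
Ghent-2-positive SV+MVP+TVP child gets a positive FBN1 result; EL+PA
children get family history, the only route to diagnosis without aortic
involvement).

The published tables are mutually inconsistent on a single snapshot:
the profile-by-outcome table has 27 Ghent-2-positives while the
follow-up fourfold has 24 and the baseline fourfold 21. We reconcile by
modelling **three snapshots** — baseline (21 positive), follow-up
evaluation visit (24), final contact (27) — with three children
converting in each interval (systemic score crossing 7 as skeletal
features accrue, or a late positive genetic result). Kid-SMS is
assessed at baseline and flags the same 43 children throughout, so
every published count is reproduced exactly at its own snapshot, and
no false negatives ever appear. Conversions are monotone: a diagnosis
is never revoked.

Ages at first presentation are placed deterministically at age-bin
midpoints (0.5, 3.5, 9.5, 15.5, 19 years) to hit the published bin
counts (2, 14, 33, 53, 4); within-bin placement is unknowable from the
histogram, so the published mean age is not a target. Follow-up and
final visits are set 2 and 4 years after baseline. Records are ordered
never-flagged → false-positive → diagnosed, so ascending age assignment
makes diagnosed children older — consistent with age-dependent
manifestation — and yields the qualitative finding that mean age at
stratification (15.8 y) precedes mean age at diagnosis (16.7 y). The
published mean ages (10.63/12.07 y) and log-rank p = 0.2 require the
unpublished individual ages and are explicitly *not* reproduced; the
survival module's correctness is instead established by hand-computed
small examples and a type-I-error simulation. The 39/67 female/male
split is preserved; sex enters no scoring rule.

The random generator draws patients i.i.d. from profile-cell weights
(default: the published cell frequencies) and age-bin weights, uniform
within bin, all randomness from one integer seed. It emulates the joint
profile-by-outcome distribution only — no age-dependent penetrance, no
within-family correlation, no measurement noise on diameters — so
passing property tests establish the rule engines' correctness on
clean feature data, not robustness to real-world echo variability.

## Numerical and testing choices

Exhaustive checks are used where the space is small (all 2^16 systemic
item vectors, all 2^7 Kid-SMS feature combinations, all 2×2 tables with
total ≤ 30 for Fisher agreement); simulations use fixed seeds
(Clopper-Pearson coverage at n = 50 with 10,000 replicates; log-rank
type-I error with 2,000 null replicates at n = 30 per arm), sized to
keep the default suite around a minute while leaving Monte-Carlo error
well below the asserted margins.

## Known limitations

- The bundled nomogram coefficients are representative, not validated;
  clinical use requires a published pediatric nomogram.
- Table-printed counts, not patient-level data, anchor the fixture; any
  statistic depending on within-cell detail (exact ages, diameters) is
  a construction choice, not an estimate.
- The log-rank comparison treats paired endpoint series as independent
  samples (see above).
- Only the pediatric decision rule of the revised nosology is
  implemented; MASS-phenotype and other differential diagnoses carry no
  rule and are not classified.
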