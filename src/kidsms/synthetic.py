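"""Synthetic cohorts: a deterministic 106-patient fixture and random draws.

The fixture reconstructs the published validation cohort of 106
children assessed for Marfan syndrome, using minimal phenotype
realizations: each record carries exactly the features its risk-profile
row requires plus the minimum extras that force its assigned Ghent-2
status.  The cohort is modelled at three time points:

* **baseline** (first presentation) — 21 Ghent-2-positive, matching the
  baseline fourfold table (21, 22, 0, 63);
* **follow-up** (evaluation visit) — 24 Ghent-2-positive after three
  conversions, matching the follow-up fourfold (24, 19, 0, 63) and the
  headline performance statistics;
* **final** (last contact) — 27 Ghent-2-positive after three further
  conversions, realizing every cell of the published profile-by-outcome
  cross-tabulation exactly.

Kid-SMS is stratified at baseline and is positive (moderate or higher)
for the same 43 children at every time point.  Ages at first
presentation are placed deterministically at age-bin midpoints to hit
the published bin counts (2, 14, 33, 53, 4); follow-up and final visits
occur 2 and 4 years later.  Internal consistency against all published
counts is asserted every time the fixture is built.

:func:`random_cohort` draws i.i.d. patients from configurable
profile-cell and age-bin weights (defaulting to the fixture cohort's
empirical frequencies) for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .cohort import FBN1Status, PhenotypeRecord, Sex, SystemicItems, Visit
from .errors import KidsmsError
from .scoring import score_record

FIXTURE_N = 106

#: Age bins of the first-presentation histogram: (label, low, high), years.
AGE_BINS: tuple[tuple[str, float, float], ...] = (
    ("0-1", 0.0, 1.0),
    ("1-6", 1.0, 6.0),
    ("6-13", 6.0, 13.0),
    ("13-18", 13.0, 18.0),
    (">18", 18.0, 20.0),
)

#: Published bin counts at first presentation.
AGE_BIN_COUNTS: dict[str, int] = {"0-1": 2, "1-6": 14, "6-13": 33, "13-18": 53, ">18": 4}

_BIN_MIDPOINTS: dict[str, float] = {"0-1": 0.5, "1-6": 3.5, "6-13": 9.5, "13-18": 15.5, ">18": 19.0}

#: Years between baseline and follow-up, and baseline and final contact.
FOLLOW_UP_INTERVAL_YEARS = 2.0
FINAL_INTERVAL_YEARS = 4.0

#: Outcome column labels: Ghent-2 positive; Ghent-2 negative with FBN1
#: mutation; neither.
OUTCOMES: tuple[str, ...] = ("ghent2", "fbn1", "neither")

#: Profile rows of the published cross-tabulation, in print order.
PROFILE_ROWS: tuple[str, ...] = (
    "SV+EL",
    "SV+3Skel",
    "SV+MVP+TVP",
    "SV+PA",
    "EL+MVP+TVP",
    "EL+PA",
    "FH",
    "SV",
    "negative",
)

#: Published profile-by-outcome cell counts at final contact.
TABLE5_COUNTS: dict[tuple[str, str], int] = {
    ("SV+EL", "ghent2"): 2,
    ("SV+3Skel", "ghent2"): 8,
    ("SV+3Skel", "neither"): 2,
    ("SV+MVP+TVP", "ghent2"): 7,
    ("SV+PA", "ghent2"): 3,
    ("EL+MVP+TVP", "ghent2"): 0,
    ("EL+PA", "ghent2"): 2,
    ("FH", "ghent2"): 2,
    ("FH", "fbn1"): 2,
    ("FH", "neither"): 7,
    ("SV", "ghent2"): 3,
    ("SV", "neither"): 5,
    ("negative", "fbn1"): 3,
    ("negative", "neither"): 60,
}

_ITEMS_NONE = SystemicItems.assume_absent()
# three skeletal features worth only 3 systemic points (below threshold)
_ITEMS_3SKEL_LOW = SystemicItems.assume_absent(
    scoliosis_or_kyphosis=True, pes_planus=True,
    pectus_excavatum_or_chest_asymmetry=True,
)
# four skeletal features worth 7 points (wrist+thumb 3, carinatum 2, hindfoot 2)
_ITEMS_3SKEL_HIGH = SystemicItems.assume_absent(
    wrist_sign=True, thumb_sign=True, pectus_carinatum=True, hindfoot_deformity=True
)
_ITEMS_MVP = SystemicItems.assume_absent(mitral_valve_prolapse=True)
# 7 systemic points with only one skeletal feature and no Kid-SMS trigger
_ITEMS_SYSTEMIC_NONSKEL = SystemicItems.assume_absent(
    dural_ectasia=True, spontaneous_pneumothorax=True,
    protrusio_acetabulae=True, myopia_gt3_diopters=True,
)
# 7 systemic points, 4 skeletal features, no vascular involvement
_ITEMS_SYSTEMIC_NOVASC = SystemicItems.assume_absent(
    wrist_sign=True, thumb_sign=True, hindfoot_deformity=True,
    protrusio_acetabulae=True,
)


def _pheno(
    sv: bool = False,
    pa: bool = False,
    el: bool = False,
    mvp: bool = False,
    tvp: bool = False,
    fh: bool = False,
    fbn1: FBN1Status = FBN1Status.NOT_TESTED,
    items: SystemicItems = _ITEMS_NONE,
) -> dict:
    return dict(
        sv_dilated=sv,
        pa_dilated=pa,
        ectopia_lentis=el,
        mitral_valve_prolapse=mvp,
        tricuspid_valve_prolapse=tvp,
        family_history_mfs=fh,
        fbn1_status=fbn1,
        systemic_items=items,
        aortic_dissection=False,
    )


def _patient_plans() -> list[dict[str, dict]]:
    """Per-patient phenotypes at each stage, in fixture order.

    Order: Kid-SMS-negative patients first, then false positives, then
    the eventually-diagnosed — so that, with ages assigned in ascending
    order, diagnosed children are older, mirroring age-dependent organ
    manifestation.
    """
    plans: list[dict[str, dict]] = []

    def add(n: int, final: dict, baseline: Optional[dict] = None,
            follow_up: Optional[dict] = None) -> None:
        for _ in range(n):
            plans.append(
                {
                    "baseline": baseline if baseline is not None else final,
                    "follow_up": follow_up if follow_up is not None else final,
                    "final": final,
                }
            )

    POS, NEG = FBN1Status.POSITIVE, FBN1Status.NEGATIVE

    # --- Kid-SMS negative (63) ---
    add(60, _pheno())  # no manifestations, FBN1 not tested
    add(1, _pheno(mvp=True, tvp=True, fbn1=POS, items=_ITEMS_MVP))  # isolated MVP+TVP
    add(2, _pheno(fbn1=POS, items=_ITEMS_SYSTEMIC_NOVASC))  # systemic score, no vessels
    # --- Kid-SMS positive, never Ghent-2 positive (16) ---
    add(2, _pheno(sv=True, items=_ITEMS_3SKEL_LOW))  # SV + skeletal, genetics not done
    add(2, _pheno(fh=True, fbn1=POS))  # FH moderate, FBN1 carriers
    add(7, _pheno(fh=True, fbn1=NEG))  # FH moderate, excluded after work-up
    add(5, _pheno(sv=True))  # isolated SV dilatation
    # --- Ghent-2 positive at baseline (21) ---
    add(2, _pheno(sv=True, el=True))
    add(4, _pheno(sv=True, items=_ITEMS_3SKEL_HIGH))
    add(6, _pheno(sv=True, mvp=True, tvp=True, fbn1=POS, items=_ITEMS_MVP))
    add(3, _pheno(sv=True, pa=True, fbn1=POS))
    add(2, _pheno(el=True, pa=True, fh=True))
    add(2, _pheno(fh=True, items=_ITEMS_SYSTEMIC_NONSKEL))
    add(2, _pheno(sv=True, fbn1=POS))
    # --- converted between baseline and follow-up (3): systemic score
    #     crosses the 7-point threshold as skeletal items accrue ---
    add(
        3,
        final=_pheno(sv=True, items=_ITEMS_3SKEL_HIGH),
        baseline=_pheno(sv=True, items=_ITEMS_3SKEL_LOW),
        follow_up=_pheno(sv=True, items=_ITEMS_3SKEL_HIGH),
    )
    # --- converted after follow-up (3): late manifestation or late
    #     genetic result ---
    add(
        1,
        final=_pheno(sv=True, items=_ITEMS_3SKEL_HIGH),
        baseline=_pheno(sv=True, items=_ITEMS_3SKEL_LOW),
        follow_up=_pheno(sv=True, items=_ITEMS_3SKEL_LOW),
    )
    add(
        1,
        final=_pheno(sv=True, mvp=True, tvp=True, fbn1=POS, items=_ITEMS_MVP),
        baseline=_pheno(sv=True, mvp=True, tvp=True, items=_ITEMS_MVP),
        follow_up=_pheno(sv=True, mvp=True, tvp=True, items=_ITEMS_MVP),
    )
    add(
        1,
        final=_pheno(sv=True, fbn1=POS),
        baseline=_pheno(sv=True),
        follow_up=_pheno(sv=True),
    )

    assert len(plans) == FIXTURE_N
    return plans


def _baseline_ages() -> list[float]:
    ages: list[float] = []
    for label, _, _ in AGE_BINS:
        ages.extend([_BIN_MIDPOINTS[label]] * AGE_BIN_COUNTS[label])
    return ages


_STAGE_OFFSET = {
    "baseline": 0.0,
    "follow_up": FOLLOW_UP_INTERVAL_YEARS,
    "final": FINAL_INTERVAL_YEARS,
}
_STAGE_VISIT = {
    "baseline": Visit.BASELINE,
    "follow_up": Visit.FOLLOW_UP,
    "final": Visit.FOLLOW_UP,
}


def _build_stage(stage: str) -> list[PhenotypeRecord]:
    plans = _patient_plans()
    ages = _baseline_ages()
    records = []
    for i, (plan, age) in enumerate(zip(plans, ages)):
        records.append(
            PhenotypeRecord(
                patient_id=f"P{i + 1:03d}",
                age_years=age + _STAGE_OFFSET[stage],
                sex=Sex.FEMALE if i < 39 else Sex.MALE,
                visit=_STAGE_VISIT[stage],
                **plan[stage],
            )
        )
    return records


def outcome_of(scored) -> str:
    """Outcome column of a scored record: ghent2 / fbn1 / neither."""
    if scored.ghent2.diagnosis:
        return "ghent2"
    if scored.record.fbn1_status is FBN1Status.POSITIVE:
        return "fbn1"
    return "neither"


def profile_outcome_counts(
    records: list[PhenotypeRecord],
) -> dict[tuple[str, str], int]:
    """Cross-tabulate Kid-SMS primary profile against diagnosis outcome."""
    counts: dict[tuple[str, str], int] = {
        (row, col): 0 for row in PROFILE_ROWS for col in OUTCOMES
    }
    for record in records:
        scored = score_record(record)
        counts[(scored.profile, outcome_of(scored))] += 1
    return counts


def _validate_fixture() -> None:
    from .performance import build_fourfold  # local import avoids a cycle

    stages = {stage: _build_stage(stage) for stage in ("baseline", "follow_up", "final")}
    scored = {
        stage: [score_record(r) for r in records] for stage, records in stages.items()
    }
    kidsms_pos = {
        stage: sum(s.kidsms.category >= 1 for s in scores)
        for stage, scores in scored.items()
    }
    assert all(n == 43 for n in kidsms_pos.values()), kidsms_pos
    g2 = {
        stage: sum(s.ghent2.diagnosis for s in scores)
        for stage, scores in scored.items()
    }
    assert g2 == {"baseline": 21, "follow_up": 24, "final": 27}, g2

    observed = profile_outcome_counts(stages["final"])
    expected = {
        (row, col): TABLE5_COUNTS.get((row, col), 0)
        for row in PROFILE_ROWS
        for col in OUTCOMES
    }
    assert observed == expected, {k: (observed[k], expected[k]) for k in observed if observed[k] != expected[k]}

    for stage, expect in (("baseline", (21, 22, 0, 63)), ("follow_up", (24, 19, 0, 63))):
        table = build_fourfold(
            stages[stage],
            lambda r: score_record(r).kidsms.category >= 1,
            lambda r: score_record(r).ghent2.diagnosis,
        )
        assert table.as_counts() == expect, (stage, table)


_validated = False


def fixture_cohort(visit: Visit = Visit.FOLLOW_UP) -> list[PhenotypeRecord]:
    """The deterministic 106-patient fixture at baseline or follow-up.

    The default follow-up snapshot yields the fourfold table
    (24, 19, 0, 63); the baseline snapshot yields (21, 22, 0, 63).
    Consistency with every published count is asserted on first build.
    """
    global _validated
    if not _validated:
        _validate_fixture()
        _validated = True
    stage = "baseline" if visit is Visit.BASELINE else "follow_up"
    return _build_stage(stage)


def fixture_final_cohort() -> list[PhenotypeRecord]:
    """The fixture at last contact (27 Ghent-2-positive).

    This is the snapshot whose profile-by-outcome cross-tabulation
    matches the published table cell-for-cell, including the three
    patients diagnosed only after the follow-up evaluation visit.
    """
    global _validated
    if not _validated:
        _validate_fixture()
        _validated = True
    return _build_stage("final")


def fixture_event_series():
    """Age-at-stratification and age-at-diagnosis series for the fixture.

    Stratification events occur at baseline (Kid-SMS is assessed at
    first presentation); diagnosis events at the first snapshot where
    Ghent-2 is positive.  Patients never reaching an endpoint are
    censored at age at last contact.

    Returns
    -------
    (EventSeries, EventSeries)
        Stratification series, diagnosis series.
    """
    from .survival import EventSeries

    stages = {s: _build_stage(s) for s in ("baseline", "follow_up", "final")}
    strat_times, strat_events = [], []
    diag_times, diag_events = [], []
    for base, fup, final in zip(stages["baseline"], stages["follow_up"], stages["final"]):
        last_age = final.age_years
        s = score_record(base)
        if s.kidsms.category >= 1:
            strat_times.append(base.age_years)
            strat_events.append(True)
        else:
            strat_times.append(last_age)
            strat_events.append(False)
        diagnosed_at = None
        for snapshot in (base, fup, final):
            if score_record(snapshot).ghent2.diagnosis:
                diagnosed_at = snapshot.age_years
                break
        if diagnosed_at is not None:
            diag_times.append(diagnosed_at)
            diag_events.append(True)
        else:
            diag_times.append(last_age)
            diag_events.append(False)
    return (
        EventSeries(tuple(strat_times), tuple(strat_events), label="Kid-SMS stratification"),
        EventSeries(tuple(diag_times), tuple(diag_events), label="Ghent-2 diagnosis"),
    )


_FIXTURE_FILES = {
    "baseline": "fixture_baseline.csv",
    "follow_up": "fixture_followup.csv",
    "final": "fixture_final.csv",
}


def fixture_csv_path(stage: str = "follow_up") -> Path:
    """Path to the shipped CSV copy of a fixture snapshot.

    ``stage`` is one of ``baseline``, ``follow_up``, ``final``.  The
    files are generated with :func:`kidsms.cohort.write_cohort` from
    the in-code fixture; tests assert file/code agreement.
    """
    try:
        name = _FIXTURE_FILES[stage]
    except KeyError:
        raise ValueError(f"unknown fixture stage: {stage!r}") from None
    return Path(resources.files("kidsms").joinpath("data", name))


# --- random cohorts ----------------------------------------------------

#: Canonical phenotype realization for each profile-by-outcome cell.
CELL_PHENOTYPES: dict[str, dict] = {
    "SV+EL:ghent2": _pheno(sv=True, el=True),
    "SV+3Skel:ghent2": _pheno(sv=True, items=_ITEMS_3SKEL_HIGH),
    "SV+3Skel:neither": _pheno(sv=True, items=_ITEMS_3SKEL_LOW),
    "SV+MVP+TVP:ghent2": _pheno(
        sv=True, mvp=True, tvp=True, fbn1=FBN1Status.POSITIVE, items=_ITEMS_MVP
    ),
    "SV+MVP+TVP:neither": _pheno(sv=True, mvp=True, tvp=True, items=_ITEMS_MVP),
    "SV+PA:ghent2": _pheno(sv=True, pa=True, fbn1=FBN1Status.POSITIVE),
    "SV+PA:neither": _pheno(sv=True, pa=True),
    "EL+MVP+TVP:ghent2": _pheno(el=True, mvp=True, tvp=True, fh=True, items=_ITEMS_MVP),
    "EL+MVP+TVP:neither": _pheno(el=True, mvp=True, tvp=True, items=_ITEMS_MVP),
    "EL+PA:ghent2": _pheno(el=True, pa=True, fh=True),
    "EL+PA:neither": _pheno(el=True, pa=True),
    "FH:ghent2": _pheno(fh=True, items=_ITEMS_SYSTEMIC_NONSKEL),
    "FH:fbn1": _pheno(fh=True, fbn1=FBN1Status.POSITIVE),
    "FH:neither": _pheno(fh=True, fbn1=FBN1Status.NEGATIVE),
    "SV:ghent2": _pheno(sv=True, fbn1=FBN1Status.POSITIVE),
    "SV:neither": _pheno(sv=True),
    "negative:fbn1": _pheno(mvp=True, tvp=True, fbn1=FBN1Status.POSITIVE, items=_ITEMS_MVP),
    "negative:neither": _pheno(),
}

#: Default profile-cell weights: the published cell counts / 106.
DEFAULT_PROFILE_WEIGHTS: dict[str, float] = {
    f"{row}:{col}": count / FIXTURE_N for (row, col), count in TABLE5_COUNTS.items()
}

#: Default age-bin weights: the published bin counts / 106.
DEFAULT_AGE_BIN_WEIGHTS: dict[str, float] = {
    label: count / FIXTURE_N for label, count in AGE_BIN_COUNTS.items()
}

_FEMALE_FRACTION = 39 / 106  # observed sex split of the study cohort


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for :func:`random_cohort`."""

    n: int
    profile_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_WEIGHTS)
    )
    age_bin_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BIN_WEIGHTS)
    )
    seed: int = 0


def _checked_weights(weights: Mapping[str, float], valid_keys, what: str) -> tuple[list[str], np.ndarray]:
    unknown = sorted(set(weights) - set(valid_keys))
    if unknown:
        raise KidsmsError(f"unknown {what} key(s): {', '.join(unknown)}")
    keys = [k for k in valid_keys if k in weights]
    probs = np.array([weights[k] for k in keys], dtype=float)
    if (probs < 0).any():
        raise KidsmsError(f"{what} weights must be non-negative")
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise KidsmsError(f"{what} weights must sum to 1, got {total}")
    return keys, probs / total


def random_cohort(spec: CohortSpec) -> list[PhenotypeRecord]:
    """Sample ``spec.n`` patients i.i.d. from the cell and age weights.

    Ages are uniform within the selected bin; every draw flows from the
    single integer seed, so equal specs yield identical cohorts.
    """
    if spec.n < 1:
        raise KidsmsError(f"cohort size must be >= 1, got {spec.n}")
    cell_keys, cell_probs = _checked_weights(
        spec.profile_weights, list(CELL_PHENOTYPES), "profile"
    )
    bin_labels = [label for label, _, _ in AGE_BINS]
    bin_keys, bin_probs = _checked_weights(spec.age_bin_weights, bin_labels, "age bin")
    bin_bounds = {label: (lo, hi) for label, lo, hi in AGE_BINS}

    rng = np.random.default_rng(spec.seed)
    cell_draws = rng.choice(len(cell_keys), size=spec.n, p=cell_probs)
    bin_draws = rng.choice(len(bin_keys), size=spec.n, p=bin_probs)
    age_fractions = rng.random(spec.n)
    sex_draws = rng.random(spec.n) < _FEMALE_FRACTION

    records = []
    for i in range(spec.n):
        lo, hi = bin_bounds[bin_keys[bin_draws[i]]]
        records.append(
            PhenotypeRecord(
                patient_id=f"R{i + 1:05d}",
                age_years=lo + (hi - lo) * age_fractions[i],
                sex=Sex.FEMALE if sex_draws[i] else Sex.MALE,
                visit=Visit.BASELINE,
                **CELL_PHENOTYPES[cell_keys[cell_draws[i]]],
            )
        )
    return records
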