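"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive expected values by different
routes than the implementation (lookup tables, exact integer
enumeration) so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
from math import comb

import pytest

from kidsms.cohort import (
    FBN1Status,
    PhenotypeRecord,
    Sex,
    SystemicItems,
    SYSTEMIC_ITEM_FIELDS,
    Visit,
)

# --- record construction helpers ---------------------------------------


def make_record(
    *,
    patient_id: str = "T001",
    age_years: float = 10.0,
    sv_dilated=False,
    pa_dilated=False,
    ectopia_lentis=False,
    mitral_valve_prolapse=False,
    tricuspid_valve_prolapse=False,
    family_history_mfs=False,
    aortic_dissection=False,
    fbn1_status=FBN1Status.NOT_TESTED,
    systemic_items=None,
    visit=Visit.BASELINE,
    **extra,
) -> PhenotypeRecord:
    return PhenotypeRecord(
        patient_id=patient_id,
        age_years=age_years,
        sex=Sex.UNKNOWN,
        sv_dilated=sv_dilated,
        pa_dilated=pa_dilated,
        ectopia_lentis=ectopia_lentis,
        mitral_valve_prolapse=mitral_valve_prolapse,
        tricuspid_valve_prolapse=tricuspid_valve_prolapse,
        family_history_mfs=family_history_mfs,
        aortic_dissection=aortic_dissection,
        fbn1_status=fbn1_status,
        systemic_items=systemic_items or SystemicItems.assume_absent(),
        visit=visit,
        **extra,
    )


def items_from_bits(bits) -> SystemicItems:
    """SystemicItems from a 16-tuple of booleans, in field order."""
    return SystemicItems(**dict(zip(SYSTEMIC_ITEM_FIELDS, bits)))


# --- independent oracles ------------------------------------------------


def systemic_points_oracle(items: SystemicItems) -> int:
    """Weighted sum with exclusive alternatives resolved by max()."""
    wrist_thumb = {(False, False): 0, (True, False): 1, (False, True): 1, (True, True): 3}
    return (
        max(2 * items.pectus_carinatum, 1 * items.pectus_excavatum_or_chest_asymmetry)
        + items.reduced_us_ls_and_increased_armspan_no_scoliosis
        + items.characteristic_face
        + wrist_thumb[(items.wrist_sign, items.thumb_sign)]
        + items.scoliosis_or_kyphosis
        + items.reduced_elbow_extension
        + max(2 * items.hindfoot_deformity, 1 * items.pes_planus)
        + 2 * items.protrusio_acetabulae
        + items.myopia_gt3_diopters
        + items.mitral_valve_prolapse
        + 2 * items.spontaneous_pneumothorax
        + items.striae_atrophicae
        + 2 * items.dural_ectasia
    )


def kidsms_category_oracle(sv, el, mvp, tvp, pa, fh, skel3) -> str:
    """Direct transcription of the risk-category table, highest first."""
    if sv and el:
        return "very_high"
    if (sv and mvp and tvp) or (sv and pa) or (sv and skel3) or (el and mvp and tvp) or (el and pa):
        return "high"
    if fh or sv:
        return "moderate"
    return "negative"


def fisher_two_sided_oracle(tp: int, fp: int, fn: int, tn: int) -> float:
    """Exact two-sided Fisher p by integer enumeration over fixed margins.

    Sums hypergeometric probabilities of all tables no more probable
    than the observed one; ties are exact because the unnormalized
    weights are integer binomial products.
    """
    r, s, k = tp + fp, fn + tn, tp + fn
    n = r + s
    lo, hi = max(0, k - s), min(k, r)
    weights = {x: comb(r, x) * comb(s, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[tp]
    total = comb(n, k)
    return sum(w for w in weights.values() if w <= w_obs) / total


def all_bool_tuples(n: int):
    return itertools.product((False, True), repeat=n)


@pytest.fixture(scope="session")
def followup_cohort():
    from kidsms.synthetic import fixture_cohort

    return fixture_cohort()


@pytest.fixture(scope="session")
def baseline_cohort():
    from kidsms.synthetic import fixture_cohort

    return fixture_cohort(Visit.BASELINE)


@pytest.fixture(scope="session")
def final_cohort():
    from kidsms.synthetic import fixture_final_cohort

    return fixture_final_cohort()
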