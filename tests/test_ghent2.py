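"""Ghent-2 systemic score and diagnosis pathways."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    all_bool_tuples,
    items_from_bits,
    make_record,
    systemic_points_oracle,
)

from kidsms.cohort import FBN1Status, SystemicItems, SYSTEMIC_ITEM_FIELDS
from kidsms.ghent2 import ghent2_diagnose, systemic_score


def test_point_values_sum_example():
    """Wrist+thumb (3) + pectus carinatum (2) + hindfoot (2) reaches 7/20."""
    items = SystemicItems.assume_absent(
        wrist_sign=True, thumb_sign=True, pectus_carinatum=True, hindfoot_deformity=True
    )
    result = systemic_score(items)
    assert result.total_points == 7
    assert result.positive
    assert sum(result.item_points.values()) == result.total_points


def test_no_items_scores_zero():
    result = systemic_score(SystemicItems.assume_absent())
    assert result.total_points == 0 and not result.positive


def test_all_items_true_caps_at_twenty():
    """With every item present the exclusive alternatives cap the total at 20:
    wrist+thumb counts once as 3, carinatum shadows excavatum, hindfoot
    shadows plain pes planus."""
    items = items_from_bits([True] * 16)
    result = systemic_score(items)
    assert result.total_points == 20
    assert result.item_points["wrist_and_thumb_sign"] == 3
    assert "wrist_or_thumb_sign" not in result.item_points
    assert "pectus_excavatum_or_chest_asymmetry" not in result.item_points
    assert "pes_planus" not in result.item_points


def test_wrist_thumb_contributes_zero_one_or_three():
    for wrist, thumb, expected in [
        (False, False, 0),
        (True, False, 1),
        (False, True, 1),
        (True, True, 3),
    ]:
        items = SystemicItems.assume_absent(wrist_sign=wrist, thumb_sign=thumb)
        assert systemic_score(items).total_points == expected


def test_exhaustive_agreement_with_weight_table_oracle():
    """All 2^16 item combinations match the independent weighted-sum oracle."""
    for bits in all_bool_tuples(16):
        items = items_from_bits(bits)
        result = systemic_score(items)
        assert result.total_points == systemic_points_oracle(items)
        assert 0 <= result.total_points <= 20
        assert result.positive == (result.total_points >= 7)


@settings(derandomize=True, max_examples=200)
@given(st.tuples(*[st.booleans()] * 16), st.integers(min_value=0, max_value=15))
def test_score_monotone_in_each_item(bits, flip_index):
    """Turning any single item on never decreases the total."""
    low = list(bits)
    low[flip_index] = False
    high = list(low)
    high[flip_index] = True
    assert (
        systemic_score(items_from_bits(high)).total_points
        >= systemic_score(items_from_bits(low)).total_points
    )


# --- diagnosis pathways -------------------------------------------------

SEVEN_POINTS = SystemicItems.assume_absent(
    wrist_sign=True, thumb_sign=True, pectus_carinatum=True, hindfoot_deformity=True
)


def test_aorta_plus_ectopia_lentis_confirms():
    record = make_record(ectopia_lentis=True)
    result = ghent2_diagnose(record, aorta_dilated=True)
    assert result.diagnosis and "aorta+EL" in result.pathways


def test_family_history_plus_systemic_confirms():
    record = make_record(family_history_mfs=True, systemic_items=SEVEN_POINTS)
    result = ghent2_diagnose(record, aorta_dilated=False)
    assert result.diagnosis and result.pathways == ("FH+systemic",)


def test_fbn1_alone_without_vascular_involvement_is_negative():
    """An FBN1 carrier with sub-threshold systemic score, no aortic
    involvement and no family history does not meet the criteria."""
    record = make_record(
        fbn1_status=FBN1Status.POSITIVE,
        systemic_items=SystemicItems.assume_absent(
            scoliosis_or_kyphosis=True, pes_planus=True, striae_atrophicae=True
        ),
    )
    result = ghent2_diagnose(record, aorta_dilated=False)
    assert not result.diagnosis and result.pathways == ()
    assert result.systemic.total_points == 3


def test_fbn1_not_tested_disables_aorta_fbn1_pathway():
    not_tested = make_record(fbn1_status=FBN1Status.NOT_TESTED)
    positive = make_record(fbn1_status=FBN1Status.POSITIVE)
    assert not ghent2_diagnose(not_tested, aorta_dilated=True).diagnosis
    assert ghent2_diagnose(positive, aorta_dilated=True).pathways == ("aorta+FBN1",)


def test_dissection_counts_as_aortic_involvement():
    record = make_record(aortic_dissection=True, ectopia_lentis=True)
    assert ghent2_diagnose(record, aorta_dilated=False).diagnosis


def test_diagnosis_reports_every_matched_pathway():
    record = make_record(
        ectopia_lentis=True, family_history_mfs=True,
        fbn1_status=FBN1Status.POSITIVE, systemic_items=SEVEN_POINTS,
    )
    result = ghent2_diagnose(record, aorta_dilated=True)
    assert result.pathways == (
        "aorta+EL", "aorta+systemic", "aorta+FBN1", "FH+aorta", "FH+EL", "FH+systemic",
    )


@settings(derandomize=True, max_examples=200)
@given(
    st.booleans(), st.booleans(), st.booleans(), st.booleans(),
    st.tuples(*[st.booleans()] * 16),
)
def test_diagnosis_monotone_in_manifestations(aorta, el, fh, fbn1, bits):
    """Adding any manifestation never revokes a diagnosis."""
    base = make_record(
        ectopia_lentis=el,
        family_history_mfs=fh,
        fbn1_status=FBN1Status.POSITIVE if fbn1 else FBN1Status.NEGATIVE,
        systemic_items=items_from_bits(bits),
    )
    before = ghent2_diagnose(base, aorta_dilated=aorta).diagnosis
    richer = base.replace(
        ectopia_lentis=True,
        family_history_mfs=fh or True,
        systemic_items=items_from_bits([a or b for a, b in zip(bits, [True] * 16)]),
    )
    after = ghent2_diagnose(richer, aorta_dilated=True).diagnosis
    assert after >= before
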