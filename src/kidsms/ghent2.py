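"""Revised Ghent (Ghent-2) nosology: systemic score and diagnosis pathways.

The systemic score is a 20-point weighted checklist of systemic
manifestations; at least 7/20 points means systemic involvement.  Three
row groups are mutually exclusive alternatives, which is what caps the
total at 20:

* wrist AND thumb sign scores 3; exactly one of the two scores 1
  (never 3 + 1 = 4);
* pectus carinatum (2) takes precedence over pectus excavatum / chest
  asymmetry (1) when both are recorded;
* hindfoot deformity (2) takes precedence over plain pes planus (1).

A confirmed Marfan diagnosis requires one of six feature conjunctions
("pathways"): aortic dilatation/dissection combined with ectopia
lentis, systemic involvement, or an FBN1 mutation; or a positive family
history combined with aortic dilatation/dissection, ectopia lentis, or
systemic involvement.  An ``fbn1_status`` of ``NOT_TESTED`` disables
(does not fail) the aorta+FBN1 pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import FBN1Status, PhenotypeRecord, SystemicItems

#: Points for each scored row of the systemic checklist.  The three
#: exclusive alternative groups above are resolved by
#: :func:`systemic_score`; this table documents the raw row weights.
ROW_POINTS: dict[str, int] = {
    "pectus_carinatum": 2,
    "pectus_excavatum_or_chest_asymmetry": 1,
    "reduced_us_ls_and_increased_armspan_no_scoliosis": 1,
    "characteristic_face": 1,
    "wrist_and_thumb_sign": 3,
    "wrist_or_thumb_sign": 1,
    "scoliosis_or_kyphosis": 1,
    "reduced_elbow_extension": 1,
    "pes_planus": 1,
    "hindfoot_deformity": 2,
    "protrusio_acetabulae": 2,
    "myopia_gt3_diopters": 1,
    "mitral_valve_prolapse": 1,
    "spontaneous_pneumothorax": 2,
    "striae_atrophicae": 1,
    "dural_ectasia": 2,
}

#: Systemic involvement threshold: positive at >= 7 of 20 points.
SYSTEMIC_THRESHOLD = 7

MAX_POINTS = 20

#: The six confirmed-MFS pathways, in reporting order.
PATHWAYS: tuple[str, ...] = (
    "aorta+EL",
    "aorta+systemic",
    "aorta+FBN1",
    "FH+aorta",
    "FH+EL",
    "FH+systemic",
)


@dataclass(frozen=True)
class SystemicScoreResult:
    """Points awarded per scored row plus the total and 7/20 positivity."""

    total_points: int
    item_points: dict[str, int]
    positive: bool


@dataclass(frozen=True)
class Ghent2Result:
    diagnosis: bool
    pathways: tuple[str, ...]
    systemic: SystemicScoreResult


def systemic_score(items: SystemicItems) -> SystemicScoreResult:
    """Score the systemic checklist (0-20 points, positive at >= 7)."""
    pts: dict[str, int] = {}

    if items.pectus_carinatum:
        pts["pectus_carinatum"] = 2
    elif items.pectus_excavatum_or_chest_asymmetry:
        pts["pectus_excavatum_or_chest_asymmetry"] = 1

    if items.reduced_us_ls_and_increased_armspan_no_scoliosis:
        pts["reduced_us_ls_and_increased_armspan_no_scoliosis"] = 1
    if items.characteristic_face:
        pts["characteristic_face"] = 1

    if items.wrist_sign and items.thumb_sign:
        pts["wrist_and_thumb_sign"] = 3
    elif items.wrist_sign or items.thumb_sign:
        pts["wrist_or_thumb_sign"] = 1

    if items.scoliosis_or_kyphosis:
        pts["scoliosis_or_kyphosis"] = 1
    if items.reduced_elbow_extension:
        pts["reduced_elbow_extension"] = 1

    if items.hindfoot_deformity:
        pts["hindfoot_deformity"] = 2
    elif items.pes_planus:
        pts["pes_planus"] = 1

    if items.protrusio_acetabulae:
        pts["protrusio_acetabulae"] = 2
    if items.myopia_gt3_diopters:
        pts["myopia_gt3_diopters"] = 1
    if items.mitral_valve_prolapse:
        pts["mitral_valve_prolapse"] = 1
    if items.spontaneous_pneumothorax:
        pts["spontaneous_pneumothorax"] = 2
    if items.striae_atrophicae:
        pts["striae_atrophicae"] = 1
    if items.dural_ectasia:
        pts["dural_ectasia"] = 2

    total = sum(pts.values())
    assert 0 <= total <= MAX_POINTS
    return SystemicScoreResult(
        total_points=total, item_points=pts, positive=total >= SYSTEMIC_THRESHOLD
    )


def ghent2_diagnose(record: PhenotypeRecord, *, aorta_dilated: bool) -> Ghent2Result:
    """Evaluate the six confirmed-MFS pathways for one record.

    ``aorta_dilated`` must be resolved beforehand (direct flag or
    nomogram, see :mod:`kidsms.nomograms`); aortic involvement here is
    dilatation *or* dissection.  Returns every matched pathway; the
    diagnosis is positive iff at least one pathway matches.
    """
    aorta = bool(aorta_dilated) or record.aortic_dissection
    systemic = systemic_score(record.systemic_items)
    el = record.ectopia_lentis
    fh = record.family_history_mfs
    fbn1 = record.fbn1_status is FBN1Status.POSITIVE

    matched = []
    if aorta and el:
        matched.append("aorta+EL")
    if aorta and systemic.positive:
        matched.append("aorta+systemic")
    if aorta and fbn1:
        matched.append("aorta+FBN1")
    if fh and aorta:
        matched.append("FH+aorta")
    if fh and el:
        matched.append("FH+EL")
    if fh and systemic.positive:
        matched.append("FH+systemic")

    return Ghent2Result(
        diagnosis=bool(matched), pathways=tuple(matched), systemic=systemic
    )
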