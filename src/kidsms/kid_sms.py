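"""Kid-Short Marfan Score (Kid-SMS) pre-test probability stratifier.

Kid-SMS assigns a child suspected of Marfan syndrome to an ordered risk
category from eight manifestation rules.  SV means dilatation of the
sinus of Valsalva (not dissection), PA dilatation of the pulmonary
artery, EL ectopia lentis, MVP/TVP mitral/tricuspid valve prolapse, FH
a positive family history, and "3Skel" at least three distinct skeletal
features of the Ghent-2 systemic checklist (features are counted, not
their point weights — wrist plus thumb sign is two features):

======================  =========
rule                    category
======================  =========
SV + EL                 very high
SV + MVP + TVP          high
SV + PA                 high
SV + 3 skeletal         high
EL + MVP + TVP          high
EL + PA                 high
FH alone                moderate
SV alone                moderate
======================  =========

A record's category is the maximum over all matched rules; all matched
rules are recorded in table order, and :func:`primary_profile` reports
the first one as the record's single reporting label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import PhenotypeRecord, SystemicItems


class RiskCategory(enum.IntEnum):
    """Ordered Kid-SMS categories: negative < moderate < high < very_high."""

    NEGATIVE = 0
    MODERATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: Skeletal subset of the systemic checklist used by the 3Skel rule.
SKELETAL_ITEM_FIELDS: tuple[str, ...] = (
    "pectus_carinatum",
    "pectus_excavatum_or_chest_asymmetry",
    "reduced_us_ls_and_increased_armspan_no_scoliosis",
    "characteristic_face",
    "wrist_sign",
    "thumb_sign",
    "scoliosis_or_kyphosis",
    "reduced_elbow_extension",
    "pes_planus",
    "hindfoot_deformity",
    "protrusio_acetabulae",
)

#: Rule labels in table order (drives matched-rule and profile reporting).
RULE_ORDER: tuple[str, ...] = (
    "SV+EL",
    "SV+MVP+TVP",
    "SV+PA",
    "SV+3Skel",
    "EL+MVP+TVP",
    "EL+PA",
    "FH",
    "SV",
)

RULE_CATEGORY: dict[str, RiskCategory] = {
    "SV+EL": RiskCategory.VERY_HIGH,
    "SV+MVP+TVP": RiskCategory.HIGH,
    "SV+PA": RiskCategory.HIGH,
    "SV+3Skel": RiskCategory.HIGH,
    "EL+MVP+TVP": RiskCategory.HIGH,
    "EL+PA": RiskCategory.HIGH,
    "FH": RiskCategory.MODERATE,
    "SV": RiskCategory.MODERATE,
}


@dataclass(frozen=True)
class KidSmsResult:
    category: RiskCategory
    matched_rules: tuple[str, ...]
    skeletal_feature_count: int


def count_skeletal_features(items: SystemicItems) -> int:
    """Count *present* skeletal items (0-11); point weights play no role."""
    item_dict = items.as_dict()
    return sum(item_dict[name] for name in SKELETAL_ITEM_FIELDS)


def kidsms_stratify(
    record: PhenotypeRecord, *, sv_dilated: bool, pa_dilated: bool
) -> KidSmsResult:
    """Stratify one record given resolved SV/PA dilatation flags.

    ``sv_dilated`` and ``pa_dilated`` must be resolved beforehand
    (direct record flags or a nomogram, see
    :func:`kidsms.nomograms.resolve_sv_dilated`).  All matched rules are
    returned; moderate rules (FH alone, SV alone) are recorded even when
    dominated by a higher rule.  Aortic dissection does not enter
    Kid-SMS: its cardiac criterion is SV dilatation.
    """
    sv = bool(sv_dilated)
    pa = bool(pa_dilated)
    el = record.ectopia_lentis
    mvp = record.mitral_valve_prolapse
    tvp = record.tricuspid_valve_prolapse
    fh = record.family_history_mfs
    skel = count_skeletal_features(record.systemic_items)

    conditions = {
        "SV+EL": sv and el,
        "SV+MVP+TVP": sv and mvp and tvp,
        "SV+PA": sv and pa,
        "SV+3Skel": sv and skel >= 3,
        "EL+MVP+TVP": el and mvp and tvp,
        "EL+PA": el and pa,
        "FH": fh,
        "SV": sv,
    }
    matched = tuple(rule for rule in RULE_ORDER if conditions[rule])
    category = max(
        (RULE_CATEGORY[rule] for rule in matched), default=RiskCategory.NEGATIVE
    )
    return KidSmsResult(
        category=RiskCategory(category),
        matched_rules=matched,
        skeletal_feature_count=skel,
    )


def primary_profile(result: KidSmsResult) -> str:
    """Single reporting label for a stratified record.

    The first matched rule in table order, or ``"negative"``.  Because
    FH precedes SV in table order, a patient with both family history
    and isolated SV dilatation reports as FH.
    """
    if not result.matched_rules:
        return "negative"
    return result.matched_rules[0]
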