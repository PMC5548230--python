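"""Per-record scoring pipeline: resolve dilatation, then score everything.

Glue between the data model and the two rule engines.  Aortic
dilatation for the Ghent-2 pathways uses the same sinus-of-Valsalva
Z >= 2 resolution as Kid-SMS.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PhenotypeRecord
from .ghent2 import Ghent2Result, SystemicScoreResult, ghent2_diagnose
from .kid_sms import KidSmsResult, kidsms_stratify, primary_profile
from .nomograms import (
    DEFAULT_PA_NOMOGRAM,
    DEFAULT_SV_NOMOGRAM,
    DEFAULT_Z_THRESHOLD,
    Nomogram,
    resolve_pa_dilated,
    resolve_sv_dilated,
)


@dataclass(frozen=True)
class ScoredRecord:
    """All scores for one patient visit."""

    record: PhenotypeRecord
    sv_dilated: bool
    pa_dilated: bool
    systemic: SystemicScoreResult
    ghent2: Ghent2Result
    kidsms: KidSmsResult
    profile: str


def score_record(
    record: PhenotypeRecord,
    *,
    sv_nomogram: Nomogram = DEFAULT_SV_NOMOGRAM,
    pa_nomogram: Nomogram = DEFAULT_PA_NOMOGRAM,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> ScoredRecord:
    """Resolve vessel dilatation and run both scoring engines.

    Raises :class:`kidsms.errors.ComputabilityError` when a dilatation
    flag cannot be resolved — an unassessed vessel never defaults to
    not-dilated.
    """
    sv = resolve_sv_dilated(record, sv_nomogram, threshold)
    pa = resolve_pa_dilated(record, pa_nomogram, threshold)
    ghent2 = ghent2_diagnose(record, aorta_dilated=sv)
    kidsms = kidsms_stratify(record, sv_dilated=sv, pa_dilated=pa)
    return ScoredRecord(
        record=record,
        sv_dilated=sv,
        pa_dilated=pa,
        systemic=ghent2.systemic,
        ghent2=ghent2,
        kidsms=kidsms,
        profile=primary_profile(kidsms),
    )
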