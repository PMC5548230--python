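"""Echocardiographic Z-score nomograms for vessel dilatation.

A nomogram maps body-surface area to the expected diameter (and its
population SD) of a vessel, so that an observed diameter becomes a
Z-score ``(observed - expected) / SD``; dilatation is declared at
Z >= 2 by convention (inclusive, configurable).

Published pediatric nomograms differ in functional form and coefficient
values, so nomograms here are pluggable coefficient sets rather than a
hard-coded formula.  Two bundled defaults use a linear-in-BSA mean and
SD with representative pediatric magnitudes (see ``docs/methods.md``);
users validating against a specific reference population should load
their preferred published coefficients via :func:`load_nomogram`.

A record that carries a direct ``sv_dilated``/``pa_dilated`` flag is
taken at its word: :func:`resolve_sv_dilated` never consults the
nomogram in that case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .cohort import PhenotypeRecord
from .errors import ComputabilityError, CovariateRangeError

#: Conventional dilatation threshold on the Z-scale (inclusive).
DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class Nomogram:
    """Linear-in-BSA diameter nomogram: mean and SD in mm, BSA in m²."""

    name: str
    predicts: str  # "sinus_of_valsalva" or "pulmonary_artery"
    mean_intercept_mm: float
    mean_slope_mm_per_m2: float
    sd_intercept_mm: float
    sd_slope_mm_per_m2: float = 0.0
    bsa_range_m2: tuple[float, float] = (0.15, 2.2)

    def __post_init__(self) -> None:
        if self.predicts not in ("sinus_of_valsalva", "pulmonary_artery"):
            raise ValueError(f"unknown vessel: {self.predicts!r}")
        lo, hi = self.bsa_range_m2
        if not 0 < lo < hi:
            raise ValueError(f"invalid bsa_range_m2: {self.bsa_range_m2}")
        # mean and SD must stay strictly positive over the admissible range
        for bsa in (lo, hi):
            if self.mean_mm(bsa, _check=False) <= 0 or self.sd_mm(bsa, _check=False) <= 0:
                raise ValueError(
                    f"nomogram {self.name!r}: mean/SD not strictly positive over BSA range"
                )

    def _check_range(self, bsa_m2: float) -> None:
        lo, hi = self.bsa_range_m2
        if not lo <= bsa_m2 <= hi:
            raise CovariateRangeError(
                f"bsa_m2={bsa_m2} outside admissible range [{lo}, {hi}] "
                f"of nomogram {self.name!r}"
            )

    def mean_mm(self, bsa_m2: float, *, _check: bool = True) -> float:
        if _check:
            self._check_range(bsa_m2)
        return self.mean_intercept_mm + self.mean_slope_mm_per_m2 * bsa_m2

    def sd_mm(self, bsa_m2: float, *, _check: bool = True) -> float:
        if _check:
            self._check_range(bsa_m2)
        return self.sd_intercept_mm + self.sd_slope_mm_per_m2 * bsa_m2


#: Bundled default for the sinus of Valsalva (aortic root).
DEFAULT_SV_NOMOGRAM = Nomogram(
    name="bundled-linear-sv",
    predicts="sinus_of_valsalva",
    mean_intercept_mm=10.2,
    mean_slope_mm_per_m2=9.8,
    sd_intercept_mm=2.0,
)

#: Bundled default for the pulmonary artery.
DEFAULT_PA_NOMOGRAM = Nomogram(
    name="bundled-linear-pa",
    predicts="pulmonary_artery",
    mean_intercept_mm=9.0,
    mean_slope_mm_per_m2=8.0,
    sd_intercept_mm=1.8,
)


def zscore(nomogram: Nomogram, diameter_mm: float, bsa_m2: float) -> float:
    """Z-score of an observed diameter under the given nomogram."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter_mm must be positive, got {diameter_mm}")
    return (diameter_mm - nomogram.mean_mm(bsa_m2)) / nomogram.sd_mm(bsa_m2)


def is_dilated(z: float, threshold: float = DEFAULT_Z_THRESHOLD) -> bool:
    """Dilatation flag: Z at or above the threshold."""
    return z >= threshold


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Du Bois & Du Bois body-surface area (m²) from height and weight.

    BSA = 0.007184 * height^0.725 * weight^0.425.  Provided explicitly —
    the package never silently derives BSA from other fields.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def _resolve(
    flag: Optional[bool],
    diameter_mm: Optional[float],
    bsa_m2: Optional[float],
    nomogram: Nomogram,
    threshold: float,
    what: str,
    patient_id: str,
) -> bool:
    if flag is not None:
        return flag
    if diameter_mm is not None and bsa_m2 is not None:
        return is_dilated(zscore(nomogram, diameter_mm, bsa_m2), threshold)
    raise ComputabilityError(
        f"patient {patient_id!r}: {what} dilatation not resolvable — "
        f"needs either a direct flag or diameter plus BSA"
    )


def resolve_sv_dilated(
    record: PhenotypeRecord,
    nomogram: Nomogram = DEFAULT_SV_NOMOGRAM,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> bool:
    """Resolve sinus-of-Valsalva dilatation for one record.

    A direct ``sv_dilated`` flag always wins and the nomogram is never
    evaluated; otherwise the Z-score of ``sv_diameter_mm`` at
    ``bsa_m2`` is compared against the threshold.  A record with
    neither fails loudly rather than defaulting to not-dilated.
    """
    return _resolve(
        record.sv_dilated,
        record.sv_diameter_mm,
        record.bsa_m2,
        nomogram,
        threshold,
        "sinus-of-Valsalva",
        record.patient_id,
    )


def resolve_pa_dilated(
    record: PhenotypeRecord,
    nomogram: Nomogram = DEFAULT_PA_NOMOGRAM,
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> bool:
    """Resolve pulmonary-artery dilatation; same contract as for SV."""
    return _resolve(
        record.pa_dilated,
        record.pa_diameter_mm,
        record.bsa_m2,
        nomogram,
        threshold,
        "pulmonary-artery",
        record.patient_id,
    )


_NOMOGRAM_KEYS = {
    "name": str,
    "predicts": str,
    "mean_intercept_mm": float,
    "mean_slope_mm_per_m2": float,
    "sd_intercept_mm": float,
}
_OPTIONAL_KEYS = {"sd_slope_mm_per_m2": float, "bsa_range_m2": list}


def load_nomogram(path: Union[str, Path]) -> Nomogram:
    """Load a nomogram from a flat JSON key-value file.

    Required keys: ``name``, ``predicts`` (``sinus_of_valsalva`` or
    ``pulmonary_artery``), ``mean_intercept_mm``,
    ``mean_slope_mm_per_m2``, ``sd_intercept_mm``.  Optional:
    ``sd_slope_mm_per_m2`` (default 0) and ``bsa_range_m2`` (two-element
    list, default ``[0.15, 2.2]``).
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a JSON object")
    missing = sorted(set(_NOMOGRAM_KEYS) - set(raw))
    if missing:
        raise ValueError(f"{path}: missing key(s): {', '.join(missing)}")
    unknown = sorted(set(raw) - set(_NOMOGRAM_KEYS) - set(_OPTIONAL_KEYS))
    if unknown:
        raise ValueError(f"{path}: unknown key(s): {', '.join(unknown)}")
    kwargs = dict(raw)
    if "bsa_range_m2" in kwargs:
        kwargs["bsa_range_m2"] = tuple(float(x) for x in kwargs["bsa_range_m2"])
    return Nomogram(**kwargs)
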