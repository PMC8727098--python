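"""Charlson Comorbidity Index (CCI) scoring.

The CCI summarises a patient's comorbid burden as a weighted sum over
conditions; higher scores indicate higher ten-year mortality risk.  Every
patient in an ovarian-cancer cohort additionally carries the malignancy
base weight (+2 by default), which is why observed cohort scores start
at 2.  Together with ECOG performance status the CCI forms the
"life quality" profile of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: condition -> weight.  COPD and uncomplicated diabetes add +1 and
#: end-organ diabetes +3 (as used here); the remainder follows the classic
#: Charlson scheme.  `cad` (coronary artery disease) is scored 1 with the
#: ischaemic-heart-disease class; hypertension carries no Charlson weight.
DEFAULT_WEIGHTS: dict[str, int] = {
    "mi": 1,
    "chf": 1,
    "pvd": 1,
    "cvd": 1,
    "dementia": 1,
    "copd": 1,
    "connective_tissue": 1,
    "ulcer": 1,
    "mild_liver": 1,
    "diabetes_uncomplicated": 1,
    "hemiplegia": 2,
    "renal": 2,
    "diabetes_end_organ": 3,
    "cad": 1,
    "hypertension": 0,
}


@dataclass(frozen=True)
class CCIWeights:
    """Weight table plus the malignancy base applied to every patient."""

    weights: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    base_malignancy_weight: int = 2

    def __post_init__(self) -> None:
        for code, w in self.weights.items():
            if int(w) != w or w < 0:
                raise ValueError(f"weight for {code!r} must be a non-negative integer")


DEFAULT_CCI = CCIWeights()


def compute_cci(
    flags: Iterable[str],
    weights: CCIWeights = DEFAULT_CCI,
    include_malignancy_base: bool = True,
) -> int:
    """Score one patient's comorbidity flags.

    The two diabetes severities are mutually exclusive: when both flags are
    present only the severer (end-organ damage) is counted.

    Raises
    ------
    ValueError
        If a flag is not in the weight table (the known codes are listed).
    """
    flagset = set(flags)
    unknown = flagset - set(weights.weights)
    if unknown:
        raise ValueError(
            f"unknown comorbidity code(s) {sorted(unknown)}; "
            f"known codes: {sorted(weights.weights)}"
        )
    if "diabetes_end_organ" in flagset:
        flagset.discard("diabetes_uncomplicated")
    score = sum(weights.weights[c] for c in flagset)
    if include_malignancy_base:
        score += weights.base_malignancy_weight
    return int(score)


def attach_life_quality(cohort, weights: CCIWeights = DEFAULT_CCI) -> pd.DataFrame:
    """Life-quality profile: one row per patient with ``cci`` and ``ecog``.

    ECOG is passed through unchanged but validated to lie in 1..5.
    """
    rows = []
    for rec in cohort:
        if not 1 <= rec.ecog <= 5:
            raise ValueError(f"patient {rec.patient_id}: ecog {rec.ecog} outside 1..5")
        rows.append(
            {
                "patient_id": rec.patient_id,
                "cci": compute_cci(rec.comorbidity_flags, weights),
                "ecog": rec.ecog,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
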