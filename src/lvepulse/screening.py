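"""Cohort screening and sex-specific LVE labeling.

A subject qualifies for analysis when (1) the pulse wave was recorded at
the left upper arm, (2) at least five valid pulse cycles survive
preprocessing, and (3) echocardiographic LVDd is available and the record
is complete. Qualified subjects are labeled LVE when their left
ventricular diastolic diameter index LVDdI = LVDd / BSA strictly exceeds
36 mm/m^2 (males) or 37 mm/m^2 (females).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import MIN_VALID_CYCLES, preprocess_recording
from .synthetic import LVDDI_THRESHOLDS

__all__ = [
    "ScreenedCohort",
    "compute_bsa",
    "compute_lvddi",
    "label_lve",
    "screen",
]

# Mandatory fields for a record to count as complete.
_REQUIRED_FIELDS = ("sex", "height_cm", "weight_kg", "lvdd_mm")


def compute_bsa(height_cm: float, weight_kg: float,
                formula: str = "dubois") -> float:
    """Body surface area (m^2) from height (cm) and weight (kg).

    Du Bois: 0.007184 * height^0.725 * weight^0.425 (default).
    Mosteller: sqrt(height * weight / 3600).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula: {formula!r}")


def compute_lvddi(lvdd_mm: float, bsa_m2: float) -> float:
    """LVDd indexed to body surface area (mm/m^2)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    return lvdd_mm / bsa_m2


def label_lve(lvddi: float, sex: str) -> str:
    """Sex-specific LVE label; strict exceedance of the threshold."""
    if sex not in LVDDI_THRESHOLDS:
        raise ValueError(f"unknown sex code: {sex!r}")
    if not np.isfinite(lvddi):
        raise ValueError("LVDdI must be finite")
    return "lve" if lvddi > LVDDI_THRESHOLDS[sex] else "non_lve"


@dataclass
class ScreenedCohort:
    """Outcome of screening: qualified subjects with labels, exclusions with reasons."""

    qualified: pd.DataFrame   # subject rows + lvddi, label columns
    excluded: pd.DataFrame    # subject rows + exclusion_reason column

    @property
    def labels(self) -> pd.Series:
        return self.qualified.set_index("subject_id")["label"]

    @property
    def n_lve(self) -> int:
        return int((self.qualified["label"] == "lve").sum())

    @property
    def n_non_lve(self) -> int:
        return int((self.qualified["label"] == "non_lve").sum())

    def to_frame(self) -> pd.DataFrame:
        """Single table with qualified flag and exclusion reason per subject."""
        q = self.qualified.copy()
        q["qualified"] = True
        q["exclusion_reason"] = ""
        e = self.excluded.copy()
        e["qualified"] = False
        if "label" not in e.columns:
            e["label"] = ""
        out = pd.concat([q, e], ignore_index=True)
        return out.sort_values("subject_id").reset_index(drop=True)


def _exclusion_reason(row, n_valid_cycles: int) -> str | None:
    if row.get("measurement_site") != "left_upper_arm":
        return "wrong_measurement_site"
    if n_valid_cycles < MIN_VALID_CYCLES:
        return "insufficient_cycles"
    missing = [f for f in _REQUIRED_FIELDS
               if f not in row or pd.isna(row[f])]
    if "lvdd_mm" in missing or not row.get("has_tte", True):
        return "missing_lvdd"
    if missing or not row.get("complete", True):
        return "incomplete_record"
    return None


def screen(subjects: pd.DataFrame, recordings: dict | None = None,
           cycles_by_subject: dict | None = None,
           preprocessing_params=None) -> ScreenedCohort:
    """Apply the three screening criteria and label qualified subjects.

    Valid-cycle counts are established by running the preprocessing
    pipeline on ``recordings`` (or on precomputed ``cycles_by_subject``);
    if neither is given, the table's ``n_valid_cycles`` column is
    trusted. Order-independent: output rows are sorted by subject_id.
    """
    qualified_rows, excluded_rows = [], []
    for _, row in subjects.sort_values("subject_id").iterrows():
        row = row.copy()
        sid = row["subject_id"]
        if cycles_by_subject is not None and sid in cycles_by_subject:
            n_valid = sum(c.valid for c in cycles_by_subject[sid])
        elif recordings is not None and sid in recordings:
            cycles = preprocess_recording(recordings[sid], preprocessing_params)
            n_valid = sum(c.valid for c in cycles)
        else:
            n_valid = int(row.get("n_valid_cycles", 0))
        row["n_valid_cycles"] = n_valid

        reason = _exclusion_reason(row, n_valid)
        if reason is not None:
            row["exclusion_reason"] = reason
            excluded_rows.append(row)
            continue

        bsa = row.get("bsa_m2")
        if pd.isna(bsa):
            bsa = compute_bsa(row["height_cm"], row["weight_kg"])
            row["bsa_m2"] = bsa
        lvddi = compute_lvddi(row["lvdd_mm"], bsa)
        row["lvddi_mm_m2"] = lvddi
        row["label"] = label_lve(lvddi, row["sex"])
        qualified_rows.append(row)

    qualified = pd.DataFrame(qualified_rows).reset_index(drop=True)
    excluded = pd.DataFrame(excluded_rows).reset_index(drop=True)
    return ScreenedCohort(qualified=qualified, excluded=excluded)
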