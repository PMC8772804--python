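"""Core data containers: abundance tables and clinical tables.

An :class:`AbundanceTable` holds a samples x taxa matrix (integer counts or
relative abundances) together with a species -> genus taxonomy map. Samples are
always rows internally, whatever the on-disk orientation was.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "validate_clinical", "obesity_class", "CLINICAL_NUMERIC"]

#: numeric clinical covariates of the cohort schema (units in the README)
CLINICAL_NUMERIC = [
    "age", "weight", "BMI", "waist", "fat_mass", "glycemia", "insulinemia",
    "HOMA_IR", "HbA1c", "total_cholesterol", "HDL_cholesterol",
    "LDL_cholesterol", "triglycerides", "ASAT", "ALAT", "GGT",
    "creatinine", "uricemia", "BSS",
]

_REQUIRED_CLINICAL = ["subject_id", "visit", "age", "sex", "center", "weight", "BMI"]


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with taxonomy annotations.

    Parameters
    ----------
    counts :
        DataFrame indexed by sample id with taxon ids as columns. Integer
        counts unless ``relative`` is set.
    taxonomy :
        Mapping species id -> genus id. May be empty for genus-level tables.
    relative :
        True when rows are relative abundances summing to 1.
    rarefaction_depth :
        Set when the table has been rarefied; every row then sums to exactly
        this depth.
    filtered :
        True for a relative table that has passed the feature filter: rows
        then sum to at most 1 (retained features keep their original
        relative abundances; no renormalization).
    """

    counts: pd.DataFrame
    taxonomy: dict = field(default_factory=dict)
    relative: bool = False
    rarefaction_depth: int | None = None
    filtered: bool = False

    def __post_init__(self):
        self.counts = self.counts.astype(float) if self.relative else self.counts
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        x = self.counts.to_numpy()
        if x.size and (x < 0).any():
            bad = self.counts.columns[(x < 0).any(axis=0)].tolist()
            raise ValueError(f"negative abundances in taxa {bad[:5]}")
        if self.relative:
            sums = x.sum(axis=1)
            if x.size and not self.filtered and (sums == 0).any():
                zero = self.counts.index[sums == 0].tolist()
                raise ValueError(f"all-zero rows in relative table: {zero[:5]}")
            if x.size and self.filtered:
                if (sums > 1 + 1e-9).any():
                    raise ValueError("filtered relative rows must sum to at most 1")
            elif x.size and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative table rows must sum to 1 +/- 1e-9")
        elif x.size and not np.allclose(x, np.round(x)):
            raise ValueError("count table must hold integers (use relative=True for proportions)")
        if self.rarefaction_depth is not None and x.size:
            if not np.all(x.sum(axis=1) == self.rarefaction_depth):
                raise ValueError("rarefied rows must sum exactly to the rarefaction depth")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def to_relative(self) -> "AbundanceTable":
        """Row-normalize counts to relative abundances (all-zero rows forbidden)."""
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            zero = list(self.counts.index[sums == 0])
            raise ValueError(f"cannot normalize all-zero samples: {zero[:5]}")
        rel = self.counts.div(sums, axis=0)
        return AbundanceTable(rel, taxonomy=dict(self.taxonomy), relative=True)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample ids {missing[:5]}")
        return AbundanceTable(
            self.counts.loc[list(sample_ids)],
            taxonomy=dict(self.taxonomy),
            relative=self.relative,
            rarefaction_depth=self.rarefaction_depth,
            filtered=self.filtered,
        )


def obesity_class(bmi: float) -> str:
    """Four-level obesity class from BMI (kg/m^2).

    <30 non-obesity; 30<=BMI<35 obesity; 35<=BMI<40 severe obesity;
    >=40 morbid obesity.
    """
    if np.isnan(bmi):
        return np.nan
    if bmi < 30:
        return "non-obesity"
    if bmi < 35:
        return "obesity"
    if bmi < 40:
        return "severe obesity"
    return "morbid obesity"


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate and annotate a per-subject-visit clinical table.

    Enforces one row per subject x visit, V2 only for subjects with a V1 row,
    and derives (or checks) the ``obesity_class`` column from BMI. Missing
    values stay as explicit NaN; models drop them pairwise and report n_used.
    """
    missing = [c for c in _REQUIRED_CLINICAL if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    bad_visit = set(clinical["visit"].unique()) - {"V1", "V2"}
    if bad_visit:
        raise ValueError(f"visit must be V1/V2, found {sorted(bad_visit)}")
    dup = clinical.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        raise ValueError("duplicate subject_id x visit rows")
    v1 = set(clinical.loc[clinical.visit == "V1", "subject_id"])
    v2 = set(clinical.loc[clinical.visit == "V2", "subject_id"])
    orphans = v2 - v1
    if orphans:
        raise ValueError(f"V2 rows without a V1 row: {sorted(orphans)[:5]}")
    out = clinical.copy()
    derived = out["BMI"].map(obesity_class)
    if "obesity_class" in out.columns:
        mismatch = (out["obesity_class"].notna()) & (out["obesity_class"] != derived)
        if mismatch.any():
            raise ValueError("obesity_class inconsistent with BMI")
    out["obesity_class"] = derived
    return out
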