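"""Cohort preparation: eligibility, MMSE decline, exposure windows, prevalence filter.

Turns a raw visit table and a raw dispensation table into one analysis table per
follow-up, applying the study rules: patients need a baseline (AD or mixed
dementia) with MMSE and at least one follow-up with MMSE; a drug exposure at a
visit means a dispensation within the 100 days preceding (and including) the
visit date; only drugs used in more than 5% of all cohort observations are kept;
and the per-visit MMSE decline is the difference to the most recent prior
non-missing MMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

ELIGIBLE_DIAGNOSES = frozenset({"AD", "MD"})

#: name <-> ATC map for the drugs named in the study; extensible by the caller.
ATC_NAME_MAP: dict[str, str] = {
    "N06DA02": "donepezil",
    "N06DA03": "rivastigmine",
    "N06DA04": "galantamine",
    "N06DX01": "memantine",
    "C10AA05": "atorvastatin",
    "C10AA01": "simvastatin",
    "B01AA03": "warfarin",
    "N05CF01": "zopiclone",
    "A10BA02": "metformin",
    "N05BA04": "oxazepam",
    "N02BE01": "paracetamol",
    "B03BA01": "cyanocobalamin",
    "C08CA02": "felodipine",
    "C03CA01": "furosemide",
    "B03BB01": "folic acid",
    "N06AX11": "mirtazapine",
}


@dataclass
class ExposureMatrix:
    """Binary drug-exposure indicators per (patient, visit) after filtering.

    ``data`` is indexed by (patient_id, followup_index) over every cohort
    observation, with one 0/1 column per included ATC code; ``drugs`` lists the
    included codes sorted by decreasing prevalence, and ``prevalence`` maps each
    included code to its overall usage proportion.
    """

    data: pd.DataFrame
    drugs: list[str]
    prevalence: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data[self.drugs]


def select_eligible(visits: pd.DataFrame) -> tuple[pd.Index, dict[str, int]]:
    """Apply the study-population rules, returning eligible patients and a flowchart.

    A patient is retained when the baseline diagnosis is AD or mixed dementia,
    the baseline MMSE is non-missing, and at least one follow-up has a
    non-missing MMSE. Exclusion counts are reported in rule order (each patient
    counted against the first rule that removes them), so counts plus the
    included total equal the number of input patients.
    """
    if visits.empty:
        return pd.Index([]), {
            "input_patients": 0,
            "excluded_diagnosis": 0,
            "excluded_no_baseline_mmse": 0,
            "excluded_no_followup_mmse": 0,
            "included": 0,
        }
    baseline = visits[visits["followup_index"] == 0]
    baseline = baseline.drop_duplicates("patient_id", keep="first")
    all_patients = pd.Index(visits["patient_id"].unique())

    good_dx = baseline.loc[
        baseline["diagnosis"].isin(ELIGIBLE_DIAGNOSES), "patient_id"
    ]
    has_baseline_mmse = baseline.loc[baseline["mmse"].notna(), "patient_id"]
    followups = visits[(visits["followup_index"] > 0) & visits["mmse"].notna()]
    has_followup_mmse = pd.Index(followups["patient_id"].unique())

    # patients with no baseline row at all fail the diagnosis rule first
    step1 = pd.Index(good_dx)
    step2 = step1.intersection(pd.Index(has_baseline_mmse))
    step3 = step2.intersection(has_followup_mmse)
    counts = {
        "input_patients": len(all_patients),
        "excluded_diagnosis": len(all_patients) - len(step1),
        "excluded_no_baseline_mmse": len(step1) - len(step2),
        "excluded_no_followup_mmse": len(step2) - len(step3),
        "included": len(step3),
    }
    return step3, counts


def compute_decline(patient_visits: pd.DataFrame) -> pd.Series:
    """Per-visit MMSE decline for one patient, indexed by followup_index.

    decline = current MMSE minus the most recent prior non-missing MMSE
    (negative values mean deterioration); the baseline and any visit without a
    prior non-missing MMSE get a missing decline.
    """
    v = patient_visits.sort_values("followup_index")
    mmse = v["mmse"].astype(float)
    prev = mmse.ffill().shift()
    decline = mmse - prev
    decline.index = v["followup_index"].to_numpy()
    return decline


def add_decline(visits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_decline` over a whole visit table.

    Returns a copy with an ``mmse_decline`` column.
    """
    v = visits.sort_values(["patient_id", "followup_index"], kind="mergesort").copy()
    grouped = v.groupby("patient_id", sort=False)["mmse"]
    prev = grouped.ffill().groupby(v["patient_id"], sort=False).shift()
    v["mmse_decline"] = v["mmse"] - prev
    return v


def _as_day_number(values: pd.Series) -> np.ndarray:
    """Calendar dates -> integer day offsets; integer inputs pass through."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype="int64")
    return pd.to_datetime(values).to_numpy().astype("datetime64[D]").astype("int64")


def build_exposure(
    visits: pd.DataFrame,
    dispensations: pd.DataFrame,
    window_days: int = 100,
) -> pd.DataFrame:
    """Raw binary exposure per (visit, ATC code) under the dispensation-window rule.

    ``exposure[(patient, visit), drug] = 1`` iff a dispensation of the drug for
    the patient falls in the closed window
    ``[visit_date − window_days, visit_date]`` (a same-day dispensation counts).
    Dates may be calendar dates or integer day offsets, consistently across the
    two tables. Dispensations for patients absent from the visit table are
    ignored with a logged warning. The result covers every visit row (rows with
    no exposure are all-zero) and every ATC code seen in the dispensations.
    """
    if window_days < 0:
        raise ConfigurationError("window_days must be nonnegative")
    keys = pd.MultiIndex.from_frame(
        visits[["patient_id", "followup_index"]], names=["patient_id", "followup_index"]
    )
    codes = sorted(dispensations["atc_code"].unique()) if len(dispensations) else []
    out = pd.DataFrame(0, index=keys, columns=codes, dtype=np.int8)
    if not len(dispensations) or not len(visits):
        return out

    known = dispensations["patient_id"].isin(set(visits["patient_id"]))
    if not known.all():
        logger.warning(
            "ignoring %d dispensations for patients not in the visit table",
            int((~known).sum()),
        )
        dispensations = dispensations[known]

    v = visits[["patient_id", "followup_index"]].copy()
    v["visit_day"] = _as_day_number(visits["visit_date"])
    d = dispensations[["patient_id", "atc_code"]].copy()
    d["dispense_day"] = _as_day_number(dispensations["dispense_date"])
    pairs = v.merge(d, on="patient_id", how="inner")
    in_window = (pairs["dispense_day"] >= pairs["visit_day"] - window_days) & (
        pairs["dispense_day"] <= pairs["visit_day"]
    )
    hits = pairs.loc[in_window, ["patient_id", "followup_index", "atc_code"]].drop_duplicates()
    if len(hits):
        row_pos = {key: i for i, key in enumerate(keys)}
        col_pos = {code: j for j, code in enumerate(codes)}
        rows = [row_pos[k] for k in zip(hits["patient_id"], hits["followup_index"])]
        cols = [col_pos[c] for c in hits["atc_code"]]
        values = out.to_numpy()
        values[rows, cols] = 1
        out = pd.DataFrame(values, index=keys, columns=codes)
    return out


def filter_prevalence(
    raw_exposure: pd.DataFrame, threshold: float = 0.05
) -> ExposureMatrix:
    """Keep drugs used in strictly more than ``threshold`` of all observations.

    Prevalence is computed over every observation (baseline and follow-ups) of
    the cohort passed in; the kept list is sorted by decreasing prevalence.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError("threshold must be in the open interval (0, 1)")
    prevalence = raw_exposure.mean(axis=0)
    kept = prevalence[prevalence > threshold].sort_values(ascending=False)
    return ExposureMatrix(
        data=raw_exposure[kept.index.tolist()],
        drugs=kept.index.tolist(),
        prevalence=kept,
    )


def build_analysis_tables(
    visits: pd.DataFrame,
    exposure: ExposureMatrix,
    followups: tuple[int, ...] = (1, 2, 3),
) -> dict[int, pd.DataFrame]:
    """One analysis table per follow-up: clustering variables plus exposure vector.

    Each table holds only rows with both MMSE score and MMSE decline present,
    with columns ``patient_id, mmse_score, mmse_decline`` followed by one binary
    column per included drug.
    """
    v = visits if "mmse_decline" in visits.columns else add_decline(visits)
    tables: dict[int, pd.DataFrame] = {}
    for f in followups:
        rows = v[(v["followup_index"] == f) & v["mmse"].notna() & v["mmse_decline"].notna()]
        table = pd.DataFrame(
            {
                "patient_id": rows["patient_id"].to_numpy(),
                "mmse_score": rows["mmse"].to_numpy(dtype=float),
                "mmse_decline": rows["mmse_decline"].to_numpy(dtype=float),
            }
        )
        keys = list(zip(rows["patient_id"], rows["followup_index"]))
        vectors = exposure.data.reindex(keys).fillna(0).astype(np.int8)
        for drug in exposure.drugs:
            table[drug] = vectors[drug].to_numpy()
        tables[f] = table.reset_index(drop=True)
    return tables


def prepare_tables(
    visits: pd.DataFrame,
    dispensations: pd.DataFrame,
    window_days: int = 100,
    prevalence_threshold: float = 0.05,
    followups: tuple[int, ...] = (1, 2, 3),
) -> tuple[dict[int, pd.DataFrame], ExposureMatrix, dict[str, int]]:
    """Full preparation pipeline: eligibility -> decline -> windows -> filter -> tables."""
    eligible, counts = select_eligible(visits)
    cohort = visits[visits["patient_id"].isin(eligible)]
    if cohort.empty:
        raise InputError("no eligible patients in the visit table")
    # dispensations of excluded patients are dropped by design, not "unknown"
    dispensations = dispensations[dispensations["patient_id"].isin(eligible)]
    raw = build_exposure(cohort, dispensations, window_days=window_days)
    exposure = filter_prevalence(raw, threshold=prevalence_threshold)
    tables = build_analysis_tables(add_decline(cohort), exposure, followups=followups)
    return tables, exposure, counts
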