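"""Synthetic dementia-registry generator with known ground truth.

Emulates a national cognitive-disorders registry linked to a prescribed-drug
registry: ~15k patients with a baseline visit and up to three follow-ups under
attrition, an MMSE trajectory whose per-follow-up (score, decline) pairs are
drawn from a four-component Gaussian mixture (the four cognitive archetypes:
high/low MMSE crossed with absent/marked decline), and per-drug dispensation
events whose probability of falling inside the 100-day pre-visit exposure window
depends on the patient's current mixture component through injected log-odds
offsets. Because the true component of every observation and the true exposure
probability of every drug are recorded, every downstream stage (eligibility,
windowing, clustering, screening) can be tested for parameter recovery without
any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

N_COMPONENTS = 4

#: epoch used to materialize day offsets as ISO calendar dates
_EPOCH = np.datetime64("2008-01-01")


@dataclass(frozen=True)
class DrugSpec:
    """One simulated medication.

    Parameters
    ----------
    name : str
        Human-readable drug name.
    atc_code : str
        WHO Anatomical Therapeutic Chemical code identifying the drug.
    baseline_prevalence : float
        Exposure probability, on the probability scale, for a patient in a
        component with zero log-odds offset. Must lie in (0, 1).
    log_odds_offsets : tuple of 4 floats
        Additive shift on the logit scale applied according to the patient's
        current true component (archetypes 1-4). Zero offsets make the drug a
        null drug (independent of cognition).
    """

    name: str
    atc_code: str
    baseline_prevalence: float
    log_odds_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def component_probabilities(self) -> np.ndarray:
        """True per-component exposure probabilities (baseline prevalence + offsets)."""
        base = math.log(self.baseline_prevalence / (1.0 - self.baseline_prevalence))
        logits = base + np.asarray(self.log_odds_offsets, dtype=float)
        return 1.0 / (1.0 + np.exp(-logits))


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic registry.

    ``component_means`` may be a (4, 2) array (same archetype means at every
    follow-up) or (max_followups, 4, 2). ``attrition`` is the probability of
    dropping out before each successive follow-up: a scalar (same for every
    interval) or a sequence of length ``max_followups``.
    """

    n_patients: int
    max_followups: int = 3
    component_means: np.ndarray = field(default=None)  # (4,2) or (F,4,2)
    component_covariances: np.ndarray = field(default=None)  # (4,2,2)
    component_weights: np.ndarray = field(default=None)  # (4,)
    drug_specs: list[DrugSpec] = field(default_factory=list)
    attrition: float | Sequence[float] = 0.0
    seed: int = 0
    # secondary realism knobs -------------------------------------------------
    window_days: int = 100  # exposed dispensations are placed inside this window
    missing_mmse_prob: float = 0.0  # per follow-up visit
    diagnosis_probs: dict = field(
        default_factory=lambda: {"AD": 0.68, "MD": 0.31, "other": 0.01}
    )
    female_prob: float = 0.6038
    age_at_diagnosis_mean: float = 77.3
    age_at_diagnosis_sd: float = 7.6
    visit_gap_mean: float = 380.0
    visit_gap_sd: float = 120.0
    visit_gap_min: int = 210
    visit_gap_max: int = 900
    out_of_window_prob: float = 0.3  # unexposed visits w/ a stale dispensation

    def __post_init__(self) -> None:
        if self.component_means is not None:
            self.component_means = np.asarray(self.component_means, dtype=float)
        if self.component_covariances is not None:
            self.component_covariances = np.asarray(self.component_covariances, dtype=float)
        if self.component_weights is not None:
            self.component_weights = np.asarray(self.component_weights, dtype=float)

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first offending field."""
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigurationError("n_patients must be an integer >= 1")
        if self.max_followups < 1:
            raise ConfigurationError("max_followups must be >= 1")
        means = self.means_per_followup()
        if means.shape != (self.max_followups, N_COMPONENTS, 2):
            raise ConfigurationError(
                "component_means must have shape (4, 2) or (max_followups, 4, 2)"
            )
        covs = self.component_covariances
        if covs is None or covs.shape != (N_COMPONENTS, 2, 2):
            raise ConfigurationError("component_covariances must have shape (4, 2, 2)")
        for i, cov in enumerate(covs):
            if not np.allclose(cov, cov.T):
                raise ConfigurationError(f"component_covariances[{i}] is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-12:
                raise ConfigurationError(
                    f"component_covariances[{i}] is not positive semidefinite"
                )
        w = self.component_weights
        if w is None or w.shape != (N_COMPONENTS,):
            raise ConfigurationError("component_weights must have shape (4,)")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigurationError("component_weights must be nonnegative and sum to 1")
        for spec in self.drug_specs:
            if not (0.0 < spec.baseline_prevalence < 1.0):
                raise ConfigurationError(
                    f"drug_specs[{spec.name}].baseline_prevalence must be in (0, 1)"
                )
            if len(spec.log_odds_offsets) != N_COMPONENTS:
                raise ConfigurationError(
                    f"drug_specs[{spec.name}].log_odds_offsets must have length 4"
                )
        for j, a in enumerate(self.attrition_per_interval()):
            if not (0.0 <= a < 1.0):
                raise ConfigurationError(f"attrition[{j}] must be in [0, 1)")
        if not (0.0 <= self.missing_mmse_prob < 1.0):
            raise ConfigurationError("missing_mmse_prob must be in [0, 1)")

    def means_per_followup(self) -> np.ndarray:
        means = self.component_means
        if means is None:
            return np.empty((self.max_followups, 0, 0))
        if means.ndim == 2:
            return np.broadcast_to(means, (self.max_followups, *means.shape)).copy()
        return means

    def attrition_per_interval(self) -> np.ndarray:
        if np.isscalar(self.attrition):
            return np.full(self.max_followups, float(self.attrition))
        return np.asarray(self.attrition, dtype=float)

    # -- (de)serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "n_patients": int(self.n_patients),
            "max_followups": int(self.max_followups),
            "component_means": self.component_means.tolist(),
            "component_covariances": self.component_covariances.tolist(),
            "component_weights": self.component_weights.tolist(),
            "drug_specs": [
                {
                    "name": d.name,
                    "atc_code": d.atc_code,
                    "baseline_prevalence": d.baseline_prevalence,
                    "log_odds_offsets": list(d.log_odds_offsets),
                }
                for d in self.drug_specs
            ],
            "attrition": (
                float(self.attrition)
                if np.isscalar(self.attrition)
                else [float(a) for a in self.attrition]
            ),
            "seed": int(self.seed),
            "window_days": int(self.window_days),
            "missing_mmse_prob": float(self.missing_mmse_prob),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["drug_specs"] = [
            DrugSpec(
                name=d["name"],
                atc_code=d["atc_code"],
                baseline_prevalence=d["baseline_prevalence"],
                log_odds_offsets=tuple(d["log_odds_offsets"]),
            )
            for d in payload.get("drug_specs", [])
        ]
        return cls(**payload)


@dataclass
class GroundTruth:
    """True generating state of a synthetic cohort.

    components : DataFrame(patient_id, followup_index, component) with component
        in 1..4 for every follow-up visit actually generated.
    exposure_probabilities : DataFrame(drug, atc_code, component, probability)
        with the true per-component exposure probability of every drug.
    """

    components: pd.DataFrame
    exposure_probabilities: pd.DataFrame

    def to_csv(self, components_path, probabilities_path) -> None:
        self.components.to_csv(components_path, index=False)
        self.exposure_probabilities.to_csv(probabilities_path, index=False)


# ---------------------------------------------------------------------------
# default study conditions


def _named_drugs() -> list[DrugSpec]:
    """The 16 medications named in the study plus their ATC codes.

    Offsets encode the reported direction of each association: dementia drugs
    and the repurposing candidates (statins, warfarin, zopiclone, metformin)
    lean toward the good-cognition archetypes; memantine, oxazepam and the
    frailty-marker drugs lean toward the poor-cognition archetypes.
    """
    return [
        DrugSpec("donepezil", "N06DA02", 0.35, (0.5, 0.3, -0.3, -0.5)),
        DrugSpec("rivastigmine", "N06DA03", 0.12, (0.4, 0.2, -0.2, -0.4)),
        DrugSpec("galantamine", "N06DA04", 0.15, (0.4, 0.2, -0.2, -0.4)),
        DrugSpec("memantine", "N06DX01", 0.18, (-0.6, -0.2, 0.3, 0.6)),
        DrugSpec("atorvastatin", "C10AA05", 0.10, (0.35, 0.1, -0.1, -0.35)),
        DrugSpec("simvastatin", "C10AA01", 0.14, (0.3, 0.1, -0.1, -0.3)),
        DrugSpec("warfarin", "B01AA03", 0.09, (0.45, 0.0, -0.2, -0.3)),
        DrugSpec("zopiclone", "N05CF01", 0.16, (0.3, 0.0, -0.1, -0.3)),
        DrugSpec("metformin", "A10BA02", 0.08, (0.4, 0.1, -0.1, -0.4)),
        DrugSpec("oxazepam", "N05BA04", 0.12, (-0.5, -0.1, 0.2, 0.5)),
        DrugSpec("paracetamol", "N02BE01", 0.30, (-0.25, 0.0, 0.1, 0.25)),
        DrugSpec("cyanocobalamin", "B03BA01", 0.18, (-0.15, 0.0, 0.1, 0.15)),
        DrugSpec("felodipine", "C08CA02", 0.10, (-0.25, 0.0, 0.1, 0.25)),
        DrugSpec("furosemide", "C03CA01", 0.14, (-0.3, 0.0, 0.15, 0.3)),
        DrugSpec("folic acid", "B03BB01", 0.12, (-0.3, 0.0, 0.15, 0.3)),
        DrugSpec("mirtazapine", "N06AX11", 0.10, (-0.3, 0.0, 0.1, 0.3)),
    ]


def default_config(n_patients: int = 15000, seed: int = 20240101) -> SyntheticConfig:
    """Default synthetic study conditions.

    Four well-separated archetype components in the (MMSE score, MMSE decline)
    plane — (1) high score, no decline; (2) high score, marked decline;
    (3) low score, little decline; (4) high decliners — with mixture weights
    shaped like the reported first-follow-up cluster sizes, 26 medications
    (16 named drugs with direction-consistent injected effects plus 10 null
    placeholder drugs) all with marginal prevalence above 5%, and per-interval
    attrition reproducing the scale of the observed cohort shrinkage across
    three follow-ups.
    """
    means = np.array(
        [
            [25.0, 1.0],  # 1: high MMSE, improvement / no decline
            [23.0, -5.5],  # 2: high MMSE with cognitive decline
            [15.0, -0.5],  # 3: low MMSE, little decline
            [12.0, -10.0],  # 4: high decliners
        ]
    )
    covs = np.array(
        [
            [[4.0, 0.0], [0.0, 1.44]],
            [[4.0, 0.0], [0.0, 2.25]],
            [[6.25, 0.0], [0.0, 2.25]],
            [[6.25, 0.0], [0.0, 4.0]],
        ]
    )
    weights = np.array([0.39, 0.29, 0.195, 0.125])
    drugs = list(_named_drugs())
    placeholder_prevalences = [0.07, 0.09, 0.11, 0.13, 0.15, 0.18, 0.21, 0.25, 0.30, 0.36]
    for i, prev in enumerate(placeholder_prevalences, start=17):
        drugs.append(DrugSpec(f"placeholder{i:02d}", f"X99XX{i:02d}", prev))
    return SyntheticConfig(
        n_patients=n_patients,
        max_followups=3,
        component_means=means,
        component_covariances=covs,
        component_weights=weights,
        drug_specs=drugs,
        attrition=(0.10, 0.65, 0.60),
        seed=seed,
        missing_mmse_prob=0.02,
    )


def null_config(
    n_patients: int = 3000,
    n_drugs: int = 26,
    prevalence_range: tuple[float, float] = (0.05, 0.40),
    seed: int = 0,
) -> SyntheticConfig:
    """Default conditions with every drug effect removed (all offsets zero).

    Drug prevalences are spread evenly over ``prevalence_range``. Used to study
    the behavior of the screen when no drug is truly associated with cognition.
    """
    cfg = default_config(n_patients=n_patients, seed=seed)
    lo, hi = prevalence_range
    prevalences = np.linspace(lo + 0.01, hi, n_drugs)
    cfg.drug_specs = [
        DrugSpec(f"nulldrug{i + 1:02d}", f"X00XX{i + 1:02d}", float(p))
        for i, p in enumerate(prevalences)
    ]
    return cfg


# ---------------------------------------------------------------------------
# generation


def _streams(seed: int, n_drugs: int) -> dict:
    """Independent substreams so that e.g. adding a drug never perturbs trajectories."""
    root = np.random.SeedSequence(seed)
    demo, traj, attr, dates, drugs_parent = root.spawn(5)
    return {
        "demographics": np.random.default_rng(demo),
        "trajectories": np.random.default_rng(traj),
        "attrition": np.random.default_rng(attr),
        "dates": np.random.default_rng(dates),
        "drugs": [np.random.default_rng(s) for s in drugs_parent.spawn(n_drugs)],
    }


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns ``(visits, dispensations, ground_truth)``. The visit table has one
    row per (patient, visit) with columns ``patient_id, followup_index,
    visit_date, days_from_baseline, mmse, diagnosis, sex, age_at_diagnosis``;
    follow-up index 0 is the baseline. The dispensation table has columns
    ``patient_id, atc_code, dispense_date, ddd_quantity``.

    Construction: each patient draws a true archetype component per follow-up;
    the follow-up-1 draw of (score, decline) fixes both the baseline MMSE
    (score − decline) and the follow-up-1 MMSE; later follow-ups take their
    MMSE from the drawn score, so their realized decline (current − previous
    visit MMSE) reflects component transitions. All MMSE values are rounded to
    integers and clipped to 0–30, so realized declines computed from the table
    are exactly consistent with consecutive MMSE values. Drug exposure at a
    visit is Bernoulli on the logit scale (baseline prevalence plus the current
    component's offset); exposed visits receive a dispensation inside the
    ``window_days`` pre-visit window, unexposed visits either none or a stale
    one strictly outside it. Identical config and seed give identical tables.
    """
    config.validate()
    n = int(config.n_patients)
    n_fu = int(config.max_followups)
    means = config.means_per_followup()
    covs = config.component_covariances
    weights = config.component_weights
    streams = _streams(config.seed, len(config.drug_specs))

    # demographics ------------------------------------------------------------
    rng = streams["demographics"]
    female = rng.random(n) < config.female_prob
    age_dx = np.round(
        rng.normal(config.age_at_diagnosis_mean, config.age_at_diagnosis_sd, n), 1
    )
    diag_labels = list(config.diagnosis_probs)
    diag_p = np.array([config.diagnosis_probs[k] for k in diag_labels], dtype=float)
    diagnosis = rng.choice(diag_labels, size=n, p=diag_p / diag_p.sum())

    # attrition: visit f is observed iff the patient survived every interval <= f
    rng = streams["attrition"]
    attr = config.attrition_per_interval()
    survive = rng.random((n, n_fu)) >= attr[None, :]
    present = np.cumprod(survive, axis=1).astype(bool)  # (n, n_fu), follow-ups 1..F

    # trajectories ------------------------------------------------------------
    rng = streams["trajectories"]
    components = np.empty((n, n_fu), dtype=int)
    for f in range(n_fu):
        components[:, f] = rng.choice(N_COMPONENTS, size=n, p=weights)
    chol = np.linalg.cholesky(covs + 1e-12 * np.eye(2))
    normals = rng.standard_normal((n, n_fu, 2))
    draws = np.empty((n, n_fu, 2))
    for f in range(n_fu):
        c = components[:, f]
        draws[:, f] = means[f, c] + np.einsum("nij,nj->ni", chol[c], normals[:, f])
    missing = rng.random((n, n_fu)) < config.missing_mmse_prob

    def _mmse(values: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(values), 0, 30).astype(int)

    baseline_mmse = _mmse(draws[:, 0, 0] - draws[:, 0, 1])
    followup_mmse = _mmse(draws[:, :, 0])

    # visit timing ------------------------------------------------------------
    rng = streams["dates"]
    base_offset = rng.integers(0, 2400, size=n)
    gaps = np.clip(
        np.rint(rng.normal(config.visit_gap_mean, config.visit_gap_sd, (n, n_fu))),
        config.visit_gap_min,
        config.visit_gap_max,
    ).astype(int)
    days_from_baseline = np.cumsum(gaps, axis=1)

    # assemble visit rows ------------------------------------------------------
    patient_ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    rows = {
        "patient_id": [],
        "followup_index": [],
        "days_from_baseline": [],
        "mmse": [],
    }
    rows["patient_id"].append(patient_ids)
    rows["followup_index"].append(np.zeros(n, dtype=int))
    rows["days_from_baseline"].append(np.zeros(n, dtype=int))
    rows["mmse"].append(baseline_mmse.astype(float))
    truth_pid, truth_fu, truth_comp = [], [], []
    for f in range(n_fu):
        mask = present[:, f]
        rows["patient_id"].append(patient_ids[mask])
        rows["followup_index"].append(np.full(mask.sum(), f + 1, dtype=int))
        rows["days_from_baseline"].append(days_from_baseline[mask, f])
        mmse_col = followup_mmse[:, f].astype(float)
        mmse_col[missing[:, f]] = np.nan
        rows["mmse"].append(mmse_col[mask])
        truth_pid.append(patient_ids[mask])
        truth_fu.append(np.full(mask.sum(), f + 1, dtype=int))
        truth_comp.append(components[mask, f] + 1)

    visits = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    visits = visits.merge(
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "diagnosis": diagnosis,
                "sex": np.where(female, "F", "M"),
                "age_at_diagnosis": age_dx,
                "baseline_offset": base_offset,
            }
        ),
        on="patient_id",
    )
    visits["visit_date"] = _EPOCH + (
        visits["baseline_offset"] + visits["days_from_baseline"]
    ).to_numpy().astype("timedelta64[D]")
    visits = visits.drop(columns="baseline_offset")
    visits = visits.sort_values(["patient_id", "followup_index"], kind="mergesort")
    visits = visits[
        [
            "patient_id",
            "followup_index",
            "visit_date",
            "days_from_baseline",
            "mmse",
            "diagnosis",
            "sex",
            "age_at_diagnosis",
        ]
    ].reset_index(drop=True)

    # drug exposures and dispensations ----------------------------------------
    # current component per visit row: baseline shares the follow-up-1 component.
    visit_pid = visits["patient_id"].to_numpy()
    visit_fu = visits["followup_index"].to_numpy()
    pid_index = {p: i for i, p in enumerate(patient_ids)}
    row_patient = np.fromiter((pid_index[p] for p in visit_pid), dtype=int, count=len(visits))
    row_component = components[row_patient, np.maximum(visit_fu - 1, 0)]
    visit_day = visits["visit_date"].to_numpy().astype("datetime64[D]")

    disp_frames = []
    window = int(config.window_days)
    for spec, rng_d in zip(config.drug_specs, streams["drugs"]):
        probs = spec.component_probabilities()[row_component]
        exposed = rng_d.random(len(visits)) < probs
        stale = (~exposed) & (rng_d.random(len(visits)) < config.out_of_window_prob)
        lag = np.where(
            exposed,
            rng_d.integers(0, window + 1, size=len(visits)),
            rng_d.integers(window + 1, 2 * window + 1, size=len(visits)),
        )
        emit = exposed | stale
        disp_frames.append(
            pd.DataFrame(
                {
                    "patient_id": visit_pid[emit],
                    "atc_code": spec.atc_code,
                    "dispense_date": visit_day[emit] - lag[emit].astype("timedelta64[D]"),
                    "ddd_quantity": np.round(
                        np.clip(rng_d.normal(30.0, 10.0, int(emit.sum())), 1.0, None), 1
                    ),
                }
            )
        )
    if disp_frames:
        dispensations = pd.concat(disp_frames, ignore_index=True)
        dispensations = dispensations.sort_values(
            ["patient_id", "atc_code", "dispense_date"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        dispensations = pd.DataFrame(
            columns=["patient_id", "atc_code", "dispense_date", "ddd_quantity"]
        )

    truth_components = pd.DataFrame(
        {
            "patient_id": np.concatenate(truth_pid) if truth_pid else [],
            "followup_index": np.concatenate(truth_fu) if truth_fu else [],
            "component": np.concatenate(truth_comp) if truth_comp else [],
        }
    ).sort_values(["patient_id", "followup_index"], kind="mergesort").reset_index(drop=True)
    truth_probs = pd.DataFrame(
        [
            {
                "drug": spec.name,
                "atc_code": spec.atc_code,
                "component": c + 1,
                "probability": p,
            }
            for spec in config.drug_specs
            for c, p in enumerate(spec.component_probabilities())
        ]
    )
    return visits, dispensations, GroundTruth(truth_components, truth_probs)


def planted_effect_config(
    drug_name: str = "planteddrug",
    prevalence: float = 0.15,
    offset: float = 0.8,
    component: int = 4,
    n_patients: int = 8000,
    n_null_drugs: int = 25,
    seed: int = 0,
) -> SyntheticConfig:
    """Null cohort plus a single drug with a log-odds offset in one component.

    Convenience constructor for sensitivity studies: equal component weights so
    every cluster is well populated, ``n_null_drugs`` null drugs, and one drug
    whose exposure odds are shifted by ``offset`` for patients in the given
    archetype ``component`` (1-4).
    """
    cfg = null_config(n_patients=n_patients, n_drugs=n_null_drugs, seed=seed)
    cfg.component_weights = np.full(N_COMPONENTS, 0.25)
    offsets = [0.0] * N_COMPONENTS
    offsets[component - 1] = offset
    cfg.drug_specs = list(cfg.drug_specs) + [
        DrugSpec(drug_name, "X99XX99", prevalence, tuple(offsets))
    ]
    return cfg
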