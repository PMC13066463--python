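"""Replicated synthetic-data studies of the screen's operating characteristics.

These are the package's self-validation experiments: the empirical false
discovery rate of the full screen when no drug is truly associated with
cognition, and the sensitivity of the screen to a planted log-odds effect.
Both generate fresh synthetic cohorts per replicate, run the complete
pipeline (preparation + Monte-Carlo screen) and measure outcomes against the
generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import prepare_tables
from .screen import run_screen
from .synthetic import generate_cohort, null_config, planted_effect_config


@dataclass
class NullFdrStudy:
    """Result of :func:`null_fdr_study`.

    ``mean_fdp`` is the false-discovery proportion averaged over every
    (cluster pair, follow-up) test family of every replicate — the quantity
    the per-family Benjamini-Hochberg correction controls at q — and
    ``se`` its Monte-Carlo standard error over replicates. Under the null
    every declared association is false, so a family's FDP is 1 when it
    declares anything and 0 otherwise.
    """

    mean_fdp: float
    se: float
    n_replicates: int
    n_families: int
    total_declared: int
    per_replicate: np.ndarray


def null_fdr_study(
    n_replicates: int = 200,
    n_patients: int = 3000,
    n_drugs: int = 26,
    n_simulations: int = 20,
    q: float = 0.05,
    stability_threshold: float = 0.80,
    seed: int = 0,
) -> NullFdrStudy:
    """Empirical FDR of the screen under a global-null generator.

    Each replicate draws a cohort in which every drug's exposure is independent
    of the patient's cognition component (all log-odds offsets zero,
    prevalences spread over 0.05-0.40), runs the full screen, and records the
    false-discovery proportion of every (cluster pair, follow-up) family.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(2 * n_replicates) % (2**31)
    per_replicate = np.empty(n_replicates)
    n_families = 0
    total_declared = 0
    for r in range(n_replicates):
        cfg = null_config(
            n_patients=n_patients, n_drugs=n_drugs, seed=int(rep_seeds[2 * r])
        )
        visits, dispensations, _ = generate_cohort(cfg)
        tables, _, _ = prepare_tables(visits, dispensations)
        results = run_screen(
            tables,
            n_simulations=n_simulations,
            q=q,
            stability_threshold=stability_threshold,
            seed=int(rep_seeds[2 * r + 1]),
            or_policy="none",
        )
        families = results.aggregates.groupby(
            ["followup_index", "cluster_a", "cluster_b"]
        )["final_significant"].sum()
        # every declaration is false under the null: FDP = 1{R > 0} per family
        per_replicate[r] = (families > 0).mean()
        n_families = len(families)
        total_declared += int(families.sum())
    return NullFdrStudy(
        mean_fdp=float(per_replicate.mean()),
        se=float(per_replicate.std(ddof=1) / np.sqrt(n_replicates)),
        n_replicates=n_replicates,
        n_families=n_families,
        total_declared=total_declared,
        per_replicate=per_replicate,
    )


@dataclass
class PlantedEffectStudy:
    """Result of :func:`planted_effect_study`: per-replicate detection flags."""

    sensitivity: float
    detected: np.ndarray
    n_replicates: int


def planted_effect_study(
    n_replicates: int = 10,
    n_patients: int = 5000,
    offset: float = 0.8,
    prevalence: float = 0.15,
    component: int = 4,
    n_simulations: int = 20,
    seed: int = 0,
) -> PlantedEffectStudy:
    """Sensitivity of the screen to one drug with a known planted effect.

    The planted drug's exposure odds are shifted by ``offset`` (log-odds) for
    patients in archetype ``component``; component weights are equal so every
    cluster is well populated. A replicate counts as a detection when the
    planted drug is declared final-significant in at least one follow-up-1
    cluster pair involving that component.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(2 * n_replicates) % (2**31)
    detected = np.zeros(n_replicates, dtype=bool)
    for r in range(n_replicates):
        cfg = planted_effect_config(
            prevalence=prevalence,
            offset=offset,
            component=component,
            n_patients=n_patients,
            seed=int(rep_seeds[2 * r]),
        )
        visits, dispensations, _ = generate_cohort(cfg)
        tables, _, _ = prepare_tables(visits, dispensations)
        results = run_screen(
            {1: tables[1]},
            n_simulations=n_simulations,
            seed=int(rep_seeds[2 * r + 1]),
            or_policy="none",
        )
        sig = results.significant
        hits = sig[
            (sig["drug"] == "X99XX99")
            & ((sig["cluster_a"] == component) | (sig["cluster_b"] == component))
        ]
        detected[r] = len(hits) > 0
    return PlantedEffectStudy(
        sensitivity=float(detected.mean()),
        detected=detected,
        n_replicates=n_replicates,
    )
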