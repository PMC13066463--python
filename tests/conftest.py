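import numpy as np
import pandas as pd
import pytest

import cogclust as cc


@pytest.fixture(scope="session")
def big_cohort():
    """Default-condition synthetic cohort (n=10,000) with prepared tables."""
    cfg = cc.default_config(n_patients=10000, seed=11)
    visits, dispensations, truth = cc.generate_cohort(cfg)
    tables, exposure, counts = cc.prepare_tables(visits, dispensations)
    return {
        "config": cfg,
        "visits": visits,
        "dispensations": dispensations,
        "truth": truth,
        "tables": tables,
        "exposure": exposure,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def followup1_fit(big_cohort):
    """Reference 4-cluster fit of the follow-up-1 table with canonical labels."""
    table = big_cohort["tables"][1]
    fit = cc.fit_kmeans(
        table[["mmse_score", "mmse_decline"]].to_numpy(), k=4, seed=3, followup_index=1
    )
    labels = cc.canonicalize(fit).apply(fit.assignment)
    return fit, labels


@pytest.fixture
def toy_visits():
    """Five patients: 2 complete, 2 without follow-up MMSE, 1 non-AD/MD."""

    def visit(pid, fu, day, mmse, dx="AD"):
        return {
            "patient_id": pid,
            "followup_index": fu,
            "visit_date": day,
            "mmse": mmse,
            "diagnosis": dx,
        }

    return pd.DataFrame(
        [
            visit("A", 0, 0, 25),
            visit("A", 1, 365, 22),
            visit("B", 0, 0, 28, dx="MD"),
            visit("B", 1, 400, 26),
            visit("C", 0, 0, 24),  # baseline only
            visit("D", 0, 0, 21),
            visit("D", 1, 380, np.nan),  # follow-up without MMSE
            visit("E", 0, 0, 27, dx="other"),
            visit("E", 1, 390, 25),
        ]
    )
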