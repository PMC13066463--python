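"""Cohort characterization tables and result exports."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .prep import add_decline


def percentage(count: int, n: int) -> float | None:
    """100*count/n rounded half-up to 2 decimals; None for an empty stratum."""
    if n == 0:
        return None
    ratio = Decimal(100) * Decimal(count) / Decimal(n)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _mean_sd(values: pd.Series) -> str:
    v = values.dropna()
    if v.empty:
        return "--"
    return f"{v.mean():.2f} [{v.std(ddof=1):.2f}]"


def characterize_cohort(
    visits: pd.DataFrame,
    cluster_labels: pd.DataFrame | None = None,
    followups: tuple[int, ...] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Baseline/follow-up characterization table of the included cohort.

    One column per time point (follow-up index 0 = baseline) with patient
    count, sex and diagnosis breakdowns (count and percentage, half-up to two
    decimals), mean [SD] of age, MMSE score and MMSE decline, days elapsed from
    baseline and from the previous visit, and at baseline the strata of
    patients by number of follow-ups. When ``cluster_labels`` (columns
    ``patient_id, followup_index, cluster``) is given, a per-cluster block of
    MMSE score / decline / days-from-baseline means is appended.
    """
    v = add_decline(visits)
    if "days_from_baseline" in v.columns:
        days = v["days_from_baseline"]
    else:
        dates = pd.to_datetime(v["visit_date"])
        days = (dates - dates.groupby(v["patient_id"]).transform("min")).dt.days
    v = v.assign(_days=days)
    v["_gap"] = v.groupby("patient_id", sort=False)["_days"].diff()

    n_followups = (
        v[v["followup_index"] > 0].groupby("patient_id")["followup_index"].max()
    )
    columns = {}
    for f in followups:
        rows = v[v["followup_index"] == f]
        n = rows["patient_id"].nunique()
        col: dict[str, object] = {"n": n}
        fem = int((rows["sex"] == "F").sum()) if "sex" in rows else 0
        col["female"] = f"{fem} ({percentage(fem, n)}%)" if n else "--"
        if "diagnosis" in rows:
            for dx in ("AD", "MD", "other"):
                cnt = int((rows["diagnosis"] == dx).sum())
                col[f"diagnosis {dx}"] = f"{cnt} ({percentage(cnt, n)}%)" if n else "--"
        if "age_at_diagnosis" in rows:
            col["age at diagnosis (mean [SD])"] = _mean_sd(rows["age_at_diagnosis"])
            col["age (mean [SD])"] = _mean_sd(
                rows["age_at_diagnosis"] + rows["_days"] / 365.25
            )
        col["MMSE score (mean [SD])"] = _mean_sd(rows["mmse"])
        col["MMSE decline (mean [SD])"] = (
            _mean_sd(rows["mmse_decline"]) if f > 0 else "--"
        )
        col["days from baseline (mean [SD])"] = _mean_sd(rows["_days"]) if f > 0 else "--"
        col["days from previous visit (mean [SD])"] = (
            _mean_sd(rows["_gap"]) if f > 0 else "--"
        )
        if f == 0:
            for stratum in (1, 2, 3):
                cnt = int((n_followups == stratum).sum())
                col[f"patients with {stratum} follow-up(s)"] = (
                    f"{cnt} ({percentage(cnt, n)}%)" if n else "--"
                )
            cnt = int((n_followups > 3).sum())
            col["patients with >3 follow-ups"] = (
                f"{cnt} ({percentage(cnt, n)}%)" if n else "--"
            )
        label = "baseline" if f == 0 else f"follow-up {f}"
        columns[label] = col
    summary = pd.DataFrame(columns)

    if cluster_labels is not None:
        merged = v.merge(cluster_labels, on=["patient_id", "followup_index"])
        block = {}
        for (f, c), rows in merged.groupby(["followup_index", "cluster"]):
            block[f"follow-up {f} / cluster {c}"] = {
                "n": len(rows),
                "MMSE score (mean [SD])": _mean_sd(rows["mmse"]),
                "MMSE decline (mean [SD])": _mean_sd(rows["mmse_decline"]),
                "days from baseline (mean [SD])": _mean_sd(rows["_days"]),
            }
        summary = pd.concat([summary, pd.DataFrame(block)], axis=1)
    return summary


def export_heatmap_matrix(
    aggregates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide drug x (cluster pair x follow-up) matrices of averaged Z-scores.

    Returns ``(mean_z, annotated)``: both have drugs as rows and one column per
    canonical cluster pair and follow-up (e.g. ``1v3_fu1``); ``annotated`` is a
    boolean mask that is True only where the association passed the stability
    rule (mirroring a heatmap in which only stable associations are annotated).
    A positive cell means a higher proportion of users in the lower-labeled
    cluster of the pair.
    """
    a = aggregates.copy()
    a["column"] = (
        a["cluster_a"].astype(int).astype(str)
        + "v"
        + a["cluster_b"].astype(int).astype(str)
        + "_fu"
        + a["followup_index"].astype(int).astype(str)
    )
    mean_z = a.pivot(index="drug", columns="column", values="mean_z")
    annotated = (
        a.pivot(index="drug", columns="column", values="final_significant")
        .fillna(False)
        .astype(bool)
    )
    order = sorted(mean_z.columns, key=lambda s: (s.split("_fu")[1], s.split("_fu")[0]))
    return mean_z[order], annotated[order]


def plot_heatmap(aggregates: pd.DataFrame, path) -> None:
    """Optional PNG heatmap of averaged Z-scores (stable cells annotated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_z, annotated = export_heatmap_matrix(aggregates)
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * mean_z.shape[1], 1 + 0.3 * mean_z.shape[0])
    )
    vmax = np.nanmax(np.abs(mean_z.to_numpy())) or 1.0
    im = ax.imshow(mean_z.to_numpy(), cmap="RdYlGn", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mean_z.shape[1]), mean_z.columns, rotation=90)
    ax.set_yticks(range(mean_z.shape[0]), mean_z.index)
    for i in range(mean_z.shape[0]):
        for j in range(mean_z.shape[1]):
            if annotated.iloc[i, j]:
                ax.text(
                    j, i, f"{mean_z.iloc[i, j]:.1f}", ha="center", va="center", fontsize=6
                )
    fig.colorbar(im, ax=ax, label="mean Z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_clusters(table: pd.DataFrame, labels: np.ndarray, path) -> None:
    """Optional scatter of one follow-up's patients colored by canonical cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {1: "tab:green", 2: "tab:purple", 3: "tab:blue", 4: "tab:red"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in sorted(np.unique(labels)):
        mask = labels == c
        ax.scatter(
            table.loc[mask, "mmse_score"],
            table.loc[mask, "mmse_decline"],
            s=4,
            alpha=0.4,
            color=colors.get(int(c), "gray"),
            label=f"cluster {c}",
        )
    ax.set_xlabel("MMSE score")
    ax.set_ylabel("MMSE decline")
    ax.legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
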