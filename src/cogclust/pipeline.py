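"""End-to-end orchestration: simulate -> prepare -> cluster -> screen -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .cluster import canonicalize, fit_kmeans, k_diagnostics, select_k
from .exceptions import InputError
from .prep import prepare_tables
from .report import characterize_cohort, export_heatmap_matrix
from .screen import DrugClusterScreen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of the pipeline; round-trips losslessly through YAML."""

    out_dir: str = "cogclust-out"
    # inputs: either simulate, or point at existing CSVs
    simulate: bool = True
    n_patients: int = 15000
    synthetic_seed: int = 20240101
    visits_path: str | None = None
    dispensations_path: str | None = None
    # preparation
    window_days: int = 100
    prevalence_threshold: float = 0.05
    followups: tuple[int, ...] = (1, 2, 3)
    # clustering
    k: int | str = 4  # integer or "auto"
    cluster_seed: int = 0
    scale: bool = True
    # screen
    q: float = 0.05
    n_simulations: int | str = 100
    stability_threshold: float = 0.80
    cl: float = 2.576
    precision: float = 0.1
    screen_seed: int = 0
    bootstrap: bool = False
    plots: bool = False

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["followups"] = list(self.followups)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if "followups" in payload:
            payload["followups"] = tuple(payload["followups"])
        return cls(**payload)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["followups"] = list(self.followups)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage, writing all artifacts under ``config.out_dir``.

    Returns the manifest (artifact name -> path). Any stage failure aborts with
    the stage name and cause. Reruns with identical config and seeds produce
    identical CSV artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log: list[dict] = []

    def _stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.append(
                {"stage": name, "seconds": round(time.perf_counter() - start, 3)}
            )
            return result

        return wrap

    def _write(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        manifest[name] = str(path)

    # -- simulate -------------------------------------------------------------
    def simulate():
        cfg = synthetic.default_config(
            n_patients=config.n_patients, seed=config.synthetic_seed
        )
        visits, dispensations, truth = synthetic.generate_cohort(cfg)
        _write("visits.csv", visits, index=False)
        _write("dispensations.csv", dispensations, index=False)
        truth.to_csv(out / "truth_components.csv", out / "truth_exposure_probs.csv")
        manifest["truth_components.csv"] = str(out / "truth_components.csv")
        manifest["truth_exposure_probs.csv"] = str(out / "truth_exposure_probs.csv")
        cfg.to_yaml(out / "synthetic_config.yaml")
        manifest["synthetic_config.yaml"] = str(out / "synthetic_config.yaml")
        return visits, dispensations

    if config.simulate:
        visits, dispensations = _stage("simulate")(simulate)
    else:
        for label, p in (
            ("visits", config.visits_path),
            ("dispensations", config.dispensations_path),
        ):
            if p is None or not Path(p).exists():
                raise InputError(f"missing required input: {label} file {p!r}")
        visits = pd.read_csv(config.visits_path)
        dispensations = pd.read_csv(config.dispensations_path)

    # -- prepare --------------------------------------------------------------
    def prepare():
        tables, exposure, counts = prepare_tables(
            visits,
            dispensations,
            window_days=config.window_days,
            prevalence_threshold=config.prevalence_threshold,
            followups=config.followups,
        )
        for f, table in tables.items():
            _write(f"analysis_followup{f}.csv", table, index=False)
        with open(out / "exclusion_flowchart.json", "w", encoding="utf-8") as fh:
            json.dump(counts, fh, indent=2)
        manifest["exclusion_flowchart.json"] = str(out / "exclusion_flowchart.json")
        return tables

    tables = _stage("prepare")(prepare)

    # -- cluster (diagnostics + reference fits) -------------------------------
    def cluster():
        chosen_k = config.k
        diag_rows = []
        for f, table in tables.items():
            points = table[["mmse_score", "mmse_decline"]].to_numpy()
            diag = k_diagnostics(points, seed=config.cluster_seed, scale=config.scale)
            diag_rows.append(
                pd.DataFrame(
                    {
                        "followup_index": f,
                        "k": diag.k_range,
                        "inertia": diag.inertia,
                        "silhouette": diag.silhouette,
                        "gap": diag.gap,
                        "gap_se": diag.gap_se,
                    }
                )
            )
            if config.k == "auto" and f == min(tables):
                chosen_k = select_k(diag)
        _write("k_diagnostics.csv", pd.concat(diag_rows, ignore_index=True), index=False)
        chosen_k = int(chosen_k)
        fits = {}
        for f, table in tables.items():
            points = table[["mmse_score", "mmse_decline"]].to_numpy()
            fit = fit_kmeans(
                points, k=chosen_k, seed=config.cluster_seed,
                followup_index=f, scale=config.scale,
            )
            labels = (
                canonicalize(fit).apply(fit.assignment)
                if chosen_k == 4
                else fit.assignment + 1
            )
            fits[f] = (fit, labels)
            _write(
                f"clusters_followup{f}.csv",
                pd.DataFrame(
                    {
                        "patient_id": table["patient_id"],
                        "followup_index": f,
                        "cluster": labels,
                    }
                ),
                index=False,
            )
            with open(out / f"centroids_followup{f}.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "k": fit.k,
                        "seed": fit.seed,
                        "inertia": fit.inertia,
                        "centroids": fit.centroids.tolist(),
                    },
                    fh,
                    indent=2,
                )
            manifest[f"centroids_followup{f}.json"] = str(
                out / f"centroids_followup{f}.json"
            )
            if config.plots:
                from .report import plot_clusters

                plot_clusters(table, labels, out / f"clusters_followup{f}.png")
                manifest[f"clusters_followup{f}.png"] = str(
                    out / f"clusters_followup{f}.png"
                )
        return chosen_k, fits

    chosen_k, fits = _stage("cluster")(cluster)

    # -- screen ---------------------------------------------------------------
    def screen():
        model = DrugClusterScreen(
            tables,
            k=chosen_k,
            q=config.q,
            stability_threshold=config.stability_threshold,
            scale=config.scale,
            bootstrap=config.bootstrap,
        )
        results = model.fit(
            n_simulations=config.n_simulations,
            seed=config.screen_seed,
            cl=config.cl,
            precision=config.precision,
        )
        _write("screen_aggregates.csv", results.aggregates, index=False)
        mean_z, annotated = export_heatmap_matrix(results.aggregates)
        _write("heatmap_mean_z.csv", mean_z)
        _write("heatmap_annotated.csv", annotated)
        if config.plots:
            from .report import plot_heatmap

            plot_heatmap(results.aggregates, out / "heatmap.png")
            manifest["heatmap.png"] = str(out / "heatmap.png")
        with open(out / "screen_summary.txt", "w", encoding="utf-8") as fh:
            fh.write(results.summary() + "\n")
        manifest["screen_summary.txt"] = str(out / "screen_summary.txt")
        return results

    results = _stage("screen")(screen)

    # -- report ---------------------------------------------------------------
    def report():
        labels = pd.concat(
            [
                pd.DataFrame(
                    {
                        "patient_id": tables[f]["patient_id"],
                        "followup_index": f,
                        "cluster": lab,
                    }
                )
                for f, (fit, lab) in fits.items()
            ],
            ignore_index=True,
        )
        cohort_visits = visits[
            visits["patient_id"].isin(
                pd.unique(pd.concat([t["patient_id"] for t in tables.values()]))
            )
        ]
        summary = characterize_cohort(cohort_visits, cluster_labels=labels)
        _write("cohort_summary.csv", summary)

    _stage("report")(report)

    config.to_yaml(out / "run_config.yaml")
    manifest["run_config.yaml"] = str(out / "run_config.yaml")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"config_hash": config.digest(), "artifacts": manifest, "log": log},
            fh,
            indent=2,
        )
    manifest["manifest.json"] = str(out / "manifest.json")
    return manifest
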