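"""Drug-cluster association screen with Monte-Carlo stability aggregation.

The statistical core of the package. For one follow-up table the screen
repeats, over Monte-Carlo simulations differing in their k-means seed (and
optionally a patient bootstrap):

1. k-means clustering of patients in the (MMSE score, MMSE decline) plane,
   canonicalized to the four cognitive archetypes;
2. for every included drug and every unordered cluster pair, a pooled
   two-proportion Z-test of the usage proportions, with Benjamini-Hochberg FDR
   control at q within each (cluster pair, follow-up) family.

Z-scores are averaged across simulations after canonical matching, and a drug x
cluster-pair association is declared significant only if it survives FDR in at
least 80% of the simulations (the stability rule). Conditional
maximum-likelihood odds ratios with exact confidence intervals accompany the
declared associations. The number of simulations can be set directly (100 in
the published analysis) or derived from pilot variability via
``N = ceil((CL * sigma / precision)**2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .cluster import canonicalize, fit_kmeans
from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: canonical unordered cluster pairs, lower archetype label first
CLUSTER_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2),
    (1, 3),
    (1, 4),
    (2, 3),
    (2, 4),
    (3, 4),
)


# ---------------------------------------------------------------------------
# elementary statistics


def two_proportion_ztest(users_a, n_a, users_b, n_b):
    """Pooled two-sided two-proportion Z-test without continuity correction.

    ``z = (p_a − p_b) / sqrt(p(1−p)(1/n_a + 1/n_b))`` with ``p`` the pooled
    proportion; the p-value comes from the standard normal. A positive z means
    a higher proportion in group a. When the pooled proportion is 0 or 1 the
    test carries no information and (z, p) = (0, 1) is returned.

    Accepts scalars or equally-shaped arrays; returns floats or arrays.
    """
    ua = np.asarray(users_a, dtype=float)
    ub = np.asarray(users_b, dtype=float)
    na = np.asarray(n_a, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    if (na < 1).any() or (nb < 1).any():
        raise InputError("group sizes must be >= 1")
    if (ua < 0).any() or (ub < 0).any() or (ua > na).any() or (ub > nb).any():
        raise InputError("user counts must lie between 0 and the group size")
    pooled = (ua + ub) / (na + nb)
    degenerate = (pooled <= 0.0) | (pooled >= 1.0)
    se = np.sqrt(
        np.where(degenerate, 1.0, pooled * (1.0 - pooled)) * (1.0 / na + 1.0 / nb)
    )
    z = np.where(degenerate, 0.0, (ua / na - ub / nb) / se)
    p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def bh_adjust(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up over one test family.

    Returns ``(reject_flags, adjusted_pvalues)``; the adjusted p-values are the
    usual monotone step-up values. Empty input gives empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def fisher_or_ci(users_a, n_a, users_b, n_b, level: float = 0.95, compute_or: bool = True):
    """Odds ratio of exposure in cluster a vs b from the 2x2 table, with exact CI.

    The table is ``[[users_a, n_a − users_a], [users_b, n_b − users_b]]``. The
    point estimate is the conditional maximum-likelihood odds ratio and the CI
    the exact conditional (Cornfield-type) interval from the noncentral
    hypergeometric likelihood; the two-sided p-value is Fisher's exact test.
    A zero margin (drug absent, or universal, in both clusters) leaves the odds
    ratio undefined: NaN estimates are returned with p = 1. With
    ``compute_or=False`` the (much cheaper) exact p-value is returned alone,
    with NaN in place of the estimate and interval.

    Returns ``(or_pe, ci_low, ci_high, exact_p)``.
    """
    if n_a < 1 or n_b < 1:
        raise InputError("group sizes must be >= 1")
    a, b = int(users_a), int(n_a - users_a)
    c, d = int(users_b), int(n_b - users_b)
    if min(a, b, c, d) < 0:
        raise InputError("user counts must lie between 0 and the group size")
    table = [[a, b], [c, d]]
    if (a + c == 0) or (b + d == 0):
        logger.info("odds ratio undefined for zero-margin table %s", table)
        return math.nan, math.nan, math.nan, 1.0
    if not compute_or:
        return math.nan, math.nan, math.nan, float(stats.fisher_exact(table)[1])
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    exact_p = float(stats.fisher_exact(table)[1])
    return float(res.statistic), float(ci.low), float(ci.high), exact_p


@dataclass
class MonteCarloPlan:
    """Simulation-count plan: ``N = ceil((CL * sigma / precision)**2)``.

    ``cl`` is the normal-quantile confidence multiplier (2.576 for 99%),
    ``precision`` the tolerated difference between the Monte-Carlo mean and the
    true mean, and ``sigma`` the largest per-drug standard deviation of the
    Z-scores across pilot simulations. ``n_required`` applies a floor of 1.
    """

    cl: float
    precision: float
    sigma: float
    n_required: int
    sigma_per_drug: pd.Series | None = None


def required_simulations(
    sigma_per_drug, cl: float = 2.576, precision: float = 0.1
) -> MonteCarloPlan:
    """Number of Monte-Carlo simulations needed for the requested precision."""
    if precision <= 0:
        raise ConfigurationError("precision must be > 0")
    if cl <= 0:
        raise ConfigurationError("cl must be > 0")
    sigmas = pd.Series(sigma_per_drug, dtype=float)
    if (sigmas < 0).any():
        raise ConfigurationError("sigma_per_drug values must be >= 0")
    sigma = float(sigmas.max()) if len(sigmas) else 0.0
    n_raw = math.ceil((cl * sigma / precision) ** 2)
    return MonteCarloPlan(
        cl=cl,
        precision=precision,
        sigma=sigma,
        n_required=max(1, n_raw),
        sigma_per_drug=sigmas if len(sigmas) else None,
    )


# ---------------------------------------------------------------------------
# one simulation


def run_single_simulation(
    table: pd.DataFrame,
    k: int = 4,
    q: float = 0.05,
    seed: int = 0,
    followup_index: int | None = None,
    scale: bool = True,
    bootstrap: bool = False,
    odds_ratios: bool = True,
) -> pd.DataFrame:
    """One Monte-Carlo step: cluster, canonicalize, test every drug x pair.

    ``table`` is a prepared analysis table (columns ``patient_id, mmse_score,
    mmse_decline`` then one binary column per drug). Returns one row per
    (drug, cluster pair) with the user counts, the Z statistic and its p-value,
    the BH-adjusted p-value and rejection flag at level ``q`` within the pair's
    family, and (when ``odds_ratios``) the conditional-MLE odds ratio of
    exposure in the lower-labeled cluster vs the higher with its exact 95% CI.
    The fit's inertia and seed are stored in ``DataFrame.attrs``.
    """
    if table.empty:
        raise InputError("analysis table is empty")
    drugs = [c for c in table.columns if c not in ("patient_id", "mmse_score", "mmse_decline")]
    if bootstrap:
        rng = np.random.default_rng(seed)
        table = table.iloc[rng.integers(0, len(table), size=len(table))]
    points = table[["mmse_score", "mmse_decline"]].to_numpy()
    fit = fit_kmeans(points, k=k, seed=seed, followup_index=followup_index, scale=scale)
    labels = canonicalize(fit).apply(fit.assignment) if k == 4 else fit.assignment + 1

    exposures = table[drugs].to_numpy()
    cluster_rows = {c: labels == c for c in np.unique(labels)}
    n_per = {c: int(mask.sum()) for c, mask in cluster_rows.items()}
    users_per = {c: exposures[mask].sum(axis=0) for c, mask in cluster_rows.items()}

    pairs = CLUSTER_PAIRS if k == 4 else tuple(
        (a, b) for i, a in enumerate(sorted(n_per)) for b in sorted(n_per)[i + 1 :]
    )
    frames = []
    for a, b in pairs:
        z, p = two_proportion_ztest(users_per[a], n_per[a], users_per[b], n_per[b])
        reject, adjusted = bh_adjust(p, q=q)
        frames.append(
            pd.DataFrame(
                {
                    "drug": drugs,
                    "followup_index": followup_index,
                    "cluster_a": a,
                    "cluster_b": b,
                    "users_a": users_per[a],
                    "n_a": n_per[a],
                    "users_b": users_per[b],
                    "n_b": n_per[b],
                    "z": z,
                    "p": p,
                    "p_adjusted": adjusted,
                    "significant": reject,
                }
            )
        )
    result = pd.concat(frames, ignore_index=True)
    if odds_ratios:
        ors = [
            fisher_or_ci(r.users_a, r.n_a, r.users_b, r.n_b)
            for r in result.itertuples()
        ]
        result[["or_pe", "ci_low", "ci_high", "fisher_p"]] = pd.DataFrame(ors)
    result.attrs["inertia"] = fit.inertia
    result.attrs["seed"] = int(seed)
    return result


# ---------------------------------------------------------------------------
# aggregation across simulations


def aggregate_simulations(
    simulation_results: list[pd.DataFrame],
    stability_threshold: float = 0.80,
    pooled_from: pd.DataFrame | None = None,
    or_policy: str = "significant",
) -> pd.DataFrame:
    """Aggregate per-simulation tests into the stability verdicts.

    Per (drug, cluster pair, follow-up): the mean Z over simulations, the
    fraction of simulations whose BH-adjusted test rejected, and the final
    verdict ``final_significant = (fraction >= stability_threshold)``. When
    ``pooled_from`` (the per-test table of a reference simulation, normally the
    best-inertia one) is given, pooled odds ratios with exact CIs are attached
    for all rows or only the declared-significant ones per ``or_policy``
    ("all" / "significant" / "none").
    """
    if not simulation_results:
        raise InputError("need at least one simulation result")
    if not (0.0 <= stability_threshold <= 1.0):
        raise ConfigurationError("stability_threshold must be in [0, 1]")
    key = ["drug", "followup_index", "cluster_a", "cluster_b"]
    reference_keys = simulation_results[0][key]
    for other in simulation_results[1:]:
        if set(map(tuple, other[key].to_numpy())) != set(
            map(tuple, reference_keys.to_numpy())
        ):
            raise InputError("simulations cover inconsistent drug/pair sets")
    stacked = pd.concat(simulation_results, ignore_index=True)
    grouped = stacked.groupby(key, dropna=False, sort=True)
    agg = grouped.agg(
        mean_z=("z", "mean"),
        frac_significant=("significant", "mean"),
        n_simulations=("z", "size"),
    ).reset_index()
    agg["final_significant"] = agg["frac_significant"] >= stability_threshold

    agg[["or_pe", "ci_low", "ci_high", "fisher_p"]] = np.nan
    if pooled_from is not None and or_policy != "none":
        counts = pooled_from.set_index(key)[["users_a", "n_a", "users_b", "n_b"]]
        todo = agg if or_policy == "all" else agg[agg["final_significant"]]
        for i in todo.index:
            row = counts.loc[tuple(agg.loc[i, key])]
            agg.loc[i, ["or_pe", "ci_low", "ci_high", "fisher_p"]] = fisher_or_ci(
                row["users_a"], row["n_a"], row["users_b"], row["n_b"]
            )
    return agg


def _sim_seeds(master_seed: int, followup: int, n: int, offset: int = 0) -> np.ndarray:
    """Deterministic per-simulation seeds, kept below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(followup), int(offset)])
    return ss.generate_state(n) % (2**31)


def run_screen(
    tables: dict[int, pd.DataFrame],
    k: int = 4,
    q: float = 0.05,
    n_simulations: int | str = 100,
    seed: int = 0,
    stability_threshold: float = 0.80,
    scale: bool = True,
    bootstrap: bool = False,
    pilot_simulations: int = 20,
    max_simulations: int = 1000,
    cl: float = 2.576,
    precision: float = 0.1,
    or_policy: str = "significant",
) -> "ScreenResults":
    """Run the full Monte-Carlo screen on prepared per-follow-up tables.

    With ``n_simulations="auto"`` a pilot of ``pilot_simulations`` runs
    estimates the per-drug standard deviation of the Z-scores and the full
    count comes from :func:`required_simulations` (capped at
    ``max_simulations``); otherwise the given count is used (the published
    analysis used 100). Each follow-up is screened independently; per-simulation
    seeds derive deterministically from ``seed``.
    """
    aggregates = []
    plans: dict[int, MonteCarloPlan | None] = {}
    counts: dict[int, int] = {}
    for f, table in sorted(tables.items()):
        if n_simulations == "auto":
            pilot_seeds = _sim_seeds(seed, f, pilot_simulations, offset=1)
            pilot = [
                run_single_simulation(
                    table, k=k, q=q, seed=s, followup_index=f, scale=scale,
                    bootstrap=bootstrap, odds_ratios=False,
                )
                for s in pilot_seeds
            ]
            stacked = pd.concat(pilot, ignore_index=True)
            sigma = stacked.groupby("drug")["z"].std(ddof=1).fillna(0.0)
            plan = required_simulations(sigma, cl=cl, precision=precision)
            n_sims = min(plan.n_required, max_simulations)
            plans[f] = plan
        else:
            n_sims = int(n_simulations)
            plans[f] = None
        counts[f] = n_sims
        sims = [
            run_single_simulation(
                table, k=k, q=q, seed=s, followup_index=f, scale=scale,
                bootstrap=bootstrap, odds_ratios=False,
            )
            for s in _sim_seeds(seed, f, n_sims)
        ]
        reference = min(sims, key=lambda df: df.attrs["inertia"])
        aggregates.append(
            aggregate_simulations(
                sims,
                stability_threshold=stability_threshold,
                pooled_from=reference,
                or_policy=or_policy,
            )
        )
    return ScreenResults(
        aggregates=pd.concat(aggregates, ignore_index=True),
        plans=plans,
        n_simulations=counts,
        k=k,
        q=q,
        stability_threshold=stability_threshold,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# model / results surface


class DrugClusterScreen:
    """Model object for the cluster-then-screen analysis.

    Built from prepared per-follow-up analysis tables (see
    :func:`cogclust.prep.prepare_tables`); ``fit`` runs the Monte-Carlo screen
    and returns a :class:`ScreenResults`.

    Parameters
    ----------
    tables : dict[int, DataFrame]
        Analysis tables keyed by follow-up index (1-based).
    k : int
        Number of clusters; the canonical archetype labeling requires 4.
    q : float
        FDR level for the per-family Benjamini-Hochberg correction.
    stability_threshold : float
        Minimum fraction of simulations in which a test must reject for the
        association to be declared significant.
    scale : bool
        Standardize the clustering variables before k-means (default True).
    bootstrap : bool
        Also resample patients with replacement in each simulation.
    """

    def __init__(
        self,
        tables: dict[int, pd.DataFrame],
        k: int = 4,
        q: float = 0.05,
        stability_threshold: float = 0.80,
        scale: bool = True,
        bootstrap: bool = False,
    ) -> None:
        if not tables:
            raise InputError("need at least one analysis table")
        self.tables = dict(tables)
        self.k = k
        self.q = q
        self.stability_threshold = stability_threshold
        self.scale = scale
        self.bootstrap = bootstrap
        self.drugs = [
            c
            for c in next(iter(tables.values())).columns
            if c not in ("patient_id", "mmse_score", "mmse_decline")
        ]

    @classmethod
    def from_registry(
        cls,
        visits: pd.DataFrame,
        dispensations: pd.DataFrame,
        window_days: int = 100,
        prevalence_threshold: float = 0.05,
        followups: tuple[int, ...] = (1, 2, 3),
        **kwargs,
    ) -> "DrugClusterScreen":
        """Construct directly from raw visit and dispensation tables."""
        from .prep import prepare_tables

        tables, _, _ = prepare_tables(
            visits,
            dispensations,
            window_days=window_days,
            prevalence_threshold=prevalence_threshold,
            followups=followups,
        )
        return cls(tables, **kwargs)

    def fit(self, n_simulations: int | str = 100, seed: int = 0, **kwargs) -> "ScreenResults":
        results = run_screen(
            self.tables,
            k=self.k,
            q=self.q,
            n_simulations=n_simulations,
            seed=seed,
            stability_threshold=self.stability_threshold,
            scale=self.scale,
            bootstrap=self.bootstrap,
            **kwargs,
        )
        results.model = self
        return results


@dataclass
class ScreenResults:
    """Fitted screen: stability aggregates plus run metadata.

    ``aggregates`` has one row per (drug, follow-up, cluster pair) with columns
    ``mean_z, frac_significant, final_significant, or_pe, ci_low, ci_high,
    fisher_p``.
    """

    aggregates: pd.DataFrame
    plans: dict[int, MonteCarloPlan | None]
    n_simulations: dict[int, int]
    k: int
    q: float
    stability_threshold: float
    seed: int
    model: "DrugClusterScreen | None" = field(default=None, repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        """Rows passing FDR in at least the stability fraction of simulations."""
        return self.aggregates[self.aggregates["final_significant"]].reset_index(drop=True)

    def heatmap_frame(self) -> pd.DataFrame:
        """Wide drug x (cluster pair, follow-up) matrix of averaged Z-scores."""
        from .report import export_heatmap_matrix

        return export_heatmap_matrix(self.aggregates)[0]

    def summary(self) -> str:
        lines = [
            "Drug-cluster association screen",
            "=" * 72,
            f"clusters (k): {self.k}    FDR level q: {self.q}    "
            f"stability threshold: {self.stability_threshold:.0%}",
            "simulations per follow-up: "
            + ", ".join(f"fu{f}: {n}" for f, n in sorted(self.n_simulations.items())),
            "",
        ]
        sig = self.significant
        if sig.empty:
            lines.append("No drug-cluster association passed the stability rule.")
        else:
            lines.append(
                f"{len(sig)} drug x cluster-pair associations passed the stability rule:"
            )
            shown = sig[
                [
                    "followup_index",
                    "drug",
                    "cluster_a",
                    "cluster_b",
                    "mean_z",
                    "frac_significant",
                    "or_pe",
                    "ci_low",
                    "ci_high",
                ]
            ].copy()
            shown.columns = [
                "follow-up",
                "drug",
                "a",
                "b",
                "mean Z",
                "frac sig",
                "OR",
                "CI low",
                "CI high",
            ]
            lines.append(shown.round(3).to_string(index=False))
        return "\n".join(lines)
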