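"""Site-centric visitation statistics and significance testing.

For each individual and each grid site the framework measures three things:
the number of uninterrupted visits ``n_is``, the mean dwell time per visit
``D_is`` (minutes), and the typical first return time ``RT_is`` (minutes).
Return times are right-censored -- the return following the last visit to a
site is never observed -- so the typical return is summarised by the
restricted mean: the area under the Kaplan-Meier survival curve of the
return times up to the largest observation.

Observed statistics are compared with their null distributions over an
ensemble of spatially unbiased random-walk replicates of the same
trajectory.  Deviations are expressed as z-scores, tested with a two-tailed
permutation test, and corrected per ant and per metric with the
Benjamini-Hochberg false discovery rate procedure.  The classical
"reductive" test -- comparing only the number of distinct sites visited,
``N_i``, against its null distribution -- is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_data import MISSING, GridSpec, SiteSequence, assign_sites
from .null_models import RWEnsemble

__all__ = [
    "VisitRecord",
    "SiteStats",
    "NullDistributions",
    "ReductiveResult",
    "compute_visits",
    "restricted_mean",
    "site_statistics",
    "null_site_distributions",
    "site_significance",
    "reductive_test",
    "bh_adjust",
    "summarize_individuals",
]

METRICS = ("n", "dwell", "return")


@dataclass(frozen=True)
class VisitRecord:
    """One uninterrupted stay of one ant at one site.

    Dwell is stop minus start (a single-fix visit has dwell 0).  The return
    time runs from this visit's stop to the next visit's start at the same
    site, regardless of intervening gaps; the last visit to a site instead
    carries the censoring time to the ant's last observed tick.
    """

    ant_id: str
    site: int
    k: int
    start_tick: int
    stop_tick: int
    dwell: float
    return_time: float | None
    censor_time: float | None

    @property
    def censored(self) -> bool:
        return self.return_time is None


def _runs(sites: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values: list of (value, start_idx, stop_idx)."""
    if len(sites) == 0:
        return []
    change = np.flatnonzero(sites[1:] != sites[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change - 1, [len(sites) - 1]])
    return [(int(sites[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def compute_visits(seq: SiteSequence) -> list[VisitRecord]:
    """Decompose a site sequence into uninterrupted visits.

    A missing fix terminates the current visit (presence is no longer
    demonstrably uninterrupted); return times may span gaps.
    """
    sites = seq.sites
    if not np.any(sites != MISSING):
        raise ValueError("no observed ticks")
    dt = seq.tick_minutes
    t0 = int(seq.ticks[0])
    last_obs_tick = int(seq.ticks[np.flatnonzero(sites != MISSING)[-1]])
    per_site: dict[int, list[tuple[int, int]]] = {}
    for value, a, b in _runs(sites):
        if value == MISSING:
            continue
        per_site.setdefault(value, []).append((t0 + a, t0 + b))
    out: list[VisitRecord] = []
    for site in sorted(per_site):
        stays = per_site[site]
        for k, (start, stop) in enumerate(stays, start=1):
            if k < len(stays):
                rt = (stays[k][0] - stop) * dt
                cz = None
            else:
                rt = None
                cz = (last_obs_tick - stop) * dt
            out.append(
                VisitRecord(
                    ant_id=seq.ant_id,
                    site=site,
                    k=k,
                    start_tick=start,
                    stop_tick=stop,
                    dwell=(stop - start) * dt,
                    return_time=rt,
                    censor_time=cz,
                )
            )
    return out


def restricted_mean(times: Sequence[float], events: Sequence[bool]) -> float:
    """Restricted mean of right-censored times: area under the Kaplan-Meier
    survival curve up to the largest observation (event or censoring).

    With no censoring this equals the arithmetic mean.  Implemented directly
    (product-limit over distinct event times) because it sits in the inner
    loop of the null-distribution computation; cross-checked against
    lifelines in the test suite.
    """
    n = len(times)
    if n == 0:
        raise ValueError("restricted_mean of empty input")
    if len(events) != n:
        raise ValueError("times/events length mismatch")
    pairs = sorted(zip([float(t) for t in times], [bool(e) for e in events]))
    t_max = pairs[-1][0]
    area = 0.0
    surv = 1.0
    prev_t = 0.0
    i = 0
    at_risk = n
    while i < n:
        t = pairs[i][0]
        # events and censorings tied at t: events drop survival first,
        # censored-at-t individuals count as at risk at t
        d = 0
        c = 0
        while i < n and pairs[i][0] == t:
            if pairs[i][1]:
                d += 1
            else:
                c += 1
            i += 1
        area += surv * (t - prev_t)
        if d and at_risk:
            surv *= 1.0 - d / at_risk
        at_risk -= d + c
        prev_t = t
    # survival beyond the last observation is undefined; restrict to t_max
    del t_max
    return area


@dataclass
class SiteStats:
    """Per-site visitation statistics of one ant plus individual summaries.

    ``per_site`` is indexed by flat site id with columns n, mean_dwell,
    rt_restricted_mean (minutes).
    """

    colony_id: str
    ant_id: str
    caste: str
    per_site: pd.DataFrame

    @property
    def n_sites_visited(self) -> int:
        """N_i: the number of distinct sites visited."""
        return len(self.per_site)

    @property
    def visit_counts(self) -> pd.Series:
        return self.per_site["n"]

    @property
    def mean_visits(self) -> float:
        """n-bar_i: mean number of visits per visited site."""
        return float(self.per_site["n"].mean())

    @property
    def mean_dwell(self) -> float:
        """D-bar_i: mean dwell time per visited site (minutes)."""
        return float(self.per_site["mean_dwell"].mean())

    @property
    def mean_return(self) -> float:
        """RT-bar_i: mean restricted-mean return time per visited site."""
        return float(self.per_site["rt_restricted_mean"].mean())


def _stats_from_codes(
    sites: np.ndarray, tick_minutes: float
) -> dict[int, tuple[int, float, float]]:
    """Fast per-site (n, mean dwell, restricted-mean return) from site codes."""
    obs_idx = np.flatnonzero(sites != MISSING)
    if len(obs_idx) == 0:
        return {}
    last_obs = int(obs_idx[-1])
    per_site: dict[int, list[tuple[int, int]]] = {}
    for value, a, b in _runs(sites):
        if value == MISSING:
            continue
        per_site.setdefault(value, []).append((a, b))
    out = {}
    for site, stays in per_site.items():
        n = len(stays)
        dwell = sum(b - a for a, b in stays) / n * tick_minutes
        times = [
            (stays[k + 1][0] - stays[k][1]) * tick_minutes for k in range(n - 1)
        ]
        events = [True] * (n - 1)
        times.append((last_obs - stays[-1][1]) * tick_minutes)
        events.append(False)
        out[site] = (n, dwell, restricted_mean(times, events))
    return out


def site_statistics(
    visits: Iterable[VisitRecord],
    seq: SiteSequence,
) -> SiteStats:
    """Aggregate visit records into per-site statistics for one ant."""
    rows = {}
    for v in visits:
        rows.setdefault(v.site, []).append(v)
    data = []
    for site in sorted(rows):
        vs = rows[site]
        times = [v.return_time if not v.censored else v.censor_time for v in vs]
        events = [not v.censored for v in vs]
        data.append(
            {
                "site": site,
                "n": len(vs),
                "mean_dwell": float(np.mean([v.dwell for v in vs])),
                "rt_restricted_mean": restricted_mean(times, events),
            }
        )
    per_site = pd.DataFrame(
        data, columns=["site", "n", "mean_dwell", "rt_restricted_mean"]
    ).set_index("site")
    return SiteStats(
        colony_id=seq.colony_id,
        ant_id=seq.ant_id,
        caste=seq.caste,
        per_site=per_site,
    )


def ant_site_statistics(seq: SiteSequence) -> SiteStats:
    """Convenience: visits + per-site statistics straight from a sequence."""
    return site_statistics(compute_visits(seq), seq)


@dataclass
class NullDistributions:
    """Null-model distributions of the three site metrics for one ant.

    For the visit count, every replicate contributes one value per site
    (zero if the replicate never visits it).  Dwell and return distributions
    are conditional on the replicate visiting the site, so their per-site
    sample sizes ("coverage") vary and can be small for rarely-visited
    sites.
    """

    n_reps: int
    n_counts: dict[int, np.ndarray]
    dwell: dict[int, np.ndarray]
    rt: dict[int, np.ndarray]
    null_N: np.ndarray  # distinct sites visited, one per replicate

    def coverage(self, site: int) -> int:
        return len(self.dwell.get(site, ()))


def null_site_distributions(
    ensemble: RWEnsemble, grid: GridSpec
) -> NullDistributions:
    """Per-site null distributions of n, dwell and return over an ensemble."""
    R = ensemble.n_reps
    if R < 2:
        raise ValueError("need an ensemble of at least 2 replicates")
    tick_minutes = ensemble.source.tick_minutes
    n_counts: dict[int, np.ndarray] = {}
    dwell: dict[int, list[float]] = {}
    rt: dict[int, list[float]] = {}
    null_N = np.zeros(R, dtype=int)
    for r in range(R):
        codes = grid.point_to_site(
            ensemble.coords[r, :, 0], ensemble.coords[r, :, 1]
        )
        stats = _stats_from_codes(codes, tick_minutes)
        null_N[r] = len(stats)
        for site, (n, d, rtm) in stats.items():
            if site not in n_counts:
                n_counts[site] = np.zeros(R, dtype=int)
                dwell[site] = []
                rt[site] = []
            n_counts[site][r] = n
            dwell[site].append(d)
            rt[site].append(rtm)
    return NullDistributions(
        n_reps=R,
        n_counts=n_counts,
        dwell={s: np.asarray(v) for s, v in dwell.items()},
        rt={s: np.asarray(v) for s, v in rt.items()},
        null_N=null_N,
    )


def _perm_p(obs: float, null: np.ndarray) -> float:
    """Two-tailed permutation p with add-one correction, capped at 1."""
    r = len(null)
    lo = int(np.count_nonzero(null <= obs)) + 1
    hi = int(np.count_nonzero(null >= obs)) + 1
    return min(1.0, 2.0 * min(lo, hi) / (r + 1))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def site_significance(
    observed: SiteStats,
    nulls: NullDistributions,
    alpha: float = 0.05,
    min_coverage: int = 50,
) -> pd.DataFrame:
    """Test every visited site of one ant against its null distributions.

    Returns one row per (site, metric) with the observed value, null mean
    and sd, z-score, two-tailed permutation p, BH-adjusted q (corrected per
    metric across the ant's visited sites), a classification and an
    ``outside_null`` flag (observed value outside the whole null range).

    Classification: *attracted* means significantly more visits, longer
    dwells, or faster returns than the null (z > 0 for n and dwell, z < 0
    for return); *avoided* is the opposite; *untestable* marks dwell/return
    metrics whose null sample ("coverage": replicates that visit the site)
    is below ``min_coverage``.
    """
    rows = []
    for site in observed.per_site.index:
        obs_n = float(observed.per_site.at[site, "n"])
        obs_d = float(observed.per_site.at[site, "mean_dwell"])
        obs_rt = float(observed.per_site.at[site, "rt_restricted_mean"])
        null_n = nulls.n_counts.get(site, np.zeros(nulls.n_reps, dtype=int))
        cov = nulls.coverage(site)
        for metric, obs_val, null in (
            ("n", obs_n, null_n),
            ("dwell", obs_d, nulls.dwell.get(site, np.array([]))),
            ("return", obs_rt, nulls.rt.get(site, np.array([]))),
        ):
            testable = metric == "n" or cov >= min_coverage
            if len(null) == 0 or not testable:
                rows.append(
                    {
                        "site": site,
                        "metric": metric,
                        "observed": obs_val,
                        "null_mean": np.nan,
                        "null_sd": np.nan,
                        "coverage": cov if metric != "n" else nulls.n_reps,
                        "z": np.nan,
                        "p": np.nan,
                        "outside_null": False,
                    }
                )
                continue
            mu = float(np.mean(null))
            sd = float(np.std(null, ddof=1)) if len(null) > 1 else 0.0
            z = (obs_val - mu) / sd if sd > 0 else np.nan
            rows.append(
                {
                    "site": site,
                    "metric": metric,
                    "observed": obs_val,
                    "null_mean": mu,
                    "null_sd": sd,
                    "coverage": cov if metric != "n" else nulls.n_reps,
                    "z": z,
                    "p": _perm_p(obs_val, null),
                    "outside_null": bool(
                        obs_val < null.min() or obs_val > null.max()
                    ),
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for metric in METRICS:
        mask = (df["metric"] == metric) & df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    # classify
    def classify(row) -> str:
        if np.isnan(row["p"]):
            return "untestable"
        if not (row["q"] < alpha):
            return "neutral"
        direction = row["observed"] - row["null_mean"]
        if row["metric"] == "return":
            return "attracted" if direction < 0 else "avoided"
        return "attracted" if direction > 0 else "avoided"

    df["classification"] = df.apply(classify, axis=1)
    df.insert(0, "ant", observed.ant_id)
    df.insert(0, "colony", observed.colony_id)
    return df


@dataclass(frozen=True)
class ReductiveResult:
    """Whole-trajectory area-coverage test based on N_i alone."""

    ant_id: str
    observed_N: int
    null_lo: float
    null_hi: float
    classification: str


def reductive_test(
    observed_N: int,
    null_N: np.ndarray,
    alpha: float = 0.05,
    ant_id: str = "",
) -> ReductiveResult:
    """Classify an ant by its number of distinct sites visited, N_i.

    *fidelity* if N_i falls below the null 0.025 quantile (covers less area
    than unbiased movement), *roaming* above the 0.975 quantile, otherwise
    *neutral*.  The quantile pair matches a two-tailed test at ``alpha`` =
    0.05; other alphas rescale the quantiles accordingly.
    """
    lo, hi = np.quantile(null_N, [alpha / 2, 1 - alpha / 2])
    if observed_N < lo:
        cls = "fidelity"
    elif observed_N > hi:
        cls = "roaming"
    else:
        cls = "neutral"
    return ReductiveResult(
        ant_id=ant_id,
        observed_N=int(observed_N),
        null_lo=float(lo),
        null_hi=float(hi),
        classification=cls,
    )


def analyse_trajectory(
    traj,
    geometry,
    grid: GridSpec,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    min_coverage: int = 50,
):
    """End-to-end site-fidelity analysis of one trajectory.

    Builds the unbiased random-walk ensemble, computes observed and null
    site statistics, and returns ``(SiteStats, tests DataFrame,
    ReductiveResult)``.
    """
    from .null_models import build_ensemble

    seq = assign_sites(traj, grid)
    stats = ant_site_statistics(seq)
    ensemble = build_ensemble(traj, geometry, n_reps, seed)
    nulls = null_site_distributions(ensemble, grid)
    tests = site_significance(stats, nulls, alpha=alpha, min_coverage=min_coverage)
    red = reductive_test(
        stats.n_sites_visited, nulls.null_N, alpha=alpha, ant_id=traj.ant_id
    )
    return stats, tests, red


def summarize_individuals(
    stats: Iterable[SiteStats],
    tests: pd.DataFrame | None = None,
    reductive: dict[str, ReductiveResult] | None = None,
) -> pd.DataFrame:
    """Per-ant summary table: N_i, n-bar_i, D-bar_i, RT-bar_i and, when
    available, the reductive class and attracted/avoided site counts."""
    rows = []
    for s in stats:
        row = {
            "colony": s.colony_id,
            "ant": s.ant_id,
            "caste": s.caste,
            "N": s.n_sites_visited,
            "mean_visits": s.mean_visits,
            "mean_dwell": s.mean_dwell,
            "mean_return": s.mean_return,
        }
        if tests is not None:
            sub = tests[(tests["colony"] == s.colony_id) & (tests["ant"] == s.ant_id)]
            for metric in METRICS:
                m = sub[sub["metric"] == metric]
                row[f"attracted_{metric}"] = int(
                    (m["classification"] == "attracted").sum()
                )
                row[f"avoided_{metric}"] = int(
                    (m["classification"] == "avoided").sum()
                )
        if reductive is not None and s.ant_id in reductive:
            row["reductive_class"] = reductive[s.ant_id].classification
        rows.append(row)
    return pd.DataFrame(rows)
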