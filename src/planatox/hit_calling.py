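"""Biological-relevancy filtering, run consistency, concentration dependence
and LOEL determination.

A statistically significant concentration only becomes a *final hit* when it
passes three further filters, each designed to suppress plate-to-plate
false positives:

* **relevancy** — the group's summary statistic (mean for normal-class
  endpoints, median for skewed, proportion for binary) must fall strictly
  outside a cutoff interval derived from many independent control
  populations (mean ± 2 SD of per-population summaries for normal-class
  endpoints, 5th–95th percentile otherwise);
* **consistency** — both experimental runs must deviate from their control
  in the same direction, each run's summary itself outside the cutoffs
  (a weaker same-direction-only mode is available);
* **concentration dependence** — a hit at concentration c counts only if
  every tested sublethal concentration above c is also a hit (or c is the
  highest sublethal concentration).

``final_hit = significant AND outside_cutoff AND consistent AND dependent``;
the LOEL per endpoint is the lowest final-hit concentration, and the overall
LOEL is the minimum across endpoints (lethality included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior_endpoints import ENDPOINT_CLASSES

__all__ = [
    "SUMMARY_STATS",
    "RelevancyCutoff",
    "group_summaries",
    "compute_cutoffs",
    "apply_relevancy",
    "consistency_filter",
    "dependence_filter",
    "assemble_hits",
    "compute_loel",
    "loel_matrix",
    "plot_loel_heatmap",
]

#: Class-matched group summary statistic compared against the cutoffs.
SUMMARY_STATS = {"binary": "proportion", "normal": "mean", "skewed": "median"}


def _summarize(values: np.ndarray, klass: str) -> float:
    if klass == "binary":
        return float(np.mean(values))  # proportion affected
    if klass == "normal":
        return float(np.mean(values))
    return float(np.median(values))


@dataclass(frozen=True)
class RelevancyCutoff:
    endpoint: str
    method: str  # "mean_2sd" or "pct_5_95"
    lower: float
    upper: float
    n_control_populations: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("cutoff lower bound exceeds upper bound")

    def outside(self, summary: float) -> bool:
        """Strict exceedance: a summary exactly on a bound is *inside*."""
        return bool(summary < self.lower or summary > self.upper)


def group_summaries(
    endpoint_table: pd.DataFrame, by_run: bool = False
) -> pd.DataFrame:
    """Class-matched summary per endpoint x concentration (x run).

    Returns columns (endpoint, concentration_uM[, run], summary, n).
    """
    keys = ["endpoint", "concentration_uM"] + (["run"] if by_run else [])
    rows = []
    for key, grp in endpoint_table.groupby(keys, sort=True):
        endpoint = key[0]
        rows.append(
            dict(
                zip(keys, key),
                summary=_summarize(
                    grp["value"].to_numpy(), ENDPOINT_CLASSES[endpoint]
                ),
                n=len(grp),
            )
        )
    return pd.DataFrame(rows)


def compute_cutoffs(
    control_endpoint_tables: Sequence[pd.DataFrame],
    mode: str = "per_population",
) -> Dict[str, RelevancyCutoff]:
    """Biological-relevancy cutoffs from independent control populations.

    ``mode="per_population"`` (default) summarizes each population with the
    class-matched statistic and derives the interval from those summaries:
    mean ± 2 SD for normal-class endpoints, 5th–95th percentile (linear
    interpolation) otherwise.  ``mode="pooled"`` pools per-animal scores
    across populations before taking the interval (proportions are still
    per-population, as a pooled Bernoulli quantile would be degenerate).
    """
    if len(control_endpoint_tables) < 2:
        raise ValueError("need at least 2 control populations")
    if mode not in ("per_population", "pooled"):
        raise ValueError(f"unknown cutoff mode {mode!r}")
    endpoints: Dict[str, List[np.ndarray]] = {}
    for table in control_endpoint_tables:
        for endpoint, grp in table.groupby("endpoint"):
            endpoints.setdefault(endpoint, []).append(grp["value"].to_numpy())

    cutoffs: Dict[str, RelevancyCutoff] = {}
    for endpoint, per_pop in endpoints.items():
        klass = ENDPOINT_CLASSES[endpoint]
        if mode == "per_population" or klass == "binary":
            scores = np.array([_summarize(v, klass) for v in per_pop])
        else:
            scores = np.concatenate(per_pop)
        if klass == "normal":
            m, s = scores.mean(), scores.std(ddof=1)
            lower, upper = m - 2 * s, m + 2 * s
            method = "mean_2sd"
        else:
            lower, upper = np.percentile(scores, [5, 95])
            method = "pct_5_95"
        cutoffs[endpoint] = RelevancyCutoff(
            endpoint, method, float(lower), float(upper), len(per_pop)
        )
    return cutoffs


def apply_relevancy(
    summaries: pd.DataFrame, cutoffs: Dict[str, RelevancyCutoff]
) -> pd.DataFrame:
    """Add the strict ``outside_cutoff`` flag to a group-summary frame."""
    missing = set(summaries["endpoint"]) - set(cutoffs)
    if missing:
        raise ValueError(f"no relevancy cutoff for endpoints: {sorted(missing)}")
    out = summaries.copy()
    out["outside_cutoff"] = [
        cutoffs[e].outside(s) for e, s in zip(out["endpoint"], out["summary"])
    ]
    return out


def consistency_filter(
    run_summaries: pd.DataFrame,
    cutoffs: Dict[str, RelevancyCutoff],
    strict: bool = True,
) -> pd.DataFrame:
    """Across-run consistency per endpoint x concentration.

    A hit is consistent when both runs deviate from their own in-plate
    control in the same direction and (in the default strict mode) each
    run's summary is itself outside the cutoff interval.  With a single run
    the flag is not evaluable (NaN, with a warning).
    """
    rows = []
    for (endpoint, conc), grp in run_summaries[
        run_summaries["concentration_uM"] != 0.0
    ].groupby(["endpoint", "concentration_uM"]):
        runs = sorted(grp["run"].unique())
        if len(runs) < 2:
            warnings.warn(
                f"{endpoint} @ {conc} µM: single run, consistency not evaluable",
                stacklevel=2,
            )
            rows.append(
                {"endpoint": endpoint, "concentration_uM": conc,
                 "consistent_across_runs": np.nan}
            )
            continue
        directions, outside = [], []
        for run in runs:
            s = float(
                grp.loc[grp["run"] == run, "summary"].iloc[0]
            )
            ctrl_rows = run_summaries[
                (run_summaries["endpoint"] == endpoint)
                & (run_summaries["concentration_uM"] == 0.0)
                & (run_summaries["run"] == run)
            ]
            ctrl = float(ctrl_rows["summary"].iloc[0]) if len(ctrl_rows) else np.nan
            directions.append(np.sign(s - ctrl))
            outside.append(cutoffs[endpoint].outside(s))
        same_dir = directions[0] == directions[1] and directions[0] != 0
        ok = same_dir and (all(outside) if strict else True)
        rows.append(
            {"endpoint": endpoint, "concentration_uM": conc,
             "consistent_across_runs": bool(ok)}
        )
    return pd.DataFrame(rows)


def dependence_filter(hits: pd.DataFrame, hit_col: str = "candidate") -> pd.DataFrame:
    """Concentration-dependence per endpoint over the tested (sublethal)
    series: a hit at c is dependent iff every tested concentration above c
    is also a hit, or c is the highest tested concentration."""
    out = hits.copy()
    out["concentration_dependent"] = False
    for endpoint, grp in out.groupby("endpoint"):
        grp = grp.sort_values("concentration_uM", ascending=False)
        all_above = True
        for idx, row in grp.iterrows():
            is_hit = bool(row[hit_col])
            out.loc[idx, "concentration_dependent"] = is_hit and all_above
            all_above = all_above and is_hit
    return out


def assemble_hits(
    test_results: pd.DataFrame,
    pooled_summaries: pd.DataFrame,
    run_summaries: pd.DataFrame,
    cutoffs: Dict[str, RelevancyCutoff],
    alpha: float = 0.05,
    strict_consistency: bool = True,
) -> pd.DataFrame:
    """Combine the four flags into HitRecords for one condition.

    ``test_results`` may mix the lethality screen and the sublethal endpoint
    screen.  Returns one row per endpoint x tested concentration with the
    flags and ``final_hit`` (the AND of all four).
    """
    sig = test_results[["endpoint", "concentration_uM", "p_adj"]].copy()
    sig["significant"] = sig["p_adj"].fillna(1.0) < alpha
    flagged = apply_relevancy(pooled_summaries, cutoffs)[
        ["endpoint", "concentration_uM", "summary", "outside_cutoff"]
    ]
    cons = consistency_filter(run_summaries, cutoffs, strict=strict_consistency)
    hits = (
        sig.merge(flagged, on=["endpoint", "concentration_uM"], how="left")
        .merge(cons, on=["endpoint", "concentration_uM"], how="left")
    )
    hits["outside_cutoff"] = hits["outside_cutoff"].fillna(False).astype(bool)
    hits["consistent_across_runs"] = (
        hits["consistent_across_runs"].fillna(False).astype(bool)
    )
    hits["candidate"] = (
        hits["significant"] & hits["outside_cutoff"] & hits["consistent_across_runs"]
    )
    hits = dependence_filter(hits, hit_col="candidate")
    hits["final_hit"] = hits["candidate"] & hits["concentration_dependent"]
    return hits.drop(columns=["candidate"])


def compute_loel(hits: pd.DataFrame) -> pd.Series:
    """Lowest final-hit concentration per endpoint plus the overall minimum.

    Endpoints with no final hit get NaN; ``overall`` is NaN only when no
    endpoint has any hit.
    """
    loels = {}
    for endpoint, grp in hits.groupby("endpoint"):
        hit_concs = grp.loc[grp["final_hit"], "concentration_uM"]
        loels[endpoint] = float(hit_concs.min()) if len(hit_concs) else np.nan
    vals = [v for v in loels.values() if not np.isnan(v)]
    loels["overall"] = min(vals) if vals else np.nan
    return pd.Series(loels, name="LOEL_uM")


def loel_matrix(per_condition: Dict[str, pd.Series]) -> pd.DataFrame:
    """Endpoint x condition LOEL matrix ('overall' as the last row)."""
    df = pd.DataFrame(per_condition)
    if "overall" in df.index:
        order = [i for i in df.index if i != "overall"] + ["overall"]
        df = df.loc[order]
    return df


def plot_loel_heatmap(matrix: pd.DataFrame, path=None, ax=None):
    """LOEL heatmap (darker = more potent); cells annotated in µM."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.2 * len(matrix.columns) + 3, 0.4 * len(matrix) + 2)
        )
    with np.errstate(divide="ignore"):
        z = -np.log10(matrix.to_numpy(dtype=float))
    im = ax.imshow(z, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            v = matrix.iat[i, j]
            ax.text(
                j, i, "-" if pd.isna(v) else f"{v:g}",
                ha="center", va="center", fontsize=8, color="white",
            )
    ax.figure.colorbar(im, ax=ax, label="-log10(LOEL / µM)")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
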