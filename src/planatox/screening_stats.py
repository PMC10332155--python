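"""Tiered hit-calling statistics for one chemical x worm type x day.

The screening decision tree:

1. *Lethality* per concentration vs the in-plate control: one-sided Fisher
   exact (increase), Benjamini–Hochberg across the concentration family;
   concentrations with adjusted p < alpha form the *lethal set* and are
   removed from every other endpoint's testing.
2. *Binary* endpoints (body shape, stickiness, phototaxis, scrunching):
   Fisher exact per concentration + BH within the endpoint's family, with
   the tail configured per endpoint.
3. *Normal-class* endpoints (speed, locomotor bursts, noxious-stimuli rate
   and strength): Welch's heteroscedastic one-way ANOVA omnibus across all
   groups; when significant, a Tamhane–Dunnett many-to-one post hoc vs the
   control (Welch-type t statistics, family-wise adjusted on the seeded
   Monte-Carlo null distribution of the max statistic).
4. *Skewed* endpoints (resting, anxiety): Kruskal–Wallis omnibus (tie
   corrected); Dunn's z vs control on pooled mid-ranks with BH adjustment,
   reported when the omnibus is significant.

Endpoint class membership is a fixed lookup
(:data:`planatox.behavior_endpoints.ENDPOINT_CLASSES`), deterministic and
testable, in place of by-eye normality inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior_endpoints import DEFAULT_TAILS, ENDPOINT_CLASSES

__all__ = [
    "ALPHA",
    "WelchAnova",
    "fisher_exact_vs_control",
    "benjamini_hochberg",
    "welch_t",
    "welch_anova",
    "tamhane_dunnett",
    "kruskal_dunn",
    "lethality_screen",
    "run_endpoint_screen",
]

ALPHA = 0.05
_TAILS = ("one_sided_increase", "one_sided_decrease", "two_sided")


def _check_tail(tail: str) -> None:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}; got {tail!r}")


def fisher_exact_vs_control(
    affected_treated: int,
    n_treated: int,
    affected_control: int,
    n_control: int,
    tail: str = "two_sided",
) -> float:
    """Exact hypergeometric p for a treated-vs-control 2x2 table.

    One-sided tails test an *increase* (or decrease) of the affected
    proportion in the treated group; the two-sided p sums point
    probabilities <= that of the observed table.
    """
    _check_tail(tail)
    for v in (affected_treated, n_treated, affected_control, n_control):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if affected_treated > n_treated or affected_control > n_control:
        raise ValueError("affected count exceeds group size")
    table = [
        [affected_treated, n_treated - affected_treated],
        [affected_control, n_control - affected_control],
    ]
    alternative = {
        "one_sided_increase": "greater",
        "one_sided_decrease": "less",
        "two_sided": "two-sided",
    }[tail]
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values: p_adj(i) = min_{j>=rank(i)} (m/j) p(j),
    capped at 1; order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x: np.ndarray, y: np.ndarray, tail: str = "two_sided") -> Tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df, and p-value.

    The one-sided-increase tail tests mean(x) > mean(y).
    """
    _check_tail(tail)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if tail == "two_sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif tail == "one_sided_increase":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class WelchAnova:
    F: float
    df1: float
    df2: float
    p: float


def welch_anova(groups: Sequence[np.ndarray]) -> WelchAnova:
    """Welch's heteroscedastic one-way ANOVA (Satterthwaite denominator df).

    Reduces to the classical one-way F when variances and group sizes are
    equal.  Raises on groups with fewer than two observations or zero
    variance (the statistic is undefined there).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if g.var(ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    W = w.sum()
    grand = (w * m).sum() / W
    num = (w * (m - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, df1, df2))
    return WelchAnova(float(F), df1, float(df2), p)


def tamhane_dunnett(
    groups: Sequence[np.ndarray],
    control_index: int = 0,
    tail: str = "two_sided",
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one Welch-type comparisons vs control with a family-wise
    max-statistic adjustment (Tamhane–Dunnett style).

    Each comparison uses the Welch t statistic with its Satterthwaite df.
    Adjusted p-values come from the seeded Monte-Carlo null distribution of
    the family maximum of independent t variates with the per-comparison
    dfs — conservative with respect to the positive correlation induced by
    the shared control.  Returns a DataFrame with one row per non-control
    group: (group, t, df, p_raw, p_adj).
    """
    _check_tail(tail)
    groups = [np.asarray(g, float) for g in groups]
    control = groups[control_index]
    others = [i for i in range(len(groups)) if i != control_index]
    if not others:
        raise ValueError("need at least one non-control group")
    ts, dfs, praw = [], [], []
    for i in others:
        t, df, p = welch_t(groups[i], control, tail)
        ts.append(t)
        dfs.append(df)
        praw.append(p)
    rng = np.random.default_rng(seed)
    null = rng.standard_t(np.asarray(dfs), size=(n_mc, len(others)))
    if tail == "two_sided":
        family = np.abs(null).max(axis=1)
        padj = [(family >= abs(t)).mean() for t in ts]
    elif tail == "one_sided_increase":
        family = null.max(axis=1)
        padj = [(family >= t).mean() for t in ts]
    else:
        family = null.min(axis=1)
        padj = [(family <= t).mean() for t in ts]
    return pd.DataFrame(
        {"group": others, "t": ts, "df": dfs, "p_raw": praw, "p_adj": padj}
    )


def kruskal_dunn(
    groups: Sequence[np.ndarray],
    control_index: int = 0,
    tail: str = "two_sided",
) -> Tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis omnibus (tie corrected) + Dunn's many-to-one z tests.

    Dunn's z uses the pooled mid-ranks with the tie-corrected variance; BH
    adjusts across the comparisons.  When every observation is identical the
    omnibus is H = 0, p = 1.  Returns (H, omnibus_p, comparisons frame).
    The post hoc is always computed; callers gate on the omnibus.
    """
    _check_tail(tail)
    groups = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        H, p_omni = 0.0, 1.0
    else:
        H, p_omni = stats.kruskal(*groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    others = [i for i in range(len(groups)) if i != control_index]
    zs, praw = [], []
    for i in others:
        var = base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[control_index]))
        if var <= 0:
            zs.append(0.0)
            praw.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[control_index]) / np.sqrt(var)
        zs.append(float(z))
        if tail == "two_sided":
            praw.append(2 * stats.norm.sf(abs(z)))
        elif tail == "one_sided_increase":
            praw.append(stats.norm.sf(z))
        else:
            praw.append(stats.norm.cdf(z))
    comp = pd.DataFrame(
        {
            "group": others,
            "z": zs,
            "p_raw": praw,
            "p_adj": benjamini_hochberg(praw),
        }
    )
    return float(H), float(p_omni), comp


# --------------------------------------------------------------------------
# Screen-level drivers
# --------------------------------------------------------------------------

def _single_condition(df: pd.DataFrame) -> None:
    for col in ("chemical", "worm_type", "day"):
        if col in df.columns and df[col].nunique() > 1:
            raise ValueError(
                f"expected a single condition; column {col!r} has "
                f"{df[col].nunique()} levels"
            )


def lethality_screen(
    records: pd.DataFrame, alpha: float = ALPHA
) -> Tuple[pd.DataFrame, Set[float]]:
    """Fisher (one-sided increase) + BH lethality testing per concentration.

    ``records`` must be one condition's WormRecord table with ``alive`` and
    ``concentration_uM`` columns including the in-plate control (0 µM).
    Returns the per-concentration results and the lethal set
    {conc : p_adj < alpha}.
    """
    _single_condition(records)
    concs = sorted(records["concentration_uM"].unique())
    if 0.0 not in concs:
        raise ValueError("no in-plate control (0 µM) rows present")
    ctrl = records[records["concentration_uM"] == 0.0]
    n_c = len(ctrl)
    dead_c = int((~ctrl["alive"]).sum())
    rows = []
    for c in concs:
        if c == 0.0:
            continue
        grp = records[records["concentration_uM"] == c]
        dead_t = int((~grp["alive"]).sum())
        p = fisher_exact_vs_control(
            dead_t, len(grp), dead_c, n_c, "one_sided_increase"
        )
        rows.append(
            {
                "endpoint": "lethality",
                "concentration_uM": c,
                "n_treated": len(grp),
                "n_control": n_c,
                "affected_treated": dead_t,
                "affected_control": dead_c,
                "statistic": dead_t / len(grp) - dead_c / n_c,
                "p_raw": p,
                "tail": "one_sided_increase",
                "test_name": "fisher",
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["omnibus_p"] = np.nan
    lethal = set(out.loc[out["p_adj"] < alpha, "concentration_uM"])
    return out, lethal


def run_endpoint_screen(
    endpoint_table: pd.DataFrame,
    lethal_set: Set[float],
    alpha: float = ALPHA,
    seed: int = 0,
    tails: Optional[Dict[str, str]] = None,
    n_mc: int = 100_000,
) -> pd.DataFrame:
    """All sublethal endpoint tests for one condition.

    Lethality rows are ignored here (see :func:`lethality_screen`); lethal
    concentrations are excluded entirely.  Binary endpoints get Fisher + BH;
    normal-class endpoints Welch ANOVA gated Tamhane–Dunnett; skewed
    endpoints Kruskal–Wallis gated Dunn + BH.  Post hoc p-values are NaN
    when the omnibus is not significant (no post hoc is emitted).
    """
    tails = tails or DEFAULT_TAILS
    cols = [
        "endpoint", "concentration_uM", "n_treated", "n_control",
        "statistic", "p_raw", "p_adj", "omnibus_p", "tail", "test_name",
        "lethal_excluded",
    ]
    if endpoint_table.empty:
        return pd.DataFrame(columns=cols)
    _single_condition(endpoint_table)
    df = endpoint_table[endpoint_table["endpoint"] != "lethality"]
    df = df[~df["concentration_uM"].isin(lethal_set)]

    rows: List[dict] = []
    for endpoint, edf in df.groupby("endpoint", sort=False):
        klass = ENDPOINT_CLASSES.get(endpoint)
        if klass is None:
            raise ValueError(f"unknown endpoint class for {endpoint!r}")
        tail = tails[endpoint]
        concs = sorted(edf["concentration_uM"].unique())
        if 0.0 not in concs:
            raise ValueError(f"{endpoint}: no in-plate control values")
        treated_concs = [c for c in concs if c != 0.0]
        values = {
            c: edf.loc[edf["concentration_uM"] == c, "value"].to_numpy()
            for c in concs
        }

        if klass == "binary":
            n_c = len(values[0.0])
            aff_c = int(values[0.0].sum())
            praw = []
            for c in treated_concs:
                praw.append(
                    fisher_exact_vs_control(
                        int(values[c].sum()), len(values[c]), aff_c, n_c, tail
                    )
                )
            padj = benjamini_hochberg(praw)
            for c, pr, pa in zip(treated_concs, praw, padj):
                rows.append(
                    {
                        "endpoint": endpoint,
                        "concentration_uM": c,
                        "n_treated": len(values[c]),
                        "n_control": n_c,
                        "statistic": values[c].mean() - values[0.0].mean(),
                        "p_raw": pr,
                        "p_adj": pa,
                        "omnibus_p": np.nan,
                        "tail": tail,
                        "test_name": "fisher",
                    }
                )
            continue

        # continuous branches need >= 2 observations per group; the Welch
        # branch additionally needs positive variance (a degenerate group —
        # e.g. zero bursts for every animal — cannot be t-tested and is
        # excluded from this endpoint's family)
        usable = [c for c in treated_concs if len(values[c]) >= 2]
        if klass == "normal":
            if values[0.0].var(ddof=1) == 0:
                continue
            usable = [c for c in usable if values[c].var(ddof=1) > 0]
        groups = [values[0.0]] + [values[c] for c in usable]
        if len(values[0.0]) < 2 or not usable:
            continue
        if klass == "normal":
            test_name = "welch_tamhane_dunnett"
            omni = welch_anova(groups).p
            post = (
                tamhane_dunnett(groups, 0, tail, n_mc=n_mc, seed=seed)
                if omni < alpha
                else None
            )
            stat_col = "t"
        else:
            test_name = "kruskal_dunn"
            _, omni, comp = kruskal_dunn(groups, 0, tail)
            post = comp if omni < alpha else None
            stat_col = "z"
        for j, c in enumerate(usable):
            if post is not None:
                stat = float(post.iloc[j][stat_col])
                pr = float(post.iloc[j]["p_raw"])
                pa = float(post.iloc[j]["p_adj"])
            else:
                stat, pr, pa = np.nan, np.nan, np.nan
            rows.append(
                {
                    "endpoint": endpoint,
                    "concentration_uM": c,
                    "n_treated": len(values[c]),
                    "n_control": len(values[0.0]),
                    "statistic": stat,
                    "p_raw": pr,
                    "p_adj": pa,
                    "omnibus_p": omni,
                    "tail": tail,
                    "test_name": test_name,
                }
            )

    out = pd.DataFrame(rows, columns=cols[:-1])
    out["lethal_excluded"] = out["concentration_uM"].isin(lethal_set)
    return out
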