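"""Fisher/BH/Welch/Tamhane-Dunnett/Kruskal-Dunn statistics and screen drivers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from planatox import screening_stats as ss
from planatox.behavior_endpoints import DEFAULT_TAILS


# ------------------------------------------------------------------ fisher ---

def fisher_enumeration_oracle(a_t, n_t, a_c, n_c, tail):
    """Brute-force hypergeometric enumeration over all tables with the
    observed margins; independent of scipy's implementation."""
    K = a_t + a_c          # total affected
    N = n_t + n_c
    support = range(max(0, K - n_c), min(K, n_t) + 1)
    pmf = {k: stats.hypergeom.pmf(k, N, K, n_t) for k in support}
    if tail == "one_sided_increase":
        return sum(p for k, p in pmf.items() if k >= a_t)
    if tail == "one_sided_decrease":
        return sum(p for k, p in pmf.items() if k <= a_t)
    obs = pmf[a_t]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "a_t, n_t, a_c, n_c, expected",
    [
        (18, 23, 0, 24, 7.4e-9),   # abnormal shapes, day 7
        (14, 21, 0, 24, 7.0e-7),   # abnormal shapes, day 12
    ],
)
def test_fisher_reference_values(a_t, n_t, a_c, n_c, expected):
    p = ss.fisher_exact_vs_control(a_t, n_t, a_c, n_c, "one_sided_increase")
    assert p == pytest.approx(expected, rel=0.05)  # 2 s.f. agreement
    assert float(f"{p:.1e}") == expected


@pytest.mark.parametrize("tail", ["one_sided_increase", "one_sided_decrease", "two_sided"])
@pytest.mark.parametrize(
    "a_t, n_t, a_c, n_c",
    [(18, 23, 0, 24), (5, 12, 2, 12), (0, 24, 0, 24), (9, 24, 0, 24),
     (3, 10, 7, 10), (12, 24, 12, 24)],
)
def test_fisher_matches_enumeration_oracle(a_t, n_t, a_c, n_c, tail):
    assert ss.fisher_exact_vs_control(a_t, n_t, a_c, n_c, tail) == pytest.approx(
        fisher_enumeration_oracle(a_t, n_t, a_c, n_c, tail), rel=1e-9
    )


def test_fisher_identical_proportions():
    assert ss.fisher_exact_vs_control(0, 24, 0, 24, "one_sided_increase") == 1.0


def test_fisher_count_errors():
    with pytest.raises(ValueError):
        ss.fisher_exact_vs_control(-1, 10, 0, 10, "two_sided")
    with pytest.raises(ValueError):
        ss.fisher_exact_vs_control(11, 10, 0, 10, "two_sided")


# ---------------------------------------------------------------------- BH ---

def bh_oracle(p):
    """Hand-computed step-up: p_adj(i) = min_{j >= rank(i)} (m/j) p_(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m / rank * p[i])
        adj[i] = running
    return adj


def test_bh_fixed_lists():
    assert ss.benjamini_hochberg([0.2]) == pytest.approx([0.2])
    assert ss.benjamini_hochberg([0.03, 0.03, 0.03]) == pytest.approx([0.03] * 3)
    assert ss.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
def test_bh_matches_hand_step_up(p):
    assert ss.benjamini_hochberg(p) == pytest.approx(bh_oracle(p), abs=1e-12)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8),
       st.randoms(use_true_random=False))
def test_bh_permutation_invariant_monotone_capped(p, rnd):
    adj = ss.benjamini_hochberg(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    adj_perm = ss.benjamini_hochberg([p[i] for i in perm])
    assert adj_perm == pytest.approx([adj[i] for i in perm], abs=1e-12)
    # adjusted values are monotone non-decreasing in raw-p rank order, <= 1
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj <= 1.0)


# ------------------------------------------------------------- Welch ANOVA ---

def test_welch_reduces_to_classical_anova():
    """Two equal-sized, equal-variance groups: Welch F == classical F to
    1e-10 (the k=2 correction term vanishes and the pooled and Welch
    standard errors coincide)."""
    rng = np.random.default_rng(1)
    base = rng.standard_normal(20)
    groups = [base, base + 0.6]
    res = ss.welch_anova(groups)
    F_classic, p_classic = stats.f_oneway(*groups)
    assert res.F == pytest.approx(F_classic, abs=1e-10)
    assert res.p == pytest.approx(p_classic, abs=1e-10)
    assert res.df2 == pytest.approx(2 * len(base) - 2, abs=1e-9)


def test_welch_close_to_classical_under_homoscedasticity():
    """With more groups the Welch denominator correction is O(1/n): the two
    statistics agree closely (not exactly) on balanced homoscedastic data."""
    rng = np.random.default_rng(1)
    base = rng.standard_normal(200)
    groups = [base + shift for shift in (0.0, 0.1, 0.25, -0.1)]
    res = ss.welch_anova(groups)
    F_classic, _ = stats.f_oneway(*groups)
    assert res.F == pytest.approx(F_classic, rel=0.02)


def test_welch_two_groups_equals_squared_t():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 25)
    res = ss.welch_anova([x, y])
    t, df, p = ss.welch_t(x, y)
    assert res.F == pytest.approx(t**2, rel=1e-9)
    assert res.p == pytest.approx(p, rel=1e-9)
    assert res.df2 == pytest.approx(df, rel=1e-9)


def test_welch_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, s, n) for m, s, n in
              [(0, 1, 12), (0.4, 2, 20), (1.0, 0.5, 8)]]
    df = pd.DataFrame(
        {"y": np.concatenate(groups),
         "g": np.repeat(list("abc"), [len(g) for g in groups])}
    )
    ref = pg.welch_anova(data=df, dv="y", between="g")
    res = ss.welch_anova(groups)
    assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
    assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


def test_welch_separation_and_errors():
    rng = np.random.default_rng(4)
    g = [rng.normal(0, 1, 24), rng.normal(10, 1, 24)]
    assert ss.welch_anova(g).p < 1e-6
    with pytest.raises(ValueError, match="zero variance"):
        ss.welch_anova([np.zeros(5), rng.normal(0, 1, 5)])
    with pytest.raises(ValueError):
        ss.welch_anova([np.array([1.0]), rng.normal(0, 1, 5)])


# --------------------------------------------------------- Tamhane-Dunnett ---

def test_tamhane_dunnett_single_comparison_matches_welch_t():
    rng = np.random.default_rng(5)
    control, treated = rng.normal(0, 1, 24), rng.normal(0.7, 1.5, 24)
    out = ss.tamhane_dunnett([control, treated], 0, "two_sided", seed=1)
    _, _, p_t = ss.welch_t(treated, control, "two_sided")
    assert out["p_adj"].iloc[0] == pytest.approx(p_t, abs=0.005)  # MC error


def test_tamhane_dunnett_multiplicity_inflates():
    rng = np.random.default_rng(6)
    groups = [rng.normal(0, 1, 24) for _ in range(5)]
    out = ss.tamhane_dunnett(groups, 0, "two_sided", seed=2)
    assert (out["p_adj"] >= out["p_raw"] - 0.01).all()


def test_tamhane_dunnett_familywise_error_controlled():
    """7-group null: P(any adjusted p < 0.05) <= 0.05 + 2 MC s.e."""
    rng = np.random.default_rng(7)
    n_rep = 250
    hits = 0
    for _ in range(n_rep):
        groups = [rng.normal(0, 1, 24) for _ in range(8)]
        out = ss.tamhane_dunnett(groups, 0, "two_sided", n_mc=20_000, seed=3)
        hits += (out["p_adj"] < 0.05).any()
    rate = hits / n_rep
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


def test_tamhane_dunnett_one_sided_detects_direction():
    rng = np.random.default_rng(8)
    control = rng.normal(1.0, 0.2, 24)
    slow = rng.normal(0.4, 0.2, 24)
    out = ss.tamhane_dunnett([control, slow], 0, "one_sided_decrease", seed=4)
    assert out["p_adj"].iloc[0] < 0.001
    out_inc = ss.tamhane_dunnett([control, slow], 0, "one_sided_increase", seed=4)
    assert out_inc["p_adj"].iloc[0] > 0.9


# ------------------------------------------------------------ Kruskal-Dunn ---

def test_kruskal_all_identical_gives_unit_p():
    H, p, comp = ss.kruskal_dunn([np.ones(10), np.ones(12)], 0)
    assert H == 0.0 and p == 1.0


def test_kruskal_two_groups_matches_mannwhitney_normal_approx():
    rng = np.random.default_rng(9)
    x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 18)  # continuous: no ties
    _, _, comp = ss.kruskal_dunn([x, y], 0)
    U = stats.mannwhitneyu(y, x, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    assert comp["p_raw"].iloc[0] == pytest.approx(U.pvalue, rel=1e-6)


def test_kruskal_dunn_bh_adjustment_applied():
    rng = np.random.default_rng(10)
    groups = [rng.lognormal(0, 1, 24) for _ in range(4)]
    _, _, comp = ss.kruskal_dunn(groups, 0)
    assert comp["p_adj"].to_numpy() == pytest.approx(
        bh_oracle(comp["p_raw"].to_numpy()), abs=1e-12
    )


def test_kruskal_dunn_type1_error_on_skewed_null():
    rng = np.random.default_rng(11)
    n_rep, hits = 400, 0
    for _ in range(n_rep):
        groups = [rng.lognormal(0, 1, 24) for _ in range(3)]
        _, p_omni, _ = ss.kruskal_dunn(groups, 0)
        hits += p_omni < 0.05
    rate = hits / n_rep
    assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_rep)


# -------------------------------------------------------- lethality screen ---

def _lethality_records(dead_per_conc, n=24, chem="x"):
    rows = []
    for conc, n_dead in dead_per_conc.items():
        for i in range(n):
            rows.append(
                {"record_id": f"{conc}-{i}", "chemical": chem,
                 "concentration_uM": conc, "worm_type": "adult", "day": 7,
                 "run": 1 + i % 2, "alive": i >= n_dead}
            )
    return pd.DataFrame(rows)


def test_lethality_screen_top_dose_total_kill():
    concs = {0.0: 0, 1.0: 0, 3.16: 0, 10.0: 0, 31.6: 0, 100.0: 0, 316.0: 0,
             1000.0: 24}
    results, lethal = ss.lethality_screen(_lethality_records(concs))
    assert lethal == {1000.0}
    assert len(results) == 7


def test_lethality_screen_all_alive():
    concs = {c: 0 for c in (0.0, 1.0, 3.16, 10.0, 31.6, 100.0, 316.0, 1000.0)}
    results, lethal = ss.lethality_screen(_lethality_records(concs))
    assert lethal == set()
    assert (results["p_adj"] == 1.0).all()


def test_lethality_screen_nine_of_24_flagged():
    """9/24 dead vs 0/24, single affected concentration among 7: the exact
    one-sided p times the worst-case BH factor stays under alpha."""
    concs = {c: 0 for c in (0.0, 1.0, 3.16, 10.0, 31.6, 100.0, 316.0)}
    concs[1000.0] = 9
    results, lethal = ss.lethality_screen(_lethality_records(concs))
    assert lethal == {1000.0}
    p_raw = fisher_enumeration_oracle(9, 24, 0, 24, "one_sided_increase")
    row = results[results.concentration_uM == 1000.0].iloc[0]
    assert row.p_raw == pytest.approx(p_raw, rel=1e-9)
    assert row.p_adj == pytest.approx(min(1.0, 7 * p_raw), rel=1e-9)


def test_lethality_screen_requires_control():
    concs = {1.0: 0, 10.0: 2}
    with pytest.raises(ValueError, match="control"):
        ss.lethality_screen(_lethality_records(concs))


# ---------------------------------------------------------- endpoint screen ---

def _endpoint_table(endpoint, klass, tail, values_by_conc):
    rows = []
    for conc, vals in values_by_conc.items():
        for i, v in enumerate(vals):
            rows.append(
                {"record_id": f"{endpoint}-{conc}-{i}", "chemical": "x",
                 "concentration_uM": conc, "worm_type": "adult", "day": 7,
                 "run": 1 + i % 2, "endpoint": endpoint, "value": v,
                 "endpoint_class": klass, "tail": tail}
            )
    return pd.DataFrame(rows)


def test_endpoint_screen_excludes_lethal_concentrations():
    rng = np.random.default_rng(12)
    vals = {c: rng.normal(1, 0.2, 24) for c in (0.0, 10.0, 100.0, 316.0)}
    table = _endpoint_table("speed", "normal", "one_sided_decrease", vals)
    out = ss.run_endpoint_screen(table, lethal_set={316.0}, seed=0)
    assert 316.0 not in set(out["concentration_uM"])


def test_endpoint_screen_gating_blocks_post_hoc():
    rng = np.random.default_rng(13)
    vals = {c: rng.normal(1, 0.2, 24) for c in (0.0, 10.0, 100.0)}
    table = _endpoint_table("speed", "normal", "one_sided_decrease", vals)
    out = ss.run_endpoint_screen(table, lethal_set=set(), seed=0)
    if (out["omnibus_p"] >= 0.05).all():
        assert out["p_adj"].isna().all()  # no post hoc emitted


def test_endpoint_screen_binary_branch():
    vals = {0.0: [0] * 24, 100.0: [1] * 18 + [0] * 6}
    table = _endpoint_table("body_shape", "binary", "one_sided_increase", vals)
    out = ss.run_endpoint_screen(table, lethal_set=set(), seed=0)
    assert out["test_name"].iloc[0] == "fisher"
    assert out["p_adj"].iloc[0] < 1e-5


def test_endpoint_screen_skewed_branch_uses_kruskal_dunn():
    rng = np.random.default_rng(14)
    vals = {0.0: rng.lognormal(0, 0.5, 24), 100.0: rng.lognormal(2.0, 0.5, 24)}
    table = _endpoint_table("resting_dark", "skewed", "one_sided_increase", vals)
    out = ss.run_endpoint_screen(table, lethal_set=set(), seed=0)
    assert out["test_name"].iloc[0] == "kruskal_dunn"
    assert out["p_adj"].iloc[0] < 0.001


def test_endpoint_screen_empty_table():
    assert ss.run_endpoint_screen(pd.DataFrame(), set()).empty


def test_endpoint_screen_unknown_endpoint_errors():
    table = _endpoint_table("mystery", "normal", "two_sided", {0.0: [1, 2], 1.0: [2, 3]})
    with pytest.raises(ValueError, match="unknown endpoint"):
        ss.run_endpoint_screen(table, set(), tails={"mystery": "two_sided"})
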