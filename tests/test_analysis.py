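"""Statistics stage: mixed ANOVA vs an independent oracle, t-tests, summaries."""

import numpy as np
import pandas as pd
import pytest

from plmotion import (
    ANOVA_EFFECTS,
    CohortSpec,
    GroupSummary,
    ParametricObserver,
    SessionConfig,
    marginal_means,
    mixed_anova_2x2x2,
    paired_t,
    run_session,
    sensitivity_from_sessions,
    simulate_cohort_direct,
    summarize_cohort,
    welch_t,
)
from plmotion.runner import CONDITIONS


def cohort_from_cells(cells, n_per_group=4, jitter=None):
    """Long table whose every participant equals the cell means (+ optional
    per-row jitter array)."""
    rows = []
    i = 0
    for group in ("expert", "novice"):
        for s in range(n_per_group):
            for domain, orientation in CONDITIONS:
                v = cells[(domain, orientation)]
                if jitter is not None:
                    v = v + jitter[i]
                    i += 1
                rows.append({
                    "participant": f"{group[0]}{s}", "group": group,
                    "domain": domain, "orientation": orientation,
                    "sensitivity": v,
                })
    return pd.DataFrame(rows)


# 4-subject toy dataset with a frozen independent oracle: sums of squares and
# F ratios from a split-plot analysis with subject nested in group
# (Error(participant/(domain*orientation)) strata), computed externally once.
TOY = {
    ("s1", "expert"): {("bird", "inverted"): 8, ("bird", "upright"): 10,
                       ("human", "inverted"): 12, ("human", "upright"): 20},
    ("s2", "expert"): {("bird", "inverted"): 9, ("bird", "upright"): 12,
                       ("human", "inverted"): 15, ("human", "upright"): 24},
    ("s3", "novice"): {("bird", "inverted"): 7, ("bird", "upright"): 9,
                       ("human", "inverted"): 11, ("human", "upright"): 15},
    ("s4", "novice"): {("bird", "inverted"): 10, ("bird", "upright"): 11,
                       ("human", "inverted"): 9, ("human", "upright"): 18},
}

TOY_ORACLE = {
    #                     SS      SS_err   F            p
    "group":              (25.00, 17.0, 25 / 8.5,      0.228483),
    "domain":             (144.0,  4.0, 72.0,          0.013606),
    "orientation":        (90.25,  2.5, 72.2,          0.013569),
    "group:domain":       (16.00,  4.0,  8.0,          0.105573),
    "group:orientation":  (2.25,   2.5,  1.8,          0.311753),
    "domain:orientation": (30.25,  4.5, 30.25 / 2.25,  0.066992),
    "group:domain:orientation": (0.25, 4.5, 0.25 / 2.25, 0.770584),
}
TOY_ERROR_SUM = 17.0 + 4.0 + 2.5 + 4.5  # all subject-related error SS


def toy_cohort():
    rows = []
    for (s, g), cells in TOY.items():
        for (d, o), v in cells.items():
            rows.append({"participant": s, "group": g, "domain": d,
                         "orientation": o, "sensitivity": float(v)})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_oracle_to_high_precision(self):
        tab = mixed_anova_2x2x2(toy_cohort()).set_index("effect")
        for effect, (ss, ss_err, f, p) in TOY_ORACLE.items():
            row = tab.loc[effect]
            assert row["ss"] == pytest.approx(ss, abs=1e-9)
            assert row["ss_error"] == pytest.approx(ss_err, abs=1e-9)
            assert row["F"] == pytest.approx(f, rel=1e-9)
            assert row["p"] == pytest.approx(p, abs=1e-5)
            assert row["ges"] == pytest.approx(ss / (ss + TOY_ERROR_SUM), rel=1e-9)
            assert (row["df_num"], row["df_den"]) == (1, 2)

    def test_ss_conservation_on_random_cohorts(self):
        from plmotion.analysis import _anova_core

        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.normal(10, 3, size=(2, 6, 2, 2))
            core = _anova_core(y)
            strata = core["_strata"]
            effect_ss = sum(core[e]["ss"] for e in ANOVA_EFFECTS)
            error_ss = (strata["ss_subjects_within_groups"]
                        + strata["ss_domain_x_subj"]
                        + strata["ss_orientation_x_subj"]
                        + strata["ss_domain_orientation_x_subj"])
            assert effect_ss + error_ss == pytest.approx(
                strata["ss_total"], rel=1e-9
            )

    def test_degenerate_identical_responses_rejected(self):
        df = cohort_from_cells({c: 5.0 for c in CONDITIONS})
        with pytest.raises(ValueError, match="degenerate"):
            mixed_anova_2x2x2(df)

    def test_unbalanced_rejected(self):
        df = toy_cohort().iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova_2x2x2(df)

    def test_power_for_reported_inversion_effect(self):
        # an upright-vs-inverted human difference of ~15.7 dots with
        # between-subject SD 10 at n=20/group is detected essentially always
        cells = {("human", "upright"): 28.97, ("human", "inverted"): 13.28,
                 ("bird", "upright"): 11.19, ("bird", "inverted"): 10.08}
        spec = CohortSpec(
            n_per_group=20,
            condition_means={(g, d, o): cells[(d, o)]
                             for g in ("expert", "novice")
                             for d, o in CONDITIONS},
            between_subject_sd=10.0,
            measurement_sd=4.0,
        )
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            df = simulate_cohort_direct(spec, np.random.default_rng(seed))
            tab = mixed_anova_2x2x2(df).set_index("effect")
            if tab.loc["orientation", "p"] < 0.05:
                hits += 1
        assert hits / n_sims > 0.9


class TestWelch:
    def test_reproduces_printed_expertise_comparison(self):
        # expert d' 1.84 (SD 0.53, n 19) vs novice 0.78 (SD 0.30, n 20)
        res = welch_t(GroupSummary(1.84, 0.53, 19), GroupSummary(0.78, 0.30, 20))
        assert res.t == pytest.approx(7.68, rel=0.01)
        assert res.df == pytest.approx(28.13, rel=0.01)
        assert res.p < 0.001

    def test_closed_form_hand_value(self):
        res = welch_t(GroupSummary(1.84, 0.53, 19), GroupSummary(0.78, 0.30, 20))
        va, vb = 0.53**2 / 19, 0.30**2 / 20
        assert res.t == pytest.approx(1.06 / np.sqrt(va + vb), rel=1e-12)
        df = (va + vb) ** 2 / (va**2 / 18 + vb**2 / 19)
        assert res.df == pytest.approx(df, rel=1e-12)

    def test_equal_summaries_give_zero(self):
        res = welch_t(GroupSummary(5, 1, 10), GroupSummary(5, 1, 10))
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_satterthwaite_limit_equal_var_and_n(self):
        res = welch_t(GroupSummary(5, 2, 12), GroupSummary(4, 2, 12))
        assert res.df == pytest.approx(22.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t(GroupSummary(5, 0, 10), GroupSummary(4, 0, 10))


class TestPairedT:
    def test_identical_scores(self):
        t, df, p = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        _, df, _ = paired_t(x, y)
        assert df == 39

    def test_toy_hand_computation(self):
        x = np.array([10.0, 12, 9, 14, 11])
        y = np.array([8.0, 11, 9, 10, 9])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, df, p = paired_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == 4

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3, 4], [1.0, 2, 3])


class TestSummaries:
    def test_marginals_reproduce_printed_values(self):
        cells = {("human", "upright"): 28.97, ("human", "inverted"): 13.28,
                 ("bird", "upright"): 11.19, ("bird", "inverted"): 10.08}
        df = cohort_from_cells(cells)
        mm = marginal_means(df).set_index(["domain", "orientation"])
        assert mm.loc[("all", "upright"), "mean"] == pytest.approx(20.08)
        assert mm.loc[("all", "inverted"), "mean"] == pytest.approx(11.68)
        assert mm.loc[("bird", "all"), "mean"] == pytest.approx(10.635)
        assert mm.loc[("human", "all"), "mean"] == pytest.approx(21.125)

    def test_constant_cohort_marginals(self):
        df = cohort_from_cells({c: 7.5 for c in CONDITIONS})
        mm = marginal_means(df)
        assert np.allclose(mm["mean"], 7.5)
        assert np.allclose(mm["se"], 0.0)

    def test_summarize_cohort_shape_and_se(self):
        df = cohort_from_cells({c: 7.5 for c in CONDITIONS})
        out = summarize_cohort(df)
        assert len(out) == 4  # 2 groups x 2 domains
        assert np.allclose(out["se"], 0.0)

    def test_sensitivity_from_sessions(self):
        observers = {c: ParametricObserver.with_threshold(20.0) for c in CONDITIONS}
        records = [
            run_session(
                SessionConfig(participant_id=f"p{i}", observers=observers,
                              compose_stimuli=False),
                np.random.default_rng(i),
            )
            for i in range(3)
        ]
        df = sensitivity_from_sessions(records)
        assert len(df) == 12
        rec = records[0]
        got = df[(df["participant"] == "p0") & (df["domain"] == "bird")
                 & (df["orientation"] == "upright")]["sensitivity"].iloc[0]
        assert got == rec.condition_threshold("bird", "upright")
        with pytest.raises(ValueError):
            sensitivity_from_sessions([])


def test_sensitivity_plot_smoke(tmp_path):
    """The condition-means plot renders one errorbar series per group."""
    import matplotlib

    matplotlib.use("Agg")
    from plmotion.plotting import plot_sensitivity

    spec = CohortSpec(n_per_group=4)
    cohort = simulate_cohort_direct(spec, np.random.default_rng(0))
    ax = plot_sensitivity(cohort)
    assert len(ax.get_legend().get_texts()) == 2
    ax.figure.savefig(tmp_path / "fig.png")
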