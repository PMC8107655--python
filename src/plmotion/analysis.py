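"""Statistical pipeline for cohort tables.

Implements the study's analysis chain: per-participant condition
sensitivities -> cell and marginal means -> a 2 x 2 x 2 mixed-design
(split-plot) ANOVA with group between subjects and domain / orientation
within subjects, with generalized eta squared effect sizes -> follow-up
paired t-tests, plus Welch's t for the between-group expertise scores.

The mixed ANOVA is computed from an explicit sums-of-squares decomposition
with subject as a random factor nested in group.  Error strata: subjects
within groups tests the group effect; the domain x subject, orientation x
subject, and domain x orientation x subject (within groups) interactions
test the within-subject effects they correspond to.  Generalized eta
squared for an effect is SS_effect / (SS_effect + sum of all four
subject-related error SS) — the all-factors-manipulated convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .runner import CONDITIONS, SessionRecord

__all__ = [
    "GroupSummary",
    "WelchResult",
    "sensitivity_from_sessions",
    "marginal_means",
    "mixed_anova_2x2x2",
    "welch_t",
    "paired_t",
    "summarize_cohort",
]

ANOVA_EFFECTS = (
    "group",
    "domain",
    "orientation",
    "group:domain",
    "group:orientation",
    "domain:orientation",
    "group:domain:orientation",
)


@dataclass(frozen=True)
class GroupSummary:
    """A printed group summary: mean, dispersion (SD), and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def sensitivity_from_sessions(records: list[SessionRecord]) -> pd.DataFrame:
    """Build the long cohort table (one row per participant x condition)
    from completed session records."""
    if not records:
        raise ValueError("no session records given")
    rows = []
    for rec in records:
        for domain, orientation in CONDITIONS:
            rows.append({
                "participant": rec.participant_id, "group": rec.group,
                "domain": domain, "orientation": orientation,
                "sensitivity": rec.condition_threshold(domain, orientation),
            })
    return pd.DataFrame(rows)


def _check_balanced(cohort: pd.DataFrame) -> None:
    counts = cohort.groupby(["participant"]).size()
    if not (counts == 4).all():
        raise ValueError("cohort must have exactly 4 rows per participant")
    per_group = cohort.groupby("group")["participant"].nunique()
    if per_group.nunique() != 1:
        raise ValueError("groups must be equal-sized")


def marginal_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cell means/SEs plus domain and orientation marginals.

    Marginal means are unweighted averages of their constituent cell means
    (equal to the mean of participant-level marginal scores in a balanced
    design); marginal SEs are between-subject SEs of those participant-level
    scores.  Returns a tidy table with columns (domain, orientation, mean,
    se, n); marginals carry "all" in the collapsed factor column.
    """
    _check_balanced(cohort)
    out = []
    cells = cohort.groupby(["domain", "orientation"])["sensitivity"]
    for (d, o), vals in cells:
        out.append({"domain": d, "orientation": o, "mean": vals.mean(),
                    "se": vals.sem(), "n": len(vals)})
    for factor, other in (("domain", "orientation"), ("orientation", "domain")):
        per_subj = cohort.groupby(["participant", factor])["sensitivity"].mean()
        for level, vals in per_subj.groupby(level=factor):
            row = {"domain": "all", "orientation": "all",
                   "mean": vals.mean(), "se": vals.sem(), "n": len(vals)}
            row[factor] = level
            out.append(row)
    return pd.DataFrame(out, columns=["domain", "orientation", "mean", "se", "n"])


def _anova_core(y: np.ndarray) -> dict[str, dict[str, float]]:
    """Split-plot SS decomposition on y with shape (2 groups, n, 2, 2).

    Axes: group g, subject s (nested in group), domain d, orientation o.
    """
    a, n, _, _ = y.shape
    gm = y.mean()
    ss = lambda m, w: w * np.sum((m - gm) ** 2)  # noqa: E731

    m_g = y.mean(axis=(1, 2, 3))
    m_d = y.mean(axis=(0, 1, 3))
    m_o = y.mean(axis=(0, 1, 2))
    m_gd = y.mean(axis=(1, 3))
    m_go = y.mean(axis=(1, 2))
    m_do = y.mean(axis=(0, 1))
    m_gdo = y.mean(axis=1)
    m_s = y.mean(axis=(2, 3))       # (g, n)
    m_sd = y.mean(axis=3)           # (g, n, 2)
    m_so = y.mean(axis=2)           # (g, n, 2)

    ss_total = np.sum((y - gm) ** 2)
    ss_g = ss(m_g, 4 * n)
    ss_d = ss(m_d, 4 * n)
    ss_o = ss(m_o, 4 * n)
    ss_gd = ss(m_gd, 2 * n) - ss_g - ss_d
    ss_go = ss(m_go, 2 * n) - ss_g - ss_o
    ss_do = ss(m_do, 2 * n) - ss_d - ss_o
    ss_gdo = ss(m_gdo, n) - ss_g - ss_d - ss_o - ss_gd - ss_go - ss_do
    ss_between_subj = ss(m_s, 4)
    ss_subj = ss_between_subj - ss_g
    ss_dsubj = ss(m_sd, 2) - ss_between_subj - ss_d - ss_gd
    ss_osubj = ss(m_so, 2) - ss_between_subj - ss_o - ss_go
    ss_dosubj = (ss_total - ss_between_subj - ss_d - ss_o - ss_do
                 - ss_gd - ss_go - ss_gdo - ss_dsubj - ss_osubj)

    df_err = a * (n - 1)
    err_total = ss_subj + ss_dsubj + ss_osubj + ss_dosubj
    table = {}
    effects = {
        "group": (ss_g, ss_subj),
        "domain": (ss_d, ss_dsubj),
        "orientation": (ss_o, ss_osubj),
        "group:domain": (ss_gd, ss_dsubj),
        "group:orientation": (ss_go, ss_osubj),
        "domain:orientation": (ss_do, ss_dosubj),
        "group:domain:orientation": (ss_gdo, ss_dosubj),
    }
    for name, (ss_eff, ss_err) in effects.items():
        if ss_err <= 0:
            raise ValueError(
                "degenerate data: zero error sum of squares for effect "
                f"{name!r} (all responses identical?)"
            )
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        f = ms_eff / ms_err
        table[name] = {
            "ss": float(ss_eff),
            "ss_error": float(ss_err),
            "df_num": 1,
            "df_den": df_err,
            "F": float(f),
            "p": float(stats.f.sf(f, 1, df_err)),
            "ges": float(ss_eff / (ss_eff + err_total)),
        }
    table["_strata"] = {
        "ss_total": float(ss_total),
        "ss_subjects_within_groups": float(ss_subj),
        "ss_domain_x_subj": float(ss_dsubj),
        "ss_orientation_x_subj": float(ss_osubj),
        "ss_domain_orientation_x_subj": float(ss_dosubj),
    }
    return table


def mixed_anova_2x2x2(cohort: pd.DataFrame) -> pd.DataFrame:
    """2 (group) x 2 (domain) x 2 (orientation) mixed-design ANOVA.

    Requires a balanced, complete long table (columns participant, group,
    domain, orientation, sensitivity) with >= 2 participants per group.
    Returns one row per effect with F, dfs, p, and generalized eta squared.
    """
    _check_balanced(cohort)
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    wide = cohort.pivot_table(
        index=["group", "participant"], columns=["domain", "orientation"],
        values="sensitivity",
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("missing cells in cohort table")
    n = len(wide.loc[groups[0]])
    if n < 2:
        raise ValueError("need >= 2 participants per group")
    domains = sorted(cohort["domain"].unique())
    orientations = sorted(cohort["orientation"].unique())
    y = np.empty((2, n, 2, 2))
    for gi, g in enumerate(groups):
        block = wide.loc[g]
        for di, d in enumerate(domains):
            for oi, o in enumerate(orientations):
                y[gi, :, di, oi] = block[(d, o)].to_numpy()
    core = _anova_core(y)
    rows = [
        {"effect": name, **{k: v for k, v in core[name].items()}}
        for name in ANOVA_EFFECTS
    ]
    return pd.DataFrame(rows)


def welch_t(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's two-sample t-test from group summaries (unequal variances,
    Welch–Satterthwaite degrees of freedom, two-sided p)."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test on matched per-participant scores; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    if d.var(ddof=1) == 0:
        if np.all(d == 0):  # identical scores: no effect at all
            return 0.0, len(x) - 1, 1.0
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group x domain summary collapsed over orientation.

    For each participant, average the two orientations within a domain;
    report the group mean and between-subject SE of those participant-level
    means.  Output shape: 2 groups x 2 domains.
    """
    _check_balanced(cohort)
    per_subj = (
        cohort.groupby(["group", "participant", "domain"])["sensitivity"]
        .mean()
        .reset_index()
    )
    out = (
        per_subj.groupby(["group", "domain"])["sensitivity"]
        .agg(mean="mean", se="sem", n="count")
        .reset_index()
    )
    return out
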