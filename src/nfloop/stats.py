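"""Subject- and group-level inferential statistics.

The central tool is a classical mixed-design (split-plot) ANOVA for
balanced complete tables: subjects are a random factor nested in the
between-subjects factors, and every effect is tested against its
conventional error term -- subjects-within-groups for between effects,
and the (within-part x subjects-within-groups) interaction for effects
involving within factors. Sums of squares are computed by
inclusion-exclusion over margin means, which for balanced data equals
the textbook decomposition.

Also provided: the per-subject linear-trend contrast over runs compared
between groups, simple and paired t tests, the 7-point run regression
and its slope comparison, the ROI deviation-contrast analysis, and the
Go/No-go reaction-time analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from nfloop.gonogo import mean_go_rt

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """Effect table plus a descriptor of the design that produced it."""

    table: pd.DataFrame  # columns: effect, ss, df1, df2, F, p, gg_epsilon, p_gg
    within: tuple[str, ...]
    between: tuple[str, ...]
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table.effect == name]
        if rows.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table.effect)}")
        return rows.iloc[0]


@dataclass
class RegressionResult:
    """Simple OLS of y on x with the F test of the slope."""

    slope: float
    intercept: float
    F: float
    df1: int
    df2: int
    r2: float
    p: float
    n: int
    sse: float  # residual sum of squares
    sxx: float  # sum of squared centered x


def _check_balanced(data: pd.DataFrame, dv: str, within: list[str], between: list[str], subject: str) -> None:
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("unbalanced table: each subject must have every within-cell exactly once")
    cells = data.groupby(subject, observed=True)[within].nunique() if within else None
    sub_groups = data.groupby(subject, observed=True)[between].nunique() if between else None
    if between:
        if (sub_groups > 1).any().any():
            raise ValueError("a subject appears in more than one between-subjects cell")
        per_cell = data.drop_duplicates(subject).groupby(between, observed=True)[subject].count()
        if per_cell.nunique() > 1:
            raise ValueError("unequal group sizes: the classical decomposition requires balance")
    if within:
        expected = int(np.prod([data[w].nunique() for w in within]))
        per_sub = data.groupby(subject, observed=True)[dv].count()
        if (per_sub != expected).any():
            raise ValueError("missing within-cells for some subject")


def _margin_ss(data: pd.DataFrame, dv: str, factors: tuple[str, ...], grand: float) -> float:
    """Sum over rows of (margin-cell mean - grand mean)^2."""
    if not factors:
        return 0.0
    m = data.groupby(list(factors), observed=True)[dv].transform("mean")
    return float(((m - grand) ** 2).sum())


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x conditions matrix."""
    k = wide.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(wide, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    between: list[str],
    subject: str,
) -> AnovaResult:
    """Classical mixed-design ANOVA on a balanced complete long table.

    Returns every main effect and interaction of the named factors.
    Greenhouse-Geisser epsilons are reported alongside, but the headline
    F/df/p use uncorrected (sphericity-assumed) degrees of freedom.
    Zero-variance error terms yield NaN F with a degenerate flag.
    """
    within, between = list(within), list(between)
    _check_balanced(data, dv, within, between, subject)
    grand = float(data[dv].mean())
    n_subjects = data[subject].nunique()
    n_groups = int(np.prod([data[b].nunique() for b in between])) if between else 1
    levels = {f: data[f].nunique() for f in within + between}

    def T(margin: tuple[str, ...]) -> float:
        return _margin_ss(data, dv, margin, grand)

    def effect_ss(factors: tuple[str, ...]) -> float:
        ss = 0.0
        for r in range(len(factors) + 1):
            for sub in itertools.combinations(factors, r):
                ss += (-1) ** (len(factors) - r) * T(sub)
        return ss

    between_full = tuple(between)
    # error terms, keyed by the within-subset of the effect
    err_ss: dict[tuple[str, ...], float] = {}
    err_df: dict[tuple[str, ...], int] = {}
    err_ss[()] = T((subject,)) - T(between_full)
    err_df[()] = n_subjects - n_groups
    within_subsets = [
        tuple(s)
        for r in range(1, len(within) + 1)
        for s in itertools.combinations(within, r)
    ]
    for S in within_subsets:
        ss = 0.0
        for r in range(len(S) + 1):
            for sub in itertools.combinations(S, r):
                sign = (-1) ** (len(S) - r)
                ss += sign * (T((subject,) + sub) - T(between_full + sub))
        err_ss[S] = ss
        err_df[S] = int(np.prod([levels[w] - 1 for w in S])) * (n_subjects - n_groups)

    rows = []
    all_factors = between + within
    for r in range(1, len(all_factors) + 1):
        for eff in itertools.combinations(all_factors, r):
            w_part = tuple(f for f in eff if f in within)
            ss = effect_ss(eff)
            df1 = int(np.prod([levels[f] - 1 for f in eff]))
            e_ss, df2 = err_ss[w_part], err_df[w_part]
            if df2 <= 0 or e_ss <= 1e-300:
                F = p = np.nan
            else:
                F = (ss / df1) / (e_ss / df2)
                p = float(sps.f.sf(F, df1, df2))
            eps = 1.0
            if w_part:
                wide = (
                    data.groupby([subject] + list(w_part), observed=True)[dv]
                    .mean()
                    .unstack(list(w_part))
                    .to_numpy()
                )
                eps = _gg_epsilon(wide)
            p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else np.nan
            rows.append(
                {
                    "effect": " * ".join(eff),
                    "ss": ss,
                    "df1": df1,
                    "df2": df2,
                    "F": F,
                    "p": p,
                    "gg_epsilon": eps,
                    "p_gg": p_gg,
                }
            )
    return AnovaResult(
        table=pd.DataFrame(rows),
        within=tuple(within),
        between=tuple(between),
        n_subjects=n_subjects,
    )


def two_sample_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Pooled-variance two-sample t test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    df = len(x) + len(y) - 2
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
        # degenerate: no within-group variance
        t = 0.0 if np.isclose(x.mean(), y.mean()) else np.inf
        return {"t": t, "df": df, "p": 1.0 if t == 0.0 else 0.0}
    res = sps.ttest_ind(x, y, equal_var=True)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}


def linear_trend_interaction(
    beta_table: pd.DataFrame,
    dv: str = "beta",
    subject: str = "subject",
    group: str = "group",
    run: str = "run",
) -> dict:
    """Group difference in the per-subject linear run trend.

    Each subject is reduced to a contrast score (centered run weights
    dotted with the per-run values); groups are compared with a pooled
    two-sample test, reported as F with df (1, N-2). With 10+10 subjects
    this is the (1, 18) test of the group x run linear-trend interaction.
    """
    runs = np.sort(beta_table[run].unique())
    w = runs - runs.mean()
    wide = beta_table.pivot_table(index=[subject, group], columns=run, values=dv)
    scores = wide[runs].to_numpy() @ w
    groups = wide.index.get_level_values(group)
    gnames = sorted(set(groups))
    if len(gnames) != 2:
        raise ValueError("exactly two groups required")
    a = scores[groups == gnames[0]]
    b = scores[groups == gnames[1]]
    tt = two_sample_t(a, b)
    return {
        "F": tt["t"] ** 2,
        "df1": 1,
        "df2": tt["df"],
        "p": tt["p"],
        "contrast_diff": float(a.mean() - b.mean()),
        "weights": w,
    }


def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Classical paired t test (two-sided); df = n - 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    degenerate = np.allclose(d.std(ddof=1), 0)
    if degenerate and np.allclose(d, 0):
        return {"t": 0.0, "df": len(d) - 1, "p": 1.0, "degenerate": True}
    res = sps.ttest_rel(x, y)
    return {
        "t": float(res.statistic),
        "df": len(d) - 1,
        "p": float(res.pvalue),
        "degenerate": degenerate,
    }


def fit_run_regression(values: np.ndarray, runs: np.ndarray | None = None) -> RegressionResult:
    """OLS of per-run means on run index; the 7-run fit has df (1, 5)."""
    y = np.asarray(values, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points for a regression")
    x = np.arange(1, n + 1, dtype=float) if runs is None else np.asarray(runs, float)
    res = sps.linregress(x, y)
    pred = res.intercept + res.slope * x
    sse = float(((y - pred) ** 2).sum())
    sxx = float(((x - x.mean()) ** 2).sum())
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        F=float(t**2),
        df1=1,
        df2=n - 2,
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=n,
        sse=sse,
        sxx=sxx,
    )


def compare_slopes(reg_a: RegressionResult, reg_b: RegressionResult) -> dict:
    """Two-sided test of equal slopes for two independent regressions.

    Pooled residual variance; df = (n_a - 2) + (n_b - 2), i.e. 10 for two
    7-point fits.
    """
    df = (reg_a.n - 2) + (reg_b.n - 2)
    if df < 1:
        raise ValueError("too few points to compare slopes")
    s2 = (reg_a.sse + reg_b.sse) / df
    se = np.sqrt(s2 * (1.0 / reg_a.sxx + 1.0 / reg_b.sxx))
    t = (reg_a.slope - reg_b.slope) / se if se > 0 else np.inf
    return {"t": float(t), "df": df, "p": float(2 * sps.t.sf(abs(t), df))}


def deviation_contrast_3way(
    beta_table: pd.DataFrame,
    dv: str = "beta",
    subject: str = "subject",
    group: str = "group",
    run: str = "run",
    roi: str = "roi",
) -> pd.DataFrame:
    """Per-ROI deviation contrast of the group x run linear-trend effect.

    Each ROI is contrasted against the mean of the remaining ROIs; the
    per-subject linear run trend of that deviation score is compared
    between groups. One row per ROI: F, df1, df2, p.
    """
    rois = sorted(beta_table[roi].unique())
    if len(rois) < 2:
        raise ValueError("need at least two ROIs")
    wide = beta_table.pivot_table(index=[subject, group, run], columns=roi, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing ROI cells in the table")
    rows = []
    for r in rois:
        others = [c for c in rois if c != r]
        dev = (wide[r] - wide[others].mean(axis=1)).reset_index(name="dev")
        out = linear_trend_interaction(dev, dv="dev", subject=subject, group=group, run=run)
        rows.append({"roi": r, "F": out["F"], "df1": out["df1"], "df2": out["df2"], "p": out["p"]})
    return pd.DataFrame(rows)


def analyze_gonogo(
    tables: dict[str, pd.DataFrame],
    groups: dict[str, str],
    rt_min_ms: float = 100.0,
    rt_max_ms: float = 1000.0,
) -> dict:
    """3-way mixed ANOVA (hand x session within, group between) on mean go RT,
    plus the four per-(group, hand) pre/post paired t tests.

    Subjects with an empty (hand, session) cell after trimming are
    excluded with a log entry.
    """
    records = []
    for sid, tab in tables.items():
        cells = mean_go_rt(tab, rt_min_ms, rt_max_ms)
        if len(cells) < 4:
            logger.warning("subject %s dropped: empty go-RT cell after trimming", sid)
            continue
        cells = cells.assign(subject=sid, group=groups[sid])
        records.append(cells)
    rt = pd.concat(records, ignore_index=True)
    anova = mixed_anova(rt, dv="rt_ms", within=["hand", "session"], between=["group"], subject="subject")
    posthoc = []
    for g in sorted(rt.group.unique()):
        for hand in sorted(rt.hand.unique()):
            sub = rt[(rt.group == g) & (rt.hand == hand)]
            wide = sub.pivot(index="subject", columns="session", values="rt_ms")
            res = paired_t(wide["pre"].to_numpy(), wide["post"].to_numpy())
            posthoc.append({"group": g, "hand": hand, **res})
    return {"anova": anova, "posthoc": pd.DataFrame(posthoc), "cell_means": rt}


def nf_performance_regression(delta_beta: np.ndarray, covariate: np.ndarray) -> RegressionResult:
    """OLS of a behavioral covariate on the first-to-last-run beta change.

    With the 10 neurofeedback subjects this is the (1, 8) test relating
    self-regulation success to, e.g., reaction-time change.
    """
    delta_beta = np.asarray(delta_beta, float)
    covariate = np.asarray(covariate, float)
    if len(delta_beta) != len(covariate) or len(delta_beta) < 3:
        raise ValueError("need matched vectors of length >= 3")
    return fit_run_regression(covariate, runs=delta_beta)
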