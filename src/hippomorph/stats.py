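"""Statistical primitives for the morphometry pipeline.

Least-squares slopes, Mann-Whitney U (exact enumeration for small samples,
tie- and continuity-corrected normal approximation otherwise),
Benjamini-Hochberg FDR, one-way / two-level mixed-design ANOVA, ANCOVA,
Wilks' lambda MANOVA with Rao's F approximation, a REML random-intercept
mixed model for unbalanced longitudinal volumes, Shapiro-Wilk, and pooled-t
post hoc comparisons. Everything returns :class:`TestResult` so downstream
tables serialize uniformly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SlopeFit",
    "FDRResult",
    "ls_slope",
    "ls_slope_many",
    "mann_whitney_u",
    "mann_whitney_u_map",
    "bh_fdr",
    "oneway_anova",
    "rm_anova_group_hemisphere",
    "ancova",
    "wilks_manova",
    "mixed_model_volume",
    "shapiro_normality",
    "pairwise_posthoc",
]


@dataclass
class TestResult:
    statistic: float
    statistic_name: str  # {"F", "U", "W", "Wilks", "t"}
    df: tuple
    p_value: float

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    n_points: int
    units: str = "per_week"


@dataclass
class FDRResult:
    q: float
    rejected: np.ndarray  # bool per test
    p_threshold: float  # largest rejected p (0 if none)


class UndefinedSlopeError(ValueError):
    """Fewer than two distinct time values: slope undefined, exclude subject."""


# ---------------------------------------------------------------------------
# least squares


def ls_slope(times, values) -> SlopeFit:
    """Ordinary least-squares line fit of ``values`` on ``times`` (weeks)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if len(np.unique(t)) < 2:
        raise UndefinedSlopeError("need >= 2 distinct time values")
    tc = t - t.mean()
    slope = float(tc @ (v - v.mean()) / (tc @ tc))
    intercept = float(v.mean() - slope * t.mean())
    return SlopeFit(slope=slope, intercept=intercept, n_points=len(t), units="per_week")


def ls_slope_many(times, values) -> np.ndarray:
    """Vectorized OLS slopes: ``values`` is (n_times, m); returns (m,) slopes."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(np.unique(t)) < 2:
        raise UndefinedSlopeError("need >= 2 distinct time values")
    tc = t - t.mean()
    return tc @ (v - v.mean(axis=0)) / (tc @ tc)


# ---------------------------------------------------------------------------
# Mann-Whitney U

EXACT_MAX_N = 8  # per-sample cutoff for the exact enumeration path


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Number of rank configurations yielding each U value (U = 0..n*m).

    Recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u): the largest
    observation belongs either to sample x (adding m to U) or to sample y.
    """
    if n == 0 or m == 0:
        c = np.zeros(n * m + 1)
        c[0] = 1.0
        return tuple(c)
    a = np.array(_u_counts(n - 1, m))
    b = np.array(_u_counts(n, m - 1))
    c = np.zeros(n * m + 1)
    c[m : m + len(a)] += a
    c[: len(b)] += b
    return tuple(c)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = np.array(_u_counts(n, m))
    total = counts.sum()
    k = int(round(u))
    lo = counts[: k + 1].sum() / total
    hi = counts[k:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _approx_two_sided_p(u: float, n: int, m: int, tie_term: float, N: int) -> float:
    mu = n * m / 2.0
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var <= 0:
        return 1.0
    # continuity correction of 0.5 toward the mean
    d = u - mu
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _tie_term(pooled_sorted: np.ndarray) -> float:
    _, counts = np.unique(pooled_sorted, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``x`` (midranks for ties). The p-value is
    exact by enumeration when both samples have at most ``EXACT_MAX_N``
    observations and there are no ties, otherwise a normal approximation with
    tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    tie_term = _tie_term(pooled)
    if tie_term == 0 and max(n, m) <= EXACT_MAX_N:
        p = _exact_two_sided_p(u, n, m)
    else:
        p = _approx_two_sided_p(u, n, m, tie_term, n + m)
    return TestResult(statistic=u, statistic_name="U", df=(n, m), p_value=p)


def mann_whitney_u_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-wise Mann-Whitney U: ``a`` is (n_a, V), ``b`` is (n_b, V).

    Returns (U, p) arrays of length V, using the same exact/approximate policy
    as :func:`mann_whitney_u` per vertex.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    N = n + m
    ranks = sps.rankdata(pooled, axis=0)
    u = ranks[:n].sum(axis=0) - n * (n + 1) / 2.0
    srt = np.sort(pooled, axis=0)
    tied = np.zeros(pooled.shape[1])
    # per-column tie term sum(t^3 - t); columns with all-distinct values give 0
    changes = np.diff(srt, axis=0) != 0
    has_ties = ~changes.all(axis=0)
    for j in np.nonzero(has_ties)[0]:
        tied[j] = _tie_term(srt[:, j])
    p = np.empty_like(u)
    exact_ok = max(n, m) <= EXACT_MAX_N
    for j in range(len(u)):
        if exact_ok and tied[j] == 0:
            p[j] = _exact_two_sided_p(u[j], n, m)
        else:
            p[j] = _approx_two_sided_p(u[j], n, m, tied[j], N)
    return u, p


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up at level ``q``.

    Rejects all p <= p_(k*), k* = max{k : p_(k) <= k q / m}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    m = p.size
    if m == 0:
        return FDRResult(q=q, rejected=np.zeros(0, dtype=bool), p_threshold=0.0)
    order = np.sort(p)
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= crit)[0]
    thresh = float(order[passing[-1]]) if passing.size else 0.0
    rejected = p <= thresh if passing.size else np.zeros(m, dtype=bool)
    return FDRResult(q=q, rejected=rejected, p_threshold=thresh)


# ---------------------------------------------------------------------------
# ANOVA family


def oneway_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA over ``groups`` (list of 1-D samples)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    all_v = np.concatenate(gs)
    grand = all_v.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = len(gs) - 1, len(all_v) - len(gs)
    if ss_w == 0 and ss_b == 0:
        return TestResult(0.0, "F", (df1, df2), 1.0)
    if ss_w == 0:
        return TestResult(np.inf, "F", (df1, df2), 0.0)
    f = (ss_b / df1) / (ss_w / df2)
    return TestResult(float(f), "F", (df1, df2), float(sps.f.sf(f, df1, df2)))


def rm_anova_group_hemisphere(left, right, groups) -> dict[str, TestResult]:
    """Two-way mixed-design ANOVA: between factor = group, within factor =
    hemisphere (2 levels).

    With two within levels the design reduces exactly: the group effect is a
    one-way ANOVA on subject means (L+R)/2; the hemisphere effect and the
    group x hemisphere interaction are the intercept test and one-way ANOVA on
    the within-subject differences d = R - L (each on half-variance scale,
    which cancels in the F ratios).

    Returns a dict with keys ``group``, ``hemisphere``, ``interaction``.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    groups = np.asarray(groups)
    ok = ~(np.isnan(left) | np.isnan(right))
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} subject(s) missing a hemisphere excluded")
        left, right, groups = left[ok], right[ok], groups[ok]
    labels = pd.unique(groups)
    k = len(labels)
    n_tot = len(left)
    means = (left + right) / 2.0
    diffs = right - left
    out: dict[str, TestResult] = {}
    if k >= 2:
        out["group"] = oneway_anova([means[groups == g] for g in labels])
    else:
        out["group"] = TestResult(np.nan, "F", (0, n_tot - 1), np.nan)
    # within-subject part on d = R - L
    cell = {g: diffs[groups == g] for g in labels}
    ss_w = sum(((d - d.mean()) ** 2).sum() for d in cell.values())
    df_w = n_tot - k
    ms_w = ss_w / df_w if df_w > 0 else np.nan
    # hemisphere main effect: unweighted mean of group means of d vs 0
    gmeans = np.array([cell[g].mean() for g in labels])
    ns = np.array([len(cell[g]) for g in labels], dtype=float)
    hbar = gmeans.mean()
    # F = hbar^2 / (MS_w * sum(1/n_g) / k^2)  (type-III style, unweighted)
    if ms_w == 0 or np.isnan(ms_w):
        out["hemisphere"] = TestResult(np.nan if np.isnan(ms_w) else np.inf, "F", (1, df_w),
                                       np.nan if np.isnan(ms_w) else (1.0 if hbar == 0 else 0.0))
    else:
        f_h = hbar**2 / (ms_w * np.sum(1.0 / ns) / k**2)
        out["hemisphere"] = TestResult(float(f_h), "F", (1, df_w), float(sps.f.sf(f_h, 1, df_w)))
    if k >= 2:
        grand = np.concatenate(list(cell.values())).mean()
        ss_b = sum(len(d) * (d.mean() - grand) ** 2 for d in cell.values())
        if ms_w == 0:
            out["interaction"] = TestResult(0.0 if ss_b == 0 else np.inf, "F", (k - 1, df_w),
                                            1.0 if ss_b == 0 else 0.0)
        else:
            f_i = (ss_b / (k - 1)) / ms_w
            out["interaction"] = TestResult(float(f_i), "F", (k - 1, df_w),
                                            float(sps.f.sf(f_i, k - 1, df_w)))
    else:
        out["interaction"] = TestResult(np.nan, "F", (0, df_w), np.nan)
    return out


def _dummies(groups) -> tuple[np.ndarray, list]:
    labels = list(pd.unique(np.asarray(groups)))
    g = np.asarray(groups)
    d = np.column_stack([(g == lab).astype(float) for lab in labels[1:]])
    return d, labels


def ancova(y, groups, covariates) -> TestResult:
    """Adjusted group effect from the GLM ``y ~ covariates + group``.

    The group factor is tested after the covariates (extra sum of squares of
    the group dummies given intercept + covariates; type-III style since the
    group term enters last and is a single factor).
    """
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(y):
        cov = cov.T
    gd, labels = _dummies(groups)
    n = len(y)
    ones = np.ones((n, 1))
    x_red = np.hstack([ones, cov])
    x_full = np.hstack([x_red, gd])
    rank_full = np.linalg.matrix_rank(x_full)
    if rank_full < x_full.shape[1]:
        # name the first column whose removal restores full column rank
        names = ["intercept"] + [f"covariate_{j}" for j in range(cov.shape[1])] + [
            f"group[{lab}]" for lab in labels[1:]
        ]
        for j in range(x_full.shape[1]):
            sub = np.delete(x_full, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank_full:
                raise np.linalg.LinAlgError(f"rank-deficient design: column {names[j]} is collinear")
        raise np.linalg.LinAlgError("rank-deficient design")
    rss_red = _rss(x_red, y)
    rss_full = _rss(x_full, y)
    df1 = gd.shape[1]
    df2 = n - x_full.shape[1]
    if rss_full <= 0:
        f = 0.0 if rss_red <= 1e-300 else np.inf
        return TestResult(f, "F", (df1, df2), 1.0 if f == 0 else 0.0)
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = max(f, 0.0)
    return TestResult(float(f), "F", (df1, df2), float(sps.f.sf(f, df1, df2)))


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def wilks_manova(scores, groups) -> TestResult:
    """One-way MANOVA via Wilks' lambda = det(W) / det(W + B).

    ``scores`` is (n_subjects, p). The p-value uses Rao's F approximation,
    which is exact for p = 1 (reducing to one-way ANOVA) and for 2 groups.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    g = np.asarray(groups)
    labels = pd.unique(g)
    k, (n, p) = len(labels), x.shape
    if k < 2:
        raise ValueError("need >= 2 groups")
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for lab in labels:
        xs = x[g == lab]
        mu = xs.mean(axis=0)
        c = xs - mu
        w += c.T @ c
        d = (mu - grand)[:, None]
        b += len(xs) * (d @ d.T)
    if n - k < p or np.linalg.matrix_rank(w) < p:
        raise np.linalg.LinAlgError(
            "singular within-group scatter (need per-group n > n_variables); "
            "reduce the number of components (PC truncation)"
        )
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "singular within-group covariance; reduce the number of components (PC truncation)"
        )
    lam = float(np.exp(logdet_w - logdet_t))
    vh, ve = k - 1.0, n - float(k)
    denom = p**2 + vh**2 - 5.0
    t = np.sqrt((p**2 * vh**2 - 4.0) / denom) if denom > 0 else 1.0
    df1 = p * vh
    df2 = (ve + vh - (p + vh + 1.0) / 2.0) * t - (p * vh - 2.0) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t <= 0:
        return TestResult(lam, "Wilks", (df1, df2), 0.0)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(sps.f.sf(f, df1, df2)) if f > 0 else 1.0
    return TestResult(lam, "Wilks", (df1, df2), p_val)


# ---------------------------------------------------------------------------
# mixed model for unbalanced longitudinal volumes


def mixed_model_volume(data: pd.DataFrame) -> dict[str, TestResult]:
    """Random-intercept mixed model for hippocampal volume with categorical
    time.

    ``data`` needs columns ``subject``, ``group``, ``week``, ``volume``.
    Fixed effects: group, week (categorical) and their interaction; a single
    subject-level random intercept, fitted by REML (statsmodels MixedLM).
    Returns Wald F tests for ``time`` and ``group_x_time``.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = data.copy()
    required = {"subject", "group", "week", "volume"}
    if not required.issubset(df.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if (df.groupby("subject")["week"].nunique() >= 2).sum() == 0:
        raise ValueError("no subject has >= 2 visits; time effects unidentifiable")
    if df["week"].nunique() < 2:
        raise ValueError("need >= 2 time points")
    weeks = sorted(df["week"].unique())
    glabels = list(pd.unique(df["group"]))
    single_group = len(glabels) < 2
    # volumes constant within every subject: no within-subject information,
    # the REML fit degenerates (zero residual variance) -> no time effect
    within_dev = df["volume"] - df.groupby("subject")["volume"].transform("mean")
    if np.abs(within_dev).max() < 1e-12 * max(1.0, np.abs(df["volume"]).max()):
        out = {"time": TestResult(0.0, "F", (float(len(weeks) - 1), 1.0), 1.0)}
        if not single_group:
            out["group_x_time"] = TestResult(0.0, "F", (float(len(weeks) - 1), 1.0), 1.0)
        return out
    # manual dummy design; group x week cells can be empty (e.g. a group not
    # scanned at some week), so all-zero interaction columns are dropped
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for g in glabels[1:]:
        cols.append((df["group"] == g).to_numpy(float))
        names.append(f"C(group)[T.{g}]")
    for w in weeks[1:]:
        cols.append((df["week"] == w).to_numpy(float))
        names.append(f"C(week)[T.{w}]")
    if not single_group:
        for g in glabels[1:]:
            for w in weeks[1:]:
                c = ((df["group"] == g) & (df["week"] == w)).to_numpy(float)
                if c.any():
                    cols.append(c)
                    names.append(f"C(group)[T.{g}]:C(week)[T.{w}]")
    exog = np.column_stack(cols)
    keep = exog.any(axis=0)
    exog = exog[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    # greedy left-to-right rank filter: when a week is observed in a single
    # group its dummy and interaction column coincide; main effects win
    kept_idx: list[int] = []
    rank = 0
    for j in range(exog.shape[1]):
        trial = exog[:, kept_idx + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept_idx.append(j)
            rank = r
    exog = exog[:, kept_idx]
    names = [names[j] for j in kept_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(df["volume"].to_numpy(float), exog, groups=df["subject"].to_numpy())
        model.data.xnames = names
        res = None
        err = None
        for method in (None, "lbfgs", "powell"):
            try:
                res = model.fit(reml=True) if method is None else model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as e:
                err = e
        if res is None:
            raise err
    n_obs = len(df)
    df_resid = n_obs - len(names) - df["subject"].nunique()
    df_resid = max(df_resid, 1)
    out: dict[str, TestResult] = {}

    fe = np.asarray(res.fe_params)
    k_fe = len(fe)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]

    def wald(term_cols: list[int], label: str):
        if not term_cols:
            out[label] = TestResult(np.nan, "F", (0, df_resid), np.nan)
            return
        c = np.zeros((len(term_cols), k_fe))
        for r, j in enumerate(term_cols):
            c[r, j] = 1.0
        cb = c @ fe
        cvc = c @ cov_fe @ c.T
        try:
            stat = float(cb @ np.linalg.solve(cvc, cb))
        except np.linalg.LinAlgError:
            stat = float(cb @ np.linalg.pinv(cvc) @ cb)
        d1 = float(len(term_cols))
        f = max(stat / d1, 0.0)
        pv = float(sps.f.sf(f, d1, df_resid))
        out[label] = TestResult(f, "F", (d1, float(df_resid)), min(max(pv, 0.0), 1.0))

    time_cols = [i for i, nm in enumerate(names) if nm.startswith("C(week)") and ":" not in nm]
    inter_cols = [i for i, nm in enumerate(names) if ":" in nm]
    wald(time_cols, "time")
    if not single_group:
        wald(inter_cols, "group_x_time")
    return out


# ---------------------------------------------------------------------------
# normality gate and post hoc


def shapiro_normality(x) -> TestResult:
    """Shapiro-Wilk test of normality (Royston's approximation, via scipy)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return TestResult(np.nan, "W", (len(x),), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(x)
    return TestResult(float(w), "W", (len(x),), float(p))


def pairwise_posthoc(groups: dict, correction: str = "none") -> dict[tuple, float]:
    """Pairwise two-sample t-tests with the pooled within-group variance from
    the preceding one-way ANOVA (Fisher's LSD); optional Bonferroni.

    ``groups`` maps label -> 1-D sample. Returns {(label_a, label_b): p}.
    """
    if correction not in {"none", "bonferroni"}:
        raise ValueError("correction must be 'none' or 'bonferroni'")
    labels = [lab for lab in groups]
    usable = {}
    for lab in labels:
        g = np.asarray(groups[lab], dtype=float)
        if len(g) < 2:
            warnings.warn(f"group {lab!r} has n < 2; its pairs are skipped")
            continue
        usable[lab] = g
    n_tot = sum(len(g) for g in usable.values())
    k = len(usable)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in usable.values())
    df_w = n_tot - k
    ms_w = ss_w / df_w if df_w > 0 else np.nan
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    n_pairs = sum(1 for a, b in pairs if a in usable and b in usable)
    out: dict[tuple, float] = {}
    for a, b in pairs:
        if a not in usable or b not in usable:
            continue
        ga, gb = usable[a], usable[b]
        if ms_w == 0:
            p = 1.0 if ga.mean() == gb.mean() else 0.0
        else:
            se = np.sqrt(ms_w * (1.0 / len(ga) + 1.0 / len(gb)))
            t = (ga.mean() - gb.mean()) / se
            p = float(2.0 * sps.t.sf(abs(t), df_w))
        if correction == "bonferroni":
            p = min(1.0, p * n_pairs)
        out[(a, b)] = p
    return out
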