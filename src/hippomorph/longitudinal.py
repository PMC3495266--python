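"""Longitudinal morphometry: per-subject volume slopes and per-vertex slope
maps, slope CDFs, control-referenced slope thresholds, percent-negative and
large-magnitude slope statistics, and FDR-corrected vertex-wise comparison.

Vertex slopes are the least-squares rate of change (mm/year, 52 weeks/year)
of each vertex's signed displacement along the subject's outward *baseline*
normal, over the subject's available visits (week 0 enters as displacement
zero). "Very negative" / "very positive" slopes fall beyond the control
mean -/+ 1 SD thresholds; their per-subject percentages are the headline
shape-change statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, enclosed_volume, vertex_normals, write_surface
from .synthetic import Cohort, Subject, WEEKS_PER_YEAR, GROUPS
from .baseline import DisplacementMap
from . import stats as st

__all__ = [
    "SlopeMap",
    "SlopeSummary",
    "ThresholdPair",
    "volume_slope_table",
    "volume_slope_analysis",
    "vertex_slope_map",
    "cohort_slope_maps",
    "group_mean_slope_map",
    "slope_cdf",
    "control_thresholds",
    "thresholds_from_moments",
    "slope_percentages",
    "compare_percentages",
    "vertexwise_slope_test",
    "export_slope_surface",
]


@dataclass
class SlopeMap:
    """Per-vertex longitudinal slopes (mm/year, positive = outward drift) for
    one subject or a group mean; left-then-right vertex concatenation."""

    label: str  # subject id or group label
    slopes: np.ndarray  # (V_left + V_right,)
    n_left: int
    n_visits: int

    @property
    def left(self) -> np.ndarray:
        return self.slopes[: self.n_left]

    @property
    def right(self) -> np.ndarray:
        return self.slopes[self.n_left :]


@dataclass
class ThresholdPair:
    lower: float  # mm/year
    upper: float
    method: str

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"degenerate thresholds: lower {self.lower} !< upper {self.upper}")


@dataclass
class SlopeSummary:
    subject_id: str
    group: str
    mean_slope: float
    pct_negative_left: float
    pct_negative_right: float
    pct_very_negative_left: float
    pct_very_negative_right: float
    pct_very_positive_left: float
    pct_very_positive_right: float

    @property
    def pct_negative(self) -> float:
        return (self.pct_negative_left + self.pct_negative_right) / 2.0

    @property
    def pct_very_negative(self) -> float:
        return (self.pct_very_negative_left + self.pct_very_negative_right) / 2.0

    @property
    def pct_very_positive(self) -> float:
        return (self.pct_very_positive_left + self.pct_very_positive_right) / 2.0


# ---------------------------------------------------------------------------
# volumes


def volume_slope_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject, per-hemisphere least-squares volume slopes (mm^3/week)."""
    rows = []
    for s in cohort.subjects:
        if len(s.visits) < 2:
            warnings.warn(f"{s.subject_id}: <2 visits, excluded from slope analyses")
            continue
        weeks = np.array(s.weeks, dtype=float)
        for hemi, side in (("left", 0), ("right", 1)):
            vols = np.array([enclosed_volume(s.visits[w][side]) for w in s.weeks])
            fit = st.ls_slope(weeks, vols)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "hemisphere": hemi,
                    "slope_mm3_per_week": fit.slope,
                    "n_visits": fit.n_points,
                }
            )
    return pd.DataFrame(rows)


def volume_slope_analysis(cohort: Cohort) -> dict:
    """Volume slope RM-ANOVA across groups plus the mixed-model time and
    group-by-time tests on raw volumes.

    Returns {"slopes": per-subject table, "tests": tidy test table}.
    """
    tab = volume_slope_table(cohort)
    wide = tab.pivot(index="subject_id", columns="hemisphere", values="slope_mm3_per_week")
    groups = tab.drop_duplicates("subject_id").set_index("subject_id").loc[wide.index, "group"]
    rm = st.rm_anova_group_hemisphere(
        wide["left"].to_numpy(), wide["right"].to_numpy(), groups.to_numpy()
    )
    rows = []
    for eff, r in rm.items():
        rows.append(
            {"analysis": "volume_slope_rm_anova", "effect": eff, "statistic_name": r.statistic_name,
             "statistic": r.statistic, "df1": r.df[0], "df2": r.df[1], "p_value": r.p_value}
        )
    for hemi, side in (("left", 0), ("right", 1)):
        long_rows = []
        for s in cohort.subjects:
            for w in s.weeks:
                long_rows.append(
                    {"subject": s.subject_id, "group": s.group, "week": w,
                     "volume": enclosed_volume(s.visits[w][side])}
                )
        mm = st.mixed_model_volume(pd.DataFrame(long_rows))
        for eff, r in mm.items():
            rows.append(
                {"analysis": f"volume_mixed_model_{hemi}", "effect": eff,
                 "statistic_name": r.statistic_name, "statistic": r.statistic,
                 "df1": r.df[0], "df2": r.df[1], "p_value": r.p_value}
            )
    return {"slopes": tab, "tests": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# vertex slope maps


def vertex_slope_map(subject: Subject) -> SlopeMap:
    """Per-vertex slope map for one subject (mm/year).

    The scalar trajectory at vertex i is the displacement of the visit vertex
    from its week-0 position projected on the subject's outward baseline
    normal; the week-0 point enters with value 0. The per-week least-squares
    slope is converted to mm/year (x 52).
    """
    if len(subject.visits) < 2:
        raise st.UndefinedSlopeError(f"{subject.subject_id}: <2 visits, slope map undefined")
    weeks = np.array(subject.weeks, dtype=float)
    parts = []
    for side in (0, 1):
        base = subject.visits[subject.weeks[0]][side]
        normals = vertex_normals(base)
        d = np.array(
            [
                np.einsum("ij,ij->i", subject.visits[w][side].vertices - base.vertices, normals)
                for w in subject.weeks
            ]
        )
        parts.append(st.ls_slope_many(weeks, d) * WEEKS_PER_YEAR)
    return SlopeMap(
        label=subject.subject_id,
        slopes=np.concatenate(parts),
        n_left=subject.visits[subject.weeks[0]][0].n_vertices,
        n_visits=len(weeks),
    )


def cohort_slope_maps(cohort: Cohort) -> dict[str, list[SlopeMap]]:
    """Slope maps per group, skipping subjects with fewer than two visits."""
    out: dict[str, list[SlopeMap]] = {}
    for s in cohort.subjects:
        if len(s.visits) < 2:
            warnings.warn(f"{s.subject_id}: <2 visits, no slope map")
            continue
        out.setdefault(s.group, []).append(vertex_slope_map(s))
    return out


def group_mean_slope_map(maps: list[SlopeMap], label: str = "group") -> SlopeMap:
    """Vertex-wise arithmetic mean of subject slope maps."""
    if not maps:
        raise ValueError("need >= 1 slope map")
    n_left = maps[0].n_left
    n = maps[0].slopes.shape
    if any(m.slopes.shape != n or m.n_left != n_left for m in maps):
        raise ValueError("slope maps have mismatched topology")
    return SlopeMap(
        label=label,
        slopes=np.mean([m.slopes for m in maps], axis=0),
        n_left=n_left,
        n_visits=0,
    )


def slope_cdf(slope_map: SlopeMap) -> pd.DataFrame:
    """Empirical CDF of a slope map over all vertices (left+right combined).

    Right-continuous: the returned cumulative fraction at a value v is
    P(slope <= v), evaluated at the sorted unique slope values.
    """
    values = np.sort(slope_map.slopes)
    if values.size == 0:
        raise ValueError("empty slope map")
    uniq, counts = np.unique(values, return_counts=True)
    return pd.DataFrame({"slope": uniq, "cum_frac": np.cumsum(counts) / values.size})


# ---------------------------------------------------------------------------
# thresholds and percentages


def thresholds_from_moments(mean: float, sd: float, method: str = "moments") -> ThresholdPair:
    """Mean -/+ 1 SD thresholds from given control slope moments (mm/year)."""
    if sd <= 0:
        raise ValueError("control slope SD must be positive")
    return ThresholdPair(lower=mean - sd, upper=mean + sd, method=method)


def control_thresholds(control_maps: list[SlopeMap], method: str = "subject_means") -> ThresholdPair:
    """Large-magnitude slope thresholds: control mean -/+ 1 SD.

    method:
      ``subject_means``   moments of the per-subject mean slopes (default);
      ``pooled_vertices`` moments of all control vertex slopes pooled;
      ``group_mean_map``  moments across vertices of the control mean map.
    """
    if len(control_maps) < 2:
        raise ValueError("need >= 2 control subjects")
    if method == "subject_means":
        vals = np.array([m.slopes.mean() for m in control_maps])
        mu, sd = vals.mean(), vals.std(ddof=1)
    elif method == "pooled_vertices":
        vals = np.concatenate([m.slopes for m in control_maps])
        mu, sd = vals.mean(), vals.std(ddof=1)
    elif method == "group_mean_map":
        gm = group_mean_slope_map(control_maps).slopes
        mu, sd = gm.mean(), gm.std(ddof=1)
    else:
        raise ValueError(f"unknown threshold method: {method}")
    if sd <= 0:
        raise ValueError("degenerate control slope distribution (zero SD)")
    return thresholds_from_moments(float(mu), float(sd), method=method)


def slope_percentages(slope_map: SlopeMap, thresholds: ThresholdPair,
                      group: str = "") -> SlopeSummary:
    """Percentages of vertices (per hemisphere) with slope < 0, slope < lower
    threshold, and slope > upper threshold; strict inequalities."""
    if not (np.isfinite(thresholds.lower) and np.isfinite(thresholds.upper)):
        raise ValueError("thresholds must be finite")

    def pct(v, pred):
        return 100.0 * float(pred(v).mean())

    l, r = slope_map.left, slope_map.right
    return SlopeSummary(
        subject_id=slope_map.label,
        group=group,
        mean_slope=float(slope_map.slopes.mean()),
        pct_negative_left=pct(l, lambda v: v < 0),
        pct_negative_right=pct(r, lambda v: v < 0),
        pct_very_negative_left=pct(l, lambda v: v < thresholds.lower),
        pct_very_negative_right=pct(r, lambda v: v < thresholds.lower),
        pct_very_positive_left=pct(l, lambda v: v > thresholds.upper),
        pct_very_positive_right=pct(r, lambda v: v > thresholds.upper),
    )


def summaries_table(summaries: list[SlopeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "mean_slope_mm_per_year": s.mean_slope,
                "pct_negative_left": s.pct_negative_left,
                "pct_negative_right": s.pct_negative_right,
                "pct_very_negative_left": s.pct_very_negative_left,
                "pct_very_negative_right": s.pct_very_negative_right,
                "pct_very_positive_left": s.pct_very_positive_left,
                "pct_very_positive_right": s.pct_very_positive_right,
            }
            for s in summaries
        ]
    )


METRICS = ("pct_negative", "pct_very_negative", "pct_very_positive")


def compare_percentages(summaries: list[SlopeSummary], posthoc_alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison of each percentage metric.

    For every metric: a Shapiro-Wilk normality gate per group (reported, not
    blocking), a one-way ANOVA on the hemisphere-averaged percentage, the
    hemisphere RM-ANOVA (group, hemisphere, interaction), and Fisher's-LSD
    post hoc pairwise p-values when the one-way ANOVA is significant.
    """
    df = summaries_table(summaries)
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 groups")
    labels = list(pd.unique(df["group"]))
    rows = []
    for metric in METRICS:
        avg = (df[f"{metric}_left"] + df[f"{metric}_right"]) / 2.0
        samples = {g: avg[df["group"] == g].to_numpy() for g in labels}
        for g, v in samples.items():
            if 3 <= len(v) <= 5000 and np.ptp(v) > 0:
                sw = st.shapiro_normality(v)
                rows.append({"metric": metric, "analysis": "shapiro", "effect": g,
                             "statistic_name": "W", "statistic": sw.statistic,
                             "df1": sw.df[0], "df2": np.nan, "p_value": sw.p_value})
        if all(np.ptp(v) == 0 for v in samples.values()) and len(
            {v[0] for v in samples.values() if len(v)}
        ) <= 1:
            rows.append({"metric": metric, "analysis": "oneway_anova", "effect": "group",
                         "statistic_name": "F", "statistic": 0.0,
                         "df1": len(labels) - 1, "df2": len(df) - len(labels), "p_value": 1.0})
            continue
        a = st.oneway_anova([samples[g] for g in labels])
        rows.append({"metric": metric, "analysis": "oneway_anova", "effect": "group",
                     "statistic_name": "F", "statistic": a.statistic,
                     "df1": a.df[0], "df2": a.df[1], "p_value": a.p_value})
        rm = st.rm_anova_group_hemisphere(
            df[f"{metric}_left"].to_numpy(), df[f"{metric}_right"].to_numpy(),
            df["group"].to_numpy()
        )
        for eff, r in rm.items():
            rows.append({"metric": metric, "analysis": "rm_anova", "effect": eff,
                         "statistic_name": r.statistic_name, "statistic": r.statistic,
                         "df1": r.df[0], "df2": r.df[1], "p_value": r.p_value})
        if a.p_value < posthoc_alpha:
            for (ga, gb), p in st.pairwise_posthoc(samples).items():
                rows.append({"metric": metric, "analysis": "posthoc_lsd",
                             "effect": f"{ga}_vs_{gb}", "statistic_name": "t",
                             "statistic": np.nan, "df1": np.nan, "df2": np.nan, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vertex-wise comparison and export


def vertexwise_slope_test(maps_a: list[SlopeMap], maps_b: list[SlopeMap],
                          q: float = 0.05) -> DisplacementMap:
    """Per-vertex Mann-Whitney U comparison of subject slopes, A vs B, with
    BH-FDR at level ``q``; the map is mean(A) - mean(B) slope difference."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("both groups need >= 2 subjects")
    a = np.stack([m.slopes for m in maps_a])
    b = np.stack([m.slopes for m in maps_b])
    _, p = st.mann_whitney_u_map(a, b)
    fdr = st.bh_fdr(p, q=q)
    return DisplacementMap(displacement=a.mean(axis=0) - b.mean(axis=0), p=p,
                           fdr_mask=fdr.rejected, q=q)


def export_slope_surface(template, slope_map: SlopeMap, path,
                         display_range: float = 0.1):
    """Write left/right VTK surfaces with the slope field clamped to
    [-display_range, +display_range] (field ``slope_display``) and the raw
    slopes (field ``slope_mm_per_year``).

    ``path`` is a stem; ``<stem>_left.vtk`` and ``<stem>_right.vtk`` are
    written. Returns the two paths.
    """
    from pathlib import Path

    path = Path(path)
    clamped = np.clip(slope_map.slopes, -display_range, display_range)
    out = []
    for hemi, mesh, sl in (
        ("left", template.left, slice(0, slope_map.n_left)),
        ("right", template.right, slice(slope_map.n_left, None)),
    ):
        p = path.parent / f"{path.name}_{hemi}.vtk"
        write_surface(
            mesh, p,
            scalars={"slope_display": clamped[sl], "slope_mm_per_year": slope_map.slopes[sl]},
        )
        out.append(p)
    return tuple(out)
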