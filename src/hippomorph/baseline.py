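"""Cross-sectional (week 0) volume and shape analyses.

Per-subject left/right enclosed volumes feed a mixed-design RM-ANOVA
(group x hemisphere) and ANCOVA variants with sex / gray-matter / illness
duration covariates; shape is summarized by per-hemisphere PCA of the
flattened corresponded surfaces and compared with a Wilks MANOVA on the
leading component scores; vertex-wise displacement maps (projection of the
subject-template difference on the outward template normal) are compared
with Mann-Whitney U and thresholded by Benjamini-Hochberg FDR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, enclosed_volume, validate_correspondence
from .synthetic import Cohort, Template, GROUPS
from . import stats as st

__all__ = [
    "ShapePCAModel",
    "DisplacementMap",
    "baseline_volume_table",
    "baseline_volume_analysis",
    "shape_pca",
    "shape_manova",
    "vertex_displacement_map",
]

DEFAULT_N_COMPONENTS = 20


@dataclass
class ShapePCAModel:
    hemisphere: str
    mean_surface: np.ndarray  # (V, 3)
    components: np.ndarray  # (K, 3V), orthonormal rows
    explained_variance_fraction: np.ndarray  # (K,), non-increasing
    scores: np.ndarray  # (n_subjects, K)
    subject_ids: list


@dataclass
class DisplacementMap:
    """Vertex-wise signed displacement contrast (positive = outward in group
    A relative to group B), with per-vertex Mann-Whitney p-values and the
    q=0.05 FDR rejection mask. Vertices are left-then-right concatenated."""

    displacement: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    q: float = 0.05


def baseline_volume_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject left/right week-0 enclosed volumes plus covariates."""
    rows = []
    for s in cohort.subjects:
        if 0 not in s.visits:
            warnings.warn(f"{s.subject_id}: no week-0 meshes, excluded from baseline analysis")
            continue
        lm, rm = s.visits[0]
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "gray_matter_volume_mm3": s.gray_matter_volume,
                "illness_duration_weeks": s.illness_duration,
                "left_volume_mm3": enclosed_volume(lm),
                "right_volume_mm3": enclosed_volume(rm),
            }
        )
    return pd.DataFrame(rows)


def baseline_volume_analysis(cohort: Cohort) -> pd.DataFrame:
    """Baseline volume comparisons, one row per test.

    Patients (OLZ+HAL pooled as PSY) vs controls: RM-ANOVA with hemisphere
    as the repeated factor, then ANCOVA re-tests of the group effect on
    hemisphere-mean volume adjusting for sex and for total gray matter.
    OLZ vs HAL at baseline is compared per hemisphere (pooled t via ANOVA)
    and with an illness-duration ANCOVA.
    """
    tab = baseline_volume_table(cohort)
    psy = np.where(tab["group"].isin(["OLZ", "HAL"]), "PSY", "CON").astype(object)
    left = tab["left_volume_mm3"].to_numpy()
    right = tab["right_volume_mm3"].to_numpy()
    rows = []

    def add(analysis, effect, r: st.TestResult):
        rows.append(
            {
                "analysis": analysis,
                "effect": effect,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic,
                "df1": r.df[0],
                "df2": r.df[1] if len(r.df) > 1 else np.nan,
                "p_value": r.p_value,
            }
        )

    rm = st.rm_anova_group_hemisphere(left, right, psy)
    for eff in ("group", "hemisphere", "interaction"):
        add("volume_rm_anova_psy_vs_con", eff, rm[eff])

    mean_vol = (left + right) / 2.0
    sex_num = (tab["sex"] == "F").astype(float).to_numpy()
    add("volume_ancova_sex", "group", st.ancova(mean_vol, psy, sex_num[:, None]))
    gm = tab["gray_matter_volume_mm3"].to_numpy()
    add("volume_ancova_gray_matter", "group", st.ancova(mean_vol, psy, gm[:, None]))

    pat = tab["group"].isin(["OLZ", "HAL"]).to_numpy()
    if pat.sum() >= 4 and tab.loc[pat, "group"].nunique() == 2:
        gpat = tab.loc[pat, "group"].to_numpy()
        for hemi, v in (("left", left[pat]), ("right", right[pat])):
            add(f"volume_olz_vs_hal_{hemi}", "group",
                st.oneway_anova([v[gpat == "OLZ"], v[gpat == "HAL"]]))
        dur = tab.loc[pat, "illness_duration_weeks"].astype(float).to_numpy()
        if np.isfinite(dur).all():
            add("volume_olz_vs_hal_ancova_duration", "group",
                st.ancova(mean_vol[pat], gpat, dur[:, None]))
    return pd.DataFrame(rows)


def shape_pca(
    meshes: list[TriangleMesh],
    hemisphere: str,
    n_components: int = DEFAULT_N_COMPONENTS,
    subject_ids: list | None = None,
) -> ShapePCAModel:
    """PCA of corresponded surfaces of one hemisphere.

    Each surface is flattened to a 3V vector; the grand mean surface is
    subtracted and the centered data decomposed by SVD. Scores are the
    projections of each centered surface onto the (orthonormal) components.
    """
    if len(meshes) < 3:
        raise ValueError("need >= 3 subjects for shape PCA")
    rep = validate_correspondence(meshes)
    if not rep.ok:
        raise ValueError(f"meshes not corresponded: {rep.mismatches[:3]}")
    x = np.stack([m.vertices.ravel() for m in meshes])  # (n, 3V)
    mean = x.mean(axis=0)
    xc = x - mean
    max_k = len(meshes) - 1
    if n_components > max_k:
        warnings.warn(f"requested {n_components} components > n-1={max_k}; truncating")
        n_components = max_k
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    k = n_components
    return ShapePCAModel(
        hemisphere=hemisphere,
        mean_surface=mean.reshape(-1, 3),
        components=vt[:k],
        explained_variance_fraction=frac[:k],
        scores=xc @ vt[:k].T,
        subject_ids=list(subject_ids) if subject_ids is not None else list(range(len(meshes))),
    )


def shape_manova(model: ShapePCAModel, groups, covariates=None) -> st.TestResult:
    """Wilks MANOVA on the PC scores; optional covariate adjustment by
    residualizing the scores on the covariates (plus intercept) first.

    Components are truncated so the within-group scatter stays nonsingular
    (number of variables < n_subjects - n_groups)."""
    scores = model.scores
    k_groups = len(pd.unique(np.asarray(groups)))
    max_p = scores.shape[0] - k_groups - 1
    if scores.shape[1] > max_p:
        warnings.warn(
            f"truncating MANOVA to {max_p} components (n={scores.shape[0]}, groups={k_groups})"
        )
        scores = scores[:, :max_p]
    if covariates is not None:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != scores.shape[0]:
            c = c.T
        x = np.hstack([np.ones((scores.shape[0], 1)), c])
        beta, *_ = np.linalg.lstsq(x, scores, rcond=None)
        scores = scores - x @ beta
    return st.wilks_manova(scores, groups)


def group_displacements(
    meshes: list[TriangleMesh], template_mesh: TriangleMesh, template_normals: np.ndarray
) -> np.ndarray:
    """(n_subjects, V) signed displacement of each subject from the template,
    projected on the outward template normal (positive = outward)."""
    out = np.empty((len(meshes), template_mesh.n_vertices))
    for i, m in enumerate(meshes):
        out[i] = np.einsum("ij,ij->i", m.vertices - template_mesh.vertices, template_normals)
    return out


def vertex_displacement_map(
    group_a: list[tuple],
    group_b: list[tuple],
    template: Template,
    q: float = 0.05,
) -> DisplacementMap:
    """Vertex-wise group comparison of baseline displacement, A vs B.

    ``group_a``/``group_b`` are lists of (left, right) mesh pairs. Vertices
    are concatenated left-then-right; the map is mean(A) - mean(B); p-values
    are two-sided Mann-Whitney U per vertex with BH-FDR at level ``q``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def disp(pairs):
        dl = group_displacements([p[0] for p in pairs], template.left, template.left_normals)
        dr = group_displacements([p[1] for p in pairs], template.right, template.right_normals)
        return np.hstack([dl, dr])

    da, db = disp(group_a), disp(group_b)
    _, p = st.mann_whitney_u_map(da, db)
    fdr = st.bh_fdr(p, q=q)
    return DisplacementMap(
        displacement=da.mean(axis=0) - db.mean(axis=0), p=p, fdr_mask=fdr.rejected, q=q
    )
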