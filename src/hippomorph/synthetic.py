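"""Synthetic longitudinal cohort generator.

Emulates a three-group (healthy controls CON, olanzapine-treated OLZ,
haloperidol-treated HAL), five-visit (weeks 0/12/24/52/104) hippocampal
surface study with visit dropout. Each subject gets corresponded left/right
meshes per retained visit, derived from one template by

* a group-mean baseline deformation field along outward template normals
  (patients contract inward over the head and lateral zones),
* a smooth zero-mean subject shape field plus a global size factor,
* a per-vertex longitudinal slope field (group mean field + subject offset +
  smooth subject field, mm/year along the baseline normal) driving visits,
* i.i.d. per-visit measurement noise along the normal.

Defaults reproduce the study conditions: group sizes 51/67/67, group-specific
retention, group mean vertex slopes -0.011 / -0.022 / -0.066 mm/year with
control subject-mean slope SD ~0.057 mm/year.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

from .mesh import TriangleMesh, vertex_normals, write_surface, read_surface

__all__ = [
    "CohortConfig",
    "Template",
    "Subject",
    "Cohort",
    "make_template",
    "sample_subject_baseline",
    "sample_longitudinal_series",
    "generate_cohort",
    "load_cohort",
    "WEEKS_PER_YEAR",
    "GROUPS",
]

WEEKS_PER_YEAR = 52.0
GROUPS = ("CON", "OLZ", "HAL")

#: Visit retention by group and week (fraction of baseline subjects scanned).
#: Controls were not scheduled at weeks 24 and 104.
DEFAULT_RETENTION = {
    "CON": {12: 0.922, 24: 0.0, 52: 0.843, 104: 0.0},
    "OLZ": {12: 0.896, 24: 0.836, 52: 0.552, 104: 0.358},
    "HAL": {12: 0.910, 24: 0.597, 52: 0.448, 104: 0.164},
}


def _per_group(value) -> dict:
    if isinstance(value, dict):
        return dict(value)
    return {g: value for g in GROUPS}


@dataclass
class CohortConfig:
    """All tunable knobs of the generator; defaults are the study conditions."""

    group_sizes: dict = dc_field(default_factory=lambda: {"CON": 51, "OLZ": 67, "HAL": 67})
    visit_weeks: tuple = (0, 12, 24, 52, 104)
    retention: dict = dc_field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_RETENTION.items()})
    template_resolution: int = 3  # icosphere subdivision level per hemisphere

    # baseline shape model
    baseline_inward_mm: dict = dc_field(
        default_factory=lambda: {"CON": 0.0, "OLZ": 0.45, "HAL": 0.45}
    )  # peak inward displacement over head+lateral zones
    baseline_subject_sd_mm: float = 0.25  # smooth subject shape field SD
    subject_size_sd: float = 0.04  # global linear size factor SD
    right_scale: float = 1.06  # right/left linear scale (right hippocampus larger)

    # longitudinal slope model (mm/year along baseline outward normal)
    slope_mean: dict = dc_field(
        default_factory=lambda: {"CON": -0.011, "OLZ": -0.022, "HAL": -0.066}
    )
    slope_spatial_sd: dict = dc_field(
        default_factory=lambda: {"CON": 0.057, "OLZ": 0.057, "HAL": 0.077}
    )  # SD across vertices of the group mean slope field
    slope_subject_sd: dict = dc_field(
        default_factory=lambda: {"CON": 0.057, "OLZ": 0.057, "HAL": 0.077}
    )  # SD of the per-subject global slope offset
    slope_field_sd: dict = dc_field(
        default_factory=lambda: {"CON": 0.12, "OLZ": 0.12, "HAL": 0.20}
    )  # SD of the smooth per-subject slope field (spatial variability)
    vertex_noise_sd: float = 0.10  # per-visit measurement noise, mm

    # covariates
    female_fraction: dict = dc_field(
        default_factory=lambda: {"CON": 0.314, "OLZ": 0.194, "HAL": 0.119}
    )
    gray_matter_mean: dict = dc_field(
        default_factory=lambda: {"CON": 705594.0, "OLZ": 691758.0, "HAL": 691758.0}
    )
    gray_matter_sd: dict = dc_field(
        default_factory=lambda: {"CON": 69608.0, "OLZ": 72941.0, "HAL": 72941.0}
    )
    illness_duration_mean: dict = dc_field(
        default_factory=lambda: {"CON": 0.0, "OLZ": 57.1, "HAL": 78.4}
    )
    illness_duration_sd: dict = dc_field(
        default_factory=lambda: {"CON": 0.0, "OLZ": 52.0, "HAL": 63.0}
    )

    smoothing_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        weeks = tuple(int(w) for w in self.visit_weeks)
        if len(weeks) < 1 or weeks[0] != 0 or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("visit_weeks must be strictly increasing and start at 0")
        self.visit_weeks = weeks
        for g, r in self.retention.items():
            for w, p in r.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"retention[{g}][{w}]={p} outside [0,1]")
        for name in ("baseline_inward_mm", "slope_mean", "slope_spatial_sd",
                     "slope_subject_sd", "slope_field_sd"):
            setattr(self, name, _per_group(getattr(self, name)))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["visit_weeks"] = list(self.visit_weeks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "visit_weeks" in d:
            d["visit_weeks"] = tuple(d["visit_weeks"])
        if "retention" in d:
            d["retention"] = {g: {int(w): p for w, p in r.items()} for g, r in d["retention"].items()}
        return cls(**d)


@dataclass
class Template:
    """Mirror-symmetric left/right template meshes with anatomical zones.

    Zones partition the vertices by longitudinal thirds (head / body / tail)
    and carry a lateral-half mask; identical vertex indexing applies to both
    hemispheres (the right mesh is the mirrored left).
    """

    left: TriangleMesh
    right: TriangleMesh
    axis_zone: np.ndarray  # per-vertex label in {"head", "body", "tail"}
    lateral: np.ndarray  # per-vertex bool, lateral half
    left_normals: np.ndarray = None
    right_normals: np.ndarray = None

    def __post_init__(self):
        if self.left_normals is None:
            self.left_normals = vertex_normals(self.left)
        if self.right_normals is None:
            self.right_normals = vertex_normals(self.right)

    @property
    def n_vertices(self) -> int:
        return self.left.n_vertices

    def zone_mask(self, *names: str) -> np.ndarray:
        """Boolean mask for a union of zone names ('head','body','tail','lateral','medial')."""
        m = np.zeros(self.n_vertices, dtype=bool)
        for nm in names:
            if nm == "lateral":
                m |= self.lateral
            elif nm == "medial":
                m |= ~self.lateral
            else:
                m |= self.axis_zone == nm
        return m


def make_template(resolution: int = 3) -> Template:
    """Build the hippocampus-like template: a bent, tapered ellipsoid
    ("banana") per hemisphere; the right mesh is the mirrored left.

    The surface starts as a unit icosphere (10*4^L + 2 vertices at
    subdivision level L), is scaled to half-axes ~(19.5, 7.6, 5.65) mm, tapered
    toward the tail and bent in the x-z plane. Head/body/tail are thirds of
    the normalized long axis; the lateral half is y > 0 on the left.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    ico = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    u = np.asarray(ico.vertices, dtype=float).copy()  # unit-sphere coords
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    # scale to hippocampal proportions (mm), taper toward the tail (x < 0)
    a, b, c = 19.5, 7.6, 5.65
    taper = 1.0 - 0.30 * (1.0 - x) / 2.0  # 1 at head (x=1), 0.7 at tail (x=-1)
    verts = np.column_stack([a * x, b * y * taper, c * z * taper])
    # bend: lift both ends in z, quadratic in the long axis
    verts[:, 2] += 4.0 * x**2
    faces = np.asarray(ico.faces, dtype=np.int64)
    left = TriangleMesh(verts, faces, hemisphere="left")
    rv = verts.copy()
    rv[:, 0] = -rv[:, 0]
    right = TriangleMesh(rv, faces[:, ::-1].copy(), hemisphere="right",
                         topology_id=left.topology_id)
    axis_zone = np.where(x > 1.0 / 3.0, "head", np.where(x < -1.0 / 3.0, "tail", "body"))
    return Template(left=left, right=right, axis_zone=axis_zone, lateral=y > 0)


# ---------------------------------------------------------------------------
# smooth random fields on the template graph


class FieldSampler:
    """Smooth, zero-mean, unit-SD random scalar fields on a mesh graph.

    White vertex noise is averaged with graph neighbors for ``iterations``
    rounds (v <- 0.5 v + 0.5 mean(neighbors)), then each field is centered
    (zero mean over vertices) and rescaled to unit SD across vertices, so the
    caller controls amplitude and mean exactly.
    """

    def __init__(self, mesh: TriangleMesh, iterations: int = 10):
        v = mesh.n_vertices
        f = mesh.faces
        rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
        cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
        adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(v, v)).tocsr()
        adj.data[:] = 1.0  # collapse duplicate edges
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self.op = sp.diags(0.5 * np.ones(v)) + sp.diags(0.5 / deg) @ adj
        self.iterations = iterations
        self.n_vertices = v

    def smooth(self, fields: np.ndarray) -> np.ndarray:
        out = fields
        for _ in range(self.iterations):
            out = self.op @ out
        return out

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """(V, n) matrix of centered unit-SD smooth fields."""
        z = self.smooth(rng.standard_normal((self.n_vertices, n)))
        z = z - z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        return z / sd


def _group_fields(template: Template, config: CohortConfig, sampler: FieldSampler):
    """Deterministic group-mean baseline-deformation and slope fields.

    Patterns come from a fixed internal seed (independent of the cohort seed)
    so the 'truth' fields are identical across replicate cohorts. All groups
    share ONE spatial progression pattern (patchy, weighted toward the head
    and lateral zones) whose amplitude and offset are group-specific: group
    contrasts are then a near-uniform level shift plus a small amplitude
    difference, while the anatomically specific patches live in the
    individual subject fields. This is what lets subject-level percentage
    statistics separate the groups even though per-vertex group differences
    stay small.
    """
    rng = np.random.default_rng(16807)
    w_headlat = sampler.smooth(template.zone_mask("head", "lateral").astype(float)[:, None])[:, 0]
    w_headlat = w_headlat / w_headlat.max()
    baseline = {}
    for g in GROUPS:
        baseline[g] = -config.baseline_inward_mm[g] * w_headlat
    raw = sampler.sample(rng, n=1)[:, 0] - 1.0 * (w_headlat - w_headlat.mean())
    pattern = (raw - raw.mean()) / raw.std()
    slope = {}
    for g in GROUPS:
        slope[g] = config.slope_mean[g] + config.slope_spatial_sd[g] * pattern
    return baseline, slope


@dataclass
class Subject:
    subject_id: str
    group: str
    sex: str
    gray_matter_volume: float
    illness_duration: float | None
    visits: dict  # week -> (left TriangleMesh, right TriangleMesh)

    @property
    def weeks(self) -> list[int]:
        return sorted(self.visits)


@dataclass
class Cohort:
    config: CohortConfig
    template: Template
    subjects: list

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "sex": s.sex,
                    "gray_matter_volume_mm3": s.gray_matter_volume,
                    "illness_duration_weeks": "" if s.illness_duration is None else s.illness_duration,
                    "weeks_available": ";".join(str(w) for w in s.weeks),
                }
            )
        return pd.DataFrame(rows)


def sample_subject_baseline(
    template: Template,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    sampler: FieldSampler | None = None,
    group_deformation: np.ndarray | None = None,
):
    """Draw one subject's week-0 meshes and metadata.

    vertex_i = (template_i + (d_group(i) + b_subject(i)) * n_i) * size, with
    the same fields applied mirror-symmetrically to both hemispheres and the
    right hemisphere additionally scaled by ``right_scale``.
    """
    if sampler is None:
        sampler = FieldSampler(template.left, config.smoothing_iterations)
    if group_deformation is None:
        group_deformation = _group_fields(template, config, sampler)[0][group]
    if config.baseline_subject_sd_mm > 0:
        b = config.baseline_subject_sd_mm * sampler.sample(rng, 2)  # (V, 2): per hemisphere
    else:
        b = np.zeros((template.n_vertices, 2))
    size = 1.0 + (config.subject_size_sd * rng.standard_normal() if config.subject_size_sd > 0 else 0.0)
    dl = group_deformation + b[:, 0]
    dr = group_deformation + b[:, 1]
    lv = (template.left.vertices + dl[:, None] * template.left_normals) * size
    rv = (template.right.vertices + dr[:, None] * template.right_normals) * size * config.right_scale
    return template.left.copy(lv), template.right.copy(rv)


def sample_longitudinal_series(
    baseline_left: TriangleMesh,
    baseline_right: TriangleMesh,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    sampler: FieldSampler | None = None,
    group_slope_field: np.ndarray | None = None,
) -> dict:
    """Generate the week -> (left, right) visit meshes for one subject.

    Displacement along the subject's baseline outward normal at week t is
    (s_group(i) + m_subject + f_subject(i)) * t/52 + noise, with visits after
    week 0 retained independently at the group's retention probability.
    """
    if sampler is None:
        sampler = FieldSampler(baseline_left, config.smoothing_iterations)
    template_like = baseline_left
    if group_slope_field is None:
        raise ValueError("group_slope_field must be supplied (see generate_cohort)")
    m = config.slope_subject_sd[group] * rng.standard_normal() if config.slope_subject_sd[group] > 0 else 0.0
    if config.slope_field_sd[group] > 0:
        f = config.slope_field_sd[group] * sampler.sample(rng, 2)  # (V, 2): per hemisphere
    else:
        f = np.zeros((template_like.n_vertices, 2))
    slope_l = group_slope_field + m + f[:, 0]  # mm/year per vertex
    slope_r = group_slope_field + m + f[:, 1]
    nl = vertex_normals(baseline_left)
    nr = vertex_normals(baseline_right)
    retention = config.retention.get(group, {})
    visits = {0: (baseline_left, baseline_right)}
    for week in config.visit_weeks[1:]:
        keep_p = retention.get(week, 1.0)
        u = rng.uniform()  # drawn for every scheduled week to keep the stream aligned
        noise_l = rng.standard_normal(template_like.n_vertices)
        noise_r = rng.standard_normal(template_like.n_vertices)
        if u >= keep_p:
            continue
        dt_years = week / WEEKS_PER_YEAR
        dl = slope_l * dt_years + config.vertex_noise_sd * noise_l
        dr = slope_r * dt_years + config.vertex_noise_sd * noise_r
        visits[week] = (
            baseline_left.copy(baseline_left.vertices + dl[:, None] * nl),
            baseline_right.copy(baseline_right.vertices + dr[:, None] * nr),
        )
    return visits


def generate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate a full cohort (deterministically from ``config.seed``); when
    ``out_dir`` is given, also write ``metadata.csv`` and per-visit VTK meshes
    under ``meshes/<subjectID>_<hemi>_<week>.vtk``."""
    template = make_template(config.template_resolution)
    sampler = FieldSampler(template.left, config.smoothing_iterations)
    base_fields, slope_fields = _group_fields(template, config, sampler)
    seq = np.random.SeedSequence(config.seed)
    subjects = []
    n_total = sum(config.group_sizes.values())
    children = seq.spawn(n_total)
    idx = 0
    for group in config.group_sizes:
        for k in range(config.group_sizes[group]):
            rng = np.random.default_rng(children[idx])
            idx += 1
            sid = f"{group}{k + 1:03d}"
            bl, br = sample_subject_baseline(
                template, group, config, rng, sampler, base_fields[group]
            )
            visits = sample_longitudinal_series(
                bl, br, group, config, rng, sampler, slope_fields[group]
            )
            sex = "F" if rng.uniform() < config.female_fraction.get(group, 0.0) else "M"
            gm = rng.normal(config.gray_matter_mean[group], config.gray_matter_sd[group])
            if group == "CON":
                dur = None
            else:
                mu, sd = config.illness_duration_mean[group], config.illness_duration_sd[group]
                # gamma with matching mean/SD keeps durations positive and right-skewed
                shape = (mu / sd) ** 2
                dur = float(rng.gamma(shape, sd**2 / mu)) if mu > 0 else 0.0
            subjects.append(
                Subject(
                    subject_id=sid,
                    group=group,
                    sex=sex,
                    gray_matter_volume=float(gm),
                    illness_duration=dur,
                    visits=visits,
                )
            )
    cohort = Cohort(config=config, template=template, subjects=subjects)
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


def save_cohort(cohort: Cohort, out_dir) -> Path:
    out_dir = Path(out_dir)
    mesh_dir = out_dir / "meshes"
    mesh_dir.mkdir(parents=True, exist_ok=True)
    cohort.metadata().to_csv(out_dir / "metadata.csv", index=False, float_format="%.10g")
    for hemi, mesh in (("left", cohort.template.left), ("right", cohort.template.right)):
        write_surface(mesh, mesh_dir / f"template_{hemi}_0.vtk")
    for s in cohort.subjects:
        for week, (lm, rm) in s.visits.items():
            write_surface(lm, mesh_dir / f"{s.subject_id}_left_{week}.vtk")
            write_surface(rm, mesh_dir / f"{s.subject_id}_right_{week}.vtk")
    return out_dir


def load_cohort(in_dir, config: CohortConfig | None = None) -> Cohort:
    """Load a cohort directory written by :func:`save_cohort`.

    The template is rebuilt from the saved template meshes; zone labels are
    reconstructed at the stored resolution.
    """
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.csv", keep_default_na=False)
    mesh_dir = in_dir / "meshes"
    tl = read_surface(mesh_dir / "template_left_0.vtk", hemisphere="left")
    level = int(round(np.log((tl.n_vertices - 2) / 10.0) / np.log(4.0)))
    template = make_template(level)
    # preserve stored template geometry (zones come from the canonical builder)
    template = Template(
        left=tl,
        right=read_surface(mesh_dir / "template_right_0.vtk", hemisphere="right"),
        axis_zone=template.axis_zone,
        lateral=template.lateral,
    )
    subjects = []
    for _, row in meta.iterrows():
        weeks = [int(w) for w in str(row["weeks_available"]).split(";") if w != ""]
        visits = {}
        for w in weeks:
            visits[w] = (
                read_surface(mesh_dir / f"{row['subject_id']}_left_{w}.vtk", hemisphere="left"),
                read_surface(mesh_dir / f"{row['subject_id']}_right_{w}.vtk", hemisphere="right"),
            )
        dur = row["illness_duration_weeks"]
        subjects.append(
            Subject(
                subject_id=row["subject_id"],
                group=row["group"],
                sex=row["sex"],
                gray_matter_volume=float(row["gray_matter_volume_mm3"]),
                illness_duration=None if dur in ("", None) else float(dur),
                visits=visits,
            )
        )
    return Cohort(config=config or CohortConfig(), template=template, subjects=subjects)
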