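"""Configuration-driven end-to-end runner.

Generates (or loads) a cohort, validates correspondence, executes the
baseline and longitudinal stages, and writes a results manifest with file
checksums so that identical seed + config gives byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import validate_correspondence, write_surface
from .synthetic import Cohort, CohortConfig, generate_cohort, load_cohort, GROUPS
from . import baseline as bl
from . import longitudinal as lg

__all__ = ["RunConfig", "StageError", "run", "report"]

log = logging.getLogger("hippomorph")

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None  # load instead of generate when set
    stages: tuple = ("baseline", "longitudinal")
    q: float = 0.05
    threshold_method: str = "subject_means"
    display_range: float = 0.1  # mm/year clamp for exported slope surfaces
    write_subject_slope_maps: bool = False
    out_dir: str = "out"
    seed: int | None = None  # overrides cohort.seed when set
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")
        unknown = set(self.stages) - {"baseline", "longitudinal"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.cohort.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig.from_dict(raw.pop("cohort", {}) or {})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=cohort, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``<out_dir>/manifest.json``). Partial outputs of a failed stage are kept
    next to a ``<stage>.partial`` marker."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": list(config.stages), "q": config.q,
                      "threshold_method": config.threshold_method,
                      "seed": config.cohort.seed, "files": {}}

    def record(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    stage = "cohort"
    try:
        t0 = time.time()
        if config.cohort_path:
            log.info("loading cohort from %s", config.cohort_path)
            cohort = load_cohort(config.cohort_path, config.cohort)
        else:
            log.info("generating cohort (seed=%d)", config.cohort.seed)
            cohort = generate_cohort(config.cohort)
        meta_path = out / "metadata.csv"
        _write_csv(cohort.metadata(), meta_path)
        record(meta_path)
        all_meshes = [m for s in cohort.subjects for w in s.weeks for m in s.visits[w]]
        rep = validate_correspondence(
            [cohort.template.left, cohort.template.right] + all_meshes
        )
        if not rep.ok:
            raise ValueError(f"correspondence check failed: {rep.mismatches[:5]}")
        log.info("cohort ready: %d subjects (%.1fs)", len(cohort.subjects), time.time() - t0)

        if "baseline" in config.stages:
            stage = "baseline"
            _run_baseline(cohort, config, out, record)
        if "longitudinal" in config.stages:
            stage = "longitudinal"
            _run_longitudinal(cohort, config, out, record)
    except Exception as e:
        (out / f"{stage}.partial").write_text(f"{type(e).__name__}: {e}\n")
        raise StageError(stage, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %s", manifest_path)
    return manifest


def _run_baseline(cohort: Cohort, config: RunConfig, out: Path, record):
    t0 = time.time()
    vols = bl.baseline_volume_table(cohort)
    _write_csv(vols, out / "baseline_volumes.csv")
    record(out / "baseline_volumes.csv")
    tests = [bl.baseline_volume_analysis(cohort)]

    groups_psy = np.where(vols["group"].isin(["OLZ", "HAL"]), "PSY", "CON")
    for hemi, side in (("left", 0), ("right", 1)):
        meshes = [s.visits[0][side] for s in cohort.subjects if 0 in s.visits]
        ids = [s.subject_id for s in cohort.subjects if 0 in s.visits]
        model = bl.shape_pca(meshes, hemi, subject_ids=ids)
        np.savez(
            out / f"pca_{hemi}.npz",
            mean_surface=model.mean_surface,
            components=model.components,
            explained_variance_fraction=model.explained_variance_fraction,
            scores=model.scores,
            subject_ids=np.array(model.subject_ids),
        )
        record(out / f"pca_{hemi}.npz")
        mv = bl.shape_manova(model, groups_psy)
        tests.append(pd.DataFrame([{
            "analysis": f"shape_manova_{hemi}", "effect": "group",
            "statistic_name": mv.statistic_name, "statistic": mv.statistic,
            "df1": mv.df[0], "df2": mv.df[1], "p_value": mv.p_value,
        }]))

    psy_pairs = [s.visits[0] for s in cohort.subjects if s.group != "CON" and 0 in s.visits]
    con_pairs = [s.visits[0] for s in cohort.subjects if s.group == "CON" and 0 in s.visits]
    if psy_pairs and con_pairs:
        dmap = bl.vertex_displacement_map(psy_pairs, con_pairs, cohort.template, q=config.q)
        nl = cohort.template.left.n_vertices
        for hemi, mesh, sl in (("left", cohort.template.left, slice(0, nl)),
                               ("right", cohort.template.right, slice(nl, None))):
            p = out / f"baseline_map_{hemi}.vtk"
            with np.errstate(divide="ignore"):
                neglog = -np.log10(np.maximum(dmap.p[sl], 1e-300))
            write_surface(mesh, p, scalars={
                "displacement_mm": dmap.displacement[sl],
                "neg_log10_p": neglog,
                "fdr_mask": dmap.fdr_mask[sl].astype(float),
            })
            record(p)
    _write_csv(pd.concat(tests, ignore_index=True), out / "baseline_tests.csv")
    record(out / "baseline_tests.csv")
    log.info("baseline stage done (%.1fs)", time.time() - t0)


def _run_longitudinal(cohort: Cohort, config: RunConfig, out: Path, record):
    t0 = time.time()
    va = lg.volume_slope_analysis(cohort)
    _write_csv(va["slopes"], out / "volume_slopes.csv")
    record(out / "volume_slopes.csv")

    maps = lg.cohort_slope_maps(cohort)
    if "CON" not in maps:
        raise ValueError("no control subjects with >= 2 visits; thresholds undefined")
    thresholds = lg.control_thresholds(maps["CON"], method=config.threshold_method)
    summaries = []
    for g, ms in maps.items():
        for m in ms:
            summaries.append(lg.slope_percentages(m, thresholds, group=g))
        gm = lg.group_mean_slope_map(ms, label=g)
        _write_csv(lg.slope_cdf(gm), out / f"cdf_{g}.csv")
        record(out / f"cdf_{g}.csv")
        for p in lg.export_slope_surface(cohort.template, gm, out / f"group_mean_{g}",
                                         display_range=config.display_range):
            record(p)
        if config.write_subject_slope_maps:
            sub_dir = out / "slope_maps"
            sub_dir.mkdir(exist_ok=True)
            for m in ms:
                for p in lg.export_slope_surface(cohort.template, m, sub_dir / m.label,
                                                 display_range=config.display_range):
                    record(p)

    st_tab = lg.summaries_table(summaries)
    _write_csv(st_tab, out / "slope_summaries.csv")
    record(out / "slope_summaries.csv")
    pct_tests = lg.compare_percentages(summaries)
    tests = [va["tests"], pct_tests.assign(analysis="pct_" + pct_tests["analysis"])]
    _write_csv(pct_tests, out / "percentage_tests.csv")
    record(out / "percentage_tests.csv")
    thr = pd.DataFrame([{ "lower_mm_per_year": thresholds.lower,
                          "upper_mm_per_year": thresholds.upper,
                          "method": thresholds.method}])
    _write_csv(thr, out / "thresholds.csv")
    record(out / "thresholds.csv")

    if "HAL" in maps and "OLZ" in maps and len(maps["HAL"]) >= 2 and len(maps["OLZ"]) >= 2:
        vt = lg.vertexwise_slope_test(maps["HAL"], maps["OLZ"], q=config.q)
        nl = cohort.template.left.n_vertices
        for hemi, mesh, sl in (("left", cohort.template.left, slice(0, nl)),
                               ("right", cohort.template.right, slice(nl, None))):
            p = out / f"vertexwise_HAL_vs_OLZ_{hemi}.vtk"
            write_surface(mesh, p, scalars={
                "mean_diff": vt.displacement[sl],
                "p": vt.p[sl],
                "fdr_mask": vt.fdr_mask[sl].astype(float),
            })
            record(p)
    _write_csv(pd.concat(tests, ignore_index=True), out / "longitudinal_tests.csv")
    record(out / "longitudinal_tests.csv")
    log.info("longitudinal stage done (%.1fs)", time.time() - t0)


def report(manifest_path) -> str:
    """Render a human-readable summary (demographics, volume tests, and the
    Table-2-style percentage metrics as group mean (SD)) from a manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out = manifest_path.parent
    missing = [f for f in manifest["files"] if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    lines = ["hippomorph run summary", "======================", ""]
    if "metadata.csv" in manifest["files"]:
        meta = pd.read_csv(out / "metadata.csv", keep_default_na=False)
        lines.append("Cohort")
        for g, sub in meta.groupby("group"):
            nf = (sub["sex"] == "F").sum()
            lines.append(f"  {g}: n={len(sub)}  (F {nf}, M {len(sub) - nf})")
        lines.append("")
    if "baseline_tests.csv" in manifest["files"]:
        bt = pd.read_csv(out / "baseline_tests.csv")
        lines.append("Baseline tests")
        for _, r in bt.iterrows():
            lines.append(
                f"  {r['analysis']}/{r['effect']}: {r['statistic_name']}"
                f"({r['df1']:g},{r['df2']:g}) = {r['statistic']:.2f}, p = {r['p_value']:.4g}"
            )
        lines.append("")
    if "slope_summaries.csv" in manifest["files"]:
        ss = pd.read_csv(out / "slope_summaries.csv")
        lines.append("Surface slope percentages, group mean (SD)")
        for metric in lg.METRICS:
            lines.append(f"  {metric}")
            for hemi in ("left", "right"):
                col = f"{metric}_{hemi}"
                cells = []
                for g in [g for g in GROUPS if g in set(ss["group"])]:
                    v = ss.loc[ss["group"] == g, col]
                    cells.append(f"{g} {v.mean():.1f} ({v.std(ddof=1):.1f})")
                lines.append(f"    {hemi:<6} " + "   ".join(cells))
        lines.append("")
    if "thresholds.csv" in manifest["files"]:
        thr = pd.read_csv(out / "thresholds.csv").iloc[0]
        lines.append(
            f"Large-magnitude thresholds ({thr['method']}): "
            f"{thr['lower_mm_per_year']:.5f} / {thr['upper_mm_per_year']:.5f} mm/year"
        )
        lines.append("")
    if "longitudinal_tests.csv" in manifest["files"]:
        lt = pd.read_csv(out / "longitudinal_tests.csv")
        lines.append("Longitudinal tests")
        for _, r in lt.iterrows():
            if r.get("analysis") == "shapiro":
                continue
            metric = f"[{r['metric']}] " if "metric" in lt.columns and pd.notna(r.get("metric")) else ""
            lines.append(
                f"  {metric}{r['analysis']}/{r['effect']}: "
                f"{r['statistic_name']} = {r['statistic']:.3g}, p = {r['p_value']:.4g}"
            )
    return "\n".join(lines) + "\n"
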