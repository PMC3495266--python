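"""Longitudinal shape change: per-vertex slope maps, control-referenced
thresholds, percent-negative / large-magnitude statistics and their group
comparison, and the vertex-wise treatment contrast.

This is the package's core analysis. Each subject's per-vertex slope
(mm/year along the outward baseline normal) is summarized as the percentage
of negative slopes and the percentage beyond the control mean +/- 1 SD
("very negative" / "very positive"); the percentages are compared across
groups by ANOVA while the per-vertex slopes themselves are compared by
Mann-Whitney U with FDR correction.
"""
import numpy as np

from hippomorph import CohortConfig, generate_cohort
import hippomorph.longitudinal as lg

cohort = generate_cohort(CohortConfig(seed=1))  # full study scale: 51/67/67
maps = lg.cohort_slope_maps(cohort)

thr = lg.control_thresholds(maps["CON"], method="subject_means")
print(f"large-magnitude slope thresholds (control mean -/+ 1 SD): "
      f"{thr.lower:.5f} / {thr.upper:.5f} mm/year")

summaries = []
print("\ngroup mean vertex slope and percentage metrics, mean (SD):")
for g in ("CON", "OLZ", "HAL"):
    ss = [lg.slope_percentages(m, thr, group=g) for m in maps[g]]
    summaries += ss
    mean_slope = np.mean([s.mean_slope for s in ss])
    pvn = np.array([s.pct_very_negative for s in ss])
    print(f"  {g}: slope {mean_slope:+.3f} mm/yr | % very negative "
          f"{pvn.mean():.1f} ({pvn.std(ddof=1):.1f})")

tab = lg.compare_percentages(summaries)
row = tab.query("metric == 'pct_very_negative' and analysis == 'oneway_anova'").iloc[0]
print(f"\nANOVA on % very-negative slopes: F({row['df1']:g},{row['df2']:g}) = "
      f"{row['statistic']:.1f}, p = {row['p_value']:.2g}")
post = tab.query("metric == 'pct_very_negative' and analysis == 'posthoc_lsd'")
for _, r in post.iterrows():
    print(f"  post hoc {r['effect']}: p = {r['p_value']:.3g}")

vt = lg.vertexwise_slope_test(maps["HAL"], maps["OLZ"], q=0.05)
print(f"\nvertex-wise HAL vs OLZ slope comparison: "
      f"{int(vt.fdr_mask.sum())} of {vt.p.size} vertices survive q=0.05 FDR")
print("A strong group effect on the percentage statistic together with few or")
print("no FDR-significant vertices means the treatments differ in how MUCH of")
print("the surface contracts strongly, not in WHERE: the affected regions vary")
print("between individuals.")
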