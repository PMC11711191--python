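"""Two-sample statistical comparisons and figure-style report assembly.

Every comparison runs Shapiro–Wilk normality per group and Levene's test
for homogeneity of variances as recorded diagnostics, then a two-sample
t test (pooled-variance when Levene's test does not reject, Welch
otherwise).  Significance stars follow the usual strict thresholds:
* p < 0.05, ** p < 0.01, *** p < 0.001.  No multiple-testing correction
is applied; the report records the number of comparisons instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class InsufficientDataError(ValueError):
    """Raised when a group has fewer than 3 observations."""


def stars_for_p(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class StatResult:
    """Outcome of one two-sample comparison with its diagnostics."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    mean_sd_a: tuple[float, float]
    mean_sd_b: tuple[float, float]
    normality_ok: tuple[bool, bool]
    variance_homogeneous: bool
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def compare_groups(a, b, alpha_diag: float = 0.05) -> StatResult:
    """Two-sample t test with normality / variance diagnostics.

    Shapiro–Wilk per group and Levene across groups are recorded; the t
    test is pooled-variance when variances look homogeneous and Welch
    when Levene rejects at ``alpha_diag``.  Two-sided throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"need n >= 3 per group, got {a.size} and {b.size}"
        )
    sw_a = sps.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0
    sw_b = sps.shapiro(b).pvalue if np.ptp(b) > 0 else 1.0
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        lev_p = 1.0
    else:
        lev_p = sps.levene(a, b).pvalue
    homogeneous = bool(lev_p >= alpha_diag)
    res = sps.ttest_ind(a, b, equal_var=homogeneous)
    p = float(res.pvalue)
    if np.isnan(p):           # both groups constant and equal
        p = 1.0
    return StatResult(
        test_name="t-test" if homogeneous else "welch-t-test",
        statistic=float(res.statistic) if np.isfinite(res.statistic) else 0.0,
        p_value=p,
        n_per_group=(a.size, b.size),
        mean_sd_a=(float(a.mean()), float(a.std(ddof=1))),
        mean_sd_b=(float(b.mean()), float(b.std(ddof=1))),
        normality_ok=(bool(sw_a >= alpha_diag), bool(sw_b >= alpha_diag)),
        variance_homogeneous=homogeneous,
        stars=stars_for_p(p),
    )


@dataclass
class ReportSet:
    """Bundle of the pipeline's summary tables, one section per analysis."""

    sections: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    n_comparisons: int = 0

    def to_markdown(self) -> str:
        lines = ["# fiberweave report", ""]
        for name, df in self.sections.items():
            lines.append(f"## {name}")
            lines.append("")
            lines.append(df.to_string(index=False))
            lines.append("")
        if self.comparisons:
            lines.append("## comparisons")
            lines.append("")
            for name, r in self.comparisons.items():
                lines.append(
                    f"- {name}: {r.test_name} p = {r.p_value:.3g} ({r.stars}); "
                    f"group means {r.mean_sd_a[0]:.3g} ± {r.mean_sd_a[1]:.3g} vs "
                    f"{r.mean_sd_b[0]:.3g} ± {r.mean_sd_b[1]:.3g}"
                )
            lines.append("")
            lines.append(f"{self.n_comparisons} comparison(s); no multiplicity correction applied.")
            lines.append("")
        return "\n".join(lines)


def report_bundle(
    thickness_table=None,
    intensity_results: dict | None = None,
    orientation_pooled: dict | None = None,
    crossing_summaries: dict | None = None,
) -> ReportSet:
    """Assemble the summary report from whichever analyses ran.

    ``intensity_results`` maps label → IntensityResult, ``orientation_pooled``
    maps label → PooledOrientation, ``crossing_summaries`` maps label →
    DensitySummary.  All summaries are reported as mean ± sd; two-group
    inputs additionally get a dorsal-vs-ventral (or perpendicular-vs-
    parallel) comparison with stars.
    """
    rs = ReportSet()
    if (thickness_table is None and not intensity_results
            and not orientation_pooled and not crossing_summaries):
        raise ValueError("need at least one upstream result")

    if thickness_table is not None:
        rs.sections["layer thickness (mm)"] = thickness_table.formatted

    if intensity_results:
        rows = []
        for label, r in intensity_results.items():
            rows.append({"sample": label, "n_rois": r.per_roi_mean.size,
                         "mean": r.grand_mean, "sd": r.grand_sd})
        rs.sections["SHG intensity (a.u.)"] = pd.DataFrame(rows)
        labels = list(intensity_results)
        if len(labels) == 2:
            a, b = (intensity_results[l] for l in labels)
            res = compare_groups(a.per_roi_mean, b.per_roi_mean)
            rs.comparisons[f"intensity {labels[0]} vs {labels[1]}"] = res

    if orientation_pooled:
        rows = []
        for label, p in orientation_pooled.items():
            rows.append({
                "sample": label,
                "pct_perpendicular": p.mean_pct_perpendicular,
                "sd_perpendicular": p.sd_pct_perpendicular,
                "pct_parallel": p.mean_pct_parallel,
                "sd_parallel": p.sd_pct_parallel,
            })
            if p.perp_values.size >= 3 and p.par_values.size >= 3:
                res = compare_groups(p.perp_values, p.par_values)
                rs.comparisons[f"orientation perpendicular vs parallel ({label})"] = res
        rs.sections["fiber orientation (%)"] = pd.DataFrame(rows)

    if crossing_summaries:
        rows = []
        for label, d in crossing_summaries.items():
            rows.append({"sample": label,
                         "mean_density_per_um3": d.mean_density_per_um3,
                         "sd_density_per_um3": d.sd_density_per_um3})
        rs.sections["fiber crossings (per um^3)"] = pd.DataFrame(rows)

    rs.n_comparisons = len(rs.comparisons)
    return rs
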