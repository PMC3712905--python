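"""Group-comparison statistics and cohort report assembly.

Cohorts (e.g. wild-type-like vs. mutant-like) are compared metric by
metric with box-and-whisker summaries (median, quartiles, whiskers at the
most extreme points within 1.5 IQR of the box) and the two-sample
Kolmogorov–Smirnov test.  No multiple-testing correction is applied; the
report records the number of tests so users can apply their own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BoxSummary",
    "GroupComparison",
    "CohortReport",
    "box_summary",
    "ks_two_sample",
    "compare_cohorts",
    "significance_marker",
]


@dataclass
class BoxSummary:
    """Box-and-whisker statistics with linear-interpolation quantiles."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass
class GroupComparison:
    """Per-metric cohort comparison: box summaries plus pairwise KS tests."""

    metric: str
    groups: dict[str, BoxSummary]
    D: float | None  # two-group shortcut; None with >2 groups
    p_value: float | None
    pairwise: dict[str, tuple[float, float]] = field(default_factory=dict)
    groups_missing: list[str] = field(default_factory=list)

    @property
    def marker(self) -> str:
        return significance_marker(self.p_value) if self.p_value is not None else ""


@dataclass
class CohortReport:
    comparisons: list[GroupComparison]
    n_tests: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.comparisons:
            for group, box in comp.groups.items():
                rows.append(
                    {
                        "metric": comp.metric,
                        "group": group,
                        "n": box.n,
                        "median": box.median,
                        "q1": box.q1,
                        "q3": box.q3,
                        "whisker_low": box.whisker_low,
                        "whisker_high": box.whisker_high,
                        "D": comp.D,
                        "p_value": comp.p_value,
                        "marker": comp.marker,
                    }
                )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"n_tests": self.n_tests, "comparisons": []}
        for comp in self.comparisons:
            out["comparisons"].append(
                {
                    "metric": comp.metric,
                    "groups": {g: asdict(b) for g, b in comp.groups.items()},
                    "D": comp.D,
                    "p_value": comp.p_value,
                    "marker": comp.marker,
                    "pairwise": {k: list(v) for k, v in comp.pairwise.items()},
                    "groups_missing": comp.groups_missing,
                }
            )
        return out

    def save(self, directory, figures: bool = False) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2)
        )
        self.to_frame().to_csv(directory / "report.csv", index=False)
        if figures:
            self._save_figures(directory)

    def _save_figures(self, directory: Path) -> None:
        """One box-and-whisker panel per metric, annotated with the KS
        significance marker."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for comp in self.comparisons:
            if not comp.groups:
                continue
            fig, ax = plt.subplots(figsize=(3 + len(comp.groups), 4))
            names = list(comp.groups)
            for i, name in enumerate(names):
                b = comp.groups[name]
                ax.bxp(
                    [
                        {
                            "med": b.median,
                            "q1": b.q1,
                            "q3": b.q3,
                            "whislo": b.whisker_low,
                            "whishi": b.whisker_high,
                            "fliers": [],
                        }
                    ],
                    positions=[i],
                    widths=0.5,
                    showfliers=False,
                )
            ax.set_xticks(range(len(names)), names)
            title = comp.metric
            if comp.marker:
                title += f"  {comp.marker}"
            ax.set_title(title)
            fig.tight_layout()
            fig.savefig(directory / f"{comp.metric}.png", dpi=120)
            plt.close(fig)

    @classmethod
    def from_json(cls, path) -> "CohortReport":
        raw = json.loads(Path(path).read_text())
        comps = []
        for c in raw["comparisons"]:
            comps.append(
                GroupComparison(
                    metric=c["metric"],
                    groups={g: BoxSummary(**b) for g, b in c["groups"].items()},
                    D=c["D"],
                    p_value=c["p_value"],
                    pairwise={k: tuple(v) for k, v in c["pairwise"].items()},
                    groups_missing=list(c["groups_missing"]),
                )
            )
        return cls(comparisons=comps, n_tests=raw["n_tests"])


def significance_marker(p: float) -> str:
    """'***' below 0.001, '*' below 0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def box_summary(values) -> BoxSummary:
    """Median, quartiles and 1.5-IQR whiskers of a sample.

    Quantiles use linear interpolation between order statistics; whiskers
    are the most extreme data points inside the 1.5 IQR fences (not the
    fences themselves).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def ks_two_sample(a, b, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: (D, p).

    D is the maximum absolute difference between the two empirical CDFs.
    The p-value uses the asymptotic two-sample formula by default, common
    practice at the cohort sizes this pipeline targets (tens of larvae);
    pass ``method="exact"`` for small samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(
    summaries_by_group: dict[str, pd.DataFrame],
    metrics: list[str],
    ks_method: str = "asymp",
) -> CohortReport:
    """One GroupComparison per metric across two or more cohorts.

    ``summaries_by_group`` maps group name to a per-larva metric table.
    A metric absent from a group is reported in ``groups_missing`` rather
    than silently dropped.  With exactly two groups carrying the metric,
    ``D``/``p_value`` hold their KS test; all pairwise tests are kept in
    ``pairwise``.
    """
    if len(summaries_by_group) < 2:
        raise ValueError("need at least two groups")
    comparisons = []
    n_tests = 0
    for metric in metrics:
        groups: dict[str, BoxSummary] = {}
        samples: dict[str, np.ndarray] = {}
        missing: list[str] = []
        for name, df in summaries_by_group.items():
            if metric not in df.columns:
                missing.append(name)
                continue
            vals = pd.to_numeric(df[metric], errors="coerce").to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                missing.append(name)
                continue
            groups[name] = box_summary(vals)
            samples[name] = vals
        pairwise: dict[str, tuple[float, float]] = {}
        names = list(samples)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                gi, gj = names[i], names[j]
                if samples[gi].size >= 2 and samples[gj].size >= 2:
                    d, p = ks_two_sample(samples[gi], samples[gj], ks_method)
                    pairwise[f"{gi}|{gj}"] = (d, p)
                    n_tests += 1
        if len(pairwise) == 1:
            (d, p), = pairwise.values()
        else:
            d = p = None
        comparisons.append(
            GroupComparison(
                metric=metric,
                groups=groups,
                D=d,
                p_value=p,
                pairwise=pairwise,
                groups_missing=missing,
            )
        )
    return CohortReport(comparisons=comparisons, n_tests=n_tests)
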