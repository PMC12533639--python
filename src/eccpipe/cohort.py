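"""Cohort-level statistics over per-sample circle catalogs.

The sample table (a pandas DataFrame: sample_id, group, n_eccDNA,
mean_length, optional expression columns) is the unit of analysis.  Two
groups are compared with an unpaired two-sided Student's t test
(pooled-variance classical form; Welch behind a flag); more than two with
one-way ANOVA.  Correlations are Pearson's r with R^2 and the two-sided p
from the t transform of r.  Cohorts can be stratified into circle-high and
circle-low halves at the median burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .caller import CircleCatalog


def per_sample_summary(
    catalogs: list[CircleCatalog],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per catalog: sample_id, group, n_eccDNA, mean_length.

    ``mean_length`` is NaN (undefined) for an empty catalog.  Duplicate
    sample ids are an error.
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    ids = [c.sample_id for c in catalogs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in catalogs")
    rows = []
    for c in catalogs:
        rows.append(
            {
                "sample_id": c.sample_id,
                "group": (groups or {}).get(c.sample_id, "all"),
                "n_eccDNA": c.n_eccDNA,
                "mean_length": c.mean_length if c.mean_length is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    test: str  # students_t | welch_t | one_way_anova
    statistic: float
    p_value: float
    fold_change: float | None  # mean(treatment) / mean(reference); 2 groups only
    reference: str | None


def compare_groups(
    table: pd.DataFrame,
    value_column: str,
    group_column: str = "group",
    reference: str | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Two groups -> unpaired two-sided t test; more -> one-way ANOVA.

    ``fold_change`` = mean(treatment)/mean(reference) for two groups; the
    reference defaults to the first group in table order.
    """
    names = list(dict.fromkeys(table[group_column]))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    values = {g: table.loc[table[group_column] == g, value_column].to_numpy(float) for g in names}
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    means = {g: float(np.mean(v)) for g, v in values.items()}
    sds = {g: float(np.std(v, ddof=1)) for g, v in values.items()}
    if len(names) == 2:
        ref = reference if reference is not None else names[0]
        if ref not in values:
            raise ValueError(f"reference group {ref!r} not present")
        treat = next(g for g in names if g != ref)
        if np.var(values[treat]) == 0 and np.var(values[ref]) == 0:
            # degenerate but permitted: identical spreads carry no noise, so
            # the statistic is 0 (equal means) or infinite (different means)
            if means[treat] == means[ref]:
                stat, p = 0.0, 1.0
            else:
                stat = np.inf * np.sign(means[treat] - means[ref])
                p = 0.0
        else:
            stat, p = stats.ttest_ind(values[treat], values[ref], equal_var=not welch)
        fold = means[treat] / means[ref] if means[ref] > 0 else None
        return GroupComparison(
            groups=names, means=means, sds=sds,
            test="welch_t" if welch else "students_t",
            statistic=float(stat), p_value=float(p),
            fold_change=fold, reference=ref,
        )
    stat, p = stats.f_oneway(*(values[g] for g in names))
    return GroupComparison(
        groups=names, means=means, sds=sds, test="one_way_anova",
        statistic=float(stat), p_value=float(p), fold_change=None, reference=None,
    )


@dataclass
class StratifiedCohort:
    labels: dict[str, str]  # sample_id -> eccDNA_high | eccDNA_low
    median: float

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.labels.values() if v == "eccDNA_high")

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.labels.values() if v == "eccDNA_low")


def stratify_high_low(table: pd.DataFrame, value_column: str) -> StratifiedCohort:
    """Median split into circle-high and circle-low groups.

    Samples strictly above the median are high, strictly below low.
    Samples exactly at the median are assigned alternately low-then-high in
    row order, each tie going to the currently smaller side (low when equal)
    so the split stays balanced within one sample.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples to stratify")
    vals = table[value_column].to_numpy(float)
    if np.ptp(vals) == 0:
        raise ValueError("degenerate split: all values identical")
    med = float(np.median(vals))
    labels: dict[str, str] = {}
    n_high = int(np.sum(vals > med))
    n_low = int(np.sum(vals < med))
    tie_next_low = True
    for sid, v in zip(table["sample_id"], vals):
        if v > med:
            labels[sid] = "eccDNA_high"
        elif v < med:
            labels[sid] = "eccDNA_low"
        else:
            # each tie goes toward the currently smaller side; at balance
            # they alternate low-then-high in row order
            if n_low < n_high or (n_low == n_high and tie_next_low):
                labels[sid] = "eccDNA_low"
                n_low += 1
                tie_next_low = False
            else:
                labels[sid] = "eccDNA_high"
                n_high += 1
                tie_next_low = True
    return StratifiedCohort(labels=labels, median=med)


def correlate(
    table: pd.DataFrame, x_column: str, y_column: str
) -> tuple[float, float, float]:
    """Pearson's r, R^2 and the two-sided p value from the t transform of r."""
    x = table[x_column].to_numpy(float)
    y = table[y_column].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance column in correlation")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def render_report(
    out_json: str,
    out_md: str,
    summaries: pd.DataFrame | None = None,
    comparisons: list[GroupComparison] | None = None,
    stratification: StratifiedCohort | None = None,
    correlations: dict[str, tuple[float, float, float]] | None = None,
) -> dict:
    """Write a machine-readable JSON + human-readable Markdown cohort report.

    Sections with no input are omitted; output is deterministic (sorted keys,
    fixed ordering) so reruns on identical inputs are byte-identical.
    """
    if summaries is None and not comparisons and stratification is None and not correlations:
        raise ValueError("at least one report section is required")
    report: dict = {}
    if summaries is not None:
        report["samples"] = summaries.to_dict(orient="records")
    if comparisons:
        report["comparisons"] = [
            {
                "groups": c.groups,
                "means": c.means,
                "sds": c.sds,
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "fold_change": c.fold_change,
                "reference": c.reference,
            }
            for c in comparisons
        ]
    if stratification is not None:
        report["stratification"] = {
            "median": stratification.median,
            "labels": dict(sorted(stratification.labels.items())),
        }
    if correlations:
        report["correlations"] = {
            k: {"pearson_r": v[0], "r_squared": v[1], "p_value": v[2]}
            for k, v in sorted(correlations.items())
        }
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["# Cohort report", ""]
    if "samples" in report:
        lines += ["## Samples", "", "| sample | group | n_eccDNA | mean length (bp) |", "|---|---|---|---|"]
        for row in report["samples"]:
            ml = row.get("mean_length")
            ml_s = "NA" if ml is None or (isinstance(ml, float) and np.isnan(ml)) else f"{ml:.1f}"
            lines.append(
                f"| {row['sample_id']} | {row['group']} | {row['n_eccDNA']} | {ml_s} |"
            )
        lines.append("")
    if "comparisons" in report:
        lines += ["## Group comparisons", ""]
        for c in report["comparisons"]:
            fc = "NA" if c["fold_change"] is None else f"{c['fold_change']:.2f}"
            lines.append(
                f"- {' vs '.join(c['groups'])} ({c['test']}): statistic={c['statistic']:.4g}, "
                f"p={c['p_value']:.3g}, fold change={fc}"
            )
        lines.append("")
    if "stratification" in report:
        s = report["stratification"]
        lines += [
            "## Median stratification",
            "",
            f"Median burden: {s['median']:.1f}",
            "",
        ]
        for sid, lab in s["labels"].items():
            lines.append(f"- {sid}: {lab}")
        lines.append("")
    if "correlations" in report:
        lines += ["## Correlations", ""]
        for k, v in report["correlations"].items():
            lines.append(
                f"- {k}: r={v['pearson_r']:.3f}, R^2={v['r_squared']:.3f}, "
                f"p={v['p_value']:.3g}"
            )
        lines.append("")
    with open(out_md, "w") as fh:
        fh.write("\n".join(lines))
    return report
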