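"""Spike-in-normalized qPCR relative expression, ddCt fold changes, t-tests.

Per-well cycle-threshold (Ct) values are averaged over technical replicates,
normalized per sample against the mean Ct of three exogenous C. elegans
spike-in references (cel-miR-39/54/238), and summarized per group as
mean +/- SEM on the log2 (Ct) scale.  The group-mean difference is the ddCt,
fold change is 2**ddCt relative to the healthy group, and significance uses
the two-tailed equal-variance Student t-test reconstructed from the summary
statistics.

Relative expression is oriented as (spike-in mean Ct - target Ct): fewer
cycles to threshold means more template, so larger values mean higher
expression and up-regulation gives positive ddCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_TARGETS = ("cel-miR-39", "cel-miR-54", "cel-miR-238")
GROUPS = ("stroke", "healthy")
CT_COLUMNS = ["sample_id", "group", "target", "replicate", "ct"]


class QpcrError(ValueError):
    """Raised for malformed Ct inputs."""


@dataclass(frozen=True)
class GroupSummary:
    target_name: str
    group: str
    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.sem < 0:
            raise QpcrError("SEM must be non-negative")
        if self.n < 2:
            raise QpcrError(
                f"group summary ({self.target_name}, {self.group}): needs n >= 2"
            )


@dataclass(frozen=True)
class ValidationResult:
    target_name: str
    ddct: float
    fold_change: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def read_ct(path) -> pd.DataFrame:
    """Read a long-format comma-separated Ct table and validate it."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"Ct table {path}: missing columns {missing}")
    return validate_ct_frame(df)


def validate_ct_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ct"] = df["ct"].astype(float)
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise QpcrError("Ct values must be finite and positive")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise QpcrError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")
    for sample, sub in df.groupby("sample_id"):
        missing_refs = set(REFERENCE_TARGETS) - set(sub["target"])
        if missing_refs:
            raise QpcrError(
                f"sample {sample!r}: missing spike-in reference(s) {sorted(missing_refs)}"
            )
    return df


def relative_expression(ct: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates and normalize to the spike-in mean per sample.

    Returns one row per (sample, non-reference target) with columns
    sample_id, group, target, rel_expr where
    rel_expr = mean(replicate-averaged spike-in Cts) - replicate-averaged target Ct.
    """
    ct = validate_ct_frame(ct)
    well = (
        ct.groupby(["sample_id", "group", "target"], as_index=False)["ct"].mean()
    )
    refs = well[well["target"].isin(REFERENCE_TARGETS)]
    ref_mean = refs.groupby("sample_id")["ct"].mean()
    targets = well[~well["target"].isin(REFERENCE_TARGETS)].copy()
    targets["rel_expr"] = targets["sample_id"].map(ref_mean) - targets["ct"]
    return targets[["sample_id", "group", "target", "rel_expr"]].reset_index(drop=True)


def group_summary(rel: pd.DataFrame) -> list[GroupSummary]:
    """Per-(target, group) mean, SEM (sd/sqrt(n), sd with n-1 denominator), n."""
    out = []
    for (target, group), sub in rel.groupby(["target", "group"], sort=True):
        n = len(sub)
        if n < 2:
            raise QpcrError(f"group ({target}, {group}) has a single sample")
        vals = sub["rel_expr"].to_numpy(dtype=float)
        out.append(GroupSummary(
            target_name=target, group=group,
            mean=float(vals.mean()),
            sem=float(vals.std(ddof=1) / math.sqrt(n)),
            n=n,
        ))
    return out


def fold_change(case: GroupSummary, control: GroupSummary) -> tuple[float, float]:
    """ddCt = case mean - control mean; fold change = 2**ddCt."""
    if case.target_name != control.target_name:
        raise QpcrError(
            f"fold change across different targets: {case.target_name} vs {control.target_name}"
        )
    ddct = case.mean - control.mean
    return ddct, 2.0 ** ddct


def t_test_from_summary(case: GroupSummary, control: GroupSummary):
    """Equal-variance two-sample Student t-test from summary statistics.

    Group standard deviations are recovered as sem * sqrt(n); df = n1 + n2 - 2.
    A zero pooled variance is degenerate: p = 1 for equal means, p = 0
    (flagged) for unequal means.
    """
    if case.target_name != control.target_name:
        raise QpcrError("t-test across different targets")
    sd1 = case.sem * math.sqrt(case.n)
    sd2 = control.sem * math.sqrt(control.n)
    df = case.n + control.n - 2
    if sd1 == 0.0 and sd2 == 0.0:
        if case.mean == control.mean:
            return 0.0, df, 1.0, False
        return math.inf if case.mean > control.mean else -math.inf, df, 0.0, True
    t, p = stats.ttest_ind_from_stats(
        case.mean, sd1, case.n, control.mean, sd2, control.n, equal_var=True
    )
    return float(t), df, float(p), False


def validate_targets(summaries: list[GroupSummary]) -> list[ValidationResult]:
    """Pair stroke/healthy summaries per target and compute ddCt, fold change, t, p."""
    by_target: dict[str, dict[str, GroupSummary]] = {}
    for s in summaries:
        by_target.setdefault(s.target_name, {})[s.group] = s
    results = []
    for target in sorted(by_target):
        pair = by_target[target]
        if set(pair) != set(GROUPS):
            raise QpcrError(f"target {target!r}: needs both stroke and healthy summaries")
        case, control = pair["stroke"], pair["healthy"]
        ddct, fc = fold_change(case, control)
        t, df, p, degenerate = t_test_from_summary(case, control)
        results.append(ValidationResult(target, ddct, fc, t, df, p, degenerate))
    return results


def validate_ct(ct: pd.DataFrame) -> list[ValidationResult]:
    """Full validation pipeline from a raw long-format Ct table."""
    return validate_targets(group_summary(relative_expression(ct)))


def read_summaries(path) -> list[GroupSummary]:
    """Read a (target, group, mean, sem, n) tab-separated summary table."""
    df = pd.read_csv(path, sep="\t")
    return [
        GroupSummary(r["target"], r["group"], float(r["mean"]), float(r["sem"]), int(r["n"]))
        for _, r in df.iterrows()
    ]


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "target": s.target_name, "group": s.group,
        "mean": s.mean, "sem": s.sem, "n": s.n,
    } for s in summaries])


def results_frame(results: list[ValidationResult],
                  summaries: list[GroupSummary] | None = None) -> pd.DataFrame:
    """Validation table mirroring the mean +/- SEM / ddCt / fold-change layout."""
    rows = []
    by_key = {}
    if summaries:
        by_key = {(s.target_name, s.group): s for s in summaries}
    for r in results:
        row = {"target": r.target_name}
        for group, label in (("stroke", "stroke"), ("healthy", "healthy")):
            s = by_key.get((r.target_name, group))
            if s is not None:
                row[f"{label}_mean"] = s.mean
                row[f"{label}_sem"] = s.sem
                row[f"{label}_n"] = s.n
        row.update({
            "ddct": r.ddct, "fold_change": r.fold_change,
            "t": r.t, "df": r.df, "p": r.p,
        })
        rows.append(row)
    return pd.DataFrame(rows)
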