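"""Event-count (vote-counting) random-effects meta-analysis of up/down calls.

Each study's qualitative call for a miRNA is encoded as a 2x2 event table: all
cases are counted as events in the reported direction and all controls as
events in the opposite direction (controls are, by construction of the
case-control designs, non-dysregulated).  The log odds ratio of that table,
with a 0.5 continuity correction applied to every cell of any zero-containing
table and the Woolf variance 1/a + 1/b + 1/c + 1/d, is then pooled across the
studies of a qualified group with an inverse-variance random-effects model.

Between-study variance tau^2 is estimated by DerSimonian-Laird by default;
restricted maximum likelihood (REML, the default of the standard R
meta-analysis package) is available as an option and differs from DL only
when k > 2 studies disagree.  Confidence intervals and p-values use the Wald
normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import QualifiedGroup

Z975 = float(stats.norm.ppf(0.975))  # 1.959964...

TAU2_METHODS = ("dl", "reml")


@dataclass(frozen=True)
class ContingencyTable:
    """Up/down event table; a,c = up events, b,d = down events (case, control)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectSize:
    """Per-study effect on the natural-log odds-ratio scale with its variance."""

    log_or: float
    variance: float

    def __post_init__(self):
        if not (math.isfinite(self.log_or) and math.isfinite(self.variance)):
            raise ValueError("effect size must be finite")
        if self.variance <= 0:
            raise ValueError("effect variance must be positive")


@dataclass(frozen=True)
class HeterogeneityEstimate:
    q: float
    tau2: float
    i2: float
    df: int
    method: str = "dl"


@dataclass(frozen=True)
class MetaResult:
    canonical_name: str
    specimen: str
    pooled_log_or: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    heterogeneity: HeterogeneityEstimate
    weights: tuple[float, ...]
    study_ids: tuple[str, ...] = ()
    effects: tuple[EffectSize, ...] = ()
    alpha: float = 0.05

    @property
    def direction(self) -> str:
        return "up" if self.pooled_log_or > 0 else "down"

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def build_contingency(direction: str, n_case: int, n_control: int) -> ContingencyTable:
    """Encode a study's up/down call as an event table.

    'up': all cases are up-events, all controls down-events -> (n1, 0, 0, n0).
    'down': the transpose orientation -> (0, n1, n0, 0).
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    if direction == "up":
        return ContingencyTable(n_case, 0, 0, n_control)
    if direction == "down":
        return ContingencyTable(0, n_case, n_control, 0)
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def continuity_correct(table: ContingencyTable, amount: float = 0.5) -> ContingencyTable:
    """Add ``amount`` to all four cells if (and only if) any cell is zero.

    The all-cells dialect, rather than zero-cells-only, is what standard
    meta-analysis software applies and is required for the odds-ratio variance
    to be the Woolf sum over the corrected cells.
    """
    if amount <= 0:
        raise ValueError("continuity amount must be positive")
    if min(table.cells()) > 0:
        return table
    a, b, c, d = table.cells()
    return ContingencyTable(a + amount, b + amount, c + amount, d + amount)


def log_odds_ratio(table: ContingencyTable) -> EffectSize:
    """ln(ad/bc) with Woolf variance 1/a + 1/b + 1/c + 1/d."""
    a, b, c, d = table.cells()
    if min(a, b, c, d) <= 0:
        raise ValueError("all cells must be positive; apply continuity correction first")
    return EffectSize(
        log_or=math.log(a * d / (b * c)),
        variance=1 / a + 1 / b + 1 / c + 1 / d,
    )


def _arrays(effects: list[EffectSize] | tuple[EffectSize, ...]):
    theta = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return theta, v


def dersimonian_laird(effects) -> HeterogeneityEstimate:
    """Method-of-moments heterogeneity from Cochran's Q.

    Q = sum u_i (theta_i - theta_fixed)^2 with fixed weights u_i = 1/v_i;
    tau2 = max(0, (Q - df) / C) with C = sum(u) - sum(u^2)/sum(u);
    I2 = max(0, (Q - df)/Q) * 100.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity estimation needs >= 2 effects")
    theta, v = _arrays(effects)
    u = 1.0 / v
    theta_fixed = float(np.sum(u * theta) / np.sum(u))
    q = float(np.sum(u * (theta - theta_fixed) ** 2))
    df = len(effects) - 1
    c = float(np.sum(u) - np.sum(u**2) / np.sum(u))
    tau2 = max(0.0, (q - df) / c)
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityEstimate(q=q, tau2=tau2, i2=i2, df=df, method="dl")


def _i2_from_tau2(tau2: float, v: np.ndarray) -> float:
    """Generalized I2 = 100 * tau2 / (tau2 + s2) with the typical within-study
    variance s2 = df / C.  For the DL estimator this reduces algebraically to
    the familiar 100 * (Q - df) / Q."""
    u = 1.0 / v
    c = float(np.sum(u) - np.sum(u**2) / np.sum(u))
    s2 = (len(v) - 1) / c
    return 100.0 * tau2 / (tau2 + s2) if tau2 > 0 else 0.0


def reml_tau2(effects, tol: float = 1e-10, max_iter: int = 200) -> HeterogeneityEstimate:
    """Restricted maximum-likelihood tau^2 via the standard fixed-point iteration.

    Q and df come from the fixed-weight Cochran decomposition; I2 uses the
    generalized tau2 / (tau2 + s2) form so it is consistent with the estimate.
    """
    base = dersimonian_laird(effects)
    theta, v = _arrays(effects)
    tau2 = base.tau2
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * theta) / np.sum(w))
        num = float(np.sum(w**2 * ((theta - mu) ** 2 - v)))
        new = max(0.0, num / float(np.sum(w**2)) + 1.0 / float(np.sum(w)))
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    return HeterogeneityEstimate(q=base.q, tau2=tau2, i2=_i2_from_tau2(tau2, v),
                                 df=base.df, method="reml")


def estimate_tau2(effects, method: str = "dl") -> HeterogeneityEstimate:
    if method not in TAU2_METHODS:
        raise ValueError(f"tau2 method must be one of {TAU2_METHODS}, got {method!r}")
    return dersimonian_laird(effects) if method == "dl" else reml_tau2(effects)


def pool_random_effects(
    effects,
    tau2: float,
    canonical_name: str = "",
    specimen: str = "",
    study_ids: tuple[str, ...] = (),
    heterogeneity: HeterogeneityEstimate | None = None,
    alpha: float = 0.05,
) -> MetaResult:
    """Inverse-variance pooling with random-effects weights w_i = 1/(v_i + tau2).

    Wald CI at the 97.5% normal quantile; two-sided normal p-value; reported
    weights normalized to sum to one.
    """
    if len(effects) < 2:
        raise ValueError("pooling needs >= 2 effects")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    theta, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if heterogeneity is None:
        heterogeneity = HeterogeneityEstimate(q=float("nan"), tau2=tau2, i2=float("nan"),
                                              df=len(effects) - 1)
    return MetaResult(
        canonical_name=canonical_name,
        specimen=specimen,
        pooled_log_or=pooled,
        se=se,
        ci_low=pooled - Z975 * se,
        ci_high=pooled + Z975 * se,
        p=max(p, np.finfo(float).tiny),
        heterogeneity=heterogeneity,
        weights=tuple(float(x) for x in w / np.sum(w)),
        study_ids=tuple(study_ids),
        effects=tuple(effects),
        alpha=alpha,
    )


def run_meta(
    group: QualifiedGroup,
    continuity: float = 0.5,
    tau2_method: str = "dl",
    alpha: float = 0.05,
) -> MetaResult:
    """Full per-group pipeline: event tables -> continuity correction ->
    log odds ratios -> heterogeneity -> random-effects pooling."""
    effects = []
    for study, report in group.members:
        table = build_contingency(report.direction, study.n_case, study.n_control)
        table = continuity_correct(table, amount=continuity)
        effects.append(log_odds_ratio(table))
    het = estimate_tau2(effects, method=tau2_method)
    return pool_random_effects(
        effects,
        het.tau2,
        canonical_name=group.canonical_name,
        specimen=group.specimen,
        study_ids=tuple(s.study_id for s, _ in group.members),
        heterogeneity=het,
        alpha=alpha,
    )


def run_all(groups, continuity: float = 0.5, tau2_method: str = "dl",
            alpha: float = 0.05) -> list[MetaResult]:
    return [run_meta(g, continuity, tau2_method, alpha) for g in groups]


def results_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Machine-readable results table, one row per qualified group."""
    rows = []
    for r in results:
        rows.append({
            "mirna": r.canonical_name,
            "specimen": r.specimen,
            "studies": ";".join(r.study_ids),
            "k": len(r.study_ids),
            "tau2": r.heterogeneity.tau2,
            "i2": r.heterogeneity.i2,
            "q": r.heterogeneity.q,
            "weights": ";".join(f"{100 * w:.2f}%" for w in r.weights),
            "p": r.p,
            "log_or": r.pooled_log_or,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "direction": r.direction,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)


def format_report(results: list[MetaResult]) -> pd.DataFrame:
    """Report-style rounding: logOR/CI/tau2/I2/weights to 2 dp, p to 3 sig figs."""
    df = results_frame(results)
    out = pd.DataFrame({
        "miRNA": df["mirna"],
        "Study": df["studies"],
        "Specimen": df["specimen"],
        "tau2": df["tau2"].round(2),
        "I2": df["i2"].map(lambda x: f"{x:.2f}%"),
        "Weight": df["weights"],
        "P-value": df["p"].map(lambda x: f"{x:.2E}"),
        "LogOR": df["log_or"].round(2),
        "95% CI": [f"[{lo:.2f}, {hi:.2f}]" for lo, hi in zip(df["ci_low"], df["ci_high"])],
    })
    return out


def forest_frame(result: MetaResult) -> pd.DataFrame:
    """Per-study forest-plot data (theta_i, v_i, normalized w_i) for one group."""
    return pd.DataFrame({
        "study_id": result.study_ids,
        "log_or": [e.log_or for e in result.effects],
        "variance": [e.variance for e in result.effects],
        "weight": result.weights,
    })
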