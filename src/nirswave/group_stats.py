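"""Group-level statistics: assumption checks and state comparisons.

Within each impairment group (severe / moderate / mild, from the manual
muscle test) the resting and motor-training states are compared metric
by metric — regional wavelet amplitude (WA), lateralization index (LI)
and pairwise wavelet phase coherence (WPCO) — with a one-way ANOVA, the
rest/training factor treated as independent groups.  Normality
(Kolmogorov–Smirnov against a fitted normal) and homogeneity of
variance (Levene) are reported as advisory checks; they do not gate the
comparisons.  Significance uses a Bonferroni-adjusted threshold,
α/m with α = 0.05 over the m = 3 metric families, reported as 0.0167.

A paired alternative (one-way ANOVA on within-subject state
differences, equivalent to a paired t-test) is available behind the
``paired`` flag for users whose design warrants it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError

GROUPS = ("severe", "moderate", "mild")
ALPHA_DEFAULT = 0.05
N_METRIC_FAMILIES = 3


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA: (F, p) for two or more groups."""
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise DomainError("each group needs at least two values")
    pooled_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if pooled_within == 0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def ks_normality(values: Sequence[float]) -> tuple[float, float] | None:
    """One-sample KS statistic against a normal fitted to the sample.

    Returns ``None`` (inapplicable) for constant input.  Advisory only.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise DomainError("need at least 5 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def levene(*groups: Sequence[float]) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (mean-centered variant)."""
    if len(groups) < 2:
        raise DomainError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise DomainError("each group needs at least two values")
    if all(np.ptp(np.abs(a - a.mean())) == 0 for a in arrays) and all(
        np.abs(a - a.mean()).sum() == 0 for a in arrays
    ):
        raise DegenerateDataError("all deviations zero; Levene undefined")
    stat, p = stats.levene(*arrays, center="mean")
    return float(stat), float(p)


def bonferroni_threshold(
    alpha: float = ALPHA_DEFAULT, m: int = N_METRIC_FAMILIES
) -> tuple[float, float]:
    """Adjusted per-comparison threshold α/m.

    Returns ``(reported, raw)``: the reported value is rounded to four
    decimals (0.05/3 → 0.0167); the raw quotient is what comparisons use
    internally.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    if m < 1:
        raise DomainError("m must be >= 1")
    raw = alpha / m
    return round(raw, 4), raw


@dataclass(frozen=True)
class ComparisonResult:
    metric: str          # "WA", "LI" or "WPCO"
    group: str
    unit: str            # region label or "A-B" region pair
    chromophore: str
    f: float | None
    p: float | None
    significant: bool | None
    n_rest: int
    n_training: int
    skipped_reason: str = ""
    ks_p_rest: float | None = None
    ks_p_training: float | None = None
    levene_p: float | None = None


def _paired_f(rest: np.ndarray, training: np.ndarray) -> tuple[float, float]:
    diff = training - rest
    if diff.size < 2 or diff.std(ddof=1) == 0:
        raise DegenerateDataError("paired differences degenerate")
    t, p = stats.ttest_1samp(diff, 0.0)
    return float(t**2), float(p)


def compare_states(
    metrics: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    m: int = N_METRIC_FAMILIES,
    paired: bool = False,
    rest_label: str = "rest",
    training_label: str = "training",
) -> pd.DataFrame:
    """Rest-vs-training comparisons for every (group, metric, unit).

    ``metrics`` is long-form with columns ``subject, group, state,
    metric, unit, chromophore, value`` (``unit`` is a region or a
    region-pair label).  One ANOVA is run per (group × metric × unit ×
    chromophore); all comparisons are emitted, flagged at the adjusted
    α/m threshold.  Groups with fewer than two subjects per state are
    skipped with a reason.  Deterministic: no randomness is involved.
    """
    required = {"subject", "group", "state", "metric", "unit", "chromophore", "value"}
    if not required.issubset(metrics.columns):
        raise DomainError(f"metrics table missing columns {required - set(metrics.columns)}")
    _, threshold = bonferroni_threshold(alpha, m)
    rows: list[ComparisonResult] = []
    keys = ["group", "metric", "unit", "chromophore"]
    for (group, metric, unit, chrom), sub in metrics.groupby(keys, sort=True):
        sub = sub.dropna(subset=["value"])
        rest = sub.loc[sub["state"] == rest_label]
        train = sub.loc[sub["state"] == training_label]
        base = dict(metric=metric, group=group, unit=unit, chromophore=chrom,
                    n_rest=len(rest), n_training=len(train))
        if len(rest) < 2 or len(train) < 2:
            rows.append(ComparisonResult(
                **base, f=None, p=None, significant=None,
                skipped_reason="fewer than 2 subjects per state",
            ))
            continue
        r_vals = rest["value"].to_numpy(dtype=float)
        t_vals = train["value"].to_numpy(dtype=float)
        try:
            if paired:
                merged = rest.merge(train, on="subject", suffixes=("_r", "_t"))
                f, p = _paired_f(
                    merged["value_r"].to_numpy(float),
                    merged["value_t"].to_numpy(float),
                )
            else:
                f, p = anova_oneway(r_vals, t_vals)
        except DegenerateDataError as exc:
            rows.append(ComparisonResult(
                **base, f=None, p=None, significant=None,
                skipped_reason=str(exc),
            ))
            continue
        ks_r = ks_normality(r_vals) if len(r_vals) >= 5 else None
        ks_t = ks_normality(t_vals) if len(t_vals) >= 5 else None
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                lev_p = levene(r_vals, t_vals)[1]
            if not np.isfinite(lev_p):
                lev_p = None
        except DegenerateDataError:
            lev_p = None
        rows.append(ComparisonResult(
            **base, f=f, p=p, significant=bool(p < threshold),
            ks_p_rest=None if ks_r is None else ks_r[1],
            ks_p_training=None if ks_t is None else ks_t[1],
            levene_p=lev_p,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
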