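"""Two-group comparison engine: t-tests, F variance test, eta-squared, CIs.

Every pairwise contrast in the package (cytokine RQ, surface-marker MFI,
per-cell GP) goes through :func:`compare_groups`, which accepts either raw
replicate values or ``(n, mean, sd)`` summaries so that comparisons can be
reproduced from published summary statistics without raw data.

Conventions
-----------
- ``mean_diff`` is ``mean(b) - mean(a)``.
- Two-tailed p values throughout; no multiple-testing correction.
- Effect size is eta-squared for a two-group contrast, computed via the
  point-biserial identity ``r2 = t**2 / (t**2 + df)``.
- The F test reports ``F = larger variance / smaller variance`` with a
  two-tailed p (doubled upper tail, capped at 1), so F >= 1 always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "ComparisonResult",
    "group_stats",
    "compare_groups",
    "effect_size_r2",
    "variance_f_test",
    "t_from_diff_sem",
    "ci_bounds",
]

VarianceModel = Literal["pooled", "welch", "auto"]


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group of replicate measurements."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValueError(f"group {self.label!r}: non-finite mean")
        if not (self.sd >= 0):
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")

    @property
    def var(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class ComparisonResult:
    """Full output of an unpaired two-group comparison (b minus a)."""

    group_a: str
    group_b: str
    mean_diff: float
    sem_diff: float
    t_stat: float
    df: float
    p_two_tailed: float
    ci_low: float
    ci_high: float
    r_squared: float
    f_stat: float
    f_p: float
    variance_model: str

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_tailed < alpha


GroupLike = Union[GroupStats, Sequence[float], np.ndarray]


def group_stats(values: Sequence[float] | np.ndarray, label: str = "group") -> GroupStats:
    """Summarize raw replicate values (ddof=1 sd)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("raw values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"group {label!r}: non-finite values")
    return GroupStats(label=label, n=int(x.size), mean=float(x.mean()),
                      sd=float(x.std(ddof=1)) if x.size > 1 else 0.0)


def _coerce(g: GroupLike, fallback_label: str) -> GroupStats:
    if isinstance(g, GroupStats):
        return g
    return group_stats(g, label=fallback_label)


def effect_size_r2(t_stat: float, df: float) -> float:
    """Eta-squared of a two-group contrast from its t statistic.

    Uses the point-biserial identity r2 = t^2 / (t^2 + df): the fraction of
    total variance explained by group membership. Zero iff t = 0, strictly
    increasing in |t|, and always in [0, 1).
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    t2 = float(t_stat) ** 2
    return t2 / (t2 + float(df))


def t_from_diff_sem(mean_diff: float, sem_diff: float) -> float:
    """t statistic implied by a mean difference and its standard error."""
    if sem_diff <= 0:
        raise ValueError("sem must be positive")
    return float(mean_diff) / float(sem_diff)


def ci_bounds(mean_diff: float, sem_diff: float, df: float,
              confidence: float = 0.95) -> tuple[float, float]:
    """Equal-tailed confidence interval for a mean difference."""
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    tcrit = float(sps.t.ppf(0.5 + confidence / 2, df))
    half = tcrit * float(sem_diff)
    return float(mean_diff) - half, float(mean_diff) + half


def variance_f_test(a: GroupLike, b: GroupLike) -> tuple[float, float]:
    """F test of variance equality; symmetric in the group order.

    F = larger sample variance / smaller sample variance, numerator df taken
    from the larger-variance group; p is the doubled upper tail, capped at 1.
    """
    ga, gb = _coerce(a, "a"), _coerce(b, "b")
    va, vb = ga.var, gb.var
    if va == 0 or vb == 0:
        raise ValueError("F test undefined: a group has zero variance")
    if va >= vb:
        f, dfn, dfd = va / vb, ga.n - 1, gb.n - 1
    else:
        f, dfn, dfd = vb / va, gb.n - 1, ga.n - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return float(f), p


def compare_groups(
    a: GroupLike,
    b: GroupLike,
    variance_model: VarianceModel = "auto",
    confidence: float = 0.95,
    f_alpha: float = 0.05,
) -> ComparisonResult:
    """Unpaired two-tailed comparison of two groups (difference = b - a).

    Parameters
    ----------
    a, b
        Raw replicate values or :class:`GroupStats` summaries.
    variance_model
        ``"pooled"`` assumes equal variances (df = n_a + n_b - 2);
        ``"welch"`` uses the Welch-Satterthwaite approximation;
        ``"auto"`` (default) runs the F test first and picks pooled when its
        p >= ``f_alpha``, Welch otherwise.
    confidence
        Coverage of the reported CI for the mean difference.
    """
    ga, gb = _coerce(a, "a"), _coerce(b, "b")
    if ga.sd == 0 and gb.sd == 0:
        raise ValueError("degenerate data: both groups have zero variance")

    f_stat, f_p = (math.nan, math.nan)
    try:
        f_stat, f_p = variance_f_test(ga, gb)
    except ValueError:
        pass  # one zero-variance group: t test still defined, F is not

    model = variance_model
    if model == "auto":
        model = "pooled" if (math.isnan(f_p) or f_p >= f_alpha) else "welch"
    if model not in ("pooled", "welch"):
        raise ValueError(f"unknown variance model {variance_model!r}")

    mean_diff = gb.mean - ga.mean
    if model == "pooled":
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * ga.var + (gb.n - 1) * gb.var) / df
        sem = math.sqrt(sp2 * (1 / ga.n + 1 / gb.n))
    else:
        ta, tb = ga.var / ga.n, gb.var / gb.n
        sem = math.sqrt(ta + tb)
        df = (ta + tb) ** 2 / (ta**2 / (ga.n - 1) + tb**2 / (gb.n - 1))

    t_stat = mean_diff / sem
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    lo, hi = ci_bounds(mean_diff, sem, df, confidence)
    return ComparisonResult(
        group_a=ga.label,
        group_b=gb.label,
        mean_diff=mean_diff,
        sem_diff=sem,
        t_stat=t_stat,
        df=float(df),
        p_two_tailed=p,
        ci_low=lo,
        ci_high=hi,
        r_squared=effect_size_r2(t_stat, df),
        f_stat=f_stat,
        f_p=f_p,
        variance_model=model,
    )
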