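"""Group-level summaries and Student's t-test on RP indexes.

Acini are treated as independent units; per-condition (or per visual
category) means of the RP index and of the radial profile are reported,
and pairs of groups are compared with the classical pooled-variance
two-sample t-test (Welch's correction available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .profiling import RPResult

__all__ = ["GroupSummary", "TTestResult", "summarize_groups", "t_test"]


@dataclass
class GroupSummary:
    """Per-group RP-index statistics plus the group-mean radial profile."""

    group: str
    n_acini: int
    mean_rp: float
    sd_rp: float
    sem_rp: float
    mean_profile: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def summarize_groups(results: list[RPResult], by: str = "condition") -> list[GroupSummary]:
    """Summarize RP indexes per group (``by`` = attribute of RPResult).

    Groups are returned in sorted label order; sd is the sample standard
    deviation (ddof=1; 0 for singleton groups, which are flagged with a
    warning).
    """
    groups: dict[str, list[RPResult]] = {}
    for res in results:
        groups.setdefault(str(getattr(res, by)), []).append(res)
    summaries = []
    for label in sorted(groups):
        members = groups[label]
        values = np.array([m.rp_index for m in members], dtype=np.float64)
        n = len(values)
        if n == 1:
            warnings.warn(f"group {label!r} has a single acinus; sd reported as 0", stacklevel=2)
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        profiles = np.array([m.profile.rp for m in members])
        summaries.append(
            GroupSummary(
                group=label,
                n_acini=n,
                mean_rp=float(values.mean()),
                sd_rp=sd,
                sem_rp=sd / np.sqrt(n) if n > 0 else 0.0,
                mean_profile=profiles.mean(axis=0),
            )
        )
    return summaries


def t_test(
    a: np.ndarray,
    b: np.ndarray,
    group_a: str = "a",
    group_b: str = "b",
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test on RP-index samples (two-sided).

    The default is the classical pooled-variance Student statistic with
    ``len(a) + len(b) - 2`` degrees of freedom; ``welch=True`` uses the
    unequal-variance form with Satterthwaite df.  Degenerate inputs are
    well-defined: two identical constant samples give t = 0, p = 1, and
    zero pooled variance with different means gives p = 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate(ma, mb, float(na + nb - 2), group_a, group_b)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / np.sqrt(se2)
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = pooled * (1.0 / na + 1.0 / nb)
        if se2 == 0:
            return _degenerate(ma, mb, df, group_a, group_b)
        t = (ma - mb) / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)), group_a=group_a, group_b=group_b)


def _degenerate(ma: float, mb: float, df: float, ga: str, gb: str) -> TTestResult:
    if ma == mb:
        return TTestResult(t=0.0, df=df, p=1.0, group_a=ga, group_b=gb)
    t = np.inf if ma > mb else -np.inf
    return TTestResult(t=float(t), df=df, p=0.0, group_a=ga, group_b=gb)
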