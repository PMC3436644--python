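"""Group inference for hierarchically sampled measurements.

Measurements in this pipeline come from a nested design: animals
("cases") are sampled within treatment groups, and sections / neurons /
frames are sampled within cases. Observations within one case are not
independent, so the group effect must be tested against the
between-case variation, not the residual. The nested-design ANOVA does
exactly that:

    F = MS_group / MS_case(group),   df = (g − 1, Σ cases − g)

with cases treated as a random factor nested in the fixed group factor.
With two balanced groups this F equals the square of the pooled
two-sample t statistic computed on the case means, which is why the
printed F values of a balanced study are recoverable from case-level
means and SDs alone (see :func:`sample_with_moments`).

The module also provides the Mann–Whitney U test (exact by full
enumeration for small samples, tie-corrected normal approximation
otherwise) and mean/SD/SEM summaries. All p-values are two-sided; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Largest pooled sample size for which the Mann–Whitney p-value is
#: computed by full enumeration of group labelings.
EXACT_ENUMERATION_MAX_N = 12


class DesignError(ValueError):
    """Invalid or unbalanced nested design."""


@dataclass(frozen=True)
class NestedDesignData:
    """Measurements organised as group → case → values."""

    groups: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, np.ndarray]] = {}
        for g, cases in self.groups.items():
            if len(cases) < 2:
                raise DesignError(f"group {g!r} needs >= 2 cases")
            clean[g] = {}
            for c, vals in cases.items():
                arr = np.asarray(vals, dtype=float).ravel()
                if arr.size < 1:
                    raise DesignError(f"case {c!r} has no measurements")
                clean[g][c] = arr
        object.__setattr__(self, "groups", clean)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_cases(self) -> int:
        return sum(len(c) for c in self.groups.values())

    @property
    def balanced(self) -> bool:
        case_counts = {len(c) for c in self.groups.values()}
        sizes = {v.size for c in self.groups.values() for v in c.values()}
        return len(case_counts) == 1 and len(sizes) == 1

    def case_means(self) -> dict[str, np.ndarray]:
        return {
            g: np.array([v.mean() for v in cases.values()])
            for g, cases in self.groups.items()
        }

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        value: str,
        group: str = "group",
        case: str = "case",
    ) -> "NestedDesignData":
        groups: dict[str, dict[str, np.ndarray]] = {}
        for (g, c), sub in df.groupby([group, case], sort=True):
            groups.setdefault(str(g), {})[str(c)] = sub[value].to_numpy(float)
        return cls(groups)

    @classmethod
    def from_case_values(
        cls, case_values: Mapping[str, Sequence[float]]
    ) -> "NestedDesignData":
        """Case-summary mode: one value per case (e.g. a case mean)."""
        return cls(
            {
                g: {f"{g}_{i}": np.array([v]) for i, v in enumerate(vals)}
                for g, vals in case_values.items()
            }
        )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ms_group: float
    ms_case: float


def _nested_sums(data: NestedDesignData):
    all_vals = np.concatenate(
        [v for cases in data.groups.values() for v in cases.values()]
    )
    grand = all_vals.mean()
    ss_group = 0.0
    ss_case = 0.0
    for cases in data.groups.values():
        g_all = np.concatenate(list(cases.values()))
        g_mean = g_all.mean()
        ss_group += g_all.size * (g_mean - grand) ** 2
        for v in cases.values():
            ss_case += v.size * (v.mean() - g_mean) ** 2
    return ss_group, ss_case


def nested_anova(data: NestedDesignData, strict: bool = True) -> AnovaResult:
    """Group effect of a nested design, tested against case-within-group.

    ``strict`` (default) rejects unbalanced designs, where the simple
    mean-square ratio is not an exact F test. The degenerate case of
    zero between-case variance has an undefined F and raises.
    """
    if strict and not data.balanced:
        raise DesignError("unbalanced design (pass strict=False to override)")
    g = data.n_groups
    n_cases = data.n_cases
    df_num = g - 1
    df_den = n_cases - g
    if df_den < 1:
        raise DesignError("need more cases than groups")
    ss_group, ss_case = _nested_sums(data)
    ms_group = ss_group / df_num
    ms_case = ss_case / df_den
    if ms_case == 0:
        raise DesignError("zero case-level variance: F undefined")
    F = ms_group / ms_case
    return AnovaResult(
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        p=float(sps.f.sf(F, df_num, df_den)),
        ms_group=float(ms_group),
        ms_case=float(ms_case),
    )


def nested_anova_oracle(data: NestedDesignData, strict: bool = True) -> AnovaResult:
    """First-principles re-computation of :func:`nested_anova`.

    Sums of squares are accumulated with explicit Python loops over
    individual observations — no shortcut identities, no vectorised
    grouping — so the two routes are independent implementations of the
    same definition.
    """
    if strict and not data.balanced:
        raise DesignError("unbalanced design (pass strict=False to override)")
    values = []
    for cases in data.groups.values():
        for v in cases.values():
            values.extend(float(x) for x in v)
    grand = sum(values) / len(values)

    ss_group = 0.0
    ss_case = 0.0
    n_cases = 0
    for cases in data.groups.values():
        g_vals = [float(x) for v in cases.values() for x in v]
        g_mean = sum(g_vals) / len(g_vals)
        ss_group += len(g_vals) * (g_mean - grand) ** 2
        for v in cases.values():
            c_vals = [float(x) for x in v]
            c_mean = sum(c_vals) / len(c_vals)
            ss_case += len(c_vals) * (c_mean - g_mean) ** 2
            n_cases += 1
    g = data.n_groups
    df_num = g - 1
    df_den = n_cases - g
    ms_group = ss_group / df_num
    ms_case = ss_case / df_den
    if ms_case == 0:
        raise DesignError("zero case-level variance: F undefined")
    F = ms_group / ms_case
    return AnovaResult(
        F=F,
        df_num=df_num,
        df_den=df_den,
        p=float(sps.f.sf(F, df_num, df_den)),
        ms_group=ms_group,
        ms_case=ms_case,
    )


def sample_with_moments(mean: float, sd: float, n: int = 4) -> np.ndarray:
    """A sample of ``n`` values with exactly the given mean and sample SD.

    Any such sample yields the same nested-design F, since the balanced
    two-group statistic depends on case values only through their first
    two moments; this makes printed case-level summaries (mean ± SD)
    sufficient inputs for re-computing F.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    z = np.arange(n, dtype=float) - (n - 1) / 2
    z /= z.std(ddof=1)
    return mean + sd * z


def nested_anova_from_moments(
    group_moments: Mapping[str, tuple[float, float]], n_cases: int = 4
) -> AnovaResult:
    """Nested-design F from per-group case-level (mean, sample SD)."""
    return nested_anova(
        NestedDesignData.from_case_values(
            {
                g: sample_with_moments(m, s, n_cases)
                for g, (m, s) in group_moments.items()
            }
        )
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    exact: bool


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a, b) pairs with a > b, ties counting ½."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    For pooled sample sizes up to ``EXACT_ENUMERATION_MAX_N`` the
    p-value is exact: every assignment of the pooled values to the two
    groups is enumerated and labelings with |U − n_a n_b / 2| at least
    as large as observed are counted. Larger samples use the normal
    approximation with midrank tie correction and continuity correction.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    U = _u_statistic(a, b)
    mu = n_a * n_b / 2

    if n_a + n_b <= EXACT_ENUMERATION_MAX_N:
        pooled = np.concatenate([a, b])
        n = n_a + n_b
        obs_dev = abs(U - mu)
        hits = 0
        total = 0
        for idx_a in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return MannWhitneyResult(U=U, p_two_sided=hits / total, exact=True)

    pooled = np.concatenate([a, b])
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=U, p_two_sided=1.0, exact=False)
    z = (abs(U - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2 * sps.norm.sf(z)
    return MannWhitneyResult(U=U, p_two_sided=float(min(p, 1.0)), exact=False)


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    sem: float
    n: int


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD (n − 1) and SEM of one group of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    mean = float(arr.mean())
    if arr.size < 2:
        return GroupSummary(mean=mean, sd=float("nan"), sem=float("nan"), n=1)
    sd = float(arr.std(ddof=1))
    return GroupSummary(mean=mean, sd=sd, sem=sd / math.sqrt(arr.size), n=int(arr.size))
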