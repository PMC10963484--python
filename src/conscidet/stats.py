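"""Statistical machinery: paired t-tests with Cohen's dz, one-way ANOVA
with η² and Bonferroni post-hocs, and a-priori power / sample-size
computation from the noncentral t and F distributions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_name: str                  # {"dz", "eta_squared"}
    label: str = ""


@dataclass(frozen=True)
class PowerSpec:
    test: str                          # {paired_t_two_tailed, oneway_anova}
    effect_size: float                 # dz (paired t) or f (ANOVA)
    alpha: float = 0.05
    power: float = 0.8
    n_groups: int = 3                  # ANOVA only

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.test not in ("paired_t_two_tailed", "oneway_anova"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.test == "oneway_anova" and self.n_groups < 2:
            raise ValueError("ANOVA needs at least 2 groups")


def paired_t(x, y, label: str = "") -> TestResult:
    """Two-tailed paired t-test with Cohen's dz = mean(d)/sd(d).

    Identical inputs return t = 0, p = 1 (no difference to test); a
    non-zero constant difference has zero variance and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, (float(len(d) - 1),), 1.0, 0.0, "dz", label)
        raise ValueError("differences have zero variance but non-zero mean")
    t, p = sps.ttest_rel(x, y)
    dz = float(d.mean() / sd)
    return TestResult(float(t), (float(len(d) - 1),), float(p), dz, "dz", label)


def oneway_anova(groups, label: str = "") -> TestResult:
    """One-way fixed-effects ANOVA with η² = SS_between / SS_total."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(groups)
    ss_total = float(((allv - allv.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance")
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_between = ss_total - ss_within
    k, n = len(groups), len(allv)
    df = (float(k - 1), float(n - k))
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), df, float(p), ss_between / ss_total,
                      "eta_squared", label)


def bonferroni_posthoc(groups, pairs=None, labels=None) -> list[TestResult]:
    """Pairwise pooled-variance two-sample t-tests with Bonferroni-adjusted
    p-values (raw p × number of comparisons, capped at 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if pairs is None:
        pairs = [(i, j) for i in range(len(groups))
                 for j in range(i + 1, len(groups))]
    m = len(pairs)
    out = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        t, p = sps.ttest_ind(gi, gj, equal_var=True)
        d = np.concatenate([gi - gi.mean(), gj - gj.mean()])
        sp = d.std(ddof=2)
        es = float((gi.mean() - gj.mean()) / sp) if sp > 0 else 0.0
        name = (labels[i] + " vs " + labels[j]) if labels else f"{i} vs {j}"
        out.append(TestResult(float(t), (float(len(gi) + len(gj) - 2),),
                              float(min(1.0, p * m)), es, "d", name))
    return out


def power_paired_t(n: int, dz: float, alpha: float = 0.05) -> float:
    """Two-tailed power from the noncentral t: ncp = dz·√n, df = n−1."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = dz * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def power_oneway_anova(n_total: int, f: float, n_groups: int = 3,
                       alpha: float = 0.05) -> float:
    """Power from the noncentral F: λ = f²·N, df = (k−1, N−k)."""
    if n_total <= n_groups:
        return 0.0
    lam = f ** 2 * n_total
    df1, df2 = n_groups - 1, n_total - n_groups
    fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def required_n(spec: PowerSpec, n_max: int = 10 ** 6) -> int:
    """Smallest sample size reaching the target power.

    Paired t: per-subject n.  ANOVA: total N under equal allocation across
    ``n_groups`` (so N is a multiple of the group count).
    """
    if spec.test == "paired_t_two_tailed":
        for n in range(2, n_max + 1):
            if power_paired_t(n, spec.effect_size, spec.alpha) >= spec.power:
                return n
    else:
        for per_group in range(2, n_max // spec.n_groups + 1):
            n_total = per_group * spec.n_groups
            if power_oneway_anova(n_total, spec.effect_size, spec.n_groups,
                                  spec.alpha) >= spec.power:
                return n_total
    raise ValueError(f"target power {spec.power} unreachable below n={n_max}")
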