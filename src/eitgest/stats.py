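"""Statistical comparison of model/calibration conditions.

The comparison protocol: a one-way ANOVA over the per-run best-accuracy
samples acts as a gate at alpha = 0.05; only if it fires are post-hoc
pairwise Student t-tests performed, with Holm-Bonferroni control of the
family-wise error rate. Effect sizes are Cohen's d with pooled standard
deviation; interval estimates are t-distribution confidence intervals for
the mean. Accuracy samples are treated as independent across seeds (the
dependence induced by shared folds is a documented approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


def anova_gate(groups: list[np.ndarray], alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-way ANOVA over condition groups; gate passes when p < alpha."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p), bool(p < alpha)


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down procedure; returns per-hypothesis reject flags.

    P-values are sorted ascending and p_(i) is rejected while
    p_(i) <= alpha / (m - i + 1) (1-based i); at the first failure all
    remaining hypotheses are retained.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank is 0-based
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def effect_size_d(a, b) -> float:
    """Cohen's d with pooled standard deviation; sign is mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def mean_ci(samples, level: float = 0.95) -> tuple[float, float, float]:
    """t-distribution confidence interval for the mean: (mean, lower, upper)."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("confidence interval needs >= 2 samples")
    m = float(x.mean())
    if np.ptp(x) == 0:  # constant sample: exactly zero-width interval
        return m, m, m
    sem = x.std(ddof=1) / np.sqrt(len(x))
    tcrit = sps.t.ppf(0.5 + level / 2, df=len(x) - 1)
    return m, m - tcrit * sem, m + tcrit * sem


@dataclass
class PairwiseRow:
    group_a: str
    group_b: str
    t: float
    p: float
    reject: bool
    d: float


@dataclass
class ComparisonReport:
    """ANOVA-gated pairwise comparison of named condition groups."""

    group_means: dict[str, float]
    group_cis: dict[str, tuple[float, float]]
    anova_f: float
    anova_p: float
    significant: bool
    alpha: float = 0.05
    pairwise: list[PairwiseRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group_means": self.group_means,
            "group_cis": self.group_cis,
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "significant": self.significant,
            "alpha": self.alpha,
            "pairwise": [vars(r) for r in self.pairwise],
        }


def compare_conditions(
    groups: dict[str, np.ndarray], alpha: float = 0.05, equal_var: bool = True
) -> ComparisonReport:
    """Run the full comparison protocol on named accuracy samples.

    Pairwise tests default to classical Student t-tests (pooled variance);
    pass ``equal_var=False`` for Welch's correction. Pairwise results are
    only populated when the ANOVA gate passes.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f, p, sig = anova_gate(arrays, alpha=alpha)
    report = ComparisonReport(
        group_means={n: float(a.mean()) for n, a in zip(names, arrays)},
        group_cis={n: mean_ci(a)[1:] for n, a in zip(names, arrays)},
        anova_f=f, anova_p=p, significant=sig, alpha=alpha,
    )
    if not sig:
        return report
    pairs = list(combinations(range(len(names)), 2))
    raw = []
    for i, j in pairs:
        t, pv = sps.ttest_ind(arrays[i], arrays[j], equal_var=equal_var)
        raw.append((float(t), float(pv)))
    rejects = holm_bonferroni([pv for _, pv in raw], alpha=alpha)
    for (i, j), (t, pv), rej in zip(pairs, raw, rejects):
        report.pairwise.append(
            PairwiseRow(names[i], names[j], t, pv, bool(rej),
                        effect_size_d(arrays[i], arrays[j]))
        )
    return report
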