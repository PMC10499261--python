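"""Normality-gated group comparisons.

The comparison procedure used throughout the study: each measure is first
tested for normality per group (Shapiro–Wilk); if every group passes, a
Student t test (2 groups) or one-way ANOVA with Tukey HSD post hoc (more
groups) is used, otherwise a Mann–Whitney U (2 groups) or Kruskal–Wallis
test (more groups). Significance is declared at p < 0.05.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as ss

__all__ = ["TestReport", "gated_group_comparison"]

ALPHA_DEFAULT = 0.05


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    gate_decision: str  # parametric | nonparametric
    group_sizes: list[int]
    shapiro_p: list[float]
    significant: bool
    alpha: float
    posthoc: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def gated_group_comparison(
    groups: list[np.ndarray], alpha: float = ALPHA_DEFAULT
) -> TestReport:
    """Compare ≥2 numeric samples with the normality-gated procedure.

    The parametric branch is taken only when *all* groups pass Shapiro–Wilk
    at ``alpha``. The gate is deterministic: the same data always take the
    same branch. Constant-valued groups are degenerate (the normality test
    and the rank tests are undefined) and raise.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {k} has fewer than 3 observations")
        if np.ptp(g) == 0:
            raise ValueError(f"group {k} is constant-valued; comparison is degenerate")

    shapiro_p = [float(ss.shapiro(g).pvalue) for g in groups]
    parametric = all(p > alpha for p in shapiro_p)
    posthoc: list[dict] = []

    if parametric:
        if len(groups) == 2:
            res = ss.ttest_ind(groups[0], groups[1])
            name = "student_t"
        else:
            res = ss.f_oneway(*groups)
            name = "one_way_anova"
            tk = ss.tukey_hsd(*groups)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    posthoc.append(
                        {
                            "groups": [i, j],
                            "statistic": float(tk.statistic[i, j]),
                            "p_value": float(tk.pvalue[i, j]),
                        }
                    )
        gate = "parametric"
    else:
        if len(groups) == 2:
            res = ss.mannwhitneyu(groups[0], groups[1])
            name = "mann_whitney_u"
        else:
            res = ss.kruskal(*groups)
            name = "kruskal_wallis"
        gate = "nonparametric"

    p = float(res.pvalue)
    return TestReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=p,
        gate_decision=gate,
        group_sizes=[int(g.size) for g in groups],
        shapiro_p=shapiro_p,
        significant=p < alpha,
        alpha=alpha,
        posthoc=posthoc,
    )
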