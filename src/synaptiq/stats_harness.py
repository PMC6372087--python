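"""Group-comparison dispatcher mirroring the study's test-selection rules.

Per group, Shapiro-Wilk checks normality and Bartlett checks variance
homogeneity.  Two normal groups with comparable variance → unpaired two-tailed
Student's t; more than two normal groups → one-way ANOVA with Dunnett's post
hoc versus the control; any non-normal group → Mann-Whitney U (two groups) or
Kruskal-Wallis with Dunn's post hoc (more).  Binned (contingency) designs use
Fisher's exact test; paired designs the paired t test.  Significance at
p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "select_and_compare", "ALPHA"]

ALPHA = 0.05
_NORMALITY_MIN_N = 3


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    groups: list[str]
    posthoc: dict[str, float] | None = None
    alpha: float = ALPHA
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str],
                  control: int) -> dict[str, float]:
    """Dunn's rank-sum z tests of each group against the control.

    Uses pooled mid-ranks with tie correction; no multiplicity adjustment
    unless configured upstream (recorded in provenance by the caller).
    """
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    out = {}
    for i in range(len(groups)):
        if i == control:
            continue
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[control] + 1.0 / sizes[i]))
        z = (mean_ranks[control] - mean_ranks[i]) / se
        out[f"{labels[control]} vs {labels[i]}"] = float(
            2.0 * stats.norm.sf(abs(z)))
    return out


def select_and_compare(groups, design: str = "unpaired", labels=None,
                       control_index: int = 0) -> ComparisonResult:
    """Apply the test-selection procedure to ``groups``.

    design="unpaired": numeric samples, normality/variance screen then
    t/ANOVA+Dunnett or Mann-Whitney/Kruskal-Wallis+Dunn.
    design="paired": two equal-length samples, paired t test (identical
    samples yield the degenerate p = 1 convention with a warning).
    design="binned": ``groups`` is a 2×2 contingency table, Fisher's exact.
    """
    if design == "binned":
        table = np.asarray(groups, dtype=int)
        if table.shape != (2, 2):
            raise ValueError("binned design requires a 2x2 contingency table")
        odds, p = stats.fisher_exact(table)
        return ComparisonResult("fisher_exact", float(odds), float(p),
                                labels or ["group1", "group2"])

    arrs = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None \
        else [f"group{i + 1}" for i in range(len(arrs))]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")

    if design == "paired":
        if len(arrs) != 2 or arrs[0].size != arrs[1].size:
            raise ValueError("paired design requires two equal-length samples")
        diff = arrs[0] - arrs[1]
        if np.allclose(diff, diff[0]) and np.allclose(diff[0], 0.0):
            warnings.warn("identical paired samples: zero-variance "
                          "differences, p = 1 by convention")
            return ComparisonResult("paired_t", 0.0, 1.0, labels,
                                    notes=["degenerate: zero-variance differences"])
        t, p = stats.ttest_rel(arrs[0], arrs[1])
        return ComparisonResult("paired_t", float(t), float(p), labels)

    if design != "unpaired":
        raise ValueError(f"unknown design {design!r}")

    notes: list[str] = []
    normal = True
    for g, lab in zip(arrs, labels):
        if g.size < _NORMALITY_MIN_N:
            warnings.warn(f"group {lab!r} too small for Shapiro-Wilk; "
                          "falling back to nonparametric tests")
            notes.append(f"{lab}: n < {_NORMALITY_MIN_N}, nonparametric fallback")
            normal = False
            break
        if np.ptp(g) == 0 or stats.shapiro(g).pvalue < ALPHA:
            normal = False
            break
    equal_var = True
    if normal:
        try:
            equal_var = stats.bartlett(*arrs).pvalue >= ALPHA
        except ValueError:
            equal_var = False

    if normal and equal_var:
        if len(arrs) == 2:
            t, p = stats.ttest_ind(arrs[0], arrs[1])
            return ComparisonResult("unpaired_t", float(t), float(p), labels,
                                    notes=notes)
        f, p = stats.f_oneway(*arrs)
        dunnett = stats.dunnett(
            *[a for i, a in enumerate(arrs) if i != control_index],
            control=arrs[control_index])
        others = [lab for i, lab in enumerate(labels) if i != control_index]
        posthoc = {f"{labels[control_index]} vs {lab}": float(pv)
                   for lab, pv in zip(others, dunnett.pvalue)}
        return ComparisonResult("anova_dunnett", float(f), float(p), labels,
                                posthoc=posthoc, notes=notes)

    if normal and not equal_var:
        notes.append("variances not comparable (Bartlett); Welch/nonparametric")
        if len(arrs) == 2:
            t, p = stats.ttest_ind(arrs[0], arrs[1], equal_var=False)
            return ComparisonResult("welch_t", float(t), float(p), labels,
                                    notes=notes)

    if len(arrs) == 2:
        total_n = arrs[0].size + arrs[1].size
        method = "exact" if total_n <= 20 else "asymptotic"
        u, p = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided",
                                  method=method)
        return ComparisonResult("mann_whitney_u", float(u), float(p), labels,
                                notes=notes)
    h, p = stats.kruskal(*arrs)
    posthoc = _dunn_posthoc(arrs, labels, control_index)
    return ComparisonResult("kruskal_dunn", float(h), float(p), labels,
                            posthoc=posthoc, notes=notes)
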