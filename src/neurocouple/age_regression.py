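"""Mass-univariate quadratic age models and cohort demographic statistics.

For every cortical area and each coupling metric (S_C, S_D) an ordinary
least squares model

    y = b0 + b1 * AGE_cen + b2 * AGE_cen^2 + e

is fit, with age centered on the pooled sample mean before squaring. The
two-sided p-value of the quadratic coefficient is corrected for multiple
comparisons with the Benjamini-Hochberg step-up procedure, one family per
metric. A significant quadratic term would signal a nonlinear aging
trajectory that a linear brain-age PLS cannot represent.

Cohort statistics cover per-group age summaries and the pooled-variance
two-sample t on mean framewise displacement (with Cohen's d), the standard
check that head motion does not differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError
from .pls_brain_age import CohortStack, CONDITIONS


@dataclass(frozen=True)
class CohortStats:
    age_summary: pd.DataFrame  # group, n, mean, min, max
    fd_t: float
    fd_df: int
    fd_p: float
    fd_cohens_d: float


def center_age(ages: np.ndarray):
    """Center on the pooled sample mean, then square: (AGE_cen, AGE_cen^2)."""
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValidationError("need at least 3 ages")
    if np.var(ages) == 0:
        raise ValidationError("zero age variance")
    cen = ages - ages.mean()
    return cen, cen**2


def fit_quadratic(y: np.ndarray, age_cen: np.ndarray, age_cen_sq: np.ndarray,
                  area: str = "", metric: str = "") -> dict:
    """OLS fit of one area's metric on centered age and its square.

    Returns the coefficients and the two-sided t-test p of the quadratic term.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValidationError("need at least 4 observations")
    x = sm.add_constant(np.column_stack([age_cen, age_cen_sq]))
    if np.linalg.matrix_rank(x) < 3:
        raise ValidationError(
            f"rank-deficient design for area {area!r} (need >= 3 distinct ages)")
    fit = sm.OLS(y, x).fit()
    return {
        "area": area,
        "metric": metric,
        "beta0": float(fit.params[0]),
        "beta_age": float(fit.params[1]),
        "beta_age2": float(fit.params[2]),
        "p_age2": float(fit.pvalues[2]),
    }


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_mass_univariate(stack: CohortStack, family: str = "per_metric") -> pd.DataFrame:
    """Quadratic age model per area per metric, BH-corrected.

    Age is centered on the full pooled sample (both groups). With
    ``family='per_metric'`` (default) each metric's N areas form one FDR
    family; ``family='joint'`` corrects across all 2N tests at once.
    Returns a tidy 2N-row table.
    """
    if family not in ("per_metric", "joint"):
        raise ValidationError(f"unknown FDR family mode {family!r}")
    results = []
    for metric in CONDITIONS:
        idx = np.flatnonzero(np.array(stack.row_condition) == metric)
        ages = stack.age[idx]
        cen, cen2 = center_age(ages)
        block = stack.brain[idx]
        rows = [fit_quadratic(block[:, j], cen, cen2, stack.node_ids[j], metric)
                for j in range(block.shape[1])]
        if family == "per_metric":
            q = bh_adjust(np.array([r["p_age2"] for r in rows]))
            for r, qv in zip(rows, q):
                r["q_age2"] = float(qv)
        results.extend(rows)
    if family == "joint":
        q = bh_adjust(np.array([r["p_age2"] for r in results]))
        for r, qv in zip(results, q):
            r["q_age2"] = float(qv)
    return pd.DataFrame(results)


def cohort_stats(subjects) -> CohortStats:
    """Group age summaries and pooled-variance t on mean FD.

    The pooled (Student) t is used rather than Welch; degrees of freedom are
    n1 + n2 - 2. Cohen's d is the mean difference over the pooled SD.
    """
    groups = {}
    for s in subjects:
        groups.setdefault(s.group, []).append(s)
    if len(groups) != 2 or any(len(v) < 2 for v in groups.values()):
        raise ValidationError("need exactly two groups with n >= 2 each")
    summary = pd.DataFrame(
        [{"group": g, "n": len(v),
          "age_mean": float(np.mean([s.age_years for s in v])),
          "age_min": float(np.min([s.age_years for s in v])),
          "age_max": float(np.max([s.age_years for s in v]))}
         for g, v in groups.items()])
    (g1, v1), (g2, v2) = groups.items()
    fd1 = np.array([s.mean_fd_mm for s in v1])
    fd2 = np.array([s.mean_fd_mm for s in v2])
    t, p = scipy.stats.ttest_ind(fd1, fd2, equal_var=True)
    n1, n2 = len(fd1), len(fd2)
    sp = np.sqrt(((n1 - 1) * fd1.var(ddof=1) + (n2 - 1) * fd2.var(ddof=1))
                 / (n1 + n2 - 2))
    d = (fd1.mean() - fd2.mean()) / sp if sp > 0 else 0.0
    return CohortStats(summary, float(t), n1 + n2 - 2, float(p), float(d))
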