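"""Between-group and within-group statistics over the MST metric table.

Between groups: pooled-variance two-tailed Student t-tests (raw values or
published summary statistics), Cohen's d on the pooled SD, and
Benjamini-Hochberg FDR adjustment across the whole family of
band x measure x metric cells.

Within a group: a two-way repeated-measures ANOVA with factors
FC measure (PLI vs PLV) and MST metric, subject as the blocking factor,
partial eta squared as effect size, and Bonferroni-corrected paired
contrasts per metric.  Because the eight metrics live on incommensurate
scales (kappa ~ 2, mean weight ~ 0.5), each metric is z-scored across
subjects x measures before entering the ANOVA; the paired contrasts are
scale-invariant per metric, so this only affects the omnibus terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, UndefinedEffectError

__all__ = [
    "ttest_two_sample",
    "ttest_from_summary",
    "cohens_d",
    "cohens_d_from_summary",
    "fdr_adjust",
    "chi_square_counts",
    "AnovaEffect",
    "WithinGroupAnovaResult",
    "within_subjects_anova",
]


def _pooled_sd(sd_a, sd_b, n_a, n_b) -> float:
    return float(
        np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    )


def ttest_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Pooled two-sample two-tailed t-test from summary statistics.

    Returns ``(t, p)`` with df = n_a + n_b - 2.  With zero pooled variance:
    equal means give (0, 1); unequal means are an error (infinite t).
    """
    if n_a < 2 or n_b < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise InvalidParameterError("standard deviations must be >= 0")
    sp = _pooled_sd(sd_a, sd_b, n_a, n_b)
    if sp == 0.0:
        if mean_a == mean_b:
            return 0.0, 1.0
        raise InvalidParameterError(
            "zero pooled variance with unequal means: t is infinite"
        )
    t, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(t), float(p)


def ttest_two_sample(values_a, values_b):
    """Pooled two-sample two-tailed t-test on raw values.

    Identical to :func:`ttest_from_summary` evaluated on the sample means
    and (ddof=1) SDs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need n >= 2 per group")
    return ttest_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def cohens_d_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD."""
    sp = _pooled_sd(sd_a, sd_b, n_a, n_b)
    if sp == 0.0:
        raise UndefinedEffectError("zero pooled SD: effect size undefined")
    return float((mean_a - mean_b) / sp)


def cohens_d(values_a, values_b) -> float:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need n >= 2 per group")
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square test (no continuity correction) on a count table."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


@dataclass
class AnovaEffect:
    """One term of the repeated-measures decomposition."""

    name: str
    ss_effect: float
    df_effect: int
    ss_error: float
    df_error: int

    @property
    def F(self) -> float:
        if self.ss_error == 0.0:
            return 0.0 if self.ss_effect == 0.0 else float("inf")
        return (self.ss_effect / self.df_effect) / (self.ss_error / self.df_error)

    @property
    def p(self) -> float:
        f = self.F
        if np.isinf(f):
            return 0.0
        return float(sps.f.sf(f, self.df_effect, self.df_error))

    @property
    def partial_eta_sq(self) -> float:
        denom = self.ss_effect + self.ss_error
        return 0.0 if denom == 0.0 else self.ss_effect / denom


@dataclass
class WithinGroupAnovaResult:
    """Two-way repeated-measures ANOVA (measure x metric) for one band."""

    band: str
    effects: dict  # name -> AnovaEffect, keys 'measure', 'metric', 'measure:metric'
    posthoc: pd.DataFrame  # per-metric paired contrasts, Bonferroni-adjusted
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects.values():
            rows.append(
                {
                    "band": self.band,
                    "effect": eff.name,
                    "F": eff.F,
                    "df1": eff.df_effect,
                    "df2": eff.df_error,
                    "p": eff.p,
                    "partial_eta_sq": eff.partial_eta_sq,
                }
            )
        return pd.DataFrame(rows)


def within_subjects_anova(
    table: pd.DataFrame,
    band: str = "",
    zscore_metrics: bool = True,
) -> WithinGroupAnovaResult:
    """Two-way repeated-measures ANOVA on a long table for one band.

    ``table`` needs columns ``subject_id``, ``measure``, ``metric``,
    ``value`` and must be complete and balanced: every subject has exactly
    one value for every measure x metric cell.  Subjects are the blocking
    factor; each effect is tested against its own subject-interaction error
    term.  Partial eta squared is SS_effect / (SS_effect + SS_error).

    Post hoc: per metric, a paired t-test between the two measures with
    Bonferroni multiplication by the number of metrics (capped at 1).
    """
    required = {"subject_id", "measure", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"table lacks columns {sorted(missing)}")
    pivot = table.pivot_table(
        index="subject_id", columns=["measure", "metric"], values="value",
        aggfunc="mean",
    )
    if pivot.isna().any().any():
        bad = pivot.columns[pivot.isna().any()].tolist()
        raise InvalidParameterError(f"missing cells for {bad}")
    measures = sorted(table["measure"].unique())
    metrics = sorted(table["metric"].unique())
    a, b, n = len(measures), len(metrics), pivot.shape[0]
    if a < 2 or n < 2:
        raise InvalidParameterError("need >= 2 measures and >= 2 subjects")
    # Y[subject, measure, metric]
    y = np.empty((n, a, b))
    for ia, mea in enumerate(measures):
        for ib, met in enumerate(metrics):
            y[:, ia, ib] = pivot[(mea, met)].to_numpy()
    if zscore_metrics:
        flat = y.reshape(n * a, b)
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        y = ((flat - mu) / sd).reshape(n, a, b)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))     # subject means
    m_a = y.mean(axis=(0, 2))     # measure means
    m_b = y.mean(axis=(0, 1))     # metric means
    m_sa = y.mean(axis=2)         # subject x measure
    m_sb = y.mean(axis=1)         # subject x metric
    m_ab = y.mean(axis=0)         # measure x metric

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_as = b * (
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    ).sum()
    ss_bs = a * (
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()

    # Degenerate terms (e.g. identical measure columns) leave ~1e-32
    # round-off in both an effect and its error sum; their ratio would be
    # noise, so sums that are negligible against the total are zeroed.
    ss_total = ((y - grand) ** 2).sum()
    tol = 1e-12 * max(ss_total, 1e-300)
    ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs = (
        0.0 if ss < tol else ss
        for ss in (ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs)
    )

    effects = {
        "measure": AnovaEffect("measure", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
    }
    if b >= 2:  # metric and interaction terms need >= 2 metric levels
        effects["metric"] = AnovaEffect(
            "metric", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)
        )
        effects["measure:metric"] = AnovaEffect(
            "measure:metric", ss_ab, (a - 1) * (b - 1), ss_abs,
            (a - 1) * (b - 1) * (n - 1),
        )

    rows = []
    if a == 2:
        for ib, met in enumerate(metrics):
            diff = y[:, 1, ib] - y[:, 0, ib]
            if np.allclose(diff.std(ddof=1), 0.0):
                t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (
                    np.inf, 0.0
                )
            else:
                t, p = sps.ttest_rel(y[:, 1, ib], y[:, 0, ib])
            rows.append(
                {
                    "band": band,
                    "metric": met,
                    "contrast": f"{measures[1]} - {measures[0]}",
                    "t": float(t),
                    "p": float(p),
                    "p_bonferroni": float(min(1.0, float(p) * b)),
                }
            )
    posthoc = pd.DataFrame(rows)
    return WithinGroupAnovaResult(
        band=band, effects=effects, posthoc=posthoc, n_subjects=n
    )
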