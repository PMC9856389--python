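"""Model/Results interface for the group comparison of MST metrics.

:class:`MSTComparison` is built from the long-format metric table that the
pipeline emits (columns ``subject_id, group, band, measure, metric,
value``); ``fit()`` runs the full statistical layer and returns an
:class:`MSTComparisonResults` carrying the between-group t/effect-size/FDR
table, the per-band within-group repeated-measures ANOVAs, and a
``summary()`` in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .stats import (
    cohens_d,
    fdr_adjust,
    ttest_two_sample,
    within_subjects_anova,
)

__all__ = ["MSTComparison", "MSTComparisonResults"]

_REQUIRED = ("subject_id", "group", "band", "measure", "metric", "value")


class MSTComparison:
    """Between- and within-group comparison of MST metric tables.

    Parameters
    ----------
    metrics : pandas.DataFrame
        Long-format table with columns ``subject_id, group, band, measure,
        metric, value``; one row per subject-level (epoch-averaged) metric.
    groups : tuple of str, optional
        The two group labels to compare, in (reference, comparison) order;
        defaults to the sorted unique labels.
    """

    def __init__(self, metrics: pd.DataFrame, groups: tuple | None = None):
        missing = set(_REQUIRED) - set(metrics.columns)
        if missing:
            raise InvalidParameterError(f"metrics lacks columns {sorted(missing)}")
        self.metrics = metrics.copy()
        labels = sorted(metrics["group"].unique())
        if groups is None:
            if len(labels) != 2:
                raise InvalidParameterError(
                    f"expected exactly 2 groups, found {labels}"
                )
            groups = tuple(labels)
        self.groups = tuple(groups)

    @classmethod
    def from_csv(cls, path, **kw) -> "MSTComparison":
        return cls(pd.read_csv(path), **kw)

    def fit(
        self,
        fdr_family: str = "all",
        zscore_metrics: bool = True,
        alpha: float = 0.05,
    ) -> "MSTComparisonResults":
        """Run all between-group tests and within-group ANOVAs.

        ``fdr_family`` is ``"all"`` (one BH family across every
        band x measure x metric cell) or ``"per_band"``.
        """
        if fdr_family not in ("all", "per_band"):
            raise InvalidParameterError(
                f"fdr_family must be 'all' or 'per_band', got {fdr_family!r}"
            )
        ga, gb = self.groups
        rows = []
        dropped = []
        cells = self.metrics.pivot_table(
            index=["band", "measure", "metric"],
            columns="group",
            values="value",
            aggfunc=list,
        )
        for (band, measure, metric), cell in cells.iterrows():
            va = np.asarray(cell[ga], dtype=float)
            vb = np.asarray(cell[gb], dtype=float)
            ok_a, ok_b = np.isfinite(va), np.isfinite(vb)
            if (~ok_a).any() or (~ok_b).any():
                dropped.append((band, measure, metric))
                warnings.warn(
                    f"dropping non-finite values in cell "
                    f"({band}, {measure}, {metric})",
                    RuntimeWarning,
                    stacklevel=2,
                )
                va, vb = va[ok_a], vb[ok_b]
            if va.size < 2 or vb.size < 2:
                continue
            t, p = ttest_two_sample(va, vb)
            try:
                d = cohens_d(va, vb)
            except ZeroDivisionError:
                d = np.nan
            rows.append(
                {
                    "band": band,
                    "measure": measure,
                    "metric": metric,
                    f"mean_{ga}": va.mean(),
                    f"sd_{ga}": va.std(ddof=1),
                    f"mean_{gb}": vb.mean(),
                    f"sd_{gb}": vb.std(ddof=1),
                    "t": t,
                    "p": p,
                    "cohens_d": d,
                }
            )
        between = pd.DataFrame(rows)
        if not between.empty:
            if fdr_family == "all":
                between["p_fdr"] = fdr_adjust(between["p"].to_numpy())
            else:
                between["p_fdr"] = between.groupby("band")["p"].transform(
                    lambda s: fdr_adjust(s.to_numpy())
                )

        within = {}
        n_measures = self.metrics["measure"].nunique()
        if n_measures >= 2:
            finite = self.metrics[np.isfinite(self.metrics["value"])]
            for group in self.groups:
                gtab = finite[finite["group"] == group]
                for band in sorted(gtab["band"].unique()):
                    btab = gtab[gtab["band"] == band]
                    # Keep only metrics complete for every subject x measure.
                    counts = btab.pivot_table(
                        index="subject_id", columns=["measure", "metric"],
                        values="value", aggfunc="mean",
                    )
                    incomplete = counts.isna().any(axis=0)
                    bad = {
                        met for (_, met) in counts.columns[incomplete]
                    }
                    good_metrics = set(btab["metric"].unique()) - bad
                    if bad:
                        warnings.warn(
                            f"group {group}, band {band}: excluding "
                            f"incomplete metrics {sorted(bad)} from the ANOVA",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        btab = btab[btab["metric"].isin(good_metrics)]
                    within[(group, band)] = within_subjects_anova(
                        btab, band=band, zscore_metrics=zscore_metrics
                    )
        return MSTComparisonResults(
            model=self,
            between=between,
            within=within,
            alpha=alpha,
            dropped_cells=dropped,
        )


@dataclass
class MSTComparisonResults:
    """Fitted group-comparison results with a printable summary."""

    model: MSTComparison
    between: pd.DataFrame
    within: dict
    alpha: float = 0.05
    dropped_cells: list = field(default_factory=list)

    def significant_cells(self, adjusted: bool = True) -> pd.DataFrame:
        """Between-group cells below alpha (FDR-adjusted by default)."""
        if self.between.empty:
            return self.between
        col = "p_fdr" if adjusted else "p"
        return self.between[self.between[col] < self.alpha]

    def significance_counts(self, adjusted: bool = True) -> dict:
        """Count of significant between-group cells, split by FC measure."""
        sig = self.significant_cells(adjusted=adjusted)
        counts = {m: 0 for m in sorted(self.model.metrics["measure"].unique())}
        if not sig.empty:
            counts.update(sig["measure"].value_counts().to_dict())
        counts["total"] = int(sum(v for k, v in counts.items() if k != "total"))
        return counts

    def within_frame(self) -> pd.DataFrame:
        """All within-group ANOVA terms stacked into one table."""
        frames = []
        for (group, band), res in self.within.items():
            f = res.to_frame()
            f.insert(0, "group", group)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def posthoc_frame(self) -> pd.DataFrame:
        frames = []
        for (group, band), res in self.within.items():
            f = res.posthoc.copy()
            f.insert(0, "group", group)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def summary(self) -> str:
        ga, gb = self.model.groups
        lines = [
            "MST group comparison",
            "=" * 60,
            f"groups: {ga} (n={self.model.metrics[self.model.metrics.group == ga].subject_id.nunique()})"
            f" vs {gb} (n={self.model.metrics[self.model.metrics.group == gb].subject_id.nunique()})",
            f"between-group cells tested: {len(self.between)}",
        ]
        counts = self.significance_counts()
        parts = ", ".join(
            f"{k}: {v}" for k, v in counts.items() if k != "total"
        )
        lines.append(
            f"significant after FDR (q<{self.alpha:g}): {counts['total']}"
            f" ({parts})"
        )
        sig = self.significant_cells()
        if not sig.empty:
            show = sig.sort_values("p_fdr").head(10)
            lines.append("-" * 60)
            lines.append("strongest between-group differences:")
            lines.append(
                show[
                    ["band", "measure", "metric", "t", "p_fdr", "cohens_d"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        if self.within:
            lines.append("-" * 60)
            lines.append("within-group measure x metric ANOVA:")
            wf = self.within_frame()
            inter = wf[wf["effect"] == "measure:metric"]
            lines.append(
                inter[["group", "band", "F", "p", "partial_eta_sq"]].to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                )
            )
        return "\n".join(lines)
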