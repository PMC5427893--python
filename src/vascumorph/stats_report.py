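"""Group statistics and effect-size reporting.

Covers the comparisons made between naive/sham/TBI cohorts: percent
reductions of group means, two-group t-tests (Welch by default, pooled
Student available), one-way ANOVA with Bonferroni-adjusted pairwise
post-hocs, Pearson correlations (r^2 with two-sided p), and a deterministic
summary report of group means +/- SEM with significance flags at p < 0.05.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConfigurationError, DegenerateInputError, SchemaError

__all__ = [
    "GroupSummary",
    "EffectResult",
    "percent_reduction",
    "group_compare",
    "correlate",
    "build_report",
    "ALPHA",
]

ALPHA = 0.05

REQUIRED_COLUMNS = ("group", "subject", "region", "metric", "value")


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sem: float
    metric_name: str = ""
    units: str = ""


@dataclass(frozen=True)
class EffectResult:
    label: str
    percent_reduction: float | None
    t_statistic: float
    p_value: float
    adjusted_p: float
    defined: bool = True


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to control,
    ``100 * (control - treated) / control``, reported to 1 decimal."""
    if control_mean == 0:
        raise ConfigurationError("control mean must be nonzero")
    return round(100.0 * (control_mean - treated_mean) / control_mean, 1)


def _t_test(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float, bool]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return float("nan"), float("nan"), False
        # separated point masses: difference certain
        return float("inf"), 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), True


def group_compare(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    design: str = "two_group_t",
    equal_var: bool = False,
) -> list[EffectResult]:
    """Two-sided group comparisons.

    ``two_group_t`` runs a single t-test on two groups (Welch by default).
    ``anova_bonferroni`` runs one-way ANOVA plus all pairwise t-tests with
    Bonferroni correction (p multiplied by the number of pairwise
    comparisons, capped at 1). Each group needs n >= 2.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], float) for k in labels]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        labels = [f"group{i}" for i in range(len(arrays))]
    if any(len(a) < 2 for a in arrays):
        raise ConfigurationError("each group needs n >= 2 for tests")

    results: list[EffectResult] = []
    if design == "two_group_t":
        if len(arrays) != 2:
            raise ConfigurationError("two_group_t requires exactly 2 groups")
        t, p, ok = _t_test(arrays[0], arrays[1], equal_var)
        pr = (
            percent_reduction(arrays[0].mean(), arrays[1].mean())
            if arrays[0].mean() != 0
            else None
        )
        results.append(
            EffectResult(
                label=f"{labels[0]} vs {labels[1]}",
                percent_reduction=pr,
                t_statistic=t,
                p_value=p,
                adjusted_p=p,
                defined=ok,
            )
        )
        return results

    if design == "anova_bonferroni":
        if len(arrays) < 2:
            raise ConfigurationError("anova requires >= 2 groups")
        f, p_anova = sps.f_oneway(*arrays)
        n_pairs = len(arrays) * (len(arrays) - 1) // 2
        results.append(
            EffectResult(
                label="anova",
                percent_reduction=None,
                t_statistic=float(f),
                p_value=float(p_anova),
                adjusted_p=float(p_anova),
                defined=bool(np.isfinite(f)),
            )
        )
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                t, p, ok = _t_test(arrays[i], arrays[j], equal_var)
                adj = min(1.0, p * n_pairs) if ok else float("nan")
                pr = (
                    percent_reduction(arrays[i].mean(), arrays[j].mean())
                    if arrays[i].mean() != 0
                    else None
                )
                results.append(
                    EffectResult(
                        label=f"{labels[i]} vs {labels[j]}",
                        percent_reduction=pr,
                        t_statistic=t,
                        p_value=p,
                        adjusted_p=adj,
                        defined=ok,
                    )
                )
        return results

    raise ConfigurationError(f"unknown design {design!r}")


def correlate(x, y) -> tuple[float, float]:
    """Pearson r^2 with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("correlate requires equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r**2), float(p)


@dataclass
class Report:
    """Deterministic group-comparison report."""

    summaries: pd.DataFrame  # group x region x metric means +/- SEM
    effects: pd.DataFrame  # sham-vs-tbi effect rows per region x metric
    alpha: float = ALPHA

    def to_markdown(self) -> str:
        buf = io.StringIO()
        buf.write("# Cohort report\n\n## Group summaries (mean ± SEM)\n\n")
        buf.write(self.summaries.to_csv(index=False, float_format="%.6g"))
        buf.write("\n## Effects (control vs treated)\n\n")
        buf.write(self.effects.to_csv(index=False, float_format="%.6g"))
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "summaries": self.summaries.to_dict(orient="records"),
                "effects": self.effects.to_dict(orient="records"),
            },
            indent=2,
            sort_keys=True,
            allow_nan=True,
        )


def build_report(
    table: pd.DataFrame,
    control_group: str = "sham",
    treated_group: str = "tbi",
    equal_var: bool = False,
) -> Report:
    """Summarize a tidy metrics table and test control vs treated.

    ``table`` must have columns group/subject/region/metric/value. For each
    region x metric the report lists group means +/- SEM and, when both the
    control and treated groups have n >= 2, the percent reduction, Welch t
    and p, and a significance flag at p < 0.05; otherwise the effect row is
    marked not computable.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"metrics table missing columns: {missing}")

    summaries = (
        table.groupby(["group", "region", "metric"], sort=True)["value"]
        .agg(n="count", mean="mean", sem=lambda v: v.sem() if len(v) > 1 else 0.0)
        .reset_index()
    )

    effect_rows = []
    for (region, metric), sub in table.groupby(["region", "metric"], sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "value"].to_numpy(float)
        trt = sub.loc[sub["group"] == treated_group, "value"].to_numpy(float)
        row = {"region": region, "metric": metric}
        if len(ctrl) >= 2 and len(trt) >= 2:
            t, p, ok = _t_test(ctrl, trt, equal_var)
            row.update(
                percent_reduction=(
                    percent_reduction(ctrl.mean(), trt.mean())
                    if ctrl.mean() != 0
                    else np.nan
                ),
                t_statistic=t,
                p_value=p,
                significant=bool(ok and p < ALPHA),
                computable=ok,
            )
        else:
            row.update(
                percent_reduction=np.nan,
                t_statistic=np.nan,
                p_value=np.nan,
                significant=False,
                computable=False,
            )
        effect_rows.append(row)
    effects = pd.DataFrame(effect_rows)
    return Report(summaries=summaries, effects=effects)
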