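"""Univariate group comparisons, confusion-matrix metrics and the final report.

The univariate stage compares each ability between the success and fail
groups with pooled-variance Student t-tests (df = n1 + n2 - 2).  No multiple
testing correction is applied -- the comparisons are exploratory -- and
every rendered p-value is explicitly labelled as uncorrected.

Note on labels: in this analysis tradition the *success-prediction rate*
a/(a+b) is reported as "model specificity" and the *fail-prediction rate*
d/(c+d) as "model sensitivity"; the report keeps those labels with a
clarifying parenthetical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ability_data import AbilitiesMatrix, SuccessVector
from .errors import ValidationError
from .plsglm import PLSGLRModel, interpret_coefficient
from .robustness import PermutationSummary
from .selection import ComponentSearchResult, SubsetSearchResult, search_table

__all__ = [
    "ConfusionMatrix", "ConfusionMetrics", "TTestResult",
    "confusion_metrics", "two_sample_t", "univariate_comparisons",
    "final_report", "render_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 prediction table.

    ``a``: actual success predicted success; ``b``: actual success predicted
    fail (false negatives); ``c``: actual fail predicted success (false
    positives); ``d``: actual fail predicted fail.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"count {name!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def fp(self) -> int:
        return self.c

    @property
    def fn(self) -> int:
        return self.b

    @property
    def total_errors(self) -> int:
        return self.b + self.c

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValidationError("prediction and truth lengths differ")
        return cls(
            a=int(np.sum((yt == 1) & (yp == 1))),
            b=int(np.sum((yt == 1) & (yp == 0))),
            c=int(np.sum((yt == 0) & (yp == 1))),
            d=int(np.sum((yt == 0) & (yp == 0))),
        )


@dataclass(frozen=True)
class ConfusionMetrics:
    """Percent metrics of a confusion matrix (full precision; rendering
    rounds accuracy to two decimals and the rates to one)."""

    accuracy: float
    success_prediction_rate: float   # a / (a+b), "specificity" label
    fail_prediction_rate: float      # d / (c+d), "sensitivity" label


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    """Accuracy 100(a+d)/n and the two per-class prediction rates."""
    if cm.n == 0:
        raise ValidationError("empty confusion matrix")
    if cm.a + cm.b == 0 or cm.c + cm.d == 0:
        raise ValidationError("each actual class must be non-empty for its rate")
    return ConfusionMetrics(
        accuracy=100.0 * (cm.a + cm.d) / cm.n,
        success_prediction_rate=100.0 * cm.a / (cm.a + cm.b),
        fail_prediction_rate=100.0 * cm.d / (cm.c + cm.d),
    )


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample Student t-test."""

    t: float
    df: int
    p: float                    # two-sided, uncorrected
    mean_a: float
    mean_b: float
    pooled_sd: float


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Student's pooled-variance t-test (two-sided, df = n1 + n2 - 2)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least two observations")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValidationError("pooled variance is zero; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        pooled_sd=float(np.sqrt(pooled_var)),
    )


def univariate_comparisons(matrix: AbilitiesMatrix, success: SuccessVector
                           ) -> pd.DataFrame:
    """Per-ability success-vs-fail group comparison (uncorrected p-values)."""
    if matrix.participant_ids != success.participant_ids:
        raise ValidationError("matrix and success vector participants differ")
    mask = success.values == 1
    if mask.all() or not mask.any():
        raise ValidationError("both outcome groups must be non-empty")
    rows = []
    for j, var in enumerate(matrix.variables):
        col = matrix.values[:, j]
        res = two_sample_t(col[mask], col[~mask])
        rows.append({
            "variable": var.name,
            "task": var.task,
            "mean_success": res.mean_a,
            "mean_fail": res.mean_b,
            "t": res.t,
            "df": res.df,
            "p_uncorrected": res.p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Final report
# ---------------------------------------------------------------------------

def _coefficient_table(model: PLSGLRModel) -> list[dict]:
    rows = []
    for name, beta, sd in zip(model.variable_names, model.beta,
                              model.standardization.sd):
        multiplier, percent = interpret_coefficient(float(beta))
        rows.append({
            "variable": name,
            "unit_1sd": float(sd),
            "coefficient": float(beta),
            "odds_multiplier": multiplier,
            "percent_change": percent,
        })
    return rows


def final_report(
    model: PLSGLRModel | None = None,
    confusion: ConfusionMatrix | None = None,
    component_search: ComponentSearchResult | None = None,
    subset_search: SubsetSearchResult | None = None,
    permutation_summary: PermutationSummary | None = None,
    univariate_table: pd.DataFrame | None = None,
    variable_names: Sequence[str] | None = None,
) -> dict:
    """Assemble the end-to-end analysis report as a JSON-serializable dict.

    Any stage not supplied renders as ``"not run"``.  When both a model and
    a univariate table (or a variable-name catalogue) are given, the model's
    predictors are checked against that catalogue.
    """
    catalogue = None
    if variable_names is not None:
        catalogue = set(variable_names)
    elif univariate_table is not None:
        catalogue = set(univariate_table["variable"])
    if model is not None and catalogue is not None:
        unknown = [n for n in model.variable_names if n not in catalogue]
        if unknown:
            raise ValidationError(
                f"model predictors absent from the catalogue: {unknown}"
            )

    report: dict = {}

    if component_search is not None:
        report["component_selection"] = {
            "selected_n_components": component_search.selected_n_components,
            "table": search_table(component_search).to_dict(orient="records"),
        }
    else:
        report["component_selection"] = "not run"

    if subset_search is not None:
        sel = subset_search.selected
        report["subset_search"] = {
            "n_candidates": len(subset_search.evaluations) + subset_search.n_failed,
            "n_failed": subset_search.n_failed,
            "selected": {
                "bitmask": sel.bitmask,
                "subset": list(sel.subset),
                "n_components": sel.n_components,
                "fp": sel.fp,
                "fn": sel.fn,
                "max_errors": sel.max_errors,
                "total_errors": sel.total_errors,
            },
            "tie_break_trail": list(subset_search.tie_break_trail),
        }
    else:
        report["subset_search"] = "not run"

    if confusion is not None:
        metrics = confusion_metrics(confusion)
        report["confusion"] = {
            "a_success_predicted_success": confusion.a,
            "b_success_predicted_fail_FN": confusion.b,
            "c_fail_predicted_success_FP": confusion.c,
            "d_fail_predicted_fail": confusion.d,
            "accuracy_pct": round(metrics.accuracy, 2),
            "success_prediction_rate_pct": round(metrics.success_prediction_rate, 1),
            "fail_prediction_rate_pct": round(metrics.fail_prediction_rate, 1),
            "labels": {
                "success_prediction_rate_pct":
                    "reported as model specificity (rate of correctly "
                    "predicted successes)",
                "fail_prediction_rate_pct":
                    "reported as model sensitivity (rate of correctly "
                    "predicted failures)",
            },
        }
    else:
        report["confusion"] = "not run"

    if model is not None:
        report["coefficients"] = {
            "n_components": model.n_components,
            "scale": "per 1 SD of the oriented predictor",
            "table": _coefficient_table(model),
        }
    else:
        report["coefficients"] = "not run"

    if permutation_summary is not None:
        d = permutation_summary.to_dict()
        d.pop("permuted_errors")
        report["permutation"] = d
    else:
        report["permutation"] = "not run"

    if univariate_table is not None:
        report["univariate"] = {
            "note": "independent pooled-variance t-tests; p-values are "
                    "uncorrected (no multiple-testing correction applied)",
            "table": univariate_table.to_dict(orient="records"),
        }
    else:
        report["univariate"] = "not run"

    return report


def render_report(report: dict) -> str:
    """Human-readable text rendering of :func:`final_report` output."""
    lines: list[str] = ["Take-over success prediction report",
                        "=" * 36, ""]

    def section(title: str) -> None:
        lines.append(title)
        lines.append("-" * len(title))

    section("Component selection")
    cs = report.get("component_selection", "not run")
    if cs == "not run":
        lines.append("not run")
    else:
        lines.append(f"selected number of components: {cs['selected_n_components']}")
        for row in cs["table"]:
            lines.append(
                f"  H={row['n_components']}: FP={row['fp']} FN={row['fn']} "
                f"max={row['max_errors']} total={row['total_errors']}"
            )
    lines.append("")

    section("Subset search")
    ss = report.get("subset_search", "not run")
    if ss == "not run":
        lines.append("not run")
    else:
        sel = ss["selected"]
        lines.append(f"candidates evaluated: {ss['n_candidates']} "
                     f"(failed: {ss['n_failed']})")
        lines.append(
            f"selected subset {sel['subset']} (bitmask {sel['bitmask']}), "
            f"H={sel['n_components']}: FP={sel['fp']} FN={sel['fn']} "
            f"max={sel['max_errors']} total={sel['total_errors']}"
        )
        for step in ss["tie_break_trail"]:
            lines.append(f"  tie-break: {step}")
    lines.append("")

    section("Confusion matrix")
    cm = report.get("confusion", "not run")
    if cm == "not run":
        lines.append("not run")
    else:
        lines.append(f"  predicted success | predicted fail")
        lines.append(f"  actual success: {cm['a_success_predicted_success']:>4} | "
                     f"{cm['b_success_predicted_fail_FN']:>4} (FN)")
        lines.append(f"  actual fail:    {cm['c_fail_predicted_success_FP']:>4} (FP) | "
                     f"{cm['d_fail_predicted_fail']:>4}")
        lines.append(f"accuracy: {cm['accuracy_pct']:.2f}%")
        lines.append(
            f"success-prediction rate (reported as specificity): "
            f"{cm['success_prediction_rate_pct']:.1f}%"
        )
        lines.append(
            f"fail-prediction rate (reported as sensitivity): "
            f"{cm['fail_prediction_rate_pct']:.1f}%"
        )
    lines.append("")

    section("Coefficients (per 1 SD)")
    co = report.get("coefficients", "not run")
    if co == "not run":
        lines.append("not run")
    else:
        for row in co["table"]:
            lines.append(
                f"  {row['variable']:<20} unit(1SD)={row['unit_1sd']:.4g} "
                f"beta={row['coefficient']:+.3f} "
                f"multiplier={row['odds_multiplier']:.3f} "
                f"({row['percent_change']:+d}%)"
            )
    lines.append("")

    section("Permutation robustness")
    pm = report.get("permutation", "not run")
    if pm == "not run":
        lines.append("not run")
    else:
        lines.append(f"permutations: {pm['n_permutations']} "
                     f"(failed: {pm['n_failed']}), mode={pm['mode']}")
        lines.append(f"baseline errors: {pm['baseline_errors']}")
        lines.append(f"minimum permuted-minus-baseline difference: "
                     f"{pm['min_difference']}")
        lines.append(f"permutations at-or-better than baseline: "
                     f"{pm['n_at_or_better']}")
        lines.append(f"fraction with fewer than 4 additional errors: "
                     f"{pm['fraction_below_4']:.4f}")
    lines.append("")

    section("Univariate group comparisons (uncorrected)")
    uv = report.get("univariate", "not run")
    if uv == "not run":
        lines.append("not run")
    else:
        lines.append(uv["note"])
        for row in uv["table"]:
            lines.append(
                f"  {row['variable']:<20} t({row['df']}) = {row['t']:+.2f}, "
                f"p = {row['p_uncorrected']:.3f} (uncorrected)"
            )
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(render_report(report))
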