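"""Group statistics for the regional metabolism / perfusion / work cohort.

Implements the statistical surface used to link the septal-to-lateral ratios
to mechanical dyssynchrony and reverse remodeling: Shapiro-Wilk-gated group
summaries (mean +/- SD or median [IQR]), paired/unpaired Student t tests with
Bonferroni correction, Pearson and Spearman correlations, Cohen's kappa with
an asymptotic 95% CI for reader agreement, and the relative change in LV
end-systolic volume (Delta LV ESV, positive = volume reduction = reverse
remodeling).

Standard routines from scipy.stats and statsmodels are used underneath;
this module fixes the conventions (pooled-variance unpaired t by default,
two-tailed p values, Bonferroni family size declared by the caller).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa


@dataclass(frozen=True)
class GroupSummary:
    n: int
    normal: bool  # normality not rejected -> mean +/- SD reported
    normality_p: float
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    iqr: tuple[float, float] | None = None

    def display(self) -> str:
        if self.normal:
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"{self.median:.2f} [{self.iqr[0]:.2f};{self.iqr[1]:.2f}]"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    test_name: str
    paired: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def _clean(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    m_comparisons: int = 1,
    *,
    welch: bool = False,
) -> TestResult:
    """Two-tailed Student t test with Bonferroni adjustment.

    Unpaired tests pool variances by default (pass ``welch=True`` for the
    unequal-variance form).  ``p_adjusted = min(1, m_comparisons * p_raw)``.
    """
    a, b = _clean(a), _clean(b)
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        if len(a) < 2:
            raise ValueError("need n >= 2 per sample")
        diff = a - b
        if np.all(diff == 0):  # identical pairs: t = 0, p = 1 by convention
            return TestResult(0.0, len(a) - 1, 1.0, 1.0, "paired t", True)
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
        name = "paired t"
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per sample")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both samples")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df)
        name = "Welch t" if welch else "unpaired t (pooled)"
    p_raw = float(res.pvalue)
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_raw=p_raw,
        p_adjusted=min(1.0, m_comparisons * p_raw),
        test_name=name,
        paired=paired,
    )


def _check_corr_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input: correlation undefined")


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with two-tailed p via the t transform."""
    x, y = _clean(x), _clean(y)
    _check_corr_inputs(x, y)
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), "pearson")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Rank correlation (Pearson on average ranks)."""
    x, y = _clean(x), _clean(y)
    _check_corr_inputs(x, y)
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), "spearman")


def cohen_kappa(
    labels_a: Sequence[bool], labels_b: Sequence[bool], alpha: float = 0.05
) -> KappaResult:
    """Cohen's kappa for two binary raters, with the asymptotic normal CI.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 agreement table; the CI uses
    the standard (Fleiss) asymptotic standard error as implemented in
    statsmodels.  Raises when chance agreement p_e = 1 (both raters constant
    and identical), where kappa is undefined.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length label vectors with n >= 2")
    table = np.zeros((2, 2))
    for ai, bi in zip(a, b):
        table[int(ai), int(bi)] += 1
    margins_a = table.sum(axis=1) / a.size
    margins_b = table.sum(axis=0) / a.size
    p_e = float(margins_a @ margins_b)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("kappa undefined: both raters constant and identical")
    res = _sm_cohens_kappa(table, return_results=True)
    z = stats.norm.ppf(1 - alpha / 2)
    se = float(res.std_kappa)
    kappa = float(res.kappa)
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_low=kappa - z * se,
        ci_high=kappa + z * se,
        n=int(a.size),
    )


def delta_esv(esv_pre: float, esv_post: float) -> float:
    """Relative LV ESV change in percent; positive = reverse remodeling."""
    if esv_pre <= 0:
        raise ValueError(f"baseline ESV must be positive, got {esv_pre}")
    return 100.0 * (esv_pre - esv_post) / esv_pre


def summarize(sample: Sequence[float], alpha_normality: float = 0.05) -> GroupSummary:
    """Mean +/- SD when Shapiro-Wilk does not reject normality, else median [IQR].

    Constant samples are reported as mean +/- 0 (the normal branch; the
    Shapiro-Wilk statistic is undefined at zero variance).
    """
    x = _clean(sample)
    if len(x) < 3:
        raise ValueError("need n >= 3 to summarize")
    if np.var(x) == 0:
        return GroupSummary(
            n=len(x), normal=True, normality_p=1.0, mean=float(x[0]), sd=0.0
        )
    p = float(stats.shapiro(x).pvalue)
    if p >= alpha_normality:
        return GroupSummary(
            n=len(x),
            normal=True,
            normality_p=p,
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)),
        )
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(
        n=len(x), normal=False, normality_p=p, median=float(med), iqr=(float(q1), float(q3))
    )


# ---------------------------------------------------------------------------
# cohort-level report


#: Regional comparisons per modality (septal-vs-lateral within each group plus
#: the two between-group wall contrasts) — the declared Bonferroni family.
DEFAULT_M_COMPARISONS = 4

METRIC_PAIRS = {
    "fdg_suv": ("suv_septal", "suv_lateral"),
    "mbf": ("mbf_septal", "mbf_lateral"),
    "work": ("work_septal", "work_lateral"),
}


def cohort_report(
    metrics: pd.DataFrame, m_comparisons: int = DEFAULT_M_COMPARISONS
) -> dict:
    """Statistical report mirroring the cohort's Results-style summary.

    `metrics` has one row per patient with columns: ``group`` ("dys" /
    "nondys"), ``suv_septal``, ``suv_lateral``, ``fdg_slr``, ``mbf_septal``,
    ``mbf_lateral``, ``mbf_slr``, ``work_septal``, ``work_lateral``,
    ``delta_esv``, ``reader_a``, ``reader_b``.  Missing values (NaN) are
    dropped per metric, so each comparison carries its own n.
    """
    report: dict = {"groups": {}, "tests": {}, "correlations": {}}
    for grp, sub in metrics.groupby("group"):
        entry: dict = {"n": int(len(sub))}
        for col in (
            "suv_septal",
            "suv_lateral",
            "fdg_slr",
            "mbf_septal",
            "mbf_lateral",
            "mbf_slr",
            "work_septal",
            "work_lateral",
            "delta_esv",
        ):
            if col in sub:
                vals = _clean(sub[col])
                if len(vals) >= 3:
                    s = summarize(vals)
                    entry[col] = {
                        "n": s.n,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)),
                        "display": s.display(),
                    }
        report["groups"][grp] = entry

    for name, (sep_col, lat_col) in METRIC_PAIRS.items():
        for grp, sub in metrics.groupby("group"):
            paired_df = sub[[sep_col, lat_col]].dropna()
            if len(paired_df) >= 2:
                tr = t_test(
                    paired_df[sep_col], paired_df[lat_col], paired=True,
                    m_comparisons=m_comparisons,
                )
                report["tests"][f"{name}_septal_vs_lateral_{grp}"] = vars(tr)
    dys = metrics[metrics["group"] == "dys"]
    nondys = metrics[metrics["group"] == "nondys"]
    for col in ("fdg_slr", "mbf_slr", "delta_esv"):
        a, b = _clean(dys.get(col, [])), _clean(nondys.get(col, []))
        if len(a) >= 2 and len(b) >= 2:
            tr = t_test(a, b, paired=False, m_comparisons=m_comparisons)
            report["tests"][f"{col}_dys_vs_nondys"] = vars(tr)

    for col, label in (("fdg_slr", "fdg_slr_vs_delta_esv"),
                       ("mbf_slr", "mbf_slr_vs_delta_esv")):
        sub = metrics[[col, "delta_esv"]].dropna()
        if len(sub) >= 3:
            cr = pearson(sub[col], sub["delta_esv"])
            report["correlations"][label] = vars(cr)

    if {"reader_a", "reader_b"} <= set(metrics.columns):
        readers = metrics[["reader_a", "reader_b"]].dropna()
        try:
            kr = cohen_kappa(readers["reader_a"].astype(bool),
                             readers["reader_b"].astype(bool))
            report["reader_agreement"] = vars(kr)
        except ValueError as exc:
            report["reader_agreement"] = {"error": str(exc)}
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float))


def report_markdown(report: dict) -> str:
    """Human-readable table of the report's headline numbers."""
    lines = ["# Cohort report", "", "## Group summaries", ""]
    for grp, entry in sorted(report.get("groups", {}).items()):
        lines.append(f"### {grp} (n = {entry['n']})")
        for metric, s in entry.items():
            if isinstance(s, dict):
                lines.append(f"- {metric}: {s['display']} (n = {s['n']})")
        lines.append("")
    lines.append("## Tests")
    for name, tr in sorted(report.get("tests", {}).items()):
        lines.append(
            f"- {name}: t = {tr['statistic']:.3f}, df = {tr['df']:.0f}, "
            f"p = {tr['p_raw']:.4g} (adjusted {tr['p_adjusted']:.4g})"
        )
    lines.append("")
    lines.append("## Correlations")
    for name, cr in sorted(report.get("correlations", {}).items()):
        lines.append(f"- {name}: r = {cr['r']:.3f}, p = {cr['p']:.4g} (n = {cr['n']})")
    if "reader_agreement" in report and "kappa" in report["reader_agreement"]:
        k = report["reader_agreement"]
        lines.append("")
        lines.append(
            f"Reader agreement: kappa = {k['kappa']:.3f} "
            f"(95% CI {k['ci_low']:.3f}-{k['ci_high']:.3f})"
        )
    return "\n".join(lines) + "\n"
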