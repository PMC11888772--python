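"""Reliability and cohort statistics for weighted-sum scores.

Implements the statistical framework used to validate the grid scoring:

* ICC(2,1) — single-measure intraclass correlation under a two-way random
  effects model with absolute agreement, with the McGraw–Wong F-based 95%
  confidence interval, and the conventional interpretation bands
  (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, 0.9–1 excellent).
* Normality-gated group comparisons (Shapiro–Wilk at 0.05 deciding between
  the independent-samples t test with mean ± SD summaries and the
  Mann–Whitney U test with median [IQR] summaries).
* Normality-gated correlations (Pearson vs Spearman), flagged significant at
  p < 0.001.
* The Walter–Eliasziw–Donner a-priori sample size for an ICC reliability
  study, plus dropout inflation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedResultError, ValidationError

logger = logging.getLogger(__name__)

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))

CORONAL_ANGLES = ("alpha_deg", "tsa_deg", "hfa_deg", "talocalcaneal_deg", "tt_deg")
SAGITTAL_ANGLES = ("beta_deg", "ttr_mm")

COHORT_COLUMNS = (
    "patient_id", "tws_x", "tws_y",
    *CORONAL_ANGLES, *SAGITTAL_ANGLES,
)
RATINGS_COLUMNS = ("patient_id", "rater_id", "reading", "tws_x", "tws_y")


@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    interpretation: str

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "interpretation": self.interpretation,
        }


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    summaries: dict  # group label -> {"style": "mean_sd"|"median_iqr", ...}
    test: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float
    normality_p: dict
    warnings: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float

    @property
    def significant(self) -> bool:
        """Correlation significance threshold is the stricter p < 0.001."""
        return self.p_value < 0.001


@dataclass
class StatsReport:
    comparisons: list
    correlations: list
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "comparisons": [
                {
                    "variable": c.variable,
                    "groups": list(c.groups),
                    "summaries": c.summaries,
                    "test": c.test,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "warnings": c.warnings,
                }
                for c in self.comparisons
            ],
            "correlations": [
                {
                    "pair": list(c.pair),
                    "method": c.method,
                    "r": c.r,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.correlations
            ],
            "skipped": self.skipped,
        }

    def to_markdown(self) -> str:
        lines = ["## Group comparisons", "",
                 "| variable | " + " | ".join(self.comparisons[0].groups if self.comparisons else ("a", "b"))
                 + " | test | p |", "|---|---|---|---|---|"]
        for c in self.comparisons:
            summ = [_format_summary(c.summaries[g]) for g in c.groups]
            star = " *" if c.significant else ""
            lines.append(f"| {c.variable} | {summ[0]} | {summ[1]} | {c.test} | {c.p_value:.3g}{star} |")
        lines += ["", "## Correlations", "", "| pair | method | r | p |", "|---|---|---|---|"]
        for c in self.correlations:
            star = " *" if c.significant else ""
            lines.append(f"| {c.pair[0]} ~ {c.pair[1]} | {c.method} | {c.r:.3f} | {c.p_value:.3g}{star} |")
        if self.skipped:
            lines += ["", "## Skipped", ""] + [f"- {s}" for s in self.skipped]
        return "\n".join(lines) + "\n"


def _format_summary(s: dict) -> str:
    if s["style"] == "mean_sd":
        return f"{s['mean']:.2f} ± {s['sd']:.2f}"
    return f"{s['median']:.2f} [{s['q1']:.2f}–{s['q3']:.2f}]"


# ---------------------------------------------------------------------------
# ICC


def icc_2_1(data: np.ndarray, confidence: float = 0.95) -> IccResult:
    """Single-measure ICC, two-way random effects, absolute agreement.

    ``data`` is an (n_subjects, k_raters) matrix with no missing cells.
    Estimate from the two-way ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with the F-based confidence interval of McGraw & Wong for ICC(A,1).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be an (n_subjects, k_raters) matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("ICC requires at least 2 subjects and 2 raters")
    if not np.isfinite(data).all():
        raise ValidationError("ICC input contains missing or non-finite cells")
    if np.ptp(data) == 0:
        raise UndefinedResultError("ICC undefined: all ratings identical")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedResultError("ICC undefined: zero variance decomposition")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect absolute agreement: the interval degenerates
        ci_low = ci_high = 1.0
    else:
        alpha = 1 - confidence
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            ci_low = ci_high = 1.0
        else:
            nu = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, nu)
            f_u = sps.f.ppf(1 - alpha / 2, nu, n - 1)
            ci_low = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            ci_high = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
    return IccResult(
        estimate=float(icc),
        ci_low=float(min(ci_low, icc)),
        ci_high=float(max(ci_high, icc)),
        n_subjects=n,
        n_raters=k,
        interpretation=interpret_icc(icc),
    )


def interpret_icc(estimate: float) -> str:
    """Map an ICC estimate to {poor, moderate, good, excellent}.

    Bands are half-open with the boundary belonging to the higher band:
    (−inf, 0.5) poor, [0.5, 0.75) moderate, [0.75, 0.9) good, [0.9, 1] excellent.
    """
    if estimate > 1:
        raise ValidationError("ICC estimate cannot exceed 1")
    for upper, label in ICC_BANDS:
        if estimate < upper:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# group comparison / correlation


def _summary(values: np.ndarray, style: str) -> dict:
    if style == "mean_sd":
        return {"style": style, "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "n": len(values)}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"style": "median_iqr", "median": float(med), "q1": float(q1),
            "q3": float(q3), "n": len(values)}


def compare_groups(
    values,
    groups,
    variable: str = "value",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Shapiro–Wilk-gated two-group comparison.

    Both groups normal at ``normality_alpha`` → independent-samples t test
    with mean ± SD summaries; otherwise Mann–Whitney U with median [IQR].
    A group smaller than 3 cannot be tested for normality and falls back to
    Mann–Whitney with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError("compare_groups needs exactly two group labels")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")

    warnings_ = []
    normality_p = {}
    if min(len(a), len(b)) < 3:
        warnings_.append(
            f"{variable}: group smaller than 3, falling back to Mann-Whitney U"
        )
        logger.warning(warnings_[-1])
        normal = False
    else:
        pa = float(sps.shapiro(a).pvalue)
        pb = float(sps.shapiro(b).pvalue)
        normality_p = {str(labels[0]): pa, str(labels[1]): pb}
        normal = pa > normality_alpha and pb > normality_alpha

    if normal:
        res = sps.ttest_ind(a, b)
        test, style = "t-test", "mean_sd"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test, style = "mann-whitney", "median_iqr"
    return GroupComparison(
        variable=variable,
        groups=(str(labels[0]), str(labels[1])),
        summaries={str(labels[0]): _summary(a, style), str(labels[1]): _summary(b, style)},
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=normality_p,
        warnings=warnings_,
    )


def correlate(x, y, pair=("x", "y"), normality_alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation: Pearson if both variables pass
    Shapiro–Wilk at ``normality_alpha``, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if len(x) < 4:
        raise ValidationError("correlation requires at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("correlation undefined for constant input")
    normal = (
        sps.shapiro(x).pvalue > normality_alpha
        and sps.shapiro(y).pvalue > normality_alpha
    )
    if normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(pair=tuple(pair), method=method, r=float(r), p_value=float(p))


# ---------------------------------------------------------------------------
# sample size


def icc_sample_size(
    rho0: float = 0.0,
    rho1: float = 0.5,
    k: int = 3,
    alpha: float = 0.05,
    power: float = 0.9,
) -> int:
    """Minimum subjects for an ICC reliability study (Walter–Eliasziw–Donner).

    Tests H0: ICC = rho0 against H1: ICC = rho1 with k ratings per subject at
    one-sided level ``alpha``:

        n = 1 + 2k (z_{1−α} + z_{1−β})² / [(k−1) (ln(C1/C0))²],
        C(ρ) = 1 + kρ/(1−ρ),

    rounded up to an integer.  At the conventional reliability design
    (k = 3, α = 0.05 one-sided, power 0.90, ρ0 = 0, ρ1 = 0.50) this gives 15.
    """
    if not (0 <= rho0 < rho1 < 1):
        raise ValidationError("need 0 <= rho0 < rho1 < 1")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha)
    z_b = sps.norm.ppf(power)
    c0 = 1 + k * rho0 / (1 - rho0)
    c1 = 1 + k * rho1 / (1 - rho1)
    n = 1 + 2 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c1 / c0) ** 2)
    return math.ceil(round(n, 9))


def inflate_for_dropout(n: int, rate: float = 0.3) -> int:
    """Smallest integer >= n·(1+rate), e.g. 15 with 30% dropout → 20."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= rate < 1:
        raise ValidationError("rate must lie in [0, 1)")
    return math.ceil(round(n * (1 + rate), 9))


# ---------------------------------------------------------------------------
# ratings / cohort tables


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    missing = set(RATINGS_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns: {sorted(missing)}")
    dup = ratings.duplicated(subset=["patient_id", "rater_id", "reading"])
    if dup.any():
        raise ValidationError(
            "duplicate (patient, rater, reading) keys: "
            f"{ratings.loc[dup, ['patient_id', 'rater_id', 'reading']].to_dict('records')}"
        )
    return ratings


def _ratings_matrix(ratings: pd.DataFrame, measure: str, index: str,
                    columns: str, fixed: dict) -> np.ndarray:
    sub = ratings
    for col, val in fixed.items():
        sub = sub[sub[col] == val]
    pivot = sub.pivot(index=index, columns=columns, values=measure)
    if pivot.isna().any().any():
        bad = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValidationError(f"missing ratings cells for {index}={bad} ({fixed})")
    return pivot.to_numpy()


def reliability_report(ratings: pd.DataFrame, measures=("tws_x", "tws_y")) -> dict:
    """Intra- and inter-rater ICC(2,1) for each weighted-sum measure.

    For every measure, four agreement entries: intra-rater per rater (the two
    readings as repeated measurements) and inter-rater per reading (the two
    raters as the measurement columns).
    """
    validate_ratings(ratings)
    raters = sorted(ratings["rater_id"].unique())
    readings = sorted(ratings["reading"].unique())
    report: dict = {}
    for measure in measures:
        entries = []
        for rater in raters:
            m = _ratings_matrix(ratings, measure, "patient_id", "reading",
                                {"rater_id": rater})
            entries.append({
                "measurement": "intra-rater",
                "label": f"rater {rater}",
                "icc": icc_2_1(m),
            })
        for reading in readings:
            m = _ratings_matrix(ratings, measure, "patient_id", "rater_id",
                                {"reading": reading})
            entries.append({
                "measurement": "inter-rater",
                "label": f"reading {reading}",
                "icc": icc_2_1(m),
            })
        report[measure] = entries
    # pooled convenience view: mean of the four estimates per measure
    report["pooled_mean_estimate"] = {
        m: float(np.mean([e["icc"].estimate for e in report[m]])) for m in measures
    }
    return report


def cohort_analysis(cohort: pd.DataFrame) -> StatsReport:
    """Group comparisons and correlations of the weighted-sum point against
    hindfoot alignment measures.

    Coronal angles (α, TSA, HFA, talocalcaneal, TT) are compared between the
    varus and valgus groups and correlated with TWSx; sagittal measures
    (β, TTR) between anterior and posterior groups and against TWSy.
    Degenerate groups (< 2 patients) skip the comparison with a warning.
    """
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    from .grid import classify  # local import to avoid cycle at module load

    if "coronal_class" not in cohort.columns or "sagittal_class" not in cohort.columns:
        classes = [classify(x, y) for x, y in zip(cohort["tws_x"], cohort["tws_y"])]
        cohort = cohort.assign(
            coronal_class=[c[0] for c in classes],
            sagittal_class=[c[1] for c in classes],
        )

    comparisons, correlations, skipped = [], [], []

    def compare_block(class_col: str, pair: tuple[str, str], variables) -> None:
        mask = cohort[class_col].isin(pair)
        sub = cohort[mask]
        counts = sub[class_col].value_counts()
        if any(counts.get(g, 0) < 2 for g in pair):
            msg = (f"{class_col} comparison skipped: group sizes "
                   f"{ {g: int(counts.get(g, 0)) for g in pair} } (need >= 2 each)")
            logger.warning(msg)
            skipped.append(msg)
            return
        for var in variables:
            comparisons.append(
                compare_groups(sub[var].to_numpy(), sub[class_col].to_numpy(), variable=var)
            )

    compare_block("coronal_class", ("varus", "valgus"), CORONAL_ANGLES)
    compare_block("sagittal_class", ("anterior", "posterior"), SAGITTAL_ANGLES)

    for tws, variables in (("tws_x", CORONAL_ANGLES), ("tws_y", SAGITTAL_ANGLES)):
        for var in variables:
            try:
                correlations.append(
                    correlate(cohort[tws].to_numpy(), cohort[var].to_numpy(), pair=(tws, var))
                )
            except (ValidationError, UndefinedResultError) as exc:
                msg = f"correlation {tws}~{var} skipped: {exc}"
                logger.warning(msg)
                skipped.append(msg)
    return StatsReport(comparisons=comparisons, correlations=correlations, skipped=skipped)
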