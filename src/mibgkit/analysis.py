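"""Repeated-measures statistics for acquisition-time studies.

The central question: does acquiring the late scan earlier than the 4-h
reference change the late H/M ratio by more than a pre-specified
clinical-relevance margin (0.10 in H/M units)?  The toolkit:

* a random-intercept (compound-symmetry) linear mixed model with a
  categorical fixed time effect, estimated by REML, giving contrasts of
  every late timepoint against the reference with t-based 95 % CIs;
* an equivalence-style margin evaluation (does the mean difference exceed
  the margin? does its CI contain the margin?);
* per-patient exceedance counts (how many individual patients move by more
  than the margin);
* the exact noncentral-t power of the paired t-test design;
* the usual two-group screens (t / Mann-Whitney / chi-square).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import ModelFitError, ValidationError

LATE_ORDER = ("early", "1h", "2h", "3h", "4h")


def _label_sort_key(label: str):
    return (LATE_ORDER.index(label), label) if label in LATE_ORDER else (len(LATE_ORDER), label)


def validate_cohort_table(table: pd.DataFrame, value: str = "hm_ratio") -> None:
    required = {"patient_id", "time_label", value}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table misses columns {sorted(missing)}")
    dup = table.duplicated(subset=["patient_id", "time_label"])
    if dup.any():
        raise ValidationError("(patient_id, time_label) pairs must be unique")
    if {"H", "M", "hm_ratio"} <= set(table.columns):
        recomputed = table["H"] / table["M"]
        if not np.allclose(recomputed, table["hm_ratio"], atol=1e-9, rtol=0):
            raise ValidationError("hm_ratio is inconsistent with H/M")


@dataclass
class TimeModelResult:
    """Contrasts of each timepoint against the reference, from a
    random-intercept mixed model."""

    contrasts: pd.DataFrame  # index: time_label; estimate, se, ci_low, ci_high, p
    reference: str
    var_patient: float
    var_residual: float
    df_resid: int
    n_patients: int
    n_obs: int
    converged: bool


def fit_time_model(
    cohort: pd.DataFrame,
    reference: str = "4h",
    value: str = "hm_ratio",
    include: Sequence[str] | None = None,
) -> TimeModelResult:
    """Random-intercept mixed model with a categorical fixed time factor.

    Estimated by restricted maximum likelihood; patients with missing
    timepoints contribute their available scans.  On complete balanced data
    the contrasts equal the means of within-patient paired differences.
    Inference uses the t distribution with ``n_obs - n_patients - n_time + 1``
    residual degrees of freedom, which reduces to the paired analysis in
    the balanced two-timepoint case.
    """
    validate_cohort_table(cohort, value=value)
    data = cohort.dropna(subset=[value]).copy()
    if include is not None:
        data = data[data["time_label"].isin(include)]
    labels = sorted(data["time_label"].unique(), key=_label_sort_key)
    if reference not in labels:
        raise ValidationError(f"reference {reference!r} absent from the cohort table")
    if len(labels) < 2:
        raise ValidationError("need at least two timepoints")
    if data["patient_id"].nunique() < 3:
        raise ValidationError("need at least three patients")

    others = [lab for lab in labels if lab != reference]
    exog = np.column_stack(
        [np.ones(len(data))] + [(data["time_label"] == lab).to_numpy(float) for lab in others]
    )
    groups = data["patient_id"].to_numpy()
    endog = data[value].to_numpy(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        try:
            fit = model.fit(reml=True)
        except Exception as exc:  # noqa: BLE001 - surface as a diagnostic error
            raise ModelFitError(f"mixed model failed to converge: {exc}") from exc
    if not np.all(np.isfinite(fit.fe_params)):
        raise ModelFitError(
            "mixed model produced non-finite fixed effects",
            trace=[str(h) for h in getattr(fit, "hist", []) or []],
        )

    n_obs = len(data)
    n_pat = data["patient_id"].nunique()
    df = n_obs - n_pat - len(labels) + 1
    if df < 1:
        raise ValidationError("not enough observations for residual degrees of freedom")
    tcrit = stats.t.ppf(0.975, df)

    rows = []
    for j, lab in enumerate(others, start=1):
        est = float(fit.fe_params[j])
        se = float(fit.bse_fe[j])
        p = 2.0 * stats.t.sf(abs(est / se), df) if se > 0 else (0.0 if est else 1.0)
        rows.append(
            {
                "time_label": lab,
                "estimate": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "p": p,
                "n": int((data["time_label"] == lab).sum()),
            }
        )
    contrasts = pd.DataFrame(rows).set_index("time_label")
    return TimeModelResult(
        contrasts=contrasts,
        reference=reference,
        var_patient=float(np.asarray(fit.cov_re)[0, 0]),
        var_residual=float(fit.scale),
        df_resid=int(df),
        n_patients=int(n_pat),
        n_obs=int(n_obs),
        converged=bool(fit.converged),
    )


@dataclass
class MarginEvaluation:
    """Clinical-relevance margin assessment of the fitted contrasts."""

    margin: float
    table: pd.DataFrame  # exceeds_margin, ci_contains_margin per contrast
    verdict: str


def evaluate_margin(result: TimeModelResult, margin: float = 0.10) -> MarginEvaluation:
    """Flag contrasts whose mean difference exceeds the margin (strictly)
    and whose 95 % CI contains the margin on the absolute-difference scale."""
    if margin <= 0:
        raise ValidationError("margin must be > 0")
    rows = []
    for lab, row in result.contrasts.iterrows():
        est = row["estimate"]
        lo, hi = (row["ci_low"], row["ci_high"]) if est >= 0 else (-row["ci_high"], -row["ci_low"])
        rows.append(
            {
                "time_label": lab,
                "estimate": est,
                "exceeds_margin": bool(abs(est) > margin),
                "ci_contains_margin": bool(lo <= margin <= hi),
            }
        )
    table = pd.DataFrame(rows).set_index("time_label")
    n_exc = int(table["exceeds_margin"].sum())
    verdict = (
        f"no contrast exceeds the {margin:g} margin"
        if n_exc == 0
        else f"{n_exc} contrast(s) exceed the {margin:g} margin"
    )
    return MarginEvaluation(margin=margin, table=table, verdict=verdict)


def exceedance_counts(
    cohort: pd.DataFrame,
    reference: str = "4h",
    margin: float = 0.10,
    value: str = "hm_ratio",
) -> pd.DataFrame:
    """Per-timepoint counts of patients whose |difference vs reference|
    strictly exceeds the margin.

    Only patients with both scans enter the denominator; the result is
    invariant to patient order and to adding patients missing either scan.
    """
    if margin <= 0:
        raise ValidationError("margin must be > 0")
    validate_cohort_table(cohort, value=value)
    wide = cohort.pivot(index="patient_id", columns="time_label", values=value)
    if reference not in wide.columns:
        raise ValidationError(f"reference {reference!r} absent from the cohort table")
    rows = []
    for lab in sorted([c for c in wide.columns if c != reference], key=_label_sort_key):
        both = wide[[lab, reference]].dropna()
        if len(both):
            d = (both[lab] - both[reference]).abs()
            rows.append(
                {
                    "time_label": lab,
                    "n_exceeding": int((d > margin).sum()),
                    "n_pairs": len(both),
                    "percent": 100.0 * (d > margin).mean(),
                }
            )
    if not rows:
        raise ValidationError("no patient has both the reference and another scan")
    return pd.DataFrame(rows).set_index("time_label")


@dataclass(frozen=True)
class PowerSpec:
    """Paired t-test design: n pairs, within-pair SD, true absolute difference."""

    n: int
    sd: float
    diff: float
    alpha: float = 0.0167
    sides: int = 1

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("need n >= 2 pairs")
        if self.sd <= 0:
            raise ValidationError("within-pair SD must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sides not in (1, 2):
            raise ValidationError("sides must be 1 or 2")


def paired_power(spec: PowerSpec) -> float:
    """Exact power of the paired t-test via the noncentral t distribution.

    Noncentrality is ``|diff| * sqrt(n) / sd``.  The default one-sided test
    reflects the design question "is the earlier acquisition more than the
    margin away from the 4-h standard"; two-sided is available via
    ``sides=2``.  With ``diff=0`` the power equals alpha.
    """
    df = spec.n - 1
    delta = abs(spec.diff) * np.sqrt(spec.n) / spec.sd
    if spec.sides == 1:
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        return float(stats.nct.sf(tcrit, df, delta))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta))


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float


def compare_groups(
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    table: Sequence[Sequence[int]] | None = None,
    test: str = "auto",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Two-group comparison: t test, Mann-Whitney U, or Pearson chi-square.

    ``auto``: a count table goes to the chi-square test (no continuity
    correction); numeric samples go to the t test when both pass a
    Shapiro-Wilk normality screen at 0.05, otherwise to Mann-Whitney.
    """
    if table is not None:
        if test not in ("auto", "chisquare"):
            raise ValidationError("a count table implies the chi-square test")
        tab = np.asarray(table, dtype=float)
        if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
            raise ValidationError("need an r x c count table with r, c >= 2")
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            raise ValidationError("chi-square undefined: empty row or column")
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return GroupComparison(test="chisquare", statistic=float(chi2), pvalue=float(p))

    if x is None or y is None:
        raise ValidationError("two groups (or a count table) are required")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least two observations")

    if test == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                stats.shapiro(x).pvalue > normality_alpha
                and stats.shapiro(y).pvalue > normality_alpha
            )
        test = "t" if normal else "mannwhitney"
    if test == "t":
        t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(p):  # zero pooled variance, identical groups
            t, p = 0.0, 1.0
        return GroupComparison(test="t", statistic=float(t), pvalue=float(p))
    if test == "mannwhitney":
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        return GroupComparison(test="mannwhitney", statistic=float(u), pvalue=float(p))
    raise ValidationError(f"unknown test {test!r}")
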