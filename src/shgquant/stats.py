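"""Cohort descriptive summaries and repeated-measures statistics.

Each patient contributes up to three fields of view per region (tumor
bulk, TB; tumor-stroma interface, TSI) and per metric (F/B, FAV).
Unadjusted group comparisons operate on per-patient means (one value
per patient per region); the random-intercept mixed model operates on
the raw ROI-level rows and absorbs the within-patient correlation of
the repeated measures.

Test-to-variable assignment is the conventional one: continuous
variables are compared with the Mann-Whitney U rank test, categorical
variables with the Pearson chi-squared test (no continuity correction),
and more than two ordered groups with Kruskal-Wallis. No
multiple-testing correction is applied; p < 0.05 is the significance
convention of the source analyses this package mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortTable",
    "PatientRecord",
    "GroupComparison",
    "MixedModelResult",
    "RandomInterceptModel",
    "RandomInterceptResults",
    "ConvergenceError",
    "aggregate_patient",
    "mann_whitney_u",
    "chi_squared",
    "kruskal_wallis",
    "bmi_categorize",
    "fit_random_intercept",
    "pooled_weighted_mean",
    "summarize_cohort",
]

MEASUREMENT_COLUMNS = ["patient_id", "region_label", "roi_index", "metric", "value"]
PATIENT_COLUMNS = [
    "patient_id", "group", "cohort", "age_years", "sex", "bmi",
    "pt_stage", "grade", "smoking",
]


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: clinical covariates plus ROI-level measurements.

    ``measurements`` is a list of (region_label, roi_index, metric,
    value) tuples with metric in {"FB", "FAV"}. Missing covariates are
    None and are counted, not imputed.
    """

    patient_id: str
    group: str
    cohort: str = "CRC"
    age_years: float | None = None
    sex: str | None = None
    bmi: float | None = None
    pt_stage: str | None = None
    grade: int | None = None
    smoking: bool | None = None
    measurements: tuple = ()


@dataclass
class CohortTable:
    """Patient covariates joined with per-region image metrics.

    Attributes
    ----------
    patients : DataFrame
        One row per patient, columns :data:`PATIENT_COLUMNS`.
    measurements : DataFrame
        One row per ROI measurement, columns :data:`MEASUREMENT_COLUMNS`.
    """

    patients: pd.DataFrame
    measurements: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MEASUREMENT_COLUMNS) - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements missing columns {sorted(missing)}")
        if "patient_id" not in self.patients.columns:
            raise ValueError("patients table needs a patient_id column")
        if self.patients["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id in patients table")

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "CohortTable":
        patients = pd.DataFrame(
            [
                {c: getattr(r, c) for c in PATIENT_COLUMNS}
                for r in records
            ]
        )
        meas_rows = [
            {
                "patient_id": r.patient_id,
                "region_label": region,
                "roi_index": roi,
                "metric": metric,
                "value": value,
            }
            for r in records
            for (region, roi, metric, value) in r.measurements
        ]
        measurements = pd.DataFrame(meas_rows, columns=MEASUREMENT_COLUMNS)
        return cls(patients=patients, measurements=measurements)


def aggregate_patient(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-patient, per-region, per-metric mean over available ROIs.

    Returns a DataFrame with columns patient_id, region_label, metric,
    value (arithmetic mean) and n_rois. Regions with no measurement for
    a patient are simply absent (missing, never zero).
    """
    if measurements.empty:
        return pd.DataFrame(
            columns=["patient_id", "region_label", "metric", "value", "n_rois"]
        )
    g = measurements.groupby(["patient_id", "region_label", "metric"], sort=True)["value"]
    out = g.agg(value="mean", n_rois="count").reset_index()
    return out


@dataclass(frozen=True)
class GroupComparison:
    """One statistical comparison: per-group summaries plus the test."""

    metric: str
    region: str | None
    group_summaries: dict
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


def _summaries(samples: dict[str, np.ndarray]) -> dict:
    out = {}
    for name, x in samples.items():
        x = np.asarray(x, dtype=float)
        out[name] = {
            "mean": float(np.mean(x)) if len(x) else float("nan"),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
            "min": float(np.min(x)) if len(x) else float("nan"),
            "max": float(np.max(x)) if len(x) else float("nan"),
            "n": int(len(x)),
        }
    return out


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
    *,
    metric: str = "", region: str | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Mann-Whitney U rank test with midrank tie handling.

    The p-value is exact (full enumeration of labelings) when
    ``len(x) + len(y) <= 16`` and the pooled sample has no ties;
    otherwise the normal approximation with tie and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 16 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return GroupComparison(
        metric=metric,
        region=region,
        group_summaries=_summaries({labels[0]: x, labels[1]: y}),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"mann-whitney-u ({method})",
    )


def chi_squared(
    table: Sequence[Sequence[float]],
    *, metric: str = "", region: str | None = None,
) -> GroupComparison:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction. Rows or columns whose margin is zero are
    dropped with a warning before computing the statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must contain nonnegative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 nonzero rows and columns")
    res = sps.chi2_contingency(t, correction=False)
    return GroupComparison(
        metric=metric,
        region=region,
        group_summaries={"table": t.astype(int).tolist()},
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="chi-squared (Pearson, no continuity correction)",
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    *, metric: str = "", region: str | None = None,
    labels: Sequence[str] | None = None,
) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected, chi-squared p, df = k-1)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    res = sps.kruskal(*arrays)
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    return GroupComparison(
        metric=metric,
        region=region,
        group_summaries=_summaries(dict(zip(labels, arrays))),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="kruskal-wallis",
    )


def bmi_categorize(bmi: float) -> str:
    """BMI class: normal (<25), overweight ([25, 30)), obese (>=30)."""
    if not bmi > 0:
        raise ValueError("bmi must be positive")
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


@dataclass(frozen=True)
class MixedModelResult:
    """Flat view of a fitted random-intercept model."""

    fixed_effects: pd.DataFrame  # columns: estimate, se, z, p
    var_patient: float
    var_residual: float
    n_patients: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.var_patient < 0 or self.var_residual < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_observations < self.n_patients:
            raise ValueError("n_observations must be >= n_patients")


class RandomInterceptModel:
    """Linear mixed model: fixed factor effect + per-patient random intercept.

    value = intercept + factor effect + u_patient + residual, with
    u_patient ~ N(0, var_patient) and residual ~ N(0, var_residual),
    estimated by restricted maximum likelihood. This is the model used
    to compare a metric between two regions (or groups) when each
    patient contributes several fields of view.

    Examples
    --------
    >>> model = RandomInterceptModel.from_dataframe(
    ...     df, value_col="value", factor_col="region_label",
    ...     patient_col="patient_id")
    >>> result = model.fit()
    >>> result.fixed_effects  # doctest: +SKIP
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame, groups: np.ndarray):
        from statsmodels.regression.mixed_linear_model import MixedLM

        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.groups = np.asarray(groups)
        if len(np.unique(self.groups)) < 2:
            raise ValueError("random-intercept model requires >= 2 patients")
        self._model = MixedLM(self.endog, np.asarray(exog, dtype=float), groups=self.groups)
        self._names = list(exog.columns)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value_col: str = "value",
        factor_col: str = "region_label",
        patient_col: str = "patient_id",
    ) -> "RandomInterceptModel":
        """Build from ROI-level rows; the factor is dummy-coded against
        its first (sorted) level as reference."""
        data = data.dropna(subset=[value_col, factor_col, patient_col])
        levels = sorted(data[factor_col].astype(str).unique())
        exog = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
        for lev in levels[1:]:
            exog[f"{factor_col}[{lev}]"] = (
                data[factor_col].astype(str) == lev
            ).astype(float)
        return cls(data[value_col].to_numpy(), exog, data[patient_col].to_numpy())

    def fit(self, reml: bool = True) -> "RandomInterceptResults":
        last_exc: Exception | None = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary-variance chatter
            for method in ("bfgs", "lbfgs", "powell"):
                try:
                    res = self._model.fit(reml=reml, method=method)
                except Exception as exc:
                    last_exc = exc
                    continue
                if res.converged:
                    return RandomInterceptResults(self, res)
        raise ConvergenceError(
            "mixed model failed to converge "
            f"(n_obs={len(self.endog)}, n_patients={len(np.unique(self.groups))}"
            + (f", last error: {last_exc}" if last_exc else ")")
        )


class RandomInterceptResults:
    """Results wrapper: estimates, variance components, summary()."""

    def __init__(self, model: RandomInterceptModel, smres):
        self.model = model
        self._res = smres

    @property
    def fixed_effects(self) -> pd.DataFrame:
        k = len(self.model._names)
        return pd.DataFrame(
            {
                "estimate": np.asarray(self._res.fe_params)[:k],
                "se": np.asarray(self._res.bse)[:k],
                "z": np.asarray(self._res.tvalues)[:k],
                "p": np.asarray(self._res.pvalues)[:k],
            },
            index=self.model._names,
        )

    @property
    def var_patient(self) -> float:
        return float(np.asarray(self._res.cov_re)[0, 0])

    @property
    def var_residual(self) -> float:
        return float(self._res.scale)

    def as_result(self) -> MixedModelResult:
        groups = self.model.groups
        return MixedModelResult(
            fixed_effects=self.fixed_effects,
            var_patient=self.var_patient,
            var_residual=self.var_residual,
            n_patients=int(len(np.unique(groups))),
            n_observations=int(len(groups)),
        )

    def summary(self):
        return self._res.summary()


def fit_random_intercept(
    data: pd.DataFrame,
    value_col: str = "value",
    factor_col: str = "region_label",
    patient_col: str = "patient_id",
    reml: bool = True,
) -> MixedModelResult:
    """Convenience wrapper: build, fit, and flatten the mixed model."""
    model = RandomInterceptModel.from_dataframe(
        data, value_col=value_col, factor_col=factor_col, patient_col=patient_col
    )
    return model.fit(reml=reml).as_result()


def pooled_weighted_mean(group_stats: Sequence[tuple[float, int]]) -> float:
    """Sample-size-weighted mean: sum(n_i * mean_i) / sum(n_i)."""
    if len(group_stats) == 0:
        raise ValueError("group_stats must be nonempty")
    means = np.array([m for m, _ in group_stats], dtype=float)
    ns = np.array([n for _, n in group_stats], dtype=float)
    if np.any(ns < 1):
        raise ValueError("all n must be >= 1")
    return float(np.sum(means * ns) / np.sum(ns))


_CATEGORICAL_COVARIATES = ["pt_stage", "grade", "smoking", "sex"]
_CONTINUOUS_COVARIATES = ["bmi", "age_years"]


def summarize_cohort(cohort: CohortTable, group_col: str = "group") -> dict:
    """Descriptive cohort report with per-variable group comparisons.

    For each metric x region: per-group mean, SD, range, N observed
    (with %), a Mann-Whitney test on per-patient means, and the
    random-intercept mixed-model group contrast on ROI-level rows side
    by side. For each categorical covariate: level counts, % and a
    chi-squared test; continuous covariates get Mann-Whitney. Tests use
    complete cases per variable; N analyzed is reported.
    """
    patients = cohort.patients
    groups = sorted(patients[group_col].dropna().astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"summarize_cohort expects exactly 2 groups; got {groups}")
    n_by_group = {g: int((patients[group_col] == g).sum()) for g in groups}
    total = len(patients)

    report: dict = {
        "groups": groups,
        "total_n": total,
        "composition": {
            g: {"n": n_by_group[g], "percent": 100.0 * n_by_group[g] / total}
            for g in groups
        },
        "metrics": [],
        "covariates": [],
        "aggregation": "unadjusted tests use per-patient ROI means; "
        "mixed model uses ROI-level rows",
    }

    agg = aggregate_patient(cohort.measurements)
    merged = agg.merge(patients[["patient_id", group_col]], on="patient_id")
    roi_level = cohort.measurements.merge(
        patients[["patient_id", group_col]], on="patient_id"
    )
    for metric in sorted(agg["metric"].unique()) if not agg.empty else []:
        for region in sorted(agg["region_label"].unique()):
            sub = merged[(merged["metric"] == metric) & (merged["region_label"] == region)]
            samples = {
                g: sub.loc[sub[group_col] == g, "value"].to_numpy() for g in groups
            }
            entry: dict = {
                "metric": metric,
                "region": region,
                "group_summaries": _summaries(samples),
                "n_observed_percent": {
                    g: 100.0 * len(samples[g]) / max(n_by_group[g], 1) for g in groups
                },
            }
            if all(len(s) >= 1 for s in samples.values()):
                cmp_ = mann_whitney_u(
                    samples[groups[0]], samples[groups[1]],
                    metric=metric, region=region, labels=tuple(groups),
                )
                entry["rank_test_p"] = cmp_.p_value
                entry["rank_test"] = cmp_.test_name
            rsub = roi_level[
                (roi_level["metric"] == metric) & (roi_level["region_label"] == region)
            ]
            if rsub[group_col].nunique() == 2 and rsub["patient_id"].nunique() >= 2:
                try:
                    mm = fit_random_intercept(
                        rsub, value_col="value", factor_col=group_col
                    )
                    entry["mixed_model_p"] = float(mm.fixed_effects["p"].iloc[1])
                    entry["mixed_model_effect"] = float(
                        mm.fixed_effects["estimate"].iloc[1]
                    )
                except ConvergenceError:
                    entry["mixed_model_p"] = float("nan")
            report["metrics"].append(entry)

    for cov in _CONTINUOUS_COVARIATES:
        if cov not in patients.columns:
            continue
        sub = patients.dropna(subset=[cov])
        samples = {g: sub.loc[sub[group_col] == g, cov].to_numpy() for g in groups}
        entry = {
            "covariate": cov,
            "type": "continuous",
            "group_summaries": _summaries(samples),
            "n_analyzed": int(sum(len(s) for s in samples.values())),
        }
        if all(len(s) >= 1 for s in samples.values()):
            entry["p_value"] = mann_whitney_u(
                samples[groups[0]], samples[groups[1]], labels=tuple(groups)
            ).p_value
        report["covariates"].append(entry)

    for cov in _CATEGORICAL_COVARIATES:
        if cov not in patients.columns:
            continue
        sub = patients.dropna(subset=[cov])
        if sub.empty:
            continue
        levels = sorted(sub[cov].astype(str).unique())
        counts = {
            g: [int(((sub[group_col] == g) & (sub[cov].astype(str) == lv)).sum()) for lv in levels]
            for g in groups
        }
        n_g = {g: sum(counts[g]) for g in groups}
        entry = {
            "covariate": cov,
            "type": "categorical",
            "levels": levels,
            "counts": counts,
            "percents": {
                g: [100.0 * c / n_g[g] if n_g[g] else float("nan") for c in counts[g]]
                for g in groups
            },
            "n_analyzed": int(sum(n_g.values())),
        }
        table = np.array([counts[g] for g in groups]).T  # levels x groups
        try:
            entry["p_value"] = chi_squared(table).p_value
        except ValueError:
            entry["p_value"] = float("nan")
        report["covariates"].append(entry)
    return report


def render_report(report: dict) -> str:
    """Plain-text rendering of a :func:`summarize_cohort` report."""
    g0, g1 = report["groups"]
    lines = [
        f"Cohort report  (N = {report['total_n']})",
        "  Total, N (%): "
        + "  ".join(
            f"{g}: {report['composition'][g]['n']} "
            f"({report['composition'][g]['percent']:.2f}%)"
            for g in (g0, g1)
        ),
        f"  [{report['aggregation']}]",
        "",
    ]
    for e in report["metrics"]:
        s0, s1 = e["group_summaries"][g0], e["group_summaries"][g1]
        lines.append(f"{e['metric']} in {e['region']}")
        for g, s in ((g0, s0), (g1, s1)):
            lines.append(
                f"  {g}: mean (SD) {s['mean']:.2f} ({s['sd']:.2f})  "
                f"range ({s['min']:.2f}, {s['max']:.2f})  n={s['n']}"
            )
        if "rank_test_p" in e:
            lines.append(f"  rank-test p = {e['rank_test_p']:.3f}")
        if "mixed_model_p" in e:
            lines.append(f"  mixed-model p = {e['mixed_model_p']:.3f}")
        lines.append("")
    for e in report["covariates"]:
        if e["type"] == "continuous":
            s0, s1 = e["group_summaries"][g0], e["group_summaries"][g1]
            lines.append(
                f"{e['covariate']}: {g0} {s0['mean']:.2f} ({s0['sd']:.2f}), "
                f"{g1} {s1['mean']:.2f} ({s1['sd']:.2f}), "
                f"p = {e.get('p_value', float('nan')):.3f}"
            )
        else:
            lines.append(
                f"{e['covariate']} (p = {e.get('p_value', float('nan')):.3f})"
            )
            for i, lv in enumerate(e["levels"]):
                lines.append(
                    f"  {lv}: "
                    + "  ".join(
                        f"{g}: {e['counts'][g][i]} ({e['percents'][g][i]:.2f}%)"
                        for g in (g0, g1)
                    )
                )
    return "\n".join(lines)
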