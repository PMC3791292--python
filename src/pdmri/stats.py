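"""Cohort statistics for fitted permeability-diffusivity tables.

Group comparisons (pooled-variance two-tailed t with Cohen's d and Bonferroni
correction over the regional comparison family, N = 12), linear age
regressions, Fisher r-to-z contrasts of independent correlations, the
median-split analysis of the PDI-FA relationship, and an orchestrator that
runs the full report on a fitted-parameter table plus covariates.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DegenerateInputError

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "CorrelationContrast",
    "MedianSplitReport",
    "CohortReport",
    "two_sample_t",
    "cohens_d",
    "bonferroni",
    "age_regression",
    "corr_diff_test",
    "median_split_analysis",
    "run_cohort_analysis",
]

#: size of the regional comparison family used for Bonferroni correction
BONFERRONI_FAMILY = 12


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one variable (pooled-variance Student t)."""

    variable: str
    group1: str
    group2: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t: float
    df: int
    p: float
    d: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ContractError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression of an outcome on age (or any predictor)."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ContractError("|r| cannot exceed 1")
        if self.slope != 0 and np.sign(self.slope) != np.sign(self.r):
            raise ContractError("slope and r must share a sign")


@dataclass(frozen=True)
class CorrelationContrast:
    """Fisher r-to-z contrast of two independent Pearson correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


@dataclass(frozen=True)
class MedianSplitReport:
    """PDI-FA coupling examined separately in the lower and upper PDI halves."""

    n_lower: int
    n_upper: int
    r_lower: float
    p_lower: float
    r_upper: float
    p_upper: float
    group_counts_lower: Mapping[str, int]
    group_counts_upper: Mapping[str, int]
    age_comparison: GroupComparison | None
    tie_warning: str | None = None


def cohens_d(m1: float, s1: float, m2: float, s2: float, n1: int, n2: int) -> float:
    """Standardized mean difference (m2 − m1) / pooled SD.

    At equal group sizes the pooled SD is sqrt((s1² + s2²)/2); in general the
    (n−1)-weighted pooled SD is used.
    """
    if s1 < 0 or s2 < 0:
        raise ContractError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        raise DegenerateInputError("both group SDs are zero")
    if n1 == n2:
        pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    else:
        pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return (m2 - m1) / pooled


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "",
    groups: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Pooled-variance two-tailed Student t-test of group1 (x) vs group2 (y).

    The t statistic and Cohen's d are both signed by (mean_x − mean_y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(f"need at least 2 per group, got {n1}/{n2}")
    s1, s2 = float(x.std(ddof=1)), float(y.std(ddof=1))
    if s1 == 0 and s2 == 0:
        raise DegenerateInputError(f"zero pooled variance for {variable or 'variable'}")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    # argument order gives d the same sign as t: (mean_x - mean_y) / pooled SD
    d = cohens_d(float(y.mean()), s2, float(x.mean()), s1, n2, n1)
    return GroupComparison(
        variable=variable, group1=groups[0], group2=groups[1],
        n1=n1, mean1=float(x.mean()), sd1=s1, n2=n2, mean2=float(y.mean()), sd2=s2,
        t=float(t), df=n1 + n2 - 2, p=float(p), d=float(d),
    )


def bonferroni(p_values: Sequence[float], n_comparisons: int = BONFERRONI_FAMILY) -> list[float]:
    """Bonferroni-adjust p-values: each p becomes min(1, N·p)."""
    p_values = list(p_values)
    if n_comparisons < len(p_values):
        raise ContractError(
            f"family size {n_comparisons} smaller than the {len(p_values)} p-values supplied"
        )
    return [min(1.0, n_comparisons * float(p)) for p in p_values]


def age_regression(age: Sequence[float], outcome: Sequence[float]) -> RegressionResult:
    """OLS regression of an outcome on age with Pearson r and a two-tailed p.

    The p-value comes from the t distribution with n − 2 degrees of freedom.
    """
    age = np.asarray(age, float)
    outcome = np.asarray(outcome, float)
    keep = np.isfinite(age) & np.isfinite(outcome)
    age, outcome = age[keep], outcome[keep]
    n = len(age)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 observations, got {n}")
    if age.std() == 0:
        raise DegenerateInputError("zero age variance")
    res = sps.linregress(age, outcome)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), n=n,
    )


def corr_diff_test(r1: float, n1: int, r2: float, n2: int) -> CorrelationContrast:
    """Fisher r-to-z test of a difference between two independent correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)), two-tailed normal p.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ContractError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ContractError("need n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationContrast(r1=float(r1), n1=n1, r2=float(r2), n2=n2, z=float(z), p=float(p))


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan"), len(x)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), len(x)


def median_split_analysis(
    table: pd.DataFrame,
    split_col: str,
    x_col: str = "pdi",
    y_col: str = "fa",
    group_col: str = "group",
    age_col: str = "age",
) -> MedianSplitReport:
    """Even median split of subjects on one continuous variable.

    Subjects are ranked on ``split_col`` and partitioned into lower/upper
    halves (odd n assigns the median subject to the lower half). Within each
    half the Pearson correlation of ``x_col`` with ``y_col`` is reported,
    together with per-half group composition and a between-half age
    comparison. Heavy ties at the median that prevent an even split produce a
    warning note rather than an error.
    """
    if len(table) < 8:
        raise ContractError(f"need at least 8 subjects, got {len(table)}")
    df = table.reset_index(drop=True)
    vals = df[split_col].to_numpy(float)
    if np.all(vals == vals[0]):
        return MedianSplitReport(
            n_lower=len(df), n_upper=0, r_lower=float("nan"), p_lower=float("nan"),
            r_upper=float("nan"), p_upper=float("nan"),
            group_counts_lower=df[group_col].value_counts().to_dict() if group_col in df else {},
            group_counts_upper={},
            age_comparison=None,
            tie_warning="all subjects identical in the split variable; no split possible",
        )
    order = np.argsort(vals, kind="stable")
    n_lower = (len(df) + 1) // 2
    lower = df.iloc[order[:n_lower]]
    upper = df.iloc[order[n_lower:]]
    tie_warning = None
    if vals[order[n_lower - 1]] == vals[order[n_lower]]:
        tie_warning = (
            f"ties at the median: split sizes {len(lower)}/{len(upper)} are order-dependent"
        )
    r_lo, p_lo, _ = _pearson(lower[x_col].to_numpy(float), lower[y_col].to_numpy(float))
    r_up, p_up, _ = _pearson(upper[x_col].to_numpy(float), upper[y_col].to_numpy(float))
    age_cmp = None
    if age_col in df.columns:
        try:
            age_cmp = two_sample_t(
                lower[age_col], upper[age_col], variable="age", groups=("lower", "upper")
            )
        except DegenerateInputError:
            age_cmp = None
    return MedianSplitReport(
        n_lower=len(lower), n_upper=len(upper),
        r_lower=r_lo, p_lower=p_lo, r_upper=r_up, p_upper=p_up,
        group_counts_lower=(lower[group_col].value_counts().to_dict() if group_col in df else {}),
        group_counts_upper=(upper[group_col].value_counts().to_dict() if group_col in df else {}),
        age_comparison=age_cmp, tie_warning=tie_warning,
    )


# --------------------------------------------------------------------------
# full-report orchestration


@dataclass
class CohortReport:
    """All tables produced by :func:`run_cohort_analysis`."""

    group_comparisons: pd.DataFrame
    age_regressions: pd.DataFrame
    correlations: pd.DataFrame
    correlation_contrasts: pd.DataFrame
    median_split: MedianSplitReport | None
    dose_correlations: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def to_csv(self, directory: str | Path) -> None:
        """Write every table as comma-delimited text under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.group_comparisons.to_csv(directory / "group_comparisons.csv", index=False)
        self.age_regressions.to_csv(directory / "age_regressions.csv", index=False)
        self.correlations.to_csv(directory / "correlations.csv", index=False)
        self.correlation_contrasts.to_csv(directory / "correlation_contrasts.csv", index=False)
        self.dose_correlations.to_csv(directory / "dose_correlations.csv", index=False)
        if self.median_split is not None:
            ms = self.median_split
            pd.DataFrame([{
                "n_lower": ms.n_lower, "n_upper": ms.n_upper,
                "r_lower": ms.r_lower, "p_lower": ms.p_lower,
                "r_upper": ms.r_upper, "p_upper": ms.p_upper,
                "group_counts_lower": str(dict(sorted(ms.group_counts_lower.items()))),
                "group_counts_upper": str(dict(sorted(ms.group_counts_upper.items()))),
                "age_t": ms.age_comparison.t if ms.age_comparison else np.nan,
                "age_p": ms.age_comparison.p if ms.age_comparison else np.nan,
                "tie_warning": ms.tie_warning or "",
            }]).to_csv(directory / "median_split.csv", index=False)

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Cohort analysis report\n======================\n\n")
        buf.write("Group comparisons (Bonferroni family N = %d)\n" % BONFERRONI_FAMILY)
        buf.write(self.group_comparisons.to_string(index=False, float_format="%.4g"))
        buf.write("\n\nAge regressions\n")
        buf.write(self.age_regressions.to_string(index=False, float_format="%.4g"))
        buf.write("\n\nCorrelations\n")
        buf.write(self.correlations.to_string(index=False, float_format="%.4g"))
        buf.write("\n\nCorrelation contrasts\n")
        buf.write(self.correlation_contrasts.to_string(index=False, float_format="%.4g"))
        if self.median_split is not None:
            ms = self.median_split
            buf.write(
                f"\n\nMedian split: n = {ms.n_lower}/{ms.n_upper}; "
                f"lower-half r = {ms.r_lower:.3f} (p = {ms.p_lower:.2g}), "
                f"upper-half r = {ms.r_upper:.3f} (p = {ms.p_upper:.2g})"
            )
        if len(self.dose_correlations):
            buf.write("\n\nMedication-dose correlations\n")
            buf.write(self.dose_correlations.to_string(index=False, float_format="%.4g"))
        if self.skipped:
            buf.write("\n\nSkipped analyses:\n")
            for s in self.skipped:
                buf.write(f"  - {s}\n")
        return buf.getvalue()


_PD_MEASURES = ("mu", "du", "dr", "pdi")
_OPTIONAL_MEASURES = ("fa", "d_axial", "d_radial")


def run_cohort_analysis(
    fits: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    bonferroni_family: int = BONFERRONI_FAMILY,
    gm_roi: str = "cingulate",
    wm_roi: str = "cc",
    split_roi: str = "cc",
) -> CohortReport:
    """Run the full statistics layer on a fitted-parameter table.

    ``fits`` holds one row per (subject, ROI) with columns mu, du, dr, pdi and
    optionally fa, d_axial, d_radial; ``covariates`` holds one row per subject
    with group, age and optionally dose. Emits per-ROI group comparisons with
    Bonferroni adjustment, per-group age regressions (PDI, Mu, FA), per-group
    PDI-FA and gray-white PDI correlations with Fisher-z contrasts, the
    median-split report on the ``split_roi`` PDI, and medication-dose
    correlations. Analyses whose inputs are missing are skipped and listed in
    ``report.skipped``.
    """
    if "subject" not in fits.columns or "subject" not in covariates.columns:
        raise ContractError("both tables must carry a 'subject' column")
    merged = fits.merge(covariates, on="subject", how="inner", validate="many_to_one")
    if merged.empty:
        raise ContractError("fit and covariate tables share no subject ids")
    if groups is None:
        labels = sorted(merged["group"].unique())
        if len(labels) != 2:
            raise ContractError(f"expected exactly 2 groups, found {labels}")
        groups = (labels[0], labels[1])
    g1, g2 = groups
    skipped: list[str] = []
    rois = list(pd.unique(merged["roi"]))
    measures = [m for m in _PD_MEASURES if m in merged.columns] + [
        m for m in _OPTIONAL_MEASURES if m in merged.columns and merged[m].notna().any()
    ]

    # -- group comparisons --------------------------------------------------
    comp_rows = []
    for roi in rois:
        sub = merged[merged["roi"] == roi]
        for m in measures:
            x = sub.loc[sub["group"] == g1, m].to_numpy(float)
            y = sub.loc[sub["group"] == g2, m].to_numpy(float)
            if not (np.isfinite(x).any() and np.isfinite(y).any()):
                continue
            try:
                gc = two_sample_t(x, y, variable=f"{roi}:{m}", groups=(g1, g2))
            except DegenerateInputError as exc:
                skipped.append(f"group comparison {roi}:{m} ({exc})")
                continue
            comp_rows.append({
                "roi": roi, "measure": m,
                f"n_{g1}": gc.n1, f"mean_{g1}": gc.mean1, f"sd_{g1}": gc.sd1,
                f"n_{g2}": gc.n2, f"mean_{g2}": gc.mean2, f"sd_{g2}": gc.sd2,
                "t": gc.t, "df": gc.df, "p": gc.p, "cohens_d": gc.d,
            })
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["p_bonferroni"] = bonferroni(
            comparisons["p"], max(bonferroni_family, len(comparisons))
        )
        comparisons["significant"] = comparisons["p_bonferroni"] < 0.05

    # -- age regressions ----------------------------------------------------
    reg_rows = []
    for roi in rois:
        sub = merged[merged["roi"] == roi]
        for m in ("pdi", "mu", "fa"):
            if m not in sub.columns or sub[m].notna().sum() == 0:
                continue
            for g in groups:
                gg = sub[sub["group"] == g]
                try:
                    rr = age_regression(gg["age"], gg[m])
                except DegenerateInputError as exc:
                    skipped.append(f"age regression {roi}:{m}:{g} ({exc})")
                    continue
                reg_rows.append({
                    "roi": roi, "measure": m, "group": g, "slope_per_year": rr.slope,
                    "intercept": rr.intercept, "r": rr.r, "p": rr.p, "n": rr.n,
                })
    regressions = pd.DataFrame(reg_rows)

    # -- correlations and contrasts ----------------------------------------
    corr_rows, contrast_rows = [], []

    def add_contrast(kind, roi, per_group):
        if len(per_group) == 2 and all(abs(r) < 1 and n >= 4 for r, _, n in per_group.values()):
            (ra, _, na), (rb, _, nb) = per_group[g1], per_group[g2]
            ct = corr_diff_test(ra, na, rb, nb)
            contrast_rows.append({
                "analysis": kind, "roi": roi, f"r_{g1}": ra, f"n_{g1}": na,
                f"r_{g2}": rb, f"n_{g2}": nb, "z": ct.z, "p": ct.p,
            })

    if "fa" in merged.columns and merged["fa"].notna().any():
        for roi in rois:
            sub = merged[merged["roi"] == roi]
            if sub["fa"].notna().sum() < 3:
                continue
            per_group = {}
            for g in groups:
                gg = sub[sub["group"] == g]
                r, p, n = _pearson(gg["pdi"].to_numpy(float), gg["fa"].to_numpy(float))
                if np.isfinite(r):
                    per_group[g] = (r, p, n)
                    corr_rows.append({
                        "analysis": "pdi_fa", "roi": roi, "group": g, "r": r, "p": p, "n": n,
                    })
            add_contrast("pdi_fa", roi, per_group)
    else:
        skipped.append("PDI-FA correlations (no FA column)")

    if gm_roi in rois and wm_roi in rois:
        gm = merged[merged["roi"] == gm_roi].set_index("subject")
        wm = merged[merged["roi"] == wm_roi].set_index("subject")
        common = gm.index.intersection(wm.index)
        per_group = {}
        for g in groups:
            ids = [s for s in common if gm.loc[s, "group"] == g]
            r, p, n = _pearson(
                gm.loc[ids, "pdi"].to_numpy(float), wm.loc[ids, "pdi"].to_numpy(float)
            )
            if np.isfinite(r):
                per_group[g] = (r, p, n)
                corr_rows.append({
                    "analysis": "gm_wm_pdi", "roi": f"{gm_roi}~{wm_roi}", "group": g,
                    "r": r, "p": p, "n": n,
                })
        add_contrast("gm_wm_pdi", f"{gm_roi}~{wm_roi}", per_group)
    else:
        skipped.append(f"gray-white PDI correlation (need ROIs {gm_roi!r} and {wm_roi!r})")

    correlations = pd.DataFrame(corr_rows)
    contrasts = pd.DataFrame(contrast_rows)

    # -- median split -------------------------------------------------------
    median_split = None
    if split_roi in rois:
        sub = merged[merged["roi"] == split_roi].copy()
        if "fa" in sub.columns and sub["fa"].notna().sum() >= 8 and len(sub) >= 8:
            median_split = median_split_analysis(sub, split_col="pdi")
        else:
            skipped.append("median-split analysis (needs >= 8 subjects with FA)")
    else:
        skipped.append(f"median-split analysis (no ROI {split_roi!r})")

    # -- medication dose ----------------------------------------------------
    dose_rows = []
    if "dose" in merged.columns and merged["dose"].notna().any():
        dosed = merged[merged["dose"].notna()]
        for roi in rois:
            sub = dosed[dosed["roi"] == roi]
            for m in measures:
                if m not in sub.columns:
                    continue
                r, p, n = _pearson(sub["dose"].to_numpy(float), sub[m].to_numpy(float))
                if np.isfinite(r):
                    dose_rows.append({"roi": roi, "measure": m, "r": r, "p": p, "n": n})
    else:
        skipped.append("medication-dose correlations (no dose column)")
    dose_correlations = pd.DataFrame(dose_rows)

    return CohortReport(
        group_comparisons=comparisons,
        age_regressions=regressions,
        correlations=correlations,
        correlation_contrasts=contrasts,
        median_split=median_split,
        dose_correlations=dose_correlations,
        skipped=skipped,
    )
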