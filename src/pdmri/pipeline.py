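"""End-to-end chaining: signal tables -> per-subject fits -> cohort report."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .decay import fit_biexp, fit_mono, shell_average
from .errors import DegenerateInputError
from .io import ROISignalTable, ShellTable
from .metrics import pdi
from .simulate import SubjectRecord, SyntheticCohort, subjects_to_covariates
from .stats import CohortReport, run_cohort_analysis

__all__ = ["fit_signal_table", "attach_subject_scalars", "fit_cohort", "analyze_cohort"]


def fit_signal_table(signals: ROISignalTable, shells: ShellTable) -> pd.DataFrame:
    """Fit mono- and bi-exponential decay for every (subject, ROI).

    Returns one row per (subject, ROI) with the two-compartment estimates
    (s0, mu, du, dr, pdi, r² and flags) and the mono-exponential ADC with its
    own r². Subjects/ROIs whose decay is degenerate are skipped.
    """
    rows = []
    frame = signals.frame
    for (subject, roi), sub in frame.groupby(["subject", "roi"], sort=True):
        per_volume = np.full(int(sub["volume"].max()) + 1, np.nan)
        per_volume[sub["volume"].to_numpy()] = sub["signal"].to_numpy()
        try:
            decay = shell_average(per_volume, shells)
            bi = fit_biexp(decay)
            mono = fit_mono(decay)
        except DegenerateInputError:
            continue
        rows.append({
            "subject": subject, "roi": roi,
            "s0": bi.s0, "mu": bi.mu, "du": bi.du, "dr": bi.dr,
            "pdi": pdi(bi.dr, bi.du), "r2_biexp": bi.rsquared,
            "converged": bi.converged, "at_bound": bi.at_bound,
            "adc": mono.adc, "r2_mono": mono.rsquared,
        })
    return pd.DataFrame(rows)


def attach_subject_scalars(fits: pd.DataFrame, subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Merge per-(subject, ROI) FA and DTI diffusivity scalars into a fit table."""
    rows = []
    for s in subjects:
        for roi in set(s.fa) | set(s.d_axial) | set(s.d_radial):
            rows.append({
                "subject": s.id, "roi": roi,
                "fa": s.fa.get(roi, np.nan),
                "d_axial": s.d_axial.get(roi, np.nan),
                "d_radial": s.d_radial.get(roi, np.nan),
            })
    if not rows:
        return fits
    scalars = pd.DataFrame(rows)
    return fits.merge(scalars, on=["subject", "roi"], how="left")


def fit_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Fit every subject/ROI of a synthetic cohort and attach its FA scalars."""
    if cohort.signals is None:
        raise ValueError("cohort was generated without signals")
    fits = fit_signal_table(cohort.signals, cohort.shells)
    return attach_subject_scalars(fits, cohort.subjects)


def analyze_cohort(cohort: SyntheticCohort, **stats_kwargs) -> tuple[pd.DataFrame, CohortReport]:
    """simulate -> fit -> stats in one call; returns (fit table, report)."""
    fits = fit_cohort(cohort)
    covariates = subjects_to_covariates(cohort.subjects)
    report = run_cohort_analysis(fits, covariates, **stats_kwargs)
    return fits, report
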