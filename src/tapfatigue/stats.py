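"""Ratio normalization, bin/period pooling, paired tests and RM-ANOVA.

Every per-bin index flows through the same inference chain.  Bin values
are first normalized per participant to ratios against a first-bin
reference: by default the participant's first LOW-height bin (so LOW and
HIGH share one reference and height effects survive normalization);
median-frequency indices are instead referenced to the first bin of
their own height, because MF baselines are not comparable across days.
Height differences are then tested with a two-sided paired t-test over
participant x bin pairs.  Change over time pools the 10 bins into 5
periods (period p = bins 2p-1 and 2p); a one-way repeated-measures ANOVA
across periods (subjects as the repeated factor) gates four follow-up
paired t-tests of periods 2..5 against period 1 at a
Bonferroni-corrected level alpha/4 = 0.0125.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = ["TestResult", "to_ratio", "to_periods", "paired_height_test",
           "rm_anova_periods", "followup_bonferroni", "analyze_group"]

BIN_COLUMNS = ["participant", "height", "index", "bin", "value"]


@dataclass
class TestResult:
    statistic: float
    p: float
    alpha: float
    significant: bool
    df: float = float("nan")
    label: str = ""


def _is_mf(index_name: str) -> bool:
    return index_name.upper().startswith("MF")


def to_ratio(table: pd.DataFrame, mf_own_height: bool = True) -> pd.DataFrame:
    """Normalize bin values to first-bin ratios, per participant and index.

    Default policy: divide by the participant's LOW-height first-bin
    value.  MF policy (indices named ``MF*``): divide by the first bin of
    the value's own height.  A zero reference propagates NaN with a
    warning.  Idempotent: ratios of ratios are unchanged.
    """
    df = table.copy()
    first_bin = int(df["bin"].min())
    out = np.empty(len(df))
    for (pid, name), grp in df.groupby(["participant", "index"], sort=False):
        refs = {}
        for height in ("LOW", "HIGH"):
            if mf_own_height and _is_mf(name):
                sel = (grp["height"] == height) & (grp["bin"] == first_bin)
            else:
                sel = (grp["height"] == "LOW") & (grp["bin"] == first_bin)
            ref = grp.loc[sel, "value"]
            refs[height] = float(ref.iloc[0]) if len(ref) else np.nan
            if refs[height] == 0:
                warnings.warn(f"zero first-bin reference for {pid}/{name}/{height}; ratios set to NaN")
                refs[height] = np.nan
        denom = grp["height"].map(refs).to_numpy(dtype=float)
        out[df.index.get_indexer(grp.index)] = grp["value"].to_numpy() / denom
    df["value"] = out
    return df


def to_periods(table: pd.DataFrame, bins_per_period: int = 2) -> pd.DataFrame:
    """Pool bins into periods (period p = bins 2p-1, 2p for the default).

    Returns per participant x height x index x period means.
    """
    df = table.copy()
    first_bin = int(df["bin"].min())
    df["period"] = (df["bin"] - first_bin) // bins_per_period + 1
    pooled = (df.groupby(["participant", "height", "index", "period"], sort=True)["value"]
                .mean().reset_index())
    return pooled


def paired_height_test(low: np.ndarray, high: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Two-sided paired t-test of HIGH vs LOW over participant x bin pairs."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    if low.shape != high.shape:
        raise ValueError(f"paired vectors must have equal length, got {low.shape} vs {high.shape}")
    ok = np.isfinite(low) & np.isfinite(high)
    low, high = low[ok], high[ok]
    n = low.size
    diff = high - low
    if n < 2:
        return TestResult(float("nan"), float("nan"), alpha, False, float("nan"))
    if np.allclose(diff, 0):
        # identical vectors: no evidence of a difference
        return TestResult(0.0, 1.0, alpha, False, n - 1)
    t, p = sps.ttest_rel(high, low)
    return TestResult(float(t), float(p), alpha, bool(p < alpha), n - 1)


def _anova_wide(periods: pd.DataFrame) -> pd.DataFrame:
    wide = periods.pivot_table(index="participant", columns="period", values="value")
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        log.warning("RM-ANOVA: dropping %d subject(s) with missing periods: %s",
                    int(incomplete.sum()), list(wide.index[incomplete]))
        wide = wide.loc[~incomplete]
    return wide


def rm_anova_periods(periods: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> TestResult:
    """One-way repeated-measures ANOVA across periods.

    Accepts a long table (participant, period, value) or a subjects x
    periods array.  Classical decomposition: F = MS_period / MS_error
    with the subject x period interaction as error; no sphericity
    correction.  Subjects with any missing period are dropped
    (complete-case).
    """
    if isinstance(periods, pd.DataFrame):
        wide = _anova_wide(periods).to_numpy()
    else:
        wide = np.asarray(periods, dtype=float)
        wide = wide[~np.isnan(wide).any(axis=1)]
    s, p = wide.shape
    if s < 2 or p < 2:
        return TestResult(float("nan"), float("nan"), alpha, False)
    grand = wide.mean()
    ss_period = s * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subject = p * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((wide - grand) ** 2)
    ss_error = ss_total - ss_period - ss_subject
    df_period = p - 1
    df_error = (p - 1) * (s - 1)
    if ss_period <= 0:
        return TestResult(0.0, 1.0, alpha, False, df_period)
    ms_period = ss_period / df_period
    ms_error = ss_error / df_error
    if ms_error <= 0:
        return TestResult(float("inf"), 0.0, alpha, True, df_period)
    f = ms_period / ms_error
    pval = float(sps.f.sf(f, df_period, df_error))
    return TestResult(float(f), pval, alpha, bool(pval < alpha), df_period)


def followup_bonferroni(periods: pd.DataFrame | np.ndarray, alpha: float = 0.05,
                        m: int = 4) -> list[TestResult]:
    """Paired t-tests of periods 2..m+1 against period 1 at level alpha/m."""
    if isinstance(periods, pd.DataFrame):
        wide = _anova_wide(periods).to_numpy()
    else:
        wide = np.asarray(periods, dtype=float)
        wide = wide[~np.isnan(wide).any(axis=1)]
    corrected = alpha / m
    out = []
    for j in range(1, min(m + 1, wide.shape[1])):
        res = paired_height_test(wide[:, 0], wide[:, j], alpha=corrected)
        res.label = f"P{j + 1} vs P1"
        out.append(res)
    return out


def analyze_group(table: pd.DataFrame, alpha: float = 0.05, m: int = 4) -> pd.DataFrame:
    """Full inference chain for a multi-participant bin table.

    For each index: ratio-normalize, test HIGH vs LOW (paired over
    participant x bin), and per height run the period RM-ANOVA; only
    when the ANOVA rejects are the four Bonferroni follow-ups (P2..P5 vs
    P1) performed.  Returns a long results table.
    """
    missing = [c for c in BIN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"bin table missing columns {missing}")
    ratios = to_ratio(table)
    rows = []
    for name, grp in ratios.groupby("index", sort=True):
        wide = grp.pivot_table(index=["participant", "bin"], columns="height", values="value")
        if {"LOW", "HIGH"} <= set(wide.columns):
            res = paired_height_test(wide["LOW"].to_numpy(), wide["HIGH"].to_numpy(), alpha)
            rows.append({"index": name, "comparison": "HIGH vs LOW", "statistic": res.statistic,
                         "p": res.p, "alpha": res.alpha, "significant": res.significant})
        pooled = to_periods(grp)
        for height, hgrp in pooled.groupby("height", sort=True):
            an = rm_anova_periods(hgrp, alpha)
            rows.append({"index": name, "comparison": f"{height}: periods (RM-ANOVA)",
                         "statistic": an.statistic, "p": an.p, "alpha": an.alpha,
                         "significant": an.significant})
            if an.significant:
                for res in followup_bonferroni(hgrp, alpha, m):
                    rows.append({"index": name, "comparison": f"{height}: {res.label}",
                                 "statistic": res.statistic, "p": res.p,
                                 "alpha": res.alpha, "significant": res.significant})
    return pd.DataFrame(rows, columns=["index", "comparison", "statistic", "p", "alpha", "significant"])
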