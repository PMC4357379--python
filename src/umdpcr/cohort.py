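"""Cohort-level statistics: platform agreement, co-occurrence, survival.

Cross-platform concordance uses Pearson correlation on paired copy-number
values; the joint distribution of monosomy 3 and 8q dosage is summarised
as a 2x3 contingency table; and survival is stratified by molecular class
with Kaplan–Meier curves, log-rank tests and Cox proportional-hazards
ratios (Efron tie handling), all via lifelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .cnv import TumourRecord, TumourProfile

logger = logging.getLogger("umdpcr")

CHR3_LEVELS = ("disomy", "monosomy")
CN8Q_LEVELS = ("normal", "gain", "amplification")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r must be in [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


@dataclass(frozen=True)
class CooccurrenceTable:
    """2x3 contingency of chromosome-3 status by 8q dosage class."""

    counts: dict                     # (chr3, 8q class) -> int
    n_total: int
    monosomy3_with_8q_aberration: int
    monosomy3_with_normal_chr8: int
    disomy3_with_8q_aberration: int

    def margin_chr3(self, status: str) -> int:
        return sum(v for (c3, _), v in self.counts.items() if c3 == status)

    def margin_8q(self, cls: str) -> int:
        return sum(v for (_, q), v in self.counts.items() if q == cls)


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored time-to-event record for one patient.

    ``event`` is True for death with metastasis, False for censoring.
    """

    tumour_id: str
    months: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.months <= 0:
            raise ValueError("survival time must be positive")


@dataclass(frozen=True)
class SurvivalFit:
    """Per-group product-limit curves plus test statistics."""

    curves: dict                     # group -> (times array, survival array)
    group_sizes: dict
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    hazard_ratios: dict = field(default_factory=dict)  # contrast -> (hr, lo, hi)

    def survival_at(self, group: str, t: float) -> float:
        """S(t) from the last step at or before t (1 before the first event)."""
        times, surv = self.curves[group]
        idx = np.searchsorted(times, t, side="right") - 1
        return float(surv[idx]) if idx >= 0 else 1.0


# ---------------------------------------------------------------------------
# Platform agreement
# ---------------------------------------------------------------------------

_PLATFORM_COLUMNS = {
    ("snp", "chr3"): "snp_chr3", ("dpcr", "chr3"): "dpcr_chr3",
    ("karyotype", "chr3"): "karyotype_chr3",
    ("snp", "8q"): "snp_8q", ("dpcr", "8q"): "dpcr_8q",
    ("karyotype", "8q"): "karyotype_chr8",
}


def platform_correlation(
    records: list[TumourRecord],
    platform_a: str,
    platform_b: str,
    locus: str,
    karyotype_sign: float = -1.0,
) -> CorrelationResult:
    """Pearson correlation between two platforms at one locus.

    Karyotype columns are ordinal codes, not copy numbers; they are only
    used when explicitly requested, mapped through ``karyotype_sign``
    (default -1: higher code = more aberrant = lower chr3 copy number,
    so a negative sign restores a positive correlation).  Pairs with a
    missing value on either side are dropped.
    """
    cols = []
    for platform in (platform_a, platform_b):
        key = (platform.lower(), locus)
        if key not in _PLATFORM_COLUMNS:
            raise ValueError(f"unknown platform/locus combination {key}")
        cols.append(_PLATFORM_COLUMNS[key])
    values = []
    for col, platform in zip(cols, (platform_a, platform_b)):
        v = np.array([getattr(r, col) if getattr(r, col) is not None else np.nan
                      for r in records], dtype=float)
        if platform.lower() == "karyotype":
            v = karyotype_sign * v
        values.append(v)
    a, b = values
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one platform's values")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(a.size))


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence(profiles: list[TumourProfile]) -> CooccurrenceTable:
    """Tabulate chromosome-3 status against 8q dosage class."""
    usable = [p for p in profiles if p.classifiable]
    counts = {(c3, q): 0 for c3 in CHR3_LEVELS for q in CN8Q_LEVELS}
    for p in usable:
        q = p.cn8q_class if p.cn8q_class != "loss" else "normal"
        key = (p.chr3_status, q)
        if key not in counts:
            raise ValueError(f"unexpected profile classes {key}")
        counts[key] += 1
    mono_ab = counts[("monosomy", "gain")] + counts[("monosomy", "amplification")]
    di_ab = counts[("disomy", "gain")] + counts[("disomy", "amplification")]
    return CooccurrenceTable(
        counts=counts,
        n_total=len(usable),
        monosomy3_with_8q_aberration=mono_ab,
        monosomy3_with_normal_chr8=counts[("monosomy", "normal")],
        disomy3_with_8q_aberration=di_ab,
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _records_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no survival records")
    return pd.DataFrame({
        "months": [r.months for r in records],
        "event": [int(r.event) for r in records],
        "group": [r.group for r in records],
    })


def km_fit(records: list[SurvivalRecord]) -> SurvivalFit:
    """Kaplan–Meier product-limit curves per group.

    Groups with subjects but no events yield a flat curve; at least one
    event overall is required.
    """
    df = _records_frame(records)
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    curves, sizes = {}, {}
    for group, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["months"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[group] = (sf.index.to_numpy(dtype=float),
                         sf.iloc[:, 0].to_numpy(dtype=float))
        sizes[group] = int(len(sub))
    return SurvivalFit(curves=curves, group_sizes=sizes)


def logrank(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Log-rank test across all groups (observed vs expected events)."""
    df = _records_frame(records)
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    if any(df.loc[df.group == g, "event"].sum() == 0 for g in groups) and \
            df["event"].sum() == 0:
        raise ValueError("log-rank needs events")
    if len(groups) == 2:
        a = df[df.group == groups[0]]
        b = df[df.group == groups[1]]
        res = _ll_logrank(a["months"], b["months"],
                          event_observed_A=a["event"], event_observed_B=b["event"])
    else:
        res = multivariate_logrank_test(df["months"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    records: list[SurvivalRecord],
    reference_group: str | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Cox proportional-hazards ratios for each group vs the reference.

    Ties are handled with the Efron approximation (lifelines' default).
    Returns {group: (HR, ci_low, ci_high)}; non-convergence raises with
    lifelines' diagnostics attached.
    """
    df = _records_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("Cox regression needs at least two groups")
    ref = reference_group if reference_group is not None else groups[0]
    if ref not in groups:
        raise ValueError(f"reference group {ref!r} not present")
    design = pd.get_dummies(df["group"], dtype=float).drop(columns=[ref])
    data = pd.concat([df[["months", "event"]], design], axis=1)
    cph = CoxPHFitter()
    cph.fit(data, duration_col="months", event_col="event")
    out = {}
    ci = cph.confidence_intervals_
    for g in design.columns:
        hr = float(np.exp(cph.params_[g]))
        lo = float(np.exp(ci.loc[g].iloc[0]))
        hi = float(np.exp(ci.loc[g].iloc[1]))
        out[f"{g}_vs_{ref}"] = (hr, lo, hi)
    return out


def survival_report(records: list[SurvivalRecord]) -> SurvivalFit:
    """KM curves plus log-rank and Cox contrasts in one bundle."""
    fit = km_fit(records)
    stat, p = logrank(records)
    hrs = cox_hr(records)
    return SurvivalFit(
        curves=fit.curves, group_sizes=fit.group_sizes,
        logrank_statistic=stat, logrank_p=p, hazard_ratios=hrs,
    )
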