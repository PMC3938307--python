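"""Per-sample iCNA burden and clinicopathological correlates.

Burden is the count of final (post-funnel) intragenic events per tumour
sample.  Samples split into three groups — ``none`` (zero events),
``high`` (strictly more than ``high_cutoff`` events) and ``rest`` — and
the groups are compared on overall survival by Kaplan-Meier estimation
with a k-group log-rank test.  Covariate comparisons use Welch's t for
two groups (Student's by flag) and one-way ANOVA for three or more;
samples with unknown covariate values are excluded from the comparison,
never dropped from the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .io_formats import ClinicalTable, ConfigError

logger = logging.getLogger("icna")

DEFAULT_HIGH_CUTOFF = 10

GROUP_NONE = "none"
GROUP_HIGH = "high"
GROUP_REST = "rest"


@dataclass
class BurdenTable:
    """sample_id, n_icna, burden_group for every tumour sample."""

    data: pd.DataFrame
    high_cutoff: int = DEFAULT_HIGH_CUTOFF

    def __post_init__(self):
        assert {"sample_id", "n_icna", "burden_group"} <= set(self.data.columns)
        assert (self.data["n_icna"] >= 0).all()

    def group_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        return row["burden_group"].iloc[0]


@dataclass
class GroupComparison:
    covariate: str
    test: str
    statistic: float
    p: float
    groups: pd.DataFrame  # group, n, median, min, max


@dataclass
class SurvivalResult:
    chi2: float
    p: float
    df: int
    medians: dict[str, float]       # group -> median months (inf = not reached)
    group_sizes: dict[str, int]
    km_curves: pd.DataFrame         # group, time, survival


def burden_group(n: int, high_cutoff: int = DEFAULT_HIGH_CUTOFF) -> str:
    if n == 0:
        return GROUP_NONE
    return GROUP_HIGH if n > high_cutoff else GROUP_REST


def count_events_per_sample(final_events, samples: list[str],
                            high_cutoff: int = DEFAULT_HIGH_CUTOFF) -> BurdenTable:
    """Complete burden table over all tumour samples (zeros included)."""
    counts = {s: 0 for s in samples}
    for ev in final_events:
        if ev.sample_id in counts:
            counts[ev.sample_id] += 1
    df = pd.DataFrame(
        {
            "sample_id": list(samples),
            "n_icna": [counts[s] for s in samples],
        }
    )
    df["burden_group"] = [burden_group(n, high_cutoff) for n in df["n_icna"]]
    logger.info(
        "iCNA burden: median=%.1f range=%d-%d over %d samples",
        df["n_icna"].median(), df["n_icna"].min(), df["n_icna"].max(), len(df),
    )
    return BurdenTable(df, high_cutoff=high_cutoff)


def compare_groups(burden: BurdenTable, clinical: ClinicalTable, covariate: str,
                   test: str = "auto", equal_var: bool = False) -> GroupComparison:
    """Compare iCNA burden across the levels of a clinical covariate.

    Two levels -> Welch's t-test (Student's with ``equal_var=True``);
    three or more -> one-way ANOVA.  ``unknown`` levels are excluded.
    """
    merged = burden.data.merge(clinical.data, on="sample_id", how="inner")
    col = merged[covariate]
    if col.dtype == bool or set(col.dropna().unique()) <= {True, False}:
        col = col.map({True: "yes", False: "no"})
    merged = merged.assign(_level=col.astype(str))
    merged = merged[merged["_level"] != "unknown"]
    levels = sorted(merged["_level"].unique())
    if len(levels) < 2:
        raise ConfigError(f"covariate {covariate!r} has fewer than 2 known levels")
    values = [merged.loc[merged["_level"] == lv, "n_icna"].to_numpy(dtype=float) for lv in levels]
    for lv, v in zip(levels, values):
        if len(v) < 2:
            raise ConfigError(f"group {lv!r} of covariate {covariate!r} has n < 2")
    if len(levels) == 2:
        if test not in ("auto", "welch_t", "student_t"):
            raise ConfigError(f"test {test!r} invalid for 2 groups")
        ev = equal_var or test == "student_t"
        stat, p = sps.ttest_ind(values[0], values[1], equal_var=ev)
        used = "student_t" if ev else "welch_t"
    else:
        if test not in ("auto", "anova"):
            raise ConfigError(f"test {test!r} invalid for {len(levels)} groups")
        stat, p = sps.f_oneway(*values)
        used = "anova"
    summary = pd.DataFrame(
        {
            "group": levels,
            "n": [len(v) for v in values],
            "median": [float(np.median(v)) for v in values],
            "min": [float(v.min()) for v in values],
            "max": [float(v.max()) for v in values],
        }
    )
    return GroupComparison(covariate, used, float(stat), float(p), summary)


def survival_stratification(burden: BurdenTable, clinical: ClinicalTable,
                            high_cutoff: int | None = None) -> SurvivalResult:
    """Kaplan-Meier curves and log-rank test across burden groups.

    Median survival uses the step-function convention (first time the
    KM estimate drops to <= 0.5); a group whose estimate never reaches
    0.5 reports ``inf`` (not reached).
    """
    df = burden.data.merge(clinical.data, on="sample_id", how="inner")
    if high_cutoff is not None and high_cutoff != burden.high_cutoff:
        df = df.assign(burden_group=[burden_group(n, high_cutoff) for n in df["n_icna"]])
    df = df.dropna(subset=["os_months", "os_event"])
    if df.empty:
        raise ConfigError("no samples with survival data")
    groups = sorted(df["burden_group"].unique())
    lr = multivariate_logrank_test(df["os_months"], df["burden_group"],
                                   df["os_event"].astype(bool))
    medians: dict[str, float] = {}
    sizes: dict[str, int] = {}
    curves = []
    for g in groups:
        sub = df[df["burden_group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["os_event"].astype(bool), label=g)
        medians[g] = float(kmf.median_survival_time_)
        sizes[g] = len(sub)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", g)
        curves.append(sf)
    return SurvivalResult(
        chi2=float(lr.test_statistic),
        p=float(lr.p_value),
        df=len(groups) - 1,
        medians=medians,
        group_sizes=sizes,
        km_curves=pd.concat(curves, ignore_index=True),
    )
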