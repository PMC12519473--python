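"""QA/QC reduction and treatment/control statistics for congener tables.

Implements the measurement side of the study: blank-based limits of
quantification (LOQ), censoring of sub-LOQ masses to zero, surrogate
recovery correction within homologue groups, aggregation to total /
LC-PCB / homologue sums, percent differences between group means, and
per-time-point t-tests on log10-transformed masses.

The canonical reduction order is censor → surrogate-correct → aggregate;
reversing censor and correct changes results (correction can push a
sub-LOQ mass above the LOQ), so the order is pinned here and regression-
tested.

A congener table is a tidy pandas DataFrame with columns
``experiment_id, day, replicate, group, matrix, peak_id, mass_ng``
(PUF masses in ng per PUF, SPME in ng per cm of fiber), one row per
(sample, peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .congener_registry import Congener, registry_by_peak

__all__ = [
    "BlankSet",
    "GroupComparison",
    "SurrogateRecovery",
    "TABLE_COLUMNS",
    "aggregate_sums",
    "censor_below_loq",
    "compare_time_point",
    "compute_loq",
    "percent_difference",
    "reduce_table",
    "surrogate_correct",
    "validate_table",
]

TABLE_COLUMNS = (
    "experiment_id",
    "day",
    "replicate",
    "group",
    "matrix",
    "peak_id",
    "mass_ng",
)

GROUPS = ("control", "treatment")
MATRICES = ("PUF", "SPME")

#: two-sided 95% normal quantile used in the blank-based LOQ
LOQ_Z = 1.96


class PipelineError(ValueError):
    """Invalid table, blank set or comparison request."""


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the congener-table contract; returns the table unchanged."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise PipelineError(f"table missing columns {missing}")
    if len(table) and (table["mass_ng"] < 0).any():
        bad = table.loc[table["mass_ng"] < 0].iloc[0]
        raise PipelineError(
            f"negative mass for peak {bad['peak_id']} day {bad['day']}"
        )
    keys = list(TABLE_COLUMNS[:-1])
    if table.duplicated(subset=keys).any():
        raise PipelineError("duplicate (experiment, day, replicate, group, "
                            "matrix, peak) records")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise PipelineError(f"unknown group labels {sorted(bad_group)}")
    return table


@dataclass(frozen=True)
class BlankSet:
    """Laboratory blanks for one matrix: per-peak lists of blank masses
    (ng per PUF, ng/cm for SPME). The study used n=19 PUF and n=3 SPME
    blanks."""

    matrix: str
    masses: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for peak, vals in self.masses.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2:
                raise PipelineError(
                    f"blank set for {peak}: need >= 2 blanks, got {arr.size}"
                )
            if (arr < 0).any():
                raise PipelineError(f"blank set for {peak}: negative mass")


@dataclass(frozen=True)
class SurrogateRecovery:
    """Fractional surrogate recovery for one homologue group (e.g. 0.64
    for 64%); masses are divided by it."""

    homologue: int
    recovery: float

    def __post_init__(self) -> None:
        if not 0 < self.recovery <= 1.5:
            raise PipelineError(
                f"recovery for homologue {self.homologue} must be in "
                f"(0, 1.5], got {self.recovery}"
            )


def compute_loq(blanks: BlankSet, sd_over_sqrt_n: bool = False) -> dict[str, float]:
    """Per-peak limit of quantification from laboratory blanks.

    LOQ = mean(blanks) + 1.96 * SD(blanks), the one-sided 95% bound on a
    single blank measurement (sample SD, ddof=1). ``sd_over_sqrt_n``
    switches to the standard-error variant (mean + 1.96 * SD/sqrt(n)) for
    workflows that treat the LOQ as a bound on the blank mean.
    """
    out: dict[str, float] = {}
    for peak, vals in blanks.masses.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1))
        if sd_over_sqrt_n:
            sd /= np.sqrt(arr.size)
        out[peak] = float(arr.mean()) + LOQ_Z * sd
    return out


def censor_below_loq(
    table: pd.DataFrame, loq: Mapping[str, float]
) -> pd.DataFrame:
    """Replace masses strictly below their peak's LOQ with zero.

    A mass exactly equal to the LOQ is retained. Idempotent. Every peak
    in the table must have an LOQ.
    """
    validate_table(table)
    missing = set(table["peak_id"]) - set(loq)
    if missing:
        raise PipelineError(f"no LOQ for peaks {sorted(missing)}")
    out = table.copy()
    limits = out["peak_id"].map(loq).to_numpy(dtype=float)
    mass = out["mass_ng"].to_numpy(dtype=float)
    out["mass_ng"] = np.where(mass < limits, 0.0, mass)
    return out


def surrogate_correct(
    table: pd.DataFrame,
    recoveries: Iterable[SurrogateRecovery],
    congeners: Iterable[Congener],
) -> pd.DataFrame:
    """Divide each peak's mass by its homologue's surrogate recovery."""
    validate_table(table)
    registry = registry_by_peak(congeners)
    rec = {r.homologue: r.recovery for r in recoveries}
    unknown = set(table["peak_id"]) - set(registry)
    if unknown:
        raise PipelineError(f"peaks not in registry: {sorted(unknown)}")
    homologues = {registry[p].homologue for p in set(table["peak_id"])}
    missing = homologues - set(rec)
    if missing:
        raise PipelineError(
            f"no surrogate recovery for homologues {sorted(missing)}"
        )
    out = table.copy()
    factor = out["peak_id"].map(
        {p: rec[registry[p].homologue] for p in set(out["peak_id"])}
    )
    out["mass_ng"] = out["mass_ng"] / factor.to_numpy(dtype=float)
    return out


def aggregate_sums(
    table: pd.DataFrame, congeners: Iterable[Congener]
) -> pd.DataFrame:
    """Per-sample sums: total PCBs, LC-PCBs (≤3 Cl) and per-homologue.

    Returns a long table with ``aggregate`` in {"total", "lc",
    "cl<k>"} and the summed ``mass_ng`` per (experiment_id, day,
    replicate, group, matrix).
    """
    validate_table(table)
    registry = registry_by_peak(congeners)
    unknown = set(table["peak_id"]) - set(registry)
    if unknown:
        raise PipelineError(f"peaks not in registry: {sorted(unknown)}")
    df = table.copy()
    df["homologue"] = df["peak_id"].map(lambda p: registry[p].homologue)
    df["is_lc"] = df["peak_id"].map(lambda p: registry[p].is_lc)
    keys = ["experiment_id", "day", "replicate", "group", "matrix"]
    pieces = []
    total = df.groupby(keys, as_index=False)["mass_ng"].sum()
    total["aggregate"] = "total"
    pieces.append(total)
    lc = (
        df.assign(mass_ng=df["mass_ng"].where(df["is_lc"], 0.0))
        .groupby(keys, as_index=False)["mass_ng"]
        .sum()
    )
    lc["aggregate"] = "lc"
    pieces.append(lc)
    homo = df.groupby(keys + ["homologue"], as_index=False)["mass_ng"].sum()
    homo["aggregate"] = homo.pop("homologue").map(lambda h: f"cl{h}")
    pieces.append(homo)
    out = pd.concat(pieces, ignore_index=True)
    return out[keys + ["aggregate", "mass_ng"]]


def reduce_table(
    table: pd.DataFrame,
    loq: Mapping[str, float],
    recoveries: Iterable[SurrogateRecovery],
    congeners: Iterable[Congener],
) -> pd.DataFrame:
    """Canonical QA/QC reduction: censor → surrogate-correct → aggregate."""
    censored = censor_below_loq(table, loq)
    corrected = surrogate_correct(censored, recoveries, congeners)
    return aggregate_sums(corrected, congeners)


def percent_difference(control_mean: float, treatment_mean: float) -> float:
    """Signed percent change of the treatment relative to the control.

    ``(control - treatment) / control * 100``; positive values are
    decreases. Reported values are conventionally rounded to the nearest
    integer percent.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    if treatment_mean < 0:
        raise ValueError("treatment mean must be >= 0")
    return (control_mean - treatment_mean) / control_mean * 100.0


@dataclass(frozen=True)
class GroupComparison:
    """Treatment-vs-control comparison of one aggregate at one day."""

    day: float
    matrix: str
    aggregate: str
    mean_control: float
    sd_control: float
    mean_treatment: float
    sd_treatment: float
    percent_difference: float
    t_statistic: float
    p_value: float
    significant: bool
    pairing: str
    censor_dominated: bool
    degenerate: bool

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise PipelineError("p_value outside [0, 1]")


def _log_eps(values: np.ndarray) -> float:
    """Half the smallest positive mass in the comparison set; 0 if all
    masses are positive (no offset needed)."""
    positive = values[values > 0]
    if positive.size == 0 or positive.size == values.size:
        return 0.0 if positive.size else 1.0
    return float(positive.min()) / 2.0


def compare_time_point(
    aggregated: pd.DataFrame,
    day: float,
    aggregate: str,
    matrix: str,
    pairing: str = "paired",
    alpha: float = 0.05,
) -> GroupComparison:
    """t-test of treatment vs control masses at one sampling day.

    Masses (from :func:`aggregate_sums`) are log10(mass + ε) transformed,
    ε being half the smallest positive mass across both groups (0 when no
    zeros are present). ``pairing="paired"`` pairs replicates by index
    (two-tailed paired t, df = n−1); ``pairing="welch"`` runs Welch's
    two-sample test. Degenerate cases — zero-variance paired differences,
    or all-zero masses — are returned with ``p_value = nan`` and flagged
    rather than raised.
    """
    if pairing not in ("paired", "welch"):
        raise PipelineError("pairing must be 'paired' or 'welch'")
    sel = aggregated[
        (aggregated["day"] == day)
        & (aggregated["aggregate"] == aggregate)
        & (aggregated["matrix"] == matrix)
    ]
    groups = {}
    for g in GROUPS:
        sub = sel[sel["group"] == g].sort_values("replicate")
        if sub.empty:
            raise PipelineError(f"no {g} rows for day={day} {matrix} {aggregate}")
        groups[g] = sub["mass_ng"].to_numpy(dtype=float)
    ctrl, trt = groups["control"], groups["treatment"]
    if pairing == "paired" and ctrl.size != trt.size:
        raise PipelineError("paired comparison needs equal replicate counts")
    both = np.concatenate([ctrl, trt])
    eps = _log_eps(both)
    censor_dominated = bool((both == 0).any())
    log_c = np.log10(ctrl + eps)
    log_t = np.log10(trt + eps)
    degenerate = False
    if pairing == "paired":
        diffs = log_c - log_t
        if np.allclose(diffs.std(ddof=1), 0.0):
            degenerate = True
            t_stat, p = (0.0, 1.0) if np.allclose(diffs, 0.0) else (np.nan, np.nan)
        else:
            t_stat, p = stats.ttest_rel(log_c, log_t)
    else:
        if np.allclose(log_c.std(ddof=1), 0) and np.allclose(log_t.std(ddof=1), 0):
            degenerate = True
            t_stat, p = (0.0, 1.0) if np.allclose(log_c.mean(), log_t.mean()) else (np.nan, np.nan)
        else:
            t_stat, p = stats.ttest_ind(log_c, log_t, equal_var=False)
    mean_c = float(ctrl.mean())
    pd_value = percent_difference(mean_c, float(trt.mean())) if mean_c > 0 else np.nan
    return GroupComparison(
        day=day,
        matrix=matrix,
        aggregate=aggregate,
        mean_control=mean_c,
        sd_control=float(ctrl.std(ddof=1)),
        mean_treatment=float(trt.mean()),
        sd_treatment=float(trt.std(ddof=1)),
        percent_difference=float(pd_value),
        t_statistic=float(t_stat),
        p_value=float(p),
        significant=bool(np.isfinite(p) and p < alpha),
        pairing=pairing,
        censor_dominated=censor_dominated,
        degenerate=degenerate,
    )


def comparison_report(
    aggregated: pd.DataFrame,
    aggregates: Sequence[str] = ("total", "lc"),
    pairing: str = "paired",
) -> pd.DataFrame:
    """All (day, matrix, aggregate) comparisons as one tidy DataFrame."""
    rows = []
    for (day, matrix) in sorted(
        set(zip(aggregated["day"], aggregated["matrix"]))
    ):
        for agg in aggregates:
            if not (
                (aggregated["day"] == day)
                & (aggregated["matrix"] == matrix)
                & (aggregated["aggregate"] == agg)
            ).any():
                continue
            cmp_ = compare_time_point(aggregated, day, agg, matrix, pairing)
            rows.append(vars(cmp_))
    return pd.DataFrame(rows)
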