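"""Luminescence-based GTP-hydrolysis quantification.

In a GTPase-coupled luminescence assay, GTP left unhydrolyzed after the
reaction window is converted to light, so the signal reports *remaining*
GTP: lower RLU means more hydrolysis. The pipeline is fixed as

1. blank correction — subtract the mean of the buffer-only blank wells
   from every condition and standard replicate;
2. percent hydrolysis — 100 · (RLU_std − RLU_replicate) / RLU_std, where
   RLU_std is the mean corrected signal of the no-hydrolysis GTP standard;
3. pairwise significance — two-sample two-tailed t-tests between
   conditions (pooled-variance Student by default, Welch optional), with
   tiers * p<0.05, ** p<0.01, *** p<0.001, ns otherwise.

Values outside [0, 100] % are reported, flagged, and never clamped: they
signal failed wells rather than numerics to hide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataInsufficiencyError

__all__ = [
    "GTPaseExperiment",
    "HydrolysisResult",
    "ComparisonRecord",
    "blank_correct",
    "percent_hydrolysis",
    "significance_tier",
    "analyze",
    "compare_conditions",
]


@dataclass
class GTPaseExperiment:
    """Replicate RLU readings per condition plus blank and standard wells."""

    conditions: dict[str, np.ndarray]
    blanks: np.ndarray
    standard: np.ndarray
    blank_corrected: bool = False
    sub_blank_flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = {
            k: np.asarray(v, dtype=float) for k, v in self.conditions.items()
        }
        self.blanks = np.asarray(self.blanks, dtype=float)
        self.standard = np.asarray(self.standard, dtype=float)
        for label, reps in self.conditions.items():
            if reps.size < 1:
                raise ValueError(f"condition {label!r} has no replicates")
        if self.standard.size < 1:
            raise ValueError("no standard (no-hydrolysis) wells")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GTPaseExperiment":
        """Read ``well_type{blank|standard|sample},condition,replicate,rlu``."""
        df = pd.read_csv(path)
        blanks = df.loc[df["well_type"] == "blank", "rlu"].to_numpy(dtype=float)
        standard = df.loc[df["well_type"] == "standard", "rlu"].to_numpy(dtype=float)
        samples = df[df["well_type"] == "sample"]
        conditions = {
            str(label): grp["rlu"].to_numpy(dtype=float)
            for label, grp in samples.groupby("condition")
        }
        return cls(conditions, blanks, standard)


def blank_correct(exp: GTPaseExperiment) -> GTPaseExperiment:
    """Subtract the mean blank RLU from every condition and standard replicate.

    Corrected values below zero are permitted but flagged per replicate in
    ``sub_blank_flags``.
    """
    if exp.blanks.size == 0:
        raise ValueError("no blank wells to correct with")
    mean_blank = float(exp.blanks.mean())
    conditions = {k: v - mean_blank for k, v in exp.conditions.items()}
    flags = {k: v < 0 for k, v in conditions.items()}
    return replace(
        exp,
        conditions=conditions,
        standard=exp.standard - mean_blank,
        blanks=exp.blanks - mean_blank,
        blank_corrected=True,
        sub_blank_flags=flags,
    )


def percent_hydrolysis(rlu_replicate, rlu_std: float):
    """100 · (RLU_std − RLU_replicate) / RLU_std on blank-corrected RLUs."""
    rlu_std = float(rlu_std)
    if rlu_std <= 0:
        raise ValueError(
            f"standard RLU must be positive after blank correction; got {rlu_std}"
        )
    out = (rlu_std - np.asarray(rlu_replicate, dtype=float)) / rlu_std * 100.0
    return float(out) if out.ndim == 0 else out


def significance_tier(p: float) -> str:
    """Star tier from a p value: * <0.05, ** <0.01, *** <0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonRecord:
    """Pairwise t-test between the % hydrolysis of two conditions."""

    condition_a: str
    condition_b: str
    t_statistic: float
    p_value: float
    tier: str


@dataclass
class HydrolysisResult:
    """Per-condition % hydrolysis with pairwise significance calls."""

    percent: dict[str, np.ndarray]  # replicate % hydrolysis per condition
    summary: pd.DataFrame  # condition, mean, sd, n, any_out_of_range
    comparisons: list[ComparisonRecord]
    test: str
    bonferroni: bool

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_a": [c.condition_a for c in self.comparisons],
                "condition_b": [c.condition_b for c in self.comparisons],
                "t": [c.t_statistic for c in self.comparisons],
                "p": [c.p_value for c in self.comparisons],
                "tier": [c.tier for c in self.comparisons],
            }
        )


def _pairwise_test(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        raise DataInsufficiencyError(
            "need ≥2 replicates per condition for a t-test"
        )
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return float(res.statistic), float(res.pvalue)


def analyze(
    exp: GTPaseExperiment,
    test: str = "student",
    *,
    bonferroni: bool = False,
) -> HydrolysisResult:
    """Full pipeline: blank-correct, % hydrolysis, pairwise significance."""
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    if not exp.blank_corrected:
        exp = blank_correct(exp)
    rlu_std = float(exp.standard.mean())
    percent = {
        label: percent_hydrolysis(reps, rlu_std)
        for label, reps in exp.conditions.items()
    }
    rows = []
    for label, vals in percent.items():
        vals = np.atleast_1d(vals)
        rows.append(
            {
                "condition": label,
                "mean_percent_hydrolysis": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n": int(vals.size),
                "out_of_range": bool(((vals < 0) | (vals > 100)).any()),
            }
        )
    summary = pd.DataFrame(rows)

    labels = list(percent)
    pairs = list(combinations(labels, 2))
    n_pairs = len(pairs)
    comparisons = []
    for a, b in pairs:
        va, vb = np.atleast_1d(percent[a]), np.atleast_1d(percent[b])
        if va.size < 2 or vb.size < 2:
            continue  # pairwise test undefined; per-condition summary stands
        t, p = _pairwise_test(va, vb, test)
        if bonferroni:
            p = min(1.0, p * n_pairs)
        comparisons.append(ComparisonRecord(a, b, t, p, significance_tier(p)))
    return HydrolysisResult(percent, summary, comparisons, test, bonferroni)


def compare_conditions(
    result: HydrolysisResult, pair: tuple[str, str]
) -> ComparisonRecord:
    """Retrieve (or compute) the pairwise comparison for two condition labels."""
    a, b = pair
    for rec in result.comparisons:
        if {rec.condition_a, rec.condition_b} == {a, b}:
            return rec
    if a not in result.percent or b not in result.percent:
        raise KeyError(f"unknown condition in pair {pair!r}")
    va = np.atleast_1d(result.percent[a])
    vb = np.atleast_1d(result.percent[b])
    t, p = _pairwise_test(va, vb, result.test)
    return ComparisonRecord(a, b, t, p, significance_tier(p))
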