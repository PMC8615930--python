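"""Method-agreement statistics for paired distance measurements.

Implements the validation layer used to compare an algorithmic distance
estimate against a reference measurement over many sessions: Bland–Altman
limits of agreement (mean difference ± 1.96 × SD), Pearson's r, a two-way
absolute-agreement single-measure intraclass correlation (ICC(2,1)) with
the Koo–Li interpretation bands, Kendall's τ-b, Welch's t-test, relative
measurement error and its binned distribution.

Differences default to reference − estimate, so a positive mean difference
means the estimator under-reads.  Standard deviations use the n−1 sample
denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "bland_altman",
    "pearson_r",
    "icc_agreement",
    "icc_label",
    "relative_error",
    "bin_errors",
    "kendall_tau_b",
    "two_sample_ttest",
    "weighted_group_mean",
    "compute_report",
    "DEFAULT_BIN_EDGES",
]

Direction = Literal["ref_minus_est", "est_minus_ref"]

#: Relative-error bin edges in percent, half-open [lo, hi) per bin.
DEFAULT_BIN_EDGES = (0.0, 5.0, 10.0, 20.0, np.inf)


@dataclass
class PairedSeries:
    """Per-session paired measurements: reference vs estimate.

    ``covariates`` may carry per-session context (age, disability score,
    aid use, gait parameters) for subgroup or correlation analyses.
    """

    ids: Sequence
    reference_m: np.ndarray
    estimate_m: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reference_m = np.asarray(self.reference_m, dtype=np.float64)
        self.estimate_m = np.asarray(self.estimate_m, dtype=np.float64)
        if len(self.ids) != self.reference_m.size or (
            self.reference_m.size != self.estimate_m.size
        ):
            raise ValueError("ids, reference_m and estimate_m must have equal length")
        if self.reference_m.size < 2:
            raise ValueError("need at least 2 paired sessions")
        if not (
            np.isfinite(self.reference_m).all() and np.isfinite(self.estimate_m).all()
        ):
            raise ValueError("paired series must not contain missing values")

    @property
    def n(self) -> int:
        return int(self.reference_m.size)


@dataclass
class AgreementReport:
    """Bundle of all agreement statistics for one method comparison."""

    n: int
    direction: str
    mean_diff_m: float
    sd_diff_m: float
    loa_low_m: float
    loa_high_m: float
    pearson_r: float
    icc: float
    icc_label: str
    error_stats: dict[str, float]
    bin_table: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _differences(p: PairedSeries, direction: Direction) -> np.ndarray:
    if direction == "ref_minus_est":
        return p.reference_m - p.estimate_m
    if direction == "est_minus_ref":
        return p.estimate_m - p.reference_m
    raise ValueError(f"unknown direction {direction!r}")


def bland_altman(
    p: PairedSeries, direction: Direction = "ref_minus_est"
) -> dict[str, float]:
    """Mean difference, sample SD and 95% limits of agreement.

    LoA = mean ± 1.96 × SD of the paired differences, exactly.
    """
    diff = _differences(p, direction)
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "mean_diff": mean,
        "sd_diff": sd,
        "loa_low": mean - 1.96 * sd,
        "loa_high": mean + 1.96 * sd,
    }


def pearson_r(p: PairedSeries) -> float:
    """Product-moment correlation between reference and estimate."""
    if p.n < 3:
        raise ValueError("pearson_r needs n >= 3")
    if np.std(p.reference_m) == 0 or np.std(p.estimate_m) == 0:
        raise ValueError("pearson_r undefined for a zero-variance series")
    return float(stats.pearsonr(p.reference_m, p.estimate_m).statistic)


def icc_label(icc: float) -> str:
    """Koo–Li interpretation band for an ICC value.

    ≥ 0.90 excellent, ≥ 0.75 good, ≥ 0.50 moderate, below poor (each band
    closed on the left at its lower boundary).
    """
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def icc_agreement(p: PairedSeries) -> dict:
    """Two-way absolute-agreement single-measure ICC (ICC(2,1)).

    Computed from the two-rater ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with k = 2 raters (reference, estimate).  Absolute agreement penalises a
    systematic offset between the methods, unlike Pearson's r.  If every
    value in both series is identical the ICC is defined as 1.
    """
    if p.n < 3:
        raise ValueError("icc_agreement needs n >= 3")
    y = np.column_stack([p.reference_m, p.estimate_m])
    n, k = y.shape
    if np.all(y == y.flat[0]):
        return {"icc": 1.0, "label": "excellent"}
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc = float(icc)
    return {"icc": icc, "label": icc_label(icc)}


def relative_error(
    p: PairedSeries, mode: Literal["absolute", "signed"] = "absolute"
) -> np.ndarray:
    """Per-session relative measurement error in percent of the reference.

    signed = (reference − estimate) / reference × 100; a negative signed
    error therefore means the estimator over-read.  ``absolute`` takes the
    magnitude.  Raises (naming the session) if any reference is zero.
    """
    zero = np.flatnonzero(p.reference_m == 0)
    if zero.size:
        raise ValueError(
            f"zero reference distance for session {p.ids[zero[0]]!r}"
        )
    signed = (p.reference_m - p.estimate_m) / p.reference_m * 100.0
    if mode == "signed":
        return signed
    if mode == "absolute":
        return np.abs(signed)
    raise ValueError(f"unknown mode {mode!r}")


def bin_errors(
    errors_pct: Sequence[float], edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> dict:
    """Histogram of error percentages over half-open bins [e_i, e_{i+1}).

    Counts always sum to n and proportions to 1; values below the first
    edge are a caller error (the default edges start at 0 and expect
    absolute errors).
    """
    errors = np.asarray(errors_pct, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    if errors.size and (errors.min() < edges[0] or errors.max() >= edges[-1]):
        raise ValueError("errors fall outside the binning range")
    idx = np.searchsorted(edges, errors, side="right") - 1
    counts = np.bincount(idx, minlength=edges.size - 1)
    n = int(errors.size)
    proportions = counts / n if n else np.zeros_like(counts, dtype=float)
    labels = [
        f"[{edges[i]:g}, {edges[i + 1]:g})" for i in range(edges.size - 1)
    ]
    return {
        "edges": edges.tolist(),
        "labels": labels,
        "counts": counts.tolist(),
        "proportions": proportions.tolist(),
        "n": n,
    }


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's rank correlation with tie correction (τ-b).

    τb = (C − D) / √((n₀ − n₁)(n₀ − n₂)) over all sample pairs, where n₁
    and n₂ count tied pairs within each variable.  Returns NaN when either
    variable is entirely tied (τ-b undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("kendall_tau_b needs two equal-length series, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
) -> dict[str, float]:
    """Two-sided t-test for a mean difference between independent groups.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance variant for sensitivity checks.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def weighted_group_mean(
    group_means: Sequence[float], group_ns: Sequence[int]
) -> float:
    """Pooled mean Σ nᵢmᵢ / Σ nᵢ of subgroup means weighted by subgroup size."""
    means = np.asarray(group_means, dtype=np.float64)
    ns = np.asarray(group_ns, dtype=np.float64)
    if means.size != ns.size or means.size == 0:
        raise ValueError("group_means and group_ns must be equal-length, non-empty")
    if np.any(ns < 1):
        raise ValueError("group sizes must be >= 1")
    return float(np.average(means, weights=ns))


def compute_report(
    p: PairedSeries,
    direction: Direction = "ref_minus_est",
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> AgreementReport:
    """Assemble the full agreement report for one method comparison."""
    ba = bland_altman(p, direction)
    icc = icc_agreement(p)
    abs_err = relative_error(p, "absolute")
    return AgreementReport(
        n=p.n,
        direction=direction,
        mean_diff_m=ba["mean_diff"],
        sd_diff_m=ba["sd_diff"],
        loa_low_m=ba["loa_low"],
        loa_high_m=ba["loa_high"],
        pearson_r=pearson_r(p),
        icc=icc["icc"],
        icc_label=icc["label"],
        error_stats={
            "mean_pct": float(np.mean(abs_err)),
            "sd_pct": float(np.std(abs_err, ddof=1)),
        },
        bin_table=bin_errors(abs_err, bin_edges),
    )
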