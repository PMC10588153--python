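"""Two-group inference for the morphometric comparison.

The study's sole inferential tool is the unpaired two-sample *t*-test with
pooled (equal) variance and ``df = n1 + n2 - 2`` — the spreadsheet-style
"equal variance" test.  It is implemented twice over the same formulas:
from raw per-specimen values and from printed summary triples
``(mean, SE, n)``, so published group summaries can be re-analysed without
the underlying data.  From a summary triple the group SD is recovered as
``SD = SE * sqrt(n)``, then

.. math::

    s_p^2 = \\frac{(n_1-1)s_1^2 + (n_2-1)s_2^2}{n_1+n_2-2}, \\qquad
    t = \\frac{\\bar x_1 - \\bar x_2}{s_p\\sqrt{1/n_1 + 1/n_2}},

with a two-tailed p-value from the central *t* distribution.

On top of the test sit the study-level procedures: the group comparison
table (one row per morphometric measurement, mean ± SE per group and p),
the circularity-threshold scan that picks the cut-off giving the smallest
two-tailed p for the low-circularity islet density (ties resolved toward
the smaller threshold; no multiple-testing correction, matching the
original procedure — the resulting selection bias is quantified in the
test-suite, not corrected), and the interobserver accuracy statistics with
the size-weighted combined mean and the combined SE recovered from the
total sum of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    DomainError,
    IncompleteSheetError,
    InsufficientDataError,
)
from .morphometry import (
    SUMMARY_MEASUREMENTS,
    SpecimenSummary,
    summaries_to_frame,
    summarize_specimen,
)
from .segmentation import SpecimenRecord

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ThresholdScanResult",
    "RaterSheet",
    "pooled_ttest_from_summary",
    "pooled_ttest_from_values",
    "summarize_values",
    "combine_group_summaries",
    "compare_groups",
    "threshold_scan",
    "DEFAULT_SCAN_GRID",
    "rater_accuracy",
    "rater_group_stats",
    "rater_sheets_from_frame",
]

logger = logging.getLogger(__name__)

#: candidate circularity thresholds scanned by default: 0.50..0.95 step 0.01
DEFAULT_SCAN_GRID = np.round(np.arange(0.50, 0.95 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class GroupSummary:
    """``mean ± SE`` over ``n`` specimens (or raters) for one measurement."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"group needs n >= 2, got n={self.n}")
        if not (self.se >= 0 and np.isfinite(self.se)):
            raise DomainError(f"standard error must be >= 0, got {self.se!r}")

    @property
    def sd(self) -> float:
        """Sample standard deviation recovered as ``SE * sqrt(n)``."""
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class ThresholdScanResult:
    """Outcome of the circularity-threshold scan.

    ``p_values`` aligns with ``grid``; skipped candidates (zero pooled
    variance) carry NaN.  ``selected_threshold`` attains the minimum p,
    ties broken toward the smaller threshold.
    """

    grid: np.ndarray
    p_values: np.ndarray
    selected_threshold: float
    selected_p: float


@dataclass
class RaterSheet:
    """One pathologist's blind answers: ``slide_id -> "ANHH" | "control"``."""

    rater_id: str
    experience: str
    answers: Mapping[str, str] = field(default_factory=dict)


def pooled_ttest_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled two-sample t-test reconstructed from two (mean, SE, n) triples.

    Degenerate input (both SDs zero): equal means give the conventional
    ``t = 0, p = 1``; unequal means leave the statistic undefined and raise
    :class:`DegenerateDataError`.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise DegenerateDataError(
            "zero variance in both groups with unequal means: t undefined"
        )
    t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(min(p, 1.0)))


def summarize_values(x: Sequence[float]) -> GroupSummary:
    """(mean, SE, n) of raw values; SE uses the n−1 sample SD."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    return GroupSummary(
        mean=float(arr.mean()),
        se=float(arr.std(ddof=1) / np.sqrt(arr.size)),
        n=int(arr.size),
    )


def pooled_ttest_from_values(
    x: Sequence[float], y: Sequence[float]
) -> TTestResult:
    """Pooled two-sample t-test on raw values (delegates to the summary form)."""
    return pooled_ttest_from_summary(summarize_values(x), summarize_values(y))


def combine_group_summaries(g1: GroupSummary, g2: GroupSummary) -> GroupSummary:
    """Pool two group summaries into one overall ``mean ± SE`` over N = n1+n2.

    The grand mean is size-weighted; the overall variance is rebuilt from
    the total sum of squares (within-group SS recovered from the SEs plus
    the between-group SS) over ``N - 1``, and the SE divides its square
    root by ``sqrt(N)``.
    """
    n = g1.n + g2.n
    grand = (g1.n * g1.mean + g2.n * g2.mean) / n
    ss_within = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    ss_between = g1.n * (g1.mean - grand) ** 2 + g2.n * (g2.mean - grand) ** 2
    var = (ss_within + ss_between) / (n - 1)
    return GroupSummary(mean=float(grand), se=float(np.sqrt(var / n)), n=n)


def compare_groups(
    summaries: Sequence[SpecimenSummary] | pd.DataFrame,
    group_a: str = "ANHH",
    group_b: str = "control",
    measurements: Sequence[str] = tuple(SUMMARY_MEASUREMENTS),
) -> pd.DataFrame:
    """Comparison table: one row per measurement, group mean ± SE and p.

    Accepts either specimen summaries or the equivalent DataFrame (with a
    ``group`` column).  Requires at least two specimens per group.
    """
    frame = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else summaries_to_frame(summaries)
    )
    rows = []
    for grp in (group_a, group_b):
        if (frame["group"] == grp).sum() < 2:
            raise InsufficientDataError(
                f"group {grp!r} has fewer than 2 specimens"
            )
    for meas in measurements:
        a = summarize_values(frame.loc[frame["group"] == group_a, meas])
        b = summarize_values(frame.loc[frame["group"] == group_b, meas])
        try:
            res = pooled_ttest_from_summary(a, b)
            t, p = res.t, res.p
        except DegenerateDataError:
            t, p = np.nan, np.nan
        rows.append(
            {
                "measurement": meas,
                f"{group_a}_mean": a.mean,
                f"{group_a}_se": a.se,
                f"{group_a}_n": a.n,
                f"{group_b}_mean": b.mean,
                f"{group_b}_se": b.se,
                f"{group_b}_n": b.n,
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def threshold_scan(
    specimens: Sequence[SpecimenRecord],
    grid: Optional[np.ndarray] = None,
    group_a: str = "ANHH",
    group_b: str = "control",
) -> ThresholdScanResult:
    """Scan circularity cut-offs for the most discriminating one.

    For every candidate threshold the per-specimen density of islets with
    circularity strictly below it (count / parenchyma cm²) is recomputed
    and the two groups compared with the pooled t-test; the threshold with
    the smallest two-tailed p is selected, ties toward the smaller value.
    Candidates where both groups have zero variance are skipped with a
    logged warning (NaN in ``p_values``).
    """
    grid = DEFAULT_SCAN_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("empty threshold grid")
    circs = [s.circularities() for s in specimens]
    areas = np.array([s.parenchyma_area_cm2 for s in specimens])
    labels = np.array([s.group for s in specimens])
    in_a, in_b = labels == group_a, labels == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise InsufficientDataError("need >= 2 specimens per group for the scan")
    p_values = np.full(grid.size, np.nan)
    for i, thr in enumerate(grid):
        dens = np.array(
            [np.count_nonzero(c < thr) for c in circs], dtype=float
        ) / areas
        ga, gb = summarize_values(dens[in_a]), summarize_values(dens[in_b])
        if ga.se == 0.0 and gb.se == 0.0:
            logger.warning(
                "threshold %.3f skipped: zero variance in both groups", thr
            )
            continue
        p_values[i] = pooled_ttest_from_summary(ga, gb).p
    if np.all(np.isnan(p_values)):
        raise DegenerateDataError("every candidate threshold was degenerate")
    best = int(np.nanargmin(p_values))  # first minimum = smallest threshold
    return ThresholdScanResult(
        grid=grid,
        p_values=p_values,
        selected_threshold=float(grid[best]),
        selected_p=float(p_values[best]),
    )


def rater_accuracy(sheet: RaterSheet, truth: Mapping[str, str]) -> float:
    """Percentage of slides a rater classified correctly.

    Every slide in ``truth`` must be answered; a missing answer raises
    :class:`IncompleteSheetError`.
    """
    if not truth:
        raise DomainError("empty truth mapping")
    missing = [sid for sid in truth if sid not in sheet.answers]
    if missing:
        raise IncompleteSheetError(
            f"rater {sheet.rater_id!r} missing answers for slides {missing}"
        )
    correct = sum(1 for sid, lab in truth.items() if sheet.answers[sid] == lab)
    return 100.0 * correct / len(truth)


def rater_group_stats(
    g1: GroupSummary, g2: GroupSummary
) -> tuple[GroupSummary, TTestResult]:
    """Combined accuracy summary and between-group test from group summaries.

    Returns the size-weighted overall ``mean ± SE`` (total-sum-of-squares
    reconstruction) and the pooled t-test between the two rater groups.
    """
    return combine_group_summaries(g1, g2), pooled_ttest_from_summary(g1, g2)


def rater_group_stats_from_rates(
    rates_by_group: Mapping[str, Sequence[float]],
) -> tuple[dict[str, GroupSummary], GroupSummary, TTestResult]:
    """Per-group, combined and between-group statistics from raw rates."""
    if len(rates_by_group) != 2:
        raise DomainError("expected exactly two experience groups")
    (k1, v1), (k2, v2) = rates_by_group.items()
    g1, g2 = summarize_values(v1), summarize_values(v2)
    combined, test = rater_group_stats(g1, g2)
    return {k1: g1, k2: g2}, combined, test


def rater_sheets_from_frame(frame: pd.DataFrame) -> list[RaterSheet]:
    """Parse the long-format rater CSV (rater_id, experience, slide_id, answer)."""
    required = {"rater_id", "experience", "slide_id", "answer"}
    if not required.issubset(frame.columns):
        raise DomainError(f"rater sheet CSV needs columns {sorted(required)}")
    sheets = []
    for (rid, exp), sub in frame.groupby(["rater_id", "experience"], sort=False):
        sheets.append(
            RaterSheet(
                rater_id=str(rid),
                experience=str(exp),
                answers=dict(zip(sub["slide_id"].astype(str), sub["answer"])),
            )
        )
    return sheets
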