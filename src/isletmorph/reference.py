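"""Published group-level summary statistics used as analysis inputs.

The original study deposited no per-islet or per-rater data; what it
printed are group summaries (mean ± standard error, n) for each
morphometric measurement and for the interobserver accuracy rates.  Those
triples are sufficient input for the pooled-variance t-test
(:func:`isletmorph.stats.pooled_ttest_from_summary`) and for the combined
accuracy reconstruction, so they are shipped here as data.

``TABLE3_SUMMARIES`` maps each measurement name (the same names used by
:mod:`isletmorph.morphometry`) to its ``(ANHH, control)`` pair of
:class:`~isletmorph.stats.GroupSummary` objects, with n = 4 ANHH and
n = 5 control specimens.  ``INTEROBSERVER_SUMMARIES`` holds the blind-test
correct-diagnosis rates (percent) for the 5 experienced and 7
less-experienced pathologists.  ``PARENCHYMA_AREA_CM2`` holds the mean ±
SE cross-sectional parenchyma areas per group.
"""

from __future__ import annotations

from .stats import GroupSummary

__all__ = [
    "TABLE3_SUMMARIES",
    "INTEROBSERVER_SUMMARIES",
    "PARENCHYMA_AREA_CM2",
]

TABLE3_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "n_islets": (GroupSummary(417.0, 67.8, 4), GroupSummary(501.0, 90.0, 5)),
    "n_islets_per_cm2": (GroupSummary(211.0, 38.6, 4), GroupSummary(200.0, 25.4, 5)),
    "total_islet_area_cm2": (
        GroupSummary(0.0403, 0.0119, 4),
        GroupSummary(0.0474, 0.00916, 5),
    ),
    "islet_area_fraction_pct": (
        GroupSummary(2.07, 0.661, 4),
        GroupSummary(1.92, 0.315, 5),
    ),
    "mean_max_diameter_um": (
        GroupSummary(107.0, 14.0, 4),
        GroupSummary(105.0, 8.97, 5),
    ),
    "n_low_circularity": (GroupSummary(82.0, 19.0, 4), GroupSummary(30.0, 5.71, 5)),
}

INTEROBSERVER_SUMMARIES: dict[str, GroupSummary] = {
    "experienced": GroupSummary(47.5, 6.12, 5),
    "less_experienced": GroupSummary(50.0, 8.63, 7),
}

PARENCHYMA_AREA_CM2: dict[str, GroupSummary] = {
    "ANHH": GroupSummary(1.99, 0.0829, 4),
    "control": GroupSummary(2.47, 0.277, 5),
}
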