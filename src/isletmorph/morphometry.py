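"""Per-specimen summaries and cytology fractions.

Each specimen (one representative pancreatic section) is reduced to the
row of quantities the comparative analysis works with: islet count, count
per cm² of parenchyma, total islet area (cm²) and its percentage of the
parenchyma, the mean maximum islet diameter, the number of islets with
circularity below the diagnostic threshold (default 0.71) raw and per cm²,
and the number of "islet clusters" (area > 100,000 µm²).

Boundary conventions follow the printed inequalities exactly: the
low-circularity count uses strict ``<``, the cluster flag strict ``>``,
the cytology measurement cut-offs (nucleus >= 9 µm, nucleolus >= 1.5 µm)
are inclusive while the diagnostic-criteria flags (nucleus > 15 µm,
nucleolus > 5 µm) are exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .segmentation import CLUSTER_AREA_UM2, UM2_PER_CM2, SpecimenRecord

__all__ = [
    "SpecimenSummary",
    "CytologySample",
    "CytologySummary",
    "DEFAULT_CIRCULARITY_THRESHOLD",
    "summarize_specimen",
    "flag_clusters",
    "summarize_cytology",
    "summaries_to_frame",
    "SUMMARY_MEASUREMENTS",
]

#: circularity threshold adopted for the low-circularity islet count
DEFAULT_CIRCULARITY_THRESHOLD = 0.71

#: measurement columns of the per-specimen summary table, in report order
SUMMARY_MEASUREMENTS = [
    "n_islets",
    "n_islets_per_cm2",
    "total_islet_area_cm2",
    "islet_area_fraction_pct",
    "mean_max_diameter_um",
    "n_low_circularity",
    "n_low_circularity_per_cm2",
]


@dataclass(frozen=True)
class SpecimenSummary:
    """One specimen's row of derived morphometric quantities."""

    specimen_id: str
    group: str
    n_islets: int
    n_islets_per_cm2: float
    total_islet_area_cm2: float
    islet_area_fraction_pct: float
    mean_max_diameter_um: float
    n_low_circularity: int
    n_low_circularity_per_cm2: float
    n_clusters: int


@dataclass(frozen=True)
class CytologySample:
    """Cell-level measurements of one representative islet.

    ``nucleus_diameters_um`` lists the measured nuclear diameters;
    ``nucleolus_diameters_um`` lists diameters only for cells whose
    nucleolus was visible at all (absent entries mean none was seen).
    """

    islet_area_um2: float
    n_cells: int
    nucleus_diameters_um: Sequence[float]
    nucleolus_diameters_um: Sequence[float]


@dataclass(frozen=True)
class CytologySummary:
    avg_cell_size_um2: float
    pct_enlarged_nuclei: float
    pct_recognizable_nucleoli: float
    flag_enlarged_nucleus_15: bool
    flag_macronucleoli_5: bool


def summarize_specimen(
    s: SpecimenRecord,
    circ_threshold: float = DEFAULT_CIRCULARITY_THRESHOLD,
    cluster_threshold_um2: float = CLUSTER_AREA_UM2,
) -> SpecimenSummary:
    """Reduce one specimen to its summary row.

    Total islet area is summed in µm² and reported in cm² (divided by 1e8
    exactly); the area fraction is that total as a percentage of the
    parenchyma area; densities divide counts by the parenchyma area.  An
    empty islet list is valid and yields zeros (mean diameter 0.0).
    """
    areas_um2 = np.array([r.metrics.area for r in s.islets], dtype=float)
    ferets = np.array([r.metrics.max_feret for r in s.islets], dtype=float)
    circs = s.circularities()
    pa = s.parenchyma_area_cm2
    n = len(s.islets)
    total_cm2 = float(areas_um2.sum()) / UM2_PER_CM2
    n_low = int(np.count_nonzero(circs < circ_threshold))
    return SpecimenSummary(
        specimen_id=s.specimen_id,
        group=s.group,
        n_islets=n,
        n_islets_per_cm2=n / pa,
        total_islet_area_cm2=total_cm2,
        islet_area_fraction_pct=100.0 * total_cm2 / pa,
        mean_max_diameter_um=float(ferets.mean()) if n else 0.0,
        n_low_circularity=n_low,
        n_low_circularity_per_cm2=n_low / pa,
        n_clusters=flag_clusters(s, cluster_threshold_um2),
    )


def flag_clusters(
    s: SpecimenRecord, cluster_threshold_um2: float = CLUSTER_AREA_UM2
) -> int:
    """Count islets whose area strictly exceeds the cluster cut-off."""
    return sum(1 for r in s.islets if r.metrics.area > cluster_threshold_um2)


def summarize_cytology(
    samples: Sequence[CytologySample],
    nucleus_cutoff_um: float = 9.0,
    nucleolus_cutoff_um: float = 1.5,
    flag_nucleus_um: float = 15.0,
    flag_nucleolus_um: float = 5.0,
) -> CytologySummary:
    """Summarise the cytology of (typically three) representative islets.

    Average cell size is ``islet_area / n_cells`` in µm² per cell, averaged
    over the samples.  The enlarged-nucleus percentage counts measured
    nuclei with diameter >= the cut-off among all measured nuclei; the
    recognizable-nucleolus percentage counts cells with a recorded
    nucleolus diameter >= the cut-off among all cells.  The two diagnostic
    flags fire when any single nucleus (resp. nucleolus) strictly exceeds
    15 µm (resp. 5 µm).
    """
    if not samples:
        raise DomainError("at least one cytology sample is required")
    sizes, nuclei, nucleoli, n_cells_total = [], [], [], 0
    for s in samples:
        if s.n_cells < 1:
            raise DomainError("cytology sample with zero cells")
        if not (s.islet_area_um2 > 0):
            raise DomainError("cytology sample with non-positive islet area")
        sizes.append(s.islet_area_um2 / s.n_cells)
        nuclei.extend(float(d) for d in s.nucleus_diameters_um)
        nucleoli.extend(float(d) for d in s.nucleolus_diameters_um)
        n_cells_total += int(s.n_cells)
    nuclei_arr = np.array(nuclei, dtype=float)
    nucleoli_arr = np.array(nucleoli, dtype=float)
    if np.any(nuclei_arr <= 0) or np.any(nucleoli_arr <= 0):
        raise DomainError("diameters must be positive")
    pct_enlarged = (
        100.0 * np.count_nonzero(nuclei_arr >= nucleus_cutoff_um) / len(nuclei_arr)
        if len(nuclei_arr)
        else 0.0
    )
    pct_nucleoli = (
        100.0 * np.count_nonzero(nucleoli_arr >= nucleolus_cutoff_um) / n_cells_total
    )
    return CytologySummary(
        avg_cell_size_um2=float(np.mean(sizes)),
        pct_enlarged_nuclei=float(pct_enlarged),
        pct_recognizable_nucleoli=float(pct_nucleoli),
        flag_enlarged_nucleus_15=bool(np.any(nuclei_arr > flag_nucleus_um)),
        flag_macronucleoli_5=bool(np.any(nucleoli_arr > flag_nucleolus_um)),
    )


def summaries_to_frame(summaries: Sequence[SpecimenSummary]) -> pd.DataFrame:
    """Summary table: one row per specimen, measurement columns in report order."""
    return pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "group": s.group,
                **{m: getattr(s, m) for m in SUMMARY_MEASUREMENTS},
                "n_clusters": s.n_clusters,
            }
            for s in summaries
        ]
    )
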