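"""From images to per-specimen islet measurement sets.

This module covers the bookkeeping between raw rasters and the morphometry
layer: thresholding a single-channel (e.g. insulin-like) image into a label
mask, extracting one measurement record per islet, and converting a binary
tissue mask into the parenchyma area that normalises islet densities.

Conventions (fixed across the package): islet components are 8-connected,
background is 4-connected, holes inside an islet are filled before
measurement, and parenchyma areas are reported in cm² with
``1 cm² = 1e8 µm²`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .errors import DomainError, NoForegroundError, ZeroAreaError
from .geometry import LabelMask, ShapeMetrics, raster_metrics

__all__ = [
    "IsletRecord",
    "SpecimenRecord",
    "UM2_PER_CM2",
    "CLUSTER_AREA_UM2",
    "extract_islets",
    "segment_channel",
    "parenchyma_area",
    "islets_to_frame",
    "ISLET_CSV_COLUMNS",
]

#: exact unit conversion used everywhere areas change scale
UM2_PER_CM2 = 1e8

#: "islet cluster" cut-off: extremely large islets with area above this
#: (in µm²) occur even in normal pancreas and are flagged, not excluded
CLUSTER_AREA_UM2 = 100_000.0

#: fixed column names and order of the per-islet CSV interchange format
ISLET_CSV_COLUMNS = [
    "specimen_id",
    "islet_id",
    "area_um2",
    "perimeter_um",
    "max_feret_um",
    "circularity",
    "touches_border",
    "is_cluster",
]


@dataclass(frozen=True)
class IsletRecord:
    """One measured islet: geometry plus analysis flags."""

    islet_id: int
    metrics: ShapeMetrics
    touches_border: bool = False
    is_cluster: bool = False


@dataclass
class SpecimenRecord:
    """One slide: group label, parenchyma area and its measured islets.

    ``group`` is ``"ANHH"`` or ``"control"``; ``parenchyma_area_cm2`` is the
    cross-sectional pancreatic tissue area of the section; ``mpp`` is kept
    for raster-born specimens and ``None`` for polygon-born (synthetic
    vector) ones.
    """

    specimen_id: str
    group: str
    parenchyma_area_cm2: float
    islets: list[IsletRecord] = field(default_factory=list)
    mpp: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.parenchyma_area_cm2 > 0):
            raise ZeroAreaError(
                f"parenchyma area must be positive, got {self.parenchyma_area_cm2!r}"
            )

    def circularities(self) -> np.ndarray:
        return np.array([r.metrics.circularity for r in self.islets], dtype=float)


def extract_islets(
    mask: LabelMask,
    min_area_um2: Optional[float] = None,
    cluster_threshold_um2: float = CLUSTER_AREA_UM2,
) -> list[IsletRecord]:
    """Measure every labelled component of a mask into islet records.

    Islets of any size enter the analysis in principle; on rasters a small
    default floor of 5 pixels (``5 * mpp**2`` µm², overridable down to one
    pixel) guards against segmentation speckle.  Components touching the
    image border are included but flagged ``touches_border`` so callers can
    exclude them.  An empty mask yields an empty list, not an error.
    """
    if min_area_um2 is None:
        min_area_um2 = 5 * mask.mpp**2
    records: list[IsletRecord] = []
    grid = mask.grid
    border_labels = set()
    if grid.size:
        for edge in (grid[0], grid[-1], grid[:, 0], grid[:, -1]):
            border_labels.update(np.unique(edge[edge > 0]).tolist())
    for label in mask.labels():
        m = raster_metrics(mask, int(label))
        if m.area < min_area_um2:
            continue
        records.append(
            IsletRecord(
                islet_id=int(label),
                metrics=m,
                touches_border=int(label) in border_labels,
                is_cluster=m.area > cluster_threshold_um2,
            )
        )
    return records


def segment_channel(
    image: np.ndarray,
    mpp: float,
    threshold_method: str = "otsu",
    fixed_threshold: Optional[float] = None,
    min_area_um2: Optional[float] = None,
) -> LabelMask:
    """Threshold a single-channel image into an islet label mask.

    Pipeline: global threshold (Otsu or fixed) -> fill holes -> drop
    components below ``min_area_um2`` (default 5 pixels) -> 8-connected
    component labelling.  A constant image under Otsu raises
    :class:`NoForegroundError`; with a fixed threshold an empty foreground
    is a legitimate zero-label mask.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("segment_channel expects a single-channel 2-D image")
    if threshold_method == "otsu":
        if np.ptp(img) == 0:
            raise NoForegroundError("constant image: Otsu threshold undefined")
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise DomainError("fixed threshold_method requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise DomainError(f"unknown threshold_method {threshold_method!r}")
    binary = ndi.binary_fill_holes(img > thr)
    if min_area_um2 is None:
        min_area_um2 = 5 * mpp**2
    min_px = max(1, int(np.ceil(min_area_um2 / mpp**2)))
    labels = skmeasure.label(binary, connectivity=2)
    if min_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        keep = counts >= min_px
        keep[0] = False
        # drop undersized components, then relabel 1..n contiguously
        remap = np.zeros(counts.size, dtype=np.int32)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
    return LabelMask(grid=labels.astype(np.int32), mpp=mpp)


def parenchyma_area(tissue_mask: np.ndarray, mpp: float) -> float:
    """Parenchyma cross-sectional area in cm² from a binary tissue mask.

    ``foreground pixels * mpp**2 / 1e8``, exactly.  An empty mask raises
    :class:`ZeroAreaError` because every downstream density would be
    undefined.
    """
    if not (np.isfinite(mpp) and mpp > 0):
        raise DomainError(f"mpp must be finite and positive, got {mpp!r}")
    n_fg = int(np.count_nonzero(np.asarray(tissue_mask)))
    if n_fg == 0:
        raise ZeroAreaError("tissue mask has no foreground pixels")
    return n_fg * mpp**2 / UM2_PER_CM2


def islets_to_frame(specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Per-islet long table in the fixed CSV interchange schema."""
    rows = []
    for s in specimens:
        for r in s.islets:
            rows.append(
                (
                    s.specimen_id,
                    r.islet_id,
                    r.metrics.area,
                    r.metrics.perimeter,
                    r.metrics.max_feret,
                    r.metrics.circularity,
                    r.touches_border,
                    r.is_cluster,
                )
            )
    return pd.DataFrame(rows, columns=ISLET_CSV_COLUMNS)


def frame_to_islets(
    islets: pd.DataFrame, specimens: pd.DataFrame
) -> list[SpecimenRecord]:
    """Rebuild specimen records from the per-islet and per-specimen tables.

    ``specimens`` needs columns ``specimen_id``, ``group`` and
    ``parenchyma_area_cm2``; ``islets`` follows :data:`ISLET_CSV_COLUMNS`.
    """
    out = []
    grouped = dict(tuple(islets.groupby("specimen_id", sort=False)))
    for row in specimens.itertuples(index=False):
        sub = grouped.get(row.specimen_id)
        recs = []
        if sub is not None:
            for r in sub.itertuples(index=False):
                recs.append(
                    IsletRecord(
                        islet_id=int(r.islet_id),
                        metrics=ShapeMetrics(
                            area=float(r.area_um2),
                            perimeter=float(r.perimeter_um),
                            max_feret=float(r.max_feret_um),
                            circularity=float(r.circularity),
                        ),
                        touches_border=bool(r.touches_border),
                        is_cluster=bool(r.is_cluster),
                    )
                )
        out.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                group=str(row.group),
                parenchyma_area_cm2=float(row.parenchyma_area_cm2),
                islets=recs,
                mpp=float(row.mpp) if hasattr(row, "mpp") and pd.notna(row.mpp) else None,
            )
        )
    return out
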