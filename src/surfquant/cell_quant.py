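"""Per-cell fluorescence quantification from labeled images.

Turns a two-channel field of view (transfection-marker "FP" channel and
surface-stain antibody "Ab" channel) plus an integer label mask into
background-corrected per-cell mean intensities.  Segmentation is upstream:
masks are consumed, never produced.

The background of each individual image is estimated from non-cell pixels
(mask label 0) and subtracted before cell-wise averaging, so per-cell values
can be negative.  Cells containing any saturated pixel in either channel are
flagged and excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FieldOfView",
    "CELL_TABLE_COLUMNS",
    "estimate_background",
    "per_cell_means",
    "flag_saturated",
    "quantify_field",
]

#: Schema of the per-cell table ("cell table") that flows through the pipeline.
CELL_TABLE_COLUMNS = [
    "sample_id",
    "replicate_id",
    "field_id",
    "cell_id",
    "fp_cell",
    "ab_cell",
    "saturated",
]


def _default_saturation(image: np.ndarray) -> float:
    """Saturation level implied by the sample format: the dtype maximum for
    integer images, +inf for floats (no representable ceiling)."""
    if np.issubdtype(image.dtype, np.integer):
        return float(np.iinfo(image.dtype).max)
    return np.inf


@dataclass
class FieldOfView:
    """One microscope field: two fluorescence channels plus a label mask.

    Parameters
    ----------
    field_id:
        Identifier of the field of view.
    fp_image, ab_image:
        2-D intensity grids (arbitrary fluorescence units), same shape as
        ``mask``.  Row-major (row, column) indexing, 0-based.
    mask:
        2-D integer label grid; 0 is background, ``k > 0`` is cell ``k``.
    fp_saturation, ab_saturation:
        Intensity at or above which a pixel counts as saturated, per channel.
        Defaults to the maximum representable value of the image dtype.
    """

    field_id: str
    fp_image: np.ndarray
    ab_image: np.ndarray
    mask: np.ndarray
    fp_saturation: float | None = None
    ab_saturation: float | None = None

    def __post_init__(self) -> None:
        self.fp_image = np.asarray(self.fp_image)
        self.ab_image = np.asarray(self.ab_image)
        self.mask = np.asarray(self.mask)
        if not (self.fp_image.shape == self.ab_image.shape == self.mask.shape):
            raise ValueError(
                f"fp_image {self.fp_image.shape}, ab_image {self.ab_image.shape} "
                f"and mask {self.mask.shape} must share one shape"
            )
        if self.fp_image.ndim != 2:
            raise ValueError("images must be 2-D")
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must be an integer label image")
        if self.mask.min() < 0:
            raise ValueError("mask labels must be non-negative")
        if self.fp_saturation is None:
            self.fp_saturation = _default_saturation(self.fp_image)
        if self.ab_saturation is None:
            self.ab_saturation = _default_saturation(self.ab_image)
        for name, sat in (("fp_saturation", self.fp_saturation),
                          ("ab_saturation", self.ab_saturation)):
            if sat <= 0:
                raise ValueError(f"{name} must be positive, got {sat}")

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted distinct nonzero labels present in the mask."""
        labels = np.unique(self.mask)
        return labels[labels > 0]


def estimate_background(
    image: np.ndarray, mask: np.ndarray, stat: str = "median"
) -> float:
    """Background level of one image: the median (default) or mean intensity
    of all non-cell (label 0) pixels.

    Computed per individual image — per field of view, per channel — never
    pooled across fields.

    Raises
    ------
    ValueError
        If the mask contains no background pixels (unusable mask) or ``stat``
        is not ``"median"`` or ``"mean"``.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share one shape")
    bg = image[mask == 0]
    if bg.size == 0:
        raise ValueError(
            "mask has no background (label 0) pixels; cannot estimate background"
        )
    if stat == "median":
        return float(np.median(bg))
    if stat == "mean":
        return float(np.mean(bg))
    raise ValueError(f"unknown background statistic {stat!r}; use 'median' or 'mean'")


def per_cell_means(
    image: np.ndarray, mask: np.ndarray, background: float
) -> dict[int, float]:
    """Mean background-subtracted intensity per labeled cell.

    For each label ``k > 0`` returns ``mean(image[mask == k]) - background``
    (subtracting the scalar background commutes with the mean).  An empty mask
    yields an empty mapping.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    means = ndimage.mean(image, labels=mask, index=labels)
    return {int(k): float(m - background) for k, m in zip(labels, means)}


def flag_saturated(
    image: np.ndarray, mask: np.ndarray, saturation_value: float
) -> set[int]:
    """Cells containing at least one pixel at or above ``saturation_value``."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    hit = np.unique(mask[image >= saturation_value])
    return {int(k) for k in hit if k > 0}


def quantify_field(
    fov: FieldOfView,
    sample_id: str,
    replicate_id: str,
    background_stat: str = "median",
) -> pd.DataFrame:
    """Quantify one field of view into a per-cell table.

    Runs background estimation, per-cell averaging and saturation flagging
    independently on the FP and Ab channels; a cell saturated in either
    channel is flagged.  Returns one row per mask label with the
    :data:`CELL_TABLE_COLUMNS` schema (empty table for an empty mask).
    """
    records: dict[str, list] = {c: [] for c in CELL_TABLE_COLUMNS}
    fp_bg = estimate_background(fov.fp_image, fov.mask, stat=background_stat)
    ab_bg = estimate_background(fov.ab_image, fov.mask, stat=background_stat)
    fp_means = per_cell_means(fov.fp_image, fov.mask, fp_bg)
    ab_means = per_cell_means(fov.ab_image, fov.mask, ab_bg)
    saturated = flag_saturated(fov.fp_image, fov.mask, fov.fp_saturation)
    saturated |= flag_saturated(fov.ab_image, fov.mask, fov.ab_saturation)
    for cell_id in sorted(fp_means):
        records["sample_id"].append(sample_id)
        records["replicate_id"].append(replicate_id)
        records["field_id"].append(fov.field_id)
        records["cell_id"].append(cell_id)
        records["fp_cell"].append(fp_means[cell_id])
        records["ab_cell"].append(ab_means[cell_id])
        records["saturated"].append(cell_id in saturated)
    table = pd.DataFrame(records)
    return table.astype({"cell_id": np.int64, "saturated": bool,
                         "fp_cell": np.float64, "ab_cell": np.float64})
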