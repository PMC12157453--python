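"""Synthetic data with the statistical structure the analyses assume.

Generates per-cell tables, control samples, toy image fields and toy
alignments with known ground truth, so every other module can be exercised
and scored without external data.

The cell-table model mirrors transient transfection of a tagged membrane
protein:

* a fraction of cells is transfected; their transfection-marker intensity
  ``fp_cell`` is lognormal (broad expression range), while untransfected
  cells show only background noise around zero;
* among transfected cells, a ``stained_fraction`` carries surface signal
  following a power-law dose-response ``ab = a * fp**k`` with multiplicative
  lognormal noise — the minimal model consistent with approximately
  power-law scaling on log-log axes, with the exponent ``k`` the single
  recoverable parameter;
* the remaining transfected cells (and all untransfected cells) show only
  additive background noise around zero in the antibody channel, emulating
  the transfected-but-unstained subpopulation.

All generators are deterministic under a fixed seed and return ground-truth
labels alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cell_quant import FieldOfView

__all__ = [
    "SyntheticConfig",
    "simulate_cell_table",
    "simulate_controls",
    "simulate_field",
    "simulate_alignment",
    "make_demo_dataset",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic per-cell and image generators.

    Defaults describe a well-trafficking construct in a transient
    transfection: ~40% transfected cells, lognormal expression spanning
    roughly three decades, a sub-linear power-law dose-response (k = 0.8)
    with 30% multiplicative noise, and 70% of transfected cells carrying
    any surface stain.
    """

    seed: int = 0
    n_cells: int = 10_000
    transfected_fraction: float = 0.4
    fp_meanlog: float = math.log(500.0)  # lognormal location of expression
    fp_sdlog: float = 1.0  # lognormal scale (decades of spread)
    dose_exponent: float = 0.8  # k in ab = a * fp**k
    dose_amplitude: float = 1.0  # a in ab = a * fp**k
    noise_sigma: float = 0.3  # multiplicative lognormal noise on ab
    stained_fraction: float = 0.7  # transfected cells with any surface signal
    fp_background_sigma: float = 5.0  # additive noise on untransfected fp
    ab_background_sigma: float = 5.0  # additive noise on unstained ab
    # image-field options
    field_shape: tuple[int, int] = (256, 256)
    cells_per_field: int = 25
    cell_radius: tuple[int, int] = (5, 11)
    background_level: float = 100.0
    saturation_value: float = 65535.0
    n_saturated_cells: int = 0

    def __post_init__(self) -> None:
        for name in ("transfected_fraction", "stained_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("noise_sigma", "fp_background_sigma", "ab_background_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dose_amplitude <= 0:
            raise ValueError("dose_amplitude must be positive")
        if self.saturation_value <= 0:
            raise ValueError("saturation_value must be positive")
        if self.n_saturated_cells > self.cells_per_field:
            raise ValueError("n_saturated_cells cannot exceed cells_per_field")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Independent generator per (config seed, stream)."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def simulate_cell_table(
    config: SyntheticConfig,
    sample_id: str = "sample",
    replicate_id: str = "r1",
    stream: int = 0,
) -> pd.DataFrame:
    """One sample-replicate per-cell table with ground-truth annotations.

    Returns the standard cell-table columns plus boolean ground-truth
    columns ``true_transfected`` and ``true_stained`` (downstream consumers
    ignore the extras).
    """
    rng = _rng(config, stream)
    n = config.n_cells
    transfected = rng.random(n) < config.transfected_fraction
    stained = transfected & (rng.random(n) < config.stained_fraction)

    fp = rng.normal(0.0, config.fp_background_sigma, size=n)
    fp[transfected] = rng.lognormal(
        config.fp_meanlog, config.fp_sdlog, size=int(transfected.sum())
    )
    ab = rng.normal(0.0, config.ab_background_sigma, size=n)
    n_stained = int(stained.sum())
    if n_stained:
        noise = np.exp(config.noise_sigma * rng.standard_normal(n_stained))
        ab[stained] = (
            config.dose_amplitude * fp[stained] ** config.dose_exponent * noise
        )
    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "replicate_id": replicate_id,
            "field_id": "synthetic",
            "cell_id": np.arange(1, n + 1),
            "fp_cell": fp,
            "ab_cell": ab,
            "saturated": False,
            "true_transfected": transfected,
            "true_stained": stained,
        }
    )
    return table


def simulate_controls(
    config: SyntheticConfig,
    replicate_id: str = "r1",
    stream: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mock-transfected and untagged-construct control tables.

    Mock cells look untransfected in both channels (background noise only);
    untagged cells express like transfected cells in the marker channel but
    carry no epitope, so their antibody channel is background-like.  Pooled
    across replicates, these define the transfection and surface-stain
    thresholds.
    """
    mock = simulate_cell_table(
        replace(config, transfected_fraction=0.0),
        sample_id="mock",
        replicate_id=replicate_id,
        stream=stream,
    )
    untagged = simulate_cell_table(
        replace(config, stained_fraction=0.0),
        sample_id="untagged",
        replicate_id=replicate_id,
        stream=stream + 1000,
    )
    return mock, untagged


def simulate_field(
    config: SyntheticConfig,
    field_id: str = "f0",
    stream: int = 2,
    max_tries: int = 10_000,
) -> tuple[FieldOfView, pd.DataFrame]:
    """A two-channel image field of non-overlapping constant-intensity disks.

    Each cell is a disk of constant intensity per channel (FP amplitude
    lognormal; Ab following the dose-response) on a uniform additive
    background.  Optionally the first ``n_saturated_cells`` cells get one
    pixel planted at the saturation value in the FP channel.

    Returns the field plus a ground-truth table with columns ``cell_id``,
    ``fp_true``, ``ab_true`` (true background-subtracted means) and
    ``saturated_true``.

    Raises
    ------
    RuntimeError
        If non-overlapping placement fails after ``max_tries`` attempts.
    """
    rng = _rng(config, stream)
    h, w = config.field_shape
    r_lo, r_hi = config.cell_radius
    centers: list[tuple[int, int, int]] = []
    tries = 0
    while len(centers) < config.cells_per_field:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {config.cells_per_field} non-overlapping cells "
                f"in a {h}x{w} field after {max_tries} tries"
            )
        tries += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        cy = int(rng.integers(r + 1, h - r - 1))
        cx = int(rng.integers(r + 1, w - r - 1))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 1) ** 2 for y, x, rr in centers):
            centers.append((cy, cx, r))

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int32)
    fp_image = np.full((h, w), config.background_level, dtype=np.float64)
    ab_image = np.full((h, w), config.background_level, dtype=np.float64)
    truth_rows = []
    n_cells = len(centers)
    fp_amp = rng.lognormal(config.fp_meanlog, config.fp_sdlog, size=n_cells)
    for k, (cy, cx, r) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        mask[disk] = k
        fp_val = float(fp_amp[k - 1])
        ab_val = float(config.dose_amplitude * fp_val**config.dose_exponent)
        fp_image[disk] = config.background_level + fp_val
        ab_image[disk] = config.background_level + ab_val
        saturate = k <= config.n_saturated_cells
        if saturate:
            fp_image[cy, cx] = config.saturation_value
        truth_rows.append(
            {
                "cell_id": k,
                "fp_true": fp_val,
                "ab_true": ab_val,
                "saturated_true": saturate,
            }
        )
    fov = FieldOfView(
        field_id=field_id,
        fp_image=fp_image,
        ab_image=ab_image,
        mask=mask,
        fp_saturation=config.saturation_value,
        ab_saturation=config.saturation_value,
    )
    return fov, pd.DataFrame(truth_rows)


def simulate_alignment(
    n_a: int = 12,
    n_b: int = 8,
    column_classes: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str], list[str]]:
    """Toy protein alignment with planted per-column conservation classes.

    Classes: ``conserved_same`` (one residue everywhere),
    ``conserved_different`` (one residue per group, differing between
    groups), ``one_conserved`` (conserved in group a, variable in group b)
    and ``both_variable`` (uniform random in both).

    Returns ``(records, group_map, classes)`` where records are
    ``(id, sequence)`` pairs for ``n_a`` "trafficking" and ``n_b``
    "non_trafficking" sequences.
    """
    if column_classes is None:
        column_classes = (
            ["conserved_same"] * 5
            + ["conserved_different"] * 5
            + ["one_conserved"] * 5
            + ["both_variable"] * 5
        )
    valid = {"conserved_same", "conserved_different", "one_conserved", "both_variable"}
    bad = set(column_classes) - valid
    if bad:
        raise ValueError(f"unknown column classes: {sorted(bad)}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    n_cols = len(column_classes)
    cols_a = np.empty((n_cols, n_a), dtype="<U1")
    cols_b = np.empty((n_cols, n_b), dtype="<U1")
    aa = np.array(list(_AA))
    for i, cls in enumerate(column_classes):
        if cls == "conserved_same":
            res = rng.choice(aa)
            cols_a[i], cols_b[i] = res, res
        elif cls == "conserved_different":
            ra, rb = rng.choice(aa, size=2, replace=False)
            cols_a[i], cols_b[i] = ra, rb
        elif cls == "one_conserved":
            cols_a[i] = rng.choice(aa)
            cols_b[i] = rng.choice(aa, size=n_b)
        else:  # both_variable
            cols_a[i] = rng.choice(aa, size=n_a)
            cols_b[i] = rng.choice(aa, size=n_b)
    records = []
    group_map = {}
    for j in range(n_a):
        rid = f"traffic_{j + 1}"
        records.append((rid, "".join(cols_a[:, j])))
        group_map[rid] = "trafficking"
    for j in range(n_b):
        rid = f"nontraffic_{j + 1}"
        records.append((rid, "".join(cols_b[:, j])))
        group_map[rid] = "non_trafficking"
    return records, group_map, list(column_classes)


def make_demo_dataset(
    config: SyntheticConfig,
    n_replicates: int = 3,
) -> dict[str, pd.DataFrame | list]:
    """A complete small study: a well-trafficking sample, a non-trafficking
    sample, both controls (per replicate), plus a toy alignment.

    Returns a dict with keys ``cells`` (one pooled cell table),
    ``alignment`` (records), ``group_map`` and ``column_classes``.
    """
    tables = []
    for rep in range(1, n_replicates + 1):
        rid = f"r{rep}"
        base = rep * 10
        tables.append(
            simulate_cell_table(config, "surface_high", rid, stream=base)
        )
        null_cfg = replace(config, stained_fraction=0.0)
        tables.append(
            simulate_cell_table(null_cfg, "surface_null", rid, stream=base + 1)
        )
        mock, untagged = simulate_controls(config, rid, stream=base + 2)
        tables.extend([mock, untagged])
    cells = pd.concat(tables, ignore_index=True)
    records, group_map, classes = simulate_alignment(seed=config.seed)
    return {
        "cells": cells,
        "alignment": records,
        "group_map": group_map,
        "column_classes": classes,
    }
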