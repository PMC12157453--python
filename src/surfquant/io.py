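"""File formats and run configuration.

Tables are CSV with a ``#``-prefixed provenance header (tool version and
configuration hash); images and masks are single-channel TIFF; alignments
are aligned FASTA; flow events are FCS 3.0/3.1; run configuration is YAML
or TOML validated against :class:`RunConfig` (unknown keys rejected).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from ._fcs import read_fcs, write_fcs
from .cell_quant import FieldOfView

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_table",
    "read_table",
    "load_field",
    "write_field",
    "read_alignment",
    "write_alignment",
    "read_group_map",
    "read_fcs_events",
    "read_fcs",
    "write_fcs",
]


class RunConfig(BaseModel):
    """Validated analysis configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    quantile: float = Field(default=0.995, gt=0.0, lt=1.0)
    n_bins: int = Field(default=20, ge=2)
    bin_mode: str = "log_spaced"  # or "equal_count"
    background_stat: str = "median"  # or "mean"
    fp_saturation: float | None = None
    ab_saturation: float | None = None
    positive_control: str | None = None
    mock_samples: list[str] = Field(default_factory=lambda: ["mock"])
    untagged_samples: list[str] = Field(default_factory=lambda: ["untagged"])
    # flow path: explicit FCS channel names, never guessed
    fp_channel: str | None = None
    ab_channel: str | None = None
    # logicle display parameters (None = estimated from the data)
    logicle_m: float = 4.5
    logicle_a: float = 0.0
    logicle_t: float | None = None
    logicle_w: float | None = None
    # conservation
    kl_direction: str = "b_vs_a"
    pseudocount: float | None = None
    seed: int = 0


def load_run_config(path) -> RunConfig:
    """Load a YAML or TOML run configuration."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig | None) -> list[str]:
    lines = [f"# surfquant {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    return lines


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a tidy CSV with a provenance comment header.

    Floating-point formatting is fixed (repr-roundtrip, 17 significant
    digits) so identical inputs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped;
    floats parsed round-trip exactly)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def load_field(
    fp_path,
    ab_path,
    mask_path,
    field_id: str | None = None,
    fp_saturation: float | None = None,
    ab_saturation: float | None = None,
) -> FieldOfView:
    """Load a two-channel field of view from single-channel TIFF files."""
    fp = tifffile.imread(fp_path)
    ab = tifffile.imread(ab_path)
    mask = np.asarray(tifffile.imread(mask_path))
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"mask TIFF {mask_path} must hold integer labels")
    return FieldOfView(
        field_id=field_id or Path(fp_path).stem,
        fp_image=fp,
        ab_image=ab,
        mask=mask,
        fp_saturation=fp_saturation,
        ab_saturation=ab_saturation,
    )


def write_field(fov: FieldOfView, directory, prefix: str | None = None) -> dict[str, Path]:
    """Write a field of view as three TIFFs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or fov.field_id
    paths = {
        "fp": directory / f"{prefix}_fp.tif",
        "ab": directory / f"{prefix}_ab.tif",
        "mask": directory / f"{prefix}_mask.tif",
    }
    tifffile.imwrite(paths["fp"], np.asarray(fov.fp_image, dtype=np.float32))
    tifffile.imwrite(paths["ab"], np.asarray(fov.ab_image, dtype=np.float32))
    tifffile.imwrite(paths["mask"], np.asarray(fov.mask, dtype=np.int32))
    return paths


def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (id, sequence) pairs."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise ValueError(f"{path} is not aligned: lengths {sorted(lengths)}")
    return records


def write_alignment(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_group_map(path) -> dict[str, str]:
    """Read a two-column CSV (sequence_id, group) into a mapping."""
    df = pd.read_csv(path, comment="#")
    cols = [c.lower() for c in df.columns]
    if "sequence_id" in cols and "group" in cols:
        df.columns = cols
        return dict(zip(df["sequence_id"].astype(str), df["group"].astype(str)))
    if df.shape[1] == 2:
        return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    raise ValueError(f"{path}: expected columns sequence_id,group")


def read_fcs_events(
    path,
    fp_channel: str,
    ab_channel: str,
    sample_id: str,
    replicate_id: str,
) -> pd.DataFrame:
    """Read an FCS file into the standard per-cell table.

    Channel names must be given explicitly (no guessing).  Flow intensities
    are used as-is — no background subtraction analogous to images — and
    events are never saturation-flagged (gate upstream if needed).
    """
    text, events = read_fcs(path)
    for ch in (fp_channel, ab_channel):
        if ch not in events.columns:
            raise ValueError(
                f"channel {ch!r} not in {path} (have: {list(events.columns)})"
            )
    n = len(events)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "replicate_id": replicate_id,
            "field_id": Path(path).stem,
            "cell_id": np.arange(1, n + 1),
            "fp_cell": events[fp_channel].to_numpy(dtype=np.float64),
            "ab_cell": events[ab_channel].to_numpy(dtype=np.float64),
            "saturated": False,
        }
    )
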