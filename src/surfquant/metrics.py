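"""Surface-delivery metrics from per-cell fluorescence tables.

Three per-sample metrics summarize how well a tagged membrane protein
reaches the cell surface:

``f+``
    The fraction of transfected cells whose surface-stain intensity
    (``ab_cell``) lies strictly above a surface-stain threshold derived from
    untagged-construct control cells.
``Ab-bar`` (``ab_mean``)
    The mean ``ab_cell`` over all transfected cells — proportional to the
    average surface concentration; optionally normalized to a positive
    control reference.
``Esurface`` (``e_surface``)
    The slope of an ordinary least-squares line through
    ``(log FP_bin, log Ab_bin)``, where cells are binned by expression level
    (``fp_cell``) and per-bin means are taken.  A dimensionless
    surface-delivery efficiency that normalizes for expression level.

Transfected cells are those with ``fp_cell`` strictly above a transfection
threshold, the 0.995 quantile of pooled mock-transfected control cells; by
construction the chance that a designated transfected cell is actually
untransfected is below 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .logicle import LogicleTransform, estimate_w, logicle  # re-exported

__all__ = [
    "Thresholds",
    "BinnedDose",
    "SampleMetrics",
    "compute_threshold",
    "thresholds_from_controls",
    "flag_transfected",
    "flag_stained",
    "fraction_stained",
    "mean_surface_signal",
    "normalize_ab",
    "define_bins",
    "assign_bins",
    "bin_sample",
    "fit_esurface",
    "sample_metrics",
    "compute_sample_metrics",
    "logicle_histogram",
    "LogicleTransform",
    "logicle",
    "estimate_w",
]

DEFAULT_QUANTILE = 0.995
DEFAULT_N_BINS = 20


@dataclass(frozen=True)
class Thresholds:
    """Transfection threshold on ``fp_cell`` and surface-stain threshold on
    ``ab_cell``, each the ``quantile`` quantile of pooled control cells
    across all biological replicates."""

    t_fp: float
    t_ab: float
    quantile: float = DEFAULT_QUANTILE
    n_mock_cells: int = 0
    n_untagged_cells: int = 0


@dataclass
class BinnedDose:
    """Shared expression-level bin edges plus per-sample per-bin means.

    ``edges`` are shared across all samples; bins are half-open
    ``[e_i, e_{i+1})`` with the last bin closed.  ``fp_bin``/``ab_bin`` map
    ``(sample_id, replicate_id)`` to per-bin mean ``fp_cell``/``ab_cell``
    (NaN for empty bins), ``n_per_bin`` to cell counts.
    """

    edges: np.ndarray
    mode: str
    fp_bin: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    ab_bin: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_per_bin: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(sample, replicate, bin) table."""
        rows = []
        for key in self.fp_bin:
            sample_id, replicate_id = key
            for i in range(self.n_bins):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "replicate_id": replicate_id,
                        "bin": i,
                        "edge_lo": self.edges[i],
                        "edge_hi": self.edges[i + 1],
                        "fp_bin": self.fp_bin[key][i],
                        "ab_bin": self.ab_bin[key][i],
                        "n": self.n_per_bin[key][i],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SampleMetrics:
    """All surface-delivery metrics for one (sample, replicate)."""

    sample_id: str
    replicate_id: str
    f_plus: float
    ab_mean: float
    ab_mean_norm: float
    e_surface: float
    fit_intercept: float
    fit_stderr: float
    n_transfected: int
    n_bins_used: int


def compute_threshold(control_values, quantile: float = DEFAULT_QUANTILE) -> float:
    """Empirical quantile of pooled control values.

    Linear interpolation between order statistics (``numpy.quantile`` method
    ``"linear"``).  With this convention the fraction of control values
    strictly above the returned threshold is at most ``1 - quantile`` for any
    control pool larger than about ``1/(1 - quantile)`` cells; a warning is
    emitted below 100 values.

    Raises
    ------
    ValueError
        If the control set is empty or ``quantile`` is outside ``(0, 1)``.
    """
    values = np.asarray(control_values, dtype=np.float64)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot compute a threshold from an empty control set")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    if values.size < 100:
        warnings.warn(
            f"only {values.size} control values; quantile threshold will be "
            "noisy (>= 100 recommended)",
            stacklevel=2,
        )
    return float(np.quantile(values, quantile, method="linear"))


def thresholds_from_controls(
    mock_fp, untagged_ab, quantile: float = DEFAULT_QUANTILE
) -> Thresholds:
    """Derive both thresholds from pooled control cells.

    ``mock_fp``: ``fp_cell`` of mock-transfected cells pooled across
    replicates.  ``untagged_ab``: ``ab_cell`` of cells expressing an untagged
    construct, pooled likewise.
    """
    mock_fp = np.asarray(mock_fp, dtype=np.float64)
    untagged_ab = np.asarray(untagged_ab, dtype=np.float64)
    return Thresholds(
        t_fp=compute_threshold(mock_fp, quantile),
        t_ab=compute_threshold(untagged_ab, quantile),
        quantile=quantile,
        n_mock_cells=int(mock_fp.size),
        n_untagged_cells=int(untagged_ab.size),
    )


def flag_transfected(table: pd.DataFrame, t_fp: float) -> pd.DataFrame:
    """Set the ``transfected`` flag: ``fp_cell`` strictly above ``t_fp``.

    Saturated cells are never flagged (they are excluded from everything).
    Returns a copy.
    """
    table = table.copy()
    saturated = (
        table["saturated"].to_numpy(dtype=bool)
        if "saturated" in table
        else np.zeros(len(table), dtype=bool)
    )
    table["transfected"] = (table["fp_cell"].to_numpy() > t_fp) & ~saturated
    return table


def flag_stained(table: pd.DataFrame, t_ab: float) -> pd.DataFrame:
    """Set the ``stained`` flag: ``ab_cell`` strictly above ``t_ab``."""
    table = table.copy()
    table["stained"] = table["ab_cell"].to_numpy() > t_ab
    return table


def _transfected(table: pd.DataFrame) -> pd.DataFrame:
    if "transfected" not in table:
        raise ValueError("table lacks a 'transfected' flag; run flag_transfected first")
    return table[table["transfected"]]


def fraction_stained(table: pd.DataFrame, t_ab: float) -> float:
    """``f+``: fraction of transfected cells with ``ab_cell`` strictly above
    the surface-stain threshold.  NaN (undefined, not 0) when the table holds
    no transfected cells."""
    cells = _transfected(table)
    if len(cells) == 0:
        return float("nan")
    return float((cells["ab_cell"].to_numpy() > t_ab).mean())


def mean_surface_signal(table: pd.DataFrame) -> float:
    """``Ab-bar``: plain mean of ``ab_cell`` over all transfected cells,
    negative values included.  NaN when no transfected cells."""
    cells = _transfected(table)
    if len(cells) == 0:
        return float("nan")
    return float(cells["ab_cell"].mean())


def normalize_ab(value: float, reference: float) -> float:
    """Express a surface signal relative to a positive-control reference."""
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return value / reference


def define_bins(pooled_fp, n_bins: int = DEFAULT_N_BINS, mode: str = "log_spaced") -> np.ndarray:
    """Shared expression-level bin edges over pooled ``fp_cell`` values.

    ``pooled_fp`` must pool ALL transfected cells across samples and
    replicates so every sample shares one set of edges.  Non-positive values
    cannot enter either mode (log spacing and the downstream log-log fit both
    need positives) and are dropped here; callers keep those cells for ``f+``
    and ``Ab-bar``.

    Modes
    -----
    ``log_spaced``
        ``n_bins`` geometrically spaced bins between the pooled minimum and
        maximum.
    ``equal_count``
        Edges at quantiles of the pooled values so each bin holds an equal
        share of pooled cells (approximately log-scaled for lognormal-like
        expression distributions).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    fp = np.asarray(pooled_fp, dtype=np.float64)
    fp = fp[np.isfinite(fp) & (fp > 0)]
    if fp.size < n_bins:
        raise ValueError(
            f"need at least n_bins={n_bins} positive fp values, got {fp.size}"
        )
    lo, hi = float(fp.min()), float(fp.max())
    if lo == hi:
        raise ValueError("cannot bin: all pooled fp values identical")
    if mode == "log_spaced":
        return np.geomspace(lo, hi, n_bins + 1)
    if mode == "equal_count":
        edges = np.quantile(fp, np.linspace(0.0, 1.0, n_bins + 1))
        return np.unique(edges)  # ties can collapse edges; keep strictly increasing
    raise ValueError(f"unknown bin mode {mode!r}; use 'log_spaced' or 'equal_count'")


def assign_bins(values, edges: np.ndarray) -> np.ndarray:
    """Bin index per value: half-open ``[e_i, e_{i+1})``, last bin closed at
    the top; -1 for values outside ``[edges[0], edges[-1]]``."""
    values = np.asarray(values, dtype=np.float64)
    idx = np.digitize(values, edges) - 1
    idx[values == edges[-1]] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def bin_sample(table: pd.DataFrame, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean ``fp_cell`` / ``ab_cell`` and counts for one sample's
    transfected cells (``fp_cell > 0`` only).  Empty bins yield NaN means."""
    cells = _transfected(table)
    fp = cells["fp_cell"].to_numpy(dtype=np.float64)
    ab = cells["ab_cell"].to_numpy(dtype=np.float64)
    keep = fp > 0
    fp, ab = fp[keep], ab[keep]
    idx = assign_bins(fp, edges)
    n_bins = len(edges) - 1
    fp_bin = np.full(n_bins, np.nan)
    ab_bin = np.full(n_bins, np.nan)
    n_per_bin = np.zeros(n_bins, dtype=np.int64)
    for i in range(n_bins):
        sel = idx == i
        n_per_bin[i] = sel.sum()
        if n_per_bin[i]:
            fp_bin[i] = fp[sel].mean()
            ab_bin[i] = ab[sel].mean()
    return fp_bin, ab_bin, n_per_bin


def fit_esurface(fp_bin, ab_bin) -> tuple[float, float, float, int]:
    """``Esurface``: slope of the least-squares line through
    ``(log fp_bin, log ab_bin)``.

    Bins with non-positive ``ab_bin`` (log undefined), non-positive
    ``fp_bin`` or NaN means (empty bins) are excluded.  Natural log is used;
    the slope is invariant to the base and to multiplicative rescaling of
    either channel.  Returns ``(slope, intercept, stderr, n_bins_used)``;
    all-NaN results when fewer than 2 usable bins remain.
    """
    fp_bin = np.asarray(fp_bin, dtype=np.float64)
    ab_bin = np.asarray(ab_bin, dtype=np.float64)
    use = np.isfinite(fp_bin) & np.isfinite(ab_bin) & (fp_bin > 0) & (ab_bin > 0)
    n_used = int(use.sum())
    if n_used < 2:
        return float("nan"), float("nan"), float("nan"), n_used
    res = stats.linregress(np.log(fp_bin[use]), np.log(ab_bin[use]))
    return float(res.slope), float(res.intercept), float(res.stderr), n_used


def sample_metrics(
    table: pd.DataFrame,
    thresholds: Thresholds,
    edges: np.ndarray,
    reference: float | None = None,
) -> SampleMetrics:
    """All metrics for one (sample, replicate) table.

    The table must contain exactly one sample-replicate.  Saturated cells are
    dropped, the transfected/stained flags are (re)computed from
    ``thresholds``, and ``f+``, ``Ab-bar`` (optionally normalized to
    ``reference``) and ``Esurface`` are evaluated on the shared ``edges``.
    """
    ids = table[["sample_id", "replicate_id"]].drop_duplicates()
    if len(ids) != 1:
        raise ValueError("sample_metrics expects a single (sample, replicate) table")
    sample_id, replicate_id = ids.iloc[0]
    if "saturated" in table:
        table = table[~table["saturated"].astype(bool)]
    table = flag_transfected(table, thresholds.t_fp)
    f_plus = fraction_stained(table, thresholds.t_ab)
    ab_mean = mean_surface_signal(table)
    ab_mean_norm = (
        normalize_ab(ab_mean, reference) if reference is not None else float("nan")
    )
    fp_bin, ab_bin, _ = bin_sample(table, edges)
    slope, intercept, stderr, n_used = fit_esurface(fp_bin, ab_bin)
    return SampleMetrics(
        sample_id=str(sample_id),
        replicate_id=str(replicate_id),
        f_plus=f_plus,
        ab_mean=ab_mean,
        ab_mean_norm=ab_mean_norm,
        e_surface=slope,
        fit_intercept=intercept,
        fit_stderr=stderr,
        n_transfected=int(table["transfected"].sum()),
        n_bins_used=n_used,
    )


def compute_sample_metrics(
    cells: pd.DataFrame,
    thresholds: Thresholds,
    n_bins: int = DEFAULT_N_BINS,
    bin_mode: str = "log_spaced",
    reference_sample: str | None = None,
) -> tuple[pd.DataFrame, BinnedDose]:
    """Metrics for every (sample, replicate) in a pooled cell table.

    Bin edges are defined once from ALL transfected cells across samples and
    replicates, then applied to each sample.  When ``reference_sample`` is
    given, ``ab_mean_norm`` is each sample's ``Ab-bar`` divided by the mean
    ``Ab-bar`` of the reference sample across its replicates.

    Returns the tidy metrics table (one row per sample-replicate) and the
    :class:`BinnedDose` with the shared edges and per-sample bin means.
    """
    cells = cells[~cells.get("saturated", pd.Series(False, index=cells.index)).astype(bool)]
    cells = flag_transfected(cells, thresholds.t_fp)
    pooled_fp = cells.loc[cells["transfected"], "fp_cell"].to_numpy()
    edges = define_bins(pooled_fp, n_bins=n_bins, mode=bin_mode)
    binned = BinnedDose(edges=edges, mode=bin_mode)

    rows = []
    for (sample_id, replicate_id), group in cells.groupby(
        ["sample_id", "replicate_id"], sort=True
    ):
        m = sample_metrics(group, thresholds, edges)
        rows.append(m)
        fp_bin, ab_bin, n_per_bin = bin_sample(
            flag_transfected(group, thresholds.t_fp), edges
        )
        key = (str(sample_id), str(replicate_id))
        binned.fp_bin[key] = fp_bin
        binned.ab_bin[key] = ab_bin
        binned.n_per_bin[key] = n_per_bin

    out = pd.DataFrame([vars(m) for m in rows])
    if reference_sample is not None:
        ref = out.loc[out["sample_id"] == reference_sample, "ab_mean"]
        if ref.empty:
            raise ValueError(f"reference sample {reference_sample!r} not found")
        reference = float(ref.mean())
        out["ab_mean_norm"] = [normalize_ab(v, reference) for v in out["ab_mean"]]
    return out, binned


def logicle_histogram(
    values,
    T: float | None = None,
    W: float | None = None,
    M: float = 4.5,
    A: float = 0.0,
    n_bins: int = 64,
) -> pd.DataFrame:
    """Histogram of intensities on a logicle display scale.

    ``T`` defaults to the data maximum, ``W`` to the width estimated from the
    5th percentile of negative values.  Returns a tidy table of display-scale
    bin edges, the corresponding data values, and counts.  Display only.
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if T is None:
        T = float(values.max()) if values.size else 1.0
        T = max(T, 1.0)
    if W is None:
        W = estimate_w(values, T, M)
    tr = LogicleTransform(T=T, W=W, M=M, A=A)
    x = tr.forward(values)
    counts, edges = np.histogram(x, bins=n_bins, range=(min(0.0, float(x.min())), 1.0))
    return pd.DataFrame(
        {
            "scale_lo": edges[:-1],
            "scale_hi": edges[1:],
            "value_lo": tr.inverse(edges[:-1]),
            "value_hi": tr.inverse(edges[1:]),
            "count": counts,
        }
    )
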