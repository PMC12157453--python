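"""Differential-conservation scoring of alignment columns.

Splits a protein multiple sequence alignment into two functional groups
(e.g. surface-trafficking vs non-trafficking isoforms), computes per-column
amino-acid frequency distributions for each group, and scores every column
with the Kullback-Leibler divergence between the two distributions (the
"KLdiv score").

The score is high for positions that are conserved *within* each group but
*differ between* the groups — candidate determinants of the functional
difference — and low for positions that are either variable or conserved
identically in both groups.

Frequencies are computed over the 20 standard amino acids; gap characters
are excluded and the distribution renormalized.  A small pseudocount (by
default ``1/n_group``) keeps both distributions strictly positive, since the
divergence would otherwise be infinite at fully disjoint columns.  Natural
logarithms are used, so scores are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AMINO_ACIDS",
    "GroupedAlignment",
    "ConservationProfile",
    "split_alignment",
    "column_frequencies",
    "kl_divergence",
    "js_divergence",
    "kldiv_profile",
    "map_columns_to_residues",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")


def _to_matrix(records: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Sequence records -> (ids, uppercase character matrix)."""
    ids = [rid for rid, _ in records]
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal aligned lengths: {sorted(lengths)}")
    mat = np.array([list(seq.upper()) for _, seq in records])
    return ids, mat


def _records_from_alignment(alignment) -> list[tuple[str, str]]:
    """Accept a Bio.Align.MultipleSeqAlignment, an iterable of SeqRecords, or
    (id, sequence) pairs."""
    records = []
    for item in alignment:
        if isinstance(item, tuple):
            records.append((str(item[0]), str(item[1])))
        else:  # SeqRecord
            records.append((str(item.id), str(item.seq)))
    if not records:
        raise ValueError("empty alignment")
    return records


@dataclass
class GroupedAlignment:
    """An alignment partitioned into two groups of sequences.

    ``group_a`` conventionally holds the trafficking isoforms and
    ``group_b`` the non-trafficking ones; every sequence belongs to exactly
    one group and all share the aligned length.  ``region`` optionally
    restricts scoring to a 1-based inclusive column interval (e.g. the EC6
    domain).
    """

    ids_a: list[str]
    matrix_a: np.ndarray
    ids_b: list[str]
    matrix_b: np.ndarray
    region: tuple[int, int] | None = None

    @property
    def n_columns(self) -> int:
        return self.matrix_a.shape[1]

    def column_range(self) -> range:
        """0-based column indices to score (whole alignment or the region)."""
        if self.region is None:
            return range(self.n_columns)
        start, end = self.region
        if not (1 <= start <= end <= self.n_columns):
            raise ValueError(
                f"region {self.region} outside alignment columns 1..{self.n_columns}"
            )
        return range(start - 1, end)


@dataclass
class ConservationProfile:
    """Per-column frequency distributions and KLdiv scores."""

    columns: np.ndarray  # 1-based alignment coordinates
    freq_a: np.ndarray  # (n_cols, 20)
    freq_b: np.ndarray  # (n_cols, 20)
    kldiv: np.ndarray
    gap_flagged: np.ndarray  # majority-gap or all-gap columns
    direction: str
    pseudocount_a: float
    pseudocount_b: float
    ref_residues: np.ndarray | None = None
    ref_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"column": self.columns, "kldiv": self.kldiv,
                            "gap_flagged": self.gap_flagged})
        if self.ref_residues is not None:
            out.insert(1, f"residue_{self.ref_id}", self.ref_residues)
        for i, aa in enumerate(AMINO_ACIDS):
            out[f"freq_a_{aa}"] = self.freq_a[:, i]
        for i, aa in enumerate(AMINO_ACIDS):
            out[f"freq_b_{aa}"] = self.freq_b[:, i]
        return out


def split_alignment(
    alignment,
    group_map: dict[str, str],
    group_a: str = "trafficking",
    group_b: str = "non_trafficking",
    region: tuple[int, int] | None = None,
) -> GroupedAlignment:
    """Partition an alignment into two groups according to ``group_map``.

    ``group_map`` maps every sequence id to a group label; ids missing from
    the map, or mapped to an unknown label, raise an error naming them.
    """
    records = _records_from_alignment(alignment)
    ids, mat = _to_matrix(records)
    missing = [rid for rid in ids if rid not in group_map]
    if missing:
        raise ValueError(f"sequence ids missing from group map: {missing}")
    unknown = sorted({group_map[rid] for rid in ids} - {group_a, group_b})
    if unknown:
        raise ValueError(
            f"unknown group labels {unknown}; expected {group_a!r} or {group_b!r}"
        )
    in_a = np.array([group_map[rid] == group_a for rid in ids])
    return GroupedAlignment(
        ids_a=[rid for rid, a in zip(ids, in_a) if a],
        matrix_a=mat[in_a],
        ids_b=[rid for rid, a in zip(ids, in_a) if not a],
        matrix_b=mat[~in_a],
        region=region,
    )


def column_frequencies(
    matrix: np.ndarray, column: int, pseudocount: float | None = None
) -> tuple[np.ndarray, int]:
    """Amino-acid frequency vector for one alignment column of one group.

    Gap characters are excluded and the distribution renormalized over the
    20-letter alphabet; unrecognized characters (X, B, Z, ...) are treated as
    gaps.  ``pseudocount`` (default ``1/n_sequences``) is added to every
    residue count before normalization, so the vector is strictly positive:

        freq_i = (count_i + eps) / (n_ungapped + 20 * eps)

    Returns ``(frequencies, n_ungapped)``; an all-gap column yields the
    uniform distribution with ``n_ungapped == 0`` (callers flag it).
    """
    if not 0 <= column < matrix.shape[1]:
        raise IndexError(f"column {column} outside 0..{matrix.shape[1] - 1}")
    if pseudocount is None:
        pseudocount = 1.0 / matrix.shape[0]
    col = matrix[:, column]
    counts = np.zeros(len(AMINO_ACIDS))
    for ch in col:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    n_ungapped = int(counts.sum())
    freq = (counts + pseudocount) / (n_ungapped + len(AMINO_ACIDS) * pseudocount)
    return freq, n_ungapped


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence ``sum_i p_i ln(p_i / q_i)`` in nats.

    Asymmetric: ``KL(p||q) != KL(q||p)`` in general.  Requires strictly
    positive ``q`` (use pseudocounts); zero iff ``p == q``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(q <= 0) or np.any(p < 0):
        raise ValueError("q must be strictly positive and p non-negative "
                         "(pseudocount smoothing misconfigured?)")
    return float(sps.entropy(p, q))


def js_divergence(p, q) -> float:
    """Symmetrized Jensen-Shannon divergence (nats), for robustness checks."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    m = 0.5 * (p + q)
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def kldiv_profile(
    grouped: GroupedAlignment,
    pseudocount: float | tuple[float, float] | None = None,
    direction: str = "b_vs_a",
    symmetrized: bool = False,
    gap_flag_fraction: float = 0.5,
) -> ConservationProfile:
    """Score every column of a grouped alignment.

    ``direction`` fixes the KL argument order: ``"b_vs_a"`` (default)
    computes ``KL(freq_b || freq_a)`` — the non-trafficking group against
    the trafficking group — and ``"a_vs_b"`` the reverse;
    ``symmetrized=True`` uses the Jensen-Shannon divergence instead.
    ``pseudocount`` is a shared value or a ``(group_a, group_b)`` pair;
    the default ``1/n_group`` per group is scale-aware (its effect on the
    frequencies shrinks as ``1/n_group**2``).  Columns where more than
    ``gap_flag_fraction`` of either group is gapped are scored but flagged;
    all-gap columns get a NaN score.
    """
    if direction not in ("a_vs_b", "b_vs_a"):
        raise ValueError("direction must be 'a_vs_b' or 'b_vs_a'")
    cols = list(grouped.column_range())
    n_a = grouped.matrix_a.shape[0]
    n_b = grouped.matrix_b.shape[0]
    if pseudocount is None:
        eps_a, eps_b = 1.0 / n_a, 1.0 / n_b
    elif np.isscalar(pseudocount):
        eps_a = eps_b = float(pseudocount)
    else:
        eps_a, eps_b = (float(p) for p in pseudocount)
    freq_a = np.empty((len(cols), len(AMINO_ACIDS)))
    freq_b = np.empty_like(freq_a)
    scores = np.empty(len(cols))
    flagged = np.zeros(len(cols), dtype=bool)
    for i, c in enumerate(cols):
        fa, ua = column_frequencies(grouped.matrix_a, c, eps_a)
        fb, ub = column_frequencies(grouped.matrix_b, c, eps_b)
        freq_a[i], freq_b[i] = fa, fb
        if ua == 0 and ub == 0:
            scores[i] = np.nan
            flagged[i] = True
            continue
        flagged[i] = (ua < n_a * (1 - gap_flag_fraction)) or (
            ub < n_b * (1 - gap_flag_fraction)
        )
        if symmetrized:
            scores[i] = js_divergence(fa, fb)
        elif direction == "b_vs_a":
            scores[i] = kl_divergence(fb, fa)
        else:
            scores[i] = kl_divergence(fa, fb)
    return ConservationProfile(
        columns=np.asarray(cols) + 1,
        freq_a=freq_a,
        freq_b=freq_b,
        kldiv=scores,
        gap_flagged=flagged,
        direction="jensen_shannon" if symmetrized else direction,
        pseudocount_a=eps_a,
        pseudocount_b=eps_b,
    )


def map_columns_to_residues(alignment, ref_id: str) -> np.ndarray:
    """Residue numbers of a reference sequence per alignment column.

    Ungapped-position counting, 1-based; columns where the reference is
    gapped get 0.
    """
    records = _records_from_alignment(alignment)
    seqs = dict(records)
    if ref_id not in seqs:
        raise ValueError(f"reference id {ref_id!r} not in alignment")
    seq = seqs[ref_id].upper()
    numbers = np.zeros(len(seq), dtype=np.int64)
    pos = 0
    for i, ch in enumerate(seq):
        if ch not in GAP_CHARS:
            pos += 1
            numbers[i] = pos
    return numbers
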