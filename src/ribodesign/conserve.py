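"""Constraint derivation from a multiple alignment, and candidate ranking.

The design pattern for a reference molecule is assembled from three
layers: positions whose alignment column is conserved above a threshold
keep the reference nucleotide; explicitly overridden positions get the
override IUPAC code (e.g. H = "not G" at a cleavage site); every other
position is constrained to differ from the reference nucleotide via the
3-letter complement codes B/D/H/V.

Candidate ranking filters measure records by GC window and target-
probability bounds, then orders by a named objective and returns a
requested order statistic (smallest, second smallest, ..., or largest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .iofmt import (
    AlignmentBlock,
    IupacPattern,
    NUCLEOTIDES,
    RnaSequence,
    is_gap,
    normalize_residues,
    not_code,
)
from .measures import MeasureRecord, OBJECTIVE_FIELDS

#: Conservation presets used for hammerhead design: the operative 96%
#: threshold, and the 95% variant that would additionally retain the
#: cleavage-site cytidine.
THRESHOLD_STRICT = 0.96
THRESHOLD_RELAXED = 0.95


@dataclass(frozen=True)
class ConservationProfile:
    """Per reference position: nucleotide frequencies among non-gap
    residues of the aligned sequences, plus coverage counts."""

    frequencies: np.ndarray  # shape (n, 4), columns in order A,C,G,U
    coverage: np.ndarray  # non-gap residue count per position

    @property
    def n(self) -> int:
        return self.frequencies.shape[0]

    def top(self, pos: int) -> tuple[str, float]:
        """Majority nucleotide and its frequency at 1-based ``pos``."""
        row = self.frequencies[pos - 1]
        k = int(np.argmax(row))
        return NUCLEOTIDES[k], float(row[k])


def map_columns_to_reference(alignment: AlignmentBlock, ref_id: str) -> dict[int, int]:
    """Bijection column -> reference position over the reference row's
    non-gap columns (both 1-based)."""
    row = alignment.row(ref_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if not is_gap(ch):
            pos += 1
            mapping[col] = pos
    return mapping


def conservation_profile(
    alignment: AlignmentBlock, ref_id: str, include_gaps: bool = False
) -> ConservationProfile:
    """Column nucleotide frequencies mapped onto reference coordinates.

    Frequencies are computed over non-gap residues by default; with
    ``include_gaps`` the denominator is the full sequence count.
    """
    colmap = map_columns_to_reference(alignment, ref_id)
    n = len(colmap)
    counts = np.zeros((n, 4))
    cover = np.zeros(n, dtype=int)
    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    for _, row in alignment.records:
        for col, pos in colmap.items():
            ch = row[col - 1]
            if is_gap(ch):
                continue
            ch = normalize_residues(ch)
            counts[pos - 1, nt_index[ch]] += 1
            cover[pos - 1] += 1
    denom = (
        np.full(n, len(alignment.records), dtype=float)
        if include_gaps
        else np.maximum(cover, 1).astype(float)
    )
    return ConservationProfile(counts / denom[:, None], cover)


def conserved_positions(
    profile: ConservationProfile, threshold: float
) -> dict[int, str]:
    """Positions whose majority nucleotide reaches ``threshold``, with
    that nucleotide."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    out: dict[int, str] = {}
    for pos in range(1, profile.n + 1):
        nt, freq = profile.top(pos)
        if freq >= threshold:
            out[pos] = nt
    return out


def build_design_pattern(
    ref_seq: RnaSequence,
    conserved: Mapping[int, str],
    overrides: Mapping[int, str] | None = None,
) -> IupacPattern:
    """Assemble the per-position IUPAC constraint string.

    Conserved positions keep their nucleotide, overridden positions take
    the override code, and all remaining positions are constrained to be
    distinct from the reference nucleotide.
    """
    overrides = dict(overrides or {})
    n = len(ref_seq)
    for pos in (*conserved, *overrides):
        if not 1 <= pos <= n:
            raise ValueError(f"position {pos} outside 1..{n}")
    clash = set(conserved) & set(overrides)
    if clash:
        raise ValueError(f"override conflicts with conserved position(s) {sorted(clash)}")
    codes = []
    for pos in range(1, n + 1):
        if pos in conserved:
            codes.append(normalize_residues(conserved[pos]))
        elif pos in overrides:
            codes.append(overrides[pos].upper())
        else:
            codes.append(not_code(ref_seq[pos]))
    return IupacPattern("".join(codes))


@dataclass(frozen=True)
class SelectionCriterion:
    """A Table-1-style candidate filter and objective.

    ``objective`` names a MeasureRecord field; ``rank`` is the order
    statistic (1 = smallest, 2 = second smallest, ...), with
    ``maximize=True`` reversing the order.
    """

    objective: str
    rank: int = 1
    maximize: bool = False
    gc_window: tuple[float, float] | None = None
    min_prob: float | None = None
    max_prob: float | None = None

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVE_FIELDS:
            raise ValueError(
                f"objective {self.objective!r} is not a measure field"
            )
        if self.rank < 1:
            raise ValueError("rank is 1-based")


def select_candidates(
    records: Sequence[MeasureRecord], criterion: SelectionCriterion
) -> list[MeasureRecord]:
    """Filter, order, and return candidates from the requested order
    statistic onward (empty when the filter removes everything).

    Ties are broken lexicographically by sequence, so the result is
    invariant under permutation of the input records.
    """
    pool = list(records)
    if criterion.gc_window is not None:
        lo, hi = criterion.gc_window
        pool = [r for r in pool if lo <= r.gc_percent < hi + 1.0]
    if criterion.min_prob is not None:
        pool = [r for r in pool if r.prob_target >= criterion.min_prob]
    if criterion.max_prob is not None:
        pool = [r for r in pool if r.prob_target <= criterion.max_prob]
    pool.sort(key=lambda r: r.sequence)  # stable lexicographic tie-break
    pool.sort(key=lambda r: getattr(r, criterion.objective), reverse=criterion.maximize)
    return pool[criterion.rank - 1 :]
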